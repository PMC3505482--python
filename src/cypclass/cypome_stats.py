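"""Descriptive analytics over clusterings and family assignments.

Cluster/family size distributions (which empirically follow a power law),
CYPome fractions of proteomes, phyletic profiles of families across species,
and conserved-family queries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mcl_core import Clustering

__all__ = [
    "PhyleticProfile",
    "size_histogram",
    "powerlaw_slope",
    "sample_powerlaw_partition",
    "cypome_fraction",
    "build_profile",
    "conserved_families",
]


@dataclass
class PhyleticProfile:
    """Family x species matrix of member counts, with a species -> taxon map."""

    counts: pd.DataFrame  # rows: families, columns: species
    taxon_of_species: dict[str, str]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts in phyletic profile")
        if self.counts.index.duplicated().any() or self.counts.columns.duplicated().any():
            raise ValueError("duplicate family or species labels")

    @property
    def families(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    def by_taxon(self) -> pd.DataFrame:
        """Counts rolled up over species into taxon groups."""
        taxa = pd.Series(self.taxon_of_species)
        return self.counts.T.groupby(taxa).sum().T


def size_histogram(clustering: Clustering) -> dict[int, int]:
    """Cluster-size histogram: size -> number of clusters of that size.

    Satisfies sum(size*count) == n_nodes and sum(count) == n_clusters.
    """
    hist: dict[int, int] = {}
    for s in clustering.sizes():
        hist[s] = hist.get(s, 0) + 1
    return hist


def powerlaw_slope(histogram: Mapping[int, int]) -> tuple[float, float]:
    """Least-squares slope and intercept on (log10 size, log10 count).

    Only sizes with positive counts enter the fit; at least three distinct
    sizes are required. For a power-law size distribution the slope is the
    negative exponent. (Maximum-likelihood exponent estimation is a known
    alternative; the simple log-log fit is the default here.)
    """
    points = [(s, c) for s, c in histogram.items() if c > 0]
    if len(points) < 3:
        raise ValueError("power-law fit requires >= 3 distinct sizes")
    x = np.log10([s for s, _ in points])
    y = np.log10([c for _, c in points])
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def sample_powerlaw_partition(
    n: int, exponent: float, seed: int, max_size: int = 20
) -> dict[int, int]:
    """Draw n cluster sizes from a truncated discrete power law P(s) ~ s^-exponent.

    Returns the size histogram of the sampled partition; used as a
    self-generated truth for exercising the fit. The default support is
    truncated at sizes the sample can populate (for n = 5,000 and exponent
    2.5 the expected count at size 20 is ~2): the simple log-log OLS
    estimator in :func:`powerlaw_slope` is only consistent where per-size
    counts are not Poisson-noise-dominated, and a long tail of count-one
    sizes flattens it.
    """
    rng = np.random.default_rng(seed)
    sizes = np.arange(1, max_size + 1)
    p = sizes ** (-exponent)
    p /= p.sum()
    draws = rng.choice(sizes, size=n, p=p)
    hist: dict[int, int] = {}
    for s in draws:
        hist[int(s)] = hist.get(int(s), 0) + 1
    return hist


def cypome_fraction(n_cyps: int, proteome_size: int) -> float:
    """Percent of a proteome that is CYPs."""
    if proteome_size == 0:
        raise ValueError("proteome_size must be positive")
    if not 0 <= n_cyps <= proteome_size:
        raise ValueError("require 0 <= n_cyps <= proteome_size")
    return 100.0 * n_cyps / proteome_size


def build_profile(
    family_of: Mapping[str, str],
    species_of: Mapping[str, str],
    taxon_of_species: Mapping[str, str] | None = None,
) -> PhyleticProfile:
    """Count family members per species into a phyletic profile.

    Proteins missing from either map are skipped.
    """
    cells: dict[tuple[str, str], int] = {}
    for pid, fam in family_of.items():
        sp = species_of.get(pid)
        if sp is None:
            continue
        cells[(fam, sp)] = cells.get((fam, sp), 0) + 1
    families = sorted({f for f, _ in cells})
    species = sorted({s for _, s in cells})
    mat = pd.DataFrame(0, index=families, columns=species, dtype=int)
    for (f, s), c in cells.items():
        mat.loc[f, s] = c
    taxa = dict(taxon_of_species or {})
    for s in species:
        taxa.setdefault(s, "unknown")
    return PhyleticProfile(counts=mat, taxon_of_species=taxa)


def conserved_families(
    profile: PhyleticProfile, species_set: Iterable[str]
) -> list[str]:
    """Families with at least one member in every listed species, sorted.

    Raises
    ------
    ValueError
        If a listed species is not in the profile.
    """
    wanted = list(dict.fromkeys(species_set))
    unknown = [s for s in wanted if s not in profile.counts.columns]
    if unknown:
        raise ValueError(f"unknown species: {unknown}")
    if not wanted:
        return sorted(profile.families)
    mask = (profile.counts[wanted] >= 1).all(axis=1)
    return sorted(profile.counts.index[mask])


def write_histogram_tsv(histogram: Mapping[int, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("size\tcount\n")
        for s in sorted(histogram):
            fh.write(f"{s}\t{histogram[s]}\n")


def plot_size_distribution(histogram: Mapping[int, int], path) -> None:
    """Log-log scatter of the size distribution with the fitted line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    slope, intercept = powerlaw_slope(histogram)
    sizes = sorted(s for s, c in histogram.items() if c > 0)
    counts = [histogram[s] for s in sizes]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.loglog(sizes, counts, "o", ms=4, label="clusters")
    xs = np.array(sizes, dtype=float)
    ax.loglog(xs, 10**intercept * xs**slope, "-", label=f"slope {slope:.2f}")
    ax.set_xlabel("cluster size")
    ax.set_ylabel("number of clusters")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
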