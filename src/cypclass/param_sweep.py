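"""Grid sweep over (E-value ceiling, coverage floor, inflation).

The sweep rebuilds the similarity graph for every (E-value, coverage) pair,
re-runs MCL for every inflation, and scores each clustering by the fractions
of singlet clusters and mega clusters (> 100 members by default). The
objective minimized is the weighted sum of the two fractions; the best grid
point defines the "optimum plane" combination.

Fractions are over clusters by default; a protein-mass variant (fraction of
proteins sitting in singlet / mega clusters) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import HitRecord
from .mcl_core import Clustering, MclParams, run_mcl
from .simgraph import EdgeFilterParams, build_graph

__all__ = [
    "MEGA_THRESHOLD",
    "SweepMetrics",
    "SweepResult",
    "evaluate_clustering",
    "sweep_grid",
    "select_optimum",
    "paper_grid",
    "adjusted_rand_index",
]

#: Clusters strictly larger than this are "mega" clusters.
MEGA_THRESHOLD = 100


@dataclass(frozen=True)
class SweepMetrics:
    n_clusters: int
    frac_singlet: float
    frac_mega: float
    objective: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_singlet <= 1.0 and 0.0 <= self.frac_mega <= 1.0):
            raise ValueError("fractions must be in [0, 1]")
        if self.n_clusters < 1:
            raise ValueError("metrics require at least one cluster")


@dataclass(frozen=True)
class SweepResult:
    e_max: float
    cov_min: float
    inflation: float
    metrics: SweepMetrics


def evaluate_clustering(
    clustering: Clustering,
    mega_threshold: int = MEGA_THRESHOLD,
    singlet_weight: float = 1.0,
    mega_weight: float = 1.0,
    by_protein: bool = False,
) -> SweepMetrics:
    """Score a clustering by its singlet and mega-cluster fractions.

    ``by_protein=True`` switches the fractions to protein mass (share of
    proteins sitting in singlet / mega clusters) instead of cluster counts.
    """
    sizes = clustering.sizes()
    if not sizes:
        raise ValueError("empty clustering")
    if by_protein:
        total = sum(sizes)
        frac_singlet = sum(s for s in sizes if s == 1) / total
        frac_mega = sum(s for s in sizes if s > mega_threshold) / total
    else:
        n = len(sizes)
        frac_singlet = sum(1 for s in sizes if s == 1) / n
        frac_mega = sum(1 for s in sizes if s > mega_threshold) / n
    return SweepMetrics(
        n_clusters=len(sizes),
        frac_singlet=frac_singlet,
        frac_mega=frac_mega,
        objective=singlet_weight * frac_singlet + mega_weight * frac_mega,
    )


def paper_grid() -> tuple[list[float], list[float], list[float]]:
    """The published sweep grid: E-value 1e-10..1e-100 by decades of ten,
    nine coverages 20..100% by 10, integer inflations (1 is rejected as
    degenerate, leaving 2..5)."""
    e_values = [10.0 ** -(10 * k) for k in range(1, 11)]
    coverages = [float(c) for c in range(20, 101, 10)]
    inflations = [2.0, 3.0, 4.0, 5.0]
    return e_values, coverages, inflations


def sweep_grid(
    hits: Iterable[HitRecord],
    query_lengths: Mapping[str, int],
    e_values: Sequence[float],
    coverages: Sequence[float],
    inflations: Sequence[float],
    mega_threshold: int = MEGA_THRESHOLD,
    mcl_defaults: MclParams | None = None,
    by_protein: bool = False,
) -> list[SweepResult]:
    """Evaluate every grid combination, in lexicographic grid order.

    The similarity graph is rebuilt once per (e_max, cov_min) pair and MCL
    re-run per inflation value.

    Raises
    ------
    ValueError
        If a grid is empty or an inflation value is <= 1 (inflation 1 means
        no clustering and is rejected, naming the value).
    """
    e_values = list(e_values)
    coverages = list(coverages)
    inflations = list(inflations)
    if not (e_values and coverages and inflations):
        raise ValueError("all three grids must be non-empty")
    for inf in inflations:
        if inf <= 1.0:
            raise ValueError(
                f"inflation {inf} rejected: values must exceed 1 (no inflation means "
                "no clustering)"
            )
    hits = list(hits)
    results: list[SweepResult] = []
    for e_max in e_values:
        for cov_min in coverages:
            graph = build_graph(
                hits, query_lengths, EdgeFilterParams(e_max=e_max, cov_min=cov_min)
            )
            for inflation in inflations:
                base = mcl_defaults or MclParams()
                params = MclParams(
                    inflation=inflation,
                    prune_threshold=base.prune_threshold,
                    tolerance=base.tolerance,
                    max_iter=base.max_iter,
                )
                clustering = run_mcl(graph, params)
                metrics = evaluate_clustering(
                    clustering, mega_threshold=mega_threshold, by_protein=by_protein
                )
                results.append(
                    SweepResult(
                        e_max=e_max,
                        cov_min=cov_min,
                        inflation=inflation,
                        metrics=metrics,
                    )
                )
    return results


def select_optimum(results: Sequence[SweepResult]) -> SweepResult:
    """Pick the grid point with minimal objective.

    Ties break deterministically: lower mega fraction, then higher coverage
    floor, then lower E-value ceiling, then higher inflation.
    """
    if not results:
        raise ValueError("no sweep results to select from")
    return min(
        results,
        key=lambda r: (
            r.metrics.objective,
            r.metrics.frac_mega,
            -r.cov_min,
            r.e_max,
            -r.inflation,
        ),
    )


def adjusted_rand_index(
    partition_a: Sequence[frozenset[str]] | Sequence[set[str]],
    partition_b: Sequence[frozenset[str]] | Sequence[set[str]],
) -> float:
    """Adjusted Rand Index between two partitions of the same id set."""
    from sklearn.metrics import adjusted_rand_score

    label_a: dict[str, int] = {}
    for i, group in enumerate(partition_a):
        for x in group:
            label_a[x] = i
    label_b: dict[str, int] = {}
    for i, group in enumerate(partition_b):
        for x in group:
            label_b[x] = i
    if set(label_a) != set(label_b):
        raise ValueError("partitions cover different id sets")
    ids = sorted(label_a)
    return float(
        adjusted_rand_score([label_a[i] for i in ids], [label_b[i] for i in ids])
    )


def write_sweep_tsv(results: Sequence[SweepResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("e_max\tcov_min\tinflation\tn_clusters\tfrac_singlet\tfrac_mega\tobjective\n")
        for r in results:
            m = r.metrics
            fh.write(
                f"{r.e_max:.3g}\t{r.cov_min:g}\t{r.inflation:g}\t{m.n_clusters}\t"
                f"{m.frac_singlet:.6g}\t{m.frac_mega:.6g}\t{m.objective:.6g}\n"
            )


def plot_optimum_plane(results: Sequence[SweepResult], inflation: float, path) -> None:
    """Heat map of the objective over (E-value, coverage) at one inflation."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    subset = [r for r in results if r.inflation == inflation]
    e_vals = sorted({r.e_max for r in subset})
    covs = sorted({r.cov_min for r in subset})
    grid = np.full((len(covs), len(e_vals)), np.nan)
    for r in subset:
        grid[covs.index(r.cov_min), e_vals.index(r.e_max)] = r.metrics.objective
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(grid, origin="lower", aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(e_vals)), [f"{e:.0e}" for e in e_vals], rotation=45)
    ax.set_yticks(range(len(covs)), [f"{c:g}" for c in covs])
    ax.set_xlabel("E-value ceiling")
    ax.set_ylabel("coverage floor (%)")
    ax.set_title(f"objective at inflation {inflation:g}")
    fig.colorbar(im, ax=ax, label="frac_singlet + frac_mega")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
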