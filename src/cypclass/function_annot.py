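"""Transfer functional categories from characterized CYPs to the classification.

A small curated set of experimentally characterized proteins carries one of
three broad category labels — primary metabolism (housekeeping biosynthesis,
e.g. sterols), secondary metabolism (natural-product pathways) and
xenobiotic metabolism (detoxification). Query proteins inherit the union of
categories of every curated reference they hit at E <= 1e-100 (any-hit
semantics: multi-category proteins are expected and meaningful).

Propagation: a family's categories are the union over its members; only
families with a *single* category ("uniquely annotated") carry their label
up to the clan level — a family spanning, say, both secondary and xenobiotic
metabolism is flagged non-unique and excluded from clan assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import HitRecord, ProteinRecord

__all__ = [
    "CATEGORIES",
    "DEFAULT_E_CUTOFF",
    "CuratedReference",
    "FunctionAnnotation",
    "annotate_proteins",
    "propagate",
]

CATEGORIES = frozenset({"primary", "secondary", "xenobiotic"})

#: Stringent transfer cutoff: only near-identical matches inherit function.
DEFAULT_E_CUTOFF = 1e-100


@dataclass(frozen=True)
class CuratedReference:
    record: ProteinRecord
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category must be one of {sorted(CATEGORIES)}, got {self.category!r}"
            )


@dataclass(frozen=True)
class FunctionAnnotation:
    """Category set attached to a protein, family, or clan."""

    unit_id: str
    categories: frozenset[str]

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError(f"{self.unit_id!r}: empty category set")
        if not self.categories <= CATEGORIES:
            raise ValueError(f"{self.unit_id!r}: unknown categories")

    @property
    def unique(self) -> bool:
        return len(self.categories) == 1


def annotate_proteins(
    hits: Iterable[HitRecord],
    curated: Sequence[CuratedReference],
    e_cutoff: float = DEFAULT_E_CUTOFF,
) -> dict[str, frozenset[str]]:
    """Map each query protein to the categories of curated references it hits.

    ``hits`` are query-vs-curated search results; a hit qualifies when its
    E-value is <= ``e_cutoff`` and its subject is a curated reference.
    Proteins with no qualifying hit are absent from the returned map.
    """
    if not curated:
        raise ValueError("curated reference set must not be empty")
    category_of = {ref.record.id: ref.category for ref in curated}
    out: dict[str, set[str]] = {}
    for h in hits:
        if h.evalue > e_cutoff:
            continue
        cat = category_of.get(h.subject_id)
        if cat is None:
            continue
        out.setdefault(h.query_id, set()).add(cat)
    return {pid: frozenset(cats) for pid, cats in out.items()}


def propagate(
    annotations: Mapping[str, frozenset[str]],
    family_of: Mapping[str, str],
    clan_of_family: Mapping[str, str],
) -> tuple[list[FunctionAnnotation], list[FunctionAnnotation]]:
    """Roll protein categories up to families, then uniquely-annotated families
    up to clans.

    Returns ``(family_annotations, clan_annotations)``, each sorted by unit id.
    Both input maps may be partial; idempotent by construction.
    """
    family_cats: dict[str, set[str]] = {}
    for pid, cats in annotations.items():
        fam = family_of.get(pid)
        if fam is None:
            continue
        family_cats.setdefault(fam, set()).update(cats)
    families = [
        FunctionAnnotation(unit_id=fam, categories=frozenset(cats))
        for fam, cats in sorted(family_cats.items())
    ]
    clan_cats: dict[str, set[str]] = {}
    for fa in families:
        if not fa.unique:
            continue  # multi-category families do not vote at clan level
        clan = clan_of_family.get(fa.unit_id)
        if clan is None:
            continue
        clan_cats.setdefault(clan, set()).update(fa.categories)
    clans = [
        FunctionAnnotation(unit_id=clan, categories=frozenset(cats))
        for clan, cats in sorted(clan_cats.items())
    ]
    return families, clans


def read_category_table(path) -> dict[str, str]:
    """Two-column TSV protein_id -> category."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("protein_id\t"):
                continue
            pid, cat = line.split("\t")
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r} for {pid!r}")
            out[pid] = cat
    return out


def write_annotation_tsv(
    annotations: Sequence[FunctionAnnotation], path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("unit_id\tcategories\tunique\n")
        for a in annotations:
            fh.write(
                f"{a.unit_id}\t{','.join(sorted(a.categories))}\t"
                f"{'yes' if a.unique else 'no'}\n"
            )
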