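"""Family/subfamily naming by identity thresholds and clan inference.

The classical naming scheme places two CYPs in the same family when their
pairwise sequence identity exceeds 40% and in the same subfamily when it
exceeds 55% (both strictly greater). Identity here is computed from a global
Needleman-Wunsch alignment (BLOSUM62, gap open 10, gap extend 0.5) as
identical columns over the full alignment length, gap columns included in
the denominator (a gapless-columns mode is available).

Clans — higher-order, presumed-monophyletic groups of families — are
inferred from cluster co-membership: families landing in one MCL cluster are
taken to share a clan. Known clan labels propagate to clanless co-members;
clusters touching two or more known clans yield merge *proposals* (never
auto-applied); singlet clusters whose family has no clan become orphans.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import ProteinRecord
from .mcl_core import Clustering

__all__ = [
    "NomenclatureParams",
    "NamedReference",
    "FamilyAssignment",
    "ClanRecord",
    "global_identity",
    "assign_family",
    "infer_clans",
]

UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class NomenclatureParams:
    family_identity_min: float = 40.0
    subfamily_identity_min: float = 55.0

    def __post_init__(self) -> None:
        if not 0.0 < self.family_identity_min < self.subfamily_identity_min <= 100.0:
            raise ValueError(
                "require 0 < family_identity_min < subfamily_identity_min <= 100"
            )


@dataclass(frozen=True)
class NamedReference:
    """A reference protein carrying curated family (and optional subfamily) names."""

    record: ProteinRecord
    family: str
    subfamily: Optional[str] = None


@dataclass(frozen=True)
class FamilyAssignment:
    protein_id: str
    family: str  # a family name, or UNASSIGNED for novel-family candidates
    subfamily: Optional[str]
    best_ref_id: Optional[str]
    best_identity: float
    runner_up_family: Optional[str] = None

    def __post_init__(self) -> None:
        if self.subfamily is not None and self.family == UNASSIGNED:
            raise ValueError("subfamily set without a family")


@dataclass(frozen=True)
class ClanRecord:
    clan_name: str
    families: frozenset[str]
    status: str  # known | novel | orphan | merge_proposal
    source_cluster_id: int
    merged_clans: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.status == "orphan" and len(self.families) != 1:
            raise ValueError("orphan clan must contain exactly one family")
        if self.status == "merge_proposal" and len(self.merged_clans) < 2:
            raise ValueError("merge proposal must list >= 2 known clans")


@lru_cache(maxsize=8)
def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def global_identity(
    seq_a: str,
    seq_b: str,
    gaps_in_denominator: bool = True,
) -> float:
    """Percent identity from a global alignment of two protein sequences.

    Needleman-Wunsch with BLOSUM62, gap open 10, gap extend 0.5. Identity is
    100 x identical columns / alignment length; with
    ``gaps_in_denominator=False`` the denominator drops gap columns.
    Selenocysteine (U) is scored as X, which BLOSUM62 lacks a row for.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    a = seq_a.upper().replace("U", "X")
    b = seq_b.upper().replace("U", "X")
    alignment = _aligner("global").align(a, b)[0]
    counts = alignment.counts()
    length = alignment.length
    identities = counts.identities
    if gaps_in_denominator:
        denom = length
    else:
        denom = length - counts.gaps
    if denom == 0:
        return 0.0
    return 100.0 * identities / denom


def assign_family(
    query: ProteinRecord,
    references: Sequence[NamedReference],
    params: NomenclatureParams = NomenclatureParams(),
    runner_up_margin: float = 2.0,
) -> FamilyAssignment:
    """Assign family/subfamily from the best-identity named reference.

    Best-hit semantics (identity relations are not transitive): the single
    highest-identity reference decides. Identity strictly above the family
    threshold assigns that reference's family; strictly above the subfamily
    threshold additionally assigns its subfamily; otherwise the protein is a
    novel-family candidate (``UNASSIGNED``). Ties break to the
    lexicographically smallest reference id. When the best hit from a
    *different* family trails the winner by at most ``runner_up_margin``
    identity points, that family is reported as runner-up.
    """
    if not references:
        raise ValueError("reference set must not be empty")
    scored = []
    for ref in references:
        ident = global_identity(query.sequence, ref.record.sequence)
        scored.append((ident, ref))
    scored.sort(key=lambda t: (-t[0], t[1].record.id))
    best_ident, best_ref = scored[0]
    runner_up = None
    if best_ident > params.family_identity_min:
        for ident, ref in scored[1:]:
            if ref.family != best_ref.family:
                if best_ident - ident <= runner_up_margin and ident > params.family_identity_min:
                    runner_up = ref.family
                break
    if best_ident > params.subfamily_identity_min:
        return FamilyAssignment(
            protein_id=query.id,
            family=best_ref.family,
            subfamily=best_ref.subfamily,
            best_ref_id=best_ref.record.id,
            best_identity=best_ident,
            runner_up_family=runner_up,
        )
    if best_ident > params.family_identity_min:
        return FamilyAssignment(
            protein_id=query.id,
            family=best_ref.family,
            subfamily=None,
            best_ref_id=best_ref.record.id,
            best_identity=best_ident,
            runner_up_family=runner_up,
        )
    return FamilyAssignment(
        protein_id=query.id,
        family=UNASSIGNED,
        subfamily=None,
        best_ref_id=best_ref.record.id,
        best_identity=best_ident,
    )


def infer_clans(
    clustering: Clustering,
    family_of: Mapping[str, str],
    known_clan_of: Mapping[str, str],
) -> list[ClanRecord]:
    """Infer clan records from cluster co-membership of named families.

    Per cluster, the known clans of its member families decide the outcome:

    * no known clan, and the cluster has several families or members — a
      novel clan named ``CLAN_<cluster_id>``;
    * exactly one known clan — that clan, extended with the cluster's
      clanless families;
    * two or more — a merge proposal listing all of them;
    * a singlet cluster whose family has no clan — an orphan clan named
      after the family.

    Each family appears in exactly one record; clusters are processed in
    cluster-id order and a family already claimed is not re-listed.
    ``family_of`` entries equal to ``UNASSIGNED`` are ignored.
    """
    labels = clustering.labels()
    by_cluster: dict[int, list[str]] = {}
    for node, cid in labels.items():
        by_cluster.setdefault(cid, []).append(node)
    records: list[ClanRecord] = []
    claimed: set[str] = set()
    for cid in sorted(by_cluster):
        members = by_cluster[cid]
        families = sorted(
            {
                family_of[p]
                for p in members
                if p in family_of and family_of[p] != UNASSIGNED
            }
            - claimed
        )
        clans = sorted({known_clan_of[f] for f in families if f in known_clan_of})
        if not families:
            continue
        if len(clans) == 0:
            if len(members) == 1 and len(families) == 1:
                rec = ClanRecord(
                    clan_name=families[0],
                    families=frozenset(families),
                    status="orphan",
                    source_cluster_id=cid,
                )
            else:
                rec = ClanRecord(
                    clan_name=f"CLAN_{cid}",
                    families=frozenset(families),
                    status="novel",
                    source_cluster_id=cid,
                )
        elif len(clans) == 1:
            rec = ClanRecord(
                clan_name=clans[0],
                families=frozenset(families),
                status="known",
                source_cluster_id=cid,
            )
        else:
            rec = ClanRecord(
                clan_name="+".join(clans),
                families=frozenset(families),
                status="merge_proposal",
                source_cluster_id=cid,
                merged_clans=frozenset(clans),
            )
        claimed |= set(families)
        records.append(rec)
    return records


def read_reference_fasta(path) -> list[NamedReference]:
    """Read named references from FASTA with ``id|family|subfamily`` headers."""
    from Bio import SeqIO

    refs: list[NamedReference] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) < 2 or not parts[1]:
            raise ValueError(
                f"reference header {rec.id!r} must carry id|family[|subfamily]"
            )
        subfamily = parts[2] if len(parts) > 2 and parts[2] else None
        refs.append(
            NamedReference(
                record=ProteinRecord(id=parts[0], sequence=str(rec.seq).upper()),
                family=parts[1],
                subfamily=subfamily,
            )
        )
    return refs


def read_clan_map(path) -> dict[str, str]:
    """Two-column TSV family -> clan."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("family\t"):
                continue
            family, clan = line.split("\t")
            out[family] = clan
    return out


def write_assignments_tsv(
    assignments: Iterable[FamilyAssignment], path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            "protein_id\tfamily\tsubfamily\tbest_ref_id\tbest_identity\trunner_up_family\n"
        )
        for a in assignments:
            fh.write(
                f"{a.protein_id}\t{a.family}\t{a.subfamily or '-'}\t"
                f"{a.best_ref_id or '-'}\t{a.best_identity:.2f}\t"
                f"{a.runner_up_family or '-'}\n"
            )


def write_clans_tsv(
    records: Iterable[ClanRecord], path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("clan_name\tstatus\tsource_cluster_id\tfamilies\tmerged_clans\n")
        for r in records:
            fams = ",".join(sorted(r.families))
            merged = ",".join(sorted(r.merged_clans)) or "-"
            fh.write(
                f"{r.clan_name}\t{r.status}\t{r.source_cluster_id}\t{fams}\t{merged}\n"
            )
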