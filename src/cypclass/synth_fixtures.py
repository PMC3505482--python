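"""Synthetic proteomes with planted family structure, plus emulated hit tables.

The generator plants disjoint sequence families: each family descends from an
independent random seed sequence, and members are derived by i.i.d.
substitutions at a rate calibrated so that the expected pairwise identity
within a family matches the target. Two members mutated independently at
per-site rate r agree at a site with probability (1-r)^2 + r^2/19, so the
substitution rate is set to r = 1 - sqrt(target). Members are distributed
round-robin across species. Sequences from different families are
independent, so their chance identity sits near the random-background level
(well under any realistic between-family ceiling).

:func:`emulate_hits` stands in for an all-vs-all local-alignment search: it
scores every pair with Smith-Waterman (BLOSUM62, gap 10/0.5) and converts
the score to an E-value through the Karlin-Altschul formula
``E = k * m * n * exp(-lambda * S)`` with standard gapped-BLOSUM62 constants.
The constants only need to rank pairs plausibly, not reproduce any specific
search tool.

By default members carry no indels, so query coverage sits near 100%; an
optional deletion mode exercises the coverage filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import HitRecord, ProteinRecord

__all__ = [
    "AMINO_ACIDS",
    "TAXON_CYCLE",
    "SyntheticSpec",
    "SyntheticTruth",
    "generate",
    "emulate_hits",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Species are cycled through these taxon labels (fungal subphyla).
TAXON_CYCLE = ("Pezizomycotina", "Agaricomycotina", "Mucoromycotina")

#: Karlin-Altschul constants for gapped BLOSUM62 scoring.
KARLIN_LAMBDA = 0.267
KARLIN_K = 0.041


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-family proteome.

    Defaults emulate a modest fungal CYPome slice: a handful of families of
    ten members each, ~450-residue proteins (typical P450 length), 80%
    within-family identity against a 25% between-family ceiling.
    """

    n_families: int = 5
    family_sizes: Optional[tuple[int, ...]] = None
    within_identity_target: float = 80.0
    between_identity_max: float = 25.0
    seq_length: int = 450
    n_species: int = 5
    seed: int = 0
    indel_rate: float = 0.0  # per-member probability of one internal deletion block

    def __post_init__(self) -> None:
        if self.within_identity_target <= self.between_identity_max:
            raise ValueError(
                "within_identity_target must exceed between_identity_max "
                f"({self.within_identity_target} <= {self.between_identity_max})"
            )
        sizes = self.sizes()
        if len(sizes) != self.n_families or any(s < 1 for s in sizes):
            raise ValueError("family_sizes must list n_families sizes >= 1")
        if self.seq_length < 10:
            raise ValueError("seq_length too short to be meaningful")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")

    def sizes(self) -> tuple[int, ...]:
        if self.family_sizes is None:
            return (10,) * self.n_families
        return tuple(self.family_sizes)


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted labels covering every generated protein."""

    family_of: dict[str, str]
    species_of: dict[str, str]
    spec: SyntheticSpec

    def partition(self) -> list[frozenset[str]]:
        groups: dict[str, set[str]] = {}
        for pid, fam in self.family_of.items():
            groups.setdefault(fam, set()).add(pid)
        return [frozenset(groups[f]) for f in sorted(groups)]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("protein_id\tfamily\tspecies\n")
            for pid in sorted(self.family_of):
                fh.write(f"{pid}\t{self.family_of[pid]}\t{self.species_of[pid]}\n")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        alternatives = AMINO_ACIDS.replace(out[i], "")
        out[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def _positional_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def generate(spec: SyntheticSpec) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Generate the planted proteome; deterministic given ``spec.seed``.

    The realized mean within-family identity is measured after generation
    (positionally in the default indel-free mode, since family members stay
    aligned) and must land within +/- 5 points of the target, else a
    RuntimeError is raised.
    """
    rng = np.random.default_rng(spec.seed)
    target = spec.within_identity_target / 100.0
    rate = 1.0 - math.sqrt(target)
    species = [f"sp{i + 1}" for i in range(spec.n_species)]
    taxon_of = {
        sp: TAXON_CYCLE[i % len(TAXON_CYCLE)] for i, sp in enumerate(species)
    }
    records: list[ProteinRecord] = []
    family_of: dict[str, str] = {}
    species_of: dict[str, str] = {}
    member_seqs: dict[str, list[str]] = {}
    counter = 0
    for f_idx, size in enumerate(spec.sizes()):
        family = f"FAM{f_idx + 1}"
        ancestor = _random_sequence(rng, spec.seq_length)
        member_seqs[family] = []
        for _ in range(size):
            seq = _mutate(rng, ancestor, rate)
            member_seqs[family].append(seq)
            if spec.indel_rate > 0 and rng.random() < spec.indel_rate:
                # one internal deletion block of up to half the sequence
                max_del = spec.seq_length // 2
                del_len = int(rng.integers(1, max_del + 1))
                start = int(rng.integers(0, spec.seq_length - del_len))
                seq = seq[:start] + seq[start + del_len:]
            pid = f"P{counter:05d}"
            counter += 1
            sp = species[counter % spec.n_species]
            records.append(
                ProteinRecord(
                    id=pid, sequence=seq, species=sp, taxon_group=taxon_of[sp]
                )
            )
            family_of[pid] = family
            species_of[pid] = sp
    _verify_within_identity(member_seqs, spec.within_identity_target)
    return records, SyntheticTruth(
        family_of=family_of, species_of=species_of, spec=spec
    )


def _verify_within_identity(
    member_seqs: dict[str, list[str]], target: float, band: float = 5.0
) -> None:
    idents: list[float] = []
    for seqs in member_seqs.values():
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                idents.append(_positional_identity(seqs[i], seqs[j]))
    if not idents:
        return
    realized = float(np.mean(idents))
    if abs(realized - target) > band:
        raise RuntimeError(
            f"realized within-family identity {realized:.1f}% is more than "
            f"{band} points from the {target:.1f}% target"
        )


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def karlin_evalue(
    score: float,
    m: int,
    n: int,
    karlin_lambda: float = KARLIN_LAMBDA,
    karlin_k: float = KARLIN_K,
) -> float:
    """Karlin-Altschul E-value for a local alignment score on an m x n search.

    Computed in log space; extreme scores underflow to exactly 0.0.
    """
    ln_e = math.log(karlin_k) + math.log(m) + math.log(n) - karlin_lambda * score
    if ln_e < -700:
        return 0.0
    return math.exp(ln_e)


def emulate_hits(
    records: Sequence[ProteinRecord],
    karlin_lambda: float = KARLIN_LAMBDA,
    karlin_k: float = KARLIN_K,
    e_report_max: float = 10.0,
) -> list[HitRecord]:
    """All-vs-all emulated search over the records (quadratic: keep <= ~500).

    Every ordered pair whose E-value is at most ``e_report_max`` yields one
    hit line; self-hits are always included. Scoring is symmetric, so both
    directions of a pair share score, E-value and identity, with query and
    subject coordinates swapped.
    """
    aligner = _local_aligner()
    hits: list[HitRecord] = []
    by_query: dict[str, list[HitRecord]] = {r.id: [] for r in records}
    for i, rec_a in enumerate(records):
        # self-hit: perfect full-length match
        self_score = aligner.score(rec_a.sequence, rec_a.sequence)
        m = len(rec_a.sequence)
        by_query[rec_a.id].append(
            _make_hit(
                rec_a.id, rec_a.id, 100.0, m, 0, 0, 1, m, 1, m,
                karlin_evalue(self_score, m, m, karlin_lambda, karlin_k),
                _bitscore(self_score, karlin_lambda, karlin_k),
            )
        )
        for rec_b in records[i + 1:]:
            score = aligner.score(rec_a.sequence, rec_b.sequence)
            e = karlin_evalue(
                score, len(rec_a.sequence), len(rec_b.sequence),
                karlin_lambda, karlin_k,
            )
            if e > e_report_max:
                continue
            aln = aligner.align(rec_a.sequence, rec_b.sequence)[0]
            counts = aln.counts()
            ident_pct = 100.0 * counts.identities / aln.length
            blocks_a, blocks_b = aln.aligned
            qs, qe = int(blocks_a[0][0]) + 1, int(blocks_a[-1][1])
            ss, se = int(blocks_b[0][0]) + 1, int(blocks_b[-1][1])
            gap_opens = len(blocks_a) - 1
            bits = _bitscore(score, karlin_lambda, karlin_k)
            by_query[rec_a.id].append(
                _make_hit(
                    rec_a.id, rec_b.id, ident_pct, aln.length,
                    counts.mismatches, gap_opens, qs, qe, ss, se, e, bits,
                )
            )
            by_query[rec_b.id].append(
                _make_hit(
                    rec_b.id, rec_a.id, ident_pct, aln.length,
                    counts.mismatches, gap_opens, ss, se, qs, qe, e, bits,
                )
            )
    for rec in records:
        hits.extend(by_query[rec.id])
    return hits


def _bitscore(score: float, karlin_lambda: float, karlin_k: float) -> float:
    return (karlin_lambda * score - math.log(karlin_k)) / math.log(2)


def _make_hit(
    q: str, s: str, ident: float, alen: int, mm: int, gaps: int,
    qs: int, qe: int, ss: int, se: int, e: float, bits: float,
) -> HitRecord:
    return HitRecord(
        query_id=q, subject_id=s, pct_identity=ident, align_len=int(alen),
        mismatches=int(mm), gap_opens=int(gaps), q_start=qs, q_end=qe,
        s_start=ss, s_end=se, evalue=e, bitscore=bits,
    )
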