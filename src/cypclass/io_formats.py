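"""Readers and writers for every external format the pipeline touches.

All downstream modules consume only the domain types defined here:
:class:`ProteinRecord`, :class:`HitRecord` and :class:`DomainHit`.

Conventions
-----------
* Coordinates are 1-based and inclusive everywhere, matching the 12-column
  tabular local-alignment hit dialect; nothing converts them.
* FASTA record ids are the first whitespace-delimited token of the header.
  Fixture metadata may be packed into that token as ``id|species|taxon``.
* An E-value printed as ``0.0`` is kept as exact zero; the similarity-graph
  weight transform caps it later.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ALPHABET",
    "QUESTIONABLE_SPAN",
    "ProteinRecord",
    "HitRecord",
    "DomainHit",
    "read_fasta",
    "write_fasta",
    "parse_hit_table",
    "write_hit_table",
    "parse_domain_table",
    "write_domain_table",
]

#: The 20 canonical residues plus the ambiguity/rare letters seen in proteomes.
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" "XBZU")

#: Domain hits spanning fewer than this many residues are flagged questionable.
QUESTIONABLE_SPAN = 25

PathLike = Union[str, Path]


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with species/taxon metadata."""

    id: str
    sequence: str
    species: str = "unknown"
    taxon_group: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        bad = set(self.sequence.upper()) - AMINO_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains non-amino-acid letters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HitRecord:
    """One directed pairwise local-alignment hit (one line of the tabular dialect)."""

    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: q_start > q_end"
            )
        if self.align_len < 1:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: align_len < 1")
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: negative E-value")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: identity outside [0, 100]"
            )

    def as_row(self) -> str:
        return "\t".join(
            str(x)
            for x in (
                self.query_id,
                self.subject_id,
                f"{self.pct_identity:.2f}",
                self.align_len,
                self.mismatches,
                self.gap_opens,
                self.q_start,
                self.q_end,
                self.s_start,
                self.s_end,
                f"{self.evalue:.3g}" if self.evalue != 0 else "0.0",
                f"{self.bitscore:.1f}",
            )
        )


@dataclass(frozen=True)
class DomainHit:
    """A domain-scanner annotation on a protein.

    ``status`` is derived at construction: hits spanning fewer than
    :data:`QUESTIONABLE_SPAN` residues are ``questionable``, all others ``ok``.
    """

    protein_id: str
    domain_id: str
    start: int
    end: int
    status: str = field(init=False)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"domain hit on {self.protein_id!r}: start < 1")
        if self.end < self.start:
            raise ValueError(f"domain hit on {self.protein_id!r}: end < start")
        object.__setattr__(
            self, "status", "questionable" if self.span < QUESTIONABLE_SPAN else "ok"
        )

    @property
    def span(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _parse_header_token(token: str, header_fields: str) -> tuple[str, str, str]:
    if header_fields == "plain":
        return token, "unknown", "unknown"
    if header_fields == "pipe":
        parts = token.split("|")
        pid = parts[0]
        species = parts[1] if len(parts) > 1 and parts[1] else "unknown"
        taxon = parts[2] if len(parts) > 2 and parts[2] else "unknown"
        return pid, species, taxon
    raise ValueError(f"unknown header_fields convention {header_fields!r}")


def read_fasta(path: PathLike, header_fields: str = "pipe") -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Parameters
    ----------
    path
        FASTA file path.
    header_fields
        Header convention for the first whitespace token: ``"pipe"`` splits it
        as ``id|species|taxon`` (missing fields default to ``"unknown"``);
        ``"plain"`` treats the whole token as the id.

    Raises
    ------
    ValueError
        On a duplicate id (naming the id) or an empty sequence.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        token = rec.id
        pid, species, taxon = _parse_header_token(token, header_fields)
        if pid in seen:
            raise ValueError(f"duplicate protein id {pid!r} in {path}")
        seen.add(pid)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for protein {pid!r} in {path}")
        records.append(
            ProteinRecord(id=pid, sequence=seq, species=species, taxon_group=taxon)
        )
    return records


def write_fasta(
    records: Iterable[ProteinRecord],
    path: PathLike,
    header_fields: str = "pipe",
) -> None:
    """Write records to FASTA, packing metadata per ``header_fields``."""
    seqrecords = []
    for r in records:
        if header_fields == "pipe":
            name = f"{r.id}|{r.species}|{r.taxon_group}"
        else:
            name = r.id
        seqrecords.append(SeqRecord(Seq(r.sequence), id=name, description=""))
    with open(path, "w") as fh:
        SeqIO.write(seqrecords, fh, "fasta")


# ---------------------------------------------------------------------------
# 12-column tabular hit dialect
# ---------------------------------------------------------------------------

_HIT_COLUMNS = 12


def parse_hit_table(source: Union[PathLike, TextIO]) -> list[HitRecord]:
    """Parse a 12-column tab-separated local-alignment hit table.

    Columns: query, subject, %identity, alignment length, mismatches,
    gap opens, q_start, q_end, s_start, s_end, E-value, bitscore.
    Lines starting with ``#`` and blank lines are skipped.

    Raises
    ------
    ValueError
        With the offending line number on a wrong column count or a
        non-numeric numeric field.
    """
    if isinstance(source, (str, Path)):
        fh: TextIO = open(source)
        close = True
    else:
        fh, close = source, False
    hits: list[HitRecord] = []
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _HIT_COLUMNS:
                raise ValueError(
                    f"line {lineno}: expected {_HIT_COLUMNS} tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                hit = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    align_len=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
            hits.append(hit)
    finally:
        if close:
            fh.close()
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(h.as_row() + "\n")


# ---------------------------------------------------------------------------
# Domain-hit TSV
# ---------------------------------------------------------------------------


def parse_domain_table(source: Union[PathLike, TextIO]) -> list[DomainHit]:
    """Parse a TSV of domain hits (protein_id, domain_id, start, end).

    ``status`` is computed from the span at load time. A header line whose
    first field is ``protein_id`` is tolerated; ``#`` comments are skipped.
    """
    if isinstance(source, (str, Path)):
        fh: TextIO = open(source)
        close = True
    else:
        fh, close = source, False
    hits: list[DomainHit] = []
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "protein_id":
                continue
            if len(fields) != 4:
                raise ValueError(
                    f"line {lineno}: expected 4 tab-separated columns, got {len(fields)}"
                )
            try:
                hit = DomainHit(
                    protein_id=fields[0],
                    domain_id=fields[1],
                    start=int(fields[2]),
                    end=int(fields[3]),
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
            hits.append(hit)
    finally:
        if close:
            fh.close()
    return hits


def write_domain_table(hits: Iterable[DomainHit], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tdomain_id\tstart\tend\n")
        for h in hits:
            fh.write(f"{h.protein_id}\t{h.domain_id}\t{h.start}\t{h.end}\n")
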