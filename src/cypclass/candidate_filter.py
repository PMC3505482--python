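"""Select candidate CYP proteins by accepted domain accessions.

A protein is *accepted* when at least one of its domain hits to an accepted
accession passes the questionable-span rule (>= 25 residues). Proteins whose
only accepted-accession hits are questionable are *flagged* for manual review
rather than silently dropped; an explicit allowlist can promote them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Collection, Iterable

from .io_formats import DomainHit, ProteinRecord

__all__ = ["DEFAULT_P450_DOMAINS", "CandidateSet", "select_candidates"]

#: Default InterPro accessions associated with cytochrome P450 proteins.
#: This list is configuration, not dogma: edit it (or pass ``accepted_domain_ids``)
#: to match the domain scanner release in use.
DEFAULT_P450_DOMAINS = frozenset(
    {
        "IPR001128",  # Cytochrome P450
        "IPR002397",  # Cytochrome P450, B-class
        "IPR002398",  # Cytochrome P450, mitochondrial
        "IPR002399",  # Cytochrome P450, E-class, group II
        "IPR002401",  # Cytochrome P450, E-class, group I
        "IPR002402",  # Cytochrome P450, E-class, group II specific
        "IPR002403",  # Cytochrome P450, E-class, group IV
        "IPR008066",  # Cytochrome P450, CYP4
        "IPR008067",  # Cytochrome P450, CYP17
        "IPR008068",  # Cytochrome P450, CYP51
        "IPR008069",  # Cytochrome P450, CYP1
        "IPR008070",  # Cytochrome P450, CYP2
        "IPR008071",  # Cytochrome P450, CYP21
        "IPR008072",  # Cytochrome P450, CYP19
        "IPR017972",  # Cytochrome P450, conserved site
        "IPR036396",  # Cytochrome P450 superfamily
    }
)


@dataclass(frozen=True)
class CandidateSet:
    """Outcome of candidate selection.

    ``accepted_ids`` have at least one full-length (non-questionable) hit to an
    accepted accession; ``flagged_ids`` are supported only by questionable hits
    and await review.
    """

    accepted_ids: frozenset[str]
    flagged_ids: frozenset[str]
    accepted_domains: frozenset[str]

    def __post_init__(self) -> None:
        if self.accepted_ids & self.flagged_ids:
            raise ValueError("accepted and flagged sets overlap")


def select_candidates(
    proteins: Iterable[ProteinRecord],
    domains: Iterable[DomainHit],
    accepted_domain_ids: Collection[str] = DEFAULT_P450_DOMAINS,
    promote: Collection[str] = (),
) -> CandidateSet:
    """Partition proteins into accepted / flagged / excluded.

    Parameters
    ----------
    proteins
        The proteome being screened; every domain hit must refer to one of them.
    domains
        Domain-scanner hits.
    accepted_domain_ids
        Accessions that define the target superfamily. Must be non-empty.
    promote
        Ids promoted from flagged to accepted after manual review.

    Raises
    ------
    ValueError
        If ``accepted_domain_ids`` is empty or a domain hit names an unknown
        protein.
    """
    accepted_domain_ids = frozenset(accepted_domain_ids)
    if not accepted_domain_ids:
        raise ValueError("accepted_domain_ids must not be empty (configuration required)")
    known_ids = {p.id for p in proteins}
    has_ok: set[str] = set()
    has_questionable: set[str] = set()
    for hit in domains:
        if hit.protein_id not in known_ids:
            raise ValueError(f"domain hit refers to unknown protein {hit.protein_id!r}")
        if hit.domain_id not in accepted_domain_ids:
            continue
        if hit.status == "ok":
            has_ok.add(hit.protein_id)
        else:
            has_questionable.add(hit.protein_id)
    flagged = has_questionable - has_ok
    accepted = has_ok | (flagged & set(promote))
    flagged -= accepted
    return CandidateSet(
        accepted_ids=frozenset(accepted),
        flagged_ids=frozenset(flagged),
        accepted_domains=accepted_domain_ids,
    )
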