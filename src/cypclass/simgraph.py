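"""Build the filtered, symmetrized similarity graph that Markov clustering consumes.

Directed pairwise hits are filtered on a best-E-value ceiling and a
query-coverage floor; an undirected edge requires *both* directions to
survive (the reciprocal-search contract). Edge weights are the mean of the
two directions' ``-log10(E)``, with ``E = 0`` mapped to a cap of 200 — the
classic Tribe-MCL transform. Every node carries a self-loop weighted by its
strongest incident edge (1.0 when isolated), which stabilizes MCL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .io_formats import HitRecord

__all__ = [
    "LOG_EVALUE_CAP",
    "EdgeFilterParams",
    "SimilarityGraph",
    "query_coverage",
    "filter_hits",
    "symmetrize",
    "build_graph",
]

#: -log10(E) is capped here; E-values of exactly zero map to the cap.
LOG_EVALUE_CAP = 200.0


@dataclass(frozen=True)
class EdgeFilterParams:
    """E-value ceiling and query-coverage floor for edge retention."""

    e_max: float = 1e-50
    cov_min: float = 60.0

    def __post_init__(self) -> None:
        if self.e_max <= 0:
            raise ValueError("e_max must be positive")
        if not 0.0 <= self.cov_min <= 100.0:
            raise ValueError("cov_min must be in [0, 100]")


@dataclass
class SimilarityGraph:
    """Undirected, weighted graph with per-node self-loops.

    ``edges`` maps a sorted node-id pair to a positive weight; ``self_loops``
    maps each node to its self-loop weight.
    """

    nodes: list[str]
    edges: dict[tuple[str, str], float]
    self_loops: dict[str, float]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for (a, b), w in self.edges.items():
            if w <= 0:
                raise ValueError(f"edge {a}-{b} has non-positive weight {w}")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge {a}-{b} references unknown node")
        missing = node_set - set(self.self_loops)
        if missing:
            raise ValueError(f"nodes missing self-loops: {sorted(missing)[:5]}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def neighbors(self, node: str) -> list[str]:
        out = []
        for a, b in self.edges:
            if a == node:
                out.append(b)
            elif b == node:
                out.append(a)
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w)
        return g

    def connected_components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.to_networkx())]

    def write_edge_list(self, path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("node_a\tnode_b\tweight\n")
            for node, w in sorted(self.self_loops.items()):
                fh.write(f"{node}\t{node}\t{w:.6g}\n")
            for (a, b), w in sorted(self.edges.items()):
                fh.write(f"{a}\t{b}\t{w:.6g}\n")

    @classmethod
    def read_edge_list(cls, path) -> "SimilarityGraph":
        edges: dict[tuple[str, str], float] = {}
        self_loops: dict[str, float] = {}
        nodes: list[str] = []
        seen: set[str] = set()

        def note(n: str) -> None:
            if n not in seen:
                seen.add(n)
                nodes.append(n)

        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("node_a\t"):
                    continue
                a, b, w = line.split("\t")
                note(a)
                note(b)
                if a == b:
                    self_loops[a] = float(w)
                else:
                    edges[(min(a, b), max(a, b))] = float(w)
        return cls(nodes=nodes, edges=edges, self_loops=self_loops)


def query_coverage(hsps: Sequence[HitRecord], query_len: int) -> float:
    """Percent of the query covered by the union of its HSP intervals.

    Overlapping HSPs are merged before summing, so the result is in [0, 100].

    Raises
    ------
    ValueError
        If the HSPs span multiple (query, subject) pairs or an interval
        exceeds ``query_len``.
    """
    if query_len < 1:
        raise ValueError("query_len must be >= 1")
    if not hsps:
        return 0.0
    pair = (hsps[0].query_id, hsps[0].subject_id)
    intervals = []
    for h in hsps:
        if (h.query_id, h.subject_id) != pair:
            raise ValueError("all HSPs must share the same query and subject")
        if h.q_end > query_len:
            raise ValueError(
                f"HSP [{h.q_start},{h.q_end}] exceeds query length {query_len}"
            )
        intervals.append((h.q_start, h.q_end))
    intervals.sort()
    covered = 0
    cur_start, cur_end = intervals[0]
    for s, e in intervals[1:]:
        if s <= cur_end + 1:  # overlapping or contiguous: one covered run
            cur_end = max(cur_end, e)
        else:
            covered += cur_end - cur_start + 1
            cur_start, cur_end = s, e
    covered += cur_end - cur_start + 1
    return 100.0 * covered / query_len


def filter_hits(
    hits: Iterable[HitRecord],
    params: EdgeFilterParams,
    query_lengths: Mapping[str, int],
) -> dict[tuple[str, str], float]:
    """Retain directed pairs passing both the E-value and coverage filters.

    Multiple HSPs per (query, subject) pair are pooled: the best (minimum)
    E-value decides the E-value test, and coverage is computed from the merged
    union of all the pair's intervals. Self-hits never become directed pairs.

    Returns
    -------
    dict
        ``(query_id, subject_id) -> best E-value`` for retained pairs.
    """
    by_pair: dict[tuple[str, str], list[HitRecord]] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        by_pair.setdefault((h.query_id, h.subject_id), []).append(h)
    retained: dict[tuple[str, str], float] = {}
    for (q, s), pair_hits in by_pair.items():
        if q not in query_lengths:
            raise ValueError(f"no query length for {q!r}")
        best_e = min(h.evalue for h in pair_hits)
        if best_e > params.e_max:
            continue
        cov = query_coverage(pair_hits, query_lengths[q])
        if cov < params.cov_min:
            continue
        retained[(q, s)] = best_e
    return retained


def _log_weight(evalue: float) -> float:
    if evalue <= 0.0:
        return LOG_EVALUE_CAP
    return min(-math.log10(evalue), LOG_EVALUE_CAP)


def symmetrize(
    directed: Mapping[tuple[str, str], float],
    nodes: Iterable[str],
) -> SimilarityGraph:
    """Build the undirected graph from reciprocally retained directed pairs.

    An edge q-s exists iff both q->s and s->q survived filtering; its weight
    is the mean of the two directions' capped ``-log10(E)``. Self-loop weight
    is the maximum incident edge weight (1.0 for isolated nodes).
    """
    node_list = list(dict.fromkeys(nodes))
    edges: dict[tuple[str, str], float] = {}
    for (q, s), e_fwd in directed.items():
        if q > s:
            continue  # handle each unordered pair once, from its sorted side
        e_rev = directed.get((s, q))
        if e_rev is None:
            continue
        edges[(q, s)] = 0.5 * (_log_weight(e_fwd) + _log_weight(e_rev))
    self_loops = {n: 1.0 for n in node_list}
    for (a, b), w in edges.items():
        self_loops[a] = max(self_loops[a], w)
        self_loops[b] = max(self_loops[b], w)
    return SimilarityGraph(nodes=node_list, edges=edges, self_loops=self_loops)


def build_graph(
    hits: Iterable[HitRecord],
    query_lengths: Mapping[str, int],
    params: EdgeFilterParams = EdgeFilterParams(),
) -> SimilarityGraph:
    """Filter directed hits and symmetrize in one call.

    Every id in ``query_lengths`` becomes a graph node, so proteins whose
    hits are all filtered away remain as isolated self-looped nodes.
    """
    directed = filter_hits(hits, params, query_lengths)
    return symmetrize(directed, query_lengths.keys())
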