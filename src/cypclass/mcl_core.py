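"""Markov clustering (MCL) of the similarity graph, implemented from scratch.

MCL simulates flow on the graph by alternating *expansion* (matrix squaring)
and *inflation* (entrywise power followed by column renormalization). Flow
concentrates inside dense regions and evaporates between them; the limit
matrix is interpreted as a disjoint partition. The inflation factor controls
cluster granularity ("tightness"): higher inflation, finer clusters.

The implementation operates on SciPy sparse matrices; the contract is defined
on values only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse

from .simgraph import EdgeFilterParams, SimilarityGraph

__all__ = ["MclParams", "Clustering", "to_stochastic", "mcl_step", "run_mcl"]


@dataclass(frozen=True)
class MclParams:
    """Parameters of the MCL iteration.

    inflation
        Entrywise power applied after expansion; must exceed 1 (inflation 1
        performs no clustering). The classification sweep uses up to 5.
    prune_threshold
        Entries below this are dropped after inflation to keep the matrix
        sparse; the column is renormalized afterwards.
    tolerance
        Convergence threshold on the maximum absolute entry change.
    max_iter
        Iteration cap; hitting it emits a warning and flags the result.
    """

    inflation: float = 5.0
    prune_threshold: float = 1e-5
    tolerance: float = 1e-8
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.inflation <= 1.0:
            raise ValueError(f"inflation must be > 1, got {self.inflation}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.prune_threshold < 0:
            raise ValueError("prune_threshold must be non-negative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")


@dataclass
class Clustering:
    """A disjoint partition of graph nodes with parameter provenance."""

    clusters: list[frozenset[str]]
    n_nodes: int
    mcl_params: Optional[MclParams] = None
    filter_params: Optional[EdgeFilterParams] = None
    converged: bool = True
    n_iterations: int = 0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if not c:
                raise ValueError("empty cluster in partition")
            if seen & c:
                raise ValueError("clusters are not disjoint")
            seen |= c
        if len(seen) != self.n_nodes:
            raise ValueError(
                f"clusters cover {len(seen)} nodes but graph has {self.n_nodes}"
            )

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    def labels(self) -> dict[str, int]:
        """node id -> cluster index (clusters sorted by size desc, then min id)."""
        order = sorted(
            range(len(self.clusters)),
            key=lambda i: (-len(self.clusters[i]), min(self.clusters[i])),
        )
        out: dict[str, int] = {}
        for rank, i in enumerate(order):
            for node in self.clusters[i]:
                out[node] = rank
        return out

    def write_tsv(self, path, header_lines: Sequence[str] = ()) -> None:
        labels = self.labels()
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("cluster_id\tprotein_id\n")
            for node in sorted(labels, key=lambda n: (labels[n], n)):
                fh.write(f"{labels[node]}\t{node}\n")


def to_stochastic(graph: SimilarityGraph) -> tuple[sparse.csc_matrix, list[str]]:
    """Column-stochastic transition matrix of the graph, self-loops included.

    Returns the matrix and the node order of its axes. Entry (i, j) is the
    probability of flow from node j to node i.
    """
    if graph.n_nodes == 0:
        raise ValueError("graph has no nodes")
    nodes = list(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for n, w in graph.self_loops.items():
        i = index[n]
        rows.append(i)
        cols.append(i)
        vals.append(w)
    for (a, b), w in graph.edges.items():
        i, j = index[a], index[b]
        rows.extend((i, j))
        cols.extend((j, i))
        vals.extend((w, w))
    m = sparse.csc_matrix(
        (vals, (rows, cols)), shape=(len(nodes), len(nodes)), dtype=np.float64
    )
    return _normalize_columns(m), nodes


def _normalize_columns(m: sparse.csc_matrix) -> sparse.csc_matrix:
    sums = np.asarray(m.sum(axis=0)).ravel()
    sums[sums == 0.0] = 1.0  # self-loops guarantee this never fires on real input
    scale = sparse.diags(1.0 / sums)
    return (m @ scale).tocsc()


def mcl_step(
    m: sparse.csc_matrix,
    inflation: float,
    prune_threshold: float = 1e-5,
) -> sparse.csc_matrix:
    """One MCL iteration: expansion, inflation, pruning, renormalization."""
    expanded = (m @ m).tocsc()
    inflated = expanded.power(inflation)
    if prune_threshold > 0:
        inflated.data[inflated.data < prune_threshold] = 0.0
        inflated.eliminate_zeros()
    return _normalize_columns(inflated)


def _interpret(m: sparse.csc_matrix, nodes: list[str]) -> list[frozenset[str]]:
    """Read a disjoint partition off the (near-)limit matrix.

    Rows with a nonzero diagonal entry (attractors) seed clusters containing
    every column with positive mass in that row. A node claimed by several
    clusters goes to the one where its mass is largest; ties break to the
    lowest cluster index. Unclaimed nodes become singletons.
    """
    n = len(nodes)
    csr = m.tocsr()
    diag = csr.diagonal()
    attractors = np.flatnonzero(diag > 0)
    claims: dict[int, tuple[float, int]] = {}  # col -> (best mass, cluster idx)
    for cluster_idx, a in enumerate(attractors):
        row = csr.getrow(a)
        for col, mass in zip(row.indices, row.data):
            if mass <= 0:
                continue
            best = claims.get(col)
            if best is None or mass > best[0]:
                claims[col] = (mass, cluster_idx)
    members: dict[int, set[int]] = {}
    for col, (_, cluster_idx) in claims.items():
        members.setdefault(cluster_idx, set()).add(col)
    clusters = [
        frozenset(nodes[i] for i in cols)
        for _, cols in sorted(members.items())
        if cols
    ]
    claimed = set(claims)
    for i in range(n):
        if i not in claimed:
            clusters.append(frozenset({nodes[i]}))
    return clusters


def run_mcl(graph: SimilarityGraph, params: MclParams = MclParams()) -> Clustering:
    """Cluster the similarity graph with MCL.

    Iterates :func:`mcl_step` until the maximum absolute entry change drops
    below ``params.tolerance`` or ``params.max_iter`` is reached (the latter
    warns and flags the clustering as unconverged), then interprets the
    matrix as a disjoint partition.
    """
    m, nodes = to_stochastic(graph)
    converged = False
    iteration = 0
    for iteration in range(1, params.max_iter + 1):
        m_next = mcl_step(m, params.inflation, params.prune_threshold)
        delta = abs(m_next - m)
        change = delta.max() if delta.nnz else 0.0
        m = m_next
        if change < params.tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge within {params.max_iter} iterations "
            f"(inflation={params.inflation}); interpreting the current matrix",
            RuntimeWarning,
            stacklevel=2,
        )
    clusters = _interpret(m, nodes)
    return Clustering(
        clusters=clusters,
        n_nodes=graph.n_nodes,
        mcl_params=params,
        converged=converged,
        n_iterations=iteration,
    )
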