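"""Independent reference implementations used only to cross-check the package.

These are deliberately written with plain dense NumPy arithmetic and naive
loops, sharing no code with the package's sparse implementation.
"""

from __future__ import annotations

import numpy as np


def bitmap_coverage(intervals: list[tuple[int, int]], query_len: int) -> float:
    """Per-residue bitmap brute force for query coverage (1-based inclusive)."""
    covered = np.zeros(query_len, dtype=bool)
    for start, end in intervals:
        covered[start - 1 : end] = True
    return 100.0 * covered.sum() / query_len


def dense_mcl_step(m: np.ndarray, inflation: float, prune: float) -> np.ndarray:
    """One MCL iteration in dense arithmetic: expand, inflate, prune, normalize."""
    expanded = m @ m
    inflated = expanded**inflation
    inflated[inflated < prune] = 0.0
    sums = inflated.sum(axis=0)
    sums[sums == 0.0] = 1.0
    return inflated / sums


def dense_mcl_partition(
    adjacency: np.ndarray,
    inflation: float,
    prune: float = 1e-5,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> set[frozenset[int]]:
    """Full dense MCL: adjacency (with self-loops on the diagonal) -> partition.

    Interpretation follows the standard row-attractor reading: rows with a
    positive diagonal seed clusters over their positively-weighted columns;
    a multiply-claimed column goes where its mass is largest (ties to the
    first attractor); unclaimed columns are singletons.
    """
    n = adjacency.shape[0]
    sums = adjacency.sum(axis=0).astype(float)
    sums[sums == 0.0] = 1.0
    m = adjacency / sums
    for _ in range(max_iter):
        m_next = dense_mcl_step(m, inflation, prune)
        if np.max(np.abs(m_next - m)) < tol:
            m = m_next
            break
        m = m_next
    assignment: dict[int, tuple[float, int]] = {}
    cluster_of_attractor: dict[int, int] = {}
    next_cluster = 0
    for row in range(n):
        if m[row, row] <= 0:
            continue
        cluster_of_attractor[row] = next_cluster
        for col in range(n):
            mass = m[row, col]
            if mass <= 0:
                continue
            if col not in assignment or mass > assignment[col][0]:
                assignment[col] = (mass, next_cluster)
        next_cluster += 1
    groups: dict[int, set[int]] = {}
    for col, (_, cid) in assignment.items():
        groups.setdefault(cid, set()).add(col)
    partition = {frozenset(g) for g in groups.values()}
    claimed = set(assignment)
    for i in range(n):
        if i not in claimed:
            partition.add(frozenset({i}))
    return partition
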