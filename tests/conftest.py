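import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from cypclass.io_formats import HitRecord, ProteinRecord
from cypclass.simgraph import SimilarityGraph
from cypclass.synth_fixtures import SyntheticSpec, emulate_hits, generate


def make_hit(q="a", s="b", evalue=1e-60, qs=1, qe=100, ident=90.0, alen=100,
             ss=1, se=100, bits=250.0):
    return HitRecord(
        query_id=q, subject_id=s, pct_identity=ident, align_len=alen,
        mismatches=0, gap_opens=0, q_start=qs, q_end=qe, s_start=ss, s_end=se,
        evalue=evalue, bitscore=bits,
    )


def clique_graph(cliques: list[list[str]], bridges=(), weight=1.0):
    """A graph of unit-weight cliques, optionally joined by weak bridges."""
    nodes = [n for c in cliques for n in c]
    edges = {}
    for c in cliques:
        for i in range(len(c)):
            for j in range(i + 1, len(c)):
                a, b = sorted((c[i], c[j]))
                edges[(a, b)] = weight
    for a, b, w in bridges:
        edges[tuple(sorted((a, b)))] = w
    loops = {n: 1.0 for n in nodes}
    for (a, b), w in edges.items():
        loops[a] = max(loops[a], w)
        loops[b] = max(loops[b], w)
    return SimilarityGraph(nodes=nodes, edges=edges, self_loops=loops)


def random_graph(rng: np.random.Generator, n_nodes: int, edge_prob=0.3):
    """Random weighted graph with self-loops, for oracle comparisons."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = {}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                edges[(nodes[i], nodes[j])] = float(rng.uniform(0.1, 10.0))
    loops = {n: 1.0 for n in nodes}
    for (a, b), w in edges.items():
        loops[a] = max(loops[a], w)
        loops[b] = max(loops[b], w)
    return SimilarityGraph(nodes=nodes, edges=edges, self_loops=loops)


@pytest.fixture(scope="session")
def small_proteome():
    """3 planted families x 5 members, short sequences for speed."""
    spec = SyntheticSpec(
        n_families=3, family_sizes=(5, 5, 5), within_identity_target=80.0,
        between_identity_max=25.0, seq_length=120, n_species=3, seed=7,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def small_hits(small_proteome):
    records, _ = small_proteome
    return emulate_hits(records)
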