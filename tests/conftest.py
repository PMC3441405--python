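import networkx as nx
import numpy as np
import pandas as pd
import pytest

from uncoupling.prep import GROUPS, PairedExpressionSet
from uncoupling.semantics import OntologyGraph


def build_graph(edges, terms=None, namespace="toy_process", weights=None):
    """OntologyGraph from (child, parent, relation) triples."""
    g = nx.MultiDiGraph()
    nodes = set(terms or [])
    for c, p, _ in edges:
        nodes |= {c, p}
    for n in sorted(nodes):
        g.add_node(n, name=n, namespace=namespace)
    for c, p, rel in edges:
        g.add_edge(c, p, key=rel)
    kwargs = {} if weights is None else {"weights": weights}
    return OntologyGraph(g, **kwargs)


@pytest.fixture
def sibling_graph():
    """Root with two is_a children A and B (weight 0.8)."""
    return build_graph([("A", "root", "is_a"), ("B", "root", "is_a")])


def make_paired_set(n_genes=20, n_reps=3, seed=0, detection=None):
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"G{i:03d}" for i in range(n_genes)], name="gene_id")
    matrices = {}
    for level, cond in GROUPS:
        matrices[(level, cond)] = pd.DataFrame(
            rng.normal(10, 1, size=(n_genes, n_reps)),
            index=genes,
            columns=[f"{level[:5]}_{cond[:4]}_{r}" for r in range(n_reps)],
        )
    det = None
    if detection is not None:
        det = {k: pd.DataFrame(detection, index=genes, columns=m.columns)
               for k, m in matrices.items()}
    return PairedExpressionSet(matrices, det)


@pytest.fixture
def small_paired_set():
    return make_paired_set()
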