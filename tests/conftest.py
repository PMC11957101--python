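"""Shared fixtures: toy graphs, random typed graphs, small PU datasets."""

from __future__ import annotations

import numpy as np
import pytest

from pugene import KnowledgeGraph, LearnerConfig, SyntheticSpec, make_pu_dataset

NODE_TYPES = ["Disease", "Compound", "Gene", "EFO", "Protein"]


def build_graph(nodes, edges):
    """Graph from (id, type) pairs and (u, v, relation) triples."""
    kg = KnowledgeGraph()
    for nid, ntype in nodes:
        kg.add_node(nid, ntype)
    for u, v, rel in edges:
        kg.add_edge(u, v, rel)
    return kg


def random_typed_graph(rng: np.random.Generator, n_nodes: int = 30,
                       edge_prob: float = 0.12):
    """Random heterogeneous graph; returns (kg, node list, edge tuple set)."""
    nodes = [
        (f"N{i:03d}", NODE_TYPES[rng.integers(len(NODE_TYPES))])
        for i in range(n_nodes)
    ]
    relations = ["rel_a", "rel_b", "rel_c"]
    edges = set()
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                rel = relations[rng.integers(len(relations))]
                edges.add((nodes[i][0], nodes[j][0], rel))
    return build_graph(nodes, sorted(edges)), nodes, edges


@pytest.fixture
def toy_kg():
    """The canonical toy metapath graph.

    D1 reaches G1, G2 through compound C1; G3 has a direct disease edge
    (no compound, so not positive).  Term E1 bridges G1 to G4; E2 links
    only positives G1-G2.
    """
    return build_graph(
        nodes=[
            ("D1", "Disease"), ("C1", "Compound"),
            ("G1", "Gene"), ("G2", "Gene"), ("G3", "Gene"), ("G4", "Gene"),
            ("E1", "EFO"), ("E2", "EFO"),
        ],
        edges=[
            ("D1", "C1", "treats"),
            ("C1", "G1", "targets"), ("C1", "G2", "targets"),
            ("D1", "G3", "associated"),
            ("G1", "E1", "annot"), ("G4", "E1", "annot"),
            ("G1", "E2", "annot"), ("G2", "E2", "annot"),
        ],
    )


@pytest.fixture(scope="session")
def fast_learner():
    """Small gradient-boosting config for plumbing tests."""
    return LearnerConfig(max_depth=3, n_estimators=30)


@pytest.fixture(scope="session")
def small_dataset():
    """Small end-to-end synthetic PU dataset (100 labeled / 200 unlabeled)."""
    spec = SyntheticSpec.from_pool_sizes(
        n_labeled=100, n_unlabeled=200, alpha=0.3, n_terms=40, seed=11
    )
    dataset, truth = make_pu_dataset(spec)
    return dataset, truth
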