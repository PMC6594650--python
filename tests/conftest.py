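"""Shared fixtures and independent oracles used across the test modules."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest

from rbgrp.phylo import DistanceMatrix


def random_tree(rng: np.random.Generator, n_leaves: int) -> dendropy.Tree:
    """A random binary tree with positive branch lengths (labels A, B, ...)."""
    taxa = dendropy.TaxonNamespace()
    labels = [chr(ord("A") + i) if n_leaves <= 26 else f"T{i:02d}"
              for i in range(n_leaves)]
    nodes = []
    for lab in labels:
        nd = dendropy.Node(taxon=taxa.require_taxon(lab))
        nodes.append(nd)
    while len(nodes) > min(3, n_leaves):
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = float(rng.uniform(0.05, 0.5))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for child in nodes:
        root.add_child(child)
        child.edge.length = float(rng.uniform(0.05, 0.5))
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def additive_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Patristic distances computed by explicit root-paths (oracle route)."""
    paths: dict[str, list[tuple[int, float]]] = {}

    def walk(node, acc):
        if node.is_leaf():
            paths[node.taxon.label] = list(acc)
            return
        for child in node.child_nodes():
            walk(child, acc + [(id(child), child.edge.length or 0.0)])

    walk(tree.seed_node, [])
    labels = sorted(paths)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pa = dict(paths[labels[i]])
            pb = dict(paths[labels[j]])
            shared = set(pa) & set(pb)
            dist = sum(v for k, v in pa.items() if k not in shared)
            dist += sum(v for k, v in pb.items() if k not in shared)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(tuple(labels), d)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
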