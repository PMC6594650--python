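"""Distance-based phylogenetics for domain segments.

The pipeline mirrors classic distance phylogenetics of protein families:
p-distances with pairwise deletion (columns with a gap or ``X`` in either
row are dropped per pair), Poisson correction ``d = -ln(1 - p)``,
Saitou-Nei neighbor joining, nonparametric bootstrap over alignment
columns, and contraction of weakly supported edges (support must exceed
50% to survive).  Trees are ``dendropy.Tree`` objects with integer
bootstrap percentages stored as internal-node labels, so standard Newick
tooling applies downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from Bio import SeqIO

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "ZeroComparableError",
    "SaturatedDistanceError",
    "read_alignment_fasta",
    "pairwise_distance",
    "distance_matrix",
    "neighbor_joining",
    "bipartitions",
    "robinson_foulds",
    "BootstrapResult",
    "bootstrap_support",
    "collapse_low_support",
    "read_newick",
    "write_newick",
]

_SKIP = {"-", "X", "?", "."}


class ZeroComparableError(ValueError):
    """No alignment column survives pairwise deletion for a sequence pair."""


class SaturatedDistanceError(ValueError):
    """p-distance >= 1: the Poisson correction is infinite."""


@dataclass(frozen=True)
class Alignment:
    names: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names/rows length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows have unequal lengths")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.names)


def read_alignment_fasta(path: str | Path) -> Alignment:
    names, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.description.strip())
        rows.append(str(rec.seq).upper())
    return Alignment(tuple(names), tuple(rows))


def pairwise_distance(row_a: str, row_b: str, correction: str = "poisson") -> float:
    """Distance between two aligned rows under pairwise deletion.

    ``correction="p"`` returns the raw proportion of differing sites;
    ``"poisson"`` applies d = -ln(1 - p).
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows have different lengths")
    compared = mismatch = 0
    for a, b in zip(row_a.upper(), row_b.upper()):
        if a in _SKIP or b in _SKIP:
            continue
        compared += 1
        mismatch += a != b
    if compared == 0:
        raise ZeroComparableError("no comparable sites after pairwise deletion")
    p = mismatch / compared
    if correction == "p":
        return p
    if correction == "poisson":
        if p >= 1.0:
            raise SaturatedDistanceError(f"p = {p}: Poisson distance infinite")
        return -math.log1p(-p)
    raise ValueError(f"unknown correction {correction!r}")


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # (n, n), symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite distances")
        if np.any(v < 0):
            raise ValueError("negative distances")
        if not np.allclose(v, v.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("diagonal not zero")
        object.__setattr__(self, "values", v)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def distance_matrix(alignment: Alignment, correction: str = "poisson") -> DistanceMatrix:
    n = len(alignment)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(
                alignment.rows[i], alignment.rows[j], correction
            )
    return DistanceMatrix(tuple(alignment.names), d)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei agglomeration on the Q criterion.

    Q ties are broken toward the lexicographically smallest pair of cluster
    representative labels (the smallest leaf label inside each cluster), so
    the output is deterministic.  Negative branch lengths are clamped to
    zero with the clamped amount shifted onto the sibling edge, as MEGA
    does.  The returned tree is unrooted: its seed node is the final
    trifurcation (bifurcation for n = 2).
    """
    labels = dm.labels
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    taxa = dendropy.TaxonNamespace()
    nodes: dict[int, dendropy.Node] = {}
    rep: dict[int, str] = {}
    for i, lab in enumerate(labels):
        nd = dendropy.Node(taxon=taxa.require_taxon(lab))
        nodes[i] = nd
        rep[i] = lab
    dist: dict[tuple[int, int], float] = {}

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(dm.values[i, j])

    active = list(range(n))
    next_id = n
    while len(active) > 3:
        m = len(active)
        # fsum: exactly rounded, so join choices cannot depend on the
        # accumulation order induced by the input label order
        r = {i: math.fsum(get(i, k) for k in sorted(active) if k != i)
             for i in active}
        best_key = None
        best_pair = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                key = (q, tuple(sorted((rep[i], rep[j]))))
                if best_key is None or key < best_key:
                    best_key, best_pair = key, (i, j)
        i, j = best_pair  # type: ignore[misc]
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        nodes[next_id] = parent
        rep[next_id] = min(rep[i], rep[j])
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (get(i, k) + get(j, k) - dij)
            dist[(min(k, next_id), max(k, next_id))] = max(dk, 0.0)
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    root = dendropy.Node()
    if len(active) == 2:
        i, j = active
        half = get(i, j) / 2.0
        for k, ln in ((i, half), (j, half)):
            root.add_child(nodes[k])
            nodes[k].edge.length = ln
    else:
        i, j, k = active
        li = 0.5 * (get(i, j) + get(i, k) - get(j, k))
        lj = 0.5 * (get(i, j) + get(j, k) - get(i, k))
        lk = 0.5 * (get(i, k) + get(j, k) - get(i, j))
        for c, ln in ((i, li), (j, lj), (k, lk)):
            root.add_child(nodes[c])
            nodes[c].edge.length = max(ln, 0.0)

    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


# ---------------------------------------------------------------------------
# bipartitions, bootstrap, collapse


def _leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions, each as its canonical side.

    The canonical side is the one *not* containing the alphabetically first
    leaf, so the same split compares equal across differently rooted trees.
    """
    all_leaves = _leaf_labels(tree)
    anchor = min(all_leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if anchor not in below else all_leaves - below
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side)
    return out


def robinson_foulds(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Unweighted RF distance via symmetric difference of bipartition sets."""
    if _leaf_labels(tree_a) != _leaf_labels(tree_b):
        raise ValueError("trees have different leaf sets")
    return len(bipartitions(tree_a) ^ bipartitions(tree_b))


@dataclass
class BootstrapResult:
    tree: dendropy.Tree
    n_replicates: int
    n_redrawn: int


def bootstrap_support(
    alignment: Alignment,
    n_replicates: int = 1000,
    seed: int | None = None,
    correction: str = "poisson",
    max_redraws: int | None = None,
) -> BootstrapResult:
    """NJ tree from the full alignment with bootstrap supports on edges.

    Columns are resampled with replacement to the original length; each
    replicate gets its own NJ tree and the support of an internal edge is
    the rounded percentage of replicates containing the same leaf
    bipartition.  Replicates whose distances are incomputable (all-gap pair
    or saturated Poisson distance) are redrawn and counted.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    main = neighbor_joining(distance_matrix(alignment, correction))
    counts: dict[frozenset[str], int] = {b: 0 for b in bipartitions(main)}
    L = alignment.n_sites
    if max_redraws is None:
        max_redraws = 10 * n_replicates + 100
    done = redrawn = 0
    while done < n_replicates:
        cols = rng.integers(0, L, size=L)
        rows = tuple("".join(row[c] for c in cols) for row in alignment.rows)
        try:
            dm = distance_matrix(Alignment(alignment.names, rows), correction)
        except (ZeroComparableError, SaturatedDistanceError):
            redrawn += 1
            if redrawn > max_redraws:
                raise RuntimeError("too many incomputable bootstrap replicates")
            continue
        rep_tree = neighbor_joining(dm)
        for b in bipartitions(rep_tree):
            if b in counts:
                counts[b] += 1
        done += 1

    all_leaves = _leaf_labels(main)
    anchor = min(all_leaves)
    for node in main.preorder_node_iter():
        if node is main.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if anchor not in below else all_leaves - below
        if side in counts:
            node.label = str(round(100.0 * counts[side] / n_replicates))
    return BootstrapResult(main, n_replicates, redrawn)


def collapse_low_support(tree: dendropy.Tree, threshold: int = 50) -> dendropy.Tree:
    """Contract internal edges whose support does not exceed *threshold*.

    Support strictly greater than the threshold survives (a 50% edge is
    collapsed at the default).  The input tree is left untouched.
    """
    out = tree.clone(depth=1)
    to_collapse = []
    for node in out.preorder_node_iter():
        if node is out.seed_node or node.is_leaf():
            continue
        if node.label is None:
            continue
        if int(node.label) <= threshold:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return out


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", suppress_internal_node_taxa=True
    )


def write_newick(tree: dendropy.Tree, path: str | Path) -> Path:
    path = Path(path)
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return path
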