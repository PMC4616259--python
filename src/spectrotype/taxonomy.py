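"""Binary-fingerprint matrices, UPGMA dendrograms, bootstrap supports.

Strain main spectra are coded as presence/absence characters over integer-Da
bins; the mean character difference (normalized Hamming distance) feeds a
deterministic UPGMA agglomeration (ties broken by the lexicographically
smallest member-label pair) whose node heights are half the merge distance,
so every tree is ultrametric. Clade supports come from a standard Felsenstein
column bootstrap mapped onto the original tree's bipartitions. Topologies are
compared by the Robinson-Foulds distance over nontrivial unrooted splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError


@dataclass
class Node:
    """Tree node; a tree is its root Node. ``length`` is the edge above."""

    name: str | None = None
    children: list = field(default_factory=list)
    length: float = 0.0
    height: float = 0.0
    support: float | None = None

    def leaves(self) -> list["Node"]:
        if not self.children:
            return [self]
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def clades(self, include_root: bool = False) -> list[frozenset]:
        """Leaf-name sets of internal nodes (root excluded by default)."""
        out = []
        stack = [(self, True)]
        while stack:
            node, is_root = stack.pop()
            if node.children:
                if include_root or not is_root:
                    out.append(frozenset(node.leaf_names()))
                stack.extend((c, False) for c in node.children)
        return out

    def splits(self) -> set[frozenset]:
        """Nontrivial unrooted bipartitions as {side, complement} pairs."""
        all_leaves = frozenset(self.leaf_names())
        out: set[frozenset] = set()
        for clade in self.clades(include_root=False):
            other = all_leaves - clade
            if len(clade) >= 2 and len(other) >= 2:
                out.add(frozenset((clade, other)))
        return out


# alias used throughout the docs: a TaxonTree is simply the root Node
TaxonTree = Node


@dataclass
class BinaryMatrix:
    """Taxa x integer-Da-bin presence/absence character matrix."""

    taxa: list[str]
    bins: np.ndarray
    cells: np.ndarray

    def __post_init__(self):
        self.bins = np.asarray(self.bins, dtype=int)
        self.cells = np.asarray(self.cells, dtype=bool)
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValidationError(f"duplicate taxon labels: {dupes}")
        if self.cells.shape != (len(self.taxa), self.bins.size):
            raise ValidationError("cell matrix shape does not match taxa x bins")
        empty = ~self.cells.any(axis=0)
        if empty.any():  # drop characters absent in every taxon
            self.bins = self.bins[~empty]
            self.cells = self.cells[:, ~empty]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells.astype(int), index=self.taxa, columns=self.bins)


def binary_matrix(msps: list) -> BinaryMatrix:
    """Code main spectra as a binary character matrix over observed bins."""
    if len(msps) < 2:
        raise ValidationError("a character matrix (and a tree) needs >= 2 taxa")
    taxa = [m.label for m in msps]
    bins = np.array(sorted({int(b) for m in msps for b in m.mz}), dtype=int)
    cells = np.zeros((len(taxa), bins.size), dtype=bool)
    lookup = {b: i for i, b in enumerate(bins)}
    for row, msp in enumerate(msps):
        for b in msp.mz:
            cells[row, lookup[int(b)]] = True
    return BinaryMatrix(taxa, bins, cells)


def _hamming(cells: np.ndarray) -> np.ndarray:
    x = cells.astype(np.int16)
    return (x[:, None, :] != x[None, :, :]).mean(axis=2)


def mean_character_distance(m: BinaryMatrix) -> pd.DataFrame:
    """Mean character difference: fraction of characters where rows differ."""
    return pd.DataFrame(_hamming(m.cells), index=m.taxa, columns=m.taxa)


def upgma(d, labels: list[str] | None = None) -> Node:
    """UPGMA agglomeration with deterministic label-order tie-breaking.

    ``d`` is a symmetric zero-diagonal matrix (DataFrame or array+labels).
    Cluster-to-cluster distance follows the size-weighted arithmetic-mean
    update; node heights are half the merge distance (ultrametric). Among
    equally close pairs the one whose (smallest member label, partner
    smallest member label) sorts first is merged.
    """
    if isinstance(d, pd.DataFrame):
        labels = list(d.index)
        dist = d.to_numpy(dtype=float)
    else:
        dist = np.asarray(d, dtype=float)
        if labels is None:
            labels = [f"T{i}" for i in range(dist.shape[0])]
    n = dist.shape[0]
    if dist.shape != (n, n) or n < 2:
        raise ValidationError("distance matrix must be square with >= 2 taxa")
    if np.isnan(dist).any():
        raise ValidationError("distance matrix contains NaN")
    if (dist < 0).any():
        raise ValidationError("distance matrix contains negative values")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValidationError("distance matrix is not symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-12):
        raise ValidationError("distance matrix diagonal must be zero")

    clusters: dict[int, dict] = {
        i: {"node": Node(name=labels[i]), "size": 1, "tag": labels[i]}
        for i in range(n)
    }
    dmat = {frozenset((i, j)): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(clusters) > 1:
        best = None
        for key, value in dmat.items():
            i, j = sorted(key, key=lambda k: clusters[k]["tag"])
            cand = (value, clusters[i]["tag"], clusters[j]["tag"], i, j)
            if best is None or cand[:3] < best[:3]:
                best = cand
        dmin, _, _, i, j = best
        ci, cj = clusters.pop(i), clusters.pop(j)
        height = dmin / 2.0
        for child in (ci, cj):
            child["node"].length = height - child["node"].height
        parent = Node(children=[ci["node"], cj["node"]], height=height)
        size = ci["size"] + cj["size"]
        for k in clusters:
            dk = (
                ci["size"] * dmat.pop(frozenset((i, k)))
                + cj["size"] * dmat.pop(frozenset((j, k)))
            ) / size
            dmat[frozenset((next_id, k))] = dk
        dmat.pop(frozenset((i, j)), None)
        clusters[next_id] = {
            "node": parent,
            "size": size,
            "tag": min(ci["tag"], cj["tag"]),
        }
        next_id += 1
    return next(iter(clusters.values()))["node"]


def bootstrap_support(
    m: BinaryMatrix, n_reps: int = 1000, seed: int | None = None
) -> Node:
    """UPGMA tree with Felsenstein column-bootstrap clade supports.

    Characters are resampled with replacement (same count) ``n_reps`` times;
    each internal node of the original tree is annotated with the percentage
    of replicate trees containing its clade. Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    if len(m.taxa) < 3:
        raise ParameterError("bootstrap needs at least 3 taxa")
    rng = np.random.default_rng(seed)
    tree = upgma(mean_character_distance(m))
    targets = tree.clades(include_root=False)
    counts = {clade: 0 for clade in targets}
    n_chars = m.cells.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, n_chars, size=n_chars)
        rep_cells = m.cells[:, cols]
        rep_tree = upgma(pd.DataFrame(_hamming(rep_cells), index=m.taxa, columns=m.taxa))
        rep_clades = set(rep_tree.clades(include_root=False))
        for clade in targets:
            if clade in rep_clades:
                counts[clade] += 1

    def annotate(node: Node, is_root: bool) -> None:
        if node.children:
            if not is_root:
                node.support = 100.0 * counts[frozenset(node.leaf_names())] / n_reps
            for child in node.children:
                annotate(child, False)

    annotate(tree, True)
    return tree


def compare_topology(a: Node, b: Node) -> dict:
    """Robinson-Foulds distance between two trees on the same leaf set.

    Returns the count of nontrivial unrooted bipartitions present in exactly
    one tree, plus the number shared; identical topologies give rf 0.
    """
    la, lb = set(a.leaf_names()), set(b.leaf_names())
    if la != lb:
        only_a, only_b = sorted(la - lb), sorted(lb - la)
        raise ValidationError(
            f"leaf sets differ (only in first: {only_a}; only in second: {only_b})"
        )
    sa, sb = a.splits(), b.splits()
    return {
        "rf_distance": len(sa ^ sb),
        "shared_bipartitions": len(sa & sb),
    }


def missing_truth_clades(tree: Node, truth: Node) -> int:
    """Count clades of a (possibly multifurcating) truth tree absent from ``tree``.

    0 means the generating taxonomy is fully recovered; the symmetric RF
    distance is not informative here because a binary tree always resolves
    more clades than a multifurcating truth.
    """
    la, lb = set(tree.leaf_names()), set(truth.leaf_names())
    if la != lb:
        raise ValidationError("leaf sets differ between tree and truth")
    have = set(tree.clades(include_root=True))
    want = {
        c for c in truth.clades(include_root=False) if 2 <= len(c) < len(lb)
    }
    return len(want - have)
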