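"""Pan-genome and core-genome phylogenies plus tree comparison.

The pan-genome tree is a parsimony tree on the binarised pan-matrix: a
neighbor-joining start tree on Hamming distances refined by
nearest-neighbor-interchange hill climbing under Fitch parsimony length, with
bipartition bootstrap supports.  The core-genome tree is neighbor joining on
p-distances of the concatenated, gap-masked, variable columns of the core
alignments (a distance stand-in for a full ML protein tree).  Tree congruence
is scored by the Robinson-Foulds bipartition distance and the branch-length
K score (least-squares optimal rescaling of the second tree).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .trees import Tree

__all__ = ["binary_encode", "to_at_rows", "parsimony_tree", "fitch_length",
           "concat_and_mask", "SuperMatrix", "distance_tree", "compare_trees",
           "neighbor_joining"]


# ----------------------------------------------------------- binary encoding
def binary_encode(pan_matrix: pd.DataFrame) -> pd.DataFrame:
    """Presence/absence view of a pan-matrix: 1 wherever abundance >= 1."""
    if (pan_matrix.to_numpy() < 0).any():
        raise ValueError("pan-matrix abundances must be non-negative")
    return (pan_matrix > 0).astype(int)


def to_at_rows(binary: pd.DataFrame) -> dict[str, str]:
    """Cosmetic A/T export (0 -> 'A', 1 -> 'T') for external parsimony tools."""
    chars = np.array(["A", "T"])
    return {g: "".join(chars[row.to_numpy()]) for g, row in binary.iterrows()}


# ------------------------------------------------------------ Fitch scoring
def fitch_length(tree: Tree, matrix: pd.DataFrame) -> int:
    """Unit-cost parsimony length of a 0/1 character matrix on a tree.

    Uses Hartigan's bottom-up rule (exact for multifurcations too, so the
    trifurcating root of an unrooted representation is scored correctly).
    """
    data = matrix.to_numpy()
    n_chars = data.shape[1]
    taxon_row = {t: i for i, t in enumerate(matrix.index)}
    length = np.zeros(n_chars, dtype=int)
    masks: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf():
            obs = data[taxon_row[node.label]]
            masks[id(node)] = np.where(obs > 0, 2, 1).astype(np.uint8)
        else:
            c0 = np.zeros(n_chars, dtype=np.int32)
            c1 = np.zeros(n_chars, dtype=np.int32)
            for child in node.children:
                m = masks[id(child)]
                c0 += m & 1
                c1 += m >> 1
            top = np.maximum(c0, c1)
            length += len(node.children) - top
            b = (np.where(c0 == top, 1, 0) | np.where(c1 == top, 2, 0))
            masks[id(node)] = b.astype(np.uint8)
    return int(length.sum())


# ------------------------------------------------------------------ NJ start
def neighbor_joining(dm: pd.DataFrame) -> Tree:
    """Neighbor joining via scikit-bio; negative branch lengths are clamped to
    zero with the deficit moved onto the sibling edge (path lengths preserved)."""
    ids = [str(i) for i in dm.index]
    sk = _skbio_nj(DistanceMatrix(dm.to_numpy(), ids))
    tree = Tree.from_newick(str(sk))
    for node in tree.postorder():
        if node is tree.root or node.length is None or node.length >= 0:
            continue
        deficit = node.length
        node.length = 0.0
        siblings = [c for c in node.parent.children if c is not node]
        if siblings and siblings[0].length is not None:
            siblings[0].length = max(0.0, siblings[0].length + deficit)
    return tree


def _hamming(binary: pd.DataFrame) -> pd.DataFrame:
    x = binary.to_numpy()
    d = (x[:, None, :] != x[None, :, :]).mean(axis=2)
    return pd.DataFrame(d, index=binary.index, columns=binary.index)


# ------------------------------------------------------------------ NNI moves
def _internal_edges(tree: Tree):
    return [n for n in tree.postorder()
            if not n.is_leaf() and n is not tree.root]


def _swap(x, c):
    px, pc = x.parent, c.parent
    ix, ic = px.children.index(x), pc.children.index(c)
    px.children[ix], pc.children[ic] = c, x
    x.parent, c.parent = pc, px


def _canonical_newick(tree: Tree) -> str:
    def emit(node) -> str:
        if node.is_leaf():
            return node.label or ""
        return "(" + ",".join(sorted(emit(c) for c in node.children)) + ")"

    return emit(tree.root)


def parsimony_tree(binary: pd.DataFrame, n_bootstrap: int = 1000,
                   seed: int = 0) -> Tree:
    """Heuristic maximum-parsimony tree of a binary character matrix.

    NJ on Hamming distances gives the start tree; NNI hill climbing under
    Fitch length runs until a full sweep brings no improvement (ties between
    equally good neighbours break on canonical newick order).  Supports are
    bipartition frequencies (percent, rounded) over ``n_bootstrap``
    column-resampled replicates, each re-analysed the same way.
    """
    if binary.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    binary = binary.set_axis(binary.index.map(str))
    tree = _search(binary)
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        counts: dict[frozenset, int] = {}
        n_cols = binary.shape[1]
        for _ in range(n_bootstrap):
            cols = rng.integers(n_cols, size=n_cols)
            rep = _search(binary.iloc[:, cols])
            for split in rep.bipartitions():
                counts[split] = counts.get(split, 0) + 1
        below: dict[int, frozenset] = {}
        all_leaves = frozenset(binary.index.astype(str))
        ref = min(all_leaves)
        for node in tree.postorder():
            if node.is_leaf():
                below[id(node)] = frozenset([node.label])
                continue
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
            if node is tree.root:
                continue
            side = below[id(node)]
            if ref in side:
                side = all_leaves - side
            if len(side) < 2 or len(all_leaves - side) < 2:
                continue
            node.support = round(100.0 * counts.get(side, 0) / n_bootstrap)
    return tree


def _search(binary: pd.DataFrame) -> Tree:
    tree = neighbor_joining(_hamming(binary))
    best = fitch_length(tree, binary)
    improved = True
    while improved:
        improved = False
        candidates: list[tuple[int, str, object]] = []
        for v in _internal_edges(tree):
            u = v.parent
            x = next(c for c in u.children if c is not v)
            for c in list(v.children):
                _swap(x, c)
                score = fitch_length(tree, binary)
                if score < best:
                    candidates.append((score, _canonical_newick(tree), (x, c)))
                _swap(c, x)
        if candidates:
            candidates.sort(key=lambda t: (t[0], t[1]))
            score, _, (x, c) = candidates[0]
            _swap(x, c)
            best = score
            improved = True
    return tree


# ------------------------------------------------- core alignment supermatrix
@dataclass
class SuperMatrix:
    """Concatenated core alignments after gap masking and constant-site removal."""

    taxa: list[str]
    rows: dict[str, str]          # taxon -> masked variable columns
    partitions: list[tuple[str, int, int]]   # (cluster, start, end) pre-mask
    n_concatenated: int
    n_after_gap_mask: int
    n_variable: int


def concat_and_mask(alignments: dict[str, dict[str, str]]) -> SuperMatrix:
    """Concatenate per-cluster alignments, drop every column with a gap in any
    taxon, then drop constant columns."""
    if not alignments:
        raise ValueError("no alignments given")
    first = next(iter(alignments.values()))
    taxa = sorted(first)
    parts, offset = [], 0
    chunks = {t: [] for t in taxa}
    for cluster in alignments:
        aln = alignments[cluster]
        if sorted(aln) != taxa:
            missing = set(taxa) ^ set(aln)
            raise ValueError(f"cluster {cluster!r}: genome rows differ ({missing})")
        width = len(next(iter(aln.values())))
        if any(len(s) != width for s in aln.values()):
            raise ValueError(f"cluster {cluster!r}: ragged alignment")
        for t in taxa:
            chunks[t].append(aln[t])
        parts.append((cluster, offset, offset + width))
        offset += width
    mat = np.array([list("".join(chunks[t])) for t in taxa])
    no_gap = ~(mat == "-").any(axis=0)
    mat2 = mat[:, no_gap]
    variable = (mat2 != mat2[0]).any(axis=0)
    kept = mat2[:, variable]
    rows = {t: "".join(kept[i]) for i, t in enumerate(taxa)}
    return SuperMatrix(taxa=taxa, rows=rows, partitions=parts,
                       n_concatenated=offset,
                       n_after_gap_mask=int(no_gap.sum()),
                       n_variable=int(variable.sum()))


def distance_tree(sm: SuperMatrix) -> Tree:
    """NJ tree on pairwise p-distances of the supermatrix rows."""
    if len(sm.taxa) < 3:
        raise ValueError("need at least 3 taxa")
    if sm.n_variable == 0:
        raise ValueError("empty supermatrix (no variable gap-free columns)")
    mat = np.array([list(sm.rows[t]) for t in sm.taxa])
    d = (mat[:, None, :] != mat[None, :, :]).mean(axis=2)
    return neighbor_joining(pd.DataFrame(d, index=sm.taxa, columns=sm.taxa))


# ------------------------------------------------------------ tree comparison
def compare_trees(t1: Tree, t2: Tree) -> tuple[int, float]:
    """(Robinson-Foulds distance, K score).

    The K score rescales t2's branch lengths by the least-squares optimal
    factor K* = sum(b1*b2)/sum(b2^2) over the union of bipartitions (trivial
    leaf splits included; splits absent from a tree enter with length 0) and
    reports sqrt(sum((K*b2 - b1)^2)).
    """
    if set(t1.leaf_labels()) != set(t2.leaf_labels()):
        raise ValueError("trees have different leaf sets")
    s1, s2 = t1.bipartitions(), t2.bipartitions()
    rf = len(set(s1) ^ set(s2))
    f1 = t1.bipartitions(include_trivial=True)
    f2 = t2.bipartitions(include_trivial=True)
    splits = sorted(set(f1) | set(f2), key=lambda s: sorted(s))
    b1 = np.array([f1.get(s, 0.0) for s in splits])
    b2 = np.array([f2.get(s, 0.0) for s in splits])
    denom = float(b2 @ b2)
    k = float(b1 @ b2) / denom if denom > 0 else 1.0
    score = float(np.sqrt(((k * b2 - b1) ** 2).sum()))
    return rf, score
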