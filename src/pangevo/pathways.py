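"""Genome x KO pathway-abundance matrices and Ward/Manhattan clustering.

The clustering reproduces the behaviour of heatmap web tools that feed an
arbitrary distance matrix (here Manhattan/L1 between genome rows) into the
Lance-Williams Ward update.  Note that Ward's method formally presumes
squared Euclidean distances; applying the update to raw L1 distances is the
tool's (and therefore this module's) documented behaviour, not a claim of
variance-minimising optimality.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = ["build_pathway_matrix", "ward_manhattan", "linkage_to_newick",
           "leaf_order"]


def build_pathway_matrix(annot: dict[str, str], membership: dict[str, str],
                         ko_panel: list[str],
                         genomes: list[str] | None = None) -> pd.DataFrame:
    """Genome x KO abundance counts from gene->KO and gene->genome maps.

    KOs absent from every genome are kept as zero columns and flagged in
    ``DataFrame.attrs['empty_kos']``.
    """
    if not ko_panel:
        raise ValueError("empty KO panel")
    if genomes is None:
        genomes = sorted(set(membership.values()))
    pm = pd.DataFrame(0, index=list(genomes), columns=list(ko_panel), dtype=int)
    for gene, ko in annot.items():
        if ko not in pm.columns or gene not in membership:
            continue
        pm.loc[membership[gene], ko] += 1
    pm.attrs["empty_kos"] = [ko for ko in ko_panel if pm[ko].sum() == 0]
    return pm


def ward_manhattan(matrix: pd.DataFrame, mode: str = "abundance") -> np.ndarray:
    """Agglomerative clustering of genome rows: L1 distances + Ward update.

    ``mode='presence'`` binarises abundances first.  Returns a scipy-style
    linkage matrix (n-1 x 4: left, right, height, size) built by the
    Lance-Williams Ward recursion applied directly to the Manhattan
    distances, with ties broken on the smallest (i, j) index pair.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least two rows to cluster")
    x = matrix.to_numpy(dtype=float)
    if mode == "presence":
        x = (x > 0).astype(float)
    elif mode != "abundance":
        raise ValueError("mode must be 'abundance' or 'presence'")
    n = x.shape[0]
    d = squareform(pdist(x, metric="cityblock"))
    size = {i: 1 for i in range(n)}
    active = list(range(n))
    dist = {frozenset((i, j)): d[i, j]
            for i in range(n) for j in range(i + 1, n)}
    merges = []
    nxt = n
    while len(active) > 1:
        best = min(((dist[frozenset((i, j))], i, j)
                    for k, i in enumerate(active) for j in active[k + 1:]),
                   key=lambda t: (t[0], min(t[1], t[2]), max(t[1], t[2])))
        h, i, j = best
        ni, nj = size[i], size[j]
        merges.append([min(i, j), max(i, j), h, ni + nj])
        for k in active:
            if k in (i, j):
                continue
            nk = size[k]
            dki = dist.pop(frozenset((k, i)))
            dkj = dist.pop(frozenset((k, j)))
            dij = h
            upd = ((ni + nk) * dki + (nj + nk) * dkj - nk * dij) / (ni + nj + nk)
            dist[frozenset((k, nxt))] = upd
        del dist[frozenset((i, j))]
        active = [k for k in active if k not in (i, j)] + [nxt]
        size[nxt] = ni + nj
        nxt += 1
    return np.array(merges, dtype=float)


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Dendrogram as a Newick string with merge heights as node depths."""
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    text = {i: labels[i] for i in range(n)}
    for step, (a, b, h, _) in enumerate(linkage):
        a, b = int(a), int(b)
        la = max(0.0, h - height[a])
        lb = max(0.0, h - height[b])
        text[n + step] = f"({text[a]}:{la:g},{text[b]}:{lb:g})"
        height[n + step] = h
    return text[n + len(linkage) - 1] + ";"


def leaf_order(linkage: np.ndarray, labels: list[str]) -> list[str]:
    """Dendrogram leaf order (left-to-right), for ordered heatmap export."""
    n = len(labels)

    def walk(idx: int) -> list[int]:
        if idx < n:
            return [idx]
        a, b = int(linkage[idx - n][0]), int(linkage[idx - n][1])
        return walk(a) + walk(b)

    return [labels[i] for i in walk(n + len(linkage) - 1)]
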