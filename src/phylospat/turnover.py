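"""Range-weighted phylogenetic turnover between cells and UPGMA clustering.

Each branch contributes its length divided by its range size, so branches
confined to few cells count more toward similarity than widespread ones.
The pairwise index defaults to the Sørensen complement
``1 - 2A / (2A + B + C)`` on those weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import BranchRangeIndex

__all__ = [
    "rw_turnover_pair",
    "turnover_matrix",
    "Dendrogram",
    "upgma",
    "cut_dendrogram",
]

_FORMS = ("sorensen", "jaccard", "simpson")


def _branch_weights(index: BranchRangeIndex) -> np.ndarray:
    r = index.range_sizes.astype(float)
    return np.where(r > 0, index.lengths / np.maximum(r, 1.0), 0.0)


def _dissimilarity(A: float, B: float, C: float, form: str) -> float:
    if form == "sorensen":
        denom = 2 * A + B + C
    elif form == "jaccard":
        denom = A + B + C
    elif form == "simpson":
        denom = A + min(B, C)
    else:
        raise ValueError(f"unknown form {form!r}; choose from {_FORMS}")
    if denom == 0:
        raise ValueError("cell with empty branch set")
    shared = 2 * A if form == "sorensen" else A
    return 1.0 - shared / denom


def rw_turnover_pair(
    c_i: int, c_j: int, index: BranchRangeIndex, form: str = "sorensen"
) -> float:
    """Range-weighted turnover between two cells (row indices of the index)."""
    w = _branch_weights(index)
    bi = index.cell_by_branch[c_i]
    bj = index.cell_by_branch[c_j]
    A = float(w[bi & bj].sum())
    B = float(w[bi & ~bj].sum())
    C = float(w[~bi & bj].sum())
    return _dissimilarity(A, B, C, form)


def turnover_matrix(
    cells, index: BranchRangeIndex, form: str = "sorensen"
) -> pd.DataFrame:
    """All-pairs turnover for the given cells.

    ``cells`` may be row indices, (i, j) cell tuples, or cell-id strings.
    Returns a square symmetric DataFrame in [0, 1] with zero diagonal,
    labelled by cell-id strings.
    """
    from .grid_io import cell_id_str, parse_cell_id

    pos = {c: k for k, c in enumerate(index.cells)}
    rows = []
    labels = []
    for c in cells:
        if isinstance(c, str):
            c = parse_cell_id(c)
        if isinstance(c, tuple):
            if c not in pos:
                raise KeyError(f"cell {c} not in index")
            rows.append(pos[c])
            labels.append(cell_id_str(c))
        else:
            rows.append(int(c))
            labels.append(cell_id_str(index.cells[int(c)]))
    if len(rows) < 2:
        raise ValueError("need at least 2 cells for a turnover matrix")
    w = _branch_weights(index)
    Bw = index.cell_by_branch[rows].astype(float) * w  # (n, n_branches)
    Bb = index.cell_by_branch[rows].astype(float)
    A = Bw @ Bb.T  # shared weight
    tot = Bw.sum(axis=1)
    if np.any(tot == 0):
        raise ValueError("cell with empty branch set")
    n = len(rows)
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            Ai = A[a, b]
            D[a, b] = D[b, a] = _dissimilarity(Ai, tot[a] - Ai, tot[b] - Ai, form)
    return pd.DataFrame(D, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Rooted binary merge tree over cells.

    ``merges`` is an (n-1, 2) int array of cluster ids (leaves are
    0..n-1, the i-th merge creates cluster n+i); ``heights`` are the merge
    heights (half the inter-cluster distance), non-decreasing.
    """

    leaves: list  # leaf labels in input order
    merges: np.ndarray  # (n-1, 2) int
    heights: np.ndarray  # (n-1,) float

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def members(self) -> list[list[int]]:
        """Leaf index sets per cluster id (leaves then merge clusters)."""
        out = [[i] for i in range(self.n_leaves)]
        for a, b in self.merges:
            out.append(out[a] + out[b])
        return out

    def to_newick(self) -> str:
        n = self.n_leaves
        height_of = np.concatenate([np.zeros(n), self.heights])
        label = [str(v) for v in self.leaves]
        for k, (a, b) in enumerate(self.merges):
            h = self.heights[k]
            la = height_of[a]
            lb = height_of[b]
            label.append(f"({label[a]}:{float(h - la)!r},{label[b]}:{float(h - lb)!r})")
        return label[-1] + ";"


def upgma(d: pd.DataFrame | np.ndarray, labels=None) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of a dissimilarity matrix.

    Merges the closest pair at height d/2; the distance from a merged
    cluster to any other is the size-weighted arithmetic mean. Ties are
    broken by the lexicographically smallest cluster-id pair, so the
    result is deterministic.
    """
    if isinstance(d, pd.DataFrame):
        labels = list(d.index) if labels is None else list(labels)
        D0 = d.to_numpy(dtype=float)
    else:
        D0 = np.asarray(d, dtype=float)
        labels = list(range(len(D0))) if labels is None else list(labels)
    n = len(D0)
    if D0.shape != (n, n) or n < 2:
        raise ValueError("need a square matrix of size >= 2")
    if not np.allclose(D0, D0.T) or np.any(np.diag(D0) != 0):
        raise ValueError("matrix must be symmetric with zero diagonal")

    dist = {}  # (id_a, id_b) with a < b -> distance
    active = list(range(n))
    size = {i: 1 for i in range(n)}
    for a in range(n):
        for b in range(a + 1, n):
            dist[(a, b)] = D0[a, b]
    merges = []
    heights = []
    next_id = n
    while len(active) > 1:
        best = min(
            ((dist[(min(a, b), max(a, b))], (min(a, b), max(a, b)))
             for i, a in enumerate(active) for b in active[i + 1:]),
            key=lambda t: (t[0], t[1]),
        )
        dmin, (a, b) = best
        merges.append((a, b))
        heights.append(dmin / 2.0)
        for c in active:
            if c in (a, b):
                continue
            da = dist[(min(a, c), max(a, c))]
            db = dist[(min(b, c), max(b, c))]
            dn = (size[a] * da + size[b] * db) / (size[a] + size[b])
            dist[(min(c, next_id), max(c, next_id))] = dn
        size[next_id] = size[a] + size[b]
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return Dendrogram(labels, np.array(merges, dtype=np.int64), np.array(heights))


def cut_dendrogram(
    dend: Dendrogram, k: int | None = None, h: float | None = None
) -> pd.Series:
    """Cluster labels from cutting the dendrogram into k clusters or at
    height h.

    Labels are integers starting at 0, ordered by decreasing cluster size
    and then by the lexicographically smallest leaf (stable across runs).
    """
    n = dend.n_leaves
    if (k is None) == (h is None):
        raise ValueError("give exactly one of k or h")
    if k is not None:
        if not (1 <= k <= n):
            raise ValueError(f"k must be in [1, {n}]")
        n_merges = n - k
    else:
        n_merges = int(np.sum(dend.heights <= h))
    parent = list(range(n + n_merges))

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for i in range(n_merges):
        a, b = dend.merges[i]
        r = n + i
        parent[find(a)] = r
        parent[find(b)] = r
    groups: dict[int, list[int]] = {}
    for leaf in range(n):
        groups.setdefault(find(leaf), []).append(leaf)
    ordered = sorted(
        groups.values(), key=lambda g: (-len(g), min(str(dend.leaves[i]) for i in g))
    )
    out = pd.Series(index=pd.Index(dend.leaves, name="cell_id"), dtype=int, name="cluster")
    for lab, g in enumerate(ordered):
        for leaf in g:
            out.iloc[leaf] = lab
    return out
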