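"""Per-cell diversity and endemism metrics.

All metrics are driven by a branch-by-cell index: a branch is present in a
cell when at least one of its descendant terminals is, so the "range" of an
internal branch is the union of its descendants' occupied cells.

Metrics
-------
TR   taxon richness (count)
WE   weighted endemism: sum over taxa present of 1/range-size
PD   phylogenetic diversity: sum of branch lengths on root paths of the
     taxa present (the root path is included even for a single-taxon cell)
PE   phylogenetic endemism: as PD but each branch divided by its range size
RPD  PD / PD on a topology-identical tree with all branch lengths equal
RPE  PE / PE on that comparison tree
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid_io import Phylogeny, PresenceMatrix

__all__ = [
    "BranchRangeIndex",
    "build_branch_index",
    "taxon_richness",
    "weighted_endemism",
    "phylogenetic_diversity",
    "phylogenetic_endemism",
    "make_equal_branch_tree",
    "relative_metrics",
    "cell_metrics",
]


@dataclass
class BranchRangeIndex:
    """Branch lengths, branch-by-cell incidence, and branch range sizes.

    Branches are the non-root nodes of the tree; ``branch_taxa`` maps
    terminal branches to matrix columns (used by the null model to
    recompute incidence after a shuffle).
    """

    lengths: np.ndarray  # (n_branches,)
    cell_by_branch: np.ndarray  # bool (n_cells, n_branches)
    branch_taxon: np.ndarray  # bool (n_branches, n_taxa): descendant terminals
    cells: list
    taxa: list

    @property
    def n_branches(self) -> int:
        return len(self.lengths)

    @property
    def range_sizes(self) -> np.ndarray:
        """Occupied-cell count per branch."""
        return self.cell_by_branch.sum(axis=0).astype(np.int64)

    def branch_cell_sets(self) -> list[set]:
        return [set(np.flatnonzero(self.cell_by_branch[:, b])) for b in range(self.n_branches)]


def _branch_taxon_matrix(tree: Phylogeny, taxa: list[str]) -> np.ndarray:
    """Boolean (n_branches, n_taxa) descendant-terminal incidence, with taxa
    in matrix column order."""
    M = tree.node_tip_matrix()  # (n_nodes, n_tips) in tip_indices order
    order = {lab: k for k, lab in enumerate(tree.tip_labels)}
    missing = [t for t in taxa if t not in order]
    if missing:
        raise ValueError(f"matrix taxa absent from tree: {missing}")
    cols = [order[t] for t in taxa]
    return M[1:][:, cols]  # drop the root row


def build_branch_index(tree: Phylogeny, m: PresenceMatrix) -> BranchRangeIndex:
    """Build the branch range index for an aligned tree/matrix pair."""
    if set(tree.tip_labels) != set(m.taxa):
        raise ValueError("tree terminals and matrix taxa differ; align first")
    D = _branch_taxon_matrix(tree, m.taxa)
    cell_by_branch = m.X.astype(np.float32) @ D.T.astype(np.float32) > 0.5
    return BranchRangeIndex(
        lengths=tree.lengths[1:].copy(),
        cell_by_branch=cell_by_branch,
        branch_taxon=D,
        cells=list(m.cells),
        taxa=list(m.taxa),
    )


def taxon_richness(m: PresenceMatrix) -> np.ndarray:
    return m.richness()


def weighted_endemism(m: PresenceMatrix) -> np.ndarray:
    r = m.range_sizes()
    if np.any(r == 0):
        raise ValueError("taxon with zero range size")
    return m.X @ (1.0 / r)


def phylogenetic_diversity(index: BranchRangeIndex) -> np.ndarray:
    return index.cell_by_branch @ index.lengths


def phylogenetic_endemism(index: BranchRangeIndex) -> np.ndarray:
    r = index.range_sizes
    w = np.where(r > 0, index.lengths / np.maximum(r, 1), 0.0)
    return index.cell_by_branch @ w


def make_equal_branch_tree(tree: Phylogeny) -> Phylogeny:
    """Same topology, every branch length = total length / branch count.

    Total tree length is preserved, so RPD/RPE sit around 1. Zero-length
    branches of the original receive the common positive length here —
    topology, not length, defines the comparison tree.
    """
    if tree.n_branches < 1:
        raise ValueError("tree has no branches")
    common = tree.total_length / tree.n_branches
    lengths = np.full(tree.n_nodes, common)
    return tree.with_lengths(lengths)


def relative_metrics(orig: np.ndarray, comp: np.ndarray) -> np.ndarray:
    """Elementwise ratio of a metric to its comparison-tree analogue."""
    orig = np.asarray(orig, float)
    comp = np.asarray(comp, float)
    if orig.shape != comp.shape:
        raise ValueError("metric vectors computed on different cells")
    if np.any(comp == 0):
        raise ZeroDivisionError("comparison-tree metric is zero in some cell")
    return orig / comp


def cell_metrics(tree: Phylogeny, m: PresenceMatrix) -> pd.DataFrame:
    """All per-cell metrics as a DataFrame indexed by cell-id string.

    Columns: x, y, TR, WE, PD, PE, PD_comp, PE_comp, RPD, RPE.
    """
    index = build_branch_index(tree, m)
    comp = make_equal_branch_tree(tree)
    index_c = BranchRangeIndex(
        lengths=comp.lengths[1:].copy(),
        cell_by_branch=index.cell_by_branch,
        branch_taxon=index.branch_taxon,
        cells=index.cells,
        taxa=index.taxa,
    )
    pd_ = phylogenetic_diversity(index)
    pe = phylogenetic_endemism(index)
    pdc = phylogenetic_diversity(index_c)
    pec = phylogenetic_endemism(index_c)
    centers = m.cell_centers()
    out = pd.DataFrame(
        {
            "x": centers[:, 0],
            "y": centers[:, 1],
            "TR": taxon_richness(m),
            "WE": weighted_endemism(m),
            "PD": pd_,
            "PE": pe,
            "PD_comp": pdc,
            "PE_comp": pec,
            "RPD": relative_metrics(pd_, pdc),
            "RPE": relative_metrics(pe, pec),
        },
        index=pd.Index(m.cell_ids, name="cell_id"),
    )
    return out
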