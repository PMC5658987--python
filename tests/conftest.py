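import numpy as np
import pytest

from phylospat.grid_io import GridSpec, Phylogeny, PresenceMatrix

TOY_NEWICK = "((A:1,B:1):1,(C:1,D:4):1);"


@pytest.fixture
def toy_tree() -> Phylogeny:
    return Phylogeny.from_newick(TOY_NEWICK)


@pytest.fixture
def toy_matrix() -> PresenceMatrix:
    # c1={A,B}, c2={B,C}, c3={D}
    X = np.array(
        [
            [1, 1, 0, 0],
            [0, 1, 1, 0],
            [0, 0, 0, 1],
        ],
        dtype=bool,
    )
    return PresenceMatrix([(0, 0), (1, 0), (2, 0)], ["A", "B", "C", "D"], X, GridSpec())


def random_instance(rng: np.random.Generator, n_taxa: int, n_cells: int):
    """A random aligned tree/matrix pair (every taxon occurs somewhere,
    every cell holds something)."""
    from phylospat.synthdata import gen_tree

    tree = gen_tree(n_taxa, int(rng.integers(1 << 30)), regime="phylogram")
    while True:
        X = rng.random((n_cells, n_taxa)) < rng.uniform(0.15, 0.5)
        if X.any(axis=1).all() and X.any(axis=0).all():
            break
    cells = [(i, 0) for i in range(n_cells)]
    m = PresenceMatrix(cells, tree.tip_labels, X, GridSpec())
    return tree, m


def brute_force_pd_pe(tree: Phylogeny, m: PresenceMatrix):
    """Independent per-cell PD/PE oracle: enumerate root paths per present
    terminal, dedupe branches, and recount every branch range by scanning
    all cells x terminals."""
    children = tree.children_lists()
    tip_node = {tree.labels[v]: v for v in tree.tip_indices}

    def root_path(v):
        path = []
        while tree.parent[v] >= 0:
            path.append(v)
            v = tree.parent[v]
        return path

    # branch ranges by brute scan
    desc_tips = {}

    def tips_below(v):
        if v in desc_tips:
            return desc_tips[v]
        if not children[v]:
            out = {tree.labels[v]}
        else:
            out = set()
            for c in children[v]:
                out |= tips_below(c)
        desc_tips[v] = out
        return out

    col = {t: k for k, t in enumerate(m.taxa)}
    branch_range = {}
    for v in range(1, tree.n_nodes):
        cells = set()
        for ci in range(m.n_cells):
            if any(m.X[ci, col[t]] for t in tips_below(v) if t in col):
                cells.add(ci)
        branch_range[v] = len(cells)

    pd_vals = np.zeros(m.n_cells)
    pe_vals = np.zeros(m.n_cells)
    for ci in range(m.n_cells):
        branches = set()
        for k, t in enumerate(m.taxa):
            if m.X[ci, k]:
                branches |= set(root_path(tip_node[t]))
        pd_vals[ci] = sum(tree.lengths[v] for v in branches)
        pe_vals[ci] = sum(tree.lengths[v] / branch_range[v] for v in branches)
    return pd_vals, pe_vals


def enumerate_fixed_marginal(row_sums, col_sums):
    """All binary matrices with the given marginals, as bytes keys."""
    import itertools

    n_cols = len(col_sums)
    out = []
    for rows in itertools.product(
        *[
            [r for r in itertools.product((0, 1), repeat=n_cols) if sum(r) == s]
            for s in row_sums
        ]
    ):
        M = np.array(rows, dtype=np.uint8)
        if list(M.sum(axis=0)) == list(col_sums):
            out.append(M.tobytes())
    return out
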