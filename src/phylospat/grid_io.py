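"""Input/output and gridding: trees, occurrence records, OTU maps, climate
tables, and the rasterized presence matrix that all downstream metrics use.

Coordinates are assumed to be planar, projected, and in metres. No CRS
handling is performed here; reproject before input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "Phylogeny",
    "PresenceMatrix",
    "read_tree",
    "load_occurrences",
    "load_otu_map",
    "apply_otu_map",
    "rasterize_points",
    "align_tree_and_matrix",
    "load_climate",
    "write_climate",
    "write_cell_table",
    "read_cell_table",
    "cell_id_str",
    "parse_cell_id",
]


def cell_id_str(cell: tuple[int, int]) -> str:
    """Serialize a cell index pair as ``"i_j"``."""
    return f"{cell[0]}_{cell[1]}"


def parse_cell_id(cid: str) -> tuple[int, int]:
    i, j = str(cid).split("_")
    return int(i), int(j)


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """An axis-aligned square grid on projected planar coordinates.

    Cells are half-open intervals
    ``[x0 + i*s, x0 + (i+1)*s) x [y0 + j*s, y0 + (j+1)*s)``,
    so a point exactly on an upper cell boundary belongs to the next cell.
    """

    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 15_000.0

    def __post_init__(self) -> None:
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Cell index pair containing point (x, y)."""
        return (
            int(math.floor((x - self.origin_x) / self.cell_size)),
            int(math.floor((y - self.origin_y) / self.cell_size)),
        )

    def cells_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`cell_of`; returns an int array of shape (n, 2)."""
        i = np.floor((np.asarray(x, float) - self.origin_x) / self.cell_size)
        j = np.floor((np.asarray(y, float) - self.origin_y) / self.cell_size)
        return np.stack([i, j], axis=1).astype(np.int64)

    def cell_center(self, cell: tuple[int, int]) -> tuple[float, float]:
        i, j = cell
        return (
            self.origin_x + (i + 0.5) * self.cell_size,
            self.origin_y + (j + 0.5) * self.cell_size,
        )

    def centers_of(self, cells) -> np.ndarray:
        """Centers of an iterable of cell pairs; shape (n, 2)."""
        arr = np.asarray(list(cells), dtype=float)
        if arr.size == 0:
            return arr.reshape(0, 2)
        return np.stack(
            [
                self.origin_x + (arr[:, 0] + 0.5) * self.cell_size,
                self.origin_y + (arr[:, 1] + 0.5) * self.cell_size,
            ],
            axis=1,
        )


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


class Phylogeny:
    """A rooted tree with branch lengths, stored as flat parent/length arrays.

    Nodes are indexed ``0 .. n_nodes-1`` in a topological (preorder) order:
    every node's parent precedes it. Node 0 is the root; the root carries no
    branch (its stored length is 0 and it is excluded from branch sums).
    Polytomies are permitted; terminal labels must be unique; all branch
    lengths must be non-negative.
    """

    def __init__(self, parent: np.ndarray, lengths: np.ndarray, labels: list):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=float)
        self.labels = list(labels)
        self._validate()

    # -- construction -------------------------------------------------------

    def _validate(self) -> None:
        n = len(self.parent)
        if not (len(self.lengths) == n and len(self.labels) == n):
            raise ValueError("parent, lengths, labels must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1 or roots[0] != 0:
            raise ValueError("exactly one root required, at index 0")
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise ValueError("nodes must be ordered parents-first")
        if np.any(np.isnan(self.lengths[1:])):
            raise ValueError("missing branch length on a non-root edge")
        if np.any(self.lengths[1:] < 0):
            raise ValueError("negative branch length")
        self._n_children = np.zeros(n, dtype=np.int64)
        np.add.at(self._n_children, self.parent[1:], 1)
        tips = [self.labels[i] for i in range(n) if self._n_children[i] == 0]
        if any(t is None or t == "" for t in tips):
            raise ValueError("every terminal must be labelled")
        if len(set(tips)) != len(tips):
            dups = sorted({t for t in tips if tips.count(t) > 1})
            raise ValueError(f"duplicate terminal names: {dups}")

    @classmethod
    def from_dendropy(
        cls, tree: dendropy.Tree, missing_length: float | None = None
    ) -> "Phylogeny":
        """Convert a dendropy tree.

        missing_length : value substituted (with a warning) for edges without
            a length; by default a missing non-root length is an error.
        """
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        lengths = np.zeros(len(nodes), dtype=float)
        labels: list = [None] * len(nodes)
        n_missing = 0
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    if missing_length is None:
                        lengths[i] = np.nan
                    else:
                        n_missing += 1
                        lengths[i] = missing_length
                else:
                    lengths[i] = nd.edge.length
            if nd.is_leaf():
                labels[i] = nd.taxon.label if nd.taxon is not None else nd.label
        if n_missing:
            logger.warning(
                "%d edges had no branch length; set to %s", n_missing, missing_length
            )
        return cls(parent, lengths, labels)

    @classmethod
    def from_newick(cls, s: str, **kw) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
        except Exception as exc:
            raise ValueError(f"could not parse newick: {exc}") from exc
        return cls.from_dendropy(tree, **kw)

    # -- basic structure ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def is_tip(self) -> np.ndarray:
        return self._n_children == 0

    @property
    def tip_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def n_branches(self) -> int:
        """Number of branches = non-root nodes."""
        return self.n_nodes - 1

    @property
    def total_length(self) -> float:
        return float(self.lengths[1:].sum())

    def children_lists(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(1, self.n_nodes):
            out[self.parent[v]].append(v)
        return out

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length per terminal label."""
        depth = np.zeros(self.n_nodes)
        for v in range(1, self.n_nodes):
            depth[v] = depth[self.parent[v]] + self.lengths[v]
        return {self.labels[i]: float(depth[i]) for i in self.tip_indices}

    def node_tip_matrix(self) -> np.ndarray:
        """Boolean (n_nodes, n_tips): node v is on the root path of tip t.

        Tip columns follow :attr:`tip_indices` order. Computed in one
        reverse-topological (post-order) pass.
        """
        tips = self.tip_indices
        col = {int(v): k for k, v in enumerate(tips)}
        M = np.zeros((self.n_nodes, len(tips)), dtype=bool)
        for k, v in enumerate(tips):
            M[v, k] = True
        for v in range(self.n_nodes - 1, 0, -1):
            M[self.parent[v]] |= M[v]
        return M

    # -- manipulation -------------------------------------------------------

    def with_lengths(self, lengths: np.ndarray) -> "Phylogeny":
        new = np.asarray(lengths, dtype=float).copy()
        new[0] = 0.0
        return Phylogeny(self.parent.copy(), new, list(self.labels))

    def prune_to(self, names) -> "Phylogeny":
        """Restrict to the given terminal names.

        Internal nodes left with a single kept child are collapsed by summing
        branch lengths; the root is always retained (even if unifurcating
        afterwards), so root-to-tip path lengths of retained terminals are
        preserved exactly.
        """
        keep = set(names)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"terminals not in tree: {sorted(missing)}")
        if not keep:
            raise ValueError("cannot prune to an empty terminal set")
        n = self.n_nodes
        kept_tip = np.array(
            [self.is_tip[v] and self.labels[v] in keep for v in range(n)]
        )
        n_kept = kept_tip.astype(np.int64).copy()
        for v in range(n - 1, 0, -1):
            n_kept[self.parent[v]] += n_kept[v]
        # children (in the induced subtree) per retained-lineage node
        live_children = np.zeros(n, dtype=np.int64)
        for v in range(1, n):
            if n_kept[v] > 0:
                live_children[self.parent[v]] += 1
        is_out = np.zeros(n, dtype=bool)
        is_out[0] = True
        is_out |= kept_tip
        is_out |= (live_children >= 2) & (n_kept > 0)
        # collapse pass-through nodes, accumulating lengths up to the nearest
        # retained ancestor
        anchor = np.zeros(n, dtype=np.int64)
        carry = np.zeros(n, dtype=float)
        for v in range(1, n):
            if n_kept[v] == 0:
                continue
            p = self.parent[v]
            if is_out[p]:
                anchor[v] = p
                carry[v] = self.lengths[v]
            else:
                anchor[v] = anchor[p]
                carry[v] = carry[p] + self.lengths[v]
        order = [v for v in range(n) if is_out[v] and (v == 0 or n_kept[v] > 0)]
        remap = {v: i for i, v in enumerate(order)}
        parent = np.array(
            [-1 if v == 0 else remap[anchor[v]] for v in order], dtype=np.int64
        )
        lengths = np.array([0.0 if v == 0 else carry[v] for v in order])
        labels = [self.labels[v] if kept_tip[v] else None for v in order]
        return Phylogeny(parent, lengths, labels)

    # -- serialization ------------------------------------------------------

    def to_newick(self) -> str:
        children = self.children_lists()

        def fmt(v: int) -> str:
            if not children[v]:
                s = self.labels[v]
            else:
                s = "(" + ",".join(fmt(c) for c in children[v]) + ")"
            if v == 0:
                return s + ";"
            return f"{s}:{float(self.lengths[v])!r}"

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * self.n_nodes + 1000))
        try:
            return fmt(0)
        finally:
            sys.setrecursionlimit(old)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


def read_tree(path, format: str = "newick", missing_length: float | None = None) -> Phylogeny:
    """Read a rooted phylogeny from a Newick or Nexus file.

    Parameters
    ----------
    path : file path
    format : "newick" or "nexus"
    missing_length : if given, edges lacking a branch length are set to this
        value with a warning; otherwise a missing length raises ValueError.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format: {format!r}")
    try:
        tree = dendropy.Tree.get(path=str(path), schema=format, preserve_underscores=True)
    except (ValueError, TypeError):
        raise
    except Exception as exc:
        raise ValueError(f"could not parse {format} tree from {path}: {exc}") from exc
    return Phylogeny.from_dendropy(tree, missing_length=missing_length)


# ---------------------------------------------------------------------------
# Occurrences and OTU maps
# ---------------------------------------------------------------------------

OCC_COLUMNS = ("name", "x", "y")


def _check_occurrences(occ: pd.DataFrame) -> pd.DataFrame:
    for col in OCC_COLUMNS:
        if col not in occ.columns:
            raise ValueError(f"occurrence table missing column {col!r}")
    occ = occ.loc[:, list(OCC_COLUMNS)].copy()
    occ["name"] = occ["name"].astype(str)
    if (occ["name"].str.len() == 0).any():
        raise ValueError("empty taxon name in occurrence table")
    xy = occ[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("non-finite coordinates in occurrence table")
    occ[["x", "y"]] = xy
    return occ


def load_occurrences(path) -> pd.DataFrame:
    """Load an occurrence CSV with header ``name,x,y``."""
    return _check_occurrences(pd.read_csv(path, comment="#"))


def load_otu_map(path) -> dict[str, str]:
    """Load a species-to-OTU CSV with header ``binomial,otu``."""
    df = pd.read_csv(path, comment="#", dtype=str)
    for col in ("binomial", "otu"):
        if col not in df.columns:
            raise ValueError(f"OTU map missing column {col!r}")
    dup = df["binomial"][df["binomial"].duplicated()]
    if len(dup):
        raise ValueError(f"binomials mapped more than once: {sorted(set(dup))}")
    return dict(zip(df["binomial"], df["otu"]))


def apply_otu_map(
    occ: pd.DataFrame, otu_map: dict[str, str], strict: bool = True
) -> pd.DataFrame:
    """Replace species names with their OTU ids; row count is unchanged.

    In strict mode an unmapped species raises; otherwise unmapped rows are
    dropped with a warning.
    """
    occ = _check_occurrences(occ)
    mapped = occ["name"].map(otu_map)
    missing = occ.loc[mapped.isna(), "name"]
    if len(missing):
        names = sorted(set(missing))
        if strict:
            raise KeyError(f"species missing from OTU map: {names}")
        logger.warning("dropping %d records of unmapped species: %s", len(missing), names)
        occ = occ.loc[mapped.notna()].copy()
        mapped = mapped.loc[mapped.notna()]
    out = occ.copy()
    out["name"] = mapped.astype(str)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Presence matrix
# ---------------------------------------------------------------------------


@dataclass
class PresenceMatrix:
    """Binary cells x taxa incidence with cell identities and (optionally)
    the grid the cells live on.

    Invariants (enforced by :meth:`validate`): entries are boolean, no
    all-zero row (cell) or column (taxon); column sums are taxon range
    sizes, row sums are per-cell richness.
    """

    cells: list  # list of (i, j) int pairs
    taxa: list  # list of str
    X: np.ndarray  # bool, shape (n_cells, n_taxa)
    grid: GridSpec | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=bool)
        self.cells = [tuple(int(v) for v in c) for c in self.cells]
        self.taxa = [str(t) for t in self.taxa]
        if self.X.shape != (len(self.cells), len(self.taxa)):
            raise ValueError("incidence shape does not match cells/taxa")

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell ids")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        if self.X.shape[0] and not self.X.any(axis=1).all():
            raise ValueError("all-zero cell row present")
        if self.X.shape[1] and not self.X.any(axis=0).all():
            raise ValueError("all-zero taxon column present")

    # -- derived quantities --------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def cell_ids(self) -> list[str]:
        return [cell_id_str(c) for c in self.cells]

    def cell_centers(self) -> np.ndarray:
        if self.grid is None:
            return np.full((self.n_cells, 2), np.nan)
        return self.grid.centers_of(self.cells)

    def range_sizes(self) -> np.ndarray:
        """Occupied-cell count per taxon (column sums)."""
        return self.X.sum(axis=0).astype(np.int64)

    def richness(self) -> np.ndarray:
        """Taxon count per cell (row sums)."""
        return self.X.sum(axis=1).astype(np.int64)

    # -- subsetting ----------------------------------------------------------

    def drop_empty(self) -> "PresenceMatrix":
        rows = self.X.any(axis=1)
        cols = self.X.any(axis=0)
        return PresenceMatrix(
            [c for c, k in zip(self.cells, rows) if k],
            [t for t, k in zip(self.taxa, cols) if k],
            self.X[np.ix_(rows, cols)],
            self.grid,
        )

    def select_taxa(self, names, drop_empty_cells: bool = True) -> "PresenceMatrix":
        names = list(names)
        idx = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in names if t not in idx]
        if missing:
            raise KeyError(f"taxa not in matrix: {missing}")
        cols = [idx[t] for t in names]
        out = PresenceMatrix(list(self.cells), names, self.X[:, cols], self.grid)
        return out.drop_empty() if drop_empty_cells else out

    def with_incidence(self, X: np.ndarray) -> "PresenceMatrix":
        return PresenceMatrix(list(self.cells), list(self.taxa), X, self.grid)

    # -- IO -------------------------------------------------------------------

    def to_triplets(self, path) -> None:
        """Write as a sparse triplet CSV ``cell_id,taxon`` (grid in header)."""
        rows, cols = np.nonzero(self.X)
        with open(path, "w") as fh:
            if self.grid is not None:
                g = self.grid
                fh.write(
                    f"# grid origin_x={g.origin_x!r} origin_y={g.origin_y!r} "
                    f"cell_size={g.cell_size!r}\n"
                )
            fh.write("cell_id,taxon\n")
            ids = self.cell_ids
            for r, c in zip(rows, cols):
                fh.write(f"{ids[r]},{self.taxa[c]}\n")

    @classmethod
    def from_triplets(cls, path, grid: GridSpec | None = None) -> "PresenceMatrix":
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("# grid ") and grid is None:
            kv = dict(tok.split("=") for tok in first[len("# grid "):].split())
            grid = GridSpec(float(kv["origin_x"]), float(kv["origin_y"]), float(kv["cell_size"]))
        df = pd.read_csv(path, comment="#", dtype=str)
        cells = sorted({parse_cell_id(c) for c in df["cell_id"]})
        taxa = sorted(set(df["taxon"]))
        ci = {c: i for i, c in enumerate(cells)}
        ti = {t: i for i, t in enumerate(taxa)}
        X = np.zeros((len(cells), len(taxa)), dtype=bool)
        for cid, t in zip(df["cell_id"], df["taxon"]):
            X[ci[parse_cell_id(cid)], ti[t]] = True
        return cls(cells, taxa, X, grid)


def rasterize_points(occ: pd.DataFrame, grid: GridSpec) -> PresenceMatrix:
    """Convert point records to per-cell presence on the grid.

    A taxon is present in a cell iff at least one of its records falls in
    that cell (duplicates collapse). Cells without any record and taxa
    without any record do not appear.
    """
    occ = _check_occurrences(occ)
    if len(occ) == 0:
        raise ValueError("no occurrence records to rasterize")
    ij = grid.cells_of(occ["x"].to_numpy(), occ["y"].to_numpy())
    cells = sorted({(int(a), int(b)) for a, b in ij})
    taxa = sorted(occ["name"].unique())
    ci = {c: i for i, c in enumerate(cells)}
    ti = {t: i for i, t in enumerate(taxa)}
    X = np.zeros((len(cells), len(taxa)), dtype=bool)
    for (a, b), name in zip(ij, occ["name"]):
        X[ci[(int(a), int(b))], ti[name]] = True
    m = PresenceMatrix(cells, taxa, X, grid).drop_empty()
    m.validate()
    return m


def align_tree_and_matrix(
    tree: Phylogeny, m: PresenceMatrix, mode: str = "strict"
) -> tuple[Phylogeny, PresenceMatrix]:
    """Reconcile a tree and a presence matrix onto their shared taxa.

    The tree is pruned to the matrix taxa. Matrix taxa absent from the tree
    raise in ``strict`` mode; in ``prune`` mode they are dropped with a
    warning (and cells emptied by the drop are removed).
    """
    if mode not in ("strict", "prune"):
        raise ValueError(f"unknown mode {mode!r}")
    tree_taxa = set(tree.tip_labels)
    mat_taxa = set(m.taxa)
    shared = tree_taxa & mat_taxa
    if not shared:
        raise ValueError("tree and matrix share no taxa")
    extra = mat_taxa - tree_taxa
    if extra:
        if mode == "strict":
            raise KeyError(f"matrix taxa missing from tree: {sorted(extra)}")
        logger.warning("dropping %d matrix taxa not in tree: %s", len(extra), sorted(extra))
    keep = sorted(shared, key=m.taxa.index)
    m2 = m.select_taxa(keep) if (extra or len(shared) < m.n_taxa) else m
    tree2 = tree.prune_to(m2.taxa) if shared != tree_taxa else tree
    return tree2, m2


# ---------------------------------------------------------------------------
# Per-cell tables and climate
# ---------------------------------------------------------------------------


def write_cell_table(
    table: pd.DataFrame, path, grid: GridSpec | None = None, header_comment: str | None = None
) -> None:
    """Write a per-cell table as CSV with ``cell_id,x,y`` leading columns.

    ``table`` must be indexed by cell-id strings (``"i_j"``). Numeric values
    are written at full double precision so the file round-trips losslessly.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty cell table")
    out = table.copy()
    out.index = out.index.astype(str)
    out.index.name = "cell_id"
    if "x" not in out.columns or "y" not in out.columns:
        if grid is not None:
            centers = grid.centers_of([parse_cell_id(c) for c in out.index])
            out.insert(0, "y", centers[:, 1])
            out.insert(0, "x", centers[:, 0])
        else:
            out.insert(0, "y", np.nan)
            out.insert(0, "x", np.nan)
    else:
        out = out[["x", "y"] + [c for c in out.columns if c not in ("x", "y")]]
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        out.to_csv(fh, float_format="%.17g")


def read_cell_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", index_col="cell_id")
    df.index = df.index.astype(str)
    return df


def load_climate(path) -> pd.DataFrame:
    """Load a per-cell climate CSV (``cell_id,<var>,...``); x/y columns are
    tolerated and dropped."""
    df = read_cell_table(path)
    return df.drop(columns=[c for c in ("x", "y") if c in df.columns])


def write_climate(climate: pd.DataFrame, path, grid: GridSpec | None = None) -> None:
    write_cell_table(climate, path, grid=grid)
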