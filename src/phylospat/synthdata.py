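"""Synthetic phylogenies, occurrence grids with planted endemism structure,
climate surfaces, and distribution-model ground truth.

Everything is generated from explicit seeds; there is no hidden global
random state. Planted blocks scale the terminal branches of selected taxa
(multiplier >> 1 emulates range-restricted long branches, << 1 short ones)
and confine their ranges to a designated region, recording ground-truth
labels per cell and per taxon for recovery tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .grid_io import GridSpec, Phylogeny, PresenceMatrix, cell_id_str

__all__ = [
    "PlantedBlock",
    "ScenarioConfig",
    "SyntheticDataset",
    "gen_tree",
    "gen_ranges",
    "plant_endemism",
    "gen_climate",
    "gen_sdm_truth",
    "generate",
]


@dataclass
class PlantedBlock:
    region: list  # list of (i, j) cells
    kind: str  # "neo" | "paleo" | "mixed"
    n_taxa: int
    multiplier: float  # terminal branch-length scale for planted taxa
    range_cap: int = 3  # max occupied cells per planted taxon
    select: str = "typical"  # "typical" (median-length terminals) or "random"

    def __post_init__(self) -> None:
        if self.kind not in ("neo", "paleo", "mixed"):
            raise ValueError(f"unknown planted kind {self.kind!r}")
        if self.select not in ("typical", "random"):
            raise ValueError(f"unknown selection rule {self.select!r}")
        if not self.multiplier > 0:
            raise ValueError("multiplier must be positive")
        if not self.region:
            raise ValueError("planted region is empty")
        self.region = [tuple(int(v) for v in c) for c in self.region]


@dataclass
class ScenarioConfig:
    n_taxa: int = 100
    nx: int = 10
    ny: int = 10
    seed: int = 0
    regime: str = "phylogram"  # or "chronogram"
    range_median: float = 8.0  # log-normal median range size, in cells
    range_sigma: float = 0.75  # log-normal spread (log scale)
    cohesive: bool = True
    blocks: list = field(default_factory=list)  # of PlantedBlock
    cell_size: float = 15_000.0
    rate_sd: float = 0.6  # log-normal rate spread for the phylogram regime

    @property
    def grid(self) -> GridSpec:
        return GridSpec(0.0, 0.0, self.cell_size)

    def all_cells(self) -> list:
        return [(i, j) for i in range(self.nx) for j in range(self.ny)]


@dataclass
class SyntheticDataset:
    tree: Phylogeny
    matrix: PresenceMatrix
    climate: pd.DataFrame | None = None
    cell_truth: pd.Series | None = None  # cell_id -> planted kind / "background"
    taxon_truth: pd.Series | None = None  # taxon -> planted kind / "background"


def gen_tree(n: int, seed: int, regime: str = "phylogram", rate_sd: float = 0.6) -> Phylogeny:
    """Pure-birth topology with n terminals.

    The chronogram regime leaves the tree ultrametric; the phylogram regime
    multiplies every branch by an independent log-normal rate.
    """
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if regime not in ("phylogram", "chronogram"):
        raise ValueError(f"unknown branch-length regime {regime!r}")
    dtree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n, rng=random.Random(seed)
    )
    dtree.seed_node.edge.length = None
    tree = Phylogeny.from_dendropy(dtree, missing_length=0.0)
    # deterministic tip labels in preorder tip order
    labels = list(tree.labels)
    width = len(str(n))
    for k, v in enumerate(tree.tip_indices):
        labels[v] = f"t{k + 1:0{width}d}"
    tree = Phylogeny(tree.parent, tree.lengths, labels)
    if regime == "phylogram":
        rng = np.random.default_rng(seed)
        rates = rng.lognormal(mean=0.0, sigma=rate_sd, size=tree.n_nodes)
        lengths = tree.lengths * rates
        lengths[0] = 0.0
        tree = tree.with_lengths(lengths)
    return tree


def _patch(center, size, cells, rng):
    """The `size` cells nearest to `center` (deterministic tie-break)."""
    arr = np.asarray(cells, dtype=float)
    d2 = ((arr - np.asarray(center, dtype=float)) ** 2).sum(axis=1)
    order = np.lexsort((arr[:, 1], arr[:, 0], d2))
    return [cells[k] for k in order[:size]]


def gen_ranges(
    taxa,
    grid: GridSpec,
    shape: tuple[int, int],
    seed: int,
    range_median: float = 8.0,
    range_sigma: float = 0.75,
    cohesive: bool = True,
) -> PresenceMatrix:
    """Place each taxon on a patch of cells within an nx x ny grid.

    Sizes are log-normal (median ``range_median`` cells, log-sd
    ``range_sigma``), truncated to [1, n_cells]. Cohesive patches are the
    cells nearest a random center; the scatter option samples cells
    independently (matching the null model's no-autocorrelation
    assumption). Unoccupied cells are dropped.
    """
    taxa = list(taxa)
    nx, ny = shape
    cells = [(i, j) for i in range(nx) for j in range(ny)]
    rng = np.random.default_rng(seed)
    n_cells = len(cells)
    X = np.zeros((n_cells, len(taxa)), dtype=bool)
    pos = {c: k for k, c in enumerate(cells)}
    for t in range(len(taxa)):
        size = int(np.clip(round(rng.lognormal(np.log(range_median), range_sigma)), 1, n_cells))
        if cohesive:
            center = (rng.integers(nx), rng.integers(ny))
            occ = _patch(center, size, cells, rng)
        else:
            idx = rng.choice(n_cells, size=size, replace=False)
            occ = [cells[k] for k in idx]
        for c in occ:
            X[pos[c], t] = True
    return PresenceMatrix(cells, taxa, X, grid).drop_empty()


def plant_endemism(dataset: SyntheticDataset, block: PlantedBlock, seed: int) -> SyntheticDataset:
    """Plant a block of endemism into an existing dataset.

    Selects ``block.n_taxa`` taxa (seeded, from those not already planted),
    scales their terminal branch lengths by the multiplier, and confines
    their ranges to at most ``range_cap`` cells inside the region. Truth
    labels are recorded per taxon and per region cell.
    """
    tree, m = dataset.tree, dataset.matrix
    region = [c for c in block.region if c in set(m.cells)]
    if not region:
        raise ValueError("planted region lies outside the occupied grid")
    rng = np.random.default_rng(seed)
    taxon_truth = (
        dataset.taxon_truth.copy()
        if dataset.taxon_truth is not None
        else pd.Series("background", index=pd.Index(m.taxa, name="taxon"))
    )
    eligible = [t for t in m.taxa if taxon_truth[t] == "background"]
    if len(eligible) < block.n_taxa:
        raise ValueError("not enough unplanted taxa left")
    if block.select == "typical":
        # taxa whose pre-scaling terminal lengths sit closest to the median:
        # keeps the planted signal homogeneous instead of dominated by one
        # extreme branch
        tip_len = {tree.labels[v]: tree.lengths[v] for v in tree.tip_indices}
        med = float(np.median([tip_len[t] for t in eligible]))
        chosen = sorted(eligible, key=lambda t: (abs(tip_len[t] - med), t))[: block.n_taxa]
    else:
        chosen = list(rng.choice(eligible, size=block.n_taxa, replace=False))

    # scale terminal branches of the chosen taxa
    lengths = tree.lengths.copy()
    tip_of = {tree.labels[v]: v for v in tree.tip_indices}
    for t in chosen:
        lengths[tip_of[t]] *= block.multiplier
    tree2 = tree.with_lengths(lengths)

    # confine ranges to the region
    X = m.X.copy()
    col = {t: k for k, t in enumerate(m.taxa)}
    pos = {c: k for k, c in enumerate(m.cells)}
    region_rows = [pos[c] for c in region]
    # round-robin placement over a seeded permutation of the region, so the
    # planted taxa cover the region evenly (no under-planted cells)
    perm = rng.permutation(len(region_rows))
    size = min(block.range_cap, len(region))
    for k_t, t in enumerate(chosen):
        k = col[t]
        X[:, k] = False
        start = (k_t * size) % len(region_rows)
        for i in range(size):
            r = perm[(start + i) % len(region_rows)]
            X[region_rows[r], k] = True
        taxon_truth[t] = block.kind

    m2 = PresenceMatrix(list(m.cells), list(m.taxa), X, m.grid).drop_empty()
    cell_truth = (
        dataset.cell_truth.copy()
        if dataset.cell_truth is not None
        else pd.Series("background", index=pd.Index(m.cell_ids, name="cell_id"))
    )
    cell_truth = cell_truth.reindex([cell_id_str(c) for c in m2.cells], fill_value="background")
    for c in region:
        cid = cell_id_str(c)
        if cid in cell_truth.index:
            cell_truth[cid] = block.kind
    taxon_truth = taxon_truth.reindex(m2.taxa, fill_value="background")
    return SyntheticDataset(tree2, m2, dataset.climate, cell_truth, taxon_truth)


def gen_climate(
    grid: GridSpec,
    shape: tuple[int, int],
    seed: int,
    noise_sd: float = 0.0,
    arid_region: list | None = None,
    arid_depression: float = 400.0,
) -> pd.DataFrame:
    """Smooth climate surfaces over an nx x ny grid.

    Four variables: annual precipitation (mm, increasing north), summer
    maximum and winter minimum temperature (degC, north-south and radial
    gradients), and climatic water deficit (mm, anti-correlated with
    precipitation). Noise is spatially smoothed; an optional arid region
    gets its precipitation depressed.
    """
    from scipy.ndimage import gaussian_filter

    nx, ny = shape
    rng = np.random.default_rng(seed)
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    fi = ii / max(nx - 1, 1)
    fj = jj / max(ny - 1, 1)

    def smooth_noise():
        if noise_sd == 0:
            return np.zeros((nx, ny))
        return gaussian_filter(rng.normal(0.0, noise_sd, size=(nx, ny)), sigma=1.0)

    precip = 200.0 + 800.0 * fj + smooth_noise()
    tsummer = 35.0 - 12.0 * fj + smooth_noise() * 0.01
    twinter = -5.0 + 10.0 * np.hypot(fi - 0.5, fj - 0.5) + smooth_noise() * 0.01
    cwd = 900.0 - 0.7 * precip + smooth_noise() * 0.1
    if arid_region:
        for (i, j) in arid_region:
            if 0 <= i < nx and 0 <= j < ny:
                precip[i, j] = max(precip[i, j] - arid_depression, 10.0)
                cwd[i, j] += 0.7 * arid_depression
    cells = [(i, j) for i in range(nx) for j in range(ny)]
    return pd.DataFrame(
        {
            "precip": [precip[i, j] for i, j in cells],
            "tmax_summer": [tsummer[i, j] for i, j in cells],
            "tmin_winter": [twinter[i, j] for i, j in cells],
            "cwd": [cwd[i, j] for i, j in cells],
        },
        index=pd.Index([cell_id_str(c) for c in cells], name="cell_id"),
    )


def gen_sdm_truth(
    grid: GridSpec,
    climate: pd.DataFrame,
    coefficients: dict[str, float],
    n_presences: int,
    seed: int,
    intercept: float = 0.0,
):
    """Known logistic suitability truth plus presences sampled from it.

    Suitability = sigmoid(intercept + sum_i b_i * z_i) with z the climate
    variables standardized over the domain. Presences are drawn cell-wise
    proportionally to suitability, with coordinates uniform in the cell.
    Returns (SuitabilitySurface, occurrence DataFrame).
    """
    from .grid_io import parse_cell_id
    from .range_model import SuitabilitySurface

    rng = np.random.default_rng(seed)
    cells = [parse_cell_id(c) for c in climate.index]
    eta = np.full(len(cells), float(intercept))
    for var, b in coefficients.items():
        if var not in climate.columns:
            raise KeyError(f"unknown climate variable {var!r}")
        v = climate[var].to_numpy(dtype=float)
        sd = v.std()
        z = (v - v.mean()) / (sd if sd > 0 else 1.0)
        eta += b * z
    suit = 1.0 / (1.0 + np.exp(-eta))
    surface = SuitabilitySurface(grid, cells, suit, label="truth")
    p = suit / suit.sum()
    draws = rng.choice(len(cells), size=int(n_presences), p=p)
    centers = grid.centers_of(cells)
    offsets = rng.uniform(-0.5, 0.5, size=(int(n_presences), 2)) * grid.cell_size
    coords = centers[draws] + offsets
    occ = pd.DataFrame({"name": "truth_species", "x": coords[:, 0], "y": coords[:, 1]})
    return surface, occ


def generate(cfg: ScenarioConfig) -> SyntheticDataset:
    """Build a full scenario: tree, ranges, climate, and planted blocks."""
    tree = gen_tree(cfg.n_taxa, cfg.seed, cfg.regime, cfg.rate_sd)
    m = gen_ranges(
        tree.tip_labels,
        cfg.grid,
        (cfg.nx, cfg.ny),
        seed=cfg.seed + 1,
        range_median=cfg.range_median,
        range_sigma=cfg.range_sigma,
        cohesive=cfg.cohesive,
    )
    arid = [c for b in cfg.blocks for c in b.region] or None
    climate = gen_climate(cfg.grid, (cfg.nx, cfg.ny), seed=cfg.seed + 2, arid_region=arid)
    ds = SyntheticDataset(tree, m, climate)
    for k, block in enumerate(cfg.blocks):
        ds = plant_endemism(ds, block, seed=cfg.seed + 10 + k)
    if ds.cell_truth is None:
        ds.cell_truth = pd.Series(
            "background", index=pd.Index(ds.matrix.cell_ids, name="cell_id")
        )
    if ds.taxon_truth is None:
        ds.taxon_truth = pd.Series(
            "background", index=pd.Index(ds.matrix.taxa, name="taxon")
        )
    return ds
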