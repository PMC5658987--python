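"""Climate-based range modeling with a distance-hybrid constraint.

Pipeline per species: down-sample records to one per fine grid cell, pool a
background sample across all species, fit a penalized presence-vs-background
model on standardized linear + quadratic climate features, threshold the
continuous suitability by maximizing sensitivity + specificity, optionally
multiply suitability by a Gaussian decay of the distance to the nearest
record (sigma defaults to 50 km) before thresholding, union species ranges
into OTU ranges, and aggregate fine cells onto the analysis grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grid_io import GridSpec, PresenceMatrix, _check_occurrences, parse_cell_id

logger = logging.getLogger(__name__)

__all__ = [
    "RangeModelConfig",
    "SuitabilitySurface",
    "BinaryRange",
    "downsample_to_grid",
    "sample_background",
    "fit_suitability",
    "auc",
    "sss_threshold",
    "gaussian_distance_weight",
    "threshold_range",
    "hybrid_range",
    "union_otu_ranges",
    "aggregate_to_coarse",
    "range_expansion_stats",
]


@dataclass
class RangeModelConfig:
    sigma: float = 50_000.0  # Gaussian decay scale, metres
    n_background: int = 10_000
    fine_cell: float = 810.0
    coarse_cell: float = 15_000.0
    regularization: float = 0.01  # weak L2 penalty on the suitability fit
    min_presences: int = 5

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if self.n_background < 1:
            raise ValueError("n_background must be >= 1")


@dataclass
class SuitabilitySurface:
    """Continuous suitability in [0, 1] per fine-grid cell for one species."""

    grid: GridSpec
    cells: list  # (i, j) pairs, the modeling domain
    values: np.ndarray  # float, same length as cells
    label: str | None = None
    _pos: dict = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.cells):
            raise ValueError("values and cells differ in length")
        if not np.isfinite(self.values).all() or (
            self.values.size and (self.values.min() < 0 or self.values.max() > 1)
        ):
            raise ValueError("suitability values must be finite and in [0, 1]")
        self._pos = {tuple(c): i for i, c in enumerate(self.cells)}

    def centers(self) -> np.ndarray:
        return self.grid.centers_of(self.cells)

    def score_at(self, coords: np.ndarray) -> np.ndarray:
        """Suitability of the cells containing the given points."""
        coords = np.asarray(coords, dtype=float).reshape(-1, 2)
        out = np.empty(len(coords))
        for k, (x, y) in enumerate(coords):
            cell = self.grid.cell_of(x, y)
            if cell not in self._pos:
                raise KeyError(f"point ({x}, {y}) falls outside the modeling domain")
            out[k] = self.values[self._pos[cell]]
        return out

    def with_values(self, values: np.ndarray) -> "SuitabilitySurface":
        return SuitabilitySurface(self.grid, list(self.cells), values, self.label)


@dataclass
class BinaryRange:
    """A thresholded presence range: a set of grid cells plus its grid."""

    label: str
    cells: frozenset  # of (i, j)
    grid: GridSpec

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def downsample_to_grid(occ: pd.DataFrame, fine: GridSpec) -> pd.DataFrame:
    """Thin records to at most one per species per fine cell; the retained
    record sits at the cell center. Idempotent."""
    occ = _check_occurrences(occ)
    ij = fine.cells_of(occ["x"].to_numpy(), occ["y"].to_numpy())
    keys = pd.DataFrame(
        {"name": occ["name"].to_numpy(), "i": ij[:, 0], "j": ij[:, 1]}
    ).drop_duplicates()
    centers = fine.centers_of(keys[["i", "j"]].to_numpy())
    return pd.DataFrame(
        {"name": keys["name"].to_numpy(), "x": centers[:, 0], "y": centers[:, 1]}
    )


def sample_background(all_occ: pd.DataFrame, n: int, seed: int) -> np.ndarray:
    """Draw n background coordinates uniformly (with replacement) from the
    pooled records of all species."""
    all_occ = _check_occurrences(all_occ)
    if len(all_occ) == 0:
        raise ValueError("empty occurrence pool for background sampling")
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, len(all_occ), size=int(n))
    return all_occ[["x", "y"]].to_numpy(dtype=float)[rows]


def _climate_matrix(climate: pd.DataFrame) -> tuple[list, np.ndarray, list[str]]:
    cells = [parse_cell_id(c) for c in climate.index]
    vars_ = [c for c in climate.columns if c not in ("x", "y")]
    return cells, climate[vars_].to_numpy(dtype=float), vars_


def fit_suitability(
    presences: np.ndarray,
    background: np.ndarray,
    climate: pd.DataFrame,
    grid: GridSpec,
    config: RangeModelConfig | None = None,
    label: str | None = None,
) -> SuitabilitySurface:
    """Fit presence-vs-background suitability on standardized linear and
    quadratic climate features.

    ``climate`` is a per-cell table (indexed by cell-id strings) on the fine
    grid; the returned surface covers every climate cell. The fit is a
    weakly penalized logistic discrimination of presence cells against
    background cells; constant climate variables are dropped with a warning.
    """
    from sklearn.linear_model import LogisticRegression

    config = config or RangeModelConfig()
    presences = np.asarray(presences, dtype=float).reshape(-1, 2)
    background = np.asarray(background, dtype=float).reshape(-1, 2)
    if len(presences) < config.min_presences:
        raise ValueError(
            f"need at least {config.min_presences} presences, got {len(presences)}"
        )
    cells, V, vars_ = _climate_matrix(climate)
    pos = {c: i for i, c in enumerate(cells)}

    def rows_for(coords):
        idx = np.empty(len(coords), dtype=np.int64)
        for k, (x, y) in enumerate(coords):
            cell = grid.cell_of(x, y)
            if cell not in pos:
                raise KeyError(f"point ({x}, {y}) has no climate cell")
            idx[k] = pos[cell]
        return idx

    ip = rows_for(presences)
    ib = rows_for(background)
    Xtrain_raw = np.vstack([V[ip], V[ib]])
    y = np.concatenate([np.ones(len(ip)), np.zeros(len(ib))])

    mu = Xtrain_raw.mean(axis=0)
    sd = Xtrain_raw.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [v for v, k in zip(vars_, keep) if not k]
        logger.warning("dropping constant climate variable(s): %s", dropped)
    if not keep.any():
        raise ValueError("all climate variables are constant over the training data")

    def features(raw):
        z = (raw[:, keep] - mu[keep]) / sd[keep]
        return np.hstack([z, z**2])

    C = 1.0 / max(config.regularization, 1e-8)
    model = LogisticRegression(C=C, max_iter=1000)
    model.fit(features(Xtrain_raw), y)
    prob = model.predict_proba(features(V))[:, 1]
    return SuitabilitySurface(grid, cells, np.clip(prob, 0.0, 1.0), label=label)


def auc(presence_scores, background_scores) -> float:
    """Probability that a random presence outscores a random background
    point, ties counted one half (exact pair-counting form via ranks)."""
    from scipy.stats import rankdata

    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("empty score set")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def sss_threshold(presence_scores, background_scores) -> float:
    """Threshold maximizing sensitivity(presences >= t) +
    specificity(background < t) over the distinct observed scores; the
    smallest maximizing score wins ties."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("empty score set")
    cand = np.unique(np.concatenate([p, b]))
    sens = (p[None, :] >= cand[:, None]).mean(axis=1)
    spec = (b[None, :] < cand[:, None]).mean(axis=1)
    total = sens + spec
    return float(cand[int(np.argmax(total))])  # argmax takes the first (smallest)


def gaussian_distance_weight(
    cell_centers: np.ndarray, occ_coords: np.ndarray, sigma: float
) -> np.ndarray:
    """w(c) = exp(-d(c)^2 / (2 sigma^2)), d = planar distance to the nearest
    occurrence record."""
    occ = np.asarray(occ_coords, dtype=float).reshape(-1, 2)
    if occ.size == 0:
        raise ValueError("need at least one occurrence record")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    centers = np.asarray(cell_centers, dtype=float).reshape(-1, 2)
    d, _ = cKDTree(occ).query(centers)
    return np.exp(-(d**2) / (2.0 * sigma**2))


def threshold_range(
    surface: SuitabilitySurface, presences: np.ndarray, background: np.ndarray
) -> BinaryRange:
    """Unconstrained binary range: cells at/above the SSS threshold of the
    raw suitability scores."""
    t = sss_threshold(surface.score_at(presences), surface.score_at(background))
    keep = surface.values >= t
    return BinaryRange(
        surface.label or "", frozenset(c for c, k in zip(surface.cells, keep) if k), surface.grid
    )


def hybrid_range(
    surface: SuitabilitySurface,
    weights: np.ndarray,
    presences: np.ndarray,
    background: np.ndarray,
) -> BinaryRange:
    """Distance-hybrid range: threshold the product weight x suitability.

    The sensitivity+specificity rule is re-applied to the product scores
    (the alternative — reusing the unconstrained threshold — can be had by
    thresholding manually).
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != surface.values.shape:
        raise ValueError("weights and surface are on different grids")
    product = surface.with_values(surface.values * weights)
    return threshold_range(product, presences, background)


def union_otu_ranges(
    species_ranges: dict[str, BinaryRange], otu_map: dict[str, str]
) -> dict[str, BinaryRange]:
    """OTU range = union of the thresholded ranges of its species."""
    missing = [s for s in species_ranges if s not in otu_map]
    if missing:
        raise KeyError(f"species missing from OTU map: {sorted(missing)}")
    out: dict[str, BinaryRange] = {}
    for sp, rng in species_ranges.items():
        otu = otu_map[sp]
        if otu in out:
            out[otu] = BinaryRange(otu, out[otu].cells | rng.cells, rng.grid)
        else:
            out[otu] = BinaryRange(otu, frozenset(rng.cells), rng.grid)
    return out


def aggregate_to_coarse(
    rng: BinaryRange, fine: GridSpec, coarse: GridSpec
) -> BinaryRange:
    """A coarse cell is present iff it contains >= 1 present fine cell
    (fine cells are assigned by their centers)."""
    centers = fine.centers_of(rng.cells)
    cells = frozenset(
        coarse.cell_of(x, y) for x, y in centers
    )
    return BinaryRange(rng.label, cells, coarse)


def ranges_to_matrix(ranges: dict[str, BinaryRange], grid: GridSpec) -> PresenceMatrix:
    """Stack binary ranges into a presence matrix (empty cells dropped)."""
    taxa = sorted(ranges)
    cells = sorted({c for t in taxa for c in ranges[t].cells})
    pos = {c: i for i, c in enumerate(cells)}
    X = np.zeros((len(cells), len(taxa)), dtype=bool)
    for k, t in enumerate(taxa):
        for c in ranges[t].cells:
            X[pos[c], k] = True
    return PresenceMatrix(cells, taxa, X, grid)


def range_expansion_stats(
    observed: PresenceMatrix, modeled: PresenceMatrix
) -> pd.DataFrame:
    """Per-taxon observed cell count, modeled cell count, and their ratio."""
    if set(observed.taxa) != set(modeled.taxa):
        raise ValueError("observed and modeled matrices cover different taxa")
    obs = dict(zip(observed.taxa, observed.range_sizes()))
    mod = dict(zip(modeled.taxa, modeled.range_sizes()))
    taxa = sorted(obs)
    o = np.array([obs[t] for t in taxa], dtype=float)
    m = np.array([mod[t] for t in taxa], dtype=float)
    if np.any(o == 0):
        raise ValueError("taxon with zero observed range")
    return pd.DataFrame(
        {"observed_cells": o.astype(int), "modeled_cells": m.astype(int), "ratio": m / o},
        index=pd.Index(taxa, name="taxon"),
    )
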