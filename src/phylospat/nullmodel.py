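"""Fixed-marginal randomization of the presence matrix and per-cell
significance estimation.

The null holds both marginals of the binary cells x taxa matrix fixed:
taxa per cell (row sums) and cells per taxon (column sums). Replicates are
drawn from a single Markov chain of curveball trades between random cell
pairs; each trade redistributes the taxa held by exactly one of the two
cells, which is the standard uniform sampler for the fixed-fixed ensemble.

p-values use (1 + count) / (1 + n_reps) with ties counted toward
significance on both sides, so they are conservative and never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diversity import build_branch_index, make_equal_branch_tree
from .grid_io import Phylogeny, PresenceMatrix

__all__ = [
    "RandomizationConfig",
    "MetricNull",
    "RandomizationResult",
    "KNOWN_METRICS",
    "shuffle_fixed_marginals",
    "randomize_metrics",
    "significance_code",
]

KNOWN_METRICS = ("pd", "pd_comp", "rpd", "pe", "pe_comp", "rpe", "we")

try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass
class RandomizationConfig:
    """Settings for the fixed-marginal randomization.

    trades_per_rep defaults to 5x the presence count of the matrix, used
    both as burn-in and as decorrelation between successive replicates of
    the chain.
    """

    n_reps: int = 999
    seed: int = 0
    trades_per_rep: int | None = None
    alpha_two_tail: float = 0.05
    alpha_one_tail: float = 0.05

    def __post_init__(self) -> None:
        if self.n_reps < 19:
            raise ValueError("n_reps must be >= 19")
        if not (0 < self.alpha_two_tail < 1 and 0 < self.alpha_one_tail < 1):
            raise ValueError("alpha levels must lie in (0, 1)")
        if self.trades_per_rep is not None and self.trades_per_rep < 1:
            raise ValueError("trades_per_rep must be positive")

    def resolve_trades(self, m: PresenceMatrix) -> int:
        if self.trades_per_rep is not None:
            return int(self.trades_per_rep)
        return int(5 * m.X.sum())


# ---------------------------------------------------------------------------
# Curveball trades
# ---------------------------------------------------------------------------

if _HAVE_NUMBA:

    @njit(cache=True)
    def _curveball_kernel(M, n_trades, seed):  # pragma: no cover - jit
        np.random.seed(seed)
        n_rows, n_cols = M.shape
        buf = np.empty(n_cols, np.int64)
        for _ in range(n_trades):
            i = np.random.randint(n_rows)
            j = np.random.randint(n_rows)
            if i == j:
                continue
            k = 0
            ki = 0
            for c in range(n_cols):
                if M[i, c] != M[j, c]:
                    buf[k] = c
                    k += 1
                    if M[i, c]:
                        ki += 1
            if k == 0 or ki == 0 or ki == k:
                continue
            for a in range(k - 1, 0, -1):
                b = np.random.randint(a + 1)
                tmp = buf[a]
                buf[a] = buf[b]
                buf[b] = tmp
            for a in range(k):
                c = buf[a]
                if a < ki:
                    M[i, c] = 1
                    M[j, c] = 0
                else:
                    M[i, c] = 0
                    M[j, c] = 1
        return M


def _curveball_python(M: np.ndarray, n_trades: int, seed: int) -> np.ndarray:
    # Mirror of the jit kernel (different RNG stream; each is deterministic).
    rng = np.random.default_rng(seed)
    n_rows = M.shape[0]
    for _ in range(n_trades):
        i, j = rng.integers(0, n_rows, size=2)
        if i == j:
            continue
        diff = np.flatnonzero(M[i] != M[j])
        if diff.size == 0:
            continue
        ki = int(M[i, diff].sum())
        if ki == 0 or ki == diff.size:
            continue
        perm = rng.permutation(diff)
        M[i, diff] = 0
        M[j, diff] = 1
        M[i, perm[:ki]] = 1
        M[j, perm[:ki]] = 0
    return M


def _run_trades(M: np.ndarray, n_trades: int, seed: int) -> np.ndarray:
    """Apply n_trades curveball trades in place to a uint8 matrix."""
    if _HAVE_NUMBA:
        return _curveball_kernel(M, np.int64(n_trades), np.int64(seed & 0x7FFFFFFF))
    return _curveball_python(M, n_trades, seed)


def shuffle_fixed_marginals(
    m: PresenceMatrix, seed: int, trades: int | None = None
) -> PresenceMatrix:
    """One fixed-marginal shuffle of the matrix (marginals preserved exactly,
    deterministic given the seed)."""
    if trades is None:
        trades = int(5 * m.X.sum())
    M = m.X.astype(np.uint8).copy()
    _run_trades(M, trades, seed)
    return m.with_incidence(M.astype(bool))


# ---------------------------------------------------------------------------
# Streaming null distributions
# ---------------------------------------------------------------------------


@dataclass
class MetricNull:
    """Observed values plus streaming tie-inclusive tail counts per cell.

    The override fields carry exact p-values through a CSV round trip,
    where the raw counts are no longer available.
    """

    observed: np.ndarray
    count_ge: np.ndarray
    count_le: np.ndarray
    n_reps: int
    p_high_override: np.ndarray | None = None
    p_low_override: np.ndarray | None = None

    @property
    def p_high(self) -> np.ndarray:
        if self.p_high_override is not None:
            return self.p_high_override
        return (1.0 + self.count_ge) / (1.0 + self.n_reps)

    @property
    def p_low(self) -> np.ndarray:
        if self.p_low_override is not None:
            return self.p_low_override
        return (1.0 + self.count_le) / (1.0 + self.n_reps)


@dataclass
class RandomizationResult:
    """Per-cell null summaries for each requested metric (common null)."""

    cells: list
    cell_ids: list
    metrics: dict[str, MetricNull]
    n_reps: int
    seed: int
    centers: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __getitem__(self, metric: str) -> MetricNull:
        return self.metrics[metric]

    def to_frame(self):
        import pandas as pd

        data = {}
        if self.centers is not None:
            data["x"] = self.centers[:, 0]
            data["y"] = self.centers[:, 1]
        for name, mn in self.metrics.items():
            data[f"{name}_obs"] = mn.observed
            data[f"{name}_p_high"] = mn.p_high
            data[f"{name}_p_low"] = mn.p_low
        return pd.DataFrame(data, index=pd.Index(self.cell_ids, name="cell_id"))

    @classmethod
    def from_frame(cls, df) -> "RandomizationResult":
        from .grid_io import parse_cell_id

        names = sorted({c[:-7] for c in df.columns if c.endswith("_p_high")})
        n_reps = -1  # unknown after round trip; p-values carried directly
        metrics = {}
        for name in names:
            ph = df[f"{name}_p_high"].to_numpy(float)
            pl = df[f"{name}_p_low"].to_numpy(float)
            obs = df[f"{name}_obs"].to_numpy(float)
            metrics[name] = MetricNull(
                obs,
                np.zeros_like(ph),
                np.zeros_like(pl),
                0,
                p_high_override=ph,
                p_low_override=pl,
            )
        cells = [parse_cell_id(c) for c in df.index]
        centers = None
        if "x" in df.columns and "y" in df.columns:
            centers = df[["x", "y"]].to_numpy(float)
        return cls(cells, list(df.index), metrics, n_reps, seed=-1, centers=centers)


class _MetricEngine:
    """Vectorized recomputation of all requested metrics for one incidence
    matrix sharing the tree-derived structures across replicates."""

    def __init__(self, tree: Phylogeny, m: PresenceMatrix, metrics: list[str]):
        unknown = [x for x in metrics if x not in KNOWN_METRICS]
        if unknown:
            raise ValueError(f"unknown metric(s): {unknown}; known: {list(KNOWN_METRICS)}")
        self.metrics = list(metrics)
        index = build_branch_index(tree, m)
        self.D_T = index.branch_taxon.T.astype(np.float32)  # (n_taxa, n_branches)
        self.L = index.lengths.astype(np.float64)
        comp = make_equal_branch_tree(tree)
        self.L_comp = comp.lengths[1:].astype(np.float64)
        self.taxon_ranges = m.range_sizes().astype(np.float64)  # fixed under null

    def compute(self, X: np.ndarray) -> dict[str, np.ndarray]:
        B = X.astype(np.float32) @ self.D_T > 0.5  # (n_cells, n_branches)
        out: dict[str, np.ndarray] = {}
        need = set(self.metrics)
        Bf = B.astype(np.float64)
        if need & {"pd", "rpd"}:
            out["pd"] = Bf @ self.L
        if need & {"pd_comp", "rpd"}:
            out["pd_comp"] = Bf @ self.L_comp
        if need & {"pe", "pe_comp", "rpe"}:
            r = B.sum(axis=0).astype(np.float64)
            r = np.maximum(r, 1.0)
            if need & {"pe", "rpe"}:
                out["pe"] = Bf @ (self.L / r)
            if need & {"pe_comp", "rpe"}:
                out["pe_comp"] = Bf @ (self.L_comp / r)
        if "rpd" in need:
            out["rpd"] = out["pd"] / out["pd_comp"]
        if "rpe" in need:
            out["rpe"] = out["pe"] / out["pe_comp"]
        if "we" in need:
            out["we"] = X.astype(np.float64) @ (1.0 / self.taxon_ranges)
        return {k: v for k, v in out.items() if k in need}


def randomize_metrics(
    tree: Phylogeny,
    m: PresenceMatrix,
    config: RandomizationConfig,
    metrics: list[str] = ("pd", "rpd", "pe", "pe_comp", "rpe"),
) -> RandomizationResult:
    """Estimate per-cell significance of the requested metrics against the
    fixed-marginal null.

    All metrics are computed on the same shuffled replicate, so joint tests
    (CANAPE) see a common null. Tail counts are accumulated streaming;
    full null vectors are never stored.
    """
    metrics = list(metrics)
    engine = _MetricEngine(tree, m, metrics)
    observed = engine.compute(m.X)
    tol = 1e-9
    counts_ge = {k: np.zeros(m.n_cells, dtype=np.int64) for k in metrics}
    counts_le = {k: np.zeros(m.n_cells, dtype=np.int64) for k in metrics}
    trades = config.resolve_trades(m)
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_reps)
    M = m.X.astype(np.uint8).copy()
    for rep in range(config.n_reps):
        _run_trades(M, trades, int(seeds[rep]))
        null = engine.compute(M)
        for k in metrics:
            counts_ge[k] += null[k] >= observed[k] - tol
            counts_le[k] += null[k] <= observed[k] + tol
    result = RandomizationResult(
        cells=list(m.cells),
        cell_ids=m.cell_ids,
        metrics={
            k: MetricNull(observed[k], counts_ge[k], counts_le[k], config.n_reps)
            for k in metrics
        },
        n_reps=config.n_reps,
        seed=config.seed,
        centers=m.cell_centers(),
    )
    return result


def significance_code(
    result: RandomizationResult | MetricNull,
    metric: str | None = None,
    alpha: float = 0.05,
    tails: int = 2,
) -> np.ndarray:
    """Per-cell codes in {"sig_low", "ns", "sig_high"}.

    Two-tailed: each tail is tested at alpha/2. One-tailed (tails=1) tests
    only the high tail at alpha.
    """
    mn = result if isinstance(result, MetricNull) else result[metric]
    codes = np.full(len(mn.observed), "ns", dtype=object)
    if tails == 2:
        codes[mn.p_high <= alpha / 2] = "sig_high"
        codes[mn.p_low <= alpha / 2] = "sig_low"
    elif tails == 1:
        codes[mn.p_high <= alpha] = "sig_high"
    else:
        raise ValueError("tails must be 1 or 2")
    return codes
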