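"""Cross-tabulation of endemism categories and turnover clusters against
climate variables."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["crosstab_by_threshold", "cluster_climate_summary"]


def _category_series(categories) -> pd.Series:
    if isinstance(categories, pd.DataFrame):
        if "category" not in categories.columns:
            raise ValueError("category table needs a 'category' column")
        s = categories["category"]
    else:
        s = pd.Series(categories)
    s = s.astype(str)
    s.index = s.index.astype(str)
    return s


def crosstab_by_threshold(
    categories,
    climate: pd.DataFrame,
    variable: str,
    threshold: float,
    strict: bool = True,
) -> pd.DataFrame:
    """Count, per category, the cells below a climate threshold.

    Comparison is strict ``<``. The output has one row per category present
    plus an ``ALL`` row over every categorized cell; columns are
    ``n_cells, n_below, frac_below``. Categorized cells without a climate
    row raise when ``strict`` (listing them) and are otherwise excluded
    with a warning.
    """
    cats = _category_series(categories)
    if variable not in climate.columns:
        raise KeyError(f"climate variable {variable!r} not found")
    clim = climate[variable]
    clim.index = clim.index.astype(str)
    missing = sorted(set(cats.index) - set(clim.index))
    if missing:
        if strict:
            raise KeyError(f"cells without climate rows: {missing}")
        logger.warning("excluding %d cells without climate rows: %s", len(missing), missing)
        cats = cats.drop(index=missing)
    if len(cats) == 0:
        raise ValueError("no categorized cells with climate data")
    below = clim.loc[cats.index] < threshold
    rows = {}
    for cat, grp in below.groupby(cats):
        rows[cat] = (len(grp), int(grp.sum()))
    rows["ALL"] = (len(below), int(below.sum()))
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["n_cells", "n_below"])
    out["frac_below"] = out["n_below"] / out["n_cells"]
    out.index.name = "category"
    return out.sort_index()


def cluster_climate_summary(
    labels: pd.Series, climate: pd.DataFrame, metrics: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster mean/min/max of each climate variable, plus a long-format
    scatter table (cell, cluster, variable, value[, metric columns]) for
    plotting."""
    labels = pd.Series(labels)
    labels.index = labels.index.astype(str)
    clim = climate.copy()
    clim.index = clim.index.astype(str)
    missing = sorted(set(labels.index) - set(clim.index))
    if missing:
        raise KeyError(f"cells without climate rows: {missing}")
    clim = clim.loc[labels.index]
    summary = clim.groupby(labels).agg(["mean", "min", "max"])
    summary.columns = [f"{v}_{s}" for v, s in summary.columns]
    summary.index.name = "cluster"

    scatter = clim.stack().rename("value").reset_index()
    scatter.columns = ["cell_id", "variable", "value"]
    scatter["cluster"] = labels.loc[scatter["cell_id"]].to_numpy()
    if metrics is not None:
        met = metrics.copy()
        met.index = met.index.astype(str)
        for col in met.columns:
            if col in ("x", "y"):
                continue
            scatter[col] = met[col].reindex(scatter["cell_id"]).to_numpy()
    return summary, scatter
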