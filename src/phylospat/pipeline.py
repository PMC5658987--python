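"""End-to-end orchestration: rasterize -> metrics -> randomize -> CANAPE ->
turnover -> climate summaries, per tree variant and per taxon subset.

Tree variants and subsets reuse the same randomization seed so that
differences between runs reflect the inputs, not Monte Carlo noise. Every
output table carries the config hash and seed in a header comment.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .canape import CanapeConfig, canape_classify
from .climate_summary import crosstab_by_threshold
from .diversity import build_branch_index, cell_metrics
from .grid_io import (
    GridSpec,
    PresenceMatrix,
    align_tree_and_matrix,
    apply_otu_map,
    load_climate,
    load_occurrences,
    load_otu_map,
    rasterize_points,
    read_tree,
    write_cell_table,
)
from .nullmodel import RandomizationConfig, randomize_metrics, significance_code
from .turnover import cut_dendrogram, turnover_matrix, upgma

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "run_full", "canape_agreement"]

METRICS = ("pd", "rpd", "pe", "pe_comp", "rpe")


@dataclass
class PipelineConfig:
    trees: dict  # name -> tree file path
    occurrences: str
    out_dir: str
    otu_map: str | None = None
    climate: str | None = None
    grid: GridSpec = field(default_factory=GridSpec)
    tree_format: str = "newick"
    rand: RandomizationConfig = field(default_factory=RandomizationConfig)
    canape: CanapeConfig = field(default_factory=CanapeConfig)
    subsets: dict = field(default_factory=dict)  # name -> list of taxa
    turnover_k: int | None = None
    climate_var: str = "precip"
    climate_threshold: float = 500.0
    align_mode: str = "strict"

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("at least one tree is required")

    def to_dict(self) -> dict:
        return {
            "trees": dict(self.trees),
            "occurrences": self.occurrences,
            "otu_map": self.otu_map,
            "climate": self.climate,
            "grid": [self.grid.origin_x, self.grid.origin_y, self.grid.cell_size],
            "tree_format": self.tree_format,
            "rand": [self.rand.n_reps, self.rand.seed, self.rand.trades_per_rep],
            "canape": [self.canape.alpha_pe, self.canape.alpha_rpe, self.canape.alpha_super],
            "subsets": {k: sorted(v) for k, v in self.subsets.items()},
            "turnover_k": self.turnover_k,
            "climate_var": self.climate_var,
            "climate_threshold": self.climate_threshold,
            "align_mode": self.align_mode,
        }

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Load a flat YAML config. Keys mirror PipelineConfig fields; grid is
    given as origin_x/origin_y/cell_size, rand as n_reps/seed/trades_per_rep,
    canape as alpha_pe/alpha_rpe/alpha_super."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    grid = GridSpec(
        float(raw.get("origin_x", 0.0)),
        float(raw.get("origin_y", 0.0)),
        float(raw.get("cell_size", 15_000.0)),
    )
    rand = RandomizationConfig(
        n_reps=int(raw.get("n_reps", 999)),
        seed=int(raw.get("seed", 0)),
        trades_per_rep=raw.get("trades_per_rep"),
    )
    canape = CanapeConfig(
        alpha_pe=float(raw.get("alpha_pe", 0.05)),
        alpha_rpe=float(raw.get("alpha_rpe", 0.025)),
        alpha_super=float(raw.get("alpha_super", 0.01)),
    )
    trees = raw["trees"]
    if isinstance(trees, str):
        trees = {"tree": trees}
    return PipelineConfig(
        trees=trees,
        occurrences=raw["occurrences"],
        out_dir=raw.get("out_dir", "out"),
        otu_map=raw.get("otu_map"),
        climate=raw.get("climate"),
        grid=grid,
        tree_format=raw.get("tree_format", "newick"),
        rand=rand,
        canape=canape,
        subsets=raw.get("subsets", {}) or {},
        turnover_k=raw.get("turnover_k"),
        climate_var=raw.get("climate_var", "precip"),
        climate_threshold=float(raw.get("climate_threshold", 500.0)),
        align_mode=raw.get("align_mode", "strict"),
    )


def canape_agreement(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Cross-classification of CANAPE categories between two runs, over
    their shared cells."""
    shared = a.index.intersection(b.index)
    return pd.crosstab(
        a.loc[shared, "category"], b.loc[shared, "category"], dropna=False
    )


def _run_one(tree, m, cfg: PipelineConfig):
    metrics_df = cell_metrics(tree, m)
    rand = randomize_metrics(tree, m, cfg.rand, list(METRICS))
    rand_df = rand.to_frame()
    for name in ("pd", "rpd"):
        rand_df[f"{name}_code"] = significance_code(rand, name, cfg.rand.alpha_two_tail, tails=2)
    canape_df = canape_classify(rand, cfg.canape)
    out = {"metrics": metrics_df, "rand": rand_df, "canape": canape_df}

    sig_cells = canape_df.index[canape_df["category"] != "NS"]
    if cfg.turnover_k is not None and len(sig_cells) >= 2:
        index = build_branch_index(tree, m)
        D = turnover_matrix(list(sig_cells), index)
        dend = upgma(D)
        k = min(cfg.turnover_k, len(sig_cells))
        labels = cut_dendrogram(dend, k=k)
        out["turnover"] = D
        out["dendrogram"] = dend
        out["clusters"] = labels
    return out


def run_full(cfg: PipelineConfig) -> dict:
    """Run the full analysis; returns {tree_name: {subset_name: results}}
    plus CANAPE agreement tables between tree variants, writing everything
    under ``out_dir/{tree}/{subset}/``."""
    occ = load_occurrences(cfg.occurrences)
    if cfg.otu_map:
        occ = apply_otu_map(occ, load_otu_map(cfg.otu_map))
    m_full = rasterize_points(occ, cfg.grid)
    logger.info("rasterized %d cells x %d taxa", m_full.n_cells, m_full.n_taxa)
    climate = load_climate(cfg.climate) if cfg.climate else None
    out_dir = Path(cfg.out_dir)
    header = f"config_hash={cfg.hash()} seed={cfg.rand.seed}"

    subsets = {"all": None, **cfg.subsets}
    results: dict = {}
    for tname, tpath in cfg.trees.items():
        tree0 = read_tree(tpath, cfg.tree_format)
        results[tname] = {}
        for sname, taxa in subsets.items():
            m = m_full if taxa is None else m_full.select_taxa(
                [t for t in m_full.taxa if t in set(taxa)]
            )
            tree, m = align_tree_and_matrix(tree0, m, mode=cfg.align_mode)
            logger.info(
                "[%s/%s] %d cells x %d taxa after alignment",
                tname, sname, m.n_cells, m.n_taxa,
            )
            res = _run_one(tree, m, cfg)
            if climate is not None and "clusters" in res:
                from .climate_summary import cluster_climate_summary

                summary, scatter = cluster_climate_summary(
                    res["clusters"], climate, metrics=res["metrics"]
                )
                res["cluster_climate"] = summary
                res["scatter"] = scatter
            if climate is not None:
                res["crosstab"] = crosstab_by_threshold(
                    res["canape"], climate, cfg.climate_var, cfg.climate_threshold,
                    strict=False,
                )
            results[tname][sname] = res

            d = out_dir / tname / sname
            d.mkdir(parents=True, exist_ok=True)
            write_cell_table(res["metrics"], d / "metrics.csv", header_comment=header)
            write_cell_table(res["rand"], d / "rand.csv", header_comment=header)
            write_cell_table(res["canape"], d / "canape.csv", header_comment=header)
            if "clusters" in res:
                write_cell_table(
                    res["clusters"].to_frame(), d / "clusters.csv",
                    grid=cfg.grid, header_comment=header,
                )
                (d / "dendrogram.nwk").write_text(res["dendrogram"].to_newick() + "\n")
                res["turnover"].to_csv(d / "turnover.csv", float_format="%.17g")
            if "crosstab" in res:
                res["crosstab"].to_csv(d / "crosstab.csv", float_format="%.17g")

    tree_names = list(cfg.trees)
    agreements = {}
    for i, a in enumerate(tree_names):
        for b in tree_names[i + 1:]:
            tab = canape_agreement(results[a]["all"]["canape"], results[b]["all"]["canape"])
            agreements[(a, b)] = tab
            tab.to_csv(out_dir / f"agreement_{a}_vs_{b}.csv")
    results["_agreement"] = agreements
    return results
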