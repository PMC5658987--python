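"""Categorical classification of cells into neo-, paleo-, mixed, and super
endemism from the joint randomization of PE, PE on the comparison tree, and
their ratio RPE.

Step 1 flags candidate cells where either PE or PE_comp is one-tailed
significantly high. Step 2 splits candidates on the RPE tails: a
significantly low ratio marks concentrations of range-restricted short
branches (NEO), a significantly high ratio marks range-restricted long
branches (PALEO); the remainder is MIXED, upgraded to SUPER when both PE
tests pass a stricter level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid_io import Phylogeny, PresenceMatrix, align_tree_and_matrix
from .nullmodel import RandomizationConfig, RandomizationResult, randomize_metrics

__all__ = ["CanapeConfig", "CATEGORIES", "canape_classify", "subset_and_rerun"]

CATEGORIES = ("NS", "NEO", "PALEO", "MIXED", "SUPER")


@dataclass
class CanapeConfig:
    alpha_pe: float = 0.05  # one-tailed candidate level for PE / PE_comp
    alpha_rpe: float = 0.025  # per-tail level for the RPE split
    alpha_super: float = 0.01  # stricter PE level for the SUPER tier

    def __post_init__(self) -> None:
        if not self.alpha_super < self.alpha_pe:
            raise ValueError("alpha_super must be stricter than alpha_pe")
        if not (0 < self.alpha_rpe < 0.5):
            raise ValueError("alpha_rpe must lie in (0, 0.5)")


def canape_classify(
    rand: RandomizationResult, config: CanapeConfig | None = None
) -> pd.DataFrame:
    """Classify each cell; requires pe, pe_comp, and rpe from a common null.

    Returns a DataFrame indexed by cell id with the category and the
    p-values the decision used.
    """
    config = config or CanapeConfig()
    missing = [k for k in ("pe", "pe_comp", "rpe") if k not in rand.metrics]
    if missing:
        raise KeyError(f"randomization result lacks metric(s): {missing}")
    p_pe = rand["pe"].p_high
    p_pec = rand["pe_comp"].p_high
    p_rpe_hi = rand["rpe"].p_high
    p_rpe_lo = rand["rpe"].p_low

    candidate = (p_pe <= config.alpha_pe) | (p_pec <= config.alpha_pe)
    category = np.full(len(p_pe), "NS", dtype=object)
    neo = candidate & (p_rpe_lo <= config.alpha_rpe)
    paleo = candidate & ~neo & (p_rpe_hi <= config.alpha_rpe)
    mixed = candidate & ~neo & ~paleo
    super_ = mixed & (p_pe <= config.alpha_super) & (p_pec <= config.alpha_super)
    category[neo] = "NEO"
    category[paleo] = "PALEO"
    category[mixed & ~super_] = "MIXED"
    category[super_] = "SUPER"

    out = pd.DataFrame(
        {
            "category": category,
            "p_pe": p_pe,
            "p_pe_comp": p_pec,
            "p_rpe_high": p_rpe_hi,
            "p_rpe_low": p_rpe_lo,
        },
        index=pd.Index(rand.cell_ids, name="cell_id"),
    )
    if rand.centers is not None:
        out.insert(0, "y", rand.centers[:, 1])
        out.insert(0, "x", rand.centers[:, 0])
    return out


def subset_and_rerun(
    tree: Phylogeny,
    m: PresenceMatrix,
    taxon_subset,
    rand_config: RandomizationConfig | None = None,
    canape_config: CanapeConfig | None = None,
    metrics: tuple[str, ...] = ("pd", "rpd", "pe", "pe_comp", "rpe"),
):
    """Rerun metrics, randomization, and CANAPE on a taxon subset.

    The tree and matrix are pruned to the subset; cells emptied by the
    pruning are dropped (not coded NS), and range sizes are recomputed on
    the subset matrix.
    """
    from .diversity import cell_metrics

    subset = set(taxon_subset)
    if not subset:
        raise ValueError("empty taxon subset")
    shared = subset & set(m.taxa) & set(tree.tip_labels)
    if not shared:
        raise ValueError("subset shares no taxa with the tree and matrix")
    m_sub = m.select_taxa([t for t in m.taxa if t in shared])
    tree_sub, m_sub = align_tree_and_matrix(tree, m_sub, mode="strict")
    rand_config = rand_config or RandomizationConfig()
    metrics_df = cell_metrics(tree_sub, m_sub)
    rand = randomize_metrics(tree_sub, m_sub, rand_config, list(metrics))
    table = canape_classify(rand, canape_config)
    return metrics_df, rand, table
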