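"""Equity-adjusted cost-effectiveness and league-table comparison.

An intervention inherits the equity weight of its linked condition(s); its
CER (cost per unit health benefit) is then divided by that weight —
equivalently, the health-benefit denominator is multiplied by the weight —
so an intervention with weight 2 sees its CER halved while weight 1 leaves
it unchanged. Interventions are ranked ascending by CER (rank 1 = most
cost-effective) before and after adjustment, and the two rankings are
compared: which interventions enter or leave the top k, per-intervention
rank shifts, and the Kendall tau-b rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from equicea.panel_io import ReferentialError, SchemaError

__all__ = [
    "intervention_equity",
    "adjust_cer",
    "build_league",
    "compare_rankings",
    "RankComparison",
]

MULTI_CONDITION_MODES = ("mean", "max", "min")


def intervention_equity(
    interventions: pd.DataFrame,
    equity: pd.DataFrame,
    multi_mode: str = "mean",
) -> pd.Series:
    """Equity weight per intervention, inherited from linked conditions.

    Single-condition interventions take that condition's weight directly;
    interventions spanning several conditions combine the linked weights
    with ``multi_mode`` ("mean" by default, or "max"/"min").
    """
    if multi_mode not in MULTI_CONDITION_MODES:
        raise ValueError(f"multi_mode must be one of {MULTI_CONDITION_MODES}")
    combine = {"mean": np.mean, "max": np.max, "min": np.min}[multi_mode]
    weight_by_condition = equity.set_index(
        equity["condition_id"].astype(str)
    )["equity_weight"]
    out = []
    for iid, cids in zip(
        interventions["intervention_id"], interventions["condition_ids"]
    ):
        unknown = [c for c in cids if c not in weight_by_condition.index]
        if unknown:
            raise ReferentialError(
                f"intervention {iid!r}: no equity weight for condition(s) "
                f"{', '.join(unknown)}"
            )
        out.append(float(combine([weight_by_condition[c] for c in cids])))
    return pd.Series(
        out,
        index=pd.Index(interventions["intervention_id"].astype(str), name="intervention_id"),
        name="equity_weight",
    )


def adjust_cer(cer: float, equity_weight: float) -> float:
    """Equity-adjusted CER: the health-benefit denominator is scaled by the
    weight, so ``adjusted = cer / equity_weight``.

    A weight of 2 halves the CER; a weight of 1 leaves it unchanged. Weights
    outside [1, 2] or non-positive CERs are rejected.
    """
    if not cer > 0:
        raise ValueError(f"CER must be positive, got {cer}")
    if not 1.0 <= equity_weight <= 2.0:
        raise ValueError(f"equity weight must lie in [1, 2], got {equity_weight}")
    return cer / equity_weight


def build_league(
    interventions: pd.DataFrame,
    weights: pd.Series,
) -> pd.DataFrame:
    """League table with unadjusted and equity-adjusted CER ranks.

    Ranks are assigned ascending (rank 1 = lowest cost per unit benefit),
    separately for the raw and the adjusted CER; ties are broken by
    lexicographic intervention_id so output is fully deterministic.

    Returns a DataFrame sorted by ``rank_adjusted`` with columns
    ``intervention_id``, ``name``, ``cer``, ``equity_weight``,
    ``adjusted_cer``, ``rank_cer``, ``rank_adjusted``, ``rank_delta``
    (positive = improved by the adjustment).
    """
    ids = interventions["intervention_id"].astype(str)
    if ids.duplicated().any():
        raise SchemaError("duplicate intervention_id in league input")
    w = weights.reindex(ids)
    if w.isna().any():
        missing = ids[w.isna().to_numpy()].tolist()[:5]
        raise ReferentialError(f"no equity weight for intervention(s): {missing}")
    table = pd.DataFrame(
        {
            "intervention_id": ids.to_numpy(),
            "name": interventions["name"].to_numpy(),
            "cer": interventions["cer"].to_numpy(dtype=float),
            "equity_weight": w.to_numpy(dtype=float),
        }
    )
    table["adjusted_cer"] = table["cer"] / table["equity_weight"]

    def ranks(by: str) -> np.ndarray:
        order = table.sort_values(
            [by, "intervention_id"], kind="stable"
        ).index.to_numpy()
        r = np.empty(len(order), dtype=int)
        r[order] = np.arange(1, len(order) + 1)
        return r

    table["rank_cer"] = ranks("cer")
    table["rank_adjusted"] = ranks("adjusted_cer")
    table["rank_delta"] = table["rank_cer"] - table["rank_adjusted"]
    return table.sort_values("rank_adjusted", kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class RankComparison:
    """How the league-table ranking changed after equity adjustment."""

    k: int
    entered_top_k: frozenset[str]
    exited_top_k: frozenset[str]
    rank_delta: pd.Series
    rank_correlation: float


def compare_rankings(league: pd.DataFrame, k: int) -> RankComparison:
    """Compare the raw and equity-adjusted rankings of a league table.

    ``entered_top_k`` are interventions inside the adjusted top k but
    outside the unadjusted one (the paper's "now included" set); exits are
    the converse, and the two sets always have equal size. Rank correlation
    is Kendall's tau-b, which tolerates the ties equity adjustment can
    create.
    """
    n = len(league)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    by_id = league.set_index(league["intervention_id"].astype(str))
    top_raw = set(by_id.index[by_id["rank_cer"] <= k])
    top_adj = set(by_id.index[by_id["rank_adjusted"] <= k])
    tau = stats.kendalltau(
        by_id["rank_cer"].to_numpy(), by_id["rank_adjusted"].to_numpy()
    ).statistic
    return RankComparison(
        k=k,
        entered_top_k=frozenset(top_adj - top_raw),
        exited_top_k=frozenset(top_raw - top_adj),
        rank_delta=(by_id["rank_cer"] - by_id["rank_adjusted"]).rename("rank_delta"),
        rank_correlation=float(tau),
    )
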