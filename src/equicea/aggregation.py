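"""Aggregation of raw panel scores into condition and group summaries.

The panel's raw output is an experts x conditions ordinal sheet; the
quantity the rest of the pipeline runs on is the per-condition mean over
non-missing scores. Conditions are also rolled up into GBD-level-2 cause
groups by an unweighted mean of the member condition means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from equicea.panel_io import ReferentialError, ScoreMatrix, VALID_SCORES

__all__ = ["mean_scores", "score_distribution", "group_means"]


def mean_scores(matrix: ScoreMatrix) -> pd.DataFrame:
    """Per-condition summary of the panel scores.

    Returns a DataFrame with one row per condition, in sheet column order:
    ``condition_id``, ``mean_score`` (mean over non-missing scores),
    ``n_raters``, and counts ``c1``..``c4`` of each score level.
    """
    scores = matrix.scores
    observed = ~np.isnan(scores)
    n_raters = observed.sum(axis=0)
    # ScoreMatrix validation guarantees n_raters >= 1, but recheck so the
    # error names the condition if an unvalidated array sneaks through.
    if (n_raters == 0).any():
        cid = matrix.condition_ids[int(np.argmax(n_raters == 0))]
        raise ValueError(f"condition {cid!r} has zero raters")
    means = np.nansum(scores, axis=0) / n_raters
    counts = {
        f"c{v}": (scores == v).sum(axis=0).astype(int) for v in VALID_SCORES
    }
    return pd.DataFrame(
        {
            "condition_id": list(matrix.condition_ids),
            "mean_score": means,
            "n_raters": n_raters.astype(int),
            **counts,
        }
    )


def score_distribution(matrix: ScoreMatrix, condition_id: str) -> tuple[int, int, int, int]:
    """Counts of scores 1..4 given to one condition (missing cells excluded)."""
    try:
        j = matrix.condition_ids.index(str(condition_id))
    except ValueError:
        raise KeyError(f"unknown condition id {condition_id!r}") from None
    col = matrix.scores[:, j]
    return tuple(int((col == v).sum()) for v in VALID_SCORES)


def group_means(summaries: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean of condition mean scores within each GBD-level-2 group.

    Every condition in ``summaries`` must appear in ``meta``; groups are
    returned sorted by descending mean score, one row per label with columns
    ``gbd_level2``, ``mean_score`` and ``n_conditions``.
    """
    meta_idx = meta.set_index(meta["condition_id"].astype(str))
    missing = [
        cid for cid in summaries["condition_id"].astype(str) if cid not in meta_idx.index
    ]
    if missing:
        raise ReferentialError(
            f"condition(s) missing from metadata: {', '.join(missing[:5])}"
        )
    joined = summaries.assign(
        gbd_level2=summaries["condition_id"].astype(str).map(meta_idx["gbd_level2"])
    )
    out = (
        joined.groupby("gbd_level2", sort=False)["mean_score"]
        .agg(mean_score="mean", n_conditions="size")
        .reset_index()
        .sort_values("mean_score", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    out["n_conditions"] = out["n_conditions"].astype(int)
    return out
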