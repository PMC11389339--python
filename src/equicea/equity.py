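"""From per-condition mean scores to standardized equity weights.

The procedure has four steps, applied in order:

1. sort conditions by mean score, descending;
2. split the sorted list into three contiguous categories (high, medium,
   low) with sizes as close to equal as the ties allow — tied means never
   straddle a category boundary;
3. lift every MCH-flagged condition (predominantly affecting women or
   children) that landed in medium or low up to the minimum mean score of
   the high category, leaving all other conditions untouched;
4. min-max standardize the post-reassignment scores to the equity-weight
   range [1, 2], so the least equity-relevant condition carries weight 1
   and the most relevant carries weight 2 (twice the weight on its health
   gains).

Alternatively, step 2 can use user-supplied score cut-points instead of
equal-count tertiles.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from equicea.panel_io import ReferentialError, ScoreMatrix
from equicea.aggregation import mean_scores

__all__ = ["categorize", "mch_reassign", "standardize", "build_equity_table"]

logger = logging.getLogger(__name__)

CATEGORIES = ("high", "medium", "low")


def _tertile_sizes(groups: list[int], n: int) -> tuple[int, ...]:
    """Split tie-group sizes into three consecutive blocks, closest to equal.

    ``groups`` holds the sizes of maximal runs of tied means, in descending
    score order. A boundary may fall only between two runs, so tied means
    always share a category. Among all placements the one whose block sizes
    are closest (L1) to the equal-count target is chosen; the target puts
    remainder conditions in earlier blocks.
    """
    m = len(groups)
    if m == 1:
        return (groups[0], 0, 0)
    if m == 2:
        return (groups[0], groups[1], 0)
    base, rem = divmod(n, 3)
    target = tuple(base + (1 if k < rem else 0) for k in range(3))
    cum = list(itertools.accumulate(groups))
    best: tuple | None = None
    for i in range(1, m - 1):
        for j in range(i + 1, m):
            sizes = (cum[i - 1], cum[j - 1] - cum[i - 1], n - cum[j - 1])
            key = (
                sum(abs(s - t) for s, t in zip(sizes, target)),
                abs(sizes[0] - target[0]),
                abs(sizes[1] - target[1]),
                i,
                j,
            )
            if best is None or key < best[0]:
                best = (key, sizes)
    assert best is not None
    return best[1]


def categorize(
    summaries: pd.DataFrame,
    cutpoints: tuple[float, float] | None = None,
) -> pd.Series:
    """Assign each condition to the high, medium or low equity category.

    Parameters
    ----------
    summaries
        Output of :func:`equicea.aggregation.mean_scores` (needs columns
        ``condition_id`` and ``mean_score``).
    cutpoints
        Optional ``(high_min, medium_min)`` score thresholds. When given,
        a condition is high if its mean is >= ``high_min``, medium if
        >= ``medium_min``, else low. When omitted (default) the conditions
        are sorted descending and split into equal-count tertiles, with
        boundaries placed so that tied means share a category.

    Returns
    -------
    pandas.Series
        Category label per condition, indexed by condition_id, in the input
        row order.
    """
    if len(summaries) < 3:
        raise ValueError("categorization needs at least 3 conditions")
    ids = summaries["condition_id"].astype(str).to_numpy()
    means = summaries["mean_score"].to_numpy(dtype=float)

    if cutpoints is not None:
        high_min, medium_min = cutpoints
        if high_min <= medium_min:
            raise ValueError("cutpoints must satisfy high_min > medium_min")
        labels = np.where(
            means >= high_min, "high", np.where(means >= medium_min, "medium", "low")
        )
        return pd.Series(labels, index=pd.Index(ids, name="condition_id"), name="category")

    # Stable descending sort: ties keep input order.
    order = np.argsort(-means, kind="stable")
    sorted_means = means[order]
    group_sizes: list[int] = []
    for k, mean in enumerate(sorted_means):
        if k and mean == sorted_means[k - 1]:
            group_sizes[-1] += 1
        else:
            group_sizes.append(1)
    sizes = _tertile_sizes(group_sizes, len(sorted_means))
    labels_sorted = np.repeat(list(CATEGORIES), sizes)
    labels = np.empty(len(ids), dtype=object)
    labels[order] = labels_sorted
    return pd.Series(labels, index=pd.Index(ids, name="condition_id"), name="category")


def mch_reassign(
    summaries: pd.DataFrame,
    categories: pd.Series,
    meta: pd.DataFrame,
) -> pd.Series:
    """Lift medium/low MCH conditions to the high-category minimum score.

    Conditions flagged as predominantly affecting women or children, when
    categorized medium or low, receive the mean score of the lowest-scoring
    high-category condition; every other condition keeps its raw mean.
    Because every medium/low mean is at most the high-category minimum, the
    reassignment never lowers a score.
    """
    ids = summaries["condition_id"].astype(str)
    means = pd.Series(
        summaries["mean_score"].to_numpy(dtype=float),
        index=pd.Index(ids, name="condition_id"),
        name="post_mch_score",
    )
    cats = categories.reindex(means.index)
    if cats.isna().any():
        raise ReferentialError("categories missing for some conditions")
    high_means = means[cats == "high"]
    if high_means.empty:
        raise ValueError("high category is empty; cannot reassign MCH conditions")
    high_min = float(high_means.min())

    meta_idx = meta.set_index(meta["condition_id"].astype(str))["mch_flag"]
    mch = means.index.to_series().map(meta_idx)
    if mch.isna().any():
        missing = mch.index[mch.isna()][:5].tolist()
        raise ReferentialError(f"condition(s) missing from metadata: {missing}")
    lifted = mch.astype(bool) & (cats != "high")
    out = means.copy()
    out[lifted] = high_min
    return out


def standardize(
    scores: pd.Series | np.ndarray,
    target_range: tuple[float, float] = (1.0, 2.0),
) -> pd.Series | np.ndarray:
    """Min-max standardize scores to the equity-weight range (default [1, 2]).

    The map is affine and order-preserving: the minimum score receives the
    lower bound, the maximum the upper bound. If all scores are identical
    there is no equity differentiation; every weight is set to the lower
    bound and a warning is logged.
    """
    lo, hi = target_range
    if not hi > lo:
        raise ValueError("target range must have upper bound > lower bound")
    values = np.asarray(scores, dtype=float)
    s_min, s_max = values.min(), values.max()
    if s_max == s_min:
        logger.warning(
            "all scores identical (%.4g): no equity differentiation, "
            "every weight set to %.4g",
            s_min,
            lo,
        )
        weights = np.full_like(values, lo)
    else:
        weights = lo + (hi - lo) * (values - s_min) / (s_max - s_min)
    if isinstance(scores, pd.Series):
        return pd.Series(weights, index=scores.index, name="equity_weight")
    return weights


def build_equity_table(
    matrix: ScoreMatrix,
    meta: pd.DataFrame,
    cutpoints: tuple[float, float] | None = None,
    target_range: tuple[float, float] = (1.0, 2.0),
) -> pd.DataFrame:
    """Run the full equity-scoring pipeline on a score sheet.

    Composes mean scores -> categorization -> MCH reassignment ->
    standardization (standardization runs on the post-reassignment scores).

    Returns a DataFrame with one row per condition in sheet order:
    ``condition_id``, ``name``, ``mch_flag``, ``raw_mean``, ``category``,
    ``post_mch_score``, ``equity_weight``.
    """
    summaries = mean_scores(matrix)
    categories = categorize(summaries, cutpoints=cutpoints)
    post = mch_reassign(summaries, categories, meta)
    weights = standardize(post, target_range=target_range)
    meta_idx = meta.set_index(meta["condition_id"].astype(str))
    ids = summaries["condition_id"].astype(str)
    return pd.DataFrame(
        {
            "condition_id": ids,
            "name": ids.map(meta_idx["name"]).fillna(""),
            "mch_flag": ids.map(meta_idx["mch_flag"]).astype(bool),
            "raw_mean": summaries["mean_score"].to_numpy(dtype=float),
            "category": categories.to_numpy(),
            "post_mch_score": post.to_numpy(),
            "equity_weight": weights.to_numpy(),
        }
    )
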