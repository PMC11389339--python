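"""End-to-end orchestration: read inputs, run every stage, write artifacts.

A run consumes the three input tables (score sheet, condition metadata,
interventions) and writes six artifacts plus a JSON manifest into the
output directory:

* ``condition_summaries.csv`` — per-condition mean scores and score counts
* ``group_summaries.csv``     — GBD-level-2 group averages
* ``equity_table.csv``        — category, post-MCH score, equity weight
* ``league_table.csv``        — both CER rankings and rank deltas
* ``rank_comparison.csv``     — per-intervention rank shift at top-k
* ``rank_comparison.json``    — entered/exited sets and Kendall tau-b
* ``manifest.json``           — config echo, package version, row counts

The manifest is written even when a stage fails, with the error recorded,
so a run directory is always self-describing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from equicea import panel_io
from equicea.aggregation import group_means, mean_scores
from equicea.equity import build_equity_table
from equicea.league import build_league, compare_rankings, intervention_equity

__all__ = ["RunConfig", "run_pipeline", "report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Paths and knobs for one pipeline run."""

    scores_path: str
    meta_path: str
    interventions_path: str
    out_dir: str
    orientation: str = "experts"
    cutpoints: tuple[float, float] | None = None
    target_range: tuple[float, float] = (1.0, 2.0)
    multi_mode: str = "mean"
    top_k: int = 30
    seed: int | None = None


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all artifacts; returns the manifest dict.

    Raises the first stage error after recording it in the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "package": "equicea",
        "version": __import__("equicea").__version__,
        "status": "running",
        "row_counts": {},
    }
    try:
        for path_attr in ("scores_path", "meta_path", "interventions_path"):
            p = Path(getattr(config, path_attr))
            if not p.exists():
                raise FileNotFoundError(f"input file not found: {p}")
        matrix = panel_io.read_score_sheet(
            config.scores_path, orientation=config.orientation
        )
        meta = panel_io.read_condition_meta(config.meta_path)
        interventions = panel_io.read_interventions(
            config.interventions_path, meta=meta
        )
        manifest["row_counts"]["experts"] = matrix.n_experts
        manifest["row_counts"]["conditions"] = matrix.n_conditions
        manifest["row_counts"]["interventions"] = len(interventions)

        summaries = mean_scores(matrix)
        summaries.to_csv(out / "condition_summaries.csv", index=False)

        groups = group_means(summaries, meta)
        groups.to_csv(out / "group_summaries.csv", index=False)
        manifest["row_counts"]["gbd_level2_groups"] = len(groups)

        equity = build_equity_table(
            matrix, meta, cutpoints=config.cutpoints, target_range=config.target_range
        )
        equity.to_csv(out / "equity_table.csv", index=False)

        weights = intervention_equity(
            interventions, equity, multi_mode=config.multi_mode
        )
        league = build_league(interventions, weights)
        league.to_csv(out / "league_table.csv", index=False)

        comparison = compare_rankings(league, k=config.top_k)
        comparison.rank_delta.sort_index().to_frame().to_csv(
            out / "rank_comparison.csv"
        )
        with open(out / "rank_comparison.json", "w") as fh:
            json.dump(
                {
                    "k": comparison.k,
                    "entered_top_k": sorted(comparison.entered_top_k),
                    "exited_top_k": sorted(comparison.exited_top_k),
                    "kendall_tau_b": comparison.rank_correlation,
                },
                fh,
                indent=2,
            )
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "error"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    logger.info("pipeline complete: %s", out)
    return manifest


def report(league_path: str | Path, k: int = 30) -> str:
    """Human-readable top-k summary of a written league table.

    Lists the top-k interventions by unadjusted and by equity-adjusted CER
    and flags which interventions entered or left the top k.
    """
    league = pd.read_csv(league_path)
    comparison = compare_rankings(league, k=k)
    by_raw = league.sort_values("rank_cer").head(k)
    by_adj = league.sort_values("rank_adjusted").head(k)
    lines = [f"Top {k} interventions (of {len(league)})", ""]
    lines.append(f"{'rank':>4}  {'by CER':<28}  {'by equity-adjusted CER':<28}")
    for r, (raw_id, adj_id) in enumerate(
        zip(by_raw["intervention_id"], by_adj["intervention_id"]), start=1
    ):
        marker = " *" if adj_id in comparison.entered_top_k else "  "
        lines.append(f"{r:>4}  {raw_id:<28}  {adj_id:<26}{marker}")
    lines.append("")
    if comparison.entered_top_k or comparison.exited_top_k:
        lines.append(
            f"entered top {k} after equity adjustment: "
            + ", ".join(sorted(comparison.entered_top_k))
        )
        lines.append(
            f"exited top {k} after equity adjustment:  "
            + ", ".join(sorted(comparison.exited_top_k))
        )
    else:
        lines.append("no ranking changes within the top list")
    lines.append(f"Kendall tau-b between rankings: {comparison.rank_correlation:.4f}")
    return "\n".join(lines)
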