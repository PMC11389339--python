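import numpy as np
import pandas as pd
import pytest

from equicea.panel_io import ScoreMatrix


@pytest.fixture
def small_matrix() -> ScoreMatrix:
    """3 experts x 4 conditions, one missing cell, exercising all score levels."""
    scores = np.array(
        [
            [4.0, 3.0, 2.0, 1.0],
            [4.0, 3.0, 1.0, 1.0],
            [4.0, np.nan, 3.0, 2.0],
        ]
    )
    return ScoreMatrix(
        expert_ids=("E1", "E2", "E3"),
        condition_ids=("C1", "C2", "C3", "C4"),
        scores=scores,
    )


@pytest.fixture
def small_meta() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "condition_id": ["C1", "C2", "C3", "C4"],
            "name": ["anaemia", "fistula", "vitiligo", "measles"],
            "gbd_level2": ["nutritional", "maternal", "skin", "infectious"],
            "mch_flag": [False, True, False, True],
        }
    )


@pytest.fixture
def small_interventions() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "intervention_id": ["I1", "I2", "I3"],
            "name": ["iron supplementation", "fistula repair", "vaccination"],
            "condition_ids": [("C1",), ("C2",), ("C3", "C4")],
            "cer": [120.0, 45.0, 10.0],
        }
    )


def panel_from_columns(columns: dict[str, list[float]]) -> ScoreMatrix:
    """Build a ScoreMatrix from per-condition score lists (NaN = missing)."""
    n_experts = max(len(v) for v in columns.values())
    scores = np.full((n_experts, len(columns)), np.nan)
    for j, vals in enumerate(columns.values()):
        scores[: len(vals), j] = vals
    return ScoreMatrix(
        expert_ids=tuple(f"E{i}" for i in range(n_experts)),
        condition_ids=tuple(columns),
        scores=scores,
    )
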