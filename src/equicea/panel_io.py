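"""Readers, writers and schema validation for the panel's tabular artifacts.

Three kinds of tables move through the pipeline:

* an expert x condition score sheet of ordinal equity scores in {1,2,3,4},
  with missing cells allowed (an expert may abstain on a condition);
* condition metadata: display name, GBD-level-2 cause group, and a flag for
  conditions predominantly affecting women of reproductive age or under-five
  children (the MCH flag);
* an intervention table linking each intervention to one or more conditions
  together with its unadjusted cost-effectiveness ratio (CER, cost per unit
  of health benefit, e.g. US$ per DALY averted).

The canonical on-disk format is UTF-8 CSV with a header row. All ids are
opaque strings. Every reader has a round-trip writer. The score sheet is
stored experts-as-rows by default; ``orientation="conditions"`` transposes.
Multi-valued condition lists use ";" as the internal delimiter so they
survive CSV quoting untouched.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ReferentialError",
    "ScoreMatrix",
    "read_score_sheet",
    "write_score_sheet",
    "read_condition_meta",
    "write_condition_meta",
    "read_interventions",
    "write_interventions",
]

VALID_SCORES = (1, 2, 3, 4)

CONDITION_LIST_SEP = ";"

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f"}


class SchemaError(ValueError):
    """A table violates its declared schema (types, bounds, uniqueness)."""


class ReferentialError(SchemaError):
    """A table references an id that does not exist in its reference table."""


@dataclass(frozen=True)
class ScoreMatrix:
    """Ordinal Delphi scores, experts x conditions, with missing cells as NaN.

    ``scores`` is a float array of shape ``(n_experts, n_conditions)`` whose
    non-NaN entries are integers in {1, 2, 3, 4}.
    """

    expert_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]
    scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "expert_ids", tuple(str(e) for e in self.expert_ids))
        object.__setattr__(self, "condition_ids", tuple(str(c) for c in self.condition_ids))
        self._validate()

    def _validate(self) -> None:
        if len(self.expert_ids) == 0:
            raise SchemaError("score matrix has no experts")
        if len(self.condition_ids) == 0:
            raise SchemaError("score matrix has no conditions")
        if len(set(self.expert_ids)) != len(self.expert_ids):
            raise SchemaError("duplicate expert ids in score matrix")
        if len(set(self.condition_ids)) != len(self.condition_ids):
            raise SchemaError("duplicate condition ids in score matrix")
        if self.scores.shape != (len(self.expert_ids), len(self.condition_ids)):
            raise SchemaError(
                f"score array shape {self.scores.shape} does not match "
                f"{len(self.expert_ids)} experts x {len(self.condition_ids)} conditions"
            )
        observed = self.scores[~np.isnan(self.scores)]
        bad = observed[~np.isin(observed, VALID_SCORES)]
        if bad.size:
            i, j = np.argwhere(
                ~np.isnan(self.scores) & ~np.isin(self.scores, VALID_SCORES)
            )[0]
            raise SchemaError(
                f"score {self.scores[i, j]!r} for expert {self.expert_ids[i]!r}, "
                f"condition {self.condition_ids[j]!r} is outside {{1,2,3,4}}"
            )
        empty = np.isnan(self.scores).all(axis=0)
        if empty.any():
            cid = self.condition_ids[int(np.argmax(empty))]
            raise SchemaError(f"condition {cid!r} has no non-missing score")

    @property
    def n_experts(self) -> int:
        return len(self.expert_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    def to_frame(self) -> pd.DataFrame:
        """Experts-as-rows DataFrame (index expert_id, columns condition_id)."""
        return pd.DataFrame(
            self.scores,
            index=pd.Index(self.expert_ids, name="expert_id"),
            columns=pd.Index(self.condition_ids, name="condition_id"),
            copy=True,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ScoreMatrix":
        return cls(
            expert_ids=tuple(str(i) for i in frame.index),
            condition_ids=tuple(str(c) for c in frame.columns),
            scores=frame.to_numpy(dtype=float),
        )


def _parse_score_cell(raw: object, row: str, col: str) -> float:
    if raw is None:
        return math.nan
    if isinstance(raw, float) and math.isnan(raw):
        return math.nan
    text = str(raw).strip()
    if text == "" or text.upper() in {"NA", "NAN"}:
        return math.nan
    try:
        value = float(text)
    except ValueError:
        raise SchemaError(
            f"cell at row {row!r}, column {col!r}: {raw!r} is not a number"
        ) from None
    if not value.is_integer() or int(value) not in VALID_SCORES:
        raise SchemaError(
            f"cell at row {row!r}, column {col!r}: score {raw!r} is outside {{1,2,3,4}}"
        )
    return value


def read_score_sheet(
    path: str | Path | io.TextIOBase,
    orientation: Literal["experts", "conditions"] = "experts",
) -> ScoreMatrix:
    """Read a Delphi score sheet from CSV (or .xlsx when openpyxl is present).

    Parameters
    ----------
    path
        CSV file whose first column holds row ids and whose header row holds
        column ids. With ``orientation="experts"`` (default) rows are experts
        and columns are conditions; ``"conditions"`` means the transpose.
    orientation
        Which axis the rows represent.

    Raises
    ------
    SchemaError
        On any non-integer or out-of-range cell (the error names the row and
        column), or on duplicate ids.
    """
    if isinstance(path, (str, Path)) and str(path).endswith((".xlsx", ".xls")):
        frame = pd.read_excel(path, index_col=0, dtype=object)
    else:
        frame = pd.read_csv(path, index_col=0, dtype=object)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise SchemaError(f"duplicate row id {dup!r} in score sheet")
    if frame.columns.has_duplicates:
        raise SchemaError("duplicate column ids in score sheet")
    parsed = pd.DataFrame(
        [
            [_parse_score_cell(frame.iat[i, j], frame.index[i], frame.columns[j])
             for j in range(frame.shape[1])]
            for i in range(frame.shape[0])
        ],
        index=frame.index,
        columns=frame.columns,
        dtype=float,
    )
    if orientation == "conditions":
        parsed = parsed.T
    elif orientation != "experts":
        raise ValueError(f"unknown orientation {orientation!r}")
    return ScoreMatrix.from_frame(parsed)


def write_score_sheet(
    matrix: ScoreMatrix,
    path: str | Path | io.TextIOBase,
    orientation: Literal["experts", "conditions"] = "experts",
) -> None:
    """Write a score sheet as CSV; missing cells become empty fields."""
    frame = matrix.to_frame()
    if orientation == "conditions":
        frame = frame.T
    out = frame.map(lambda v: "" if math.isnan(v) else str(int(v)))
    out.to_csv(path)


def _parse_bool(raw: object, context: str) -> bool:
    text = str(raw).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise SchemaError(f"{context}: cannot parse {raw!r} as a boolean flag")


_META_COLUMNS = ("condition_id", "name", "gbd_level2", "mch_flag")


def read_condition_meta(path: str | Path | io.TextIOBase) -> pd.DataFrame:
    """Read condition metadata.

    Expected columns: ``condition_id``, ``name``, ``gbd_level2``,
    ``mch_flag`` (any of 0/1, true/false, yes/no). Returns a DataFrame with
    those columns, ``mch_flag`` as bool, and ids as strings.
    """
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in _META_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"condition metadata missing column(s): {', '.join(missing)}")
    frame = frame[list(_META_COLUMNS)].copy()
    frame["condition_id"] = frame["condition_id"].astype(str)
    if frame["condition_id"].duplicated().any():
        dup = frame.loc[frame["condition_id"].duplicated(), "condition_id"].iloc[0]
        raise SchemaError(f"duplicate condition_id {dup!r} in condition metadata")
    if frame["gbd_level2"].isna().any() or (frame["gbd_level2"].str.strip() == "").any():
        raise SchemaError("gbd_level2 must be non-empty for every condition")
    frame["mch_flag"] = [
        _parse_bool(v, f"condition {cid!r} mch_flag")
        for cid, v in zip(frame["condition_id"], frame["mch_flag"])
    ]
    frame["name"] = frame["name"].fillna("").astype(str)
    return frame.reset_index(drop=True)


def write_condition_meta(meta: pd.DataFrame, path: str | Path | io.TextIOBase) -> None:
    out = meta[list(_META_COLUMNS)].copy()
    out["mch_flag"] = out["mch_flag"].astype(bool).map({True: "1", False: "0"})
    out.to_csv(path, index=False)


_INTERVENTION_COLUMNS = ("intervention_id", "name", "condition_ids", "cer")


def read_interventions(
    path: str | Path | io.TextIOBase,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Read the intervention/CER table.

    Expected columns: ``intervention_id``, ``name``, ``condition_ids``
    (";"-separated list of condition ids), ``cer`` (positive cost per unit
    health benefit). When ``meta`` is given, every referenced condition must
    exist in it.
    """
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in _INTERVENTION_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"intervention table missing column(s): {', '.join(missing)}")
    frame = frame[list(_INTERVENTION_COLUMNS)].copy()
    frame["intervention_id"] = frame["intervention_id"].astype(str)
    if frame["intervention_id"].duplicated().any():
        dup = frame.loc[frame["intervention_id"].duplicated(), "intervention_id"].iloc[0]
        raise SchemaError(f"duplicate intervention_id {dup!r}")
    frame["name"] = frame["name"].fillna("").astype(str)

    def parse_conditions(iid: str, raw: object) -> tuple[str, ...]:
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            raw = ""
        parts = tuple(
            p.strip() for p in str(raw).split(CONDITION_LIST_SEP) if p.strip()
        )
        if not parts:
            raise SchemaError(f"intervention {iid!r}: empty condition list")
        return parts

    frame["condition_ids"] = [
        parse_conditions(iid, raw)
        for iid, raw in zip(frame["intervention_id"], frame["condition_ids"])
    ]
    cer = pd.to_numeric(frame["cer"], errors="coerce")
    if cer.isna().any():
        iid = frame.loc[cer.isna(), "intervention_id"].iloc[0]
        raise SchemaError(f"intervention {iid!r}: CER is not a number")
    if (cer <= 0).any():
        iid = frame.loc[cer <= 0, "intervention_id"].iloc[0]
        raise SchemaError(f"intervention {iid!r}: CER must be positive")
    frame["cer"] = cer.astype(float)
    if meta is not None:
        known = set(meta["condition_id"].astype(str))
        for iid, cids in zip(frame["intervention_id"], frame["condition_ids"]):
            unknown = [c for c in cids if c not in known]
            if unknown:
                raise ReferentialError(
                    f"intervention {iid!r} references unknown condition(s): "
                    f"{', '.join(unknown)}"
                )
    return frame.reset_index(drop=True)


def write_interventions(table: pd.DataFrame, path: str | Path | io.TextIOBase) -> None:
    out = table[list(_INTERVENTION_COLUMNS)].copy()
    out["condition_ids"] = out["condition_ids"].map(
        lambda cids: CONDITION_LIST_SEP.join(cids)
    )
    out.to_csv(path, index=False)


def check_conditions_exist(
    condition_ids: Iterable[str], meta: pd.DataFrame, context: str
) -> None:
    """Raise ReferentialError if any id is absent from the metadata table."""
    known = set(meta["condition_id"].astype(str))
    unknown = [c for c in condition_ids if str(c) not in known]
    if unknown:
        raise ReferentialError(f"{context}: unknown condition(s): {', '.join(unknown)}")
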