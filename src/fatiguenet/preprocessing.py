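"""Binarization, study-group assignment, and tongue/pulse outlier exclusion.

Coding conventions follow normalized clinical data entry: a TCM symptom
scored none/mild/severe (0/1/2) is positive as soon as it is present at all;
a qualitative index is positive for any '+' grade; a quantitative index is
positive when it falls outside its normal range.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from fatiguenet.containers import TonguePulseTable

logger = logging.getLogger(__name__)

KINDS = ("tcm_symptom", "qualitative_index", "quantitative_index")

#: qualitative grade tokens -> positive flag
_QUALITATIVE = {"-": 0, "−": 0, "neg": 0, "negative": 0,
                "+": 1, "++": 1, "+++": 1, "+-": 1, "±": 1}


@dataclass(frozen=True)
class FeatureRecord:
    """One raw feature value for one subject."""

    code: str
    kind: str
    value: object
    normal_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.kind == "quantitative_index":
            if self.normal_range is None:
                raise ValueError(f"{self.code}: quantitative index requires a normal range")
            lo, hi = self.normal_range
            if lo > hi:
                raise ValueError(f"{self.code}: normal range low must be <= high")


def binarize(record: FeatureRecord) -> int:
    """Collapse a raw record to 0/1.

    TCM severity >= 1 (mild counts as positive), any qualitative '+' grade,
    or a quantitative value outside the normal range all map to 1.
    """
    if record.kind == "tcm_symptom":
        score = float(record.value)
        if score not in (0.0, 1.0, 2.0):
            raise ValueError(f"{record.code}: TCM severity must be 0, 1 or 2, got {record.value!r}")
        return int(score >= 1)
    if record.kind == "qualitative_index":
        token = str(record.value).strip().lower()
        if token not in _QUALITATIVE:
            raise ValueError(f"{record.code}: unknown qualitative token {record.value!r}")
        return _QUALITATIVE[token]
    lo, hi = record.normal_range  # quantitative
    return int(not lo <= float(record.value) <= hi)


def binarize_matrix(raw: pd.DataFrame, kinds: dict[str, str],
                    normal_ranges: dict[str, tuple[float, float]] | None = None) -> pd.DataFrame:
    """Binarize a raw subjects x features table column by column.

    Missing values count as absent/negative (0); the number of imputed cells
    is logged. ``kinds`` maps each column to its record kind.
    """
    normal_ranges = normal_ranges or {}
    n_missing = int(raw.isna().to_numpy().sum())
    if n_missing:
        logger.info("binarize_matrix: %d missing cells treated as negative (0)", n_missing)
    out = {}
    for col in raw.columns:
        kind = kinds[col]
        rng = normal_ranges.get(col)
        out[col] = [
            0 if pd.isna(v) else binarize(FeatureRecord(col, kind, v, rng))
            for v in raw[col]
        ]
    return pd.DataFrame(out, index=raw.index, dtype=np.int8)


def assign_group(h20: float, fatigue_present: bool, has_disease: bool) -> str:
    """Assign one subject to a study group.

    Diagnosed disease plus fatigue defines the disease-fatigue group (no H20
    bound). Without positive indexes, fatigue with H20 in [60, 79] is
    sub-health fatigue, and no fatigue with H20 in [80, 100] is healthy.
    Anything else is unclassified and excluded from analysis.
    """
    if not 0.0 <= h20 <= 100.0:
        raise ValueError(f"H20 score must be in [0, 100], got {h20}")
    if has_disease:
        return "disease" if fatigue_present else "unclassified"
    if fatigue_present:
        return "subhealth" if 60.0 <= h20 <= 79.0 else "unclassified"
    return "healthy" if 80.0 <= h20 <= 100.0 else "unclassified"


def assign_groups(h20: pd.Series, fatigue: pd.Series, has_disease: pd.Series) -> pd.Series:
    """Vectorized :func:`assign_group` over aligned subject series."""
    return pd.Series(
        [assign_group(float(h), bool(f), bool(d))
         for h, f, d in zip(h20, fatigue, has_disease)],
        index=h20.index, name="group",
    )


def tukey_hinges(x: np.ndarray) -> tuple[float, float]:
    """Lower and upper Tukey hinges (medians of the halves, median included when n is odd)."""
    x = np.sort(np.asarray(x, float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 values for hinges")
    half = (n + 1) // 2
    return float(np.median(x[:half])), float(np.median(x[n - half:]))


def _quartiles(x: np.ndarray, method: str) -> tuple[float, float]:
    if method == "hinges":
        return tukey_hinges(x)
    if method == "linear":
        q1, q3 = np.percentile(x, [25, 75])
        return float(q1), float(q3)
    raise ValueError(f"unknown quartile method {method!r}")


def exclude_outlier_subjects(table: TonguePulseTable, fence_inner: float = 1.5,
                             fence_outer: float = 3.0, quartile_method: str = "hinges",
                             ) -> tuple[TonguePulseTable, pd.DataFrame]:
    """Drop subjects with an outlying or extreme tongue/pulse value.

    A value beyond quartile +/- fence_inner * IQR is an outlier, beyond
    fence_outer * IQR an extreme; subjects with either in any block variable
    are dropped. Returns the reduced table and a log with one row per
    flagged (subject, variable, value, severity). Variables with zero IQR
    are skipped (and logged), since fences degenerate there.
    """
    if table.data.empty:
        raise ValueError("cannot screen an empty table")
    if fence_inner <= 0 or fence_outer <= 0:
        raise ValueError("fences must be positive")

    cols = table.tongue_cols + table.pulse_cols
    records: list[dict] = []
    drop: set = set()
    for col in cols:
        x = table.data[col].to_numpy(float)
        q1, q3 = _quartiles(x, quartile_method)
        iqr = q3 - q1
        if iqr == 0:
            logger.info("exclude_outlier_subjects: %s has zero IQR, skipped", col)
            continue
        if math.isinf(fence_inner):
            continue
        lo_in, hi_in = q1 - fence_inner * iqr, q3 + fence_inner * iqr
        lo_out, hi_out = q1 - fence_outer * iqr, q3 + fence_outer * iqr
        for sid, v in zip(table.data.index, x):
            if v < lo_in or v > hi_in:
                severity = "extreme" if (v < lo_out or v > hi_out) else "outlier"
                records.append({"subject": sid, "variable": col, "value": v,
                                "severity": severity})
                drop.add(sid)

    log = pd.DataFrame(records, columns=["subject", "variable", "value", "severity"])
    kept = table.data.loc[[i for i in table.data.index if i not in drop]]
    logger.info("exclude_outlier_subjects: dropped %d of %d subjects",
                len(drop), len(table.data))
    return TonguePulseTable(kept, list(table.tongue_cols), list(table.pulse_cols)), log
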