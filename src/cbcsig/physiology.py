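"""Physiological derived measures and their association with composite scores.

Covers percent body-weight change across the stress day, Pearson correlation
of physiological measures with composite behavior scores, and the percent of
score variance a correlate explains (100*r^2). Animals with missing values
are dropped pairwise from correlations with a logged warning, mirroring
cohorts with incomplete weight records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


class PhysiologyError(ValueError):
    pass


@dataclass(frozen=True)
class PhysiologyRecord:
    """Per-animal weights (g) around the stress day and serum corticosterone (ng/mL)."""

    animal_id: str
    weight_day0: float | None
    weight_day1: float | None
    cort_30min: float | None
    cort_3h: float | None


def percent_weight_change(weight_day0: float, weight_day1: float) -> float:
    """100 * (day1 - day0) / day0; negative values indicate weight loss."""
    if weight_day0 <= 0:
        raise PhysiologyError(f"weight_day0 must be > 0, got {weight_day0}")
    return 100.0 * (weight_day1 - weight_day0) / weight_day0


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p from the t distribution (n-2 df)."""
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size != ya.size:
        raise PhysiologyError("x and y must have equal length")
    if xa.size < 3:
        raise PhysiologyError("pearson_correlation requires n >= 3")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise PhysiologyError("inputs must be finite")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise PhysiologyError("correlation undefined: zero variance")
    res = stats.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue)


def variance_explained(r: float, digits: int | None = 0) -> float:
    """Percent of variance explained by a correlate: 100 * r^2.

    Rounded to ``digits`` decimal places (default: nearest integer); pass
    ``digits=None`` for the unrounded value.
    """
    if not -1.0 <= r <= 1.0:
        raise PhysiologyError(f"|r| must be <= 1, got {r}")
    pct = 100.0 * r * r
    return pct if digits is None else float(round(pct, digits))


def correlate_pairs(
    scores: pd.DataFrame, physiology: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Correlate physiology columns against score columns, animal-matched.

    ``pairs`` is a list of ``(physiology_column, score_column)``. Missing
    values are dropped pairwise with a warning naming the excluded animals.
    """
    merged = physiology.merge(scores, on="animal_id", how="inner")
    rows = []
    for phys_col, score_col in pairs:
        for col in (phys_col, score_col):
            if col not in merged.columns:
                raise PhysiologyError(f"column {col!r} not found")
        sub = merged[["animal_id", phys_col, score_col]].dropna()
        dropped = sorted(set(merged["animal_id"]) - set(sub["animal_id"]))
        if dropped:
            log.warning(
                "correlate %s:%s: dropping %d animals with missing values: %s",
                phys_col, score_col, len(dropped), dropped,
            )
        r, p = pearson_correlation(sub[phys_col], sub[score_col])
        rows.append(
            {
                "x": phys_col,
                "y": score_col,
                "n": len(sub),
                "r": r,
                "p": p,
                "variance_explained_pct": variance_explained(r, digits=1),
            }
        )
    return pd.DataFrame(rows)


def physiology_frame(records) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "weight_day0": r.weight_day0,
                "weight_day1": r.weight_day1,
                "cort_30min": r.cort_30min,
                "cort_3h": r.cort_3h,
            }
            for r in records
        ]
    )
    df["weight_change_pct"] = [
        percent_weight_change(w0, w1) if w0 is not None and w1 is not None else np.nan
        for w0, w1 in zip(df["weight_day0"], df["weight_day1"])
    ]
    return df
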