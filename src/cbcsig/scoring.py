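"""Cutoff Behavioral Criteria (CBC): thresholds, composite scores, phenotypes.

For each avoidance measure a cutoff is placed at the 20th percentile of the
control distribution (LOW_IS_AFFECTED measures) or the 80th percentile
(HIGH_IS_AFFECTED measures: latencies to anxiogenic zones, time in protected
zones). An animal falling strictly outside its cutoff on a measure is
"affected" and scores 1 for that measure; binary scores are summed into the
composite (avoidance sub-score 0-20 with the default registry). Stress
animals whose total exceeds the maximum observed control total are classified
vulnerable; the rest are resilient. Startle measures (mean startle,
sensitization) are scored the same way at the 80th percentile but summed into
a separate startle sub-score, reported alongside the 0-20 avoidance score.

Tie rules are deterministic and conservative: a value exactly at the cutoff
is unaffected, and a stress total exactly equal to the control maximum is
resilient.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cbcsig.registry import Direction, MetricSpec, avoidance_metrics, startle_metrics


class ScoringError(ValueError):
    """Raised for invalid scoring inputs (missing metrics, no controls, NaNs)."""


class Phenotype(str, enum.Enum):
    CONTROL = "control"
    RESILIENT = "resilient"
    VULNERABLE = "vulnerable"


@dataclass(frozen=True)
class BehaviorMeasurement:
    """One (animal, assay, metric, value) observation from the behavioral battery."""

    animal_id: str
    group: str  # "control" | "stress"
    assay: str
    metric_name: str
    value: float


@dataclass(frozen=True)
class ThresholdSpec:
    """A per-metric cutoff derived from the control distribution."""

    metric_name: str
    direction: Direction
    percentile_used: int
    cutoff_value: float
    n_controls: int


@dataclass(frozen=True)
class CompositeScore:
    animal_id: str
    avoidance_subscore: int
    startle_subscore: int

    @property
    def total(self) -> int:
        return self.avoidance_subscore + self.startle_subscore


@dataclass(frozen=True)
class PhenotypeLabel:
    animal_id: str
    label: Phenotype


_PERCENTILE_METHODS = {"linear": "linear", "nearest_rank": "inverted_cdf"}


def derive_threshold(
    control_values,
    direction: Direction,
    percentile_method: str = "linear",
    metric_name: str = "",
) -> ThresholdSpec:
    """Cutoff at the 20th (LOW_IS_AFFECTED) or 80th (HIGH_IS_AFFECTED) control percentile.

    The default percentile estimator linearly interpolates between order
    statistics; ``percentile_method="nearest_rank"`` uses the inverted-CDF
    order statistic instead. Requires at least two finite control values.
    """
    values = np.asarray(list(control_values), dtype=float)
    if values.size < 2:
        raise ScoringError(f"{metric_name or 'metric'}: need >= 2 control values")
    if not np.all(np.isfinite(values)):
        raise ScoringError(f"{metric_name or 'metric'}: non-finite control values")
    if percentile_method not in _PERCENTILE_METHODS:
        raise ScoringError(f"unknown percentile method {percentile_method!r}")
    pct = 20 if direction is Direction.LOW_IS_AFFECTED else 80
    cutoff = float(
        np.percentile(values, pct, method=_PERCENTILE_METHODS[percentile_method])
    )
    return ThresholdSpec(
        metric_name=metric_name,
        direction=direction,
        percentile_used=pct,
        cutoff_value=cutoff,
        n_controls=int(values.size),
    )


def score_measure(value: float, threshold: ThresholdSpec) -> int:
    """1 if the value falls strictly outside the cutoff in the affected direction, else 0."""
    if not math.isfinite(value):
        raise ScoringError(f"{threshold.metric_name}: non-finite value")
    if threshold.direction is Direction.LOW_IS_AFFECTED:
        return int(value < threshold.cutoff_value)
    return int(value > threshold.cutoff_value)


def composite_score(
    animal_id: str,
    binary_scores: dict[str, int],
    registry: list[MetricSpec],
) -> CompositeScore:
    """Sum binary scores into avoidance and startle sub-scores.

    Every registry metric must be present in ``binary_scores``; missing
    metrics are reported by name.
    """
    missing = [m.metric_name for m in registry if m.metric_name not in binary_scores]
    if missing:
        raise ScoringError(f"missing binary scores for metrics: {missing}")
    avoid = sum(int(binary_scores[m.metric_name]) for m in avoidance_metrics(registry))
    startle = sum(int(binary_scores[m.metric_name]) for m in startle_metrics(registry))
    return CompositeScore(animal_id, avoid, startle)


def classify_phenotype(
    scores: list[CompositeScore], groups: dict[str, str]
) -> list[PhenotypeLabel]:
    """Label each animal control / resilient / vulnerable.

    A stress animal is vulnerable iff its total strictly exceeds the maximum
    control total ("outside the range of the control group"); otherwise it is
    resilient. Controls are always labeled control.
    """
    control_totals = [s.total for s in scores if groups.get(s.animal_id) == "control"]
    if not control_totals:
        raise ScoringError("classification requires at least one control score")
    ceiling = max(control_totals)
    labels = []
    for s in scores:
        group = groups.get(s.animal_id)
        if group == "control":
            label = Phenotype.CONTROL
        elif s.total > ceiling:
            label = Phenotype.VULNERABLE
        else:
            label = Phenotype.RESILIENT
        labels.append(PhenotypeLabel(s.animal_id, label))
    return labels


@dataclass
class SequencingSelection:
    """Animals selected for sequencing, by stratum."""

    stress_low: list[str]
    stress_high: list[str]
    control: list[str]


def select_for_sequencing(
    scores: list[CompositeScore],
    groups: dict[str, str],
    k_low: int = 3,
    k_high: int = 3,
    k_control: int = 6,
) -> SequencingSelection:
    """Pick sequencing animals: extremes of the stress score distribution plus controls.

    Selects the ``k_low`` lowest-scoring and ``k_high`` highest-scoring stress
    animals and ``k_control`` controls spanning the control score range
    (evenly spaced by rank). Ties break lexicographically by animal id.
    """
    stress = sorted(
        (s for s in scores if groups.get(s.animal_id) == "stress"),
        key=lambda s: (s.total, s.animal_id),
    )
    controls = sorted(
        (s for s in scores if groups.get(s.animal_id) == "control"),
        key=lambda s: (s.total, s.animal_id),
    )
    if len(stress) < max(k_low, k_high) or (k_low + k_high) > len(stress):
        raise ScoringError(
            f"need {k_low}+{k_high} stress animals, have {len(stress)}"
        )
    if len(controls) < k_control:
        raise ScoringError(f"need {k_control} controls, have {len(controls)}")
    low = [s.animal_id for s in stress[:k_low]]
    high = [s.animal_id for s in stress[len(stress) - k_high:]]
    if k_control > 0:
        idx = np.round(np.linspace(0, len(controls) - 1, k_control)).astype(int)
        ctrl = [controls[i].animal_id for i in idx]
    else:
        ctrl = []
    return SequencingSelection(stress_low=low, stress_high=high, control=ctrl)


def group_summary(values) -> tuple[float, float]:
    """Mean and SEM (sample SD with n-1 denominator over sqrt(n); 0 for n=1)."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ScoringError("group_summary requires at least one value")
    mean = float(vals.mean())
    sem = 0.0 if vals.size == 1 else float(vals.std(ddof=1) / np.sqrt(vals.size))
    return mean, sem


# ---------------------------------------------------------------------------
# Table-level driver


def score_cohort(
    measurements: list[BehaviorMeasurement] | pd.DataFrame,
    registry: list[MetricSpec],
    percentile_method: str = "linear",
):
    """Derive thresholds from controls, score and classify every animal.

    Returns ``(thresholds, scores, labels)`` where thresholds is a dict by
    metric name. The measurement table must contain one value per animal per
    registry metric.
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements
    else:
        df = measurements_frame(measurements)
    required = {"animal_id", "group", "metric_name", "value"}
    if not required.issubset(df.columns):
        raise ScoringError(f"measurement table missing columns {required - set(df.columns)}")
    groups = dict(zip(df["animal_id"], df["group"]))
    wide = df.pivot_table(index="animal_id", columns="metric_name", values="value")
    thresholds: dict[str, ThresholdSpec] = {}
    for m in registry:
        if m.metric_name not in wide.columns:
            raise ScoringError(f"no measurements for registry metric {m.metric_name}")
        controls = wide.loc[
            [a for a in wide.index if groups[a] == "control"], m.metric_name
        ]
        thresholds[m.metric_name] = derive_threshold(
            controls, m.direction, percentile_method, metric_name=m.metric_name
        )
    scores = []
    for animal in sorted(wide.index):
        binary = {
            m.metric_name: score_measure(
                float(wide.loc[animal, m.metric_name]), thresholds[m.metric_name]
            )
            for m in registry
        }
        scores.append(composite_score(animal, binary, registry))
    labels = classify_phenotype(scores, groups)
    return thresholds, scores, labels


def measurements_frame(measurements: list[BehaviorMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "animal_id": m.animal_id,
                "group": m.group,
                "assay": m.assay,
                "metric_name": m.metric_name,
                "value": m.value,
            }
            for m in measurements
        ]
    )


def thresholds_frame(thresholds: dict[str, ThresholdSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metric_name": t.metric_name,
                "direction": t.direction.value,
                "percentile_used": t.percentile_used,
                "cutoff_value": t.cutoff_value,
                "n_controls": t.n_controls,
            }
            for t in thresholds.values()
        ]
    )


def scores_frame(
    scores: list[CompositeScore], labels: list[PhenotypeLabel]
) -> pd.DataFrame:
    label_by_id = {l.animal_id: l.label.value for l in labels}
    return pd.DataFrame(
        [
            {
                "animal_id": s.animal_id,
                "avoidance_subscore": s.avoidance_subscore,
                "startle_subscore": s.startle_subscore,
                "total": s.total,
                "label": label_by_id.get(s.animal_id, ""),
            }
            for s in scores
        ]
    )
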