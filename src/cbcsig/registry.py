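"""Behavioral metric registry shared by the generator and the scoring engine.

The default registry reconstructs a two-day avoidance battery: two open field
tests (bright and dim), two elevated plus mazes (bright light and dim red
light), and a light-dark box, for a total of 20 avoidance measures — the
composite avoidance score therefore ranges 0-20. Two acoustic-startle measures
(mean startle, sensitization) form a separate startle sub-score.

Directions encode which tail of the control distribution marks an "affected"
animal: anxious animals take longer to enter anxiogenic zones and spend more
time in protected zones (HIGH_IS_AFFECTED), and show less time, fewer entries
and shorter distances in anxiogenic zones (LOW_IS_AFFECTED).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import yaml


class Assay(str, enum.Enum):
    OFT_LIGHT = "OFT_LIGHT"
    OFT_DIM = "OFT_DIM"
    EPM_LIGHT = "EPM_LIGHT"
    EPM_DIM = "EPM_DIM"
    LD = "LD"
    ASR = "ASR"


class Direction(str, enum.Enum):
    LOW_IS_AFFECTED = "LOW_IS_AFFECTED"
    HIGH_IS_AFFECTED = "HIGH_IS_AFFECTED"


@dataclass(frozen=True)
class MetricSpec:
    """One behavioral measure: its assay, affected direction and control distribution.

    ``control_mean``/``control_sd`` parameterize the control population the
    synthetic generator draws from; the scoring engine only uses the name,
    assay and direction. ``distribution`` may be ``"normal"`` or
    ``"lognormal"`` (the latter a natural choice for latencies).
    """

    assay: Assay
    metric_name: str
    direction: Direction
    control_mean: float = 0.0
    control_sd: float = 1.0
    distribution: str = "normal"

    def __post_init__(self) -> None:
        if self.control_sd <= 0:
            raise ValueError(f"control_sd must be > 0 for {self.metric_name}")
        if self.distribution not in ("normal", "lognormal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")

    @property
    def is_startle(self) -> bool:
        return self.assay is Assay.ASR


def _oft(assay: Assay, prefix: str) -> list[MetricSpec]:
    H, L = Direction.HIGH_IS_AFFECTED, Direction.LOW_IS_AFFECTED
    return [
        MetricSpec(assay, f"{prefix}_center_latency_s", H, 30.0, 20.0),
        MetricSpec(assay, f"{prefix}_center_frequency", L, 12.0, 5.0),
        MetricSpec(assay, f"{prefix}_center_time_s", L, 40.0, 20.0),
        MetricSpec(assay, f"{prefix}_total_distance_cm", L, 3000.0, 800.0),
        MetricSpec(assay, f"{prefix}_center_distance_cm", L, 300.0, 120.0),
    ]


def _epm(assay: Assay, prefix: str) -> list[MetricSpec]:
    H, L = Direction.HIGH_IS_AFFECTED, Direction.LOW_IS_AFFECTED
    return [
        MetricSpec(assay, f"{prefix}_open_latency_s", H, 60.0, 40.0),
        MetricSpec(assay, f"{prefix}_open_time_s", L, 80.0, 40.0),
        # time in the protected closed arms: more is more anxious
        MetricSpec(assay, f"{prefix}_closed_time_s", H, 400.0, 80.0),
    ]


def default_registry(include_startle: bool = True) -> list[MetricSpec]:
    """The default 20-metric avoidance registry (plus 2 startle measures).

    5 measures per open field test x 2, 3 per elevated plus maze x 2, and 4
    for the light-dark box give the 20 avoidance metrics; ``mean_startle`` and
    ``sensitization_pct`` (both HIGH_IS_AFFECTED) form the startle sub-score
    and are excluded when ``include_startle`` is False.
    """
    H, L = Direction.HIGH_IS_AFFECTED, Direction.LOW_IS_AFFECTED
    registry = (
        _oft(Assay.OFT_LIGHT, "oft_light")
        + _oft(Assay.OFT_DIM, "oft_dim")
        + _epm(Assay.EPM_LIGHT, "epm_light")
        + _epm(Assay.EPM_DIM, "epm_dim")
        + [
            MetricSpec(Assay.LD, "ld_total_distance_cm", L, 1500.0, 400.0),
            MetricSpec(Assay.LD, "ld_light_latency_s", H, 20.0, 15.0),
            MetricSpec(Assay.LD, "ld_light_frequency", L, 10.0, 4.0),
            MetricSpec(Assay.LD, "ld_light_time_s", L, 120.0, 60.0),
        ]
    )
    if include_startle:
        registry += [
            MetricSpec(Assay.ASR, "mean_startle", H, 20.0, 8.0),
            MetricSpec(Assay.ASR, "sensitization_pct", H, 0.0, 40.0),
        ]
    _check_unique(registry)
    return registry


def _check_unique(registry: list[MetricSpec]) -> None:
    names = [m.metric_name for m in registry]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate metric names in registry: {dupes}")


def avoidance_metrics(registry: list[MetricSpec]) -> list[MetricSpec]:
    return [m for m in registry if not m.is_startle]


def startle_metrics(registry: list[MetricSpec]) -> list[MetricSpec]:
    return [m for m in registry if m.is_startle]


def registry_to_yaml(registry: list[MetricSpec], path) -> None:
    payload = [
        {
            "assay": m.assay.value,
            "metric_name": m.metric_name,
            "direction": m.direction.value,
            "control_mean": float(m.control_mean),
            "control_sd": float(m.control_sd),
            "distribution": m.distribution,
        }
        for m in registry
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def registry_from_yaml(path) -> list[MetricSpec]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    registry = [
        MetricSpec(
            assay=Assay(item["assay"]),
            metric_name=item["metric_name"],
            direction=Direction(item["direction"]),
            control_mean=float(item.get("control_mean", 0.0)),
            control_sd=float(item.get("control_sd", 1.0)),
            distribution=item.get("distribution", "normal"),
        )
        for item in payload
    ]
    _check_unique(registry)
    return registry
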