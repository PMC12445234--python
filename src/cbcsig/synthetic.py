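"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a two-group design (default 19 controls / 20
stress-exposed animals, matching the analyzed cohort) in which stress
animals are a latent mixture of resilient and vulnerable classes:

* Every animal carries a latent anxiety score ``a = shift*1[vulnerable] + d``
  with personal deviation ``d ~ N(0, 1)``; ``shift`` is ``anxiety_shift_sd``
  in control-SD units.
* Each avoidance metric is drawn from its control distribution and loaded on
  the latent axis: in standardized affected-direction units the value is
  ``shift*1[vulnerable] + w*d + sqrt(1-w^2)*eps`` with metric loading ``w``
  (default 0.4) and independent noise ``eps ~ N(0,1)``. Controls therefore
  follow each MetricSpec's distribution exactly, and vulnerable-latent
  animals are shifted by ``anxiety_shift_sd`` control SDs toward the affected
  tail of every avoidance metric.
* Startle traces contain pulse-locked transients on a noisy baseline; per-
  animal gain varies log-normally and is independent of the latent class (in
  the emulated design, group differences are carried by avoidance, not
  startle). ASR metrics are computed from the traces with the startle module,
  closing the loop with the analysis code.
* 3-h corticosterone is generated to correlate with the latent anxiety score
  at approximately ``cort_behavior_r`` (imposed within group on the
  empirically standardized latent scores).
* RNA-seq counts are negative-binomial with configurable dispersion, library
  sizes varied +/-20%, and planted log2 fold changes tied to sample groups.

One master seed is split into per-stage substreams (class assignment,
metrics, traces, physiology), so each stage is individually reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from cbcsig import startle as startle_mod
from cbcsig.expression import CountMatrix
from cbcsig.registry import (
    Assay,
    Direction,
    MetricSpec,
    default_registry,
)
from cbcsig.scoring import BehaviorMeasurement
from cbcsig.physiology import PhysiologyRecord, percent_weight_change


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class GroupLevels:
    """Mean/SD of a physiological measure for control and stress animals."""

    control_mean: float
    control_sd: float
    stress_mean: float
    stress_sd: float


@dataclass
class CohortConfig:
    """All generator knobs; defaults reproduce the emulated study conditions."""

    n_control: int = 19
    n_stress: int = 20
    vulnerable_fraction: float = 0.3
    metric_registry: list[MetricSpec] = field(default_factory=default_registry)
    anxiety_shift_sd: float = 3.0
    metric_loading: float = 0.4
    cort_behavior_r: float = 0.55
    # percent weight change day0 -> day1 (negative = loss)
    weight_change_params: GroupLevels = field(
        default_factory=lambda: GroupLevels(0.5, 1.0, -5.0, 2.0)
    )
    cort_30min_params: GroupLevels = field(
        default_factory=lambda: GroupLevels(60.0, 20.0, 450.0, 90.0)
    )
    cort_3h_params: GroupLevels = field(
        default_factory=lambda: GroupLevels(50.0, 15.0, 300.0, 80.0)
    )
    body_weight_mean_g: float = 400.0
    body_weight_sd_g: float = 25.0
    # startle trace parameters (habituation trial: 15 x 110 dB pulses)
    sampling_rate: float = 50.0
    n_pulses: int = 15
    pulse_db: float = 110.0
    isi_range_s: tuple[float, float] = (15.0, 30.0)
    pre_stimulus_s: float = 5.0
    startle_gain_mean: float = 20.0
    startle_gain_log_sd: float = 0.4
    trace_noise_sd: float = 0.5
    trace_baseline: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_control < 2 or self.n_stress < 2:
            raise ConfigurationError("n_control and n_stress must each be >= 2")
        if not 0.0 <= self.vulnerable_fraction <= 1.0:
            raise ConfigurationError("vulnerable_fraction must lie in [0, 1]")
        if self.anxiety_shift_sd < 0:
            raise ConfigurationError("anxiety_shift_sd must be >= 0")
        if not 0.0 < self.metric_loading < 1.0:
            raise ConfigurationError("metric_loading must lie in (0, 1)")
        if not -1.0 <= self.cort_behavior_r <= 1.0:
            raise ConfigurationError("cort_behavior_r must lie in [-1, 1]")
        names = [m.metric_name for m in self.metric_registry]
        if len(set(names)) != len(names):
            raise ConfigurationError("metric names must be unique in the registry")


@dataclass(frozen=True)
class Animal:
    animal_id: str
    group: str  # "control" | "stress"
    latent_class: str  # "none" | "resilient_latent" | "vulnerable_latent"
    latent_anxiety: float


@dataclass
class Cohort:
    """A simulated cohort: animals, behavior table, physiology, startle traces."""

    animals: list[Animal]
    measurements: list[BehaviorMeasurement]
    physiology: list[PhysiologyRecord]
    traces: dict[str, startle_mod.ActivityTrace]
    config: CohortConfig

    def animals_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "animal_id": a.animal_id,
                    "group": a.group,
                    "latent_class": a.latent_class,
                    "latent_anxiety": a.latent_anxiety,
                }
                for a in self.animals
            ]
        )

    def groups(self) -> dict[str, str]:
        return {a.animal_id: a.group for a in self.animals}


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort; byte-identical for identical config and seed."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_assign, rng_metric, rng_trace, rng_phys = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    animals: list[Animal] = []
    width = max(2, len(str(max(config.n_control, config.n_stress))))
    for i in range(config.n_control):
        delta = rng_assign.normal()
        animals.append(Animal(f"C{i + 1:0{width}d}", "control", "none", delta))
    for i in range(config.n_stress):
        delta = rng_assign.normal()
        vulnerable = rng_assign.random() < config.vulnerable_fraction
        cls = "vulnerable_latent" if vulnerable else "resilient_latent"
        shift = config.anxiety_shift_sd if vulnerable else 0.0
        animals.append(Animal(f"S{i + 1:0{width}d}", "stress", cls, shift + delta))

    measurements = _simulate_avoidance(animals, config, rng_metric)
    traces, asr_measurements = _simulate_startle(animals, config, rng_trace)
    measurements.extend(asr_measurements)
    physiology = _simulate_physiology(animals, config, rng_phys)
    return Cohort(animals, measurements, physiology, traces, config)


def _affected_sign(direction: Direction) -> float:
    return 1.0 if direction is Direction.HIGH_IS_AFFECTED else -1.0


def _simulate_avoidance(animals, config, rng) -> list[BehaviorMeasurement]:
    w = config.metric_loading
    resid = math.sqrt(1.0 - w * w)
    out = []
    avoidance = [m for m in config.metric_registry if m.assay is not Assay.ASR]
    for animal in animals:
        shift = (
            config.anxiety_shift_sd
            if animal.latent_class == "vulnerable_latent"
            else 0.0
        )
        # the animal's personal deviation on the shared anxiety axis
        delta = animal.latent_anxiety - shift
        for m in avoidance:
            z = shift + w * delta + resid * rng.normal()
            value = _metric_value(m, z)
            out.append(
                BehaviorMeasurement(
                    animal.animal_id, animal.group, m.assay.value, m.metric_name, value
                )
            )
    return out


def _metric_value(m: MetricSpec, z_affected: float) -> float:
    """Map a standardized affected-direction deviate onto the metric's scale."""
    s = _affected_sign(m.direction)
    if m.distribution == "lognormal":
        # moment-matched lognormal: control mean/SD preserved on the raw scale
        sigma2 = math.log(1.0 + (m.control_sd / m.control_mean) ** 2)
        sigma = math.sqrt(sigma2)
        mu = math.log(m.control_mean) - sigma2 / 2.0
        return float(math.exp(mu + sigma * s * z_affected))
    value = m.control_mean + m.control_sd * s * z_affected
    if m.metric_name.endswith(("_s", "_cm", "_frequency")):
        value = max(value, 0.0)  # physical measures cannot be negative
    return float(value)


def simulate_activity_trace(
    stimulus_schedule,
    startle_gain: float,
    noise_sd: float,
    seed=None,
    sampling_rate: float = 50.0,
    baseline: float = 1.0,
    duration_s: float | None = None,
    pulse_gains=None,
) -> startle_mod.ActivityTrace:
    """Baseline noise plus a pulse-locked transient at each stimulus.

    The transient at stimulus ``k`` peaks at ``startle_gain * pulse_gains[k]
    * intensity / 110`` exactly at pulse onset and decays within ~40 ms, so a
    noise-free trace returns the injected height through
    ``startle_amplitude``. ``seed`` may be an int or a Generator. Raises on
    an empty schedule or stimuli outside the trace.
    """
    schedule = [(float(t), float(db)) for t, db in stimulus_schedule]
    if not schedule:
        raise ConfigurationError("stimulus schedule must not be empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if duration_s is None:
        duration_s = schedule[-1][0] + 5.0
    n = int(round(duration_s * sampling_rate))
    if schedule[-1][0] >= duration_s or schedule[0][0] < 0:
        raise ConfigurationError("stimulus times must fall within the trace duration")
    gains = np.ones(len(schedule)) if pulse_gains is None else np.asarray(pulse_gains, float)
    if gains.size != len(schedule):
        raise ConfigurationError("pulse_gains must match the schedule length")
    activity = baseline + (rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0)
    activity = np.clip(np.broadcast_to(activity, (n,)).copy(), 0.0, None)
    decay_len = max(int(round(0.04 * sampling_rate)), 1)
    shape = np.exp(-np.arange(decay_len) / max(decay_len / 4.0, 1.0))
    shape[0] = 1.0
    for (t, db), g in zip(schedule, gains):
        height = startle_gain * g * db / 110.0
        i = int(round(t * sampling_rate))
        seg = min(decay_len, n - i)
        activity[i : i + seg] += height * shape[:seg]
    return startle_mod.ActivityTrace(sampling_rate, activity, schedule)


def _simulate_startle(animals, config, rng):
    traces: dict[str, startle_mod.ActivityTrace] = {}
    measurements: list[BehaviorMeasurement] = []
    for animal in animals:
        isi = rng.uniform(*config.isi_range_s, size=config.n_pulses)
        times = config.pre_stimulus_s + np.cumsum(isi) - isi[0]
        schedule = [(float(t), config.pulse_db) for t in times]
        gain = config.startle_gain_mean * math.exp(
            rng.normal(0.0, config.startle_gain_log_sd)
            - config.startle_gain_log_sd**2 / 2.0
        )
        trace = simulate_activity_trace(
            schedule,
            startle_gain=gain,
            noise_sd=config.trace_noise_sd,
            seed=rng,
            sampling_rate=config.sampling_rate,
            baseline=config.trace_baseline,
        )
        traces[animal.animal_id] = trace
        result = startle_mod.summarize_trace(animal.animal_id, trace)
        for name, value in (
            ("mean_startle", result.mean_startle),
            ("sensitization_pct", result.sensitization_pct),
        ):
            measurements.append(
                BehaviorMeasurement(
                    animal.animal_id, animal.group, Assay.ASR.value, name, value
                )
            )
    return traces, measurements


def _simulate_physiology(animals, config, rng) -> list[PhysiologyRecord]:
    latent = np.array([a.latent_anxiety for a in animals])
    latent_z = (latent - latent.mean()) / (latent.std() or 1.0)
    r = config.cort_behavior_r
    resid = math.sqrt(max(1.0 - r * r, 0.0))
    records = []
    for animal, lz in zip(animals, latent_z):
        stress = animal.group == "stress"
        wp = config.weight_change_params
        w0 = rng.normal(config.body_weight_mean_g, config.body_weight_sd_g)
        pct = rng.normal(
            wp.stress_mean if stress else wp.control_mean,
            wp.stress_sd if stress else wp.control_sd,
        )
        w1 = w0 * (1.0 + pct / 100.0)
        c30 = config.cort_30min_params
        cort30 = max(
            rng.normal(
                c30.stress_mean if stress else c30.control_mean,
                c30.stress_sd if stress else c30.control_sd,
            ),
            0.0,
        )
        c3h = config.cort_3h_params
        mean3h = c3h.stress_mean if stress else c3h.control_mean
        sd3h = c3h.stress_sd if stress else c3h.control_sd
        cort3h = max(mean3h + sd3h * (r * lz + resid * rng.normal()), 0.0)
        records.append(PhysiologyRecord(animal.animal_id, w0, w1, cort30, cort3h))
    return records


# ---------------------------------------------------------------------------
# Count simulation with planted differential expression


@dataclass(frozen=True)
class PlantedGene:
    """A gene given a log2 fold change in the named sample group(s)."""

    gene_index: int
    log2_fold_change: float
    groups: tuple[str, ...]  # subset of {"stress_low", "stress_high", "control"}


@dataclass
class DePlantSpec:
    """Shape of the simulated count matrix and the effects planted into it."""

    n_genes: int = 300
    gene_lengths: np.ndarray | None = None  # bp; generated log-uniform if None
    baseline_mean: np.ndarray | float = 100.0
    dispersion: float = 0.05
    planted: list[PlantedGene] = field(default_factory=list)
    library_size_range: tuple[float, float] = (0.8, 1.2)

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        base = np.broadcast_to(np.asarray(self.baseline_mean, float), (self.n_genes,))
        if np.all(base == 0):
            raise ConfigurationError("baseline_mean must not be all zero")
        if np.any(base < 0):
            raise ConfigurationError("baseline_mean must be non-negative")
        for pg in self.planted:
            if not 0 <= pg.gene_index < self.n_genes:
                raise ConfigurationError(
                    f"planted gene index {pg.gene_index} out of range"
                )


def simulate_counts(sample_groups, spec: DePlantSpec, seed=None) -> CountMatrix:
    """Negative-binomial counts for the given samples with planted fold changes.

    ``sample_groups`` is a sequence of ``(sample_id, group)`` pairs (groups
    as produced by sequencing selection: control / stress_low / stress_high).
    Planted genes are shifted by their log2 fold change in the indicated
    group(s); library sizes vary uniformly over ``library_size_range``.
    """
    spec.validate()
    samples = [(str(s), str(g)) for s, g in sample_groups]
    if not samples:
        raise ConfigurationError("need at least one sample")
    present = {g for _, g in samples}
    for pg in spec.planted:
        missing = set(pg.groups) - present
        if missing:
            raise ConfigurationError(
                f"planted gene {pg.gene_index} references absent group(s) {sorted(missing)}"
            )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g, s = spec.n_genes, len(samples)
    base = np.broadcast_to(np.asarray(spec.baseline_mean, float), (g,)).copy()
    lengths = (
        np.asarray(spec.gene_lengths, float)
        if spec.gene_lengths is not None
        else np.exp(rng.uniform(np.log(500.0), np.log(5000.0), size=g))
    )
    if lengths.size != g or np.any(lengths <= 0):
        raise ConfigurationError("gene_lengths must be n_genes positive values")
    mu = np.tile(base[:, None], (1, s))
    for pg in spec.planted:
        for j, (_, grp) in enumerate(samples):
            if grp in pg.groups:
                mu[pg.gene_index, j] *= 2.0 ** pg.log2_fold_change
    lib = rng.uniform(*spec.library_size_range, size=s)
    mu = mu * lib
    shape = 1.0 / spec.dispersion
    lam = np.where(mu > 0, rng.gamma(shape, 1.0, size=mu.shape) * mu / shape, 0.0)
    counts = rng.poisson(lam)
    digits = len(str(g))
    return CountMatrix(
        gene_ids=[f"g{i + 1:0{digits}d}" for i in range(g)],
        gene_names=[f"gene {i + 1}" for i in range(g)],
        gene_lengths=lengths,
        sample_ids=[sid for sid, _ in samples],
        sample_groups=[grp for _, grp in samples],
        counts=counts,
    )


# ---------------------------------------------------------------------------
# On-disk formats


def write_cohort(cohort: Cohort, outdir, write_traces: bool = False) -> dict[str, str]:
    """Write measurement/physiology/animal tables (and optionally traces) as TSV.

    Returns a mapping of artifact name to path. Traces are two-column
    (time_s, activity) TSVs, one per animal, and are skipped by default
    because they dominate output size.
    """
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    from cbcsig.scoring import measurements_frame
    from cbcsig.physiology import physiology_frame

    paths = {}
    for name, df in (
        ("animals", cohort.animals_frame()),
        ("measurements", measurements_frame(cohort.measurements)),
        ("physiology", physiology_frame(cohort.physiology)),
    ):
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = str(p)
    if write_traces:
        tdir = out / "traces"
        tdir.mkdir(exist_ok=True)
        for animal_id, trace in cohort.traces.items():
            p = tdir / f"{animal_id}.tsv"
            trace.to_frame().to_csv(p, sep="\t", index=False)
            paths[f"trace:{animal_id}"] = str(p)
    return paths


def config_to_yaml(config: CohortConfig, path) -> None:
    payload = {
        "n_control": config.n_control,
        "n_stress": config.n_stress,
        "vulnerable_fraction": config.vulnerable_fraction,
        "anxiety_shift_sd": config.anxiety_shift_sd,
        "metric_loading": config.metric_loading,
        "cort_behavior_r": config.cort_behavior_r,
        "seed": config.seed,
        "weight_change_params": list(
            (config.weight_change_params.control_mean,
             config.weight_change_params.control_sd,
             config.weight_change_params.stress_mean,
             config.weight_change_params.stress_sd)
        ),
        "metrics": [
            {
                "assay": m.assay.value,
                "metric_name": m.metric_name,
                "direction": m.direction.value,
                "control_mean": m.control_mean,
                "control_sd": m.control_sd,
                "distribution": m.distribution,
            }
            for m in config.metric_registry
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def config_from_yaml(path) -> CohortConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    kwargs = {
        k: payload[k]
        for k in (
            "n_control", "n_stress", "vulnerable_fraction", "anxiety_shift_sd",
            "metric_loading", "cort_behavior_r", "seed",
        )
        if k in payload
    }
    if "weight_change_params" in payload:
        kwargs["weight_change_params"] = GroupLevels(*payload["weight_change_params"])
    if "metrics" in payload:
        kwargs["metric_registry"] = [
            MetricSpec(
                assay=Assay(m["assay"]),
                metric_name=m["metric_name"],
                direction=Direction(m["direction"]),
                control_mean=float(m.get("control_mean", 0.0)),
                control_sd=float(m.get("control_sd", 1.0)),
                distribution=m.get("distribution", "normal"),
            )
            for m in payload["metrics"]
        ]
    config = CohortConfig(**kwargs)
    config.validate()
    return config
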