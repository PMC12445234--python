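"""Acoustic startle response (ASR) metrics from activity traces.

Startle is quantified from a uniformly sampled activity signal (a percent
pixel-change surrogate) with a known stimulus schedule. The amplitude of a
single startle is the maximum activity in a short response window following
pulse onset minus the mean pre-pulse baseline activity; mean startle averages
the amplitudes of the 15 identical habituation pulses, and sensitization is
the percent change of the last-triad mean relative to the first-triad mean
(negative values indicate habituation).

The response window defaults to the 50 ms following pulse onset (startle
latency follows the pulse; a centered window would dilute the response with
pre-pulse baseline) and the baseline to the mean activity over the 1 s
preceding onset. Both are configurable, as is flooring negative amplitudes
at zero (off by default: the difference formula permits negatives).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class StartleError(ValueError):
    """Raised for invalid traces, schedules, or windows."""


@dataclass
class ActivityTrace:
    """A uniformly sampled activity signal with its stimulus schedule.

    Parameters
    ----------
    sampling_rate
        Samples per second; must be positive.
    activity
        Non-negative activity values (percent pixel change surrogate).
    stimuli
        ``(time_s, intensity_db)`` pairs with strictly increasing times, all
        within the trace duration.
    """

    sampling_rate: float
    activity: np.ndarray
    stimuli: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if self.sampling_rate <= 0:
            raise StartleError("sampling_rate must be > 0")
        if self.activity.ndim != 1:
            raise StartleError("activity must be a 1-D signal")
        times = [t for t, _ in self.stimuli]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise StartleError("stimulus times must be strictly increasing")
        if times and (times[0] < 0 or times[-1] >= self.duration_s):
            raise StartleError("stimulus times must fall within the trace")

    @property
    def duration_s(self) -> float:
        return self.activity.size / self.sampling_rate

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.activity.size) / self.sampling_rate
        return pd.DataFrame({"time_s": t, "activity": self.activity})

    @classmethod
    def from_tsv(cls, path, sampling_rate=None, stimuli=()) -> "ActivityTrace":
        df = pd.read_csv(path, sep="\t")
        if not {"time_s", "activity"}.issubset(df.columns):
            raise StartleError(f"{path}: expected columns time_s, activity")
        if sampling_rate is None:
            dt = np.diff(df["time_s"].to_numpy())
            if dt.size == 0 or not np.allclose(dt, dt[0]):
                raise StartleError(f"{path}: cannot infer a uniform sampling rate")
            sampling_rate = 1.0 / dt[0]
        return cls(sampling_rate, df["activity"].to_numpy(), list(stimuli))


@dataclass
class StartleResult:
    """Per-animal startle summary."""

    animal_id: str
    amplitudes: list[float]
    mean_startle: float
    sensitization_pct: float
    threshold_curve: dict[float, float] = field(default_factory=dict)


def startle_amplitude(
    trace: ActivityTrace,
    stimulus_index: int,
    window_s: float = 0.05,
    baseline_s: float = 1.0,
    floor_at_zero: bool = False,
) -> float:
    """Amplitude of one startle: max activity in the response window minus baseline.

    The response window is ``[onset, onset + window_s]`` and the baseline is
    the mean activity over ``[onset - baseline_s, onset)``. Raises if either
    window exceeds the trace bounds. The result may be negative unless
    ``floor_at_zero`` is set.
    """
    if not 0 <= stimulus_index < len(trace.stimuli):
        raise StartleError(f"no stimulus with index {stimulus_index}")
    onset, _ = trace.stimuli[stimulus_index]
    sr = trace.sampling_rate
    i_on = int(round(onset * sr))
    i_lo = i_on - int(round(baseline_s * sr))
    i_hi = i_on + int(round(window_s * sr)) + 1  # window end inclusive
    if i_lo < 0:
        raise StartleError(
            f"stimulus {stimulus_index}: needs {baseline_s} s of pre-stimulus baseline"
        )
    if i_hi > trace.activity.size:
        raise StartleError(f"stimulus {stimulus_index}: response window exceeds trace")
    baseline = float(trace.activity[i_lo:i_on].mean())
    peak = float(trace.activity[i_on:i_hi].max())
    amp = peak - baseline
    return max(amp, 0.0) if floor_at_zero else amp


def startle_amplitudes(trace: ActivityTrace, **kwargs) -> list[float]:
    """Amplitudes for every stimulus in the trace, in schedule order."""
    return [startle_amplitude(trace, i, **kwargs) for i in range(len(trace.stimuli))]


def mean_startle(
    amplitudes, expected_count: int = 15, allow_any_count: bool = False
) -> float:
    """Arithmetic mean of the habituation-trial startle amplitudes.

    The habituation trial presents 15 identical pulses, so exactly 15
    amplitudes are expected; pass ``allow_any_count=True`` to average any
    non-empty list.
    """
    amps = np.asarray(list(amplitudes), dtype=float)
    if amps.size == 0:
        raise StartleError("mean_startle requires at least one amplitude")
    if not allow_any_count and amps.size != expected_count:
        raise StartleError(
            f"expected {expected_count} amplitudes, got {amps.size} "
            "(pass allow_any_count=True to override)"
        )
    return float(amps.mean())


def sensitization(amplitudes) -> float:
    """Percent change of mean startle from stimuli 1-3 to stimuli 13-15.

    ``100 * (mean(amps[13..15]) - mean(amps[1..3])) / mean(amps[1..3])``;
    positive values indicate sensitization, negative habituation. Raises when
    fewer than 15 amplitudes are given or the first-triad mean is zero.
    """
    amps = np.asarray(list(amplitudes), dtype=float)
    if amps.size < 15:
        raise StartleError(f"sensitization requires >= 15 amplitudes, got {amps.size}")
    first = float(amps[0:3].mean())
    last = float(amps[12:15].mean())
    if first == 0:
        raise StartleError("sensitization undefined: first-triad mean is zero")
    return 100.0 * (last - first) / first


def threshold_curve(trials) -> dict[float, float]:
    """Mean startle amplitude per stimulus intensity.

    ``trials`` is an iterable of ``(intensity_db, amplitude)`` pairs from the
    threshold-determination session (70-110 dB pulses, each played several
    times in pseudo-random order).
    """
    by_db: dict[float, list[float]] = {}
    for db, amp in trials:
        by_db.setdefault(float(db), []).append(float(amp))
    return {db: float(np.mean(v)) for db, v in sorted(by_db.items())}


def summarize_trace(animal_id: str, trace: ActivityTrace, **kwargs) -> StartleResult:
    """Full startle summary (amplitudes, mean, sensitization) for one habituation trace."""
    amps = startle_amplitudes(trace, **kwargs)
    return StartleResult(
        animal_id=animal_id,
        amplitudes=amps,
        mean_startle=mean_startle(amps, allow_any_count=True),
        sensitization_pct=sensitization(amps),
        threshold_curve=threshold_curve((db, a) for (_, db), a in zip(trace.stimuli, amps)),
    )


def summary_frame(results) -> pd.DataFrame:
    """Per-animal startle summary table (one column per tested intensity)."""
    rows = []
    for r in results:
        row = {
            "animal_id": r.animal_id,
            "mean_startle": r.mean_startle,
            "sensitization_pct": r.sensitization_pct,
        }
        for db, amp in r.threshold_curve.items():
            row[f"amp_{int(db)}dB"] = amp
        rows.append(row)
    return pd.DataFrame(rows)
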