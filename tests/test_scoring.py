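"""Cutoff derivation, binary scoring, composite scores, phenotype classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbcsig.registry import Direction, default_registry
from cbcsig.scoring import (
    CompositeScore,
    Phenotype,
    ScoringError,
    ThresholdSpec,
    classify_phenotype,
    composite_score,
    derive_threshold,
    group_summary,
    score_measure,
    select_for_sequencing,
)


def percentile_oracle(values, pct):
    """Brute-force linear-interpolation percentile between order statistics."""
    v = sorted(values)
    h = (len(v) - 1) * pct / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


class TestDeriveThreshold:
    def test_low_direction_matches_oracle(self):
        t = derive_threshold(range(1, 11), Direction.LOW_IS_AFFECTED)
        assert t.cutoff_value == pytest.approx(2.8)
        assert t.cutoff_value == pytest.approx(percentile_oracle(range(1, 11), 20))
        assert t.percentile_used == 20

    def test_high_direction_matches_oracle(self):
        t = derive_threshold(range(1, 11), Direction.HIGH_IS_AFFECTED)
        assert t.cutoff_value == pytest.approx(8.2)
        assert t.cutoff_value == pytest.approx(percentile_oracle(range(1, 11), 80))
        assert t.percentile_used == 80

    @given(
        values=st.lists(
            st.floats(min_value=-1e6, max_value=1e6), min_size=2, max_size=40
        ),
        direction=st.sampled_from(list(Direction)),
    )
    @settings(max_examples=100, deadline=None)
    def test_linear_method_agrees_with_oracle(self, values, direction):
        t = derive_threshold(values, direction)
        pct = 20 if direction is Direction.LOW_IS_AFFECTED else 80
        assert t.cutoff_value == pytest.approx(
            percentile_oracle(values, pct), rel=1e-9, abs=1e-9
        )

    def test_degenerate_controls_flag_nobody(self):
        t = derive_threshold([5.0] * 8, Direction.LOW_IS_AFFECTED)
        assert t.cutoff_value == 5.0
        assert score_measure(5.0, t) == 0

    def test_too_few_or_nan_controls_rejected(self):
        with pytest.raises(ScoringError):
            derive_threshold([1.0], Direction.LOW_IS_AFFECTED)
        with pytest.raises(ScoringError):
            derive_threshold([1.0, np.nan], Direction.LOW_IS_AFFECTED)

    def test_nearest_rank_method(self):
        t = derive_threshold(
            range(1, 11), Direction.LOW_IS_AFFECTED, percentile_method="nearest_rank"
        )
        # inverted-CDF 20th percentile of 1..10 is the 2nd order statistic
        assert t.cutoff_value == 2.0

    def test_calibration_at_large_n(self):
        """~20% of a large control sample falls outside its own cutoff."""
        rng = np.random.default_rng(42)
        values = rng.normal(size=10_000)
        for direction in Direction:
            t = derive_threshold(values, direction)
            flagged = np.mean([score_measure(v, t) for v in values])
            assert flagged == pytest.approx(0.20, abs=0.02)


class TestScoreMeasure:
    @pytest.mark.parametrize(
        "value, cutoff, direction, expected",
        [
            (2.8, 2.8, Direction.LOW_IS_AFFECTED, 0),  # tie -> unaffected
            (2.0, 2.8, Direction.LOW_IS_AFFECTED, 1),
            (9.0, 8.2, Direction.HIGH_IS_AFFECTED, 1),
            (8.2, 8.2, Direction.HIGH_IS_AFFECTED, 0),
            (3.0, 2.8, Direction.LOW_IS_AFFECTED, 0),
        ],
    )
    def test_strict_inequality_rule(self, value, cutoff, direction, expected):
        t = ThresholdSpec("m", direction, 20, cutoff, 10)
        assert score_measure(value, t) == expected


class TestCompositeScore:
    def test_all_affected_reaches_twenty(self):
        reg = default_registry(include_startle=False)
        score = composite_score("a1", {m.metric_name: 1 for m in reg}, reg)
        assert score.avoidance_subscore == 20
        assert score.total == 20

    def test_nothing_affected_is_zero(self):
        reg = default_registry()
        score = composite_score("a1", {m.metric_name: 0 for m in reg}, reg)
        assert score.total == 0

    def test_counts_only_flagged_metrics(self):
        reg = default_registry()
        binary = {m.metric_name: 0 for m in reg}
        binary["oft_light_center_latency_s"] = 1
        binary["ld_light_time_s"] = 1
        score = composite_score("a1", binary, reg)
        assert score.avoidance_subscore == 2
        assert score.startle_subscore == 0

    def test_startle_counts_separately(self):
        reg = default_registry()
        binary = {m.metric_name: 0 for m in reg}
        binary["mean_startle"] = 1
        score = composite_score("a1", binary, reg)
        assert (score.avoidance_subscore, score.startle_subscore) == (0, 1)

    def test_missing_metric_listed(self):
        reg = default_registry()
        with pytest.raises(ScoringError, match="mean_startle"):
            composite_score(
                "a1", {m.metric_name: 0 for m in reg if not m.is_startle}, reg
            )

    def test_monotone_in_affected_direction(self):
        """Pushing any metric value further toward the affected tail never lowers the score."""
        reg = default_registry(include_startle=False)
        rng = np.random.default_rng(7)
        thresholds = {
            m.metric_name: ThresholdSpec(m.metric_name, m.direction, 20, 0.0, 10)
            for m in reg
        }
        values = {m.metric_name: rng.normal() for m in reg}
        base = composite_score(
            "a", {k: score_measure(v, thresholds[k]) for k, v in values.items()}, reg
        )
        for m in reg:
            pushed = dict(values)
            step = 1.0 if m.direction is Direction.HIGH_IS_AFFECTED else -1.0
            pushed[m.metric_name] += step * 10
            moved = composite_score(
                "a", {k: score_measure(v, thresholds[k]) for k, v in pushed.items()}, reg
            )
            assert moved.total >= base.total


class TestClassification:
    def _scores(self, pairs):
        return [CompositeScore(a, t, 0) for a, t in pairs]

    def test_above_control_range_is_vulnerable(self):
        scores = self._scores([("c1", 0), ("c2", 6), ("s1", 14)])
        groups = {"c1": "control", "c2": "control", "s1": "stress"}
        labels = {l.animal_id: l.label for l in classify_phenotype(scores, groups)}
        assert labels["s1"] is Phenotype.VULNERABLE

    def test_equal_to_control_max_is_resilient(self):
        scores = self._scores([("c1", 6), ("s1", 6)])
        labels = {
            l.animal_id: l.label
            for l in classify_phenotype(scores, {"c1": "control", "s1": "stress"})
        }
        assert labels["s1"] is Phenotype.RESILIENT

    def test_all_zero_scores_all_resilient(self):
        scores = self._scores([("c1", 0), ("s1", 0), ("s2", 0)])
        groups = {"c1": "control", "s1": "stress", "s2": "stress"}
        labels = classify_phenotype(scores, groups)
        assert all(
            l.label is Phenotype.RESILIENT
            for l in labels
            if groups[l.animal_id] == "stress"
        )

    def test_controls_never_relabelled(self):
        scores = self._scores([("c1", 0), ("c2", 19), ("s1", 5)])
        groups = {"c1": "control", "c2": "control", "s1": "stress"}
        assert all(
            l.label is Phenotype.CONTROL
            for l in classify_phenotype(scores, groups)
            if groups[l.animal_id] == "control"
        )

    def test_no_controls_rejected(self):
        with pytest.raises(ScoringError):
            classify_phenotype(self._scores([("s1", 5)]), {"s1": "stress"})


class TestSelection:
    def _setup(self):
        stress = [("s1", 0), ("s2", 1), ("s3", 2), ("s4", 5), ("s5", 13), ("s6", 14), ("s7", 15)]
        controls = [(f"c{i}", i) for i in range(6)]
        scores = [CompositeScore(a, t, 0) for a, t in stress + controls]
        groups = {a: "stress" for a, _ in stress} | {a: "control" for a, _ in controls}
        return scores, groups

    def test_extremes_selected(self):
        scores, groups = self._setup()
        sel = select_for_sequencing(scores, groups, 3, 3, 6)
        assert sel.stress_low == ["s1", "s2", "s3"]
        assert sel.stress_high == ["s5", "s6", "s7"]
        assert len(sel.control) == 6

    def test_empty_high_stratum(self):
        scores, groups = self._setup()
        sel = select_for_sequencing(scores, groups, 3, 0, 6)
        assert sel.stress_high == []

    def test_tie_breaks_by_animal_id(self):
        scores = [CompositeScore(a, t, 0) for a, t in
                  [("sb", 2), ("sa", 2), ("sc", 0), ("sd", 9), ("se", 9)]]
        scores += [CompositeScore("c1", 1, 0), CompositeScore("c2", 3, 0)]
        groups = {s.animal_id: ("control" if s.animal_id.startswith("c") else "stress")
                  for s in scores}
        sel = select_for_sequencing(scores, groups, k_low=2, k_high=2, k_control=2)
        assert sel.stress_low == ["sc", "sa"]  # sa beats sb at the tied rank
        assert sel.stress_high == ["sd", "se"]

    def test_insufficient_animals_rejected(self):
        scores, groups = self._setup()
        with pytest.raises(ScoringError):
            select_for_sequencing(scores, groups, 5, 5, 6)


class TestGroupSummary:
    @pytest.mark.parametrize(
        "values, mean, sem",
        [
            ([13, 14, 15], 14.0, 0.58),
            ([0, 1, 2], 1.0, 0.58),
            ([7], 7.0, 0.0),
        ],
    )
    def test_mean_and_sem(self, values, mean, sem):
        m, s = group_summary(values)
        assert m == pytest.approx(mean)
        assert s == pytest.approx(sem, abs=0.005)

    def test_empty_rejected(self):
        with pytest.raises(ScoringError):
            group_summary([])
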