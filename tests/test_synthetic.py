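"""Synthetic cohort generator: structure, determinism, planted effects."""

import pickle

import numpy as np
import pytest
from scipy import stats

from cbcsig import scoring
from cbcsig.registry import Assay, default_registry
from cbcsig.synthetic import (
    CohortConfig,
    ConfigurationError,
    DePlantSpec,
    PlantedGene,
    simulate_activity_trace,
    simulate_cohort,
    simulate_counts,
)
from cbcsig.startle import startle_amplitude, startle_amplitudes, sensitization


class TestCohortStructure:
    def test_study_design_sizes(self, default_cohort):
        frame = default_cohort.animals_frame()
        assert len(frame) == 39
        assert (frame["group"] == "control").sum() == 19
        assert (frame["group"] == "stress").sum() == 20

    def test_every_animal_measured_on_every_metric(self, default_cohort):
        registry = default_cohort.config.metric_registry
        seen = {}
        for m in default_cohort.measurements:
            seen.setdefault(m.animal_id, set()).add(m.metric_name)
        expected = {m.metric_name for m in registry}
        assert all(metrics == expected for metrics in seen.values())
        assert len(seen) == 39

    def test_latent_class_consistent_with_group(self, default_cohort):
        for a in default_cohort.animals:
            assert (a.latent_class == "none") == (a.group == "control")

    def test_reproducibility_is_byte_identical(self):
        c1 = simulate_cohort(CohortConfig(seed=42))
        c2 = simulate_cohort(CohortConfig(seed=42))
        assert pickle.dumps(c1.measurements) == pickle.dumps(c2.measurements)
        assert pickle.dumps(c1.physiology) == pickle.dumps(c2.physiology)
        for k in c1.traces:
            np.testing.assert_array_equal(c1.traces[k].activity, c2.traces[k].activity)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_cohort(CohortConfig(n_control=0))
        with pytest.raises(ConfigurationError):
            simulate_cohort(CohortConfig(vulnerable_fraction=1.5))
        with pytest.raises(ConfigurationError):
            simulate_cohort(CohortConfig(anxiety_shift_sd=-1.0))

    def test_vulnerable_latent_anxiety_exceeds_resilient(self):
        """Vulnerable-latent animals have strictly higher mean latent anxiety
        than resilient-latent animals in every seed."""
        for seed in range(200):
            cfg = CohortConfig(
                n_control=4, n_stress=20, anxiety_shift_sd=3.0,
                vulnerable_fraction=0.3, seed=seed,
            )
            frame = simulate_cohort(cfg).animals_frame()
            vul = frame.loc[frame["latent_class"] == "vulnerable_latent", "latent_anxiety"]
            res = frame.loc[frame["latent_class"] == "resilient_latent", "latent_anxiety"]
            if len(vul) and len(res):
                assert vul.mean() > res.mean()

    def test_null_configuration_groups_indistinguishable(self):
        """With no shift and no vulnerable class, stress and control metric
        distributions coincide (two-sample KS p not concentrated at 0)."""
        ps = []
        for seed in range(60):
            cfg = CohortConfig(
                anxiety_shift_sd=0.0, vulnerable_fraction=0.0, seed=seed
            )
            cohort = simulate_cohort(cfg)
            metric = cfg.metric_registry[0].metric_name
            by_group = {"control": [], "stress": []}
            for m in cohort.measurements:
                if m.metric_name == metric:
                    by_group[m.group].append(m.value)
            ps.append(stats.ks_2samp(by_group["control"], by_group["stress"]).pvalue)
        ps = np.asarray(ps)
        assert (ps < 0.05).mean() <= 0.15
        assert 0.30 <= ps.mean() <= 0.70

    def test_monotone_in_anxiety_shift(self):
        """A larger shift never lowers the mean composite of vulnerable-latent
        animals (common random numbers via the shared seed)."""
        for seed in range(5):
            means = []
            for shift in (0.5, 1.5, 3.0, 5.0):
                cfg = CohortConfig(anxiety_shift_sd=shift, seed=seed)
                cohort = simulate_cohort(cfg)
                _, scores, _ = scoring.score_cohort(
                    cohort.measurements, cfg.metric_registry
                )
                vul = {
                    a.animal_id
                    for a in cohort.animals
                    if a.latent_class == "vulnerable_latent"
                }
                totals = [s.total for s in scores if s.animal_id in vul]
                if not totals:  # this seed drew no vulnerable animals
                    break
                means.append(np.mean(totals))
            assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))

    def test_cort_correlates_with_latent_anxiety(self):
        """Empirical corr(cort 3h, latent anxiety) within +/-0.1 of the target
        for homogeneous cohorts of >= 200 animals."""
        for seed in range(5):
            cfg = CohortConfig(
                n_control=250, n_stress=2, vulnerable_fraction=0.0, seed=seed
            )
            cohort = simulate_cohort(cfg)
            latent = {a.animal_id: a.latent_anxiety for a in cohort.animals}
            ids = [a.animal_id for a in cohort.animals if a.group == "control"]
            cort = {r.animal_id: r.cort_3h for r in cohort.physiology}
            r = np.corrcoef([latent[i] for i in ids], [cort[i] for i in ids])[0, 1]
            assert abs(r - cfg.cort_behavior_r) <= 0.1


class TestActivityTraceSimulation:
    def test_zero_gain_zero_noise_is_flat(self):
        trace = simulate_activity_trace(
            [(5.0, 110.0)], startle_gain=0.0, noise_sd=0.0, seed=0, baseline=1.0
        )
        np.testing.assert_allclose(trace.activity, 1.0)

    def test_injected_height_recovered_exactly(self):
        """Closed loop with the startle module: noise-free amplitude equals the
        injected transient height."""
        g = 7.25
        trace = simulate_activity_trace(
            [(5.0, 110.0)], startle_gain=g, noise_sd=0.0, seed=0
        )
        assert startle_amplitude(trace, 0) == pytest.approx(g)

    def test_intensity_scaling(self):
        trace = simulate_activity_trace(
            [(5.0, 55.0)], startle_gain=10.0, noise_sd=0.0, seed=0
        )
        assert startle_amplitude(trace, 0) == pytest.approx(5.0)

    def test_decaying_pulse_gains_give_habituation(self):
        schedule = [(5.0 + 20.0 * k, 110.0) for k in range(15)]
        gains = np.linspace(1.0, 0.2, 15)
        trace = simulate_activity_trace(
            schedule, startle_gain=10.0, noise_sd=0.0, seed=0, pulse_gains=gains
        )
        amps = startle_amplitudes(trace)
        assert sensitization(amps) < 0

    def test_empty_schedule_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_activity_trace([], startle_gain=1.0, noise_sd=0.0)

    def test_stimulus_outside_duration_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_activity_trace(
                [(20.0, 110.0)], startle_gain=1.0, noise_sd=0.0, duration_s=10.0
            )


class TestSimulateCounts:
    def test_planted_shift_visible_in_group_means(self, samples_5c_3v3):
        spec = DePlantSpec(
            n_genes=100,
            baseline_mean=200.0,
            dispersion=0.01,
            planted=[PlantedGene(3, 2.0, ("stress_high",))],
        )
        cm = simulate_counts(samples_5c_3v3, spec, seed=0)
        sf = cm.counts.sum(axis=0) / cm.counts.sum(axis=0).mean()
        q = cm.counts / sf
        groups = np.asarray(cm.sample_groups)
        ratio = q[3, groups == "stress_high"].mean() / q[3, groups == "control"].mean()
        assert np.log2(ratio) == pytest.approx(2.0, abs=0.4)

    def test_library_sizes_vary_within_bounds(self, samples_5c_3v3):
        spec = DePlantSpec(n_genes=500, baseline_mean=100.0, dispersion=0.01)
        cm = simulate_counts(samples_5c_3v3, spec, seed=1)
        totals = cm.counts.sum(axis=0)
        assert totals.max() / totals.min() < 1.2 / 0.8 * 1.1

    def test_all_zero_baseline_rejected(self, samples_3v3):
        with pytest.raises(ConfigurationError):
            simulate_counts(
                samples_3v3, DePlantSpec(n_genes=5, baseline_mean=0.0), seed=0
            )

    def test_planted_index_out_of_range_rejected(self, samples_3v3):
        spec = DePlantSpec(
            n_genes=5, planted=[PlantedGene(9, 2.0, ("stress_high",))]
        )
        with pytest.raises(ConfigurationError):
            simulate_counts(samples_3v3, spec, seed=0)

    def test_planted_group_must_exist(self, samples_3v3):
        spec = DePlantSpec(n_genes=5, planted=[PlantedGene(0, 2.0, ("control",))])
        with pytest.raises(ConfigurationError):
            simulate_counts(samples_3v3, spec, seed=0)

    def test_dispersion_matches_request(self, samples_3v3):
        """Sampled counts show roughly the requested NB dispersion."""
        spec = DePlantSpec(n_genes=4000, baseline_mean=100.0, dispersion=0.2,
                           library_size_range=(1.0, 1.0))
        cm = simulate_counts(samples_3v3, spec, seed=3)
        mean = cm.counts.mean(axis=1)
        var = cm.counts.var(axis=1, ddof=1)
        phi = np.median((var - mean) / mean**2)
        assert phi == pytest.approx(0.2, abs=0.06)


class TestStartleIndependence:
    def test_startle_gain_not_tied_to_latent_class(self):
        """Startle sub-scores do not separate groups in the emulated design."""
        gains = {"vulnerable_latent": [], "resilient_latent": []}
        for seed in range(20):
            cfg = CohortConfig(seed=seed)
            cohort = simulate_cohort(cfg)
            by_id = {m.animal_id: m.value for m in cohort.measurements
                     if m.metric_name == "mean_startle"}
            for a in cohort.animals:
                if a.latent_class in gains:
                    gains[a.latent_class].append(by_id[a.animal_id])
        _, p = stats.ttest_ind(gains["vulnerable_latent"], gains["resilient_latent"])
        assert p > 0.01
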