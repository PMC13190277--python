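import numpy as np
import pytest

from strokephys import (
    CohortSpec,
    PassiveModel,
    SpikingModel,
    StepDescriptor,
    ValidationError,
    if_step_grid,
    lif_rheobase,
    lif_steady_rate,
    simulate_ais_profile,
    simulate_cohort,
    simulate_lesion_sections,
    simulate_passive,
    simulate_single_ap_protocol,
    simulate_spiking,
)
from strokephys.morphometry import lesion_volume

from conftest import closed_form_passive


class TestPassiveSimulator:
    def test_noiseless_matches_closed_form(self, passive_model):
        step = StepDescriptor(0.0, -100.0, 0.1, 1.0)
        sweep = simulate_passive(passive_model, [step], rate=10_000.0)[0]
        oracle = closed_form_passive(passive_model, step, sweep)
        np.testing.assert_allclose(sweep.voltage, oracle, atol=1e-9)

    def test_steady_state_is_ohmic(self, passive_model):
        # R_in = 150 MOhm, I = -100 pA -> steady deflection -15 mV
        step = StepDescriptor(0.0, -100.0, 0.05, 1.0)
        sweep = simulate_passive(passive_model, [step])[0]
        end = int(1.05 * sweep.sampling_rate) - 1
        assert sweep.voltage[end] == pytest.approx(-85.0, abs=1e-6)

    def test_one_tau_after_onset(self, passive_model):
        # at t = tau the deflection is (1 - 1/e) of the steady value
        step = StepDescriptor(0.0, -100.0, 0.1, 1.0)
        sweep = simulate_passive(passive_model, [step])[0]
        onset = int(0.1 * sweep.sampling_rate)
        k = onset + int(0.020 * sweep.sampling_rate) - 1  # 20 ms = tau
        expected = -70.0 - 15.0 * (1 - np.exp(-1))
        assert sweep.voltage[k] == pytest.approx(expected, abs=1e-9)

    def test_depolarising_step_refused(self, passive_model):
        with pytest.raises(ValidationError):
            simulate_passive(passive_model, [StepDescriptor(0.0, 50.0, 0.1, 1.0)])

    def test_noise_seeds_differ_but_mean_matches(self):
        model = PassiveModel(noise_sd=0.2)
        step = StepDescriptor(0.0, -100.0, 0.05, 0.3)
        a = simulate_passive(model, [step], rate=10_000.0, seed=1)[0]
        b = simulate_passive(model, [step], rate=10_000.0, seed=2)[0]
        assert not np.array_equal(a.voltage, b.voltage)
        # Monte-Carlo: the mean trajectory at a probe sample matches the
        # closed form within 3 SE over 100 replicates
        probe = int(0.2 * 10_000)
        vals = [
            simulate_passive(model, [step], rate=10_000.0, seed=100 + s)[0].voltage[probe]
            for s in range(100)
        ]
        oracle = closed_form_passive(PassiveModel(), step, a)[probe]
        se = np.std(vals, ddof=1) / 10.0
        assert abs(np.mean(vals) - oracle) < 3 * se

    def test_seed_determinism(self):
        model = PassiveModel(noise_sd=0.3)
        step = StepDescriptor(0.0, -50.0, 0.05, 0.2)
        a = simulate_passive(model, [step], seed=7)[0]
        b = simulate_passive(model, [step], seed=7)[0]
        assert np.array_equal(a.voltage, b.voltage)


class TestSpikingSimulator:
    def test_grid_rheobase_matches_closed_form(self, spiking_model):
        # (V_T - E_L)/R = 25 mV / 100 MOhm = 250 pA, on the 25 pA grid
        grid = if_step_grid()
        assert lif_rheobase(spiking_model, [s.amplitude_pA for s in grid]) == 250.0
        sweeps, truths = simulate_spiking(spiking_model, grid)
        spiking = [s.step.amplitude_pA for s, t in zip(sweeps, truths) if t.n_spikes > 0]
        assert min(spiking) == 250.0

    def test_counts_match_isi_formula(self, spiking_model):
        """Noiseless spike counts per level agree with the LIF ISI closed form."""
        grid = if_step_grid(start_pA=275.0)
        sweeps, truths = simulate_spiking(spiking_model, grid)
        for sweep, truth in zip(sweeps, truths):
            predicted = lif_steady_rate(spiking_model, sweep.step.amplitude_pA)
            assert abs(truth.n_spikes - predicted) <= 1.0

    def test_below_rheobase_silent(self, spiking_model):
        sweeps, truths = simulate_spiking(
            spiking_model, [StepDescriptor(0.0, 225.0, 0.1, 1.0)]
        )
        assert truths[0].n_spikes == 0

    def test_counts_nondecreasing_in_current(self, spiking_model):
        _, truths = simulate_spiking(spiking_model, if_step_grid())
        counts = [t.n_spikes for t in truths]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_template_slope_floor_enforced(self):
        with pytest.raises(ValidationError, match="50 V/s"):
            SpikingModel(ap_peak_amp=10.0, ap_rise_ms=1.0)

    def test_template_must_fit_refractory_period(self):
        with pytest.raises(ValidationError, match="refractory"):
            SpikingModel(t_ref=1.0, ap_rise_ms=0.4, ap_fall_ms=0.8)

    def test_seed_determinism(self, spiking_model):
        model = SpikingModel(noise_sd=0.3)
        step = [StepDescriptor(0.0, 300.0, 0.1, 1.0)]
        a, ta = simulate_spiking(model, step, seed=3)
        b, tb = simulate_spiking(model, step, seed=3)
        assert np.array_equal(a[0].voltage, b[0].voltage)
        assert ta[0].spike_start_indices == tb[0].spike_start_indices


class TestSingleAPProtocol:
    def test_first_single_ap_matches_brute_force(self, spiking_model):
        res = simulate_single_ap_protocol(spiking_model, start_pA=100.0, seed=0)
        assert not res.protocol_failed
        # brute force: every earlier step in the escalation has != 1 spike
        for truth in res.truths[: res.first_single_ap_index]:
            assert truth.n_spikes != 1
        assert res.truths[res.first_single_ap_index].n_spikes == 1

    def test_ceiling_reached_sets_flag(self, spiking_model):
        res = simulate_single_ap_protocol(
            spiking_model, start_pA=25.0, ceiling_pA=100.0, seed=0
        )
        assert res.protocol_failed and res.first_single_ap_index is None

    def test_nonpositive_increment_rejected(self, spiking_model):
        with pytest.raises(ValidationError):
            simulate_single_ap_protocol(spiking_model, increment_pA=0.0)


class TestAISProfile:
    def test_trapezoid_truth_length(self):
        _, truth = simulate_ais_profile(plateau_um=20.0, edge_um=1.0, baseline=0.0)
        assert truth.length_um == pytest.approx(21.34)

    def test_rectangle_truth_is_plateau(self):
        _, truth = simulate_ais_profile(plateau_um=20.0, edge_um=0.0)
        assert truth.length_um == pytest.approx(20.0)

    def test_intensity_scaling_leaves_truth_unchanged(self):
        _, t1 = simulate_ais_profile(f_max=1000.0)
        _, t2 = simulate_ais_profile(f_max=10_000.0)
        assert t1 == t2

    def test_noise_keeps_intensity_nonnegative(self):
        profile, _ = simulate_ais_profile(noise_sd=500.0, f_max=1000.0, seed=0)
        assert np.all(profile.intensity >= 0)


class TestLesionSections:
    def test_volume_round_trip(self):
        series = simulate_lesion_sections(0.75, n_sections=12, seed=4)
        assert lesion_volume(series) == pytest.approx(0.75, rel=1e-9)

    def test_single_section_default_factors(self):
        # 1e6 um^2 x 30 um x 3 / 1e9 = 0.09 mm^3
        series = simulate_lesion_sections(0.09, n_sections=1, seed=0)
        assert series.section_areas_um2[0] == pytest.approx(1e6)

    def test_zero_sections_zero_volume(self):
        series = simulate_lesion_sections(0.0, n_sections=0)
        assert lesion_volume(series) == 0.0


class TestCohortSimulator:
    def test_zero_effects_zero_noise_constant(self):
        spec = CohortSpec(
            intercept=3.0,
            re_sd_intercept=0.0,
            re_sd_hemisphere=0.0,
            residual_sd=0.0,
            seed=0,
        )
        df, _ = simulate_cohort(spec)
        assert np.allclose(df["outcome_value"], 3.0)

    def test_declared_group_effect_recovered_empirically(self):
        """Monte-Carlo: the empirical stroke-sham mean difference over 200
        replicate cohorts matches the declared -0.70 effect within 3 SE."""
        diffs = []
        for rep in range(200):
            spec = CohortSpec(
                fixed_effects={"group[stroke]": -0.70},
                re_sd_intercept=0.5,
                re_sd_hemisphere=0.2,
                residual_sd=0.8,
                seed=5000 + rep,
            )
            df, _ = simulate_cohort(spec)
            by = df.groupby("group")["outcome_value"].mean()
            diffs.append(by["stroke"] - by["sham"])
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs) - (-0.70)) < 3 * se

    def test_negative_sd_rejected(self):
        with pytest.raises(ValidationError):
            CohortSpec(re_sd_intercept=-1.0)

    def test_log_scale_outcomes_positive(self):
        spec = CohortSpec(intercept=3.0, scale="log", residual_sd=0.5, seed=1)
        df, _ = simulate_cohort(spec)
        assert (df["outcome_value"] > 0).all()

    def test_unknown_effect_term_rejected(self):
        with pytest.raises(ValidationError, match="unknown terms"):
            simulate_cohort(CohortSpec(fixed_effects={"group[zombie]": 1.0}))

    def test_seed_determinism(self):
        a, _ = simulate_cohort(CohortSpec(seed=9))
        b, _ = simulate_cohort(CohortSpec(seed=9))
        assert a.equals(b)
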