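"""Generator: presets, rate profiles, Poisson sampling, cohort structure."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.integrate import quad

import triphasic as tp
from triphasic.synth import RateProfile, _tri_kernel


class TestPresets:
    def test_s1_preset_means_match_published_response_statistics(self):
        s1 = tp.make_preset("S1_default")
        assert s1.onset_mean_ms == 14.7
        assert s1.baseline_mean_hz == 1.2
        assert s1.peak_mean_ms == 21.4
        assert s1.dur_mean_ms == 27.0
        assert s1.amp_mean_hz == 83.0
        assert s1.responsive_prob == 0.367
        assert (s1.suppressed_prob, s1.rebound_prob) == (0.223, 0.309)
        assert (s1.rebound_peak_mean_ms, s1.rebound_amp_mean_hz) == (289.0, 31.4)

    def test_m1_preset_means_match_published_response_statistics(self):
        m1 = tp.make_preset("M1_default")
        assert m1.baseline_mean_hz == 0.6
        assert m1.onset_mean_ms == 24.3
        assert (m1.suppressed_prob, m1.rebound_prob) == (0.084, 0.081)

    def test_unknown_preset_raises(self):
        with pytest.raises(ValueError, match="unknown preset"):
            tp.make_preset("S2_default")

    def test_degenerate_spreads_give_identical_units(self):
        from triphasic.synth import sample_unit
        preset = replace(tp.make_preset("S1_default"), baseline_sd_hz=0.0,
                         onset_sd_ms=0.0, dur_sd_ms=0.0, amp_sd_hz=0.0,
                         supp_frac_sd=0.0, rebound_peak_sd_ms=0.0,
                         rebound_amp_sd_hz=0.0, responsive_prob=1.0,
                         suppressed_prob=1.0, rebound_prob=1.0)
        cfg = replace(tp.RecordingConfig("r"), pv_frac=0.0, calibrate_kernels=False)
        units = [sample_unit(np.random.default_rng(k), preset, cfg, f"u{k}", 20.0, 8.0)
                 for k in range(6)]
        # depth varies (laminar weighting scales amplitude); everything else is fixed
        for u in units:
            assert u.baseline_hz == units[0].baseline_hz
            assert u.onset_ms == units[0].onset_ms
            assert u.dur_ms == units[0].dur_ms
            assert u.supp_frac == units[0].supp_frac


class TestProtocol:
    def test_lag_required_iff_paired_pulse(self):
        with pytest.raises(ValueError):
            tp.StimulusProtocol("hand", lag_ms=150.0)
        with pytest.raises(ValueError):
            tp.StimulusProtocol("paired_pulse")
        assert tp.StimulusProtocol("paired_pulse", lag_ms=150.0).lag_ms == 150.0

    def test_silencing_condition_uses_27_trials_by_default_suite(self):
        suite = tp.default_protocol_suite()
        combos = [p for p in suite if p.kind == "hand_plus_cortex"]
        assert combos and all(p.n_trials == 27 for p in combos)
        assert all(p.pulse_ms == 20.0 for p in suite if p.kind == "cortex_laser")


def _unit(**over):
    base = dict(unit_id="u", area="S1", is_pv=False, is_single=True, depth_frac=0.5,
                baseline_hz=1.2, responsive=True, onset_ms=14.7, peak_ms=21.4,
                dur_ms=27.0, peak_hz=83.0)
    base.update(over)
    return tp.UnitGroundTruth(**base)


class TestRateProfile:
    def test_non_responsive_unit_is_constant_baseline(self):
        u = _unit(responsive=False)
        r = tp.rate_profile(u, tp.StimulusProtocol("hand"))
        t = np.linspace(-0.5, 0.499, 777)
        assert np.allclose(r(t), 1.2)

    def test_hand_off_is_baseline_everywhere(self):
        u = _unit(suppressed=True, supp_frac=0.1, rebound=True,
                  rebound_peak_ms=290.0, rebound_hz=30.0)
        r = tp.rate_profile(u, tp.StimulusProtocol("hand_off"))
        t = np.linspace(-0.5, 0.499, 777)
        assert np.allclose(r(t), 1.2)

    def test_suppression_window_rate_is_supp_frac_times_baseline(self):
        u = _unit(suppressed=True, supp_frac=0.082)
        r = tp.rate_profile(u, tp.StimulusProtocol("hand"))
        assert r(np.array([0.140]))[0] == pytest.approx(0.0984)

    def test_integral_matches_quadrature(self):
        u = _unit(suppressed=True, supp_frac=0.3, rebound=True,
                  rebound_peak_ms=290.0, rebound_hz=31.4)
        r = tp.rate_profile(u, tp.StimulusProtocol("hand"))
        num, _ = quad(lambda t: r(np.array([t]))[0], 0.0, 0.5, limit=400)
        assert r.integral_hz_s(0.0, 0.5) == pytest.approx(num, rel=1e-4)

    def test_negative_rate_raises_not_clamps(self):
        u = _unit(suppressed=True, supp_frac=0.5)
        prof = tp.rate_profile(u, tp.StimulusProtocol("hand"))
        object.__setattr__  # keep linters quiet; mutate the suppression delta directly
        prof._supp = (110.0, 170.0, -2.0 * u.baseline_hz)
        with pytest.raises(ValueError, match="negative"):
            prof(np.array([0.140]))

    def test_paired_pulse_second_kernel_scaled(self):
        u = _unit()
        proto = tp.StimulusProtocol("paired_pulse", lag_ms=150.0)
        r = tp.rate_profile(u, proto, recovery={150.0: 0.5})
        t_peak1 = u.peak_ms / 1000.0
        t_peak2 = (u.peak_ms + 150.0) / 1000.0
        assert r(np.array([t_peak1]))[0] == pytest.approx(1.2 + 83.0)
        assert r(np.array([t_peak2]))[0] == pytest.approx(1.2 + 0.5 * 83.0)

    def test_cortex_laser_drives_pv_plateau_and_scales_with_intensity(self):
        u = _unit(is_pv=True)
        full = tp.rate_profile(u, tp.StimulusProtocol("cortex_laser", pulse_ms=20.0))
        quarter = tp.rate_profile(
            u, tp.StimulusProtocol("cortex_laser", pulse_ms=20.0, intensity_frac=0.25))
        assert full(np.array([0.010]))[0] == pytest.approx(1.2 + 100.0)
        assert quarter(np.array([0.010]))[0] == pytest.approx(1.2 + 25.0)


class TestSampleSpikes:
    def test_constant_rate_mean_count_matches_poisson(self):
        proto = tp.StimulusProtocol("hand", n_trials=1000)
        rate = lambda t: np.full(np.shape(t), 2.0)
        t = tp.sample_spikes(rate, proto, seed=3, max_rate_hz=2.0)
        mean_per_trial = len(t) / 1000
        se = np.sqrt(2.0 / 1000)
        assert abs(mean_per_trial - 2.0) < 3 * se

    def test_zero_rate_gives_no_spikes(self):
        proto = tp.StimulusProtocol("hand")
        t = tp.sample_spikes(lambda t: np.zeros(np.shape(t)), proto, seed=0,
                             max_rate_hz=0.0)
        assert len(t) == 0

    def test_kernel_area_sets_mean_extra_spikes(self):
        u = _unit(baseline_hz=0.0)
        proto = tp.StimulusProtocol("hand", n_trials=1000)
        prof = tp.rate_profile(u, proto)
        area = prof.integral_hz_s(-0.5, 0.5)  # closed-form kernel area
        t = tp.sample_spikes(prof, proto, seed=5, max_rate_hz=prof.max_rate_hz)
        se = np.sqrt(area / 1000)
        assert abs(len(t) / 1000 - area) < 3 * se

    def test_identical_seed_identical_spikes(self):
        u = _unit(suppressed=True, supp_frac=0.1)
        proto = tp.StimulusProtocol("hand")
        prof = tp.rate_profile(u, proto)
        a = tp.sample_spikes(prof, proto, seed=42)
        b = tp.sample_spikes(prof, proto, seed=42)
        assert np.array_equal(a, b)

    def test_unbounded_rate_rejected(self):
        proto = tp.StimulusProtocol("hand")
        with pytest.raises(ValueError, match="bounded"):
            tp.sample_spikes(lambda t: np.full(np.shape(t), np.inf), proto, seed=0,
                             max_rate_hz=np.inf)


class TestSimulateCohort:
    def test_cohort_shape_and_determinism(self, small_cohort):
        manifest, spikes, trials, units = small_cohort
        assert units.groupby(["recording_id", "area"]).size().min() >= 15
        m2, s2, t2, u2 = tp.simulate_cohort(tp.default_cohort_configs(2), seed=11)
        assert s2.equals(spikes) and t2.equals(trials) and u2.equals(units)
        assert m2.to_json() == manifest.to_json()

    def test_spike_times_sorted_nonnegative_and_ids_resolvable(self, small_cohort):
        _, spikes, _, units = small_cohort
        assert (spikes["spike_time_s"] >= 0).all()
        for _, grp in spikes.groupby("unit_id"):
            assert np.all(np.diff(grp["spike_time_s"].to_numpy()) >= 0)
        assert set(spikes["unit_id"]) <= set(units["unit_id"])

    def test_responsive_fraction_matches_binomial(self, default_cohort):
        manifest, *_ = default_cohort
        ut = manifest.unit_table()
        s1 = ut[ut["area"] == "S1"]
        frac = s1["responsive"].mean()
        p = tp.make_preset("S1_default").responsive_prob
        se = np.sqrt(p * (1 - p) / len(s1))
        assert abs(frac - p) < 3 * se

    def test_monotonic_peak_rate_increases_expected_counts(self):
        u_lo = _unit(peak_hz=20.0)
        u_hi = _unit(peak_hz=40.0)
        proto = tp.StimulusProtocol("hand")
        lo = tp.rate_profile(u_lo, proto).integral_hz_s(0.0, 0.1)
        hi = tp.rate_profile(u_hi, proto).integral_hz_s(0.0, 0.1)
        assert hi > lo

    def test_kernel_calibration_targets_measured_readout(self):
        # noise-free binned readout of a calibrated kernel returns the target
        from triphasic.synth import calibrate_kernel, _measure_binned
        t0, tpk, t1 = calibrate_kernel(14.7, 21.4, 27.0, amp=83.0,
                                       thr_on=20.0, thr_fall=8.0)
        m_on, m_pk, m_du = _measure_binned(t0, tpk, t1, 83.0, 20.0, 8.0)
        assert m_on == pytest.approx(14.7, abs=0.6)
        assert m_pk == pytest.approx(21.4, abs=0.6)
        assert m_du == pytest.approx(27.0, abs=1.0)
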