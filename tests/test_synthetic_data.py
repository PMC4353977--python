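import numpy as np
import pytest

from thetanet import extract_period, theta_power, welch_psd
from thetanet.signal_io import Period, ValidationError
from thetanet.synthetic_data import (
    FcConfig, SrmConfig, StateSchedule, ThetaSource, analytic_coherence,
    RegionMixing, build_envelope, effective_source_density,
    expected_welch_peak_density, lorentzian_density, pink_noise, render_source,
    synthesize_fc_session, synthesize_srm_session, _child_rng,
)

FS = 500.0


class TestPinkNoise:
    def test_white_limit_flat(self):
        x = pink_noise(150_000, FS, level=1.0, alpha=0.0,
                       rng=np.random.default_rng(0))
        psd = welch_psd(x, FS)
        band = (psd.freqs >= 1) & (psd.freqs <= 100)
        assert psd.power_db[band].max() - psd.power_db[band].min() < 1.0 + 1.5

    def test_one_over_f_slope(self):
        x = pink_noise(150_000, FS, level=1.0, alpha=1.0,
                       rng=np.random.default_rng(1))
        psd = welch_psd(x, FS)
        band = (psd.freqs >= 2) & (psd.freqs <= 100)
        slope = np.polyfit(np.log10(psd.freqs[band]),
                           psd.power_db[band] / 10.0, 1)[0]
        assert abs(slope + 1.0) < 0.15

    def test_density_level_calibration(self):
        x = pink_noise(200_000, FS, level=2.0, alpha=1.0,
                       rng=np.random.default_rng(2))
        psd = welch_psd(x, FS)
        i8 = np.argmin(np.abs(psd.freqs - 8.0))
        expected_db = 10 * np.log10(4.0 / 8.0)
        assert abs(psd.power_db[i8] - expected_db) < 1.0

    def test_determinism_and_validation(self):
        a = pink_noise(1000, FS, rng=np.random.default_rng(7))
        b = pink_noise(1000, FS, rng=np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValidationError):
            pink_noise(1000, FS, alpha=-1.0)
        with pytest.raises(ValidationError):
            pink_noise(1, FS)


class TestRenderSource:
    def test_zero_diffusion_is_pure_sinusoid(self):
        src = ThetaSource("s", 8.0, 0.0, 1.0)
        sch = StateSchedule({"A": 1.0}, onset_ramp_s=0)
        sig = render_source(src, sch, [Period("A", 0, 60)], FS, 60.0,
                            np.random.default_rng(0))
        psd = welch_psd(sig, FS)
        assert theta_power(psd, (5, 11)).peak_freq_hz == 8.0
        t = np.arange(len(sig)) / FS
        np.testing.assert_allclose(sig, np.cos(2 * np.pi * 8 * t), atol=1e-12)

    def test_doubled_amplitude_doubles_peak_density(self):
        src = ThetaSource("s", 8.0, 5.0, 5.0)
        tl = [Period("A", 0, 120)]
        rng = lambda: np.random.default_rng(42)
        base = render_source(src, StateSchedule({"A": 1.0}, 0), tl, FS, 120, rng())
        enc = render_source(src, StateSchedule({"A": 2.0}, 0), tl, FS, 120, rng())
        d = theta_power(welch_psd(enc, FS)).tp_db - \
            theta_power(welch_psd(base, FS)).tp_db
        assert abs(d - 6.02) < 0.5

    def test_measured_peak_matches_analytic_across_linewidths(self):
        for diffusion in (0.5, 5.0, 50.0):
            src = ThetaSource("s", 8.0, diffusion, 5.0)
            sig = render_source(src, StateSchedule({"A": 1.0}, 0),
                                [Period("A", 0, 300)], FS, 300,
                                np.random.default_rng(3))
            measured = theta_power(welch_psd(sig, FS), (5, 11)).tp_db
            expected = 10 * np.log10(expected_welch_peak_density(src, 1.0, FS))
            assert abs(measured - expected) < 0.5, f"D={diffusion}"

    def test_overlapping_scheduled_periods_rejected(self):
        src = ThetaSource("s", 8.0, 1.0, 1.0)
        tl = [Period("Enc1", 0, 10), Period("Enc2", 5, 15)]
        with pytest.raises(ValidationError):
            render_source(src, StateSchedule({"Enc1": 2.0, "Enc2": 2.0}), tl,
                          FS, 15, np.random.default_rng(0))


class TestEnvelope:
    def test_ramp_decay_and_hold(self):
        sch = StateSchedule({"Base": 1.0, "Enc1": 2.0, "Post1": 1.0},
                            onset_ramp_s=10.0, post_decay_tau_s=20.0)
        tl = [Period("Base", 0, 30), Period("Enc1", 30, 60), Period("Post1", 60, 120)]
        env = build_envelope(sch, tl, 10.0, 120.0)
        assert env[int(29 * 10)] == 1.0
        assert env[int(34.9 * 10)] < 2.0 < env[int(41 * 10)] + 1e-9
        assert env[int(59 * 10)] == pytest.approx(2.0)
        # exponential decay through Post1
        v20 = env[int(80 * 10)]
        assert v20 == pytest.approx(1 + np.exp(-1.0), abs=0.01)

    def test_novelty_schedule_values(self):
        cfg = SrmConfig(fs=FS, base_s=10, enc_s=10, post_s=5, transfer_s=2)
        sch = cfg.schedules()["limbic"]
        assert sch.multipliers["Enc1"] == pytest.approx(1.7)
        assert sch.multipliers["Enc4"] == pytest.approx(1.35)
        assert sch.multipliers["Enc5"] == pytest.approx(1.7)


class TestAnalyticCoherence:
    def test_limits(self):
        mix = RegionMixing({"A": {"s": 1.0}, "B": {"s": 1.0}}, noise_level=1e-12)
        assert analytic_coherence(mix, {"s": 1.0}, ("A", "B"), 8.0) == \
            pytest.approx(1.0)
        # equal signal and noise densities -> 1/2
        mix2 = RegionMixing({"A": {"s": 1.0}, "B": {"s": 1.0}},
                            noise_level=np.sqrt(8.0))  # density 8/8 = 1 at 8 Hz
        assert analytic_coherence(mix2, {"s": 1.0}, ("A", "B"), 8.0) == \
            pytest.approx(0.5)

    def test_two_source_mixing_matches_monte_carlo(self):
        from thetanet.coherence import coherence, band_coherence
        src1 = ThetaSource("s1", 8.0, 5.0, 3.0)
        src2 = ThetaSource("s2", 8.0, 5.0, 2.0)
        wA = {"s1": 1.0, "s2": 0.5}
        wB = {"s1": 0.4, "s2": 1.0}
        mix = RegionMixing({"A": wA, "B": wB}, noise_level=1.0)
        dens = {s.name: effective_source_density(s, 1.0, 1.5)
                for s in (src1, src2)}
        expected = analytic_coherence(mix, dens, ("A", "B"), 8.0)
        vals = []
        tl = [Period("A", 0, 120)]
        sch = StateSchedule({"A": 1.0}, 0)
        for seed in range(10):
            s1 = render_source(src1, sch, tl, FS, 120, _child_rng(seed, "s1"))
            s2 = render_source(src2, sch, tl, FS, 120, _child_rng(seed, "s2"))
            nA = pink_noise(len(s1), FS, 1.0, 1.0, _child_rng(seed, "nA"))
            nB = pink_noise(len(s1), FS, 1.0, 1.0, _child_rng(seed, "nB"))
            xa = wA["s1"] * s1 + wA["s2"] * s2 + nA
            xb = wB["s1"] * s1 + wB["s2"] * s2 + nB
            vals.append(band_coherence(coherence(xa, xb, FS), (7, 9)))
        assert abs(np.mean(vals) - expected) < 0.05

    def test_lorentzian_total_power(self):
        src = ThetaSource("s", 8.0, 2.0, 3.0)
        f = np.linspace(0.01, 100, 200_001)
        total = np.trapezoid(lorentzian_density(f, src), f)
        # 0-100 Hz captures all but the far tails of the line
        assert total == pytest.approx(src.base_amp ** 2 / 2, rel=5e-3)


class TestSessions:
    def test_seed_determinism(self):
        cfg = SrmConfig(fs=FS, base_s=10, enc_s=10, post_s=5, n_trials=2,
                        regions=("MOB", "MeA"))
        s1, g1 = synthesize_srm_session(cfg, seed=9)
        s2, g2 = synthesize_srm_session(cfg, seed=9)
        np.testing.assert_array_equal(s1.signals, s2.signals)
        assert g1.analytic_tp_db == g2.analytic_tp_db

    def test_adding_region_preserves_other_streams(self):
        base = SrmConfig(fs=FS, base_s=10, enc_s=10, post_s=5, n_trials=1,
                         regions=("MOB", "MeA"))
        more = SrmConfig(fs=FS, base_s=10, enc_s=10, post_s=5, n_trials=1,
                         regions=("MOB", "MeA", "LS"))
        s1, _ = synthesize_srm_session(base, seed=4)
        s2, _ = synthesize_srm_session(more, seed=4)
        np.testing.assert_array_equal(s1.signals[0], s2.signals[0])
        np.testing.assert_array_equal(s1.signals[1], s2.signals[1])

    def test_fc_tone_timing(self):
        cfg = FcConfig(fs=FS, base_s=300, tone_s=40, iti_s=180, n_tones=3)
        tl = {p.name: p for p in cfg.timeline()}
        assert tl["Tone1"].start_s == 300
        assert tl["Tone2"].start_s == 520
        assert tl["Tone3"].start_s == 740
        assert tl["Stim1"].end_s - tl["Stim1"].start_s == 15.0

    def test_srm_timeline_structure(self):
        cfg = SrmConfig(fs=FS, base_s=300, enc_s=300, post_s=300, transfer_s=15)
        tl = {p.name: p for p in cfg.timeline()}
        assert tl["Base"].end_s == 300
        assert tl["Enc1"].start_s == 315
        assert tl["Post1"].start_s == 615
        assert tl["Stimulus"].start_s == 315 and tl["Stimulus"].end_s == 330

    def test_object_config_weak_and_transient(self):
        cfg = SrmConfig(stimulus="object", fs=FS, base_s=10, enc_s=10, post_s=5)
        assert cfg.limbic_gain == 0.0
        assert cfg.bulb_gain == pytest.approx(0.3)
        assert cfg.post_decay_tau_s is None

    def test_ground_truth_serializes(self, tmp_path):
        cfg = SrmConfig(fs=FS, base_s=10, enc_s=10, post_s=5, n_trials=1,
                        regions=("MOB", "MeA"))
        _, gt = synthesize_srm_session(cfg, seed=0)
        gt.to_json(tmp_path / "gt.json")
        import json
        back = json.loads((tmp_path / "gt.json").read_text())
        assert back["seed"] == 0
        assert "MOB" in back["analytic_tp_db"]


class TestRecoveryFits:
    def test_onset_and_decay_on_noiseless_series(self):
        from thetanet.synthetic_data import fit_exp_decay_tau, fit_onset_ramp
        t = np.arange(0, 300, 0.5)
        amp_ramp = 1 + 1.0 * np.minimum(t / 15.0, 1.0)
        assert abs(fit_onset_ramp(t, 20 * np.log10(amp_ramp)) - 15.0) < 0.5
        amp_decay = 1 + 0.9 * np.exp(-t / 60.0)
        assert abs(fit_exp_decay_tau(t, 20 * np.log10(amp_decay)) - 60.0) < 1.0
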