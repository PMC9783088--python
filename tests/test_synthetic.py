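"""Synthetic bench-style observation generators."""

import numpy as np
import pytest

import wicksim as ws
from wicksim import calibration, synthetic
from wicksim.trace import WickingTrace


def _true_trace(n_points=6):
    # sqrt(t) trajectory anchored at the CF4 wicking rate, sampled in
    # the pre-saturation regime
    t = np.linspace(10.0, 60.0, n_points)
    return WickingTrace(
        times=t, front=0.04 * np.sqrt(t / 67.3), source="simulated",
        strip_length=0.06,
    )


class TestWickingObservations:
    def test_quantization_without_noise(self):
        trace = WickingTrace(times=[10.0], front=[0.042], source="simulated")
        noise = synthetic.NoiseModel(front_noise_sd=0.0, quantization=0.005, seed=0)
        obs = synthetic.generate_wicking_observations(trace, noise)
        assert obs.front[0] == pytest.approx(0.040)

    def test_same_seed_reproduces_output(self):
        trace = _true_trace()
        noise = synthetic.NoiseModel(seed=42)
        a = synthetic.generate_wicking_observations(trace, noise)
        b = synthetic.generate_wicking_observations(trace, noise)
        np.testing.assert_array_equal(a.front, b.front)

    def test_different_seeds_differ(self):
        trace = _true_trace()
        a = synthetic.generate_wicking_observations(trace, synthetic.NoiseModel(seed=1))
        b = synthetic.generate_wicking_observations(trace, synthetic.NoiseModel(seed=2))
        assert not np.array_equal(a.front, b.front)

    def test_noise_sd_matches_specification(self):
        # Monte-Carlo check of the generator against its own contract:
        # pre-quantization scatter of 1e4 replicates within 3% of the
        # nominal 2 mm
        trace = WickingTrace(times=[30.0], front=[0.03], source="simulated")
        vals = []
        for seed in range(10_000):
            noise = synthetic.NoiseModel(
                front_noise_sd=0.002, quantization=0.0, seed=seed
            )
            vals.append(
                synthetic.generate_wicking_observations(trace, noise).front[0]
            )
        assert np.std(vals) == pytest.approx(0.002, rel=0.03)

    def test_clamped_to_strip(self):
        trace = WickingTrace(
            times=[10.0], front=[0.059], source="simulated", strip_length=0.06
        )
        noise = synthetic.NoiseModel(front_noise_sd=0.01, seed=3)
        for seed in range(50):
            obs = synthetic.generate_wicking_observations(
                trace, synthetic.NoiseModel(front_noise_sd=0.01, seed=seed)
            )
            assert 0.0 <= obs.front[0] <= 0.06


class TestAnalyteProfiles:
    def test_cf4_dna_plateau_and_peak(self):
        noise = synthetic.NoiseModel(concentration_cv=0.0)
        prof = synthetic.generate_analyte_profile("CF4", "DNA", "stimulated", noise)
        # 400 ng/uL over the first 2 cm, 700 ng/uL peak at the 5 cm segment
        assert prof.concentration[0] == pytest.approx(400.0)
        assert prof.concentration[1] == pytest.approx(400.0)
        assert prof.concentration[4] == pytest.approx(700.0)

    def test_mf1_dna_capped_below_400(self):
        noise = synthetic.NoiseModel(concentration_cv=0.0)
        prof = synthetic.generate_analyte_profile("MF1", "DNA", "stimulated", noise)
        assert np.all(prof.concentration[:4] <= 200.0)
        assert prof.concentration.max() < 400.0

    def test_fusion5_dna_first_two_centimetres(self):
        noise = synthetic.NoiseModel(concentration_cv=0.0)
        prof = synthetic.generate_analyte_profile("Fusion5", "DNA", "stimulated", noise)
        assert prof.concentration[0] == pytest.approx(400.0)
        assert prof.concentration[1] == pytest.approx(400.0)

    def test_segments_cover_strip_contiguously(self):
        prof = synthetic.generate_analyte_profile("CF4")
        np.testing.assert_allclose(prof.segment_edges, np.arange(7) * 0.01)

    def test_zero_cv_identical_across_seeds(self):
        a = synthetic.generate_analyte_profile(
            "CF4", noise=synthetic.NoiseModel(concentration_cv=0.0, seed=1)
        )
        b = synthetic.generate_analyte_profile(
            "CF4", noise=synthetic.NoiseModel(concentration_cv=0.0, seed=99)
        )
        np.testing.assert_array_equal(a.concentration, b.concentration)

    def test_unknown_identifiers_rejected(self):
        with pytest.raises(ws.UnknownMembraneError):
            synthetic.generate_analyte_profile("unknown")
        with pytest.raises(ValueError, match="analyte"):
            synthetic.generate_analyte_profile("CF4", analyte="lipid")
        with pytest.raises(ValueError, match="saliva"):
            synthetic.generate_analyte_profile("CF4", saliva_type="frozen")


class TestViscositySeries:
    def test_noise_free_series_is_constant_at_mean(self):
        noise = synthetic.NoiseModel(concentration_cv=0.0)
        series = synthetic.generate_viscosity_series("stimulated", noise)
        assert len(series) == 21
        np.testing.assert_allclose(series, 0.002)
        series_us = synthetic.generate_viscosity_series("unstimulated", noise)
        np.testing.assert_allclose(series_us, 0.00234)

    def test_unstimulated_mean_exceeds_stimulated(self):
        # ordering of the two saliva types holds in at least 95 of 100
        # seeds at 1% coefficient of variation
        wins = 0
        for seed in range(100):
            noise = synthetic.NoiseModel(concentration_cv=0.01, seed=seed)
            ss = synthetic.generate_viscosity_series("stimulated", noise)
            us = synthetic.generate_viscosity_series("unstimulated", noise)
            wins += us.mean() > ss.mean()
        assert wins >= 95

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_viscosity_series("lukewarm")


class TestPipelineRecovery:
    def test_sqrt_coefficient_recovered_from_noisy_traces(self):
        # full-pipeline smoke test: ruler noise of 1 mm on 6 readings
        # still recovers the generating sqrt(t) coefficient within 5%
        # (median over 200 seeds)
        true = _true_trace(6)
        c_true = 0.04 / np.sqrt(67.3)
        errors = []
        for seed in range(200):
            noise = synthetic.NoiseModel(
                front_noise_sd=0.001, quantization=0.001, seed=seed
            )
            obs = synthetic.generate_wicking_observations(true, noise)
            c_hat = calibration.fit_front_law(obs).value
            errors.append(abs(c_hat - c_true) / c_true)
        assert np.median(errors) < 0.05
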