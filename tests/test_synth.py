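"""Generator determinism, ground-truth storage and validation paths."""
import numpy as np
import pytest

from lipospin import synth
from lipospin.exceptions import ValidationError
from lipospin.types import Atmosphere


class TestDeterminism:
    def test_fast_motion_bit_identical(self):
        a = synth.gen_fast_motion_spectrum((2.0, 2.2, 2.4), noise_sigma=0.01, seed=9)
        b = synth.gen_fast_motion_spectrum((2.0, 2.2, 2.4), noise_sigma=0.01, seed=9)
        assert np.array_equal(a.intensity, b.intensity)

    def test_slow_motion_bit_identical(self):
        a = synth.gen_slow_motion_spectrum(25.0, 9.0, noise_sigma=0.01, seed=3)
        b = synth.gen_slow_motion_spectrum(25.0, 9.0, noise_sigma=0.01, seed=3)
        assert np.array_equal(a.intensity, b.intensity)

    def test_titration_bit_identical(self):
        a = synth.gen_titration(88.0, noise_sigma=0.01, seed=4)
        b = synth.gen_titration(88.0, noise_sigma=0.01, seed=4)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.intensity, rb.intensity)


class TestFastMotion:
    def test_truth_records_width_and_tau(self):
        spec = synth.gen_fast_motion_spectrum((2.0, 2.0, 2.0), seed=0)
        assert spec.truth.params["delta_h0"] == pytest.approx(2.0)
        assert spec.truth.params["tau_2B_ns"] == pytest.approx(0.0, abs=1e-12)

    def test_width_inversion_roundtrip(self):
        widths = synth.fast_motion_widths_for_taus(1.44, 2.03)
        spec = synth.gen_fast_motion_spectrum(widths)
        assert spec.truth.params["tau_2B_ns"] == pytest.approx(1.44, rel=1e-10)
        assert spec.truth.params["tau_2C_ns"] == pytest.approx(2.03, rel=1e-10)

    def test_narrow_sweep_rejected(self):
        with pytest.raises(ValidationError, match="sweep"):
            synth.gen_fast_motion_spectrum((2.0, 2.0, 2.0), splitting=60.0)


class TestPowder:
    def test_apar_below_aperp_rejected(self):
        with pytest.raises(ValidationError):
            synth.gen_slow_motion_spectrum(9.0, 25.0)

    def test_bias_measured_and_stored(self):
        spec = synth.gen_slow_motion_spectrum(26.8, 9.45)
        assert "bias_outer" in spec.truth.params
        assert abs(spec.truth.params["bias_outer"]) < 0.5
        # the pseudo-powder inner splitting underestimates 2 Aperp
        assert spec.truth.params["bias_inner"] < 0.0

    def test_observed_splitting_calibration(self):
        from lipospin import cwepr

        spec = synth.gen_slow_motion_for_observed(53.6, 17.9, noise_sigma=0.0)
        pair = cwepr.extract_outer_inner_splittings(spec)
        assert pair.two_Amax == pytest.approx(53.6, abs=0.02)
        assert pair.two_Amin == pytest.approx(17.9, abs=0.02)

    def test_frozen_shift_emulates_headgroup_polarity_change(self):
        from lipospin import cwepr

        a = synth.gen_frozen_spectrum(34.0)
        b = synth.gen_frozen_spectrum(35.25)
        delta = cwepr.extract_2Az(b) - cwepr.extract_2Az(a)
        assert delta == pytest.approx(2.5, abs=0.1)

    def test_frozen_robust_to_convolution_width(self):
        from lipospin import cwepr

        a = synth.gen_frozen_spectrum(34.0, conv_width=1.0)
        b = synth.gen_frozen_spectrum(34.0, conv_width=2.0)
        bound = abs(a.truth.params["bias_2Az"]) + abs(b.truth.params["bias_2Az"]) + 0.1
        assert abs(cwepr.extract_2Az(b) - cwepr.extract_2Az(a)) < bound


class TestSRDecay:
    def test_noise_free_matches_model(self):
        decay = synth.gen_sr_decay(5.0, amplitude=2.0, baseline=3.0)
        expected = 3.0 - 2.0 * np.exp(-decay.time / 5.0)
        np.testing.assert_allclose(decay.signal, expected, rtol=1e-12)

    def test_truncated_window_warns(self):
        with pytest.warns(UserWarning, match="5 T1"):
            synth.gen_sr_decay(5.0, t_max=5.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            synth.gen_sr_decay(5.0, n_points=32)

    def test_pair_encodes_w_truth(self):
        air, n2 = synth.gen_sr_pair(2.2, T1_n2=5.0)
        w = 1.0 / air.truth.params["T1"] - 1.0 / n2.truth.params["T1"]
        assert w == pytest.approx(2.2, rel=1e-12)
        assert air.atmosphere is Atmosphere.AIR and n2.atmosphere is Atmosphere.N2


class TestTitration:
    def test_saturation_limit(self):
        series = synth.gen_titration(
            88.0, lipid_grid_mM=[1e4, 2e4, 4e4, 8e4, 1.6e5],
            noise_sigma=0.0, scale_jitter=0.0, n_series=1,
        )
        np.testing.assert_allclose(series[0].intensity, 100.0, rtol=1e-3)

    def test_midpoint_near_kd_without_depletion(self):
        # Kd placed at the top grid point: the f-curve midpoint sits there
        from lipospin.binding import bound_fraction

        f = bound_fraction(2.0, 2.0, 2000.0)
        assert f == pytest.approx(0.5, abs=0.01)


class TestQuenchingPair:
    def test_fraction_above_one_rejected(self):
        with pytest.raises(ValidationError):
            synth.gen_quenching_pair(1.2)

    def test_noise_free_percent(self):
        from lipospin.quenching import remaining_percent

        control, sample = synth.gen_quenching_pair(0.78)
        assert remaining_percent(sample, control) == pytest.approx(78.0, abs=1e-12)

    def test_unbiased_under_noise(self):
        from lipospin.quenching import remaining_percent

        vals = []
        for seed in range(100):
            control, sample = synth.gen_quenching_pair(0.5, noise_sigma=0.01, seed=seed)
            vals.append(remaining_percent(sample, control))
        assert abs(np.mean(vals) - 50.0) < 0.5
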