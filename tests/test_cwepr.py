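"""Line-feature extraction and the CW-EPR observables.

Round-trip tests assert recovery of generator ground truth; formula-level
tests check the order-parameter and correlation-time algebra against
independent brute-force arithmetic.
"""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipospin import cwepr, synth
from lipospin.cwepr import (
    K_TAU,
    LineFeatures,
    SplittingPair,
    correlation_times,
    extract_2Az,
    extract_line_features,
    extract_outer_inner_splittings,
    invert_order_parameter,
    order_parameter,
    tpc_params,
)
from lipospin.exceptions import ExtractionError, ValidationError
from lipospin.types import DEFAULT_TENSOR, NitroxideTensor


def _features(h_plus, h_zero, h_minus, delta_h0=2.0, dh_plus=2.0):
    return LineFeatures(
        h_plus=h_plus, h_zero=h_zero, h_minus=h_minus,
        delta_h0=delta_h0, dh_plus=dh_plus, dh_minus=2.0,
        centers=(3335.0, 3350.0, 3365.0),
    )


def _order_parameter_oracle(two_Amax, two_Amin, tensor, correct=True):
    """Straight-line re-derivation of the order-parameter algebra."""
    A_par = two_Amax / 2
    A_perp = two_Amin / 2
    delta = tensor.Azz - (tensor.Axx + tensor.Ayy) / 2
    if correct:
        S_app = (A_par - A_perp) / delta
        A_perp = A_perp + 1.4 * (1 - S_app)
    a0 = (tensor.Axx + tensor.Ayy + tensor.Azz) / 3
    a0p = (A_par + 2 * A_perp) / 3
    return (A_par - A_perp) / delta * (a0 / a0p)


class TestLineFeatures:
    def test_noise_free_central_width_roundtrip(self):
        spec = synth.gen_fast_motion_spectrum((2.4, 2.0, 2.8))
        f = extract_line_features(spec)
        assert f.delta_h0 == pytest.approx(2.0, abs=spec.step)

    def test_symmetric_spectrum_has_equal_outer_amplitudes(self):
        spec = synth.gen_fast_motion_spectrum((2.0, 2.0, 2.0))
        f = extract_line_features(spec)
        assert f.h_plus == pytest.approx(f.h_minus, rel=1e-6)

    def test_low_field_width_accuracy_under_noise(self):
        # the sharp low-field line must be read to +-0.1 G at 1 % noise
        vals = [
            extract_line_features(
                synth.gen_fast_motion_spectrum((1.2, 1.8, 2.2), noise_sigma=0.01, seed=s)
            ).dh_plus
            for s in range(100)
        ]
        assert np.std(vals) <= 0.1
        assert abs(np.mean(vals) - 1.2) <= 0.1

    def test_too_few_lines_raises(self):
        spec = synth.gen_fast_motion_spectrum((2.0, 2.0, 2.0))
        spec.meta = spec.meta  # keep regime tag
        flat = spec
        flat.intensity = np.exp(-((flat.field - 3350.0) ** 2) / 8.0)  # single bump
        with pytest.raises(ExtractionError):
            extract_line_features(flat)


class TestTpcParams:
    def test_equal_amplitudes_give_unit_ratio(self):
        p = tpc_params(_features(1.0, 1.0, 1.0))
        assert p["h0_over_hminus"] == pytest.approx(1.0)

    def test_twenty_percent_narrower_line_recovered(self):
        a = extract_line_features(synth.gen_fast_motion_spectrum((1.5, 1.8, 2.0)))
        b = extract_line_features(synth.gen_fast_motion_spectrum((1.2, 1.8, 2.0)))
        assert tpc_params(b)["dh_plus"] / tpc_params(a)["dh_plus"] == pytest.approx(
            0.8, abs=0.05
        )

    def test_ratio_invariant_under_intensity_rescale(self):
        spec = synth.gen_fast_motion_spectrum((1.5, 1.8, 2.0), noise_sigma=0.01, seed=1)
        p1 = tpc_params(extract_line_features(spec))
        spec.intensity = spec.intensity * 37.5
        p2 = tpc_params(extract_line_features(spec))
        assert p2["h0_over_hminus"] == pytest.approx(p1["h0_over_hminus"], rel=1e-9)
        assert p2["dh_plus"] == pytest.approx(p1["dh_plus"], rel=1e-9)


class TestCorrelationTimes:
    def test_symmetric_amplitudes_zero_tau2b(self):
        tau = correlation_times(_features(2.0, 3.0, 2.0))
        assert tau.tau_2B_ns == 0.0

    def test_all_equal_amplitudes_zero_tau2c(self):
        tau = correlation_times(_features(3.0, 3.0, 3.0))
        assert tau.tau_2C_ns == 0.0

    def test_closed_form_hand_arithmetic(self):
        # h0/h- = 2.25, h0/h+ = 1.44 with dH0 = 2 G
        f = _features(h_plus=1.0 / 1.44, h_zero=1.0, h_minus=1.0 / 2.25)
        tau = correlation_times(f)
        assert tau.tau_2B_ns == pytest.approx(K_TAU * 2.0 * (1.5 - 1.2) * 1e9, rel=1e-12)
        assert tau.tau_2C_ns == pytest.approx(K_TAU * 2.0 * 0.7 * 1e9, rel=1e-12)

    def test_inverted_amplitude_order_flagged(self):
        tau = correlation_times(_features(3.0, 2.0, 3.0))
        assert tau.flagged and tau.tau_2C_ns < 0

    def test_recovery_within_five_percent_at_one_percent_noise(self, seeds):
        widths = synth.fast_motion_widths_for_taus(1.44, 2.03)
        for seed in seeds:
            spec = synth.gen_fast_motion_spectrum(widths, noise_sigma=0.01, seed=seed)
            tau = correlation_times(extract_line_features(spec))
            assert tau.tau_2B_ns == pytest.approx(1.44, rel=0.05)
            assert tau.tau_2C_ns == pytest.approx(2.03, rel=0.05)


class TestOrderParameter:
    def test_rigid_limit_is_one(self):
        pair = SplittingPair(
            two_Amax=2 * DEFAULT_TENSOR.Azz,
            two_Amin=DEFAULT_TENSOR.Axx + DEFAULT_TENSOR.Ayy,
        )
        res = order_parameter(pair)
        assert res.S == pytest.approx(1.0, abs=1e-12)
        assert res.polarity_factor == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_limit_is_zero_without_inner_correction(self):
        a0 = DEFAULT_TENSOR.a0
        pair = SplittingPair(two_Amax=2 * a0 + 1e-9, two_Amin=2 * a0)
        res = order_parameter(pair, inner_correction=False)
        assert res.S == pytest.approx(0.0, abs=1e-9)

    @given(
        s_app=st.floats(0.05, 0.95),
        a_par=st.floats(16.0, 33.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_agrees_with_brute_force_oracle(self, s_app, a_par):
        delta = DEFAULT_TENSOR.delta
        a_perp = a_par - s_app * delta
        if a_perp <= 0.5 or a_perp >= a_par:
            return
        pair = SplittingPair(two_Amax=2 * a_par, two_Amin=2 * a_perp)
        res = order_parameter(pair)
        oracle = _order_parameter_oracle(2 * a_par, 2 * a_perp, DEFAULT_TENSOR)
        assert res.S == pytest.approx(oracle, abs=1e-12)

    def test_inversion_closed_form_oracle(self):
        # closed form under the a0' = a0 constraint, independent of fsolve
        for s in (0.13, 0.54, 0.63, 0.69):
            t = DEFAULT_TENSOR
            A_perp_true = t.a0 - s * t.delta / 3.0
            A_par = t.a0 + 2.0 * s * t.delta / 3.0
            A_perp_obs = (A_perp_true - 1.4 + 1.4 * A_par / t.delta) / (1.0 + 1.4 / t.delta)
            pair = invert_order_parameter(s)
            assert pair.two_Amax == pytest.approx(2 * A_par, abs=1e-8)
            assert pair.two_Amin == pytest.approx(2 * A_perp_obs, abs=1e-8)
            assert order_parameter(pair).S == pytest.approx(s, abs=1e-10)

    def test_unresolved_inner_splitting_flagged_fallback(self):
        res = order_parameter(SplittingPair(two_Amax=53.6))
        assert res.flagged
        assert 0 < res.S < 1


class TestSlowMotionExtraction:
    def test_outer_splitting_roundtrip(self):
        spec = synth.gen_slow_motion_spectrum(25.0, 9.0)
        pair = extract_outer_inner_splittings(spec)
        assert pair.two_Amax == pytest.approx(50.0, abs=2 * spec.step)

    def test_degenerate_pattern_gives_near_zero_s(self):
        # convolution biases outer (+) and inner (-) splittings a little, so
        # the measured S of an isotropic pattern is small but not exactly 0
        spec = synth.gen_slow_motion_spectrum(15.0, 15.0)
        res = order_parameter(extract_outer_inner_splittings(spec))
        assert abs(res.S) < 0.06

    def test_outer_shift_bounded_by_reported_bias(self):
        a = synth.gen_slow_motion_spectrum(26.8, 9.45, conv_width=1.25)
        b = synth.gen_slow_motion_spectrum(26.8, 9.45, conv_width=2.5)
        shift = abs(
            extract_outer_inner_splittings(b).two_Amax
            - extract_outer_inner_splittings(a).two_Amax
        )
        bound = abs(a.truth.params["bias_outer"]) + abs(b.truth.params["bias_outer"]) + 0.1
        assert shift < bound

    def test_end_to_end_s_recovery_under_noise(self, seeds):
        target = invert_order_parameter(0.63)
        for seed in seeds:
            spec = synth.gen_slow_motion_for_observed(
                target.two_Amax, target.two_Amin, noise_sigma=0.01, seed=seed
            )
            res = order_parameter(extract_outer_inner_splittings(spec))
            assert res.S == pytest.approx(0.63, abs=0.01)


class TestFrozen:
    def test_roundtrip_within_grid_step(self):
        spec = synth.gen_frozen_spectrum(34.0)
        assert extract_2Az(spec) == pytest.approx(68.0, abs=2 * spec.step)

    def test_intensity_rescale_invariance(self):
        spec = synth.gen_frozen_spectrum(34.0, noise_sigma=0.01, seed=2)
        before = extract_2Az(spec)
        spec.intensity = spec.intensity * 0.037
        assert extract_2Az(spec) == pytest.approx(before, rel=1e-12)

    def test_field_translation_invariance(self):
        spec = synth.gen_frozen_spectrum(34.0, noise_sigma=0.01, seed=2)
        before = extract_2Az(spec)
        spec.field = spec.field + 250.0
        assert extract_2Az(spec) == pytest.approx(before, abs=1e-9)

    def test_recovery_within_band_under_noise(self, seeds):
        for seed in seeds:
            spec = synth.gen_frozen_for_observed(68.0, noise_sigma=0.01, seed=seed)
            assert extract_2Az(spec) == pytest.approx(68.0, abs=0.2)

    def test_regime_guard(self):
        spec = synth.gen_fast_motion_spectrum((2.0, 2.0, 2.0))
        with pytest.raises(ValidationError, match="frozen"):
            extract_2Az(spec)
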