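"""Saturation-recovery T1 fits, oxygen transport parameters and profiles."""
import numpy as np
import pytest

from lipospin import synth
from lipospin.exceptions import ValidationError
from lipospin.srepr import T1Fit, build_profile, compare_profiles, compute_otp, fit_t1
from lipospin.types import Atmosphere, MembraneComposition, SpinLabelPosition

TPC, C5, C16 = SpinLabelPosition.TPC, SpinLabelPosition.C5, SpinLabelPosition.C16


def _fit_stub(T1, se=0.01, atmosphere=Atmosphere.AIR, position=C16, comp=None):
    return T1Fit(
        T1=T1, T1_se=se, amplitude=1.0, baseline=1.0, residual_rms=0.0,
        converged=True, atmosphere=atmosphere, position=position, composition=comp,
    )


class TestFitT1:
    def test_noise_free_exact(self):
        decay = synth.gen_sr_decay(5.0, amplitude=2.0, baseline=3.0)
        fit = fit_t1(decay)
        assert fit.T1 == pytest.approx(5.0, rel=1e-3)
        assert fit.amplitude == pytest.approx(2.0, rel=1e-3)

    def test_two_percent_noise_within_three_se(self):
        decay = synth.gen_sr_decay(5.0, noise_sigma=0.02, seed=21)
        fit = fit_t1(decay)
        assert abs(fit.T1 - 5.0) <= 3.0 * fit.T1_se

    def test_truncated_decay_flagged_with_warning(self):
        with pytest.warns(UserWarning):
            decay = synth.gen_sr_decay(5.0, t_max=5.0)
        with pytest.warns(UserWarning, match="3 T1"):
            fit = fit_t1(decay)
        assert fit.converged

    def test_inverted_storage_handled(self):
        decay = synth.gen_sr_decay(5.0, amplitude=2.0, baseline=3.0)
        decay.signal = 6.0 - decay.signal  # stored upside down
        fit = fit_t1(decay)
        assert fit.T1 == pytest.approx(5.0, rel=1e-3)


class TestComputeOtp:
    def test_equal_t1_gives_zero(self):
        otp = compute_otp(_fit_stub(5.0), _fit_stub(5.0, atmosphere=Atmosphere.N2))
        assert otp.W == pytest.approx(0.0, abs=1e-15)

    def test_printed_equation_example(self):
        otp = compute_otp(_fit_stub(2.0), _fit_stub(5.0, atmosphere=Atmosphere.N2))
        assert otp.W == pytest.approx(0.3, abs=1e-12)

    def test_antisymmetric_under_atmosphere_swap(self):
        air = _fit_stub(2.0)
        n2 = _fit_stub(5.0, atmosphere=Atmosphere.N2)
        w_fwd = 1.0 / air.T1 - 1.0 / n2.T1
        # swapping roles flips the sign of the difference of rates
        w_rev = 1.0 / n2.T1 - 1.0 / air.T1
        assert w_fwd == -w_rev
        assert compute_otp(air, n2).W == pytest.approx(w_fwd)

    def test_metadata_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compute_otp(
                _fit_stub(2.0, position=C5),
                _fit_stub(5.0, atmosphere=Atmosphere.N2, position=C16),
            )

    def test_amplitude_rescaling_leaves_w_unchanged(self):
        air, n2 = synth.gen_sr_pair(2.2, noise_sigma=0.01, seed=7)
        w1 = compute_otp(fit_t1(air), fit_t1(n2)).W
        air.signal = air.signal * 12.0
        n2.signal = n2.signal * 12.0
        w2 = compute_otp(fit_t1(air), fit_t1(n2)).W
        assert w2 == pytest.approx(w1, rel=1e-6)

    def test_roundtrip_within_three_se(self):
        air, n2 = synth.gen_sr_pair(2.2, noise_sigma=0.01, seed=3)
        otp = compute_otp(fit_t1(air), fit_t1(n2))
        assert abs(otp.W - 2.2) <= 3.0 * otp.W_se


class TestProfiles:
    def test_headgroup_center_difference(self):
        profile = build_profile([(TPC, 0.5, 0.02), (C16, 2.2, 0.05)], kind="otp")
        delta, se = profile.difference(TPC, C16)
        assert delta == pytest.approx(1.7, abs=1e-12)
        assert se == pytest.approx(np.hypot(0.02, 0.05), rel=1e-12)

    def test_single_position_rejected(self):
        with pytest.raises(ValidationError):
            build_profile([(TPC, 0.5)])

    def test_input_order_irrelevant(self):
        a = build_profile([(TPC, 0.5), (C5, 0.7), (C16, 2.2)])
        b = build_profile([(C16, 2.2), (TPC, 0.5), (C5, 0.7)])
        assert a.positions == b.positions == [TPC, C5, C16]
        assert a.values == b.values

    def test_conflicting_duplicates_named(self):
        with pytest.raises(ValidationError, match="C16"):
            build_profile([(C16, 2.2), (C16, 1.0), (TPC, 0.5)])

    def test_compare_identical_profiles_zero(self):
        p = build_profile([(TPC, 0.5), (C16, 2.2)])
        deltas = compare_profiles(p, p)
        assert all(d == pytest.approx(0.0) for d, _ in deltas.values())

    def test_kind_mismatch_rejected(self):
        a = build_profile([(TPC, 0.5), (C16, 2.2)], kind="otp")
        b = build_profile([(TPC, 71.0), (C16, 68.25)], kind="polarity")
        with pytest.raises(ValidationError):
            compare_profiles(a, b)

    def test_curcumin_center_reduction_recovered(self):
        # control vs curcumin profiles differing by -1.4 1/µs at the center
        def profile(w_center, seed):
            entries = []
            for pos, w in ((TPC, 1.0), (C16, w_center)):
                air, n2 = synth.gen_sr_pair(w, noise_sigma=0.02, seed=seed + pos.depth_rank)
                fit_air = fit_t1(air)
                fit_n2 = fit_t1(n2)
                otp = compute_otp(fit_air, fit_n2)
                entries.append((pos, otp.W, otp.W_se))
            return build_profile(entries, kind="otp")

        control = profile(2.7, seed=100)
        treated = profile(1.3, seed=200)
        delta, se = compare_profiles(control, treated)[C16]
        assert delta == pytest.approx(-1.4, abs=max(3 * se, 0.05))

    def test_polarity_headgroup_shift_recovered(self):
        from lipospin.cwepr import extract_2Az

        def pol(two_az, seed):
            spec = synth.gen_frozen_for_observed(two_az, noise_sigma=0.01, seed=seed)
            return extract_2Az(spec)

        a = build_profile([(TPC, pol(71.0, 1), 0.1), (C16, pol(68.25, 2), 0.1)], kind="polarity")
        b = build_profile([(TPC, pol(73.5, 3), 0.1), (C16, pol(68.64, 4), 0.1)], kind="polarity")
        delta, _ = compare_profiles(a, b)[TPC]
        assert delta == pytest.approx(2.5, abs=0.3)

    def test_end_to_end_w_profile_recovery(self, seeds):
        truths = {TPC: 1.0, C5: 1.2, C16: 2.7}
        for seed in seeds:
            entries = []
            for pos, w in truths.items():
                air, n2 = synth.gen_sr_pair(
                    w, noise_sigma=0.02, seed=seed * 10 + pos.depth_rank, label=pos
                )
                otp = compute_otp(fit_t1(air), fit_t1(n2))
                assert abs(otp.W - w) <= 3.0 * otp.W_se
                entries.append(otp)
            profile = build_profile(entries, kind="otp")
            delta, se = profile.difference(TPC, C16)
            assert abs(delta - 1.7) <= 3.0 * se
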