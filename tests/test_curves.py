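"""Unit tests of the per-indent analysis chain (segmentation through BASh)."""

import numpy as np
import pytest

from fiberindent.curves import (
    FitError,
    IndentationCurve,
    LoadSchedule,
    SegmentationError,
    TipGeometry,
    UnreliableStiffnessError,
    compensate_machine_compliance,
    contact_area,
    contact_depth,
    correct_drift,
    creep_corrected_stiffness,
    fit_hold_creep,
    fit_unloading,
    indentation_modulus,
    process_curve,
    segment_schedule,
    unloading_stiffness,
)
from fiberindent.simulate import (
    DEFAULT_HEMISPHERE,
    CurveGeneratorConfig,
    simulate_curve,
)


def synthetic_unload_curve(zfun, F_max=4.0, n=200, schedule=None):
    """Minimal curve whose unload segment follows depth = zfun(force)."""
    schedule = schedule or LoadSchedule(peak_uN=F_max)
    F = np.linspace(F_max, schedule.stop_fraction * F_max, n)
    t = np.linspace(0.0, schedule.unload_s, n)
    return IndentationCurve(
        time_s=t,
        force_uN=F,
        depth_nm=zfun(F),
        segments=np.full(n, "unload", dtype="<U8"),
        schedule=schedule,
        F_max_uN=F_max,
        tau_u_s=schedule.hold_s,
    )


def synthetic_hold_curve(zfun, duration=10.0, n=400):
    t = np.linspace(0.0, duration, n)
    return IndentationCurve(
        time_s=t,
        force_uN=np.full(n, 10.0),
        depth_nm=zfun(t),
        segments=np.full(n, "hold", dtype="<U8"),
        schedule=LoadSchedule(),
        F_max_uN=10.0,
        tau_u_s=10.0,
    )


class TestSegmentation:
    def test_generator_round_trip(self):
        cfg = CurveGeneratorConfig(seed=3)
        curve, truth = simulate_curve(cfg)
        seg = segment_schedule(
            curve.time_s, curve.force_uN, curve.depth_nm, cfg.schedule
        )
        agreement = (seg.segments == truth.segments_true).mean()
        assert agreement > 0.99  # boundary samples may differ by one period

    def test_peak_force_identified_on_clean_data(self):
        cfg = CurveGeneratorConfig(schedule=LoadSchedule(peak_uN=20.0), seed=0)
        curve, _ = simulate_curve(cfg)
        seg = segment_schedule(
            curve.time_s, curve.force_uN, curve.depth_nm, cfg.schedule
        )
        assert seg.F_max_uN == pytest.approx(20.0, rel=0.01)

    def test_truncated_record_raises(self):
        cfg = CurveGeneratorConfig(seed=1)
        curve, _ = simulate_curve(cfg)
        cut = curve.time_s < curve.schedule.ramp_s + 5.0  # ends mid-hold
        with pytest.raises(SegmentationError):
            segment_schedule(
                curve.time_s[cut], curve.force_uN[cut], curve.depth_nm[cut],
                cfg.schedule,
            )


class TestDriftAndCompliance:
    def test_zero_drift_leaves_curve_unchanged(self):
        curve, _ = simulate_curve(CurveGeneratorConfig(seed=2))
        out = correct_drift(curve)
        assert np.allclose(out.depth_nm, curve.depth_nm, atol=1e-9)
        assert out.drift_rate_nm_s == pytest.approx(0.0, abs=1e-9)

    def test_injected_drift_recovered(self):
        curve, _ = simulate_curve(
            CurveGeneratorConfig(drift_rate_nm_s=0.5, seed=2)
        )
        out = correct_drift(curve)
        assert out.drift_rate_nm_s == pytest.approx(0.5, rel=0.05)

    def test_missing_drift_segment_flags_warning(self):
        curve, _ = simulate_curve(CurveGeneratorConfig(seed=2))
        keep = curve.segments != "drift"
        trimmed = IndentationCurve(
            time_s=curve.time_s[keep],
            force_uN=curve.force_uN[keep],
            depth_nm=curve.depth_nm[keep],
            segments=curve.segments[keep],
            schedule=curve.schedule,
            F_max_uN=curve.F_max_uN,
            tau_u_s=curve.tau_u_s,
        )
        out = correct_drift(trimmed)
        assert out.drift_warning
        assert np.array_equal(out.depth_nm, trimmed.depth_nm)

    def test_machine_compliance_identity_arithmetic_and_inverse(self):
        curve, _ = simulate_curve(CurveGeneratorConfig(seed=2))
        same = compensate_machine_compliance(curve, 0.0)
        assert np.array_equal(same.depth_nm, curve.depth_nm)
        shifted = compensate_machine_compliance(curve, 1.0)
        i = np.argmin(np.abs(curve.force_uN - 10.0))
        assert curve.depth_nm[i] - shifted.depth_nm[i] == pytest.approx(
            curve.force_uN[i], rel=1e-12
        )
        back = compensate_machine_compliance(shifted, -1.0)
        assert np.allclose(back.depth_nm, curve.depth_nm, atol=1e-12)


class TestUnloadingFit:
    def test_exact_sqrt_form_reproduced(self):
        curve = synthetic_unload_curve(lambda F: 1.0 + 2.0 * np.sqrt(F))
        fit = fit_unloading(curve)
        F_check = np.linspace(0.5, 4.0, 20)
        assert np.allclose(fit.depth(F_check), 1.0 + 2.0 * np.sqrt(F_check),
                           atol=1e-6)
        assert fit.compliance(4.0) == pytest.approx(0.5, rel=1e-6)

    def test_hertz_form_exponent_recovered(self):
        curve = synthetic_unload_curve(lambda F: 3.0 * F ** (2.0 / 3.0))
        fit = fit_unloading(curve)
        assert fit.D4 == pytest.approx(2.0 / 3.0, abs=1e-3)
        assert abs(fit.D2) < 1e-3

    def test_noisy_generator_curve_predicts_peak_depth(self):
        cfg = CurveGeneratorConfig(
            force_noise_sd_uN=0.2, depth_noise_sd_nm=0.1, seed=5
        )
        curve, truth = simulate_curve(cfg)
        fit = fit_unloading(curve)
        assert float(fit.depth(20.0)) == pytest.approx(
            truth.z_el_peak_nm, rel=0.02
        )

    def test_too_few_samples_raises(self):
        curve = synthetic_unload_curve(lambda F: np.sqrt(F), n=6)
        with pytest.raises((SegmentationError, FitError)):
            fit_unloading(curve)


class TestStiffness:
    def test_sqrt_curve_hand_value(self):
        curve = synthetic_unload_curve(lambda F: 1.0 + 2.0 * np.sqrt(F))
        fit = fit_unloading(curve)
        assert unloading_stiffness(fit, 4.0) == pytest.approx(2.0, rel=1e-6)

    def test_linear_fit_unit_stiffness(self):
        from fiberindent.curves import UnloadingFit

        fit = UnloadingFit(D1=0.0, D2=0.0, D3=1.0, D4=1.0, residual_norm=0.0,
                           n_points=10)
        assert unloading_stiffness(fit, 7.0) == pytest.approx(1.0)

    def test_generator_stiffness_matches_analytic_contact_stiffness(self):
        cfg = CurveGeneratorConfig(seed=4)
        curve, truth = simulate_curve(cfg)
        fit = fit_unloading(curve)
        S_u = unloading_stiffness(fit, curve.F_max_uN)
        assert S_u == pytest.approx(truth.S_peak_uN_nm, rel=0.03)


class TestCreep:
    def test_exact_power_law_recovered(self):
        curve = synthetic_hold_curve(lambda t: 5.0 + 0.3 * t**0.5)
        fit = fit_hold_creep(curve)
        assert fit.D5 == pytest.approx(5.0, abs=1e-6)
        assert fit.D6 == pytest.approx(0.3, abs=1e-6)
        assert fit.D7 == pytest.approx(0.5, abs=1e-6)

    def test_rate_hand_value(self):
        curve = synthetic_hold_curve(lambda t: 5.0 + 0.3 * t**0.5)
        fit = fit_hold_creep(curve)
        # zdot(10) = D6 D7 t^(D7-1) = 0.3*0.5*10^-0.5
        assert fit.rate(10.0) == pytest.approx(0.04743, abs=1e-5)

    def test_constant_hold_flags_no_creep(self):
        curve = synthetic_hold_curve(lambda t: np.full_like(t, 30.0))
        fit = fit_hold_creep(curve)
        assert fit.no_creep

    def test_feng_ngan_zero_creep_limit(self):
        assert creep_corrected_stiffness(2.0, 0.0, -20.0) == pytest.approx(2.0)

    def test_feng_ngan_hand_value(self):
        # 1/S = 1/2 - 0.5/(-20) = 0.525
        assert creep_corrected_stiffness(2.0, 0.5, -20.0) == pytest.approx(
            1.0 / 0.525
        )

    def test_dominant_creep_raises(self):
        with pytest.raises(UnreliableStiffnessError):
            creep_corrected_stiffness(2.0, -11.0, -20.0)


class TestContactGeometry:
    def test_contact_depth_hand_value_and_limits(self):
        assert contact_depth(100.0, 20.0, 0.5, 0.75) == pytest.approx(70.0)
        assert contact_depth(100.0, 20.0, 1e12, 0.75) == pytest.approx(100.0)
        assert contact_depth(100.0, 20.0, 0.5, 0.0) == pytest.approx(100.0)

    def test_hemisphere_full_immersion(self):
        tip = TipGeometry(shape="hemisphere", R_nm=300.0)
        assert contact_area(tip, 300.0) == pytest.approx(np.pi * 300.0**2)

    def test_zero_depth_zero_area(self):
        for shape in ("hemisphere", "pyramid", "cube_corner"):
            assert contact_area(TipGeometry(shape=shape, R_nm=100.0), 0.0) == 0.0

    def test_cube_corner_ideal_coefficient_for_sharp_tip(self):
        # a sharp cap (R -> 0) recovers the ideal projected area 2.598 z^2
        tip = TipGeometry(shape="cube_corner", R_nm=0.01)
        assert contact_area(tip, 100.0) == pytest.approx(2.598e4, rel=1e-3)

    def test_pyramid_area_is_C1_across_transition(self):
        from fiberindent.curves import _spherocone_transition

        tip = TipGeometry(shape="pyramid", R_nm=100.0)
        z_star, _ = _spherocone_transition(tip.R_nm, tip._tan_psi)
        h = 1e-6
        below = (contact_area(tip, z_star) - contact_area(tip, z_star - h)) / h
        above = (contact_area(tip, z_star + h) - contact_area(tip, z_star)) / h
        assert above == pytest.approx(below, rel=1e-4)

    def test_calibrated_polynomial_overrides(self):
        tip = TipGeometry(
            shape="pyramid", R_nm=100.0, area_coefficients=(24.5, 100.0, 0.0)
        )
        assert contact_area(tip, 10.0) == pytest.approx(24.5 * 100.0 + 1000.0)

    def test_negative_depth_raises(self):
        with pytest.raises(ValueError):
            contact_area(TipGeometry(shape="hemisphere", R_nm=300.0), -1.0)


class TestBASh:
    def test_normalization(self):
        # beta=1, A=pi nm^2, S=2 uN/nm -> M = 1000 GPa (= 1 uN/nm^2)
        assert indentation_modulus(2.0, np.pi, 1.0) == pytest.approx(1000.0)

    def test_beta_scaling(self):
        M1 = indentation_modulus(2.0, 100.0, 1.0)
        M2 = indentation_modulus(2.0, 100.0, 2.0)
        assert M2 == pytest.approx(M1 / 2.0)


class TestProcessPipeline:
    def test_invariants_on_processed_curves(self):
        rng = np.random.default_rng(11)
        for seed in rng.integers(0, 2**31 - 1, size=5):
            cfg = CurveGeneratorConfig(
                creep_D6_nm=0.5, depth_noise_sd_nm=0.2, force_noise_sd_uN=0.02,
                seed=int(seed),
            )
            curve, _ = simulate_curve(cfg)
            res = process_curve(curve, cfg.tip)
            assert res.M_GPa > 0
            assert res.z_c_nm <= res.z_max_nm
            if res.creep_rate_nm_s > 0:
                assert res.S_uN_nm <= res.S_u_uN_nm

    def test_time_shift_and_depth_offset_invariance(self):
        cfg = CurveGeneratorConfig(creep_D6_nm=0.5, seed=9)
        curve, _ = simulate_curve(cfg)
        # both records go through raw-channel segmentation so only the
        # time shift and depth offset differ between them
        ref = process_curve(
            segment_schedule(
                curve.time_s, curve.force_uN, curve.depth_nm, cfg.schedule
            ),
            cfg.tip,
        )
        res = process_curve(
            segment_schedule(
                curve.time_s + 123.0, curve.force_uN, curve.depth_nm + 40.0,
                cfg.schedule,
            ),
            cfg.tip,
        )
        assert res.M_GPa == pytest.approx(ref.M_GPa, rel=1e-6)

    def test_corrected_stiffness_closer_to_elastic_truth(self):
        """The Feng-Ngan step recovers the true elastic contact stiffness
        better than the raw unloading slope on every creeping curve."""
        rng = np.random.default_rng(21)
        for seed in rng.integers(0, 2**31 - 1, size=10):
            cfg = CurveGeneratorConfig(creep_D6_nm=0.8, creep_D7=0.4,
                                       seed=int(seed))
            curve, truth = simulate_curve(cfg)
            res = process_curve(curve, cfg.tip)
            assert abs(res.S_uN_nm - truth.S_peak_uN_nm) < abs(
                res.S_u_uN_nm - truth.S_peak_uN_nm
            )

    def test_batch_order_preserved(self):
        configs = [
            CurveGeneratorConfig(M_true_GPa=m, seed=i)
            for i, m in enumerate([3.0, 5.0, 8.0])
        ]
        results = [
            process_curve(simulate_curve(c)[0], c.tip) for c in configs
        ]
        recovered = [r.M_GPa for r in results]
        assert recovered == sorted(recovered)
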