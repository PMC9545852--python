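"""Voxelwise VFA and Look-Locker fits against closed-form and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

from vfat1.signal_models import IrAcquisition, Tissue, VfaAcquisition, ir_ll_signal
from vfat1.t1_fitting import T1Map, fit_map, molli_fit, vfa_fit_linear

from conftest import spgr_forward

IR8 = IrAcquisition(inversion_times=(100.0, 180.0, 850.0, 930.0, 1600.0,
                                     1680.0, 2350.0, 3100.0))


def nonlinear_vfa_oracle(signals, angles_deg, tr):
    """Brute-force SPGR fit: T1 grid with the amplitude solved linearly at
    each candidate, then bounded scalar refinement.  Independent of the
    package's linearized estimator."""
    signals = np.asarray(signals, dtype=float)

    def rss(t1):
        model = spgr_forward(t1, tr, 1.0, angles_deg)
        m0 = (model @ signals) / (model @ model)
        return ((signals - m0 * model) ** 2).sum()

    grid = np.logspace(np.log10(50.0), np.log10(5000.0), 400)
    best = grid[np.argmin([rss(t) for t in grid])]
    res = minimize_scalar(rss, bounds=(best / 1.3, best * 1.3), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


class TestVfaFitLinear:
    def test_two_point_liver_example(self):
        acq = VfaAcquisition(tr=3.5, flip_angles=(5.0, 15.0))
        t1, m0, err = vfa_fit_linear(np.array([48.00, 31.17]), acq)
        assert t1 == pytest.approx(752.0, abs=1.0)
        assert m0 == pytest.approx(1000.0, abs=2.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(t1=st.floats(200.0, 3000.0), m0=st.floats(10.0, 5000.0),
           k=st.floats(0.5, 1.3))
    def test_exact_recovery_with_matching_b1(self, t1, m0, k):
        acq = VfaAcquisition(tr=3.5, b1_ratio=k)
        signals = spgr_forward(t1, acq.tr, m0, acq.flip_angles, k=k)
        t1_fit, m0_fit, err = vfa_fit_linear(signals, acq)
        assert t1_fit == pytest.approx(t1, rel=1e-9)
        assert m0_fit == pytest.approx(m0, rel=1e-9)
        assert err < 1e-6 * m0

    def test_low_b1_fitted_at_nominal_angles(self, six_angle_acq):
        # k = 0.4 data fitted assuming k = 1: T1 collapses to ~0.16x truth
        signals = spgr_forward(752.0, 3.5, 1000.0, six_angle_acq.flip_angles, k=0.4)
        t1_fit, _, _ = vfa_fit_linear(signals, six_angle_acq)
        assert t1_fit == pytest.approx(0.16 * 752.0, rel=0.01)
        # on model-inconsistent data the two estimators weight residuals
        # differently, so agreement is approximate rather than exact
        oracle = nonlinear_vfa_oracle(signals, six_angle_acq.flip_angles, 3.5)
        assert t1_fit == pytest.approx(oracle, rel=5e-3)

    def test_matches_nonlinear_oracle_on_random_draws(self, six_angle_acq):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            t1 = rng.uniform(200.0, 2500.0)
            m0 = rng.uniform(100.0, 2000.0)
            signals = spgr_forward(t1, 3.5, m0, six_angle_acq.flip_angles)
            t1_lin, _, _ = vfa_fit_linear(signals, six_angle_acq)
            t1_nl = nonlinear_vfa_oracle(signals, six_angle_acq.flip_angles, 3.5)
            assert abs(t1_lin - t1_nl) / t1_nl < 1e-3

    def test_noise_robustness_median(self, six_angle_acq):
        # Gaussian noise at 1% of peak signal over 10,000 voxels
        rng = np.random.default_rng(7)
        clean = spgr_forward(752.0, 3.5, 1000.0, six_angle_acq.flip_angles)
        noisy = np.clip(clean + rng.normal(0, 0.01 * clean.max(), (10000, 6)), 0, None)
        t1s = fit_map(noisy[:, None, None, :], six_angle_acq, "vfa").t1.ravel()
        assert np.nanmedian(t1s) == pytest.approx(752.0, rel=0.02)

    def test_all_zero_signals_flagged_invalid(self, six_angle_acq):
        t1, m0, err = vfa_fit_linear(np.zeros(6), six_angle_acq)
        assert np.isnan(t1) and np.isnan(m0)

    def test_unphysical_slope_flagged_invalid(self, six_angle_acq):
        # signals proportional to sin(alpha) linearize to slope exactly 0,
        # outside the physical E1 range (0, 1)
        signals = np.sin(np.radians(np.array(six_angle_acq.flip_angles)))
        t1, m0, _ = vfa_fit_linear(signals, six_angle_acq)
        assert np.isnan(t1) and np.isnan(m0)

    def test_length_mismatch_rejected(self, six_angle_acq):
        with pytest.raises(ValueError):
            vfa_fit_linear(np.ones(4), six_angle_acq)


class TestMolliFit:
    def test_ideal_inversion_recovery(self):
        signals = np.abs(ir_ll_signal(1.0, 2.0, 600.0, np.array(IR8.inversion_times)))
        t1, t1s, a, b, err = molli_fit(signals, IR8)
        assert t1 == pytest.approx(600.0, rel=1e-6)
        assert (a, b) == (pytest.approx(1.0, rel=1e-6), pytest.approx(2.0, rel=1e-6))

    def test_look_locker_correction(self):
        # A=1, B=1.8, T1*=700 -> corrected T1 = 700*(1.8-1) = 560
        tis = np.linspace(100.0, 3200.0, 8)
        acq = IrAcquisition(inversion_times=tuple(tis))
        signals = np.abs(ir_ll_signal(1.0, 1.8, 700.0, tis))
        t1, t1s, a, b, err = molli_fit(signals, acq)
        assert t1 == pytest.approx(560.0, rel=1e-6)
        assert t1s == pytest.approx(700.0, rel=1e-6)

    def test_signed_data_polarity_noop(self):
        # all samples past the zero-crossing: magnitude handling is a no-op
        tis = tuple(np.linspace(900.0, 3200.0, 6))
        acq = IrAcquisition(inversion_times=tis)
        signals = ir_ll_signal(1.0, 2.0, 600.0, np.array(tis))
        assert np.all(signals > 0)
        res_mag = molli_fit(signals, acq, magnitude_data=True)
        res_signed = molli_fit(signals, acq, magnitude_data=False)
        assert res_mag == pytest.approx(res_signed)

    def test_noiseless_draws_unbiased(self):
        rng = np.random.default_rng(11)
        tis = np.array(IR8.inversion_times)
        errs = []
        for _ in range(1000):
            t1 = rng.uniform(300.0, 1500.0)
            boa = rng.uniform(1.8, 2.4)
            a = rng.uniform(0.5, 3.0)
            signals = np.abs(ir_ll_signal(a, boa * a, t1 / (boa - 1.0), tis))
            t1_fit = molli_fit(signals, IR8)[0]
            errs.append((t1_fit - t1) / t1)
        assert np.max(np.abs(errs)) < 1e-6

    def test_one_percent_noise_median(self):
        rng = np.random.default_rng(5)
        tis = np.array(IR8.inversion_times)
        clean = ir_ll_signal(50.0, 105.0, 752.0 / 1.1, tis)
        noisy = np.abs(clean + rng.normal(0, 0.5, (2000, tis.size)))
        t1s = fit_map(noisy[:, None, None, :], IR8, "molli").t1.ravel()
        assert np.nanmedian(t1s) == pytest.approx(752.0, rel=0.02)

    def test_nonpositive_amplitude_invalid(self):
        # pure noise around zero has no recoverable recovery curve
        signals = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        res = molli_fit(signals, IR8, magnitude_data=False)
        assert np.isnan(res[0]) or res[2] > 0


class TestFitMap:
    def test_uniform_phantom(self, six_angle_acq):
        signals = spgr_forward(752.0, 3.5, 1000.0, six_angle_acq.flip_angles)
        vols = np.broadcast_to(signals, (8, 9, 3, 6)).copy()
        result = fit_map(vols, six_angle_acq, "vfa")
        assert result.valid_mask.all()
        assert result.t1 == pytest.approx(np.full((8, 9, 3), 752.0))

    def test_two_compartment_matches_scalar_fit(self, six_angle_acq):
        liver = spgr_forward(752.0, 3.5, 1000.0, six_angle_acq.flip_angles)
        vessel = spgr_forward(1600.0, 3.5, 1400.0, six_angle_acq.flip_angles)
        vols = np.zeros((4, 4, 1, 6))
        vols[:2] = liver
        vols[2:] = vessel
        result = fit_map(vols, six_angle_acq, "vfa")
        assert result.t1[:2] == pytest.approx(752.0)
        scalar = vfa_fit_linear(vessel, six_angle_acq)[0]
        assert result.t1[2:] == pytest.approx(scalar)

    def test_empty_mask_is_all_invalid(self, six_angle_acq):
        vols = np.ones((4, 4, 2, 6))
        result = fit_map(vols, six_angle_acq, "vfa", mask=np.zeros((4, 4, 2), bool))
        assert not result.valid_mask.any()
        assert np.isnan(result.t1).all()

    def test_shape_mismatch_rejected(self, six_angle_acq):
        with pytest.raises(ValueError):
            fit_map(np.ones((4, 4, 2, 6)), six_angle_acq, "vfa",
                    mask=np.ones((4, 4, 3), bool))

    def test_t1map_invariants_enforced(self):
        with pytest.raises(ValueError):
            T1Map(t1=np.full((2, 2), -1.0), m0=np.ones((2, 2)),
                  valid_mask=np.ones((2, 2), bool), fit_error=np.zeros((2, 2)))
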