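"""Synthetic liver slab, B1+ fields, Rician noise, and study assembly."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import spearmanr

from vfat1.phantom import (ScannerProfile, SubjectProfile, add_rician_noise,
                           default_scanners, make_anatomy, make_b1_field,
                           make_subjects, simulate_session, simulate_study)
from vfat1.pipeline import fit_session
from vfat1.signal_models import Tissue, VfaAcquisition, predict_b1_bias

from conftest import spgr_forward


def noiseless(scanner: ScannerProfile, b1_center=None, b1_amp=None) -> ScannerProfile:
    center, amp, smooth = scanner.b1_field_params
    return dataclasses.replace(
        scanner, noise_sd=0.0,
        b1_field_params=(center if b1_center is None else b1_center,
                         amp if b1_amp is None else b1_amp, smooth))


class TestAnatomy:
    def test_vessel_inside_nonempty_liver(self):
        _, _, liver, vessel = make_anatomy()
        assert liver.any() and vessel.any()
        assert not (vessel & ~liver).any()

    def test_zero_vessel_radius_uniform_liver(self):
        t1, _, liver, vessel = make_anatomy(vessel_radius=0.0, liver_t1=700.0)
        assert not vessel.any()
        assert set(np.unique(t1[liver])) == {700.0}

    def test_liver_area_matches_analytic_ellipse(self):
        # rasterized pixel count within one perimeter band of pi*a*b
        _, _, liver, _ = make_anatomy(shape=(64, 64, 1), vessel_radius=0.0)
        a, b = 0.42 * 64, 0.34 * 64
        area = np.pi * a * b
        perimeter = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))
        assert abs(liver.sum() - area) < perimeter

    def test_vessel_outside_liver_rejected(self):
        with pytest.raises(ValueError):
            make_anatomy(vessel_center=(0.02, 0.02), vessel_radius=0.01)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            make_anatomy(shape=(16, 16, 1))


class TestB1Field:
    def test_zero_amplitude_uniform(self, subject):
        prof = ScannerProfile("A", "S", 3.0, tr=3.5, b1_field_params=(0.9, 0.0, 0.5))
        field = make_b1_field((32, 32, 3), prof, subject, seed=3)
        assert np.all(field == 0.9)

    def test_deterministic_per_seed(self, subject):
        prof = default_scanners()[0]
        f1 = make_b1_field((32, 32, 2), prof, subject, seed=9)
        f2 = make_b1_field((32, 32, 2), prof, subject, seed=9)
        f3 = make_b1_field((32, 32, 2), prof, subject, seed=10)
        assert np.array_equal(f1, f2)
        assert not np.array_equal(f1, f3)

    def test_range_clipped(self, subject):
        prof = ScannerProfile("A", "S", 3.0, tr=3.5, b1_field_params=(0.75, 0.35, 0.3))
        big = dataclasses.replace(subject, size_factor=1.2)
        field = make_b1_field((48, 48, 1), prof, big, seed=1)
        assert field.min() >= 0.4 and field.max() <= 1.3

    def test_30t_spread_exceeds_15t(self, subject):
        # empirical within-liver spread over 20 seeds
        _, _, liver, _ = make_anatomy(shape=(48, 48, 1))
        prof3, prof15 = default_scanners()[0], default_scanners()[3]
        spread3 = np.mean([np.ptp(make_b1_field((48, 48, 1), prof3, subject, s)[liver])
                           for s in range(20)])
        spread15 = np.mean([np.ptp(make_b1_field((48, 48, 1), prof15, subject, s)[liver])
                            for s in range(20)])
        assert spread3 > spread15


class TestRicianNoise:
    def test_zero_sd_identity(self):
        vol = np.arange(12.0).reshape(3, 4)
        assert np.array_equal(add_rician_noise(vol, 0.0, seed=1), vol)

    def test_rayleigh_mean_at_zero_signal(self):
        # |n1 + i n2| is Rayleigh with mean sigma*sqrt(pi/2)
        sigma = 2.5
        out = add_rician_noise(np.zeros(10**6), sigma, seed=4)
        assert out.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.01)

    def test_high_snr_limit(self):
        out = add_rician_noise(np.full(10**6, 100.0), 2.0, seed=4)
        assert out.mean() == pytest.approx(100.0, rel=0.005)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            add_rician_noise(np.ones(3), -0.1)


class TestSimulateSession:
    def test_noiseless_uniform_b1_recovers_truth(self, subject, ideal_scanner):
        ses = simulate_session(subject, ideal_scanner, "VFA_BH", 1, seed=0)
        _, summary = fit_session(ses)
        assert summary.median_t1 == pytest.approx(752.0, abs=1e-6)

    def test_denoised_signals_satisfy_closed_form(self, subject):
        # simulated stack at zero noise equals the SPGR model evaluated at
        # the stored ground-truth parameters, voxel by voxel
        prof = noiseless(default_scanners()[0])
        ses = simulate_session(subject, prof, "VFA_BH", 1, seed=5)
        voxels = ses.liver_mask
        for i, fa in enumerate(ses.coords):
            expected = spgr_forward(ses.true_t1[voxels], prof.tr,
                                    np.where(ses.vessel_mask[voxels], 1400.0, 1000.0),
                                    ses.true_b1[voxels] * fa)
            assert np.allclose(ses.volumes[..., i][voxels], expected)

    def test_scan_pair_shares_anatomy_not_noise(self, subject):
        prof = default_scanners()[0]
        s1 = simulate_session(subject, prof, "VFA_BH", 1, seed=6)
        s2 = simulate_session(subject, prof, "VFA_BH", 2, seed=7)
        assert np.array_equal(s1.true_t1, s2.true_t1)
        assert not np.array_equal(s1.volumes, s2.volumes)

    def test_fb_average_noise_scales_with_repeats(self, subject, ideal_scanner):
        prof = dataclasses.replace(ideal_scanner, noise_sd=1.0)
        r = 8
        ses = simulate_session(subject, prof, "VFA_FB", 1, seed=8,
                               n_repeats=r, motion_amplitude=0)
        # high-SNR: per-voxel SD of the mean ~ single-shot SD / sqrt(R)
        stack = ses.volumes[..., -1, :]  # largest flip angle = highest signal
        sd_single = stack.std(axis=-1, ddof=1)[ses.liver_mask].mean()
        avg = stack.mean(axis=-1)
        clean = simulate_session(subject, noiseless(ideal_scanner), "VFA_FB", 1,
                                 seed=8, n_repeats=1, motion_amplitude=0)
        resid = (avg - clean.volumes[..., -1, 0])[ses.liver_mask]
        assert resid.std() == pytest.approx(sd_single / np.sqrt(r), rel=0.1)

    def test_molli_requires_capable_scanner(self, subject):
        prof = ScannerProfile("G1", "G", 3.0, tr=4.0, has_molli=False)
        with pytest.raises(ValueError):
            simulate_session(subject, prof, "MOLLI", 1, seed=0)

    def test_molli_contrast_ignores_b1(self, subject):
        low = noiseless(default_scanners()[0], b1_center=0.8, b1_amp=0.0)
        uni = noiseless(default_scanners()[0], b1_center=1.0, b1_amp=0.0)
        s_low = simulate_session(subject, low, "MOLLI", 1, seed=1)
        s_uni = simulate_session(subject, uni, "MOLLI", 1, seed=1)
        assert np.array_equal(s_low.volumes, s_uni.volumes)


class TestStudy:
    def test_session_counts_full_crossing(self):
        study = simulate_study(n_subjects=8, seed=0)
        m = study.manifest()
        counts = m.groupby("method").size()
        assert counts["VFA_BH"] == 8 * 6 * 2
        assert counts["VFA_FB"] == 8 * 6 * 2
        assert counts["MOLLI"] == 8 * 3 * 2
        assert not m.duplicated(["subject_id", "scanner_id", "method", "scan_index"]).any()

    def test_dropout_limits_last_subject(self):
        study = simulate_study(n_subjects=8, seed=0, dropout=True)
        m = study.manifest()
        last = m[m["subject_id"] == "sub08"]
        assert last["scanner_id"].nunique() == 3

    def test_manifest_deterministic(self, tmp_path):
        m1 = simulate_study(n_subjects=3, seed=42).manifest()
        m2 = simulate_study(n_subjects=3, seed=42).manifest()
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        m1.to_csv(p1, index=False)
        m2.to_csv(p2, index=False)
        assert p1.read_bytes() == p2.read_bytes()

    def test_subject_t1_ordering_and_spread(self):
        subjects = make_subjects(50, seed=3, between_subject_cv=0.075)
        t30 = np.array([s.liver_t1_30t for s in subjects])
        assert all(s.liver_t1_30t > s.liver_t1_15t for s in subjects)
        assert t30.std() / t30.mean() == pytest.approx(0.075, abs=0.03)

    def test_scanner_bias_recoverable_from_pipeline(self, subject):
        # noiseless uniform-field study: per-scanner pipeline bias ranks
        # exactly as the analytic single-voxel prediction
        tissue = Tissue(t1=752.0, m0=1000.0)
        measured, predicted = [], []
        for i, prof in enumerate(default_scanners()):
            k = 0.8 + 0.09 * i
            prof = noiseless(dataclasses.replace(prof, field_strength=3.0),
                             b1_center=k, b1_amp=0.0)
            ses = simulate_session(subject, prof, "VFA_BH", 1, seed=i)
            # threshold scaled with the scanner's bias so the vessel (2x
            # liver T1) stays excluded while the biased liver stays in
            _, summary = fit_session(ses, vessel_threshold=1.5 * 752.0 * k**2)
            measured.append(100.0 * (summary.median_t1 - 752.0) / 752.0)
            predicted.append(predict_b1_bias(k, tissue, prof.vfa_acquisition))
        rho = spearmanr(measured, predicted).statistic
        assert rho == pytest.approx(1.0)
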