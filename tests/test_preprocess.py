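"""Preprocessing chain: blood nulling, rigid registration, frame rejection,
beat-to-beat b correction and the linear least-squares tensor fit."""

import numpy as np
import pytest

from dtcmr import (
    bmatrix_row,
    build_tensor_field,
    correct_b_values,
    fit_tensor_lls,
    inject_artifacts,
    null_blood_pixels,
    register_frames,
    reject_frames,
    restore_blood_pixels,
    simulate_dwis,
)
from dtcmr.containers import AcquisitionProtocol, LVPhantomSpec, M2SE


def test_bmatrix_row_trace_equals_b(rng):
    g = rng.normal(size=3)
    g /= np.linalg.norm(g)
    row = bmatrix_row(375.0, g)
    assert row[:3].sum() == pytest.approx(375.0)
    # expansion consistent with the full quadratic form
    D = rng.normal(size=(3, 3))
    D = D + D.T
    duniq = np.array([D[0, 0], D[1, 1], D[2, 2], D[0, 1], D[0, 2], D[1, 2]])
    assert row @ duniq == pytest.approx(375.0 * g @ D @ g)


class TestBloodNulling:
    def test_no_hot_pixels_is_identity(self, truth, clean_series):
        sub = clean_series.copy()
        sub.frames = sub.frames.copy()
        sub.frames[:, truth.blood_pool] = 0.0  # remove the blood signal
        out, ledger = null_blood_pixels(sub, threshold_factor=2.0)
        assert ledger == []
        assert np.array_equal(out.frames, sub.frames)

    def test_nulled_set_equals_blood_mask(self, truth, clean_series):
        out, ledger = null_blood_pixels(clean_series, threshold_factor=2.0)
        nulled = np.zeros(clean_series.shape, dtype=bool)
        for (_, r, c, _) in ledger:
            nulled[r, c] = True
        assert np.array_equal(nulled, truth.blood_pool)
        assert np.all(out.frames[:, truth.blood_pool] == 0.0)

    def test_null_register_restore_roundtrip(self, clean_series):
        nulled, ledger = null_blood_pixels(clean_series)
        registered, shifts = register_frames(nulled)
        assert np.allclose(shifts, 0.0)
        restored = restore_blood_pixels(registered, ledger, shifts)
        np.testing.assert_array_equal(restored.frames, clean_series.frames)

    def test_blood_intensity_conserved_through_registration(self, truth,
                                                            clean_series):
        shifted = inject_artifacts(clean_series, 6, (4.0, -3.0), seed=2)
        nulled, ledger = null_blood_pixels(shifted)
        registered, shifts = register_frames(nulled, subpixel=False)
        restored = restore_blood_pixels(registered, ledger, shifts)
        total_before = sum(v for (_, _, _, v) in ledger)
        # all blood intensity is back somewhere in the restored frames
        assert restored.frames.sum() == pytest.approx(
            nulled.frames.sum() + total_before)

    def test_empty_mask_rejected(self, clean_series):
        bad = clean_series.copy()
        bad.myocardium = np.zeros_like(bad.myocardium)
        with pytest.raises(ValueError):
            null_blood_pixels(bad)


class TestRegistration:
    def test_identical_frames_need_no_shift(self, clean_series):
        _, shifts = register_frames(clean_series)
        assert np.allclose(shifts, 0.0)

    @pytest.mark.parametrize("shift", [(3.0, -2.0), (5.0, 4.0)])
    def test_integer_shifts_recovered_exactly(self, clean_series, shift):
        corrupted = inject_artifacts(clean_series, 4, shift, seed=3)
        registered, shifts = register_frames(corrupted, subpixel=False)
        for (i, dx, dy) in corrupted.provenance["artifacts"]:
            assert shifts[i, 0] == pytest.approx(-dx)
            assert shifts[i, 1] == pytest.approx(-dy)
            np.testing.assert_allclose(registered.frames[i],
                                       clean_series.frames[i], atol=1e-12)

    def test_subpixel_shift_recovered_within_half_pixel(self, clean_series):
        corrupted = inject_artifacts(clean_series, 3, (0.5, 0.5), seed=4)
        _, shifts = register_frames(corrupted, subpixel=True)
        for (i, dx, dy) in corrupted.provenance["artifacts"]:
            assert abs(shifts[i, 0] + dx) <= 0.5
            assert abs(shifts[i, 1] + dy) <= 0.5

    def test_all_zero_frame_errors(self, clean_series):
        bad = clean_series.copy()
        bad.frames[0] = 0.0
        with pytest.raises(ValueError):
            register_frames(bad)


class TestRejection:
    def test_clean_series_keeps_everything(self, clean_series):
        out, rejected = reject_frames(clean_series, min_correlation=0.8)
        assert rejected == []
        assert out.n_frames == clean_series.n_frames

    def test_noise_frames_rejected_exactly(self, truth):
        spec = truth.spec.replace(noise_sigma=0.02)
        t = build_tensor_field(spec)
        series = simulate_dwis(t, AcquisitionProtocol.steam(), seed=9)
        corrupted = inject_artifacts(series, 4, (0, 0), seed=10,
                                     replace_with_noise=True)
        injected = {i for (i, _, _) in corrupted.provenance["artifacts"]}
        _, rejected = reject_frames(corrupted, min_correlation=0.8)
        assert set(rejected) == injected

    def test_impossible_threshold_surfaces_rank_deficiency(self, truth):
        spec = truth.spec.replace(noise_sigma=0.05)
        t = build_tensor_field(spec)
        series = simulate_dwis(t, AcquisitionProtocol.steam(), seed=9)
        with pytest.raises(ValueError, match="rank-deficient"):
            reject_frames(series, min_correlation=1.0)


class TestBCorrection:
    def test_nominal_rr_is_identity(self, clean_series):
        out = correct_b_values(clean_series, nominal_rr_ms=1000.0,
                               delta_ms=2.4)
        np.testing.assert_allclose(out.bvals, clean_series.bvals)

    def test_hand_computed_scaling(self, clean_series):
        series = clean_series.copy()
        series.rr_ms = np.full(series.n_frames, 1100.0)
        series.bvals = np.full(series.n_frames, 450.0)
        out = correct_b_values(series, nominal_rr_ms=1000.0, delta_ms=2.4)
        expected = 450.0 * (1100.0 - 0.8) / (1000.0 - 0.8)
        np.testing.assert_allclose(out.bvals, expected)
        assert expected == pytest.approx(495.0, abs=0.1)

    def test_m2se_passes_through(self, truth, m2se_quiet):
        series = simulate_dwis(truth, m2se_quiet, seed=1)
        series.rr_ms = series.rr_ms + 100.0
        out = correct_b_values(series, nominal_rr_ms=1000.0)
        np.testing.assert_array_equal(out.bvals, series.bvals)

    def test_rr_below_delta_third_rejected(self, clean_series):
        series = clean_series.copy()
        series.rr_ms[0] = 0.5
        with pytest.raises(ValueError):
            correct_b_values(series, nominal_rr_ms=1000.0, delta_ms=2.4)


class TestTensorFit:
    def test_noiseless_isotropic_recovery(self, steam_quiet):
        d = 1.2e-3
        spec = LVPhantomSpec(eigenvalues=(d, d, d))
        truth = build_tensor_field(spec)
        series = simulate_dwis(truth, steam_quiet, seed=0)
        fitted = fit_tensor_lls(series)
        D = fitted.tensors[truth.myocardium]
        md = np.trace(D, axis1=1, axis2=2) / 3.0
        np.testing.assert_allclose(md, d, rtol=1e-12)
        off = D - md[:, None, None] * np.eye(3)
        assert np.abs(off).max() < 1e-15

    def test_noiseless_anisotropic_recovery(self, truth, clean_series):
        fitted = fit_tensor_lls(clean_series)
        m = truth.myocardium
        err = np.abs(fitted.tensors[m] - truth.tensors.tensors[m])
        assert err.max() <= 1e-9

    def test_global_intensity_scale_invariance(self, truth, clean_series):
        scaled = clean_series.copy()
        scaled.frames = scaled.frames * 7.3
        a = fit_tensor_lls(clean_series)
        b = fit_tensor_lls(scaled)
        m = truth.myocardium
        np.testing.assert_allclose(a.tensors[m], b.tensors[m], atol=1e-14)
        np.testing.assert_allclose(b.log_s0[m] - a.log_s0[m], np.log(7.3))

    def test_duplicated_frame_equals_double_weight(self, clean_series, truth):
        """Including a frame twice must act exactly like weighting its row by
        two in the normal equations (each image enters separately)."""
        dup = clean_series.subset(np.r_[np.arange(clean_series.n_frames), 0])
        fitted = fit_tensor_lls(dup)

        # weighted-normal-equation oracle
        from dtcmr.preprocess import bmatrix_row as bm
        n = clean_series.n_frames
        X = np.hstack([np.ones((n, 1)),
                       -np.array([bm(clean_series.bvals[i],
                                     clean_series.bvecs[i])
                                  for i in range(n)])])
        w = np.ones(n)
        w[0] = 2.0
        m = truth.myocardium
        Y = np.log(clean_series.frames[:, m])
        beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w[:, None] * Y))
        got = fitted.tensors[m][:, [0, 1, 2, 0, 0, 1], [0, 1, 2, 1, 2, 2]]
        np.testing.assert_allclose(got, beta[1:].T, atol=1e-12)

    def test_nonpositive_signal_flags_pixel(self, clean_series, truth):
        bad = clean_series.copy()
        rows, cols = np.nonzero(truth.myocardium)
        bad.frames[0, rows[0], cols[0]] = 0.0
        fitted = fit_tensor_lls(bad)
        assert not fitted.valid[rows[0], cols[0]]
        assert np.isnan(fitted.tensors[rows[0], cols[0]]).all()

    def test_rank_deficient_design_rejected(self, clean_series):
        # only one direction retained -> coplanar design
        one_dir = [i for i in range(clean_series.n_frames)
                   if np.allclose(clean_series.bvecs[i], clean_series.bvecs[0])]
        sub = clean_series.subset(np.array(one_dir))
        with pytest.raises(ValueError, match="rank"):
            fit_tensor_lls(sub)


def test_b_correction_strictly_improves_jittered_recovery(truth):
    """With RR jitter and no noise, fitting with the per-beat corrected b
    recovers the truth exactly while the nominal b does not."""
    protocol = AcquisitionProtocol.steam(rr_jitter_ms=30.0)
    series = simulate_dwis(truth, protocol, seed=21)
    corrected = correct_b_values(series, protocol.rr_nominal_ms,
                                 protocol.delta_ms)
    m = truth.myocardium
    err_nom = np.abs(fit_tensor_lls(series).tensors[m]
                     - truth.tensors.tensors[m]).max()
    err_cor = np.abs(fit_tensor_lls(corrected).tensors[m]
                     - truth.tensors.tensors[m]).max()
    assert err_cor < 1e-12
    assert err_nom > 1e-7
    assert err_cor < err_nom
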