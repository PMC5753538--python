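"""Strain computation and the group-statistics layer."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dtcmr import (
    LVPhantomSpec,
    build_tensor_field,
    compare_phases,
    compare_sequences,
    correlate_score_rr,
    correlate_with_strain,
    simulate_displacements,
    strain_from_displacements,
)
from dtcmr.containers import DisplacementSeries


@pytest.fixture(scope="module")
def ring():
    spec = LVPhantomSpec(r_endo_mm=14.0, r_epi_mm=24.0)
    return spec, build_tensor_field(spec)


class TestStrainFromDisplacements:
    def test_zero_displacement_zero_strain(self, ring):
        spec, truth = ring
        disp = DisplacementSeries(
            disp=np.zeros((4, spec.grid_size, spec.grid_size, 2)),
            dt_ms=30.0, pixel_spacing_mm=spec.pixel_spacing_mm)
        curve = strain_from_displacements(disp, truth.coords)
        assert np.allclose(curve.radial, 0.0)
        assert np.allclose(curve.circumferential, 0.0)

    def test_rigid_translation_is_strain_free(self, ring):
        spec, truth = ring
        d = np.zeros((3, spec.grid_size, spec.grid_size, 2))
        d[1, ..., 0] = 2.5    # uniform x translation
        d[2, ..., 1] = -1.0
        disp = DisplacementSeries(disp=d, dt_ms=30.0,
                                  pixel_spacing_mm=spec.pixel_spacing_mm)
        curve = strain_from_displacements(disp, truth.coords)
        assert np.abs(curve.radial).max() < 1e-12
        assert np.abs(curve.circumferential).max() < 1e-12

    def test_peaks_recovered_within_2_percent(self, ring):
        spec, truth = ring
        disp = simulate_displacements(spec, 0.50, -0.177)
        curve = strain_from_displacements(disp, truth.coords)
        assert curve.peak_radial == pytest.approx(0.50, rel=0.02)
        assert curve.peak_circumferential == pytest.approx(-0.177, rel=0.02)
        # peak at mid-series, endpoints at rest
        assert curve.radial[0] == pytest.approx(0.0, abs=1e-12)
        k = np.argmax(curve.radial)
        assert k == disp.n_frames // 2

    def test_error_shrinks_with_resolution(self):
        errs = []
        for n, h in ((64, 1.5), (128, 0.75)):
            spec = LVPhantomSpec(grid_size=n, pixel_spacing_mm=h,
                                 centre=((n - 1) / 2, (n - 1) / 2),
                                 r_endo_mm=14.0, r_epi_mm=24.0)
            truth = build_tensor_field(spec)
            disp = simulate_displacements(spec, 0.50, -0.177)
            curve = strain_from_displacements(disp, truth.coords)
            errs.append(abs(curve.peak_radial - 0.50))
        assert errs[1] < errs[0]


def _exact_wilcoxon_p(diff):
    """Brute-force two-sided signed-rank p by enumerating all 2^n sign
    patterns of the ranked absolute differences."""
    d = np.asarray(diff, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = [np.array(signs) @ ranks
             for signs in itertools.product((0.0, 1.0), repeat=n)]
    w_all = np.array(w_all)
    mean_w = ranks.sum() / 2.0
    p = np.mean(np.abs(w_all - mean_w) >= abs(w_obs - mean_w) - 1e-12)
    return p


def _summary_table(values_by_cell):
    rows = []
    for (subj, seq, phase), v in values_by_cell.items():
        rows.append({"subject": subj, "sequence": seq, "phase": phase,
                     "metric": v})
    return pd.DataFrame(rows)


class TestWilcoxon:
    def test_identical_samples_yield_p_one(self):
        cells = {}
        for s in range(8):
            cells[(s, "STEAM", "systole")] = 1.0 + s
            cells[(s, "M2SE", "systole")] = 1.0 + s
        res = compare_sequences(_summary_table(cells), "metric", "systole")
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_exact_enumeration(self, rng):
        """The signed-rank p-value equals the brute-force enumeration over
        all sign patterns for small n (here n = 8, all differences of one
        sign and a mixed case)."""
        for diffs in (np.abs(rng.normal(size=8)) + 0.1,
                      rng.normal(size=8) + 0.3):
            base = rng.normal(size=8)
            cells = {}
            for s in range(8):
                cells[(s, "STEAM", "systole")] = base[s] + diffs[s]
                cells[(s, "M2SE", "systole")] = base[s]
            res = compare_sequences(_summary_table(cells), "metric", "systole")
            assert res.p_value == pytest.approx(_exact_wilcoxon_p(diffs),
                                                abs=1e-12)

    def test_sequence_swap_symmetry(self, rng):
        cells = {}
        for s in range(10):
            cells[(s, "STEAM", "systole")] = rng.normal()
            cells[(s, "M2SE", "systole")] = rng.normal()
        t = _summary_table(cells)
        a = compare_sequences(t, "metric", "systole",
                              sequences=("STEAM", "M2SE"))
        b = compare_sequences(t, "metric", "systole",
                              sequences=("M2SE", "STEAM"))
        assert a.p_value == pytest.approx(b.p_value)

    def test_row_order_invariance(self, rng):
        cells = {}
        for s in range(9):
            cells[(s, "STEAM", "systole")] = rng.normal()
            cells[(s, "M2SE", "systole")] = rng.normal()
        t = _summary_table(cells)
        shuffled = t.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert (compare_sequences(t, "metric", "systole").p_value
                == compare_sequences(shuffled, "metric", "systole").p_value)

    def test_too_few_pairs_rejected(self):
        cells = {(0, "STEAM", "systole"): 1.0, (0, "M2SE", "systole"): 2.0}
        with pytest.raises(ValueError):
            compare_sequences(_summary_table(cells), "metric", "systole")


class TestFriedman:
    def test_identical_phases_not_significant(self):
        cells = {}
        for s in range(10):
            for ph in ("systole", "sweet_spot", "diastole"):
                cells[(s, "STEAM", ph)] = float(s)
        res = compare_phases(_summary_table(cells), "metric", "STEAM")
        assert res[0].p_value > 0.9
        assert len(res) == 1    # no post-hoc tests without significance

    def test_shifted_phase_detected_with_bonferroni(self, rng):
        cells = {}
        for s in range(10):
            base = rng.normal()
            cells[(s, "STEAM", "systole")] = base + rng.normal(0, 0.01)
            cells[(s, "STEAM", "sweet_spot")] = base + rng.normal(0, 0.01)
            cells[(s, "STEAM", "diastole")] = base + 50.0
        res = compare_phases(_summary_table(cells), "metric", "STEAM")
        fried = res[0]
        assert fried.significant
        pairwise = res[1:]
        assert len(pairwise) == 3
        assert all(r.alpha == pytest.approx(0.05 / 3) for r in pairwise)
        hits = {r.test: r.significant for r in pairwise}
        assert sum(hits.values()) == 2
        for name, sig in hits.items():
            assert sig == ("diastole" in name)

    def test_bonferroni_threshold_value(self, rng):
        cells = {}
        for s in range(10):
            cells[(s, "STEAM", "systole")] = float(s)
            cells[(s, "STEAM", "sweet_spot")] = float(s) + 10
            cells[(s, "STEAM", "diastole")] = float(s) + 20
        res = compare_phases(_summary_table(cells), "metric", "STEAM")
        assert res[1].alpha == pytest.approx(0.0167, abs=5e-4)


class TestCorrelations:
    def test_perfect_linear_relation(self):
        x = np.linspace(0.3, 0.7, 10)
        res = correlate_with_strain(2.0 * x + 1.0, x)
        assert res.coefficient == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_slope_recovery_within_ci_over_seeds(self):
        """Synthetic cohorts with E2A mobility = a + b * peak radial strain +
        noise: the 95% CI of the fitted slope covers the true slope in the
        vast majority of 100 seeded replicates."""
        true_a, true_b = 5.0, 80.0
        covered = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            strain_peaks = r.normal(0.5, 0.05, size=15)
            mobility = true_a + true_b * strain_peaks + r.normal(0, 3.0, 15)
            res = correlate_with_strain(mobility, strain_peaks)
            se = res.extra["band_s"] / np.sqrt(res.extra["band_sxx"])
            t = res.extra["band_tcrit"]
            if abs(res.slope - true_b) <= t * se:
                covered += 1
        assert covered >= 85

    def test_permutation_destroys_significance(self, rng):
        strain_peaks = rng.normal(0.5, 0.05, size=15)
        mobility = 80.0 * strain_peaks + rng.normal(0, 2.0, 15)
        assert correlate_with_strain(mobility, strain_peaks).p_value < 0.01
        pvals = []
        for _ in range(1000):
            perm = rng.permutation(mobility)
            pvals.append(correlate_with_strain(perm, strain_peaks).p_value)
        assert np.mean(np.array(pvals) < 0.05) < 0.12  # ~alpha, not enriched

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_with_strain(np.ones(6), np.linspace(0, 1, 6))


class TestSpearman:
    def test_monotone_extremes(self):
        rr = np.array([800.0, 900, 950, 1000, 1100, 1200])
        up = np.array([0, 0.5, 1, 1.5, 2, 3], dtype=float)  # tie-free ranks
        assert correlate_score_rr(up, rr).coefficient == pytest.approx(1.0)
        assert correlate_score_rr(up[::-1], rr).coefficient == pytest.approx(-1.0)

    def test_midrank_tie_handling_matches_hand_ranking(self):
        scores = np.array([1.0, 1.0, 2.0, 3.0, 3.0])
        rr = np.array([900.0, 950.0, 1000.0, 1050.0, 1100.0])

        def midranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        rs, rt = midranks(scores), midranks(rr)
        expected = np.corrcoef(rs, rt)[0, 1]
        assert correlate_score_rr(scores, rr).coefficient == pytest.approx(
            expected)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            correlate_score_rr(np.full(6, 2.0), np.linspace(800, 1200, 6))
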