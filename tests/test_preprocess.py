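"""Preprocessing chain: smoothing, baseline, alignment, peak integration."""

import numpy as np
import pandas as pd
import pytest

from breathdiscrim import preprocess as pp
from breathdiscrim.datatypes import Breathogram
from breathdiscrim.synthetic import (CohortDesign, PeakModel,
                                     generate_chromatograms,
                                     generate_feature_matrix)


def flat_trace(n=500, value=0.0, sample_id="s"):
    rt = np.linspace(0, 100, n)
    return Breathogram(sample_id, rt, np.full(n, value))


class TestSmooth:
    def test_polynomial_reproduced(self):
        rt = np.linspace(0, 10, 301)
        y = 2.0 - 0.5 * rt + 0.1 * rt**2
        out = pp.smooth(Breathogram("s", rt, y), window=21, polyorder=3)
        np.testing.assert_allclose(out.intensity, y, atol=1e-8)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        b = flat_trace(2000)
        noisy = b.copy_with(b.intensity + rng.normal(0, 1.0, 2000))
        out = pp.smooth(noisy, window=15, polyorder=2)
        assert out.intensity.std() < noisy.intensity.std()

    def test_window_one_is_identity(self):
        rng = np.random.default_rng(1)
        b = flat_trace(100).copy_with(rng.random(100))
        out = pp.smooth(b, window=1, polyorder=0)
        np.testing.assert_array_equal(out.intensity, b.intensity)

    def test_bad_windows_rejected(self):
        b = flat_trace(50)
        with pytest.raises(ValueError, match="odd"):
            pp.smooth(b, window=4)
        with pytest.raises(ValueError, match="larger than the trace"):
            pp.smooth(b, window=51)


class TestBaseline:
    def test_pure_ramp_removed(self):
        rt = np.linspace(0, 100, 1000)
        ramp = 5.0 * rt / 100
        out = pp.correct_baseline(Breathogram("s", rt, ramp), asymmetry=0.5)
        assert np.max(np.abs(out.intensity)) < 0.05 * 5.0

    def test_peak_area_preserved_on_ramp(self):
        rt = np.linspace(0, 100, 2000)
        peak = 10.0 / (1.5 * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((rt - 50) / 1.5) ** 2)
        ramp = 3.0 * rt / 100
        out = pp.correct_baseline(Breathogram("s", rt, ramp + peak))
        win = (rt > 40) & (rt < 60)
        area = np.trapezoid(out.intensity[win] - out.intensity[win].min(), rt[win])
        assert area == pytest.approx(10.0, rel=0.05)

    def test_baseline_free_trace_unchanged(self):
        rt = np.linspace(0, 100, 1500)
        peaks = sum(3.0 / (1.0 * np.sqrt(2 * np.pi)) *
                    np.exp(-0.5 * ((rt - c) / 1.0) ** 2) for c in (25, 50, 75))
        out = pp.correct_baseline(Breathogram("s", rt, peaks))
        assert np.trapezoid(out.intensity, rt) == pytest.approx(
            np.trapezoid(peaks, rt), rel=0.01)

    def test_nonconvergence_flagged(self):
        rt = np.linspace(0, 100, 800)
        rng = np.random.default_rng(2)
        y = np.abs(rng.normal(0, 1, 800)) + rt / 10
        out = pp.correct_baseline(Breathogram("s", rt, y), max_iter=1)
        assert out.meta["baseline_converged"] is False

    def test_bad_parameters_rejected(self):
        b = flat_trace()
        with pytest.raises(ValueError):
            pp.correct_baseline(b, asymmetry=1.5)
        with pytest.raises(ValueError):
            pp.correct_baseline(b, stiffness=-1)


class TestAlign:
    def make_peaky(self, shift_points=0, n=2000, sample_id="s"):
        rt = np.linspace(0, 200, n)
        dx = rt[1] - rt[0]
        y = sum(np.exp(-0.5 * ((rt - c - shift_points * dx) / 2.0) ** 2)
                for c in (40, 90, 150))
        return Breathogram(sample_id, rt, y)

    def test_already_aligned_gives_zero_shifts(self):
        samples = [self.make_peaky(sample_id=f"s{i}") for i in range(3)]
        _, qc = pp.align(samples, segment_len=400, max_shift=10)
        assert (qc["max_abs_shift"] == 0).all()

    def test_constructed_shift_recovered(self):
        k = 6
        ref = self.make_peaky(0, sample_id="ref")
        shifted = self.make_peaky(k, sample_id="shifted")
        aligned, qc = pp.align([ref, shifted], reference=ref,
                               segment_len=500, max_shift=10)
        shifts = qc.set_index("sample_id").filter(like="seg").loc["shifted"]
        # segments containing a peak recover the -k correction
        assert (shifts == -k).any()
        assert np.abs(shifts).max() <= k
        np.testing.assert_allclose(aligned[1].intensity[50:-50],
                                   ref.intensity[50:-50], atol=0.02)

    def test_shift_beyond_bound_saturates_in_qc(self):
        ref = self.make_peaky(0, sample_id="ref")
        far = self.make_peaky(15, sample_id="far")
        _, qc = pp.align([ref, far], reference=ref, segment_len=500, max_shift=5)
        assert qc.set_index("sample_id").loc["far", "max_abs_shift"] <= 5

    def test_total_signal_nearly_preserved(self):
        ref = self.make_peaky(0, sample_id="ref")
        shifted = self.make_peaky(4, sample_id="s")
        aligned, _ = pp.align([ref, shifted], reference=ref,
                              segment_len=500, max_shift=10)
        before = np.trapezoid(shifted.intensity, shifted.rt)
        after = np.trapezoid(aligned[1].intensity, aligned[1].rt)
        assert after == pytest.approx(before, rel=0.02)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pp.align([], segment_len=100, max_shift=5)


class TestDetectIntegrate:
    def synthetic_cohort(self, n_compounds=8, seed=0, **pm_kwargs):
        design = CohortDesign(n_per_class={"CIR": 3, "CLD": 3},
                              n_compounds=n_compounds, effect_sizes={}, seed=seed)
        cohort = generate_feature_matrix(design)
        pm = PeakModel(rt_max=900.0, n_points=9000, **pm_kwargs)
        return cohort, generate_chromatograms(cohort, pm)

    def test_noiseless_registry_matches_simulated_compounds(self):
        cohort, chroms = self.synthetic_cohort()
        table, fm = pp.detect_and_integrate(chroms, min_prominence=0.01,
                                            match_tol=10.0)
        assert len(table.registry) == cohort.features.n_compounds
        assert fm.shape == (6, 8)

    def test_prominence_above_maximum_gives_no_peaks(self):
        _, chroms = self.synthetic_cohort()
        with pytest.warns(UserWarning, match="no peaks"):
            _, fm = pp.detect_and_integrate(chroms, min_prominence=1e9,
                                            match_tol=10.0)
        assert fm.shape[1] == 0

    def test_identical_traces_give_identical_rows(self):
        _, chroms = self.synthetic_cohort()
        twin = [chroms[0], chroms[0].copy_with(chroms[0].intensity)]
        twin[1].sample_id = "twin"
        _, fm = pp.detect_and_integrate(twin, min_prominence=0.01, match_tol=10.0)
        np.testing.assert_allclose(fm.iloc[0], fm.iloc[1], rtol=1e-12)

    def test_areas_nonnegative_and_match_truth_noiselessly(self):
        cohort, chroms = self.synthetic_cohort()
        _, fm = pp.detect_and_integrate(chroms, min_prominence=0.01, match_tol=10.0)
        assert (fm.to_numpy() >= 0).all()
        truth = cohort.features.X.to_numpy()
        got = fm.to_numpy()
        np.testing.assert_allclose(np.sort(got, axis=1), np.sort(truth, axis=1),
                                   rtol=0.02)


class TestFullChain:
    def test_roundtrip_correlation_with_truth(self):
        # moderate noise/drift/jitter: preprocessed areas track planted values
        design = CohortDesign(n_per_class={"CIR": 10, "CLD": 10}, n_compounds=20,
                              effect_sizes={j: 1.5 for j in range(5)}, seed=3)
        cohort = generate_feature_matrix(design)
        pm = PeakModel(rt_max=2000.0, n_points=12000, jitter_sd=1.0,
                       drift_amplitude=0.05, bleed_slope=0.1, noise_sd=0.01)
        chroms = generate_chromatograms(cohort, pm)
        fm, qc, table = pp.preprocess_cohort(
            chroms, window=9, polyorder=3, min_prominence=0.05, match_tol=8.0,
            segment_len=1500, max_shift=15, min_fraction=0.5)
        truth = cohort.features.X
        # match registry compounds to simulated ones by retention order
        assert fm.n_compounds == truth.shape[1]
        cors = [np.corrcoef(truth.iloc[:, j], fm.X.iloc[:, j])[0, 1]
                for j in range(truth.shape[1])]
        assert np.median(cors) >= 0.95

    def test_sample_order_permutation_permutes_rows(self):
        design = CohortDesign(n_per_class={"CIR": 3, "CLD": 3}, n_compounds=10,
                              effect_sizes={}, seed=5)
        cohort = generate_feature_matrix(design)
        chroms = generate_chromatograms(cohort, PeakModel(rt_max=900, n_points=9000))
        fm1, _, _ = pp.preprocess_cohort(chroms, min_prominence=0.01, match_tol=10)
        fm2, _, _ = pp.preprocess_cohort(chroms[::-1], min_prominence=0.01,
                                         match_tol=10)
        pd.testing.assert_frame_equal(fm1.X, fm2.X.loc[fm1.X.index])
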