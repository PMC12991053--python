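"""Posterior filtering, peak calling, median reconstruction and merging."""

import numpy as np
import pytest

from cnaseg.bcp import MCMCSettings, run_bcp
from cnaseg.segmentation import (
    SegmentationConfig,
    SegmentedProfile,
    detect_peaks,
    estimate_sigma,
    filter_probabilities,
    merge_segments,
    reconstruct_profile,
    segment,
)


class TestFilterProbabilities:
    def test_absolute_threshold(self):
        out = filter_probabilities([0.02, 0.5, 0.04, 0.9], SegmentationConfig(epsilon=0.05))
        assert np.allclose(out, [0.0, 0.5, 0.0, 0.9])

    def test_threshold_is_strict(self):
        out = filter_probabilities([0.05, 0.06], SegmentationConfig(epsilon=0.05))
        assert np.allclose(out, [0.0, 0.06])

    def test_relative_mode_uses_fraction_of_max(self):
        cfg = SegmentationConfig(epsilon=0.1, relative_epsilon=True)
        out = filter_probabilities([0.08, 0.9, 0.095, 0.1], cfg)
        # effective threshold 0.09
        assert np.allclose(out, [0.0, 0.9, 0.095, 0.1])

    def test_all_zero_passthrough(self):
        assert np.allclose(filter_probabilities(np.zeros(5)), np.zeros(5))

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            filter_probabilities([0.2, 1.4])


class TestDetectPeaks:
    def test_isolated_maxima(self):
        assert detect_peaks([0, 0, 0.9, 0, 0, 0.8, 0]).tolist() == [2, 5]

    def test_plateau_center(self):
        assert detect_peaks([0, 0.7, 0.7, 0.7, 0]).tolist() == [2]

    def test_even_plateau_left_of_center(self):
        assert detect_peaks([0, 0.7, 0.7, 0.7, 0.7, 0]).tolist() == [2]

    def test_all_zeros_empty(self):
        assert detect_peaks(np.zeros(6)).size == 0

    def test_edge_peaks_are_peaks(self):
        assert detect_peaks([0.9, 0, 0, 0.8]).tolist() == [0, 3]

    def test_min_separation_keeps_higher(self):
        cfg = SegmentationConfig(min_peak_separation=4)
        assert detect_peaks([0, 0.5, 0, 0.9, 0, 0, 0], cfg).tolist() == [3]


class TestEstimateSigma:
    def test_noiseless_piecewise_zero(self):
        x = np.array([1.0] * 10 + [3.0] * 10)
        assert estimate_sigma(x, [10]) == 0.0

    def test_recovers_gaussian_scale(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0.0, 0.1, 10_000)
        assert estimate_sigma(x, []) == pytest.approx(0.1, rel=0.05)

    def test_location_invariant(self, rng):
        x = rng.normal(size=500)
        assert estimate_sigma(x + 42.0, [250]) == pytest.approx(
            estimate_sigma(x, [250]), abs=1e-12
        )

    def test_single_bin_segments_fallback(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0.0, 0.2, 400)
        sig = estimate_sigma(x, list(range(1, 400)))
        assert sig == pytest.approx(0.2, rel=0.15)


class TestReconstructProfile:
    def test_exact_medians(self):
        prof = reconstruct_profile([1, 1, 1, 5, 5, 5], [3])
        assert prof.starts.tolist() == [0, 3]
        assert prof.ends.tolist() == [2, 5]
        assert prof.values.tolist() == [1.0, 5.0]
        assert prof.changepoints.tolist() == [3]

    def test_no_changepoints_single_median(self):
        prof = reconstruct_profile([1.0, 2.0, 9.0, 2.0], [])
        assert prof.n_segments == 1
        assert prof.values[0] == 2.0

    def test_median_robust_to_outlier(self):
        prof = reconstruct_profile([1.0, 1.0, 100.0, 1.0], [])
        assert prof.values[0] == 1.0

    def test_invalid_changepoints_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_profile(np.arange(6.0), [2, 2])
        with pytest.raises(ValueError):
            reconstruct_profile(np.arange(6.0), [0])
        with pytest.raises(ValueError):
            reconstruct_profile(np.arange(6.0), [6])


class TestMergeSegments:
    def test_small_gap_merged(self):
        x = np.array([1.0] * 3 + [1.01] * 3 + [5.0] * 4)
        prof = SegmentedProfile([0, 3, 6], [2, 5, 9], [1.0, 1.01, 5.0], sigma_hat=0.1)
        merged = merge_segments(prof, x, SegmentationConfig(eta=0.5))
        assert merged.n_segments == 2
        assert merged.values[0] == pytest.approx(1.005)
        assert merged.values[1] == 5.0

    def test_eta_zero_disables_merging(self):
        x = np.array([1.0] * 3 + [1.01] * 3)
        prof = SegmentedProfile([0, 3], [2, 5], [1.0, 1.01], sigma_hat=0.1)
        merged = merge_segments(prof, x, SegmentationConfig(eta=0.0))
        assert merged.n_segments == 2

    def test_postcondition_and_idempotence_on_noise(self):
        rng = np.random.default_rng(17)
        cfg = SegmentationConfig(eta=0.5)
        for _ in range(30):
            x = rng.normal(0.0, 0.3, 120)
            cps = np.sort(rng.choice(np.arange(1, 120), size=10, replace=False))
            prof = reconstruct_profile(x, cps)
            merged = merge_segments(prof, x, cfg)
            gaps = np.abs(np.diff(merged.values))
            assert np.all(gaps >= cfg.eta * merged.sigma_hat)
            again = merge_segments(merged, x, cfg)
            assert again.starts.tolist() == merged.starts.tolist()
            assert again.values.tolist() == merged.values.tolist()


@pytest.fixture(scope="module")
def noisy_fit():
    rng = np.random.default_rng(2)
    levels = np.repeat([2.0, 2.3, 2.0, 1.7, 2.0], 40)
    x = levels + rng.normal(0.0, 0.08, 200)
    res = run_bcp(x, settings=MCMCSettings(seed=21))
    return x, res


class TestSegmentPipeline:
    def test_zero_noise_exact_recovery(self):
        x = np.repeat([2.0, 2.2, 1.8, 2.0], 25)
        _, prof = segment(x, settings=MCMCSettings(seed=5))
        assert prof.changepoints.tolist() == [25, 50, 75]
        assert np.allclose(prof.values, [2.0, 2.2, 1.8, 2.0])

    def test_constant_input_single_segment(self):
        x = np.full(80, 2.0)
        _, prof = segment(x, settings=MCMCSettings(seed=6))
        assert prof.n_segments == 1

    def test_tiling(self, noisy_fit):
        x, res = noisy_fit
        _, prof = segment(x, result=res)
        assert prof.starts[0] == 0
        assert prof.ends[-1] == x.size - 1
        assert np.all(prof.starts[1:] == prof.ends[:-1] + 1)

    def test_epsilon_monotonicity(self, noisy_fit):
        """Raising epsilon never increases the number of changepoints."""
        x, res = noisy_fit
        counts = []
        for eps in (0.01, 0.05, 0.2, 0.5, 0.9):
            _, prof = segment(x, config=SegmentationConfig(epsilon=eps, eta=0.0),
                              result=res)
            counts.append(prof.changepoints.size)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_eta_monotonicity(self, noisy_fit):
        """Raising eta never increases the number of surviving segments."""
        x, res = noisy_fit
        counts = []
        for eta in (0.0, 0.25, 0.5, 1.0, 2.0, 4.0):
            _, prof = segment(x, config=SegmentationConfig(eta=eta), result=res)
            counts.append(prof.n_segments)
        assert all(a >= b for a, b in zip(counts, counts[1:]))
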