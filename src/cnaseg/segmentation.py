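"""Turn posterior changepoint probabilities into a segmented profile.

Pipeline: threshold the posterior changepoint probabilities at epsilon
(absolute, or a fraction of the largest probability), call peaks on the
filtered track, reconstruct segment levels as medians between consecutive
changepoints, then undo changepoints whose adjacent segment medians are not at
least eta robust standard deviations apart.  The median is preferred over the
mean for segment levels because it is robust to outlying bins.

Changepoints are reported as the 0-based index of the first bin of the new
segment throughout; the probability track is indexed by indicator position
(track index i = boundary after bin i), so a peak at track index i becomes
changepoint i + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .bcp import (
    BCPHyperparameters,
    BCPResult,
    MCMCSettings,
    _as_values,
    run_bcp,
)

__all__ = [
    "SegmentationConfig",
    "SegmentedProfile",
    "filter_probabilities",
    "detect_peaks",
    "estimate_sigma",
    "reconstruct_profile",
    "merge_segments",
    "segment",
]

# MAD -> Gaussian-consistent standard deviation
_MAD_SCALE = 1.4826022185056018


@dataclass(frozen=True)
class SegmentationConfig:
    """Postprocessing thresholds.

    epsilon: probability filter threshold in [0, 1]; with
        ``relative_epsilon`` the effective threshold is
        epsilon * max(posterior probability), e.g. 0.1 for "10% of the
        largest posterior changepoint probability".
    eta: merge threshold in robust-SD units; adjacent segments whose medians
        differ by less than eta * sigma_hat are merged.
    min_peak_separation: minimal distance in bins between detected peaks
        (the higher peak wins when two are closer).
    """

    epsilon: float = 0.05
    relative_epsilon: bool = False
    eta: float = 0.5
    min_peak_separation: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError(f"epsilon must be in [0, 1], got {self.epsilon}")
        if self.eta < 0.0:
            raise ValueError("eta must be non-negative")
        if self.min_peak_separation < 1:
            raise ValueError("min_peak_separation must be a positive integer")


@dataclass
class SegmentedProfile:
    """Ordered segments tiling bins 0..n-1; values are segment medians."""

    starts: np.ndarray  # 0-based inclusive
    ends: np.ndarray  # 0-based inclusive
    values: np.ndarray
    sigma_hat: float = float("nan")

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if not (self.starts.size == self.ends.size == self.values.size):
            raise ValueError("starts, ends, values must have equal length")
        if self.starts.size == 0 or self.starts[0] != 0:
            raise ValueError("segments must start at bin 0")
        if np.any(self.starts[1:] != self.ends[:-1] + 1):
            raise ValueError("segments must tile contiguously")
        if np.any(self.ends < self.starts):
            raise ValueError("segment ends must not precede starts")

    @property
    def n_bins(self) -> int:
        return int(self.ends[-1]) + 1

    @property
    def n_segments(self) -> int:
        return self.starts.size

    @property
    def changepoints(self) -> np.ndarray:
        """First-bin indices of segments 2..k."""
        return self.starts[1:].copy()

    def dense(self) -> np.ndarray:
        """Per-bin reconstructed signal."""
        out = np.empty(self.n_bins)
        for s, e, v in zip(self.starts, self.ends, self.values):
            out[s : e + 1] = v
        return out


def filter_probabilities(p_star, config: SegmentationConfig | None = None):
    """Zero out posterior probabilities <= the (possibly relative) threshold."""
    config = config or SegmentationConfig()
    p = np.asarray(p_star, dtype=np.float64)
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    eps = config.epsilon
    if config.relative_epsilon:
        eps = config.epsilon * (p.max() if p.size else 0.0)
    out = np.where(p > eps, p, 0.0)
    return out


def detect_peaks(filtered, config: SegmentationConfig | None = None) -> np.ndarray:
    """Local maxima of the filtered probability track.

    Returns sorted track indices i with filtered[i] > 0 and filtered[i] >=
    both neighbors (track boundaries count as zero neighbors); plateaus yield
    their center index, left-of-center for even-length plateaus; peaks closer
    than ``min_peak_separation`` are resolved in favor of the higher one.
    """
    config = config or SegmentationConfig()
    f = np.asarray(filtered, dtype=np.float64)
    if f.size == 0 or not np.any(f > 0.0):
        return np.array([], dtype=np.int64)
    padded = np.concatenate(([-1.0], f, [-1.0]))
    peaks, props = find_peaks(
        padded,
        height=np.finfo(np.float64).tiny,
        distance=config.min_peak_separation,
        plateau_size=1,
    )
    # find_peaks reports the plateau midpoint rounded down (left-of-center)
    return np.sort(peaks - 1).astype(np.int64)


def _segment_bounds(n: int, changepoints) -> tuple[np.ndarray, np.ndarray]:
    cps = np.asarray(changepoints, dtype=np.int64)
    if cps.size:
        if np.any(np.diff(cps) <= 0):
            raise ValueError("changepoints must be strictly increasing")
        if cps[0] <= 0 or cps[-1] >= n:
            raise ValueError("changepoints must lie in (0, n)")
    starts = np.concatenate(([0], cps))
    ends = np.concatenate((cps - 1, [n - 1]))
    return starts, ends


def reconstruct_profile(x, changepoints) -> SegmentedProfile:
    """Segment levels as medians of x between consecutive changepoints."""
    v = _as_values(x)
    starts, ends = _segment_bounds(v.size, changepoints)
    values = np.array([np.median(v[s : e + 1]) for s, e in zip(starts, ends)])
    return SegmentedProfile(starts, ends, values)


def estimate_sigma(x, changepoints) -> float:
    """Pooled robust noise scale: Gaussian-consistent MAD of the residuals of
    x around its per-segment medians.  If every segment is a single bin the
    residuals are vacuously zero, so the global MAD of first differences
    (scaled by 1/sqrt(2)) is used instead."""
    v = _as_values(x)
    prof = reconstruct_profile(v, changepoints)
    if np.all(prof.ends == prof.starts):
        d = np.diff(v)
        return float(_MAD_SCALE * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))
    resid = v - prof.dense()
    return float(_MAD_SCALE * np.median(np.abs(resid - np.median(resid))))


def merge_segments(
    profile: SegmentedProfile, x, config: SegmentationConfig | None = None
) -> SegmentedProfile:
    """Iteratively undo changepoints whose adjacent medians are closer than
    eta * sigma_hat, smallest gap first, recomputing the merged median after
    each merge.  The output has every adjacent pair at least eta * sigma_hat
    apart."""
    config = config or SegmentationConfig()
    v = _as_values(x)
    sigma = profile.sigma_hat
    if not np.isfinite(sigma):
        sigma = estimate_sigma(v, profile.changepoints)
    starts = list(profile.starts)
    ends = list(profile.ends)
    values = list(profile.values)
    threshold = config.eta * sigma
    while len(values) > 1:
        gaps = np.abs(np.diff(values))
        k = int(np.argmin(gaps))
        if gaps[k] >= threshold:
            break
        ends[k] = ends[k + 1]
        del starts[k + 1], ends[k + 1], values[k + 1]
        values[k] = float(np.median(v[starts[k] : ends[k] + 1]))
    return SegmentedProfile(
        np.array(starts), np.array(ends), np.array(values), sigma_hat=sigma
    )


def segment(
    x,
    hyper: BCPHyperparameters | None = None,
    settings: MCMCSettings | None = None,
    config: SegmentationConfig | None = None,
    result: BCPResult | None = None,
):
    """Full pipeline on a single value vector: MCMC posterior probabilities ->
    filter -> peak detection -> median reconstruction -> merge.

    Returns ``(BCPResult, SegmentedProfile)``.  Pass ``result`` to reuse an
    already-fitted posterior.  A multi-chromosome ``BinnedProfile`` is
    dispatched to :func:`cnaseg.io.segment_binned`, which applies the
    pipeline per chromosome and returns its per-chromosome mapping.
    """
    config = config or SegmentationConfig()
    if hasattr(x, "chromosomes"):  # BinnedProfile
        from .io import segment_binned

        return segment_binned(x, hyper=hyper, settings=settings, config=config)
    v = _as_values(x)
    if result is None:
        result = run_bcp(v, hyper, settings)
    filtered = filter_probabilities(result.posterior_prob[:-1], config)
    peak_idx = detect_peaks(filtered, config)
    changepoints = peak_idx + 1  # track index i -> new segment starts at i+1
    profile = reconstruct_profile(v, changepoints)
    profile = replace(profile, sigma_hat=estimate_sigma(v, changepoints))
    profile = merge_segments(profile, v, config)
    return result, profile
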