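"""Changepoint-detection metrics and the simulation benchmark driver.

A predicted changepoint is a true positive when it lies within +/- 2 genomic
bins of a true changepoint, and each predicted changepoint may be assigned to
at most one true changepoint (and vice versa).  The matching maximizes the
number of matched pairs and, among maximal matchings, minimizes the total
bin distance — a greedy nearest-neighbor pass can under-count true positives,
so the assignment is solved exactly.  Precision, recall and

    F1 = 2 * precision * recall / (precision + recall)

follow, with the convention that precision and F1 are zero when no
changepoints are predicted (they would otherwise be undefined).

Agreement between two segmentations of the same bins is quantified by the
normalized mutual information NMI(X, Y) = I(X, Y) / sqrt(H(X) * H(Y)) of the
per-bin segment labelings, computed from plug-in (empirical) entropies; 1
means identical partitions, 0 no association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .bcp import BCPHyperparameters, MCMCSettings
from .segmentation import SegmentationConfig, segment
from .simulate import (
    DEFAULT_NOISE_LEVELS,
    DEFAULT_PURITIES,
    SimulationConfig,
    generate_dataset,
)

__all__ = [
    "MatchResult",
    "MetricReport",
    "match_changepoints",
    "precision_recall_f1",
    "segmentation_labels",
    "nmi",
    "score_sample",
    "run_benchmark",
    "summarize_benchmark",
]


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    matched_pairs: list  # (true index, predicted index)


@dataclass
class MetricReport:
    precision: float
    recall: float
    f1: float
    nmi: float = float("nan")


def _check_sorted_unique(a, name):
    arr = np.asarray(a, dtype=np.int64)
    if arr.size and np.any(np.diff(arr) <= 0):
        raise ValueError(f"{name} must be sorted and duplicate-free")
    return arr


def match_changepoints(true_cps, predicted_cps, tolerance: int = 2) -> MatchResult:
    """One-to-one matching of predicted to true changepoints within
    ``tolerance`` bins, maximizing pair count then minimizing total distance."""
    t = _check_sorted_unique(true_cps, "true_cps")
    p = _check_sorted_unique(predicted_cps, "predicted_cps")
    if t.size == 0 or p.size == 0:
        return MatchResult(tp=0, fp=int(p.size), fn=int(t.size), matched_pairs=[])
    dist = np.abs(t[:, None] - p[None, :]).astype(np.float64)
    # forbidden pairs get a cost so large that the solver only uses them when
    # unavoidable; such assignments are then discarded
    big = (tolerance + 1.0) * (t.size + p.size + 1.0)
    cost = np.where(dist <= tolerance, dist, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (int(t[r]), int(p[c]))
        for r, c in zip(rows, cols)
        if dist[r, c] <= tolerance
    ]
    tp = len(pairs)
    return MatchResult(
        tp=tp, fp=int(p.size) - tp, fn=int(t.size) - tp, matched_pairs=pairs
    )


def precision_recall_f1(match: MatchResult) -> MetricReport:
    """Precision/recall/F1 from matched counts.

    No predictions => precision = F1 = 0; no true changepoints => recall (and
    F1) are undefined and reported as NaN — the simulations always contain at
    least one true changepoint.
    """
    tp, fp, fn = match.tp, match.fp, match.fn
    if tp + fp == 0:
        recall = 0.0 if tp + fn > 0 else float("nan")
        return MetricReport(precision=0.0, recall=recall, f1=0.0)
    precision = tp / (tp + fp)
    if tp + fn == 0:
        return MetricReport(precision=precision, recall=float("nan"), f1=float("nan"))
    recall = tp / (tp + fn)
    if precision + recall == 0.0:
        return MetricReport(precision=0.0, recall=0.0, f1=0.0)
    f1 = 2.0 * precision * recall / (precision + recall)
    return MetricReport(precision=precision, recall=recall, f1=f1)


def segmentation_labels(changepoints, n_bins: int) -> np.ndarray:
    """Per-bin segment labels (0, 1, 2, ... left to right) induced by a
    sorted changepoint list of first-bin indices."""
    cps = _check_sorted_unique(changepoints, "changepoints")
    labels = np.zeros(n_bins, dtype=np.int64)
    for cp in cps:
        labels[cp:] += 1
    return labels


def nmi(labels_x, labels_y) -> float:
    """Normalized mutual information of two equal-length labelings, with the
    geometric-mean (sqrt) normalization and natural-log plug-in entropies.

    Two identical single-segment labelings agree perfectly (1.0); if exactly
    one labeling is single-segment the quantity is undefined (NaN).
    """
    x = np.asarray(labels_x)
    y = np.asarray(labels_y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("labelings must be equal-length 1-D vectors")
    n = x.size
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    kx = xi.max() + 1
    ky = yi.max() + 1
    joint = np.zeros((kx, ky))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    hx = -np.sum(px * np.log(px, where=px > 0, out=np.zeros_like(px)))
    hy = -np.sum(py * np.log(py, where=py > 0, out=np.zeros_like(py)))
    if hx == 0.0 or hy == 0.0:
        return 1.0 if (hx == 0.0 and hy == 0.0) else float("nan")
    nz = joint > 0
    mi = np.sum(joint[nz] * (np.log(joint[nz]) - np.log(px[:, None] * py[None, :])[nz]))
    return float(max(mi, 0.0) / np.sqrt(hx * hy))


def score_sample(truth, profile, tolerance: int = 2) -> MetricReport:
    """Score a segmented profile against simulation ground truth: matching
    P/R/F1 on the changepoint lists plus NMI of the induced labelings."""
    match = match_changepoints(
        truth.true_changepoints, profile.changepoints, tolerance=tolerance
    )
    report = precision_recall_f1(match)
    n = truth.cn_state.size
    report.nmi = nmi(
        segmentation_labels(truth.true_changepoints, n),
        segmentation_labels(profile.changepoints, n),
    )
    return report


def run_benchmark(
    n_samples: int = 50,
    purities=DEFAULT_PURITIES,
    noise_levels=DEFAULT_NOISE_LEVELS,
    seed: int = 0,
    base_config: SimulationConfig | None = None,
    hyper: BCPHyperparameters | None = None,
    settings: MCMCSettings | None = None,
    seg_config: SegmentationConfig | None = None,
    tolerance: int = 2,
) -> pd.DataFrame:
    """simulate -> segment -> score over a (noise level, purity, replicate)
    grid; returns one tidy row per sample, fully reproducible from ``seed``.

    The per-sample MCMC seed is derived from the sample's simulation sub-seed
    so the whole table is a deterministic function of the master seed.
    """
    hyper = hyper or BCPHyperparameters()
    settings = settings or MCMCSettings()
    seg_config = seg_config or SegmentationConfig()
    rows = []
    for meta, truth in generate_dataset(
        n_samples, purities, noise_levels, seed=seed, base_config=base_config
    ):
        fit_settings = MCMCSettings(
            burnin=settings.burnin,
            m=settings.m,
            seed=(meta["seed"] + 1) % (2**31 - 1),
            thin=settings.thin,
        )
        _, profile = segment(
            truth.observed, hyper=hyper, settings=fit_settings, config=seg_config
        )
        report = score_sample(truth, profile, tolerance=tolerance)
        rows.append(
            {
                **meta,
                "n_true": truth.true_changepoints.size,
                "n_predicted": profile.changepoints.size,
                "precision": report.precision,
                "recall": report.recall,
                "f1": report.f1,
                "nmi": report.nmi,
            }
        )
    return pd.DataFrame(rows)


def summarize_benchmark(results: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean and SD of the per-sample metrics."""
    return (
        results.groupby(["noise_level", "purity"])[
            ["precision", "recall", "f1", "nmi"]
        ]
        .agg(["mean", "std"])
        .reset_index()
    )
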