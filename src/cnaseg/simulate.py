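"""Synthetic copy-number profiles for evaluating the segmentation method.

Each profile is a piecewise-constant integer copy-number state sequence over
n fixed-size genomic bins: segment lengths are drawn uniformly from
{length_min..length_max} (defaults 30..50 bins) and each segment receives a
copy-number state from {1..5} with probabilities {0.09, 0.5, 0.27, 0.09,
0.05} — a diploid-dominated mixture with more gains than deep losses, typical
of the tumors the method targets.  The tumor signal is diluted by purity P
against a constant healthy level of 2 (mixed = P*C + (1-P)*2) and corrupted
by multiplicative Gaussian noise, observed = mixed * (1 + e) with
e ~ N(0, (noise_level * base_noise_sd)^2): the per-bin noise SD is
proportional to the bin's mixed copy number, so higher copy states are
noisier, and noise_level acts as a coverage surrogate (1 = a typical
experimental sample; {0.5, 1, 2, 4} span high to very low coverage).
base_noise_sd = 0.05 calibrates the relative bin-level scatter of a typical
low-pass run at noise level 1.

Adjacent segments that happen to draw the same state are merged in the
reported ground truth, so every true changepoint is a real state change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_states",
    "apply_purity",
    "add_noise",
    "simulate_sample",
    "generate_dataset",
    "write_sample",
    "DEFAULT_PURITIES",
    "DEFAULT_NOISE_LEVELS",
]

DEFAULT_PURITIES = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))
DEFAULT_NOISE_LEVELS = (0.5, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class SimulationConfig:
    n_bins: int = 1000
    length_min: int = 30
    length_max: int = 50
    state_values: tuple = (1, 2, 3, 4, 5)
    state_probs: tuple = (0.09, 0.5, 0.27, 0.09, 0.05)
    purity: float = 0.2
    noise_level: float = 1.0
    base_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be positive")
        if not (1 <= self.length_min <= self.length_max <= self.n_bins):
            raise ValueError("need 1 <= length_min <= length_max <= n_bins")
        if len(self.state_values) != len(self.state_probs):
            raise ValueError("state_values and state_probs must align")
        if abs(sum(self.state_probs) - 1.0) > 1e-9:
            raise ValueError("state_probs must sum to 1")
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.noise_level < 0.0 or self.base_noise_sd < 0.0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class GroundTruth:
    """True state sequence plus the noise-free and observed signals."""

    cn_state: np.ndarray
    true_changepoints: np.ndarray  # first-bin indices of segments 2..k
    mixed_signal: np.ndarray
    observed: np.ndarray
    purity: float
    noise_level: float


def simulate_states(config: SimulationConfig, rng: np.random.Generator):
    """Draw the piecewise-constant state sequence.

    Returns (cn_state per bin, true_changepoints); adjacent same-state
    segments are merged so every reported changepoint changes the state.
    """
    n = config.n_bins
    states = np.asarray(config.state_values)
    probs = np.asarray(config.state_probs, dtype=np.float64)
    cn = np.empty(n, dtype=np.int64)
    pos = 0
    while pos < n:
        length = int(rng.integers(config.length_min, config.length_max + 1))
        state = states[rng.choice(states.size, p=probs)]
        cn[pos : pos + length] = state
        pos += length
    cps = np.flatnonzero(np.diff(cn)) + 1
    return cn, cps


def apply_purity(cn_state, purity: float) -> np.ndarray:
    """Dilute the tumor signal against a healthy diploid background:
    mixed = P * C + (1 - P) * 2."""
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    return purity * np.asarray(cn_state, dtype=np.float64) + (1.0 - purity) * 2.0


def add_noise(
    mixed_signal, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Multiplicative Gaussian noise: observed = mixed * (1 + e) with
    e ~ N(0, (noise_level * base_noise_sd)^2)."""
    mixed = np.asarray(mixed_signal, dtype=np.float64)
    sd = config.noise_level * config.base_noise_sd
    return mixed * (1.0 + rng.normal(0.0, 1.0, mixed.size) * sd)


def simulate_sample(config: SimulationConfig) -> GroundTruth:
    """One seeded sample: states -> purity mixing -> multiplicative noise."""
    rng = np.random.default_rng(config.seed)
    cn, cps = simulate_states(config, rng)
    mixed = apply_purity(cn, config.purity)
    observed = add_noise(mixed, config, rng)
    return GroundTruth(
        cn_state=cn,
        true_changepoints=cps,
        mixed_signal=mixed,
        observed=observed,
        purity=config.purity,
        noise_level=config.noise_level,
    )


def generate_dataset(
    n_samples: int = 50,
    purities=DEFAULT_PURITIES,
    noise_levels=DEFAULT_NOISE_LEVELS,
    seed: int = 0,
    base_config: SimulationConfig | None = None,
) -> Iterator[tuple[dict, GroundTruth]]:
    """Seeded grid of samples: ``n_samples`` replicates per (noise level,
    purity) condition.  Yields (metadata, GroundTruth) pairs; metadata carries
    purity, noise_level, replicate and the per-sample sub-seed, so any single
    sample can be regenerated independently."""
    base = base_config or SimulationConfig()
    root = np.random.default_rng(seed)
    for noise in noise_levels:
        for purity in purities:
            for rep in range(n_samples):
                sub_seed = int(root.integers(0, 2**31 - 1))
                cfg = SimulationConfig(
                    n_bins=base.n_bins,
                    length_min=base.length_min,
                    length_max=base.length_max,
                    state_values=base.state_values,
                    state_probs=base.state_probs,
                    purity=float(purity),
                    noise_level=float(noise),
                    base_noise_sd=base.base_noise_sd,
                    seed=sub_seed,
                )
                meta = {
                    "purity": float(purity),
                    "noise_level": float(noise),
                    "replicate": rep,
                    "seed": sub_seed,
                }
                yield meta, simulate_sample(cfg)


def write_sample(
    truth: GroundTruth,
    path,
    truth_path=None,
    chromosome: str = "chr1",
    bin_size: int = 500_000,
) -> None:
    """Write a simulated sample as the 4-column TSV the CLI reads
    (chromosome, start, end, value; 0-based half-open) with an optional
    ground-truth sidecar TSV (bin, cn_state)."""
    n = truth.observed.size
    df = pd.DataFrame(
        {
            "chromosome": chromosome,
            "start": np.arange(n, dtype=np.int64) * bin_size,
            "end": (np.arange(n, dtype=np.int64) + 1) * bin_size,
            "value": truth.observed,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    if truth_path is not None:
        pd.DataFrame(
            {"bin": np.arange(n, dtype=np.int64), "cn_state": truth.cn_state}
        ).to_csv(truth_path, sep="\t", index=False)
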