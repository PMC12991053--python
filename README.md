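# cnaseg

Bayesian changepoint segmentation of binned copy-number profiles, built for
the low-signal regime of liquid-biopsy sequencing.

Copy-number alterations (CNAs) — somatic gains and losses of large genomic
regions — can be read from low-pass whole-genome sequencing (~0.1–5×) as
per-bin read-depth ratios. In cell-free DNA the tumor contributes only a
small fraction P of the material, so every copy-number step is compressed
toward the diploid level (an altered state C appears as P·C + (1−P)·2) and
is easily lost in bin-level noise. `cnaseg` is for analysts of such samples
who need *sensitive* segment-boundary detection and a reconstructed,
quantitative (floating-point) copy-number profile to feed downstream tools
for absolute copy number or tumor-fraction estimation.

## The model

The core is the Barry–Hartigan product-partition changepoint model: for bin
values X₁..X_n there is an unknown partition ρ into contiguous blocks;
X_i ~ N(μ_i, σ²) independently with a block-constant mean, and the mean of a
block spanning bins i+1..j has prior N(μ₀, σ₀²/(j−i)). With uniform priors
U(0, p0) on the per-position changepoint probability and U(0, w0) on the
signal-to-noise ratio w = σ²/(σ²+σ₀²), everything else integrates out, and a
systematic-scan Gibbs sampler (the Erdman–Emerson MCMC scheme) yields the
marginal posterior changepoint probability per bin boundary,

  p*_i = (1/M) Σ_m 1{U_i^{(m)} = 1},

plus the posterior mean profile with a pointwise 95% credible band.
Segmentation then (i) zeroes probabilities ≤ ε, (ii) calls peaks on the
filtered track, (iii) sets segment levels to the medians between consecutive
changepoints, and (iv) undoes changepoints whose adjacent medians are closer
than η robust standard deviations. No set of copy-number states is assumed,
which is what preserves sensitivity at low purity. See `docs/methods.md` for
the full account.

An exact-enumeration oracle (`cnaseg.exact_posterior`, n ≤ 14) provides the
ground truth the sampler is tested against, and `cnaseg.simulate` +
`cnaseg.evaluate` implement the synthetic benchmark (purity-diluted
piecewise-constant profiles with state-dependent multiplicative noise,
scored by ±2-bin one-to-one changepoint matching and NMI).

## Worked example

```python
import numpy as np
from cnaseg import (BayesianChangepointModel, SimulationConfig,
                    simulate_sample, score_sample)

# a synthetic 1000-bin profile: 20% tumor fraction, typical noise
truth = simulate_sample(SimulationConfig(purity=0.2, noise_level=1.0, seed=7))

model = BayesianChangepointModel(truth.observed)   # p0=0.01, w0=0.2
results = model.fit(burnin=500, iterations=2000, seed=1)
print(results.summary())

profile = results.segment(epsilon=0.05, eta=0.5)
print(f"segments: {profile.n_segments}  (true: {truth.true_changepoints.size + 1})")
report = score_sample(truth, profile)
print(f"precision {report.precision:.3f}  recall {report.recall:.3f}  "
      f"f1 {report.f1:.3f}  nmi {report.nmi:.3f}")
```

prints

```
Bayesian changepoint model (product partition, MCMC)
====================================================
No. bins:               1000
Priors:                 p0=0.01, w0=0.2
Burn-in / retained:     500 / 2000
Seed:                   1
Positions with p*>0.5:  16
Posterior mean range:   [1.788, 2.562]
segments: 21  (true: 19)
precision 0.900  recall 1.000  f1 0.947  nmi 0.987
```

Sixteen boundaries are individually near-certain (p* > 0.5); the remaining
evidence is spread over neighboring bins and resolved by the peak/merge
stage. The fit recovers all 18 true changepoints (recall 1.0) within ±2
bins, at the cost of two spurious boundaries (precision 0.9); the segment
labeling agrees with the truth at NMI 0.987. Fitting 1000 bins takes about a
second on one core; `results.plot()` draws the input / posterior-probability
/ reconstruction diagnostic panel.

## Command line

```sh
cnaseg segment sample.tsv --seed 7 --output-prefix sample   # SEG table + p* bedGraph
cnaseg simulate --n-samples 5 --output-dir sim/             # synthetic grid + truth
cnaseg benchmark --n-samples 20 --output bench.tsv          # simulate→segment→score
cnaseg plot sample.tsv --output panel.png                   # diagnostic panel
```

Inputs are bedGraph or headered chromosome/start/end/value TSV (1-based
dialects auto-detected); values are used as-is, so apply GC/mappability
correction upstream. Every run logs its fully resolved configuration and
seed, and identical seeds give byte-identical outputs.

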