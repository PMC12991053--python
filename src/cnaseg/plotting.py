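"""Diagnostic plotting: input track, posterior changepoint probabilities with
the filter threshold, and the reconstructed segment profile with the
posterior mean and its 95% credible band."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_diagnostics"]


def plot_diagnostics(x, result, profile, epsilon: float = 0.05, axes=None):
    """Three stacked panels: data, posterior probabilities (epsilon dashed),
    reconstruction.  Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=np.float64)
    bins = np.arange(x.size)
    if axes is None:
        fig, axes = plt.subplots(3, 1, figsize=(10, 7), sharex=True)
    else:
        fig = axes[0].figure

    ax = axes[0]
    ax.plot(bins, x, ".", ms=2.5, color="0.4")
    ax.set_ylabel("observed value")
    ax.set_title("input profile")

    ax = axes[1]
    ax.vlines(bins, 0, result.posterior_prob, color="tab:blue", lw=1)
    ax.axhline(epsilon, ls="--", color="tab:red", lw=1, label=f"$\\epsilon$={epsilon:g}")
    ax.set_ylabel("posterior $p^*$")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="upper right", frameon=False)

    ax = axes[2]
    ax.plot(bins, x, ".", ms=2, color="0.8")
    ax.fill_between(
        bins, result.ci_lower, result.ci_upper, color="tab:orange", alpha=0.3,
        label="95% CI",
    )
    ax.plot(bins, result.posterior_mean, color="tab:orange", lw=1, label="posterior mean")
    ax.plot(bins, profile.dense(), color="tab:red", lw=1.5, label="segments (median)")
    for cp in profile.changepoints:
        ax.axvline(cp - 0.5, color="0.6", ls=":", lw=0.8)
    ax.set_xlabel("genomic bin")
    ax.set_ylabel("copy-number signal")
    ax.legend(loc="upper right", frameon=False, fontsize=8)
    fig.tight_layout()
    return fig
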