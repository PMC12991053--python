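"""Model/Results interface over the changepoint sampler and segmentation.

``BayesianChangepointModel`` is constructed from a value vector (or a
DataFrame column) plus the two prior hyperparameters; ``fit`` runs the MCMC
approximation and returns a ``ChangepointResults`` carrying the posterior
changepoint probabilities, the posterior mean profile with pointwise 95%
credible bounds, and a ``segment`` method for the filtering / peak calling /
median reconstruction / merging stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bcp import (
    BCPHyperparameters,
    BCPResult,
    MCMCSettings,
    _as_values,
    run_bcp,
)
from .segmentation import SegmentationConfig, SegmentedProfile, segment

__all__ = ["BayesianChangepointModel", "ChangepointResults"]


class BayesianChangepointModel:
    """Product-partition changepoint model for one binned value vector.

    Parameters
    ----------
    endog : array-like
        Observed per-bin values (e.g. GC-corrected log2 ratios or normalized
        read depths); must be finite — drop masked bins first.
    p0, w0 : float
        Upper bounds of the uniform priors on the per-position changepoint
        probability and on the signal-to-noise ratio w = sigma^2 /
        (sigma^2 + sigma_0^2).  Smaller p0 favors fewer changepoints (use for
        clean, high-purity samples); larger p0 increases recall on noisy ones.
    """

    def __init__(self, endog, p0: float = 0.01, w0: float = 0.2):
        self.endog = _as_values(endog)
        self.hyper = BCPHyperparameters(p0=p0, w0=w0)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, value_col: str = "value", **kwargs):
        values = pd.to_numeric(data[value_col], errors="coerce")
        return cls(values.dropna().to_numpy(), **kwargs)

    @property
    def nobs(self) -> int:
        return self.endog.size

    def fit(
        self,
        burnin: int = 500,
        iterations: int = 2000,
        seed: int = 0,
        thin: int = 1,
    ) -> "ChangepointResults":
        settings = MCMCSettings(burnin=burnin, m=iterations, seed=seed, thin=thin)
        result = run_bcp(self.endog, self.hyper, settings)
        return ChangepointResults(self, result, settings)


class ChangepointResults:
    """Posterior summaries of a fitted changepoint model."""

    def __init__(
        self,
        model: BayesianChangepointModel,
        result: BCPResult,
        settings: MCMCSettings,
    ):
        self.model = model
        self.settings = settings
        self._result = result

    @property
    def posterior_prob(self) -> np.ndarray:
        return self._result.posterior_prob

    @property
    def posterior_mean(self) -> np.ndarray:
        return self._result.posterior_mean

    @property
    def ci_lower(self) -> np.ndarray:
        return self._result.ci_lower

    @property
    def ci_upper(self) -> np.ndarray:
        return self._result.ci_upper

    @property
    def bcp_result(self) -> BCPResult:
        return self._result

    def segment(
        self,
        epsilon: float = 0.05,
        eta: float = 0.5,
        relative_epsilon: bool = False,
        min_peak_separation: int = 1,
    ) -> SegmentedProfile:
        config = SegmentationConfig(
            epsilon=epsilon,
            relative_epsilon=relative_epsilon,
            eta=eta,
            min_peak_separation=min_peak_separation,
        )
        _, profile = segment(self.model.endog, config=config, result=self._result)
        return profile

    def summary(self) -> str:
        r = self._result
        h = self.model.hyper
        n_hi = int(np.sum(r.posterior_prob[:-1] > 0.5))
        lines = [
            "Bayesian changepoint model (product partition, MCMC)",
            "=" * 52,
            f"No. bins:               {self.model.nobs}",
            f"Priors:                 p0={h.p0:g}, w0={h.w0:g}",
            f"Burn-in / retained:     {self.settings.burnin} / "
            f"{r.n_iterations_used}"
            + (f" (thin {self.settings.thin})" if self.settings.thin > 1 else ""),
            f"Seed:                   {self.settings.seed}",
            f"Positions with p*>0.5:  {n_hi}",
            f"Posterior mean range:   [{r.posterior_mean.min():.4g}, "
            f"{r.posterior_mean.max():.4g}]",
        ]
        return "\n".join(lines)

    def plot(self, epsilon: float = 0.05, ax=None, **segment_kwargs):
        from .plotting import plot_diagnostics

        profile = self.segment(epsilon=epsilon, **segment_kwargs)
        return plot_diagnostics(
            self.model.endog, self._result, profile, epsilon=epsilon, axes=ax
        )
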