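"""Model and results objects for the Bayesian CJS survival analysis.

``CJSModel`` is constructed from one encounter-history set (or several,
for the site-comparison structure), holds the model specification, and its
``fit`` method runs the MCMC sampler and returns ``CJSResults`` — the
carrier of posterior draws, convergence diagnostics, summary tables and
derived quantities (annual survival, time-varying survival series,
covariate-slope summaries, population comparisons).

Example
-------
>>> from upwellsurv import simulate, CJSModel
>>> truth = simulate.TruthConfig(n_individuals=200, phi=0.9, p=0.4, seed=1)
>>> hist = simulate.simulate_histories(truth)
>>> res = CJSModel(hist, structure="phi_dot").fit(n_iter=3000, n_burn=500)
>>> res.summary()  # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .histories import EncounterHistories
from .likelihood import (
    CJSModelSpec,
    dataset_loglik,
    drop_missing_covariate,
    resolve_structure,
)
from .mcmc import (
    MCMCConfig,
    PosteriorDraws,
    PriorSpec,
    sample_posterior,
    split_rhat,
    summarize_draws,
)
from . import posterior as _post

__all__ = ["CJSModel", "CJSResults"]


class CJSModel:
    """Cormack-Jolly-Seber model for one population (or two, for phi_site).

    Parameters
    ----------
    histories
        An :class:`EncounterHistories` set, or a list of them (one per
        site) for ``structure="phi_site"``.
    structure
        One of ``phi_dot``, ``phi_site``, ``phi_time``, ``phi_length``,
        ``phi_perf`` — or the classical shorthand ``"."``, ``"Po"``,
        ``"t"``, ``"L"``, ``"F"``.  Detection is always fully time-varying
        with p pinned at 0 in unsearched months.
    standardize_covariate
        Center and scale the covariate before fitting (slope per covariate
        standard deviation).

    Individuals missing the covariate under phi_length/phi_perf are
    excluded from the fit; the count is recorded on the model as
    ``n_dropped_missing_covariate``.
    """

    def __init__(
        self,
        histories: EncounterHistories | list[EncounterHistories],
        structure: str = "phi_dot",
        standardize_covariate: bool = True,
    ) -> None:
        structure = resolve_structure(structure)
        multi = isinstance(histories, (list, tuple))
        hs = list(histories) if multi else [histories]
        if structure == "phi_site":
            if len(hs) != 2:
                raise ValueError("phi_site expects exactly two history sets")
        elif multi:
            raise ValueError(f"{structure} expects a single history set")

        T = hs[0].n_occasions
        # p is pinned at 0 wherever *no* site in the fit searched; with
        # site-specific detection the per-site masks live on each history set
        mask = ~np.logical_or.reduce([h.searched for h in hs])
        spec = CJSModelSpec(survival_structure=structure, fixed_zero_mask=mask)

        self.n_dropped_missing_covariate = 0
        if structure in ("phi_length", "phi_perf"):
            hs[0], self.n_dropped_missing_covariate = drop_missing_covariate(
                hs[0], spec.covariate_name
            )
        spec.standardize_covariate = standardize_covariate
        self.spec = spec
        self.histories = hs if multi else hs[0]
        self.n_occasions = T

    def loglike(self, state) -> float:
        """Marginal CJS log-likelihood at a given parameter state."""
        return dataset_loglik(self.histories, self.spec, state)

    def fit(
        self,
        config: MCMCConfig | None = None,
        priors: PriorSpec | None = None,
        **config_kwargs,
    ) -> "CJSResults":
        """Sample the posterior; keyword arguments override MCMC defaults
        (``n_chains=3, n_iter=10000, n_burn=1000, seed=0``)."""
        if config is None:
            config = MCMCConfig(**config_kwargs)
        elif config_kwargs:
            raise ValueError("pass either a config object or keyword overrides")
        draws = sample_posterior(self.histories, self.spec, priors, config)
        return CJSResults(self, draws)


class CJSResults:
    """Posterior draws and derived quantities of a fitted CJS model."""

    def __init__(self, model: CJSModel, draws: PosteriorDraws) -> None:
        self.model = model
        self.draws = draws

    # -- diagnostics -----------------------------------------------------
    @property
    def max_rhat(self) -> float:
        """Largest split-chain Gelman-Rubin statistic over all parameters."""
        return max(
            split_rhat(self.draws, name) for name in self.draws.names
        )

    def converged(self, threshold: float = 1.1) -> bool:
        return self.max_rhat < threshold

    def summary(self) -> pd.DataFrame:
        return summarize_draws(self.draws)

    # -- parameter access ------------------------------------------------
    def _phi_name(self, site: str | None = None) -> str:
        s = self.model.spec.survival_structure
        if s == "phi_dot":
            return "phi"
        if s == "phi_site":
            if site is None:
                raise ValueError("phi_site fit: specify the site")
            return f"phi[{site}]"
        raise ValueError(f"no scalar survival parameter under {s}")

    def phi_draws(self, site: str | None = None) -> np.ndarray:
        """Flat monthly-survival draws (phi_dot / phi_site structures)."""
        return self.draws.flat(self._phi_name(site))

    def beta_draws(self) -> np.ndarray:
        """Flat covariate-slope draws (phi_length / phi_perf structures)."""
        if self.model.spec.survival_structure not in ("phi_length", "phi_perf"):
            raise ValueError("no slope under this structure")
        return self.draws.flat("beta")

    # -- derived quantities ----------------------------------------------
    def annual_survival(self, site: str | None = None) -> dict:
        """Posterior summary of annual survival (monthly phi to the 12th)."""
        ann = _post.annual_survival(self.phi_draws(site))
        lo, hi = np.quantile(ann, [0.025, 0.975])
        return {
            "mean": float(ann.mean()),
            "median": float(np.median(ann)),
            "q2.5": float(lo),
            "q97.5": float(hi),
        }

    def slope_summary(self) -> dict:
        return _post.slope_summary(self.beta_draws())

    def survival_series(self) -> pd.DataFrame:
        """Monthly survival summaries of a phi_time fit, with confounded
        intervals flagged."""
        if self.model.spec.survival_structure != "phi_time":
            raise ValueError("survival_series requires a phi_time fit")
        T = self.model.n_occasions
        cols = [self.draws.flat(f"phi[{t}]") for t in range(1, T)]
        searched = self.model.histories.searched
        return _post.survival_series(np.column_stack(cols), searched)

    def compare_phi(
        self,
        other: "CJSResults",
        label_a: str = "A",
        label_b: str = "B",
        site_a: str | None = None,
        site_b: str | None = None,
    ) -> _post.ComparisonResult:
        """Posterior probability that this population's phi exceeds the
        other's, pairing draws by (chain, iteration) index."""
        return _post.prob_difference(
            self.phi_draws(site_a), other.phi_draws(site_b), label_a, label_b
        )
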