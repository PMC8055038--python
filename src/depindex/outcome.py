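"""Bayesian logistic regression of visit non-attendance on the index.

The deprivation index enters as the plug-in per-person posterior mean of
theta; alternatives are (b) each component indicator singly (univariable)
and (c) all components jointly. Coefficients get independent Normal(0,
prior_sd^2) priors and are sampled by random-walk Metropolis with an
adaptive proposal covariance during burn-in (frozen afterwards, so the
post-burn-in chain is a valid Markov chain). Odds-ratio point estimates
are the posterior mean of the exponentiated draws, with 2.5/97.5%
quantiles as the credible interval; pointwise log-likelihoods are kept so
model fits can be compared by the same WAIC routine as the IRT models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .evaluation import WaicResult, compare_waic, waic
from .irt import McmcConfig
from ._util import child_seed

__all__ = [
    "OutcomeFit",
    "bayes_logistic",
    "univariable_table",
    "compare_index_vs_components",
]


@dataclass
class OutcomeFit:
    coef_draws: np.ndarray  # S x (p+1), column 0 = intercept
    covariate_names: list[str]
    waic_result: WaicResult
    acceptance_rate: float

    def or_summary(self) -> pd.DataFrame:
        """Posterior mean and 95% CrI of exp(coef) per covariate."""
        draws = np.exp(self.coef_draws[:, 1:])
        lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
        return pd.DataFrame(
            {
                "covariate": self.covariate_names,
                "or_mean": draws.mean(axis=0),
                "ci_lo": lo,
                "ci_hi": hi,
            }
        )


def _log_posterior(
    coefs: np.ndarray, y: np.ndarray, W: np.ndarray, prior_sd: float
) -> float:
    eta = W @ coefs
    # log Bernoulli likelihood via logaddexp: log sigma(eta) = -log1p(exp(-eta))
    ll = -(np.logaddexp(0.0, -eta) * y + np.logaddexp(0.0, eta) * (1 - y)).sum()
    lp = -0.5 * (coefs**2).sum() / prior_sd**2
    return float(ll + lp)


def bayes_logistic(
    y: np.ndarray,
    covariates: np.ndarray | pd.DataFrame,
    prior_sd: float = 2.5,
    mcmc: McmcConfig | None = None,
) -> OutcomeFit:
    """Fit the Bayesian logistic model by adaptive random-walk Metropolis.

    Raises on a single-class outcome; warns (the prior regularizes) when
    the classes are perfectly separated by some covariate.
    """
    mcmc = mcmc if mcmc is not None else McmcConfig(iterations=6000, burn_in=2000, chains=2)
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        Xc = covariates.to_numpy(dtype=float)
    else:
        Xc = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Xc.shape[0] == 1 and Xc.size == len(y):
            Xc = Xc.T
        names = [f"x{i + 1}" for i in range(Xc.shape[1])]
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome has a single class; logistic fit impossible")
    if not np.isfinite(Xc).all():
        raise ValueError("covariates must be finite")
    N, p = Xc.shape
    if N <= p:
        raise ValueError("need more observations than covariates")
    for jj in range(p):
        col = Xc[:, jj]
        if col.var() > 0 and (
            col[y == 1].min() > col[y == 0].max()
            or col[y == 0].min() > col[y == 1].max()
        ):
            warnings.warn(
                f"covariate {names[jj]!r} perfectly separates the outcome; "
                "posterior is driven by the prior scale",
                stacklevel=2,
            )
    W = np.column_stack([np.ones(N), Xc])
    d = p + 1

    S_chain = mcmc.draws_per_chain
    draws = np.empty((S_chain * mcmc.chains, d))
    accepted_total = 0
    for chain in range(mcmc.chains):
        rng = np.random.default_rng(child_seed(mcmc.seed, f"logistic-chain-{chain}"))
        coefs = 0.1 * chain * rng.standard_normal(d)
        logp = _log_posterior(coefs, y, W, prior_sd)
        scale = 2.38 / np.sqrt(d)
        chol = np.eye(d) * 0.1
        history = np.zeros((mcmc.iterations, d))
        s = chain * S_chain
        accepted = 0
        for it in range(mcmc.iterations):
            prop = coefs + scale * (chol @ rng.standard_normal(d))
            logp_prop = _log_posterior(prop, y, W, prior_sd)
            if np.log(rng.uniform()) < logp_prop - logp:
                coefs, logp = prop, logp_prop
                accepted += 1
            history[it] = coefs
            # adapt proposal covariance during burn-in only
            if it < mcmc.burn_in and it >= 200 and it % 100 == 0:
                cov = np.cov(history[: it + 1].T) + 1e-8 * np.eye(d)
                chol = np.linalg.cholesky(cov)
            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                draws[s] = coefs
                s += 1
        accepted_total += accepted

    eta = draws @ W.T  # S x N
    loglik = -(
        np.logaddexp(0.0, -eta) * y[None, :] + np.logaddexp(0.0, eta) * (1 - y)[None, :]
    )
    return OutcomeFit(
        coef_draws=draws,
        covariate_names=names,
        waic_result=waic(loglik),
        acceptance_rate=accepted_total / (mcmc.iterations * mcmc.chains),
    )


def univariable_table(
    y: np.ndarray,
    covariates: pd.DataFrame,
    prior_sd: float = 2.5,
    mcmc: McmcConfig | None = None,
) -> pd.DataFrame:
    """One single-covariate fit per column; errors are reported per row."""
    rows = []
    for name in covariates.columns:
        try:
            f = bayes_logistic(y, covariates[[name]], prior_sd, mcmc)
            rows.append(f.or_summary().assign(covariate=name))
        except ValueError as err:
            rows.append(
                pd.DataFrame(
                    [{"covariate": name, "or_mean": np.nan, "ci_lo": np.nan,
                      "ci_hi": np.nan, "error": str(err)}]
                )
            )
    out = pd.concat(rows, ignore_index=True)
    out["analysis"] = "univariable"
    return out


def compare_index_vs_components(
    y: np.ndarray,
    index: np.ndarray,
    components: pd.DataFrame,
    prior_sd: float = 2.5,
    mcmc: McmcConfig | None = None,
    threshold: float = 5.0,
) -> dict:
    """Index-only vs all-components model, compared by WAIC.

    The parsimony argument for the index: it summarizes the correlated
    indicators in one number, so the single-covariate model should fit at
    least as well (by WAIC) as the saturated component model when the
    outcome depends on the indicators only through the latent trait.
    """
    index = np.asarray(index, dtype=float)
    if len(index) != len(y) or len(components) != len(y):
        raise ValueError("designs must share rows with the outcome")
    fit_index = bayes_logistic(y, index[:, None], prior_sd, mcmc)
    fit_comp = bayes_logistic(y, components, prior_sd, mcmc)
    report = compare_waic(fit_index.waic_result, fit_comp.waic_result, threshold)
    return {
        "index_waic": fit_index.waic_result.to_dict(),
        "components_waic": fit_comp.waic_result.to_dict(),
        "difference": report["difference"],
        "preferred": "index" if report["preferred"] == "a"
        else ("components" if report["preferred"] == "b" else "none"),
        "substantial": report["substantial"],
        "index_or": fit_index.or_summary().iloc[0].to_dict(),
    }
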