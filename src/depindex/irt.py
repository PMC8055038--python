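"""Hierarchical Bayesian two-parameter IRT fitted by data-augmentation Gibbs.

Model. Each binary deprivation indicator x_ij (person i, item j, province
k = k(i)) is generated by a latent utility

    x*_ij = alpha_jk + beta_jk * theta_i + eps_ij,   eps ~ N(0, 1),
    x_ij  = 1{x*_ij > 0},

so the response function is probit: P(x_ij = 1) = Phi(alpha_jk + beta_jk
theta_i). theta_i ~ N(0, 1) is the individual deprivation index; fixing its
location and scale identifies the model, and constraining every
discrimination beta_jk > 0 removes the reflection (theta, beta) <->
(-theta, -beta), which is legitimate because all items are coded so that 1
is the deprivation-associated level.

Two variants share the machinery:

- pooled: common item parameters alpha_j, beta_j across provinces, priors
  alpha_j ~ N(0, 2^2), beta_j ~ N(0, 2^2) truncated positive;
- hierarchical: province-specific alpha_jk ~ N(mu_j^a, tau_j^a2) and
  beta_jk ~ N(mu_j^b, tau_j^b2) (truncated positive), with hypermeans
  ~ N(0, 2^2) and tau^2 ~ Inverse-Gamma(2, 1).

Sampler. Augmenting with the latent utilities makes every full conditional
conjugate (the classic probit data-augmentation scheme): truncated-normal
utilities, normal theta updates, a bivariate-normal linear regression per
(item, province) cell for (alpha, beta), and normal/inverse-gamma hyper
updates. Each step is exposed as a module function so its closed form can
be unit-tested in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .containers import ItemResponseMatrix
from ._util import child_seed, truncnorm_onesided

__all__ = [
    "IrtModelSpec",
    "McmcConfig",
    "PosteriorDraws",
    "Diagnostics",
    "step_latent_utilities",
    "step_theta",
    "step_item_params",
    "step_hyper",
    "item_regression_posterior",
    "fit",
    "pointwise_loglik",
    "posterior_index",
]

logger = logging.getLogger(__name__)


@dataclass
class IrtModelSpec:
    """Model variant and prior settings."""

    variant: str = "hierarchical"  # "pooled" | "hierarchical"
    prior_loc_sd: float = 2.0  # sd of N(0, .) prior on pooled params / hypermeans
    # hypervariance prior: "half_cauchy" puts a half-Cauchy(A) on tau via the
    # inverse-gamma scale-mixture (heavy tail, mass near zero — adapts between
    # genuinely varying and exchangeable provinces); "inv_gamma" is a plain
    # conjugate Inverse-Gamma(shape, scale) on tau^2
    hyper_tau_prior: str = "half_cauchy"
    hyper_tau_cauchy_scale: float = 1.0  # A of half-Cauchy(A) on tau
    hyper_tau_shape: float = 2.0  # inverse-gamma shape for tau^2
    hyper_tau_scale: float = 1.0  # inverse-gamma scale for tau^2

    def __post_init__(self) -> None:
        if self.variant not in ("pooled", "hierarchical"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.hyper_tau_prior not in ("half_cauchy", "inv_gamma"):
            raise ValueError(f"unknown hyper_tau_prior {self.hyper_tau_prior!r}")
        if (
            min(
                self.prior_loc_sd,
                self.hyper_tau_shape,
                self.hyper_tau_scale,
                self.hyper_tau_cauchy_scale,
            )
            <= 0
        ):
            raise ValueError("all prior scales must be positive")


@dataclass
class McmcConfig:
    iterations: int = 5000
    burn_in: int = 2500
    thin: int = 1
    chains: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("need 0 <= burn_in < iterations")
        if self.thin < 1 or self.chains < 1:
            raise ValueError("thin and chains must be >= 1")

    @property
    def draws_per_chain(self) -> int:
        return (self.iterations - self.burn_in + self.thin - 1) // self.thin


@dataclass
class PosteriorDraws:
    """Post-burn-in, thinned MCMC draws, chain-tagged."""

    alpha: np.ndarray  # S x J x K
    beta: np.ndarray  # S x J x K
    theta: np.ndarray  # S x N
    chain_id: np.ndarray  # S
    spec: IrtModelSpec
    item_labels: list[str]
    province_labels: list[str]
    province_idx: np.ndarray  # N (model cell per person; all 0 when pooled)
    ids: pd.Index
    person_province: np.ndarray | None = None  # N observed labels, for export
    mu_alpha: np.ndarray | None = None  # S x J (hierarchical)
    mu_beta: np.ndarray | None = None
    tau2_alpha: np.ndarray | None = None
    tau2_beta: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[0]

    def long_frame(self, include_theta: bool = False) -> pd.DataFrame:
        """Draws in long format (chain, iter, parameter, value) for export."""
        rows = []
        S, J, K = self.alpha.shape
        it = np.arange(S)
        for j, item in enumerate(self.item_labels):
            for k, prov in enumerate(self.province_labels):
                for name, arr in (("alpha", self.alpha), ("beta", self.beta)):
                    rows.append(
                        pd.DataFrame(
                            {
                                "chain": self.chain_id,
                                "iter": it,
                                "parameter": f"{name}[{item},{prov}]",
                                "value": arr[:, j, k],
                            }
                        )
                    )
        if include_theta:
            for i, pid in enumerate(self.ids):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": self.chain_id,
                            "iter": it,
                            "parameter": f"theta[{pid}]",
                            "value": self.theta[:, i],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


@dataclass
class Diagnostics:
    rhat: dict[str, np.ndarray] = field(default_factory=dict)
    ess: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def max_rhat(self) -> float:
        vals = [np.nanmax(v) for v in self.rhat.values() if np.size(v)]
        return float(max(vals)) if vals else float("nan")

    @property
    def min_ess(self) -> float:
        vals = [np.nanmin(v) for v in self.ess.values() if np.size(v)]
        return float(min(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# Gibbs full conditionals
# ---------------------------------------------------------------------------


def step_latent_utilities(
    X: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
    theta: np.ndarray,
    province_idx: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw x*_ij ~ N(alpha_jk + beta_jk theta_i, 1) truncated by the response.

    Positive side (0, inf) when x_ij = 1, (-inf, 0] when x_ij = 0.
    """
    mean = alpha.T[province_idx] + beta.T[province_idx] * theta[:, None]
    return truncnorm_onesided(mean, X > 0.5, rng)


def theta_full_conditional(
    x_star: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
    province_idx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form mean and variance of theta_i | x*, alpha, beta.

    Under the N(0,1) prior: V_i = (1 + sum_j beta_jk^2)^{-1} and
    m_i = V_i sum_j beta_jk (x*_ij - alpha_jk).
    """
    B = beta.T[province_idx]  # N x J
    A = alpha.T[province_idx]
    V = 1.0 / (1.0 + (B**2).sum(axis=1))
    m = V * (B * (x_star - A)).sum(axis=1)
    return m, V


def step_theta(
    x_star: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
    province_idx: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Conjugate trait update under the N(0,1) prior."""
    m, V = theta_full_conditional(x_star, alpha, beta, province_idx)
    return m + np.sqrt(V) * rng.standard_normal(m.shape)


def item_regression_posterior(
    x_star_j: np.ndarray,
    theta: np.ndarray,
    prior_mean: np.ndarray,
    prior_var: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact bivariate-normal posterior of (alpha, beta) for one cell.

    Linear regression of the cell's utilities on (1, theta) with unit
    residual variance and independent normal priors on the two
    coefficients. ``prior_var`` entries may be ``np.inf`` (flat).
    Returns (mean, covariance); the beta > 0 constraint is applied at the
    sampling stage, not here.
    """
    theta = np.asarray(theta, dtype=float)
    x = np.asarray(x_star_j, dtype=float)
    prior_var = np.asarray(prior_var, dtype=float)
    prior_prec = np.where(np.isfinite(prior_var), 1.0 / prior_var, 0.0)
    n = theta.size
    # 2x2 precision = W'W + diag(prior precision), W = [1, theta]; analytic
    p00 = n + prior_prec[0]
    p01 = theta.sum()
    p11 = (theta**2).sum() + prior_prec[1]
    det = p00 * p11 - p01**2
    if det <= 1e-12 * max(p00 * p11, 1.0):
        raise np.linalg.LinAlgError(
            "degenerate item regression: trait values carry no information"
        )
    cov = np.array([[p11, -p01], [-p01, p00]]) / det
    b = np.array(
        [
            x.sum() + prior_prec[0] * prior_mean[0],
            theta @ x + prior_prec[1] * prior_mean[1],
        ]
    )
    return cov @ b, cov


def _sample_cell(
    mean: np.ndarray,
    cov: np.ndarray,
    beta_current: float,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Two-block sub-Gibbs on one cell's constrained bivariate posterior.

    alpha | beta is normal; beta | alpha is normal truncated to (0, inf).
    The constrained joint is the exact invariant distribution of this scan.
    """
    va, vb, cab = cov[0, 0], cov[1, 1], cov[0, 1]
    # alpha | beta
    m_a = mean[0] + cab / vb * (beta_current - mean[1])
    s2_a = va - cab**2 / vb
    alpha = m_a + np.sqrt(max(s2_a, 0.0)) * rng.standard_normal()
    # beta | alpha, truncated > 0
    m_b = mean[1] + cab / va * (alpha - mean[0])
    s_b = np.sqrt(max(vb - cab**2 / va, 1e-300))
    beta = float(
        truncnorm_onesided(np.array([m_b / s_b]), np.array([True]), rng)[0] * s_b
    )
    return float(alpha), beta


def step_item_params(
    x_star: np.ndarray,
    theta: np.ndarray,
    province_idx: np.ndarray,
    prior_mean_alpha: np.ndarray,
    prior_var_alpha: np.ndarray,
    prior_mean_beta: np.ndarray,
    prior_var_beta: np.ndarray,
    beta_current: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Update every (item, province) cell's (alpha_jk, beta_jk).

    Priors are independent normals per coordinate (J-vectors, shared across
    provinces within an item); beta is kept positive by drawing its block
    from the positive-truncated conditional.
    """
    J = x_star.shape[1]
    K = int(province_idx.max()) + 1
    alpha_new = np.empty((J, K))
    beta_new = np.empty((J, K))
    pp_a = np.where(np.isfinite(prior_var_alpha), 1.0 / prior_var_alpha, 0.0)
    pp_b = np.where(np.isfinite(prior_var_beta), 1.0 / prior_var_beta, 0.0)
    for k in range(K):
        sel = province_idx == k
        th = theta[sel]
        xs = x_star[sel]
        n_k, s1, s2 = th.size, th.sum(), (th**2).sum()
        # per-item 2x2 posterior, all items of province k at once
        p00 = n_k + pp_a
        p11 = s2 + pp_b
        det = p00 * p11 - s1**2
        if np.any(det <= 1e-12 * np.maximum(p00 * p11, 1.0)):
            raise np.linalg.LinAlgError(
                "degenerate item regression: trait values carry no information"
            )
        c00, c11, c01 = p11 / det, p00 / det, -s1 / det
        b0 = xs.sum(axis=0) + pp_a * prior_mean_alpha
        b1 = th @ xs + pp_b * prior_mean_beta
        m_a = c00 * b0 + c01 * b1
        m_b = c01 * b0 + c11 * b1
        # two-block sub-Gibbs: alpha | beta normal, beta | alpha truncated > 0
        alpha = (
            m_a
            + c01 / c11 * (beta_current[:, k] - m_b)
            + np.sqrt(np.maximum(c00 - c01**2 / c11, 0.0)) * rng.standard_normal(J)
        )
        mb_cond = m_b + c01 / c00 * (alpha - m_a)
        sb_cond = np.sqrt(np.maximum(c11 - c01**2 / c00, 1e-300))
        beta = (
            truncnorm_onesided(mb_cond / sb_cond, np.ones(J, dtype=bool), rng) * sb_cond
        )
        alpha_new[:, k] = alpha
        beta_new[:, k] = beta
    return alpha_new, beta_new


def refresh_item_params_collapsed(
    X: np.ndarray,
    theta: np.ndarray,
    province_idx: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
    prior_mean_alpha: np.ndarray,
    prior_var_alpha: np.ndarray,
    prior_mean_beta: np.ndarray,
    prior_var_beta: np.ndarray,
    rng: np.random.Generator,
    scale: float = 2.38**2 / 2.0,
    prop_chol: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Metropolis refresh of (alpha_jk, beta_jk) with the utilities collapsed.

    The data-augmentation update of the item parameters mixes slowly for
    low-prevalence items: their (alpha, beta) posterior is a long banana
    ridge and the utilities move in near-lockstep with the intercept. This
    extra step targets p(alpha, beta | theta, x, hyper) directly — a
    two-parameter probit-regression posterior per cell — with a symmetric
    Gaussian proposal. ``prop_chol`` (J x K x 2 x 2 lower-triangular, e.g.
    adapted from burn-in draws) shapes the proposal; without it the
    conjugate regression covariance is used. Either way the step leaves the
    same joint posterior invariant and decorrelates successive
    item-parameter draws.
    """
    J = X.shape[1]
    K = int(province_idx.max()) + 1
    alpha = alpha.copy()
    beta = beta.copy()
    pp_a = np.where(np.isfinite(prior_var_alpha), 1.0 / prior_var_alpha, 0.0)
    pp_b = np.where(np.isfinite(prior_var_beta), 1.0 / prior_var_beta, 0.0)
    for k in range(K):
        sel = province_idx == k
        th = theta[sel]
        xk = X[sel]  # n_k x J
        sign = np.where(xk > 0.5, 1.0, -1.0)
        z = rng.standard_normal((2, J))
        root_scale = np.sqrt(scale)
        if prop_chol is not None:
            l00 = root_scale * prop_chol[:, k, 0, 0]
            l10 = root_scale * prop_chol[:, k, 1, 0]
            l11 = root_scale * prop_chol[:, k, 1, 1]
        else:
            n_k, s1, s2 = th.size, th.sum(), (th**2).sum()
            p00, p11 = n_k + pp_a, s2 + pp_b
            det = p00 * p11 - s1**2
            v00, v11, v01 = p11 / det, p00 / det, -s1 / det
            # cholesky of scale * cov, per item (analytic 2x2)
            l00 = np.sqrt(scale * v00)
            l10 = scale * v01 / l00
            l11 = np.sqrt(np.maximum(scale * v11 - l10**2, 1e-300))
        a_prop = alpha[:, k] + l00 * z[0]
        b_prop = beta[:, k] + l10 * z[0] + l11 * z[1]

        def cell_logpost(a: np.ndarray, b: np.ndarray) -> np.ndarray:
            eta = a[None, :] + b[None, :] * th[:, None]
            ll = special.log_ndtr(sign * eta).sum(axis=0)
            lp = -0.5 * pp_a * (a - prior_mean_alpha) ** 2
            lp = lp - 0.5 * pp_b * (b - prior_mean_beta) ** 2
            return ll + lp

        logp_cur = cell_logpost(alpha[:, k], beta[:, k])
        valid = b_prop > 0
        logp_prop = np.full(J, -np.inf)
        if valid.any():
            logp_prop[valid] = cell_logpost(a_prop, b_prop)[valid]
        accept = np.log(rng.uniform(size=J)) < logp_prop - logp_cur
        alpha[accept, k] = a_prop[accept]
        beta[accept, k] = b_prop[accept]
    return alpha, beta


def mu_full_conditional(
    values: np.ndarray, tau2: np.ndarray, spec: IrtModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form mean and variance of the per-item hypermean update."""
    K = values.shape[1]
    prior_prec = 1.0 / spec.prior_loc_sd**2
    prec = K / tau2 + prior_prec
    return (values.sum(axis=1) / tau2) / prec, 1.0 / prec


def tau2_full_conditional(
    values: np.ndarray, mu: np.ndarray, spec: IrtModelSpec
) -> tuple[float, np.ndarray]:
    """Closed-form inverse-gamma (shape, scale) of the hypervariance update."""
    K = values.shape[1]
    ss = ((values - mu[:, None]) ** 2).sum(axis=1)
    return spec.hyper_tau_shape + K / 2.0, spec.hyper_tau_scale + ss / 2.0


def step_hyper(
    values: np.ndarray,
    tau2: np.ndarray,
    spec: IrtModelSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Conjugate hyper update for one parameter family (alpha or beta).

    ``values`` is J x K (province-level draws per item). Per item j:
    mu_j | . ~ N over the K values with prior N(0, prior_loc_sd^2), then
    tau2_j | . ~ Inverse-Gamma(shape + K/2, scale + SS/2).
    """
    J = values.shape[0]
    mu_mean, mu_var = mu_full_conditional(values, tau2, spec)
    mu = mu_mean + rng.standard_normal(J) * np.sqrt(mu_var)
    shape, scale = tau2_full_conditional(values, mu, spec)
    tau2_new = scale / rng.gamma(shape, 1.0, size=J)
    return mu, tau2_new


def step_hyper_half_cauchy(
    values: np.ndarray,
    tau2: np.ndarray,
    eta: np.ndarray,
    spec: IrtModelSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hyper update under a half-Cauchy(A) prior on tau, per item.

    Uses the inverse-gamma scale mixture (tau^2 | eta ~ IG(1/2, 1/eta),
    eta ~ IG(1/2, 1/A^2) gives tau ~ half-Cauchy(A)), so every conditional
    stays conjugate:

        tau2_j | . ~ IG(1/2 + K/2, 1/eta_j + SS_j/2)
        eta_j  | . ~ IG(1,       1/A^2 + 1/tau2_j)
    """
    J, K = values.shape
    mu_mean, mu_var = mu_full_conditional(values, tau2, spec)
    mu = mu_mean + rng.standard_normal(J) * np.sqrt(mu_var)
    ss = ((values - mu[:, None]) ** 2).sum(axis=1)
    tau2_new = (1.0 / eta + ss / 2.0) / rng.gamma(0.5 + K / 2.0, 1.0, size=J)
    eta_new = (
        1.0 / spec.hyper_tau_cauchy_scale**2 + 1.0 / tau2_new
    ) / rng.gamma(1.0, 1.0, size=J)
    return mu, tau2_new, eta_new


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _chol2x2(cov: np.ndarray) -> np.ndarray:
    """Lower-triangular cholesky of stacked 2x2 covariances, jitter-floored."""
    c00 = np.maximum(cov[..., 0, 0], 1e-6)
    c11 = np.maximum(cov[..., 1, 1], 1e-6)
    c01 = cov[..., 0, 1]
    out = np.zeros_like(cov)
    out[..., 0, 0] = np.sqrt(c00)
    out[..., 1, 0] = c01 / out[..., 0, 0]
    out[..., 1, 1] = np.sqrt(np.maximum(c11 - out[..., 1, 0] ** 2, 1e-6))
    return out


def _initial_values(
    X: np.ndarray, J: int, K: int, chain: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dispersed starts: probit-transformed prevalences, beta = 1, theta from
    standardized row sums, all jittered per chain."""
    prev = np.clip(X.mean(axis=0), 0.02, 0.98)
    alpha0 = np.tile(special.ndtri(prev)[:, None] * np.sqrt(2.0), (1, K))
    alpha0 += 0.25 * chain * rng.standard_normal(alpha0.shape)
    beta0 = np.clip(1.0 + 0.25 * chain * rng.standard_normal((J, K)), 0.2, None)
    rows = X.sum(axis=1).astype(float)
    sd = rows.std()
    theta0 = (rows - rows.mean()) / (sd if sd > 0 else 1.0)
    theta0 += 0.25 * chain * rng.standard_normal(theta0.shape)
    return alpha0, beta0, theta0


def fit(
    X: ItemResponseMatrix, spec: IrtModelSpec, mcmc: McmcConfig
) -> tuple[PosteriorDraws, Diagnostics]:
    """Run the Gibbs sampler on complete-case data.

    The pooled variant ignores province labels (all persons share one item
    parameter column); the hierarchical variant adds the hyper level.
    Deterministic given ``mcmc.seed``.
    """
    resp = X.responses
    if resp.isna().any().any():
        raise ValueError("fit requires complete cases; run complete_cases() first")
    Xv = resp.to_numpy(dtype=float)
    N, J = Xv.shape
    var0 = Xv.var(axis=0)
    if (var0 == 0).any():
        bad = resp.columns[int(np.argmax(var0 == 0))]
        raise ValueError(f"item {bad!r} has zero variance; cannot be fitted")

    hierarchical = spec.variant == "hierarchical"
    if hierarchical:
        prov_labels = X.provinces
        prov_idx = X.province_index(prov_labels)
    else:
        prov_labels = ["pooled"]
        prov_idx = np.zeros(N, dtype=int)
    K = len(prov_labels)

    S_chain = mcmc.draws_per_chain
    S = S_chain * mcmc.chains
    alpha_d = np.empty((S, J, K))
    beta_d = np.empty((S, J, K))
    theta_d = np.empty((S, N))
    chain_id = np.repeat(np.arange(mcmc.chains), S_chain)
    mu_a_d = np.empty((S, J)) if hierarchical else None
    mu_b_d = np.empty((S, J)) if hierarchical else None
    t2_a_d = np.empty((S, J)) if hierarchical else None
    t2_b_d = np.empty((S, J)) if hierarchical else None

    for chain in range(mcmc.chains):
        rng = np.random.default_rng(child_seed(mcmc.seed, f"irt-chain-{chain}"))
        alpha, beta, theta = _initial_values(Xv, J, K, chain, rng)
        mu_a = np.zeros(J)
        mu_b = np.zeros(J)
        t2_a = np.full(J, spec.prior_loc_sd**2)
        t2_b = np.full(J, spec.prior_loc_sd**2)
        eta_a = np.ones(J)
        eta_b = np.ones(J)
        s = chain * S_chain
        # adaptive proposal covariance for the collapsed refresh: Welford
        # over the burn-in (alpha, beta) trajectory per cell, frozen after
        w_count = 0
        w_mean = np.zeros((J, K, 2))
        w_m2 = np.zeros((J, K, 2, 2))
        prop_chol: np.ndarray | None = None
        for it in range(mcmc.iterations):
            x_star = step_latent_utilities(Xv, alpha, beta, theta, prov_idx, rng)
            theta = step_theta(x_star, alpha, beta, prov_idx, rng)
            alpha, beta = step_item_params(
                x_star, theta, prov_idx, mu_a, t2_a, mu_b, t2_b, beta, rng
            )
            for _ in range(2):
                alpha, beta = refresh_item_params_collapsed(
                    Xv, theta, prov_idx, alpha, beta, mu_a, t2_a, mu_b, t2_b,
                    rng, prop_chol=prop_chol,
                )
            if it < mcmc.burn_in:
                w_count += 1
                v = np.stack([alpha, beta], axis=-1)
                d = v - w_mean
                w_mean += d / w_count
                w_m2 += d[..., :, None] * (v - w_mean)[..., None, :]
                if w_count >= 100 and w_count % 50 == 0:
                    prop_chol = _chol2x2(w_m2 / (w_count - 1))
            if hierarchical and K >= 2:
                if spec.hyper_tau_prior == "half_cauchy":
                    mu_a, t2_a, eta_a = step_hyper_half_cauchy(
                        alpha, t2_a, eta_a, spec, rng
                    )
                    mu_b, t2_b, eta_b = step_hyper_half_cauchy(
                        beta, t2_b, eta_b, spec, rng
                    )
                else:
                    mu_a, t2_a = step_hyper(alpha, t2_a, spec, rng)
                    mu_b, t2_b = step_hyper(beta, t2_b, spec, rng)
            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                alpha_d[s] = alpha
                beta_d[s] = beta
                theta_d[s] = theta
                if hierarchical:
                    mu_a_d[s], mu_b_d[s] = mu_a, mu_b
                    t2_a_d[s], t2_b_d[s] = t2_a, t2_b
                s += 1

    draws = PosteriorDraws(
        alpha=alpha_d,
        beta=beta_d,
        theta=theta_d,
        chain_id=chain_id,
        spec=spec,
        item_labels=list(resp.columns),
        province_labels=prov_labels,
        province_idx=prov_idx,
        ids=resp.index,
        person_province=X.province.to_numpy(dtype=object),
        mu_alpha=mu_a_d,
        mu_beta=mu_b_d,
        tau2_alpha=t2_a_d,
        tau2_beta=t2_b_d,
    )
    return draws, compute_diagnostics(draws, mcmc)


def compute_diagnostics(draws: PosteriorDraws, mcmc: McmcConfig) -> Diagnostics:
    """R-hat and effective sample size for the item parameters (via arviz)."""
    import arviz as az

    S_chain = draws.n_draws // mcmc.chains
    diag = Diagnostics()
    for name, arr in (("alpha", draws.alpha), ("beta", draws.beta)):
        chained = arr.reshape(mcmc.chains, S_chain, *arr.shape[1:])
        if mcmc.chains >= 2 and S_chain >= 4:
            ds = az.convert_to_dataset({name: chained})
            diag.rhat[name] = np.asarray(az.rhat(ds)[name])
            diag.ess[name] = np.asarray(az.ess(ds)[name])
        else:
            diag.rhat[name] = np.full(arr.shape[1:], np.nan)
            diag.ess[name] = np.full(arr.shape[1:], np.nan)
    return diag


# ---------------------------------------------------------------------------
# Posterior functionals
# ---------------------------------------------------------------------------


def pointwise_loglik(
    draws: PosteriorDraws, X: ItemResponseMatrix, chunk: int = 500
) -> np.ndarray:
    """S x (N*J) pointwise log-likelihood, conditional on the theta draws.

    Entry (s, (i, j)) = log Phi(eta) if x_ij = 1 else log Phi(-eta), with
    eta = alpha_jk^(s) + beta_jk^(s) theta_i^(s); computed through the
    log-CDF so saturated cells do not underflow.
    """
    Xv = X.responses.to_numpy(dtype=float)
    if np.isnan(Xv).any():
        raise ValueError("pointwise_loglik requires complete cases")
    prov = draws.province_idx
    S, N, J = draws.n_draws, Xv.shape[0], Xv.shape[1]
    out = np.empty((S, N * J))
    sign = np.where(Xv > 0.5, 1.0, -1.0)  # N x J
    for s0 in range(0, S, chunk):
        sl = slice(s0, min(s0 + chunk, S))
        a = draws.alpha[sl][:, :, prov].transpose(0, 2, 1)  # c x N x J
        b = draws.beta[sl][:, :, prov].transpose(0, 2, 1)
        eta = a + b * draws.theta[sl][:, :, None]
        out[sl] = special.log_ndtr(sign * eta).reshape(sl.stop - sl.start, N * J)
    return out


def posterior_index(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-person posterior summary of the deprivation index theta.

    Columns: id, province, theta_mean, theta_sd, q2.5, q50, q97.5 — the
    boxplot-ready export of individual scores grouped by province.
    """
    th = draws.theta
    q = np.percentile(th, [2.5, 50.0, 97.5], axis=0)
    if draws.person_province is not None:
        prov = draws.person_province
    else:
        prov = np.asarray(draws.province_labels, dtype=object)[draws.province_idx]
    return pd.DataFrame(
        {
            "id": draws.ids,
            "province": prov,
            "theta_mean": th.mean(axis=0),
            "theta_sd": th.std(axis=0, ddof=1),
            "q2.5": q[0],
            "q50": q[1],
            "q97.5": q[2],
        }
    )
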