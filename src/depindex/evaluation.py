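"""Model comparison by WAIC and item characteristic curves.

WAIC (widely applicable information criterion) from an S x n pointwise
log-likelihood matrix (S posterior draws, n observations; here one
observation = one person-item response):

    lppd   = sum_i log( mean_s exp(ll_si) )        (log-sum-exp, stable)
    p_waic = sum_i var_s(ll_si)                     (sample variance, S-1)
    WAIC   = -2 (lppd - p_waic)
    SE     = sqrt( n * var_i(waic_i) ),  waic_i = -2 (lppd_i - p_waic_i)

Lower WAIC is better; a difference of at least 5 is treated as substantial.

The item characteristic curve (ICC) reports the posterior endorsement
probability Phi(alpha_jk + beta_jk * theta) over a grid of the deprivation
index theta. Under the probit parameterisation the curve's inflection sits
at theta = -alpha/beta (where the probability is exactly 0.5) and beta is
its slope scale, so the familiar location/discrimination reading carries
over via the transformation (-alpha/beta, beta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .irt import PosteriorDraws, pointwise_loglik
from .containers import ItemResponseMatrix

__all__ = [
    "WaicResult",
    "ICCCurve",
    "waic",
    "waic_from_fit",
    "compare_waic",
    "icc_curve",
    "discrimination_table",
]


@dataclass
class WaicResult:
    lppd: float
    p_waic: float
    waic: float
    se: float
    n_obs: int

    def __post_init__(self) -> None:
        if self.p_waic < 0:
            raise ValueError("p_waic must be non-negative")
        if abs(self.waic - (-2.0 * (self.lppd - self.p_waic))) > 1e-8:
            raise ValueError("waic inconsistent with lppd and p_waic")

    def to_dict(self) -> dict:
        return {
            "lppd": self.lppd,
            "p_waic": self.p_waic,
            "waic": self.waic,
            "se": self.se,
            "n_obs": self.n_obs,
        }


def _waic_from_pointwise(lppd_i: np.ndarray, p_waic_i: np.ndarray) -> WaicResult:
    n = lppd_i.size
    waic_i = -2.0 * (lppd_i - p_waic_i)
    lppd = float(lppd_i.sum())
    p_waic = float(p_waic_i.sum())
    se = float(np.sqrt(n * np.var(waic_i, ddof=1))) if n > 1 else 0.0
    return WaicResult(lppd, p_waic, -2.0 * (lppd - p_waic), se, n)


def waic(loglik: np.ndarray) -> WaicResult:
    """WAIC from a full S x n pointwise log-likelihood matrix."""
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("loglik must be S x n with S >= 2")
    if not np.all(np.isfinite(ll)):
        raise ValueError("loglik entries must be finite")
    S = ll.shape[0]
    lppd_i = special.logsumexp(ll, axis=0) - np.log(S)
    p_waic_i = ll.var(axis=0, ddof=1)
    return _waic_from_pointwise(lppd_i, p_waic_i)


def waic_from_fit(
    draws: PosteriorDraws, X: ItemResponseMatrix, chunk: int = 250
) -> WaicResult:
    """WAIC of an IRT fit without materialising the full S x (N*J) matrix.

    Streams over draw chunks with an online log-sum-exp for lppd and a
    Welford accumulator for the pointwise variances; algebraically
    identical to :func:`waic` on the full matrix.
    """
    Xv = X.responses.to_numpy(dtype=float)
    n = Xv.size
    S = draws.n_draws
    if S < 2:
        raise ValueError("need at least two draws")
    lse = np.full(n, -np.inf)
    mean = np.zeros(n)
    m2 = np.zeros(n)
    count = 0
    prov = draws.province_idx
    sign = np.where(Xv > 0.5, 1.0, -1.0)
    for s0 in range(0, S, chunk):
        sl = slice(s0, min(s0 + chunk, S))
        a = draws.alpha[sl][:, :, prov].transpose(0, 2, 1)
        b = draws.beta[sl][:, :, prov].transpose(0, 2, 1)
        ll = special.log_ndtr(
            sign * (a + b * draws.theta[sl][:, :, None])
        ).reshape(-1, n)
        lse = np.logaddexp(lse, special.logsumexp(ll, axis=0))
        # pairwise (Chan et al.) combine of chunk mean/SS into running stats
        n_c = ll.shape[0]
        m_c = ll.mean(axis=0)
        ss_c = ((ll - m_c) ** 2).sum(axis=0)
        if count == 0:
            mean, m2, count = m_c, ss_c, n_c
        else:
            delta = m_c - mean
            tot = count + n_c
            m2 = m2 + ss_c + delta**2 * (count * n_c / tot)
            mean = (count * mean + n_c * m_c) / tot
            count = tot
    lppd_i = lse - np.log(S)
    p_waic_i = m2 / (S - 1)
    return _waic_from_pointwise(lppd_i, p_waic_i)


def compare_waic(a: WaicResult, b: WaicResult, threshold: float = 5.0) -> dict:
    """Report WAIC difference (a - b), preference, and the substantial flag."""
    if a.n_obs != b.n_obs:
        raise ValueError("WAIC comparison requires identical n_obs")
    diff = a.waic - b.waic
    preferred = "a" if a.waic < b.waic else ("b" if b.waic < a.waic else "none")
    return {
        "waic_a": a.waic,
        "waic_b": b.waic,
        "difference": diff,
        "preferred": preferred,
        "substantial": bool(abs(diff) >= threshold),
        "threshold": threshold,
    }


# ---------------------------------------------------------------------------
# Item characteristic curves
# ---------------------------------------------------------------------------


@dataclass
class ICCCurve:
    item: str
    province: str  # province label or "overall"
    theta_grid: np.ndarray
    prob_mean: np.ndarray
    prob_lo: np.ndarray
    prob_hi: np.ndarray
    inflection_location: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.theta_grid) <= 0):
            raise ValueError("theta_grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item": self.item,
                "province": self.province,
                "theta": self.theta_grid,
                "mean": self.prob_mean,
                "lo": self.prob_lo,
                "hi": self.prob_hi,
            }
        )


def _cell_draws(
    draws: PosteriorDraws, item: str, province: str, overall: str = "hypermean"
) -> tuple[np.ndarray, np.ndarray]:
    if item not in draws.item_labels:
        raise KeyError(f"unknown item {item!r}")
    j = draws.item_labels.index(item)
    if province == "overall":
        if draws.mu_alpha is not None:
            if overall == "hypermean":
                return draws.mu_alpha[:, j], draws.mu_beta[:, j]
            # alternative: average of the province-level parameters
            return draws.alpha[:, j].mean(axis=1), draws.beta[:, j].mean(axis=1)
        return draws.alpha[:, j, 0], draws.beta[:, j, 0]  # pooled: common params
    if province not in draws.province_labels:
        raise KeyError(f"unknown province {province!r}")
    k = draws.province_labels.index(province)
    return draws.alpha[:, j, k], draws.beta[:, j, k]


def icc_curve(
    draws: PosteriorDraws,
    item: str,
    province: str,
    theta_grid: np.ndarray | None = None,
    overall: str = "hypermean",
) -> ICCCurve:
    """Posterior ICC for one item in one province (or "overall").

    Per grid point: posterior mean and central 95% interval of
    Phi(alpha + beta*theta) over the draws. ``overall`` uses the item's
    hypermean draws (hierarchical) or the common parameters (pooled);
    ``overall="average"`` averages the province-level parameters instead.
    """
    grid = (
        np.asarray(theta_grid, dtype=float)
        if theta_grid is not None
        else np.linspace(-3.0, 3.0, 61)
    )
    a, b = _cell_draws(draws, item, province, overall)
    probs = special.ndtr(a[:, None] + b[:, None] * grid[None, :])
    lo, hi = np.percentile(probs, [2.5, 97.5], axis=0)
    return ICCCurve(
        item=item,
        province=province,
        theta_grid=grid,
        prob_mean=probs.mean(axis=0),
        prob_lo=lo,
        prob_hi=hi,
        inflection_location=float(np.mean(-a / b)),
    )


def discrimination_table(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior summaries of beta_jk and inflection -alpha/beta per cell.

    Ranked by posterior mean discrimination (largest first), mirroring the
    reading that the items with the highest discriminatory parameters
    separate deprivation levels best.
    """
    rows = []
    for j, item in enumerate(draws.item_labels):
        for k, prov in enumerate(draws.province_labels):
            b = draws.beta[:, j, k]
            infl = -draws.alpha[:, j, k] / b
            rows.append(
                {
                    "item": item,
                    "province": prov,
                    "beta_mean": b.mean(),
                    "beta_sd": b.std(ddof=1),
                    "beta_q2.5": np.percentile(b, 2.5),
                    "beta_q97.5": np.percentile(b, 97.5),
                    "inflection_mean": infl.mean(),
                    "inflection_q2.5": np.percentile(infl, 2.5),
                    "inflection_q97.5": np.percentile(infl, 97.5),
                }
            )
    return (
        pd.DataFrame(rows)
        .sort_values("beta_mean", ascending=False)
        .reset_index(drop=True)
    )
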