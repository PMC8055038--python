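"""Synthetic cohort generator with known ground truth.

The original coinfection-cohort records are not public, so every downstream
stage is exercised on simulated cohorts whose statistical structure mirrors
the published baseline table: four provinces (Quebec, Ontario, British
Columbia, Saskatchewan) of sizes 613/409/563/197, nineteen dichotomous
deprivation-direction indicators with province-specific prevalences, MCAR
missingness at the published per-cell rates (0-13%), and a binary
second-visit non-attendance outcome generated from the latent trait with a
marginal rate near 30%.

Generative model (latent-normal / probit 2PL): theta_i ~ N(0,1) per person,
x*_ij = alpha_jk + beta_jk * theta_i + eps_ij with eps ~ N(0,1), and
x_ij = 1{x* > 0}, where k is person i's province. Marginally over theta the
endorsement probability of item j in province k is
Phi(alpha_jk / sqrt(1 + beta_jk^2)), which is inverted by
:func:`calibrate_alpha` to hit a target prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .containers import ItemResponseMatrix
from ._util import child_seed

__all__ = [
    "CohortConfig",
    "TruthRecord",
    "calibrate_alpha",
    "simulate_items",
    "apply_missingness",
    "simulate_outcome",
    "calibrate_outcome_intercept",
    "default_config",
    "fictitious_sample",
    "PROVINCES",
    "PROVINCE_SIZES",
    "CANDIDATE_ITEMS",
    "PAPER9_ITEMS",
    "BASELINE_COUNTS",
]

# ---------------------------------------------------------------------------
# Published baseline-table calibration
# ---------------------------------------------------------------------------

PROVINCES = ["Quebec", "Ontario", "British Columbia", "Saskatchewan"]
PROVINCE_SIZES = [613, 409, 563, 197]

# (deprived count, non-deprived count, missing count) per province, in the
# order of PROVINCES. "Deprived" is the level coded 1.
BASELINE_COUNTS: dict[str, list[tuple[int, int, int]]] = {
    "education_hs_or_less": [(461, 149, 3), (255, 153, 1), (400, 152, 11), (179, 17, 1)],
    "vulnerably_housed": [(107, 493, 13), (18, 391, 0), (59, 498, 6), (17, 180, 0)],
    "living_alone": [(359, 241, 13), (200, 209, 0), (336, 221, 6), (69, 128, 0)],
    "income_lt_1500": [(508, 99, 6), (265, 139, 5), (426, 129, 8), (158, 29, 10)],
    "not_married": [(520, 76, 17), (311, 98, 0), (439, 113, 11), (145, 52, 0)],
    "unemployed": [(486, 126, 1), (319, 89, 1), (444, 111, 8), (162, 34, 1)],
    "non_gbmsm": [(456, 151, 6), (254, 154, 1), (445, 103, 15), (190, 7, 0)],
    "indigenous": [(17, 585, 11), (61, 347, 1), (188, 370, 5), (160, 36, 1)],
    "incarceration": [(395, 199, 19), (205, 171, 33), (350, 139, 74), (158, 33, 6)],
    "idu_ever": [(502, 109, 2), (279, 130, 0), (484, 73, 6), (182, 15, 0)],
    "idu_6mo": [(223, 385, 5), (97, 312, 0), (237, 319, 7), (107, 90, 0)],
    "snorted_6mo": [(144, 446, 23), (71, 323, 15), (104, 427, 32), (35, 158, 4)],
    "sex_client_ever": [(183, 421, 9), (94, 311, 4), (136, 413, 14), (23, 174, 0)],
    "sex_work_ever": [(188, 417, 8), (80, 328, 1), (213, 340, 10), (46, 151, 0)],
    "sex_work_6mo": [(41, 561, 11), (9, 395, 5), (39, 501, 23), (11, 130, 56)],
    "depression": [(193, 419, 1), (239, 170, 0), (337, 224, 2), (109, 88, 0)],
    "psych_hospital": [(127, 466, 20), (99, 310, 0), (149, 406, 8), (43, 154, 0)],
    "schizophrenia": [(22, 510, 81), (7, 399, 3), (14, 537, 12), (13, 183, 1)],
    "std_6mo": [(34, 568, 11), (35, 369, 5), (43, 502, 18), (5, 185, 7)],
}

CANDIDATE_ITEMS = list(BASELINE_COUNTS)

#: The nine indicators retained by the published variable-selection process.
PAPER9_ITEMS = [
    "education_hs_or_less",
    "income_lt_1500",
    "unemployed",
    "non_gbmsm",
    "indigenous",
    "incarceration",
    "idu_ever",
    "idu_6mo",
    "psych_hospital",
]

# Frozen fixture seed for the ground-truth discriminations; the LogNormal
# draws below are deterministic forever, so recovery tests have fixed truth.
_FIXTURE_BETA_SEED = 20210419
_DEFAULT_OUTCOME_SLOPE = float(np.log(1.17))
_DEFAULT_OUTCOME_RATE = 0.30


def baseline_prevalence(item: str, province_idx: int) -> float:
    dep, nondep, _ = BASELINE_COUNTS[item][province_idx]
    return dep / (dep + nondep)


def baseline_missing_rate(item: str, province_idx: int) -> float:
    counts = BASELINE_COUNTS[item][province_idx]
    return counts[2] / PROVINCE_SIZES[province_idx]


# ---------------------------------------------------------------------------
# Config and truth containers
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Generative configuration with ground-truth item parameters.

    ``true_alpha``/``true_beta``/``missing_rates`` are (J, K) arrays over
    items x provinces; ``outcome_intercept``/``outcome_slope`` are on the
    log-odds scale of the non-attendance model.
    """

    province_labels: list[str]
    province_sizes: list[int]
    item_labels: list[str]
    true_alpha: np.ndarray
    true_beta: np.ndarray
    missing_rates: np.ndarray
    outcome_intercept: float
    outcome_slope: float
    seed: int

    def __post_init__(self) -> None:
        self.true_alpha = np.atleast_2d(np.asarray(self.true_alpha, dtype=float))
        self.true_beta = np.atleast_2d(np.asarray(self.true_beta, dtype=float))
        self.missing_rates = np.atleast_2d(np.asarray(self.missing_rates, dtype=float))
        K, J = len(self.province_labels), len(self.item_labels)
        if len(self.province_sizes) != K:
            raise ValueError("province_sizes and province_labels disagree")
        if any(n < 1 for n in self.province_sizes):
            raise ValueError("province sizes must be >= 1")
        for name, arr in [
            ("true_alpha", self.true_alpha),
            ("true_beta", self.true_beta),
            ("missing_rates", self.missing_rates),
        ]:
            if arr.shape != (J, K):
                raise ValueError(f"{name} must have shape (J, K) = ({J}, {K})")
        if not (self.true_beta > 0).all():
            raise ValueError("all true_beta must be > 0")
        if (self.missing_rates < 0).any() or (self.missing_rates > 0.5).any():
            raise ValueError("missing_rates must lie in [0, 0.5]")

    @property
    def n_total(self) -> int:
        return int(sum(self.province_sizes))

    def to_yaml(self, path) -> None:
        import yaml

        payload = {
            "province_labels": list(self.province_labels),
            "province_sizes": [int(n) for n in self.province_sizes],
            "item_labels": list(self.item_labels),
            "true_alpha": self.true_alpha.tolist(),
            "true_beta": self.true_beta.tolist(),
            "missing_rates": self.missing_rates.tolist(),
            "outcome_intercept": float(self.outcome_intercept),
            "outcome_slope": float(self.outcome_slope),
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ValueError("cohort config requires an explicit seed")
        return cls(**raw)

    def restrict_items(self, items: list[str]) -> "CohortConfig":
        idx = [self.item_labels.index(i) for i in items]
        return CohortConfig(
            province_labels=self.province_labels,
            province_sizes=self.province_sizes,
            item_labels=list(items),
            true_alpha=self.true_alpha[idx],
            true_beta=self.true_beta[idx],
            missing_rates=self.missing_rates[idx],
            outcome_intercept=self.outcome_intercept,
            outcome_slope=self.outcome_slope,
            seed=self.seed,
        )


@dataclass
class TruthRecord:
    """Ground truth accompanying one simulated cohort."""

    theta_true: np.ndarray
    alpha_true: np.ndarray
    beta_true: np.ndarray
    outcome_prob: np.ndarray = field(default_factory=lambda: np.empty(0))

    def theta_frame(self, ids: pd.Index, province: pd.Series) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": ids, "province": province.values, "theta_true": self.theta_true}
        )


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def calibrate_alpha(prevalence: float, beta: float) -> float:
    """Latent intercept hitting a marginal prevalence under theta ~ N(0,1).

    Averaging the probit response over the standard-normal trait gives
    P(x=1) = Phi(alpha / sqrt(1 + beta^2)); solving for alpha yields
    alpha = Phi^{-1}(p) * sqrt(1 + beta^2).
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly in (0, 1)")
    if beta <= 0:
        raise ValueError("beta must be positive")
    return float(special.ndtri(prevalence) * np.sqrt(1.0 + beta**2))


def calibrate_outcome_intercept(
    slope: float, target_rate: float, *, tol: float = 1e-10
) -> float:
    """Intercept making E[expit(a + slope*theta)] = target_rate, theta~N(0,1).

    Solved by 1-D root finding with Gauss-Hermite quadrature for the
    expectation over the trait distribution.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    w = weights / weights.sum()

    def marginal(a: float) -> float:
        return float(w @ special.expit(a + slope * nodes)) - target_rate

    return float(optimize.brentq(marginal, -20.0, 20.0, xtol=tol))


def _frozen_beta(n_items: int, n_prov: int) -> np.ndarray:
    rng = np.random.default_rng(_FIXTURE_BETA_SEED)
    return rng.lognormal(mean=0.0, sigma=0.3, size=(n_items, n_prov))


def default_config(seed: int = 0, items: list[str] | None = None) -> CohortConfig:
    """Published-table-calibrated config: 4 provinces, 19 (or chosen) items.

    Discriminations are the frozen LogNormal(0, 0.3^2) fixture truths;
    intercepts are calibrated so each item/province cell reproduces the
    published prevalence; missing rates reproduce the published "Missing"
    rows; the outcome model targets OR 1.17 per index unit at a 30% marginal
    non-attendance rate.
    """
    items = list(items) if items is not None else list(CANDIDATE_ITEMS)
    beta_all = _frozen_beta(len(CANDIDATE_ITEMS), len(PROVINCES))
    rows = [CANDIDATE_ITEMS.index(i) for i in items]
    beta = beta_all[rows]
    alpha = np.empty_like(beta)
    miss = np.empty_like(beta)
    for jj, item in enumerate(items):
        for k in range(len(PROVINCES)):
            alpha[jj, k] = calibrate_alpha(baseline_prevalence(item, k), beta[jj, k])
            miss[jj, k] = baseline_missing_rate(item, k)
    slope = _DEFAULT_OUTCOME_SLOPE
    intercept = calibrate_outcome_intercept(slope, _DEFAULT_OUTCOME_RATE)
    return CohortConfig(
        province_labels=list(PROVINCES),
        province_sizes=list(PROVINCE_SIZES),
        item_labels=items,
        true_alpha=alpha,
        true_beta=beta,
        missing_rates=miss,
        outcome_intercept=intercept,
        outcome_slope=slope,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate_items(config: CohortConfig) -> tuple[ItemResponseMatrix, TruthRecord]:
    """Draw one complete (pre-missingness) cohort from the latent-normal model."""
    rng = np.random.default_rng(child_seed(config.seed, "simulate_items"))
    J = len(config.item_labels)
    N = config.n_total
    prov_idx = np.repeat(np.arange(len(config.province_labels)), config.province_sizes)
    theta = rng.standard_normal(N)
    # latent utilities: N x J
    mean = config.true_alpha.T[prov_idx] + config.true_beta.T[prov_idx] * theta[:, None]
    x_star = mean + rng.standard_normal((N, J))
    x = (x_star > 0).astype(float)
    ids = pd.Index([f"P{i:05d}" for i in range(N)], name="id")
    labels = pd.Series(
        np.asarray(config.province_labels, dtype=object)[prov_idx], index=ids
    )
    responses = pd.DataFrame(x, index=ids, columns=config.item_labels)
    truth = TruthRecord(
        theta_true=theta, alpha_true=config.true_alpha, beta_true=config.true_beta
    )
    return ItemResponseMatrix(responses, labels), truth


def apply_missingness(
    X: ItemResponseMatrix, rates: np.ndarray, seed: int
) -> ItemResponseMatrix:
    """MCAR-mask each cell with its (item, province) rate."""
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    if (rates < 0).any() or (rates >= 1).any():
        raise ValueError("missing rates must lie in [0, 1)")
    if rates.shape != (len(X.items), len(X.provinces)):
        raise ValueError("rates must have shape (J, K)")
    rng = np.random.default_rng(child_seed(seed, "apply_missingness"))
    prov_idx = X.province_index()
    cell_rates = rates.T[prov_idx]  # N x J
    mask = rng.uniform(size=cell_rates.shape) < cell_rates
    responses = X.responses.copy()
    vals = responses.to_numpy(dtype=float)
    vals[mask] = np.nan
    responses.iloc[:, :] = vals
    return ItemResponseMatrix(responses, X.province.copy())


def simulate_outcome(
    theta: np.ndarray, intercept: float, slope: float, seed: int
) -> np.ndarray:
    """Bernoulli non-attendance outcome from the logistic model on the trait."""
    theta = np.asarray(theta, dtype=float)
    if not np.isfinite(theta).all():
        raise ValueError("theta must be finite")
    rng = np.random.default_rng(child_seed(seed, "simulate_outcome"))
    p = special.expit(intercept + slope * theta)
    return (rng.uniform(size=theta.shape) < p).astype(int)


def simulate_cohort(
    config: CohortConfig,
) -> tuple[ItemResponseMatrix, np.ndarray, TruthRecord]:
    """Full draw: items, MCAR missingness, outcome. Deterministic given seed."""
    X, truth = simulate_items(config)
    Xm = apply_missingness(X, config.missing_rates, config.seed)
    y = simulate_outcome(
        truth.theta_true, config.outcome_intercept, config.outcome_slope, config.seed
    )
    truth.outcome_prob = special.expit(
        config.outcome_intercept + config.outcome_slope * truth.theta_true
    )
    return Xm, y, truth


def fictitious_sample(seed: int = 1842) -> pd.DataFrame:
    """Deterministic cohort-like sample with all 19 candidate indicators.

    Stands in for the non-public cohort in examples and tests; regenerating
    with the same seed is bit-identical, so nothing needs to be shipped on
    disk.
    """
    config = default_config(seed=seed)
    X, y, _ = simulate_cohort(config)
    return X.to_frame(outcome=pd.Series(y, index=X.responses.index))
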