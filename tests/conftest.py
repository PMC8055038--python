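"""Shared fixtures: small synthetic cohorts and reusable MCMC fits."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import depindex as d
from depindex import irt
from depindex.preprocess import complete_cases

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """Complete-case paper9 cohort at reduced province sizes, with truth."""
    cfg = d.default_config(seed=42, items=d.PAPER9_ITEMS)
    cfg.province_sizes = [150, 100, 140, 60]
    X, y, truth = d.simulate_cohort(cfg)
    Xcc, _ = complete_cases(X)
    keep = Xcc.responses.index
    pos = [list(X.responses.index).index(i) for i in keep]
    theta_true = truth.theta_true[pos]
    return Xcc, y, truth, theta_true


@pytest.fixture(scope="session")
def pooled_fit_small(small_cohort):
    """A short pooled fit reused by several posterior-functional tests."""
    Xcc, *_ = small_cohort
    mcmc = irt.McmcConfig(iterations=500, burn_in=250, chains=2, seed=7)
    draws, diag = irt.fit(Xcc, irt.IrtModelSpec("pooled"), mcmc)
    return Xcc, draws, diag


@pytest.fixture
def raw_records():
    """Tiny raw table exercising every dichotomization rule kind."""
    return pd.DataFrame(
        {
            "id": ["a", "b", "c", "d", "e"],
            "province": ["QC", "QC", "ON", "ON", "BC"],
            "income_monthly": [1500.0, 1499.99, 800.0, np.nan, 2500.0],
            "education": [
                "More than high school",
                "High school diploma or less",
                "High school diploma or less",
                "More than high school",
                "",
            ],
            "idu_ever": [0, 1, 1, 0, 1],
        }
    )
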