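"""Seed-stream plumbing and truncated-normal draws shared across modules."""

from __future__ import annotations

import hashlib

import numpy as np
from scipy import special

__all__ = ["child_seed", "rng_for", "truncnorm_onesided"]


def child_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2**31.

    Every stochastic pipeline stage draws its randomness from a child seed
    derived from the single run seed and the stage name, so stages can be
    re-run independently yet the whole pipeline is reproducible from one seed.
    """
    h = hashlib.sha256(f"{int(master_seed)}::{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def rng_for(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(master_seed, stage))


def truncnorm_onesided(
    mean: np.ndarray, positive: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw from N(mean, 1) truncated to (0, inf) or (-inf, 0] elementwise.

    ``positive`` selects the (0, inf) side. Uses the inverse log-CDF
    (``ndtri_exp``) so draws stay finite and correctly distributed even when
    the truncation point sits > 6 SDs into the tail.
    """
    mean = np.asarray(mean, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    u = rng.uniform(size=mean.shape)
    # avoid log(0); u in (0,1)
    logu = np.log(np.clip(u, 1e-300, 1.0))
    out = np.empty_like(mean)
    # z > -mean  (x* = mean + z > 0):  S(z) = u * S(-mean)
    pos = positive
    out[pos] = mean[pos] - special.ndtri_exp(logu[pos] + special.log_ndtr(mean[pos]))
    # z <= -mean (x* <= 0):  F(z) = u * F(-mean)
    neg = ~positive
    out[neg] = mean[neg] + special.ndtri_exp(logu[neg] + special.log_ndtr(-mean[neg]))
    return out
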