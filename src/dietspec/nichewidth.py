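"""Niche-width decomposition on a continuous prey trait (WIC / BIC / TNW).

The total niche width TNW of a population on a continuous trait (here prey
size in mm) is the population variance of all trait values pooled across
individuals.  By the law of total variance it splits exactly into a
within-individual component (WIC, the item-weighted mean of the individual
variances) and a between-individual component (BIC, the item-weighted
variance of the individual means):

    TNW = WIC + BIC,
    WIC = sum_i (n_i / n) Var_i,     BIC = sum_i (n_i / n) (mean_i - mean)^2.

All variances use the n-denominator (maximum-likelihood) form so the
decomposition identity holds exactly.  The specialization index is the ratio
WIC/TNW in [0, 1]: small values mean individuals each use a narrow, distinct
slice of the population's size range; 1 means every individual spans the full
population niche.

The null hypothesis -- all individuals sample from the same pooled size
distribution -- is tested by permuting the pooled trait values across
individuals (preserving each individual's sample size n_i) and recomputing
the ratio; the p-value is one-tailed toward small ratios with the
(r+1)/(R+1) convention.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diet import monte_carlo_p


@dataclass(frozen=True)
class NicheWidthResult:
    """WIC, BIC, TNW (squared trait units), the WIC/TNW ratio, and optionally
    the permutation-null distribution and p-value."""

    wic: float
    bic: float
    tnw: float
    ratio: float
    null_ratio: np.ndarray | None = None
    p_value: float | None = None
    replicates: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "wic": self.wic,
            "bic": self.bic,
            "tnw": self.tnw,
            "ratio": self.ratio,
            "p_value": self.p_value,
            "replicates": self.replicates,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_csv(self, path) -> None:
        pd.DataFrame([self.to_dict()]).drop(columns=["seed"]).to_csv(
            path, index=False
        )


def _prepare(
    sizes: Mapping[str, Sequence[float]], log_transform: bool
) -> tuple[np.ndarray, np.ndarray]:
    groups = [np.asarray(v, dtype=float) for v in sizes.values()]
    if len(groups) < 2:
        raise ValueError("niche-width decomposition needs at least 2 individuals")
    if any(g.size == 0 for g in groups):
        raise ValueError("every individual must contribute at least one value")
    pooled = np.concatenate(groups)
    if pooled.size < 2:
        raise ValueError("need at least 2 trait values in total")
    if log_transform:
        if (pooled <= 0).any():
            raise ValueError("log transform requires strictly positive values")
        pooled = np.log(pooled)
    n_i = np.array([g.size for g in groups])
    return pooled, n_i


def _decompose(pooled: np.ndarray, n_i: np.ndarray) -> tuple[float, float, float]:
    """(wic, bic, tnw) for pooled values laid out in contiguous per-individual
    blocks of sizes n_i, using n-denominator variances."""
    n = pooled.size
    starts = np.concatenate(([0], np.cumsum(n_i)[:-1]))
    sums = np.add.reduceat(pooled, starts)
    sqsums = np.add.reduceat(pooled**2, starts)
    means = sums / n_i
    variances = np.maximum(sqsums / n_i - means**2, 0.0)
    grand_mean = pooled.mean()
    wic = float(np.sum(n_i / n * variances))
    bic = float(np.sum(n_i / n * (means - grand_mean) ** 2))
    tnw = float(pooled.var())
    return wic, bic, tnw


def wic_tnw(
    sizes: Mapping[str, Sequence[float]], log_transform: bool = False
) -> NicheWidthResult:
    """Decompose the total niche width into WIC and BIC (no null test).

    ``sizes`` maps individual id -> list of trait values.  Raises if the
    pooled variance is zero (niche width undefined).
    """
    pooled, n_i = _prepare(sizes, log_transform)
    wic, bic, tnw = _decompose(pooled, n_i)
    if tnw <= 0:
        raise ValueError("zero total variance: niche width undefined")
    return NicheWidthResult(wic=wic, bic=bic, tnw=tnw, ratio=wic / tnw)


def wic_tnw_null_test(
    sizes: Mapping[str, Sequence[float]],
    replicates: int = 999,
    seed: int | None = None,
    log_transform: bool = False,
    rng: np.random.Generator | None = None,
) -> NicheWidthResult:
    """WIC/TNW with the permutation null test.

    Each replicate reassigns the pooled trait values to individuals at random
    without replacement, preserving every n_i, and recomputes WIC/TNW; the
    p-value is one-tailed toward small ratios (strong size specialization).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    observed = wic_tnw(sizes, log_transform)
    pooled, n_i = _prepare(sizes, log_transform)
    if rng is None:
        rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(pooled, (replicates, 1)), axis=1)
    n = pooled.size
    starts = np.concatenate(([0], np.cumsum(n_i)[:-1]))
    sums = np.add.reduceat(perms, starts, axis=1)
    sqsums = np.add.reduceat(perms**2, starts, axis=1)
    means = sums / n_i
    variances = np.maximum(sqsums / n_i - means**2, 0.0)
    wic_null = (n_i / n * variances).sum(axis=1)
    # TNW is permutation-invariant
    null_ratio = wic_null / observed.tnw
    p_value = monte_carlo_p(null_ratio, observed.ratio, tail="low")
    return NicheWidthResult(
        wic=observed.wic,
        bic=observed.bic,
        tnw=observed.tnw,
        ratio=observed.ratio,
        null_ratio=null_ratio,
        p_value=p_value,
        replicates=replicates,
        seed=seed,
    )
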