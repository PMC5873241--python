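"""Proportional-similarity diet-overlap indices and their Monte Carlo null.

For individual i with diet proportions p_ij over resource categories j, the
proportional similarity to the population diet q is

    PS_i = 1 - 0.5 * sum_j |p_ij - q_j|,

ranging from 0 (no overlap with the population diet: an extreme specialist on
a resource nobody else uses) to 1 (the individual's diet matches the
population diet exactly).  The population-level index of similarity IS is the
mean of the PS_i.

The population diet q defaults to the equal-weight mean of the individual
proportion vectors, q_j = (1/N) sum_i p_ij, so each forager contributes
equally regardless of how many items it took; a pooled-count alternative
(q_j = total count of j / total items) is available via ``q_weighting``.
Note that a pure specialist on resource j has PS_i = q_j exactly.

The null hypothesis -- all individuals sample from the same population diet --
is tested by redrawing each individual's diet as an n_i-trial multinomial over
the observed q and recomputing IS (including q) on each replicate; the
one-tailed p-value toward small IS uses the (r+1)/(R+1) convention, so the
smallest attainable p with 999 replicates is 0.001.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import DietMatrix

Q_WEIGHTINGS = ("equal", "pooled")

#: absolute slack when counting null replicates tied with the observed value
_TIE_TOL = 1e-12


@dataclass(frozen=True)
class PSiResult:
    """Per-individual PS_i values, population IS, and (optionally) the
    Monte Carlo null distribution and p-value."""

    psi: dict[str, float]
    is_value: float
    population_diet: dict[str, float]
    null_is: np.ndarray | None = None
    p_value: float | None = None
    replicates: int | None = None
    seed: int | None = None

    @property
    def psi_range(self) -> tuple[float, float]:
        values = list(self.psi.values())
        return (min(values), max(values))

    def to_dict(self) -> dict:
        return {
            "psi": self.psi,
            "is_value": self.is_value,
            "population_diet": self.population_diet,
            "p_value": self.p_value,
            "replicates": self.replicates,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def psi_to_csv(self, path) -> None:
        pd.Series(self.psi, name="psi").rename_axis("individual_id").to_csv(path)


def population_diet(diet: DietMatrix, q_weighting: str = "equal") -> np.ndarray:
    """The population diet-proportion vector q_j."""
    if q_weighting not in Q_WEIGHTINGS:
        raise ValueError(f"q_weighting must be one of {Q_WEIGHTINGS}")
    if q_weighting == "equal":
        return diet.proportions().mean(axis=0)
    totals = diet.counts.sum(axis=0)
    return totals / totals.sum()


def _psi_values(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    return 1.0 - 0.5 * np.abs(p - q).sum(axis=-1)


def psi(diet: DietMatrix, q_weighting: str = "equal") -> PSiResult:
    """Compute PS_i for every individual and the population IS (no null test)."""
    if diet.n_individuals < 2:
        raise ValueError(
            "PS_i measures overlap with the rest of the population and is "
            "undefined for a single-individual matrix"
        )
    p = diet.proportions()
    q = population_diet(diet, q_weighting)
    values = _psi_values(p, q)
    if diet.n_resources == 1:
        warnings.warn(
            "diet matrix has a single resource category: every PS_i is 1 and "
            "the specialization indices are degenerate",
            stacklevel=2,
        )
    return PSiResult(
        psi=dict(zip(diet.individual_ids, values.tolist())),
        is_value=float(values.mean()),
        population_diet=dict(zip(diet.resource_labels, q.tolist())),
    )


def resample_null_counts(
    diet: DietMatrix,
    replicates: int,
    rng: np.random.Generator,
    q_weighting: str = "equal",
) -> np.ndarray:
    """Draw ``replicates`` null count matrices: each individual's diet redrawn
    as an n_i-trial multinomial over the observed population diet q (q fixed
    across replicates).  Shape (replicates, N, K)."""
    q = population_diet(diet, q_weighting)
    n_i = diet.row_totals()
    draws = np.stack(
        [rng.multinomial(n, q, size=replicates) for n in n_i], axis=1
    )
    return draws


def null_is_distribution(
    null_counts: np.ndarray, q_weighting: str = "equal"
) -> np.ndarray:
    """IS recomputed on each resampled matrix (q re-estimated per replicate,
    so the null distribution is of the same estimator as the observed IS)."""
    p = null_counts / null_counts.sum(axis=2, keepdims=True)
    if q_weighting == "equal":
        q = p.mean(axis=1)
    else:
        totals = null_counts.sum(axis=1)
        q = totals / totals.sum(axis=1, keepdims=True)
    return _psi_values(p, q[:, None, :]).mean(axis=1)


def monte_carlo_p(
    null: np.ndarray, observed: float, tail: str = "low"
) -> float:
    """(r+1)/(R+1) Monte Carlo p-value; ties count as extreme."""
    null = np.asarray(null, dtype=float)
    if tail == "low":
        r = int(np.count_nonzero(null <= observed + _TIE_TOL))
    elif tail == "high":
        r = int(np.count_nonzero(null >= observed - _TIE_TOL))
    elif tail == "two":
        r = int(np.count_nonzero(np.abs(null) >= abs(observed) - _TIE_TOL))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (r + 1) / (null.size + 1)


def psi_null_test(
    diet: DietMatrix,
    replicates: int = 999,
    seed: int | None = None,
    q_weighting: str = "equal",
    rng: np.random.Generator | None = None,
) -> PSiResult:
    """PS_i/IS with the multinomial Monte Carlo null test.

    Tests the null hypothesis that all individuals sample equally from the
    overall population diet; small IS (strong specialization) is the
    alternative, so the p-value is one-tailed toward low IS.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    observed = psi(diet, q_weighting)
    if rng is None:
        rng = np.random.default_rng(seed)
    null_counts = resample_null_counts(diet, replicates, rng, q_weighting)
    null_is = null_is_distribution(null_counts, q_weighting)
    p_value = monte_carlo_p(null_is, observed.is_value, tail="low")
    return PSiResult(
        psi=observed.psi,
        is_value=observed.is_value,
        population_diet=observed.population_diet,
        null_is=null_is,
        p_value=p_value,
        replicates=replicates,
        seed=seed,
    )
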