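"""Independent brute-force oracles used to validate the fast implementations.

Each oracle is a literal, loop-level translation of the defining formula or
an exhaustive enumeration of the null distribution; none shares code with
the implementation it checks.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from scipy.stats import multinomial

from dietspec import DietMatrix
from dietspec.diet import population_diet


def nodf_brute(matrix) -> float:
    """Loop-level NODF: paired overlap scores under strictly decreasing fill."""
    b = (np.asarray(matrix) >= 1).astype(int)
    n, k = b.shape

    def axis_total(mat: np.ndarray) -> float:
        total = 0.0
        for u, v in itertools.combinations(range(mat.shape[0]), 2):
            fu, fv = int(mat[u].sum()), int(mat[v].sum())
            if fu == fv:
                continue
            big, small = (u, v) if fu > fv else (v, u)
            fill_small = int(mat[small].sum())
            if fill_small == 0:
                continue
            shared = int(np.logical_and(mat[big], mat[small]).sum())
            total += 100.0 * shared / fill_small
        return total

    pairs = n * (n - 1) / 2 + k * (k - 1) / 2
    return (axis_total(b) + axis_total(b.T)) / pairs


def _compositions(n: int, k: int):
    """All k-part compositions of n (weak, ordered)."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


def _is_of(counts: np.ndarray, q_weighting: str) -> float:
    p = counts / counts.sum(axis=1, keepdims=True)
    if q_weighting == "equal":
        q = p.mean(axis=0)
    else:
        q = counts.sum(axis=0) / counts.sum()
    return float((1.0 - 0.5 * np.abs(p - q).sum(axis=1)).mean())


def exact_psi_null_p(diet: DietMatrix, q_weighting: str = "equal") -> float:
    """Exact P(IS_null <= IS_obs) under the multinomial null, by enumerating
    every joint resample outcome (feasible for tiny matrices)."""
    q = population_diet(diet, q_weighting)
    n_i = diet.row_totals()
    k = diet.n_resources
    observed = _is_of(diet.counts.astype(float), q_weighting)
    per_individual = []
    for n in n_i:
        outcomes = []
        for c in _compositions(int(n), k):
            outcomes.append((np.array(c), float(multinomial.pmf(c, int(n), q))))
        per_individual.append(outcomes)
    total = 0.0
    for joint in itertools.product(*per_individual):
        counts = np.stack([c for c, _ in joint])
        prob = float(np.prod([p for _, p in joint]))
        if _is_of(counts.astype(float), q_weighting) <= observed + 1e-12:
            total += prob
    return total


def _ratio_of(values: np.ndarray, n_i: np.ndarray) -> float:
    """WIC/TNW of pooled values laid out in contiguous blocks of sizes n_i
    (n-denominator variances), written independently of the implementation."""
    groups = np.split(values, np.cumsum(n_i)[:-1])
    n = values.size
    wic = sum(len(g) / n * np.mean((g - np.mean(g)) ** 2) for g in groups)
    tnw = np.mean((values - np.mean(values)) ** 2)
    return wic / tnw


def exact_wic_tnw_p(sizes: dict) -> float:
    """Exact permutation P(ratio_null <= ratio_obs) by enumerating every
    assignment of the pooled values to individuals (feasible for <= 8 items)."""
    groups = [np.asarray(v, dtype=float) for v in sizes.values()]
    pooled = np.concatenate(groups)
    n_i = np.array([g.size for g in groups])
    observed = _ratio_of(pooled, n_i)
    n = pooled.size
    hits = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if _ratio_of(pooled[list(perm)], n_i) <= observed + 1e-12:
            hits += 1
    return hits / total
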