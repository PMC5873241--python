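"""Individual-resource network metrics: C_ws modularity and NODF nestedness.

The individual diet-overlap network connects foragers i and j with weight
equal to their pairwise proportional diet similarity,

    w_ij = 1 - 0.5 * sum_k |p_ik - p_jk|,

the same overlap family as the PS_i index, so one overlap definition runs
through the whole package.

C_ws compares the mean weighted clustering coefficient of this network with
its mean edge weight (density):

    C_ws = (mean_clustering - density) / max(mean_clustering, density)

(0 when the maximum is 0).  The node clustering uses the geometric-mean
weighted-triangle form, c_i = sum_{j<k} (w_ij w_jk w_ik)^(1/3) normalised by
the total number of triplet pairs (N-1)(N-2)/2, so a node embedded in a small
tight cluster scores low relative to a node whose overlaps span the whole
network.  C_ws near 0 means no modularity (all generalists, or specialists
nested inside generalists); C_ws < 0 means discrete specialist clusters;
C_ws > 0 means idiosyncratic specialist diets.

NODF ("nestedness based on overlap and decreasing fill") scores, for every
ordered row pair with strictly decreasing fill, the percentage of the sparser
row's presences shared by the fuller row, and likewise for columns; the index
is the mean paired score over all row pairs and column pairs, from 0 (no
nestedness) to 100 (strict subset chains).

Null models: C_ws uses the same multinomial diet resampling as the PS_i test
(two-sided, since departures in both directions are interpretable); NODF uses
the marginal-probability binary null in which cell (i, j) is present with
probability (rowfill_i/K + colfill_j/N) / 2 computed from the observed binary
matrix, one-tailed toward high nestedness.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np

from .diet import monte_carlo_p, resample_null_counts
from .records import DietMatrix


@dataclass(frozen=True)
class OverlapNetwork:
    """Symmetric pairwise diet-overlap network with weights in [0, 1] and a
    zero diagonal."""

    individual_ids: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        n = len(self.individual_ids)
        if w.shape != (n, n):
            raise ValueError("weights must be square and match individual_ids")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if w.min() < -1e-9 or w.max() > 1 + 1e-9:
            raise ValueError("weights must lie in [0, 1]")

    def to_edgelist_csv(self, path, include_zero: bool = False) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "weight"])
            n = len(self.individual_ids)
            for i in range(n):
                for j in range(i + 1, n):
                    w = self.weights[i, j]
                    if include_zero or w > 0:
                        writer.writerow(
                            [self.individual_ids[i], self.individual_ids[j], repr(w)]
                        )

    def to_graphml(self, path) -> None:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.individual_ids)
        n = len(self.individual_ids)
        for i in range(n):
            for j in range(i + 1, n):
                if self.weights[i, j] > 0:
                    g.add_edge(
                        self.individual_ids[i],
                        self.individual_ids[j],
                        weight=float(self.weights[i, j]),
                    )
        nx.write_graphml(g, path)


@dataclass(frozen=True)
class CwsResult:
    cws: float
    mean_clustering: float
    density: float
    null_cws: np.ndarray | None = None
    p_value: float | None = None
    replicates: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "cws": self.cws,
            "mean_clustering": self.mean_clustering,
            "density": self.density,
            "p_value": self.p_value,
            "replicates": self.replicates,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass(frozen=True)
class NodfResult:
    nodf: float
    null_nodf: np.ndarray | None = None
    null_mean: float | None = None
    p_value: float | None = None
    replicates: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "nodf": self.nodf,
            "null_mean": self.null_mean,
            "p_value": self.p_value,
            "replicates": self.replicates,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _pairwise_overlap(p: np.ndarray) -> np.ndarray:
    w = 1.0 - 0.5 * np.abs(p[:, None, :] - p[None, :, :]).sum(axis=2)
    np.fill_diagonal(w, 0.0)
    return np.clip(w, 0.0, 1.0)


def overlap_network(diet: DietMatrix) -> OverlapNetwork:
    """Build the pairwise proportional-similarity network from a diet matrix."""
    if diet.n_individuals < 2:
        raise ValueError("an overlap network needs at least 2 individuals")
    return OverlapNetwork(
        individual_ids=diet.individual_ids,
        weights=_pairwise_overlap(diet.proportions()),
    )


def cws_statistic(weights: np.ndarray) -> tuple[float, float, float]:
    """(C_ws, mean_clustering, density) for one weight matrix."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    a = np.cbrt(w)
    # (a^3)_ii sums ordered neighbour pairs (j, k), both distinct from i;
    # normalising by all (N-1)(N-2) ordered triplet pairs keeps tight,
    # disconnected clusters low-scoring relative to the network density
    tri = np.einsum("ij,jk,ki->i", a, a, a)
    c = tri / ((n - 1) * (n - 2)) if n > 2 else np.zeros(n)
    mean_clustering = float(c.mean())
    density = float(w.sum() / (n * (n - 1)))
    top = max(mean_clustering, density)
    cws = (mean_clustering - density) / top if top > 0 else 0.0
    return float(cws), mean_clustering, density


def cws(
    network: OverlapNetwork,
    diet: DietMatrix | None = None,
    replicates: int = 999,
    seed: int | None = None,
    q_weighting: str = "equal",
    rng: np.random.Generator | None = None,
) -> CwsResult:
    """C_ws with (optionally) its multinomial-resampling null test.

    The null redraws every individual's diet from the observed population
    diet (exactly as the PS_i null), rebuilds the overlap network, and
    recomputes C_ws; the p-value is two-sided on |C_ws|.  Pass ``diet=None``
    to skip the null test and report the observed statistic only.
    """
    n = len(network.individual_ids)
    if n < 3:
        raise ValueError("C_ws requires at least 3 individuals (triplets)")
    value, mean_clustering, density = cws_statistic(network.weights)
    if diet is None:
        return CwsResult(cws=value, mean_clustering=mean_clustering, density=density)
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    null_counts = resample_null_counts(diet, replicates, rng, q_weighting)
    p = null_counts / null_counts.sum(axis=2, keepdims=True)
    null_cws = np.empty(replicates)
    for r in range(replicates):
        null_cws[r] = cws_statistic(_pairwise_overlap(p[r]))[0]
    p_value = monte_carlo_p(null_cws, value, tail="two")
    return CwsResult(
        cws=value,
        mean_clustering=mean_clustering,
        density=density,
        null_cws=null_cws,
        p_value=p_value,
        replicates=replicates,
        seed=seed,
    )


def _as_binary(matrix) -> np.ndarray:
    if isinstance(matrix, DietMatrix):
        return matrix.binary()
    b = np.asarray(matrix)
    if b.ndim != 2:
        raise ValueError("matrix must be 2-dimensional")
    return (b >= 1).astype(np.int64)


def _nodf_axis_scores(b: np.ndarray) -> float:
    """Sum of paired NODF scores over all (unordered) row pairs of ``b``."""
    fills = b.sum(axis=1)
    overlap = b @ b.T
    fv = fills[None, :].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(fv > 0, 100.0 * overlap / np.where(fv > 0, fv, 1), 0.0)
    decreasing = fills[:, None] > fills[None, :]
    return float(score[decreasing & (fv > 0)].sum())


def nodf(matrix) -> float:
    """NODF nestedness of a binary matrix (0-100).

    Accepts a binary array or a :class:`DietMatrix` (counts thresholded at
    >= 1).  Rows or columns that are entirely zero contribute zero-score
    pairs; an all-zero matrix is an error.
    """
    b = _as_binary(matrix)
    if b.sum() == 0:
        raise ValueError("NODF is undefined for an all-zero matrix")
    n, k = b.shape
    pairs = n * (n - 1) / 2 + k * (k - 1) / 2
    if pairs == 0:
        raise ValueError("NODF needs at least 2 rows or 2 columns")
    total = _nodf_axis_scores(b) + _nodf_axis_scores(b.T)
    return total / pairs


def nodf_null_matrix_probabilities(b: np.ndarray) -> np.ndarray:
    """Cell presence probabilities of the marginal-average binary null:
    P_ij = (rowfill_i / K + colfill_j / N) / 2."""
    n, k = b.shape
    row = b.sum(axis=1) / k
    col = b.sum(axis=0) / n
    return (row[:, None] + col[None, :]) / 2.0


def nodf_null_test(
    matrix,
    replicates: int = 999,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    probabilities: np.ndarray | None = None,
) -> NodfResult:
    """NODF with the marginal-probability Monte Carlo null.

    Each replicate is an independent-cell binary matrix with cell
    probabilities from :func:`nodf_null_matrix_probabilities` (or an
    explicitly supplied ``probabilities`` matrix, e.g. when calibrating
    against a known generating model); empty rows or columns in a replicate
    are retained (their pairs score 0).  One-tailed p toward high
    nestedness; the null-mean NODF is reported for comparison.

    Note the default null is conditional on the observed margins: because
    the cell probabilities are re-estimated from each dataset, its p-value
    is approximate (typically conservative) rather than exactly uniform
    under margin-homogeneous data.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    b = _as_binary(matrix)
    observed = nodf(b)
    if rng is None:
        rng = np.random.default_rng(seed)
    probs = (
        nodf_null_matrix_probabilities(b)
        if probabilities is None
        else np.asarray(probabilities, dtype=float)
    )
    if probs.shape != b.shape:
        raise ValueError("probabilities must match the matrix shape")
    n, k = b.shape
    draws = rng.random((replicates, n, k)) < probs
    pairs = n * (n - 1) / 2 + k * (k - 1) / 2
    null_nodf = np.empty(replicates)
    for r in range(replicates):
        br = draws[r].astype(np.int64)
        null_nodf[r] = (_nodf_axis_scores(br) + _nodf_axis_scores(br.T)) / pairs
    p_value = monte_carlo_p(null_nodf, observed, tail="high")
    return NodfResult(
        nodf=observed,
        null_nodf=null_nodf,
        null_mean=float(null_nodf.mean()),
        p_value=p_value,
        replicates=replicates,
        seed=seed,
    )
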