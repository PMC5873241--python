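"""Overlap network construction, C_ws modularity, and NODF nestedness."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from dietspec import (
    cws,
    cws_statistic,
    nodf,
    nodf_null_test,
    overlap_network,
)
from dietspec.network import nodf_null_matrix_probabilities
from conftest import matrix
from oracles import nodf_brute


class TestOverlapNetwork:
    def test_identical_diets_fully_connected_with_weight_one(self):
        net = overlap_network(matrix([[2, 2], [1, 1], [3, 3]]))
        off = net.weights[~np.eye(3, dtype=bool)]
        assert off == pytest.approx(np.ones(6))

    def test_disjoint_diets_weight_zero(self):
        net = overlap_network(matrix([[4, 0], [0, 4]]))
        assert net.weights[0, 1] == pytest.approx(0.0)

    def test_half_overlap_worked_example(self):
        # p_i = (0.5, 0.5), p_j = (1, 0) -> w = 0.5
        net = overlap_network(matrix([[2, 2], [4, 0]]))
        assert net.weights[0, 1] == pytest.approx(0.5)

    def test_exports(self, tmp_path):
        import networkx as nx

        net = overlap_network(matrix([[2, 2], [4, 0], [0, 4]]))
        net.to_edgelist_csv(tmp_path / "edges.csv")
        net.to_graphml(tmp_path / "net.graphml")
        g = nx.read_graphml(tmp_path / "net.graphml")
        assert g.number_of_nodes() == 3
        lines = (tmp_path / "edges.csv").read_text().strip().splitlines()
        assert lines[0] == "source,target,weight"
        assert len(lines) == 1 + 2  # the zero-weight pair is omitted


class TestCws:
    def test_uniform_generalists_no_modularity(self):
        result = cws(overlap_network(matrix([[3, 3], [1, 1], [2, 2], [4, 4]])))
        assert result.cws == pytest.approx(0.0)
        assert result.mean_clustering == pytest.approx(1.0)

    def test_two_disjoint_specialist_pairs_fully_modular(self):
        # weight 1 within pairs, 0 across: no triangles, density 1/3
        result = cws(overlap_network(matrix([[5, 0], [5, 0], [0, 5], [0, 5]])))
        assert result.cws == pytest.approx(-1.0)
        assert result.density == pytest.approx(1 / 3)

    def test_two_specialist_groups_of_three_negative(self):
        counts = [[5, 0]] * 3 + [[0, 5]] * 3
        result = cws(overlap_network(matrix(counts)))
        assert result.cws < 0

    def test_requires_three_individuals(self):
        with pytest.raises(ValueError, match="at least 3"):
            cws(overlap_network(matrix([[1, 0], [0, 1]])))

    def test_null_test_on_generalist_population_not_significant(self):
        diet = matrix([[8, 8], [7, 9], [9, 7], [8, 8]])
        result = cws(overlap_network(diet), diet, replicates=199, seed=4)
        assert result.p_value > 0.05
        assert result.replicates == 199

    def test_statistic_zero_when_network_empty(self):
        value, mean_clustering, density = cws_statistic(np.zeros((3, 3)))
        assert value == 0.0 and mean_clustering == 0.0 and density == 0.0


NESTED_5X5 = np.array(
    [
        [1, 1, 1, 1, 1],
        [1, 1, 1, 1, 0],
        [1, 1, 1, 0, 0],
        [1, 1, 0, 0, 0],
        [1, 0, 0, 0, 0],
    ]
)


class TestNodf:
    def test_strict_subset_chain_is_fully_nested(self):
        chain3 = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]])
        assert nodf(chain3) == pytest.approx(100.0)
        assert nodf(NESTED_5X5) == pytest.approx(100.0)

    def test_equal_fills_have_no_nestedness(self):
        assert nodf(np.eye(4, dtype=int)) == pytest.approx(0.0)

    def test_two_by_three_worked_example(self):
        assert nodf(np.array([[1, 1, 0], [0, 1, 1]])) == pytest.approx(50.0)

    def test_counts_are_thresholded(self):
        assert nodf(matrix([[7, 2, 1], [3, 1, 0], [9, 0, 0]])) == pytest.approx(100.0)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            nodf(np.zeros((3, 3), dtype=int))

    binary = hnp.arrays(np.int8, (4, 5), elements=st.integers(0, 1)).filter(
        lambda b: b.sum() > 0
    )

    @given(binary)
    def test_invariant_under_row_and_column_permutation(self, b):
        rng = np.random.default_rng(1)
        permuted = b[rng.permutation(4)][:, rng.permutation(5)]
        assert nodf(permuted) == pytest.approx(nodf(b))

    @given(
        hnp.arrays(np.int8, (4, 4), elements=st.integers(0, 1)).filter(
            lambda b: b.sum() > 0
        )
    )
    def test_square_matrix_transpose_symmetry(self, b):
        assert nodf(b.T) == pytest.approx(nodf(b))

    @given(binary)
    def test_matches_brute_force_oracle(self, b):
        assert nodf(b) == pytest.approx(nodf_brute(b))


class TestNodfNullTest:
    def test_full_matrix_null_is_degenerate(self):
        result = nodf_null_test(np.ones((3, 4), dtype=int), replicates=99, seed=0)
        assert result.p_value == pytest.approx(1.0)
        assert result.null_mean == pytest.approx(result.nodf)

    def test_null_probabilities_average_marginal_fills(self):
        b = np.array([[1, 1, 0], [1, 0, 0]])
        probs = nodf_null_matrix_probabilities(b)
        assert probs[0, 0] == pytest.approx((2 / 3 + 2 / 2) / 2)
        assert probs[1, 2] == pytest.approx((1 / 3 + 0 / 2) / 2)

    def test_strictly_nested_matrix_is_significant(self):
        # a fully nested observed matrix beats (almost) every null replicate;
        # occasional null replicates are themselves fully nested, so the
        # p-value sits at or just above the 1/(R+1) floor
        result = nodf_null_test(NESTED_5X5, replicates=999, seed=2)
        assert result.nodf == pytest.approx(100.0)
        assert result.p_value <= 0.05
        assert result.null_mean < 100.0

    def test_replicates_below_one_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            nodf_null_test(NESTED_5X5, replicates=0)


@settings(max_examples=5)
@given(hnp.arrays(np.int8, (3, 4), elements=st.integers(0, 1)).filter(
    lambda b: b.sum(axis=1).all() and b.sum(axis=0).all()
))
def test_nodf_agrees_with_vegan_reference(b):
    """Cross-check against the independent R implementation (vegan)."""
    rows = ";".join(",".join(str(int(x)) for x in row) for row in b)
    script = (
        f'm <- do.call(rbind, lapply(strsplit(strsplit("{rows}", ";")[[1]], ","),'
        " as.numeric));"
        "suppressMessages(library(vegan));"
        's <- nestednodf(m, order = TRUE, weighted = FALSE)$statistic["NODF"];'
        "cat(sprintf('%.10f', s))"
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, check=True
    )
    assert nodf(b) == pytest.approx(float(out.stdout), abs=1e-6)
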