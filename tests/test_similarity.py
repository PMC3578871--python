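import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster import hierarchy as scipy_hierarchy
from scipy.spatial.distance import squareform

from petalscreen import (
    QpcrRecord,
    adjacent_pearson,
    ddct_fold_change,
    hierarchical_cluster,
    log2_nonadjacent_profile,
    pairwise_spearman,
    pass_percentage,
    platform_concordance,
)
from petalscreen.io_formats import ExpressionMatrix

from .conftest import matrix_from_rows


def _matrix_with_columns(cols: dict[str, list[float]]) -> ExpressionMatrix:
    labels = list(cols)
    values = np.array(list(cols.values()), dtype=float).T
    genes = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(genes, labels, values)


class TestSpearman:
    def test_self_correlation_unity(self):
        m = _matrix_with_columns({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert pairwise_spearman(m).value("a", "b") == pytest.approx(1.0)

    def test_reversed_ranks(self):
        m = _matrix_with_columns({"a": [1, 2, 3, 4], "b": [4, 3, 2, 1]})
        assert pairwise_spearman(m).value("a", "b") == pytest.approx(-1.0)

    def test_hand_rank_computation(self):
        # ranks (1,2,3) vs (1,3,2): rho = 1 - 6*2/(3*8) = 0.5
        m = _matrix_with_columns({"a": [1, 2, 3], "b": [1, 3, 2]})
        assert pairwise_spearman(m).value("a", "b") == pytest.approx(0.5)

    def test_constant_column_is_nan_not_zero(self):
        m = _matrix_with_columns({"a": [1, 2, 3], "b": [5, 5, 5]})
        assert math.isnan(pairwise_spearman(m).value("a", "b"))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 100, size=12)
        b = rng.uniform(0, 100, size=12)
        m1 = _matrix_with_columns({"a": a, "b": b})
        # exp is strictly monotone; scaling too
        m2 = _matrix_with_columns({"a": np.exp(a / 50), "b": 3 * b + 1})
        r1 = pairwise_spearman(m1).value("a", "b")
        r2 = pairwise_spearman(m2).value("a", "b")
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_requires_three_genes(self):
        m = _matrix_with_columns({"a": [1, 2], "b": [2, 1]})
        with pytest.raises(ValueError):
            pairwise_spearman(m)


class TestAdjacentPearson:
    def test_identical_columns(self, scheme):
        m = matrix_from_rows({"g1": [1] * 8, "g2": [2] * 8, "g3": [5] * 8})
        for r in adjacent_pearson(m, scheme, "raw").values():
            assert r == pytest.approx(1.0)
        for r in adjacent_pearson(m, scheme, "log2p1").values():
            assert r == pytest.approx(1.0)

    def test_anticorrelated_raw(self, scheme):
        # sepal (0,1,2) against petal mean (2,1,0)
        rows = {
            "g1": [0, 2, 2, 2, 0, 0, 0, 0],
            "g2": [1, 1, 1, 1, 0, 0, 0, 0],
            "g3": [2, 0, 0, 0, 0, 0, 0, 0],
        }
        r = adjacent_pearson(matrix_from_rows(rows), scheme, "raw")
        assert r[("sepal", "petal")] == pytest.approx(-1.0)

    def test_perfect_linear_relation(self, scheme):
        # petal = 2 * sepal: r = 1 raw; log2p1 shifts but keeps r high
        rows = {
            "g1": [1, 2, 2, 2, 0, 0, 0, 0],
            "g2": [2, 4, 4, 4, 0, 0, 0, 0],
            "g3": [4, 8, 8, 8, 0, 0, 0, 0],
        }
        r = adjacent_pearson(matrix_from_rows(rows), scheme, "raw")
        assert r[("sepal", "petal")] == pytest.approx(1.0)

    def test_zero_variance_nan(self, scheme):
        rows = {"g1": [5, 1, 1, 1, 0, 0, 0, 0], "g2": [5, 2, 2, 2, 0, 0, 0, 0]}
        r = adjacent_pearson(matrix_from_rows(rows), scheme, "raw")
        assert math.isnan(r[("sepal", "petal")])


class TestLog2NonadjacentProfile:
    def test_constant_gene_is_zero(self, scheme):
        m = matrix_from_rows({"g1": [5] * 8})
        profile = log2_nonadjacent_profile(m, scheme)
        assert np.allclose(profile.loc["g1"], 0.0)

    def test_hand_value(self, scheme):
        # sepal 8 vs non-adjacent floral mean (stamen, carpel) = 2 -> log2(4)
        m = matrix_from_rows({"g1": [8, 1, 1, 1, 2, 2, 9, 9]})
        profile = log2_nonadjacent_profile(m, scheme, pseudocount=1e-9)
        assert profile.loc["g1", "sepal"] == pytest.approx(2.0, abs=1e-6)

    def test_nonadjacent_sets(self, scheme):
        # under default adjacency: sepal vs {stamen, carpel}; carpel vs {sepal, petal}
        m = matrix_from_rows({"g1": [16, 4, 4, 4, 2, 2, 0, 0]})
        profile = log2_nonadjacent_profile(m, scheme, pseudocount=1e-9)
        # carpel entry compares carpel=2 with mean(sepal=16, petal=4) = 10
        assert profile.loc["g1", "carpel"] == pytest.approx(
            math.log2(2 / 10), abs=1e-6
        )

    def test_scale_invariance_at_small_pseudocount(self, scheme):
        m1 = matrix_from_rows({"g1": [8, 1, 1, 1, 2, 2, 9, 9]})
        m2 = matrix_from_rows({"g1": [80, 10, 10, 10, 20, 20, 90, 90]})
        p1 = log2_nonadjacent_profile(m1, scheme, pseudocount=1e-12)
        p2 = log2_nonadjacent_profile(m2, scheme, pseudocount=1e-12)
        assert np.allclose(p1.values, p2.values, atol=1e-6)


class TestHierarchicalCluster:
    def test_identical_columns_merge_at_zero(self):
        m = _matrix_with_columns({"a": [1, 2, 3], "b": [1, 2, 3], "c": [3, 1, 2]})
        dend = hierarchical_cluster(m)
        left, right, height = dend.merges[0]
        assert {left, right} == {("a",), ("b",)}
        assert height == pytest.approx(0.0)

    def test_planted_petal_structure_merges_first(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(1, 100, size=30)
        cols = {
            "dorsal": base,
            "lateral": base * 1.01 + 0.1,  # r > 0.999 with dorsal
            "ventral": rng.permutation(base),
            "sepal": rng.uniform(1, 100, size=30),
        }
        dend = hierarchical_cluster(_matrix_with_columns(cols))
        left, right, _ = dend.merges[0]
        assert {left, right} == {("dorsal",), ("lateral",)}

    def test_heights_nondecreasing(self, random_matrix_factory):
        dend = hierarchical_cluster(random_matrix_factory(25, seed=11))
        heights = dend.heights
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_permutation_invariant_heights(self, random_matrix_factory):
        m = random_matrix_factory(20, seed=13)
        d1 = hierarchical_cluster(m, categories=list(m.organ_labels))
        d2 = hierarchical_cluster(m, categories=list(reversed(m.organ_labels)))
        assert np.allclose(d1.heights, d2.heights)

    def test_matches_scipy_average_linkage(self, random_matrix_factory):
        m = random_matrix_factory(40, seed=17)
        dend = hierarchical_cluster(m)
        corr = np.corrcoef(m.values.T)
        link = scipy_hierarchy.linkage(
            squareform(1 - corr, checks=False), method="average"
        )
        assert np.allclose(sorted(dend.heights), sorted(link[:, 2]), atol=1e-10)

    def test_constant_column_error_names_category(self):
        m = _matrix_with_columns({"a": [1, 2, 3], "b": [4, 4, 4]})
        with pytest.raises(ValueError, match="'b'"):
            hierarchical_cluster(m)

    def test_newick_serialization(self):
        m = _matrix_with_columns({"a": [1, 2, 3], "b": [1, 2, 3], "c": [3, 1, 2]})
        newick = hierarchical_cluster(m).to_newick()
        assert newick.endswith(";")
        assert newick.count("(") == 2


class TestDdct:
    def test_hand_fold_change(self):
        sample = QpcrRecord("g", "stamen", 20.0, 18.0)
        calibrator = QpcrRecord("g", "leaf", 22.0, 18.0)
        # ddCt = (20-18) - (22-18) = -2 -> 2^2 = 4
        assert ddct_fold_change(sample, calibrator) == pytest.approx(4.0)

    def test_identity(self):
        rec = QpcrRecord("g", "leaf", 21.0, 18.0)
        assert ddct_fold_change(rec, rec) == pytest.approx(1.0)

    def test_downregulation(self):
        sample = QpcrRecord("g", "stamen", 21.0, 18.0)
        calibrator = QpcrRecord("g", "leaf", 20.0, 18.0)
        assert ddct_fold_change(sample, calibrator) == pytest.approx(0.5)

    def test_gene_mismatch(self):
        with pytest.raises(ValueError):
            ddct_fold_change(
                QpcrRecord("g1", "stamen", 20, 18), QpcrRecord("g2", "leaf", 20, 18)
            )


class TestPlatformConcordance:
    def test_identical_platforms(self):
        import pandas as pd

        rng = np.random.default_rng(3)
        a = pd.DataFrame(
            rng.uniform(0, 50, size=(10, 8)), index=[f"g{i}" for i in range(10)]
        )
        result = platform_concordance(a, a.copy())
        assert result.pass_pct == 100.0
        assert np.allclose(result.per_gene_r, 1.0)

    def test_zero_passes(self):
        import pandas as pd

        x = np.arange(8, dtype=float)
        a = pd.DataFrame([x] * 10, index=[f"g{i}" for i in range(10)])
        b = pd.DataFrame([x[::-1]] * 10, index=[f"g{i}" for i in range(10)])
        result = platform_concordance(a, b)
        assert result.pass_pct == 0.0

    def test_constant_profile_counts_as_nonpass(self):
        import pandas as pd

        a = pd.DataFrame([[1, 2, 3], [5, 5, 5]], index=["g1", "g2"])
        b = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["g1", "g2"])
        result = platform_concordance(a, b)
        assert math.isnan(result.per_gene_r["g2"])
        assert not result.passes["g2"]
        assert result.pass_pct == 50.0

    def test_pass_percentage_rounding(self):
        assert pass_percentage(49, 60) == 81.7
        assert pass_percentage(0, 10) == 0.0
        assert pass_percentage(1, 3) == 33.3
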