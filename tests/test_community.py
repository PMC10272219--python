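"""Composition tables, Bray-Curtis, NMDS, ANOSIM (incl. scikit-bio
cross-check), Rosner outliers and Tukey-Kramer comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from herbivar.census import Census, CensusValidationError, LeafRecord
from herbivar.community import (
    anosim,
    bray_curtis,
    composition_table,
    nmds,
    rosner_outliers,
    tukey_hsd,
)

from conftest import make_census


def comp_df(rows, labels=None):
    df = pd.DataFrame(rows)
    if labels is not None:
        df.insert(0, "forest", labels)
        df.insert(1, "env", labels)
    return df


class TestCompositionTable:
    def test_ffg_fraction_of_leaves(self, small_catalog):
        specs = [{"DT2": 1}] * 4 + [{}] * 6  # DT2 is a hole DT
        census = make_census(specs, small_catalog)
        table = composition_table(census, "ffg")
        assert table.iloc[0]["hole"] == pytest.approx(0.4)
        assert table.iloc[0]["mine"] == 0.0

    def test_plant_rows_sum_to_one(self, small_catalog):
        specs = [("A", {}), ("A", {}), ("B", {}), ("C", {})] * 3
        table = composition_table(make_census(specs, small_catalog), "plant")
        vals = table.drop(columns=["forest", "env"])
        assert np.allclose(vals.sum(axis=1), 1.0, atol=1e-12)

    def test_disjoint_plant_pools_give_unit_bray(self, small_catalog):
        records = [
            LeafRecord(f"A{i}", "F1", "E", "Q", f"TropTaxon{i % 3}", {})
            for i in range(9)
        ] + [
            LeafRecord(f"B{i}", "F2", "E", "Q", f"TempTaxon{i % 3}", {})
            for i in range(9)
        ]
        census = Census.from_records(records, small_catalog)
        table = composition_table(census, "plant")
        d = bray_curtis(table)
        cross = d.iloc[0, 1]
        assert cross == pytest.approx(1.0)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = bray_curtis(comp_df([{"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0}]))
        assert d.iloc[0, 1] == pytest.approx(0.0)

    def test_formula_value(self):
        d = bray_curtis(comp_df([{"a": 2.0, "b": 1.0}, {"a": 1.0, "b": 1.0}]))
        assert d.iloc[0, 1] == pytest.approx(0.2)

    def test_symmetric_zero_diagonal_bounded(self, rng):
        x = [dict(enumerate(row)) for row in rng.random((6, 4))]
        d = bray_curtis(comp_df(x)).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert ((d >= 0) & (d <= 1)).all()

    def test_zero_row_flagged(self):
        d = bray_curtis(comp_df([{"a": 0.0}, {"a": 1.0}, {"a": 2.0}]))
        assert math.isnan(d.iloc[0, 1]) and not math.isnan(d.iloc[1, 2])


class TestNMDS:
    def test_three_points_embed_exactly(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
        res = nmds(d, k=2, n_restarts=8, seed=0)
        assert res.stress <= 1e-6

    def test_rank_invariance_under_scaling(self):
        rng = np.random.default_rng(3)
        d = squareform(pdist(rng.random((7, 3))))
        s1 = nmds(d, k=2, n_restarts=6, seed=1).stress
        s2 = nmds(2.0 * d, k=2, n_restarts=6, seed=1).stress
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_more_dimensions_never_worse(self):
        rng = np.random.default_rng(4)
        d = squareform(pdist(rng.random((8, 5))))
        s2 = nmds(d, k=2, n_restarts=10, seed=2).stress
        s3 = nmds(d, k=3, n_restarts=10, seed=2).stress
        assert s3 <= s2 + 1e-6

    def test_asymmetric_input_rejected(self):
        with pytest.raises(CensusValidationError):
            nmds(np.array([[0, 1], [2, 0]], float))


def separated_matrix():
    """Two groups of 3 where every between-distance exceeds every
    within-distance."""
    d = np.full((6, 6), 10.0)
    groups = np.array(["a", "a", "a", "b", "b", "b"])
    for i in range(6):
        for j in range(6):
            if groups[i] == groups[j]:
                d[i, j] = 1.0 if i != j else 0.0
    d += np.arange(36).reshape(6, 6) * 1e-3  # break ties
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    return d, groups


class TestAnosim:
    def test_fully_separated_R_is_one(self):
        d, groups = separated_matrix()
        res = anosim(d, groups, seed=0)
        assert res.R == pytest.approx(1.0)
        # smallest attainable exact p for 2 groups of 3: 2 of 20 arrangements
        assert res.p == pytest.approx(0.1)

    def test_R_matches_scikit_bio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(8)
        d = squareform(pdist(rng.random((10, 4))))
        groups = ["a"] * 5 + ["b"] * 5
        ours = anosim(d, groups, n_perm=99, seed=0)
        theirs = skbio_stats.anosim(
            skbio_stats.DistanceMatrix(d), grouping=list(groups), permutations=99
        )
        assert ours.R == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_null_R_centered_at_zero(self):
        rng = np.random.default_rng(5)
        rs = []
        for _ in range(100):
            d = squareform(pdist(rng.random((9, 3))))
            groups = rng.permutation(["a"] * 4 + ["b"] * 5)
            rs.append(anosim(d, groups, n_perm=0, seed=0, exact_limit=0).R)
        se = np.std(rs, ddof=1) / 10
        assert abs(np.mean(rs)) <= 3 * se

    def test_exact_enumeration_small_designs(self):
        d, groups = separated_matrix()
        res = anosim(d, groups, seed=0)
        assert res.exact  # C(6,3) = 20 arrangements -> exact path
        assert res.p == pytest.approx(1 / 10)  # 2 of 20 arrangements reach R=1

    def test_seeded_determinism_random_path(self):
        rng = np.random.default_rng(6)
        d = squareform(pdist(rng.random((15, 3))))
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        a = anosim(d, groups, n_perm=199, seed=3)
        b = anosim(d, groups, n_perm=199, seed=3)
        assert (a.R, a.p) == (b.R, b.p)

    def test_singleton_group_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(CensusValidationError):
            anosim(d, ["a", "a", "b"])


class TestRosner:
    def test_flags_gross_outlier(self):
        res = rosner_outliers([5.1, 4.9, 5.0, 5.2, 50.0, 5.05, 4.95, 5.1], k_max=1)
        assert res.outliers == [4]

    def test_constant_vector_no_outliers(self):
        res = rosner_outliers([2.0] * 10, k_max=2)
        assert res.outliers == [] and res.note == "zero variance"

    def test_matches_textbook_two_stage_case(self):
        # masked pair: two far values only detectable by the iterative test
        x = [1.0, 1.1, 0.9, 1.05, 0.95, 1.02, 0.98, 1.0, 8.0, 8.1]
        res = rosner_outliers(x, k_max=3)
        assert set(res.outliers) == {8, 9}

    def test_null_calibration(self):
        rng = np.random.default_rng(0)
        n_flagged = sum(
            bool(rosner_outliers(rng.normal(size=30), k_max=3).outliers)
            for _ in range(100)
        )
        assert n_flagged <= 10  # >= 90% of clean samples report no outliers

    def test_small_sample_rejected(self):
        with pytest.raises(CensusValidationError):
            rosner_outliers([1.0, 2.0, 3.0], k_max=3)


class TestTukey:
    def test_two_group_q_equals_sqrt2_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=8), rng.normal(0.5, size=11)
        res = tukey_hsd({"a": a, "b": b})
        t = stats.ttest_ind(a, b).statistic
        assert res.loc[0, "q"] == pytest.approx(math.sqrt(2) * abs(t), abs=1e-9)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(2)
        groups = {g: rng.normal(loc=m, size=7) for g, m in zip("abc", (0, 0.3, 2.0))}
        ours = tukey_hsd(groups).set_index(["group_a", "group_b"])
        ref = stats.tukey_hsd(*groups.values())
        for (i, gi), (j, gj) in [((0, "a"), (1, "b")), ((0, "a"), (2, "c")), ((1, "b"), (2, "c"))]:
            assert ours.loc[(gi, gj), "p_adj"] == pytest.approx(
                ref.pvalue[i, j], abs=1e-9
            )

    def test_null_calibration(self):
        rng = np.random.default_rng(3)
        fp = sum(
            (tukey_hsd({"a": rng.normal(size=6), "b": rng.normal(size=6)})["p_adj"] < 0.05).any()
            for _ in range(100)
        )
        assert fp <= 10

    def test_large_shift_detected(self):
        rng = np.random.default_rng(4)
        groups = {
            "a": rng.normal(0, 1, size=8),
            "b": rng.normal(0, 1, size=8),
            "c": rng.normal(10, 1, size=8),
        }
        res = tukey_hsd(groups).set_index(["group_a", "group_b"])
        assert res.loc[("a", "c"), "p_adj"] < 0.001
        assert res.loc[("b", "c"), "p_adj"] < 0.001

    def test_zero_variance_rejected(self):
        with pytest.raises(CensusValidationError):
            tukey_hsd({"a": [1.0, 1.0], "b": [2.0, 2.0]})
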