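"""Bipartite network metrics against closed forms and brute-force oracles,
plus bootstrap standardization and degree profiles."""

import math
from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from herbivar.census import CensusValidationError, aggregate
from herbivar.networks import (
    IncidenceMatrix,
    _entropy_nats,
    _h2_max_fill,
    _h2_min_fill,
    bootstrap_networks,
    build_incidence,
    connectance,
    degree_profile,
    h2prime,
    nestedness_nodf,
    network_metrics,
    partner_diversity_plants,
    robustness_dts,
)

from conftest import make_census


def im(weights, plants=None, dts=None):
    w = np.asarray(weights, dtype=np.int64)
    plants = plants or tuple(f"P{i}" for i in range(w.shape[0]))
    dts = dts or tuple(f"D{j}" for j in range(w.shape[1]))
    return IncidenceMatrix(plants=tuple(plants), dts=tuple(dts), weights=w)


class TestBuildIncidence:
    def test_sums_counts_per_taxon(self, small_catalog):
        census = make_census(
            [("P1", {"DT2": 2}), ("P1", {"DT2": 1, "DT3": 1})], small_catalog
        )
        m = build_incidence(census)
        assert m.plants == ("P1",)
        assert m.dts == ("DT2", "DT3")
        assert m.weights.tolist() == [[3, 1]]

    def test_undamaged_taxon_dropped(self, small_catalog):
        census = make_census(
            [("P1", {"DT2": 1}), ("P2", {})], small_catalog
        )
        assert build_incidence(census).plants == ("P1",)

    def test_marginals_match_independent_tally(self, small_catalog, rng):
        specs = []
        for _ in range(80):
            taxon = f"P{rng.integers(4)}"
            dts = {d: int(rng.integers(1, 4)) for d in small_catalog.dt_codes if rng.random() < 0.3}
            specs.append((taxon, dts))
        census = make_census(specs, small_catalog)
        m = build_incidence(census)
        tally = {}
        for r in census.iter_leaves():
            for d, n in r.dt_abundances.items():
                tally[d] = tally.get(d, 0) + n
        col_sums = dict(zip(m.dts, m.weights.sum(axis=0)))
        assert col_sums == tally

    def test_no_damage_errors(self, small_catalog):
        census = make_census([("P1", {})], small_catalog)
        with pytest.raises(CensusValidationError):
            build_incidence(census)


class TestConnectance:
    def test_full_matrix(self):
        assert connectance(im(np.ones((3, 4)))) == 1.0

    def test_single_link(self):
        assert connectance(im([[1, 0], [0, 0]])) == 0.25

    def test_counts_cells_exactly(self, rng):
        w = rng.integers(0, 3, size=(5, 7))
        assert connectance(im(w)) == (w > 0).sum() / 35

    def test_invariant_to_weight_scaling(self, rng):
        w = rng.integers(0, 3, size=(4, 4))
        w[0, 0] = 1  # keep nonzero
        assert connectance(im(w)) == connectance(im(w * 17))


def nodf_brute(b):
    """O(n^4) pair-enumeration NODF oracle."""
    def axis_pairs(mat):
        vals = []
        fills = mat.sum(axis=1)
        for i, j in combinations(range(mat.shape[0]), 2):
            hi, lo = (i, j) if fills[i] > fills[j] else (j, i)
            if fills[i] == fills[j] or fills[lo] == 0:
                vals.append(0.0)
            else:
                shared = sum(
                    1 for k in range(mat.shape[1]) if mat[hi, k] and mat[lo, k]
                )
                vals.append(100.0 * shared / fills[lo])
        return vals

    vals = axis_pairs(b) + axis_pairs(b.T)
    return float(np.mean(vals))


class TestNODF:
    def test_perfectly_nested_triangle(self):
        b = [[1, 1, 1], [1, 1, 0], [1, 0, 0]]
        assert nestedness_nodf(im(b)) == pytest.approx(100.0)

    def test_checkerboard_is_zero(self):
        assert nestedness_nodf(im(np.eye(2, dtype=int))) == 0.0

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(25):
            b = (rng.random((6, 6)) < 0.5).astype(int)
            if b.sum() == 0 or b.shape[0] < 2:
                continue
            m = im(b)
            assert nestedness_nodf(m) == pytest.approx(nodf_brute(b), abs=1e-9)

    def test_invariant_to_row_column_permutation(self, rng):
        b = (rng.random((7, 5)) < 0.4).astype(int)
        m = im(b)
        bp = b[rng.permutation(7)][:, rng.permutation(5)]
        assert nestedness_nodf(im(bp)) == pytest.approx(nestedness_nodf(m), abs=1e-9)

    def test_degenerate_single_row_is_nan(self):
        assert math.isnan(nestedness_nodf(im([[1, 1, 0]])))


class TestPartnerDiversity:
    def test_single_partner_plants(self):
        assert partner_diversity_plants(im([[3, 0], [0, 5]])) == 0.0

    def test_two_equal_partners(self):
        assert partner_diversity_plants(im([[2, 2]])) == pytest.approx(math.log(2))

    def test_mean_over_rows_matches_manual(self):
        w = np.array([[1, 1, 2], [4, 0, 0], [1, 1, 0]])
        per_row = []
        for row in w:
            p = row[row > 0] / row.sum()
            per_row.append(-(p * np.log(p)).sum())
        assert partner_diversity_plants(im(w)) == pytest.approx(np.mean(per_row))


class TestRobustness:
    def test_complete_network_closed_form(self):
        # flat survival curve: 1 - 1/(2P), independent of removal order
        assert robustness_dts(im(np.ones((5, 3)))) == pytest.approx(0.9)

    def test_single_plant_hosting_all(self):
        assert robustness_dts(im([[2, 3, 1]])) == pytest.approx(0.5)

    def test_sampled_estimate_within_3se_of_exact(self, rng):
        w = (rng.random((4, 5)) < 0.5).astype(int)
        w[w.sum(axis=1) == 0, 0] = 1
        w = w[:, w.sum(axis=0) > 0]
        m = im(w)
        exact = robustness_dts(m)  # P=4 -> all 24 orders enumerated
        n_orders = 200
        areas = []
        for _ in range(n_orders):
            # sample independently via the public API with a small exact cap
            areas.append(
                robustness_dts(m, n_orders=1, rng=rng, exact_max_plants=0)
            )
        se = np.std(areas, ddof=1) / math.sqrt(n_orders)
        assert abs(np.mean(areas) - exact) <= max(3 * se, 1e-12)

    def test_complete_beats_one_host_per_dt(self):
        complete = robustness_dts(im(np.ones((4, 4))))
        diagonal = robustness_dts(im(np.eye(4, dtype=int)))
        assert complete > diagonal


def enum_matrices(r, c):
    """All nonnegative integer matrices with row sums r and column sums c."""
    R, C = len(r), len(c)

    def rec(row, cols_left):
        if row == R:
            if all(x == 0 for x in cols_left):
                yield []
            return

        def rowvecs(idx, rem, vec):
            if idx == C:
                if rem == 0:
                    yield list(vec)
                return
            for v in range(min(rem, cols_left[idx]) + 1):
                yield from rowvecs(idx + 1, rem - v, vec + [v])

        for rv in rowvecs(0, r[row], []):
            for rest in rec(row + 1, [cl - v for cl, v in zip(cols_left, rv)]):
                yield [rv] + rest

    for rows in rec(0, list(c)):
        yield np.array(rows)


class TestH2Prime:
    def test_diagonal_equal_marginals_fully_specialized(self):
        assert h2prime(np.diag([4, 4, 4, 4])) == pytest.approx(1.0)

    def test_uniform_matrix_unspecialized(self):
        assert h2prime(np.ones((4, 4), dtype=int)) == pytest.approx(0.0)

    def test_extreme_fills_match_exhaustive_enumeration_2x2(self):
        for r1 in range(1, 8):
            for r2 in range(1, 8):
                if r1 + r2 > 8:
                    continue
                for c1 in range(1, r1 + r2):
                    r = np.array([r1, r2])
                    c = np.array([c1, r1 + r2 - c1])
                    ents = [_entropy_nats(w) for w in enum_matrices(r, c)]
                    assert _entropy_nats(_h2_min_fill(r, c)) == pytest.approx(
                        min(ents), abs=1e-9
                    )
                    assert _entropy_nats(_h2_max_fill(r, c)) == pytest.approx(
                        max(ents), abs=1e-9
                    )

    def test_degenerate_matrix_flagged(self):
        assert math.isnan(h2prime(np.array([[1, 2]])))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 15), st.integers(3, 15))
    def test_bounded_on_random_weighted_matrices(self, seed, R, C):
        rng = np.random.default_rng(seed)
        w = rng.poisson(1.2, size=(R, C))
        w = w[w.sum(axis=1) > 0][:, w.sum(axis=0) > 0] if w.sum() else w
        val = h2prime(w)
        if not math.isnan(val):
            assert 0.0 <= val <= 1.0


class TestBootstrap:
    @pytest.fixture(scope="class")
    @staticmethod
    def quarry(small_catalog):
        rng = np.random.default_rng(99)
        specs = []
        for _ in range(120):
            taxon = f"P{rng.integers(5)}"
            dts = {
                d: int(rng.integers(1, 3))
                for d in small_catalog.dt_codes
                if rng.random() < 0.25
            }
            specs.append((taxon, dts))
        return make_census(specs, small_catalog)

    def test_full_sample_reps_identical(self, quarry):
        br = bootstrap_networks(quarry, sample_size=120, n_boot=5, seed=1)
        assert br.reps.drop(columns="robustness").nunique().max() == 1

    def test_fixed_seed_reproducible(self, quarry):
        a = bootstrap_networks(quarry, sample_size=60, n_boot=10, seed=42)
        b = bootstrap_networks(quarry, sample_size=60, n_boot=10, seed=42)
        assert a.reps.equals(b.reps)

    def test_mean_connectance_tracks_full_quarry(self, quarry):
        full = connectance(build_incidence(quarry))
        br = bootstrap_networks(
            quarry, sample_size=100, n_boot=200, seed=7, which=("connectance",)
        )
        sd = br.reps["connectance"].std()
        assert abs(br.reps["connectance"].mean() - full) <= max(3 * sd, 0.05)

    def test_too_few_leaves_errors(self, quarry):
        with pytest.raises(CensusValidationError):
            bootstrap_networks(quarry, sample_size=500, n_boot=2, seed=0)

    def test_bootstrap_matches_direct_incidence_build(self, quarry):
        """A rep drawing every leaf reproduces build_incidence exactly."""
        br = bootstrap_networks(quarry, sample_size=120, n_boot=1, seed=3)
        direct = build_incidence(quarry)
        assert br.reps["connectance"].iloc[0] == pytest.approx(connectance(direct))
        assert br.reps["h2prime"].iloc[0] == pytest.approx(h2prime(direct))


class TestDegreeProfile:
    def test_degrees_and_absent_dts(self, small_catalog):
        census = make_census(
            [("P1", {"DT2": 1}), ("P2", {"DT2": 2}), ("P3", {"DT3": 1})],
            small_catalog,
        )
        prof = degree_profile(census)
        col = prof.columns[1]
        assert prof.loc["DT2", col] == 2
        assert prof.loc["DT3", col] == 1
        assert prof["ffg"].loc["DT2"] == "hole"

    def test_generalists_attain_higher_degree_than_specialists(self):
        from herbivar.synthetic import default_study_config, generate_census

        census = generate_census(default_study_config(seed=6))
        prof = degree_profile(census)
        by_class = {
            d.dt_code: d.spec_class
            for d in default_study_config().dt_pool
        }
        deg = prof.drop(columns="ffg")
        med = deg.median(axis=1)
        gen = med[[d for d in med.index if by_class[d] == "generalized"]]
        spec = med[[d for d in med.index if by_class[d] == "specialized"]]
        assert gen.median() > spec.median()

    def test_drop_singletons_never_increases_degree(self, small_catalog):
        census = make_census(
            [("P1", {"DT2": 1}), ("P2", {"DT3": 1}), ("P3", {"DT3": 2})],
            small_catalog,
        )
        full = degree_profile(census).drop(columns="ffg")
        nosing = degree_profile(census, drop_singletons=True).drop(columns="ffg")
        assert (nosing <= full).all().all()
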