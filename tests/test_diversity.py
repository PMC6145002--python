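"""Alpha/beta diversity: grid aggregation, LCBD identities, Baselga
decomposition, permutation test, and paired comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enmstack.climate import ScenarioTag
from enmstack.diversity import (BetaTriplet, GridSystem, PairCounts,
                                PresenceAbsenceMatrix, decompose_matrix,
                                decompose_pair, jaccard_d, jaccard_matrix, lcbd,
                                lcbd_permutation_test, mean_triplet, paired_t,
                                pair_counts, richness, richness_change,
                                ternary_coords)
from enmstack.ensemble import BinaryRange


def pa_from_lists(*site_species: list[str]) -> PresenceAbsenceMatrix:
    species = sorted({s for lst in site_species for s in lst})
    data = pd.DataFrame([[s in lst for s in species] for lst in site_species],
                        index=[f"site{i}" for i in range(len(site_species))],
                        columns=species)
    return PresenceAbsenceMatrix(data)


def lcbd_oracle(x: np.ndarray):
    """Independent oracle: hand double-centering with explicit loops, plus
    the Gower pairwise identity SStotal = (1/n) sum_{i<j} d^2_ij."""
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            a = np.sum(x[i] & x[j])
            b = np.sum(x[i] & ~x[j])
            c = np.sum(~x[i] & x[j])
            d[i, j] = 0.0 if a + b + c == 0 else (b + c) / (a + b + c)
    A = -0.5 * d**2
    g = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            g[i, j] = (A[i, j] - A[i].mean() - A[:, j].mean() + A.mean())
    sstotal = np.trace(g)
    ss_pairwise = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    return np.diag(g) / sstotal, sstotal, ss_pairwise


class TestGridAggregation:
    def _range(self, mask):
        return BinaryRange("sp", ScenarioTag("baseline"),
                           np.asarray(mask, dtype=bool), 0.5, cell_size_km=10)

    def test_empty_fine_mask_all_absent(self):
        grid = GridSystem((10, 10), 10, 50)
        assert not grid.aggregate(np.zeros((10, 10), dtype=bool)).any()

    def test_single_fine_cell_maps_to_its_coarse_cell(self):
        grid = GridSystem((10, 10), 10, 50)  # 2x2 coarse cells
        mask = np.zeros((10, 10), dtype=bool)
        mask[7, 2] = True  # coarse row 1, col 0
        vec = grid.aggregate(mask)
        assert vec.sum() == 1
        coords = grid.site_coords_km()
        hit = coords.iloc[int(np.flatnonzero(vec)[0])]
        assert (hit["coarse_row"], hit["coarse_col"]) == (1, 0)

    def test_partial_edge_cells_kept(self):
        grid = GridSystem((12, 12), 10, 50)  # 120 km -> 3x3 coarse, edges partial
        assert grid.n_sites == 9

    def test_region_mask_restricts_sites(self):
        region = np.zeros((10, 10), dtype=bool)
        region[:5, :5] = True
        grid = GridSystem((10, 10), 10, 50, region_mask=region)
        assert grid.n_sites == 1

    def test_union_rule_matches_truth(self):
        rng = np.random.default_rng(0)
        grid = GridSystem((20, 20), 10, 50)
        mask = rng.random((20, 20)) > 0.8
        vec = grid.aggregate(mask)
        # brute force: coarse cell (R, C) covers fine rows 5R..5R+4
        for k, sid in enumerate(grid.site_ids):
            row = grid.site_coords_km().iloc[k]
            R, C = int(row["coarse_row"]), int(row["coarse_col"])
            block = mask[5 * R:5 * R + 5, 5 * C:5 * C + 5]
            assert vec[k] == block.any()


class TestRichness:
    def test_identity_matrix(self):
        pa = PresenceAbsenceMatrix(pd.DataFrame(np.eye(4, dtype=bool)))
        assert (richness(pa) == 1).all()

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        x = rng.random((20, 30)) > 0.6
        pa = PresenceAbsenceMatrix(pd.DataFrame(x))
        np.testing.assert_array_equal(richness(pa).to_numpy(),
                                      [row.sum() for row in x])

    def test_change_classification(self):
        cur = pd.Series([3, 2, 5], index=list("abc"))
        fut = pd.Series([4, 2, 1], index=list("abc"))
        out = richness_change(cur, fut)
        assert out["class"].tolist() == ["gain", "stable", "loss"]
        assert out["delta"].tolist() == [1, 0, -4]

    def test_change_site_mismatch_rejected(self):
        with pytest.raises(ValueError):
            richness_change(pd.Series([1], index=["a"]), pd.Series([1], index=["b"]))


class TestPairedT:
    def test_hand_arithmetic(self):
        # differences {-1, 0, -2}: mean -1, sd 1 -> t = -sqrt(3), df = 2
        t, p, df = paired_t([5, 5, 5], [4, 5, 3])
        assert t == pytest.approx(-np.sqrt(3))
        assert df == 2

    def test_direction_follows_shift(self):
        rng = np.random.default_rng(2)
        cur = rng.normal(10, 1, 200)
        t_up, *_ = paired_t(cur, cur + 0.5 + rng.normal(0, 0.2, 200))
        t_dn, *_ = paired_t(cur, cur - 0.5 + rng.normal(0, 0.2, 200))
        assert t_up > 0 > t_dn

    def test_null_p_uniform(self):
        rng = np.random.default_rng(3)
        ps = [paired_t(rng.normal(size=30), rng.normal(size=30))[1]
              for _ in range(400)]
        # p-values approximately uniform under the null
        assert abs(np.mean(np.array(ps) < 0.5) - 0.5) < 0.08
        assert abs(np.mean(np.array(ps) < 0.1) - 0.1) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            paired_t([1, 2, 3], [2, 3, 4])


class TestJaccardDecomposition:
    def test_jaccard_examples(self):
        assert jaccard_d(PairCounts(3, 0, 0)) == 0.0
        assert jaccard_d(PairCounts(0, 2, 3)) == 1.0
        assert jaccard_d(PairCounts(1, 1, 1)) == pytest.approx(2 / 3)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            jaccard_d(PairCounts(0, 0, 0))

    def test_nested_pair_pure_nestedness(self):
        t = decompose_pair(PairCounts(1, 2, 0))
        assert t.repl == 0.0
        assert t.nes == pytest.approx(2 / 3)
        assert t.s == pytest.approx(1 / 3)

    def test_symmetric_turnover(self):
        t = decompose_pair(PairCounts(1, 1, 1))
        assert t.repl == pytest.approx(2 / 3)
        assert t.nes == pytest.approx(0.0)
        assert t.s == pytest.approx(1 / 3)

    def test_identical_sites(self):
        t = decompose_pair(PairCounts(4, 0, 0))
        assert (t.s, t.repl, t.nes) == (1.0, 0.0, 0.0)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_closure_property(self, a, b, c):
        if a + b + c == 0:
            return
        t = decompose_pair(PairCounts(a, b, c))
        assert abs(t.s + t.repl + t.nes - 1) < 1e-12
        assert 0 <= t.s <= 1 and 0 <= t.repl <= 1 and 0 <= t.nes <= 1
        if min(b, c) == 0:
            assert t.repl == 0.0

    def test_matrix_decomposition_matches_pairwise(self):
        rng = np.random.default_rng(4)
        x = rng.random((12, 18)) > 0.5
        x = x[x.any(axis=1)]
        pa = PresenceAbsenceMatrix(pd.DataFrame(x))
        table = decompose_matrix(pa)
        k = 0
        for i in range(len(x)):
            for j in range(i + 1, len(x)):
                t = decompose_pair(pair_counts(x[i], x[j]))
                assert table.iloc[k]["S"] == pytest.approx(t.s)
                assert table.iloc[k]["Repl"] == pytest.approx(t.repl)
                assert table.iloc[k]["Nes"] == pytest.approx(t.nes)
                k += 1


class TestLcbd:
    def test_two_sites_split_evenly(self):
        res = lcbd(pa_from_lists(["sp1"], ["sp2"]))
        np.testing.assert_allclose(res.lcbd, [0.5, 0.5])

    def test_worked_three_site_example(self):
        # sites {sp1}, {sp1}, {sp2}: hand double-centering gives
        # LCBD = (1/6, 1/6, 2/3), SStotal = 2/3, BDtotal = 1/3
        res = lcbd(pa_from_lists(["sp1"], ["sp1"], ["sp2"]))
        np.testing.assert_allclose(res.lcbd, [1 / 6, 1 / 6, 2 / 3], atol=1e-12)
        assert res.sstotal == pytest.approx(2 / 3)
        assert res.bdtotal == pytest.approx(1 / 3)

    def test_matches_hand_oracle_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.random((rng.integers(3, 12), rng.integers(3, 15))) > 0.5
            x = x[x.any(axis=1)]
            if len(x) < 2:
                continue
            try:
                res = lcbd(x)
            except ValueError:
                continue
            o_lcbd, o_ss, o_ss_pair = lcbd_oracle(x)
            np.testing.assert_allclose(res.lcbd, o_lcbd, atol=1e-10)
            assert res.sstotal == pytest.approx(o_ss, abs=1e-10)
            assert res.sstotal == pytest.approx(o_ss_pair, abs=1e-10)

    def test_lcbd_sums_to_one(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            x = rng.random((10, 12)) > 0.4
            x = x[x.any(axis=1)]
            if len(x) < 2:
                continue
            try:
                res = lcbd(x)
            except ValueError:
                continue
            assert res.lcbd.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(res.lcbd >= -1e-15)

    def test_empty_sites_excluded_and_recorded(self):
        pa = pa_from_lists(["sp1"], [], ["sp2"], [])
        res = lcbd(pa)
        assert res.excluded_sites == ["site1", "site3"]
        assert len(res.lcbd) == 2

    def test_identical_sites_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            lcbd(pa_from_lists(["sp1"], ["sp1"], ["sp1"]))

    def test_homogenization_direction(self):
        # adding a ubiquitous species never increases BDtotal
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.random((8, 10)) > 0.5
            x = x[x.any(axis=1)]
            if len(x) < 2:
                continue
            try:
                before = lcbd(x).bdtotal
            except ValueError:
                continue
            xa = np.column_stack([x, np.ones(len(x), dtype=bool)])
            assert lcbd(xa).bdtotal <= before + 1e-12


class TestPermutationTest:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        x = rng.random((12, 15)) > 0.5
        a = lcbd_permutation_test(x, n_perm=99, seed=4)
        b = lcbd_permutation_test(x, n_perm=99, seed=4)
        np.testing.assert_array_equal(a.p_values, b.p_values)

    def test_planted_unique_site_most_significant(self):
        rng = np.random.default_rng(9)
        x = np.zeros((10, 12), dtype=bool)
        x[:, :6] = rng.random((10, 6)) > 0.3  # common pool
        x[0] = False
        x[0, 6:] = True  # site 0 has a completely different composition
        res = lcbd_permutation_test(x, n_perm=199, seed=0)
        assert np.argmin(res.p_values) == 0
        assert np.argmax(res.lcbd) == 0

    def test_pvalues_have_add_one_floor(self):
        rng = np.random.default_rng(10)
        x = rng.random((8, 10)) > 0.5
        res = lcbd_permutation_test(x, n_perm=49, seed=1)
        assert np.all(res.p_values >= 1 / 50)
        assert np.all(res.p_values <= 1.0)


class TestTriplets:
    def test_mean_triplet_identity_and_average(self):
        t = mean_triplet(np.array([[1.0, 0.0, 0.0]]))
        assert (t.s, t.repl, t.nes) == (1.0, 0.0, 0.0)
        t2 = mean_triplet(np.array([[1, 0, 0], [0, 1, 0.0]]))
        assert (t2.s, t2.repl, t2.nes) == (0.5, 0.5, 0.0)

    def test_mean_matches_brute_force(self):
        rng = np.random.default_rng(11)
        raw = rng.dirichlet([1, 1, 1], size=100)
        t = mean_triplet(raw)
        np.testing.assert_allclose([t.s, t.repl, t.nes], raw.mean(axis=0))
        assert t.s + t.repl + t.nes == pytest.approx(1.0)

    def test_ternary_vertices_and_centroid(self):
        assert ternary_coords(BetaTriplet(1, 0, 0)) == pytest.approx((0.5, np.sqrt(3) / 2))
        assert ternary_coords(BetaTriplet(0, 1, 0)) == pytest.approx((0.0, 0.0))
        assert ternary_coords(BetaTriplet(0, 0, 1)) == pytest.approx((1.0, 0.0))
        third = BetaTriplet(1 / 3, 1 / 3, 1 / 3)
        assert ternary_coords(third) == pytest.approx((0.5, np.sqrt(3) / 6))


def test_jaccard_matrix_agrees_with_pair_counts():
    rng = np.random.default_rng(12)
    x = rng.random((10, 14)) > 0.5
    x = x[x.any(axis=1)]
    from scipy.spatial.distance import squareform

    d = squareform(jaccard_matrix(x))
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            assert d[i, j] == pytest.approx(jaccard_d(pair_counts(x[i], x[j])))


def test_extinction_contraction_raises_nestedness_share():
    """Losing narrow-ranged species entirely (pure contraction) converts
    turnover into richness-difference nestedness: the mean Nes share of the
    triplets rises in aggregate and in nearly every replicate (the response
    is a strong tendency, not a pointwise law — uniform thinning of shared
    species can push the other way)."""
    rng = np.random.default_rng(13)
    increases = 0
    total = 0
    deltas = []
    for _ in range(30):
        # widespread core + narrow endemics
        x = np.zeros((12, 20), dtype=bool)
        x[:, :10] = rng.random((12, 10)) > 0.3
        for sp in range(10, 20):  # narrow species occupy 1-2 sites
            sites = rng.choice(12, size=rng.integers(1, 3), replace=False)
            x[sites, sp] = True
        x = x[x.any(axis=1)]
        pa = PresenceAbsenceMatrix(pd.DataFrame(x))
        before = mean_triplet(decompose_matrix(pa)).nes
        xc = x.copy()
        xc[:, 10:] = False  # extinction of all narrow endemics
        xc = xc[xc.any(axis=1)]
        after = mean_triplet(decompose_matrix(PresenceAbsenceMatrix(pd.DataFrame(xc)))).nes
        total += 1
        deltas.append(after - before)
        if after >= before - 1e-12:
            increases += 1
    assert np.mean(deltas) > 0
    assert increases >= 0.85 * total
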