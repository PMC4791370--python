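"""Distance construction, ordination, clustering and permutation tests."""

import numpy as np
import pandas as pd
import pytest
import skbio.stats.distance as skd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from domlink import multivariate_stats as ms


def _dm(points, ids=None):
    ids = ids or [f"S{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(np.asarray(points))), ids=ids)


class TestDistance:
    def test_identical_rows_give_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        for metric in ("euclidean", "bray_curtis", "hellinger"):
            assert ms.distance(df, metric)["a", "b"] == pytest.approx(0.0)

    def test_bray_curtis_disjoint_support(self):
        df = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"])
        assert ms.distance(df, "bray_curtis")["a", "b"] == pytest.approx(1.0)

    def test_hellinger_hand_case(self):
        df = pd.DataFrame([[1.0, 0.0], [0.25, 0.75]], index=["a", "b"])
        d = ms.distance(df, "hellinger")["a", "b"]
        expected = np.hypot(1 - 0.5, 0.0 - np.sqrt(0.75))
        assert d == pytest.approx(expected, abs=1e-12)
        assert d == pytest.approx(1.0, abs=1e-6)

    def test_sqrt_transform_applied_before_bray(self):
        df = pd.DataFrame([[1.0, 4.0], [4.0, 1.0]], index=["a", "b"])
        d = ms.distance(df, "bray_curtis", transform="sqrt")
        raw = pdist(np.sqrt(df.to_numpy()), "braycurtis")[0]
        assert d["a", "b"] == pytest.approx(raw)

    def test_negative_entries_rejected(self):
        df = pd.DataFrame([[1.0, -0.1], [0.5, 0.5]], index=["a", "b"])
        with pytest.raises(ValueError):
            ms.distance(df, "bray_curtis")


class TestPcoa:
    def test_reconstructs_euclidean_configuration(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        res = ms.pcoa(_dm(pts))
        assert np.abs(pdist(res.coordinates.to_numpy()) - pdist(pts)).max() < 1e-8

    def test_collinear_points_have_rank_one(self):
        pts = np.array([[0.0], [1.0], [2.0], [3.5]])
        res = ms.pcoa(_dm(pts))
        assert (res.eigenvalues > 1e-8).sum() == 1

    def test_eigenvalue_sum_equals_trace(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 4))
        d2 = squareform(pdist(pts)) ** 2
        res = ms.pcoa(_dm(pts))
        assert res.eigenvalues.sum() == pytest.approx(
            np.trace(ms._gower_center(d2)), abs=1e-8
        )

    def test_negative_eigenvalues_reported(self):
        df = pd.DataFrame(
            np.random.default_rng(2).dirichlet(np.ones(6), size=8),
            index=[f"S{i}" for i in range(8)],
        )
        res = ms.pcoa(ms.distance(df, "bray_curtis"))
        assert (res.eigenvalues < 0).any()

    def test_axes_sorted_descending(self):
        rng = np.random.default_rng(3)
        res = ms.pcoa(_dm(rng.normal(size=(9, 5))))
        assert (np.diff(res.eigenvalues) <= 1e-12).all()


class TestAnosim:
    def test_hand_ranked_four_sample_case(self):
        # condensed distances (12,13,14,23,24,34) = (3,4,5,6,1,2); groups
        # {1,2} vs {3,4}: within ranks {3,2} mean 2.5, between {4,5,6,1}
        # mean 4; R = (4 - 2.5) / (6/2) = 0.5
        d = squareform([3.0, 4.0, 5.0, 6.0, 1.0, 2.0])
        dm = DistanceMatrix(d, ids=list("abcd"))
        assert ms.anosim_r(dm, ["g1", "g1", "g2", "g2"]) == pytest.approx(0.5)

    def test_perfect_separation_gives_one(self):
        pts = np.vstack([np.zeros((3, 2)) + [[0, 0], [0.1, 0], [0, 0.1]],
                         np.ones((3, 2)) * 10 + [[0, 0], [0.1, 0], [0, 0.1]]])
        dm = _dm(pts)
        assert ms.anosim_r(dm, ["a"] * 3 + ["b"] * 3) == pytest.approx(1.0)

    def test_all_equal_distances_give_zero(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(d, ids=list("abcd"))
        assert ms.anosim_r(dm, ["a", "a", "b", "b"]) == pytest.approx(0.0)

    def test_matches_skbio_on_random_data(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            pts = rng.normal(size=(12, 4))
            dm = _dm(pts)
            g = rng.choice(["x", "y", "z"], size=12).tolist()
            if len(set(g)) < 2:
                continue
            mine = ms.anosim_r(dm, g)
            ref = skd.anosim(dm, np.array(g), permutations=0)["test statistic"]
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_range_property_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            n = int(rng.integers(5, 12))
            pts = rng.normal(size=(n, 3))
            g = rng.choice(["a", "b"], size=n)
            if len(set(g)) < 2:
                continue
            r = ms.anosim_r(_dm(pts), g.tolist())
            assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12


def brute_force_best_partition(dm, rank_sq=None):
    """Oracle: exhaustive two-group partition search maximizing ANOSIM R."""
    n = dm.shape[0]
    rank_sq = ms._rank_matrix(dm) if rank_sq is None else rank_sq
    best_r, best_codes = -np.inf, None
    for bits in range(1, 2 ** (n - 1)):
        codes = np.array([(bits >> i) & 1 for i in range(n)])
        r = ms._anosim_from_ranks(rank_sq, codes)
        if r > best_r:
            best_r, best_codes = r, codes
    return best_r, best_codes


class TestKrCluster:
    def test_recovers_separated_clouds(self):
        rng = np.random.default_rng(7)
        pts = np.vstack([rng.normal(0, 1, (5, 3)), rng.normal(8, 1, (5, 3))])
        dm = _dm(pts)
        part, r = ms.kr_cluster(dm, k=2, restarts=20, seed=0)
        assert r == pytest.approx(1.0)
        codes = pd.factorize(part.assignment)[0]
        assert len(set(codes[:5])) == 1 and codes[0] != codes[5]

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(8)
        for s in range(10):
            pts = rng.normal(size=(9, 3))
            dm = _dm(pts)
            best_r, _ = brute_force_best_partition(dm)
            _, r = ms.kr_cluster(dm, k=2, restarts=50, seed=s)
            assert r == pytest.approx(best_r, abs=1e-12)

    def test_matches_exhaustive_search_at_study_size(self):
        # n = 17: all 2^16 - 1 two-group partitions, R computed straight
        # from its definition (vectorized), as an independent oracle
        rng = np.random.default_rng(31)
        for s in range(2):
            n = 17
            dm = _dm(rng.normal(size=(n, 3)))
            rank_sq = ms._rank_matrix(dm)
            iu = np.triu_indices(n, 1)
            total = rank_sq[iu].sum()
            m_pairs = n * (n - 1) / 2
            bits = np.arange(1, 2 ** (n - 1))
            memb = (bits[:, None] >> np.arange(n - 1)[None, :]) & 1
            a = np.hstack([np.zeros((len(bits), 1)), memb]).astype(float)
            b = 1.0 - a
            wsum = (
                np.einsum("bi,ij,bj->b", a, rank_sq, a)
                + np.einsum("bi,ij,bj->b", b, rank_sq, b)
            ) / 2.0
            n_a = a.sum(axis=1)
            pairs_w = n_a * (n_a - 1) / 2 + (n - n_a) * (n - n_a - 1) / 2
            r_within = wsum / pairs_w
            r_between = (total - wsum) / (m_pairs - pairs_w)
            best = ((r_between - r_within) / (m_pairs / 2)).max()
            _, r = ms.kr_cluster(dm, 2, restarts=50, seed=s)
            assert r == pytest.approx(best, abs=1e-10)

    def test_label_order_invariance(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(10, 3))
        dm = _dm(pts)
        perm = rng.permutation(10)
        dm_p = DistanceMatrix(
            np.asarray(dm.data)[np.ix_(perm, perm)],
            ids=[list(dm.ids)[i] for i in perm],
        )
        _, r1 = ms.kr_cluster(dm, 2, restarts=50, seed=1)
        _, r2 = ms.kr_cluster(dm_p, 2, restarts=50, seed=1)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        dm = _dm(rng.normal(size=(12, 3)))
        p1, r1 = ms.kr_cluster(dm, 3, restarts=10, seed=4)
        p2, r2 = ms.kr_cluster(dm, 3, restarts=10, seed=4)
        assert r1 == r2 and p1.assignment.equals(p2.assignment)


class TestPermanova:
    def test_hand_computed_pseudo_f(self):
        # 1-D points A: 0,1,2; B: 10,11,12 (euclidean)
        # SSW = (1+4+1)/3 * 2 = 4; SST = 924/6 = 154; F = 150/1 = 150
        pts = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        res = ms.permanova(_dm(pts), ["A"] * 3 + ["B"] * 3, permutations=99, seed=0)
        assert res.statistic == pytest.approx(150.0, abs=1e-10)

    def test_matches_skbio_statistic(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(15, 4))
        g = (["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        dm = _dm(pts)
        mine = ms.permanova(dm, g, permutations=9, seed=0).statistic
        ref = skd.permanova(dm, np.array(g), permutations=9)["test statistic"]
        assert mine == pytest.approx(ref, abs=1e-10)

    def test_strong_separation_minimal_p(self):
        rng = np.random.default_rng(12)
        pts = np.vstack([rng.normal(0, 0.1, (9, 2)), rng.normal(50, 0.1, (8, 2))])
        res = ms.permanova(_dm(pts), ["A"] * 9 + ["B"] * 8, permutations=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_p_on_permutation_grid(self):
        rng = np.random.default_rng(13)
        res = ms.permanova(
            _dm(rng.normal(size=(10, 3))), ["A"] * 5 + ["B"] * 5,
            permutations=99, seed=2,
        )
        assert (res.p_value * 100) == pytest.approx(round(res.p_value * 100))
        assert res.p_value >= 1 / 100


class TestAnova:
    def test_equal_means_give_zero_f(self):
        v = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], index=list("abcdef"))
        f, p = ms.anova_oneway(v, ["g1"] * 3 + ["g2"] * 3)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(14)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        v = pd.Series(np.concatenate([a, b]))
        f, p = ms.anova_oneway(v, ["A"] * 8 + ["B"] * 9)
        t, pt = stats.ttest_ind(a, b)
        assert f == pytest.approx(t**2)
        assert p == pytest.approx(pt)

    def test_large_shift_significant(self):
        rng = np.random.default_rng(15)
        v = pd.Series(np.concatenate([rng.normal(0, 1, 10), rng.normal(8, 1, 10)]))
        _, p = ms.anova_oneway(v, ["A"] * 10 + ["B"] * 10)
        assert p < 1e-3


class TestEffectSize:
    def _data(self, rng, shift, n_per=10, n_feat=20):
        base = rng.lognormal(3, 0.4, size=(2 * n_per, n_feat))
        base[n_per:, 0] *= shift
        idx = [f"S{i}" for i in range(2 * n_per)]
        return (
            pd.DataFrame(base, index=idx, columns=[f"f{i}" for i in range(n_feat)]),
            ["A"] * n_per + ["B"] * n_per,
        )

    def test_planted_shift_reported(self):
        df, g = self._data(np.random.default_rng(16), shift=100.0)
        res = ms.effect_size_ranking(df, g, seed=0)
        top = res[0]
        assert top.feature == "f0"
        assert top.lda_score >= 2.0
        assert top.enriched_group == "B"
        assert top.kw_p < 0.05

    def test_constant_feature_never_reported(self):
        # identical across groups *in relative terms*: fix the row sums so
        # the per-sample scaling leaves the feature constant
        rng = np.random.default_rng(17)
        comp = rng.dirichlet(np.ones(19), size=20) * 0.95
        df = pd.DataFrame(comp, index=[f"S{i}" for i in range(20)],
                          columns=[f"f{i}" for i in range(19)])
        df["const"] = 0.05
        res = ms.effect_size_ranking(df, ["A"] * 10 + ["B"] * 10, seed=0)
        assert "const" not in {r.feature for r in res}

    def test_requires_three_per_group(self):
        df, _ = self._data(np.random.default_rng(18), shift=1.0, n_per=2)
        with pytest.raises(ValueError):
            ms.effect_size_ranking(df, ["A", "A", "B", "B"], seed=0)

    def test_requires_two_groups(self):
        df, g = self._data(np.random.default_rng(19), shift=1.0)
        with pytest.raises(ValueError):
            ms.effect_size_ranking(df, ["A"] * len(df), seed=0)


class TestDistLM:
    def _setup(self, rng, n=24):
        x = pd.DataFrame(
            rng.normal(size=(n, 4)),
            index=[f"S{i}" for i in range(n)],
            columns=["driver", "n1", "n2", "n3"],
        )
        dm = _dm(x[["driver"]].to_numpy(), ids=list(x.index))
        return dm, x

    def test_generating_predictor_selected_first(self):
        dm, x = self._setup(np.random.default_rng(20))
        res = ms.distlm(dm, x, permutations=999, seed=0)
        assert res.selected[0] == "driver"
        assert res.marginal.loc["driver", "p_value"] == pytest.approx(1 / 1000)
        assert res.marginal.loc["driver", "r2"] == pytest.approx(1.0, abs=1e-8)

    def test_saturated_orthonormal_basis_gives_full_r2(self):
        rng = np.random.default_rng(21)
        n = 10
        pts = rng.normal(size=(n, 3))
        dm = _dm(pts)
        basis = pd.DataFrame(np.eye(n)[:, : n - 1], index=[f"S{i}" for i in range(n)])
        g = ms._gower_center(np.asarray(dm.data) ** 2)
        xc = basis.to_numpy() - basis.to_numpy().mean(axis=0)
        r2, _, _ = ms._r2_f(g, xc)
        assert r2 == pytest.approx(1.0, abs=1e-8)

    def test_collinear_columns_refused_by_name(self):
        dm, x = self._setup(np.random.default_rng(22))
        x["dup"] = 2.0 * x["n1"] + 1.0
        with pytest.raises(ValueError, match="dup|n1"):
            ms.distlm(dm, x, permutations=9, seed=0)

    def test_adjusted_r2_not_above_r2(self):
        dm, x = self._setup(np.random.default_rng(23))
        res = ms.distlm(dm, x, permutations=99, seed=0)
        assert res.adj_r2 <= res.r2 <= 1.0 + 1e-12


class TestDbrda:
    def test_single_binary_predictor_one_axis(self):
        rng = np.random.default_rng(24)
        pts = rng.normal(size=(10, 3))
        dm = _dm(pts)
        x = pd.DataFrame({"g": [0] * 5 + [1] * 5}, index=[f"S{i}" for i in range(10)])
        res = ms.dbrda(dm, x)
        tol = 1e-8 * np.abs(res.eigenvalues).max()
        assert (res.eigenvalues > tol).sum() == 1
        assert res.constrained

    def test_constrained_variance_bounded_by_pcoa(self):
        rng = np.random.default_rng(25)
        pts = rng.normal(size=(12, 4))
        dm = _dm(pts)
        x = pd.DataFrame(rng.normal(size=(12, 2)), index=[f"S{i}" for i in range(12)])
        con = ms.dbrda(dm, x)
        unc = ms.pcoa(dm)
        assert con.eigenvalues[con.eigenvalues > 0].sum() <= (
            unc.eigenvalues[unc.eigenvalues > 0].sum() + 1e-10
        )

    def test_saturated_basis_equals_pcoa(self):
        rng = np.random.default_rng(26)
        pts = rng.normal(size=(9, 3))
        dm = _dm(pts)
        basis = pd.DataFrame(np.eye(9)[:, :8], index=[f"S{i}" for i in range(9)])
        con = ms.dbrda(dm, basis)
        unc = ms.pcoa(dm)
        assert np.allclose(
            np.sort(con.eigenvalues)[::-1][:5], np.sort(unc.eigenvalues)[::-1][:5],
            atol=1e-8,
        )
        assert np.abs(
            pdist(con.coordinates.to_numpy()) - pdist(unc.coordinates.to_numpy())
        ).max() < 1e-8

    def test_empty_selection_refused(self):
        rng = np.random.default_rng(27)
        dm = _dm(rng.normal(size=(6, 2)))
        with pytest.raises(ValueError):
            ms.dbrda(dm, pd.DataFrame(index=[f"S{i}" for i in range(6)]))


class TestRelate:
    def test_identity_gives_rho_one(self):
        rng = np.random.default_rng(28)
        dm = _dm(rng.normal(size=(10, 3)))
        res = ms.relate(dm, dm, permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(29)
        dm1 = _dm(rng.normal(size=(10, 3)))
        d2 = np.asarray(dm1.data) ** 2  # monotone on non-negative distances
        dm2 = DistanceMatrix(d2, ids=list(dm1.ids))
        res = ms.relate(dm1, dm2, permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_label_mismatch_refused(self):
        rng = np.random.default_rng(30)
        dm1 = _dm(rng.normal(size=(5, 2)))
        dm2 = _dm(rng.normal(size=(5, 2)), ids=list("vwxyz"))
        with pytest.raises(ValueError):
            ms.relate(dm1, dm2)
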