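"""From-scratch permutational statistics vs independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

import foodwebkit as fwk
from foodwebkit.permstats import PermStatsError


def brute_one_way_f(D, labels):
    """Independent one-way pseudo-F from within-group distance sums."""
    labels = np.asarray(labels)
    n = len(labels)
    sst = (D ** 2).sum() / (2 * n)
    ssw = 0.0
    for lv in np.unique(labels):
        idx = np.where(labels == lv)[0]
        ssw += (D[np.ix_(idx, idx)] ** 2).sum() / (2 * len(idx))
    a = len(np.unique(labels))
    return ((sst - ssw) / (a - 1)) / (ssw / (n - a))


class TestPermanova:
    def test_euclidean_univariate_equals_classical_anova(self, rng):
        y = rng.normal(size=18)
        g = np.repeat(["a", "b", "c"], 6)
        D = squareform(pdist(y[:, None]))
        res = fwk.permanova(D, pd.DataFrame({"g": g}), n_perm=99, seed=0)
        F = stats.f_oneway(*[y[g == lv] for lv in "abc"]).statistic
        assert res.terms[0].pseudo_f == pytest.approx(F, rel=1e-9)

    def test_matches_scikit_bio_pseudo_f(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova
        X = rng.uniform(size=(15, 6))
        D = squareform(pdist(X, metric="braycurtis"))
        g = np.repeat(["a", "b", "c"], 5)
        ours = fwk.permanova(D, pd.DataFrame({"g": g}), n_perm=99, seed=0)
        theirs = sk_permanova(DistanceMatrix(D), g, permutations=99)
        assert ours.terms[0].pseudo_f == pytest.approx(
            theirs["test statistic"], rel=1e-9)

    def test_perfect_separation_floor_p(self):
        # two tight clusters far apart
        y = np.array([0.0, 0.0, 0.001, 10.0, 10.0, 10.001])
        D = squareform(pdist(y[:, None]))
        g = ["a"] * 3 + ["b"] * 3
        res = fwk.permanova(D, pd.DataFrame({"g": g}), n_perm=99,
                            permutations="exhaustive")
        f_obs = res.terms[0].pseudo_f
        count = sum(brute_one_way_f(D, np.array(g)[list(p)])
                    >= f_obs * (1 - 1e-6)
                    for p in itertools.permutations(range(6)))
        assert count == 72  # 2 partitions x (3! x 3!) orderings
        assert res.terms[0].p == pytest.approx(count / 720)
        assert res.terms[0].p == pytest.approx(2 / 20)

    @pytest.mark.parametrize("groups", [
        ["a", "a", "a", "b", "b", "b"],
        ["a", "a", "b", "b", "c", "c"],
        ["a", "a", "a", "a", "b", "b"],
    ])
    def test_exhaustive_p_equals_full_enumeration(self, groups, rng):
        """Permutation P under exhaustive enumeration equals an independent
        brute-force oracle over all 720 relabelings."""
        X = rng.uniform(size=(6, 4))
        D = squareform(pdist(X, metric="braycurtis"))
        res = fwk.permanova(D, pd.DataFrame({"g": groups}), n_perm=99,
                            permutations="exhaustive")
        f_obs = brute_one_way_f(D, groups)
        count = sum(brute_one_way_f(D, np.asarray(groups)[list(p)])
                    >= f_obs - 1e-12
                    for p in itertools.permutations(range(6)))
        assert res.terms[0].pseudo_f == pytest.approx(f_obs, rel=1e-9)
        assert res.terms[0].p == pytest.approx(count / 720)

    def test_balanced_type_iii_conserves_total_ss(self, rng):
        X = rng.uniform(size=(24, 5))
        D = squareform(pdist(X, metric="braycurtis"))
        design = pd.DataFrame({
            "year": np.tile(np.repeat(["Pre", "2013"], 6), 2),
            "section": np.repeat(["LE", "ME"], 12)})
        res = fwk.permanova(D, design, n_perm=99, seed=0)
        total_terms = sum(t.ss for t in res.terms) + res.residual_ss
        assert total_terms == pytest.approx(res.total_ss, rel=1e-9)

    def test_two_way_detects_imposed_factor(self, rng):
        base = rng.uniform(1, 3, size=(24, 6))
        base[12:, :3] *= 6.0  # strong section effect
        D = squareform(pdist(base, metric="braycurtis"))
        design = pd.DataFrame({
            "year": np.tile(np.repeat(["Pre", "2013"], 6), 2),
            "section": np.repeat(["LE", "ME"], 12)})
        res = fwk.permanova(D, design, n_perm=199, seed=1)
        assert res["section"].p <= 0.01
        assert res["year"].p > 0.05

    def test_seed_invariance_in_distribution(self, rng):
        X = rng.uniform(size=(14, 5))
        D = squareform(pdist(X, metric="braycurtis"))
        g = pd.DataFrame({"g": np.repeat(["a", "b"], 7)})
        p1 = fwk.permanova(D, g, n_perm=9999, seed=1).terms[0].p
        p2 = fwk.permanova(D, g, n_perm=9999, seed=2).terms[0].p
        se = math.sqrt(p1 * (1 - p1) / 9999)
        assert abs(p1 - p2) <= 3 * max(se, 1e-3)

    def test_invalid_inputs_rejected(self):
        D = np.zeros((4, 4))
        with pytest.raises(PermStatsError):
            fwk.permanova(D, pd.DataFrame({"g": ["a"] * 4}), n_perm=99)
        bad = np.arange(16, dtype=float).reshape(4, 4)
        with pytest.raises(PermStatsError, match="symmetric"):
            fwk.permanova(bad, pd.DataFrame({"g": ["a", "a", "b", "b"]}),
                          n_perm=99)


class TestPairwise:
    def test_small_groups_get_monte_carlo_flag(self, rng):
        X = rng.uniform(size=(5, 4))
        D = squareform(pdist(X, metric="braycurtis"))
        out = fwk.pairwise(D, ["a", "a", "a", "b", "b"], n_perm=99, seed=0)
        assert out[0].n_unique_perms == math.comb(5, 3) == 10
        assert out[0].monte_carlo

    def test_bonferroni_threshold_for_six_comparisons(self, rng):
        X = rng.uniform(size=(16, 4))
        D = squareform(pdist(X, metric="braycurtis"))
        labels = np.repeat(["Pre", "2012", "2013", "2014"], 4)
        out = fwk.pairwise(D, labels, n_perm=99, seed=0)
        assert len(out) == 6
        assert out[0].alpha_adjusted == pytest.approx(0.05 / 6, abs=1e-6)
        assert out[0].alpha_adjusted == pytest.approx(0.0083, abs=5e-4)

    def test_pseudo_t_is_sqrt_of_two_group_f(self, rng):
        X = rng.uniform(size=(10, 4))
        D = squareform(pdist(X, metric="braycurtis"))
        labels = np.repeat(["a", "b"], 5)
        out = fwk.pairwise(D, labels, n_perm=99, seed=0)
        assert out[0].pseudo_t == pytest.approx(
            math.sqrt(brute_one_way_f(D, labels)), rel=1e-9)

    def test_null_pair_large_p(self, rng):
        X = np.vstack([rng.uniform(size=(1, 4))] * 8) \
            + rng.normal(0, 1e-3, size=(8, 4))
        D = squareform(pdist(X, metric="braycurtis"))
        out = fwk.pairwise(D, np.repeat(["a", "b"], 4), n_perm=999, seed=0)
        assert out[0].p > 0.1


class TestAnosim:
    def brute_r(self, D, labels):
        n = len(labels)
        ranks = stats.rankdata(squareform(D, checks=False))
        iu = np.triu_indices(n, 1)
        within = np.asarray(labels)[iu[0]] == np.asarray(labels)[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (n * (n - 1) / 4)

    def test_complete_separation_gives_r_one(self):
        y = np.array([0.0, 0.1, 0.2, 5.0, 5.1, 5.2])
        D = squareform(pdist(y[:, None]))
        res = fwk.anosim(D, ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_matches_brute_force_ranks_small_n(self, rng):
        for trial in range(20):
            X = rng.uniform(size=(9, 4))
            D = squareform(pdist(X, metric="braycurtis"))
            labels = list(rng.choice(["a", "b"], size=9))
            if len(set(labels)) < 2 or min(labels.count("a"),
                                           labels.count("b")) < 2:
                continue
            res = fwk.anosim(D, labels, n_perm=99, seed=trial)
            assert res.r == pytest.approx(self.brute_r(D, labels), abs=1e-12)
            assert -1 <= res.r <= 1

    def test_matches_scikit_bio(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import anosim as sk_anosim
        X = rng.uniform(size=(12, 5))
        D = squareform(pdist(X, metric="braycurtis"))
        g = np.repeat(["a", "b", "c"], 4)
        ours = fwk.anosim(D, g, n_perm=99, seed=0)
        theirs = sk_anosim(DistanceMatrix(D), g, permutations=99)
        assert ours.r == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_null_mean_near_zero(self, rng):
        X = rng.uniform(size=(10, 4))
        D = squareform(pdist(X, metric="braycurtis"))
        rs = []
        for i in range(300):
            labels = rng.permutation(["a"] * 5 + ["b"] * 5)
            rs.append(self.brute_r(D, labels))
        assert abs(np.mean(rs)) < 0.05


class TestSimper:
    def test_single_differing_taxon_contributes_all(self):
        M = pd.DataFrame({"A": [1.0, 1.0, 1.0, 1.0],
                          "B": [2.0, 2.0, 5.0, 5.0]})
        out = fwk.simper(M, ["g1", "g1", "g2", "g2"], "g1", "g2")
        assert out.iloc[0]["taxon"] == "B"
        assert out.iloc[0]["contribution_pct"] == pytest.approx(100.0)

    def test_decomposition_sums_to_mean_dissimilarity(self, rng):
        M = pd.DataFrame(rng.uniform(0, 10, size=(9, 7)))
        labels = ["g1"] * 5 + ["g2"] * 4
        out = fwk.simper(M, labels, "g1", "g2")
        dis = 100.0 * squareform(pdist(M.values, metric="braycurtis"))
        between = dis[:5, 5:]
        assert out["contribution"].sum() == pytest.approx(
            between.mean(), rel=1e-9)
        assert out["contribution_pct"].sum() == pytest.approx(100.0, rel=1e-9)

    def test_matches_brute_force_per_taxon(self, rng):
        M = pd.DataFrame(rng.uniform(0, 5, size=(6, 4)),
                         columns=list("wxyz"))
        labels = ["g1"] * 3 + ["g2"] * 3
        out = fwk.simper(M, labels, "g1", "g2").set_index("taxon")
        for col in "wxyz":
            acc = 0.0
            for i in range(3):
                for j in range(3, 6):
                    x1, x2 = M.iloc[i], M.iloc[j]
                    acc += 100 * abs(x1[col] - x2[col]) / (x1 + x2).sum()
            assert out.loc[col, "contribution"] == pytest.approx(
                acc / 9, rel=1e-9)

    def test_identical_groups_zero_contributions(self):
        M = pd.DataFrame([[1.0, 2.0]] * 4)
        out = fwk.simper(M, ["g1", "g1", "g2", "g2"], "g1", "g2")
        assert (out["contribution"] == 0).all()

    def test_cutoff_flags_reporting_rows(self, rng):
        M = pd.DataFrame(rng.uniform(0, 10, size=(8, 12)))
        out = fwk.simper(M, ["g1"] * 4 + ["g2"] * 4, "g1", "g2",
                         cutoff_pct=2.0)
        assert out["report"].equals(out["contribution_pct"] >= 2.0)


class TestNMDS:
    def test_line_embeds_with_negligible_stress(self):
        pts = np.array([0.0, 1.0, 2.5, 4.0, 7.0])
        D = np.abs(np.subtract.outer(pts, pts))
        res = fwk.nmds(D, k=1, seed=0)
        assert res.stress < 1e-6
        assert res.converged

    def test_stress_non_increasing_in_k(self, rng):
        X = rng.uniform(size=(9, 6))
        D = squareform(pdist(X, metric="braycurtis"))
        sc = fwk.nmds_scree(D, ks=(1, 2, 3), seed=0)
        assert sc[2].stress <= sc[1].stress + 1e-12
        assert sc[3].stress <= sc[2].stress + 1e-12

    def test_four_point_instance_matches_multistart_reference(self):
        """A 4-point metric instance: heavy multi-start reference and the
        default solver agree on final stress."""
        D = np.array([[0, 1, 2, 2.2],
                      [1, 0, 1.1, 2.0],
                      [2, 1.1, 0, 1.05],
                      [2.2, 2.0, 1.05, 0.0]])
        res = fwk.nmds(D, k=2, restarts=4, seed=0)
        ref = fwk.nmds(D, k=2, restarts=40, seed=99)
        assert res.stress == pytest.approx(ref.stress, abs=1e-3)

    def test_deterministic_orientation(self, rng):
        X = rng.uniform(size=(7, 5))
        D = squareform(pdist(X, metric="braycurtis"))
        a = fwk.nmds(D, k=2, seed=3)
        b = fwk.nmds(D, k=2, seed=3)
        assert np.allclose(a.coordinates, b.coordinates)
        assert np.allclose(a.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_k_must_be_less_than_n(self):
        with pytest.raises(PermStatsError):
            fwk.nmds(np.zeros((3, 3)), k=3)
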