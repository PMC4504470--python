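import itertools

import numpy as np
import pandas as pd
import pytest

from cyanodelim import simulate
from cyanodelim.core_io import CommunityMatrix, CyanodelimError, EnvTable
from cyanodelim.ecology import (DissimilarityMatrix, anosim, bioenv_bvstep,
                                bioenv_exhaustive, dissimilarity,
                                matrix_correlation, normalize_env,
                                significance_stars, simper)


def env_table(arr, cols=None, index=None):
    arr = np.asarray(arr, dtype=float)
    cols = cols or [f"v{i}" for i in range(arr.shape[1])]
    index = index or [f"L{i}" for i in range(arr.shape[0])]
    return EnvTable(pd.DataFrame(arr, columns=cols, index=index))


class TestNormalize:
    def test_zscore_hand_values(self):
        env = normalize_env(env_table([[1], [2], [3]]))
        assert np.allclose(env.data["v0"], [-1, 0, 1])

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        env = normalize_env(env_table(rng.normal(size=(8, 3))))
        again = normalize_env(env)
        assert np.allclose(env.data, again.data, atol=1e-12)

    def test_columns_zero_mean_unit_sd(self):
        rng = np.random.default_rng(1)
        env = normalize_env(env_table(rng.normal(2, 5, size=(12, 4))))
        assert np.allclose(env.data.mean(), 0, atol=1e-9)
        assert np.allclose(env.data.std(ddof=1), 1, atol=1e-9)

    def test_substrate_expanded_then_scaled(self):
        raw = EnvTable(pd.DataFrame({"sst": [1.0, 2.0, 3.0, 4.0]},
                                    index=list("abcd")),
                       substrate=pd.Series(["acid", "volcanic", "acid",
                                            "volcanic"], index=list("abcd")))
        env = normalize_env(raw)
        assert set(env.data.columns) == {"sst", "substrate_acid",
                                         "substrate_volcanic"}
        # indicator (1,0,1,0) z-scored with sd sqrt(1/3)
        assert np.allclose(sorted(env.data["substrate_acid"])[:2],
                           [-np.sqrt(3) / 2] * 2)

    def test_constant_column_named_in_error(self):
        with pytest.raises(CyanodelimError, match="v1"):
            normalize_env(env_table([[1, 7], [2, 7], [3, 7]]))


class TestDissimilarity:
    def test_identical_rows_zero(self):
        cm = CommunityMatrix(pd.DataFrame([[1, 0, 1]] * 2,
                                          index=["a", "b"]))
        assert dissimilarity(cm, "sorensen").matrix[0, 1] == 0

    def test_disjoint_rows_one(self):
        cm = CommunityMatrix(pd.DataFrame([[1, 1, 0, 0], [0, 0, 1, 1]],
                                          index=["a", "b"]))
        assert dissimilarity(cm, "sorensen").matrix[0, 1] == pytest.approx(1)

    def test_sorensen_hand_value(self):
        cm = CommunityMatrix(pd.DataFrame([[1, 1, 0], [1, 0, 1]],
                                          index=["a", "b"]))
        # a=1 shared, b=c=1 exclusive: 1 - 2/4
        assert dissimilarity(cm, "sorensen").matrix[0, 1] == pytest.approx(0.5)

    def test_counts_rejected_by_sorensen(self):
        cm = CommunityMatrix(pd.DataFrame([[2, 0], [0, 1]], index=["a", "b"]))
        with pytest.raises(CyanodelimError, match="presence/absence"):
            dissimilarity(cm, "sorensen")

    def test_all_zero_row_rejected(self):
        cm = CommunityMatrix(pd.DataFrame([[1, 0], [0, 0]], index=["a", "b"]))
        with pytest.raises(CyanodelimError, match="all-zero"):
            dissimilarity(cm, "sorensen")


def separated_matrix():
    """Two groups of 3 with every within distance below every between."""
    D = np.full((6, 6), 0.9)
    for block in (slice(0, 3), slice(3, 6)):
        D[block, block] = 0.1
    np.fill_diagonal(D, 0)
    ids = [f"L{i}" for i in range(6)]
    groups = {i: ("A" if k < 3 else "B") for k, i in enumerate(ids)}
    return DissimilarityMatrix(D, ids, "sorensen"), groups


class TestAnosim:
    def test_perfect_separation_R_one(self):
        D, groups = separated_matrix()
        res = anosim(D, groups, n_perm=999, seed=0, pairwise=False)
        assert res.R == pytest.approx(1.0)

    def test_all_equal_distances_R_zero(self):
        D = np.full((6, 6), 0.5)
        np.fill_diagonal(D, 0)
        ids = [f"L{i}" for i in range(6)]
        groups = {i: ("A" if k < 3 else "B") for k, i in enumerate(ids)}
        res = anosim(DissimilarityMatrix(D, ids, "braycurtis"), groups,
                     n_perm=99, seed=0, pairwise=False)
        assert res.R == pytest.approx(0.0)

    def test_permutation_p_matches_exact_enumeration(self):
        rng = np.random.default_rng(3)
        M = rng.uniform(0.2, 1.0, (6, 6))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0)
        ids = [f"L{i}" for i in range(6)]
        groups = {i: ("A" if k < 3 else "B") for k, i in enumerate(ids)}
        dm = DissimilarityMatrix(D, ids, "braycurtis")
        res = anosim(dm, groups, n_perm=10_000, seed=1, pairwise=False)
        # exact: all 20 assignments of 3 A's among 6 localities
        from scipy.spatial.distance import squareform
        from scipy.stats import rankdata
        ranks = squareform(rankdata(squareform(D, checks=False)),
                           checks=False)
        iu = np.triu_indices(6, 1)

        def stat(lab):
            lab = np.asarray(lab)
            within = lab[iu[0]] == lab[iu[1]]
            return (ranks[iu][~within].mean()
                    - ranks[iu][within].mean()) / (15 / 2)
        obs = stat([g == "A" for g in (groups[i] for i in ids)])
        perms = [stat([i in c for i in range(6)])
                 for c in itertools.combinations(range(6), 3)]
        exact_p = np.mean([p >= obs - 1e-12 for p in perms])
        assert res.p == pytest.approx(exact_p, abs=0.02)

    def test_R_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(9)
        M = rng.uniform(0.1, 1.0, (8, 8))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0)
        ids = [f"L{i}" for i in range(8)]
        groups = {i: ("A" if k < 4 else "B") for k, i in enumerate(ids)}
        r1 = anosim(DissimilarityMatrix(D, ids, "braycurtis"), groups,
                    n_perm=9, seed=0, pairwise=False).R
        r2 = anosim(DissimilarityMatrix(D ** 2, ids, "braycurtis"), groups,
                    n_perm=9, seed=0, pairwise=False).R
        assert r1 == pytest.approx(r2)

    def test_matches_skbio_statistic(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import anosim as sk_anosim
        cm, _, _ = simulate.simulate_community(n_localities=12, seed=5)
        D = dissimilarity(cm, "sorensen")
        groups = {i: ("A" if k < 6 else "B") for k, i in enumerate(D.ids)}
        mine = anosim(D, groups, n_perm=9, seed=0, pairwise=False).R
        ref = sk_anosim(DistanceMatrix(D.matrix, D.ids),
                        [groups[i] for i in D.ids], permutations=9)
        assert mine == pytest.approx(float(ref["test statistic"]))

    def test_singleton_group_pairwise_not_computable(self):
        D = np.full((5, 5), 0.5)
        np.fill_diagonal(D, 0)
        ids = [f"L{i}" for i in range(5)]
        groups = dict(zip(ids, ["A", "A", "B", "B", "C"]))
        res = anosim(DissimilarityMatrix(D, ids, "braycurtis"), groups,
                     n_perm=9, seed=0)
        assert np.isnan(res.pairwise_R.loc["A", "C"])
        assert not np.isnan(res.pairwise_R.loc["A", "B"])


class TestSimper:
    def test_single_differing_unit_contributes_all(self):
        cm = CommunityMatrix(pd.DataFrame(
            [[1, 1], [1, 1], [1, 0], [1, 0]],
            index=list("abcd"), columns=["u1", "u2"]))
        groups = dict(zip("abcd", "AABB"))
        tab = simper(cm, groups)
        assert tab.loc["u2", "percent"] == pytest.approx(100.0)

    def test_hand_two_by_two(self):
        cm = CommunityMatrix(pd.DataFrame(
            [[2, 0], [0, 1]], index=["a", "b"], columns=["u1", "u2"]))
        tab = simper(cm, {"a": "A", "b": "B"})
        assert tab.loc["u1", "average"] == pytest.approx(2 / 3)
        assert tab.loc["u2", "average"] == pytest.approx(1 / 3)
        assert tab.loc["u1", "percent"] == pytest.approx(200 / 3)

    def test_percents_sum_to_hundred(self):
        rng = np.random.default_rng(7)
        cm = CommunityMatrix(pd.DataFrame(
            rng.integers(0, 5, (8, 6)),
            index=[f"L{i}" for i in range(8)]))
        groups = {f"L{i}": ("A" if i < 4 else "B") for i in range(8)}
        tab = simper(cm, groups)
        assert tab["percent"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_identical_groups_warn_empty(self):
        cm = CommunityMatrix(pd.DataFrame(
            [[1, 1], [1, 1]], index=["a", "b"]))
        with pytest.warns(UserWarning):
            tab = simper(cm, {"a": "A", "b": "B"})
        assert tab.empty


class TestBioenv:
    def test_planted_monotone_signal_selected(self):
        rng = np.random.default_rng(2)
        g = np.sort(rng.normal(size=20))
        X = np.column_stack([g] + [rng.normal(size=20) for _ in range(5)])
        env = normalize_env(env_table(X))
        D = DissimilarityMatrix(np.abs(g[:, None] - g[None, :]),
                                list(env.data.index), "euclidean")
        res = bioenv_bvstep(D, env, n_restarts=20, collin_mode=None, seed=0)
        assert res.best_vars == ("v0",)
        assert res.best_rho >= 0.95  # stopped by the rho criterion

    def test_greedy_bounded_by_exhaustive(self):
        cm, env, _ = simulate.simulate_community(n_localities=15,
                                                 n_env_vars=6, seed=3)
        D = dissimilarity(cm, "sorensen")
        envn = normalize_env(env)
        greedy = bioenv_bvstep(D, envn, n_restarts=15, collin_mode=None,
                               seed=1)
        exact = bioenv_exhaustive(D, envn)
        assert greedy.best_rho <= exact.best_rho + 1e-12

    def test_exhaustive_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix, bioenv
        cm, env, _ = simulate.simulate_community(n_localities=12,
                                                 n_env_vars=5, seed=4)
        D = dissimilarity(cm, "sorensen")
        envn = normalize_env(env)
        mine = bioenv_exhaustive(D, envn)
        ref = bioenv(DistanceMatrix(D.matrix, D.ids), envn.data)
        assert mine.best_rho == pytest.approx(
            float(ref["correlation"].max()), abs=1e-9)

    def test_model_frequencies_tally(self):
        cm, env, _ = simulate.simulate_community(n_localities=15, seed=6)
        D = dissimilarity(cm, "sorensen")
        res = bioenv_bvstep(D, normalize_env(env), n_restarts=10,
                            collin_mode=None, seed=0)
        assert sum(m["frequency"] for m in res.models) == pytest.approx(1.0)

    def test_literal_distance_rule_drops_dissimilar_columns(self):
        # z-scored independent columns sit far apart in Euclidean terms,
        # so the literal reading excludes all but the first variable
        rng = np.random.default_rng(1)
        env = normalize_env(env_table(rng.normal(size=(20, 4))))
        D = DissimilarityMatrix(
            np.abs(rng.normal(size=(20, 1)) - rng.normal(size=(1, 20))) * 0
            + dissimilarity(env, "euclidean").matrix,
            list(env.data.index), "euclidean")
        with pytest.raises(CyanodelimError, match="fewer than 2"):
            bioenv_bvstep(D, env, n_restarts=2, collin_mode="distance")

    def test_correlation_rule_drops_duplicates_only(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=20)
        X = np.column_stack([base, base + 1e-9 * rng.normal(size=20),
                             rng.normal(size=20)])
        env = normalize_env(env_table(X))
        D = dissimilarity(env, "euclidean")
        res = bioenv_bvstep(D, env, n_restarts=5, collin_mode="correlation",
                            seed=0)
        assert res.excluded == ["v1"]


class TestMatrixCorrelation:
    def _dm(self, D, tag="braycurtis"):
        ids = [f"L{i}" for i in range(D.shape[0])]
        return DissimilarityMatrix(D, ids, tag)

    def test_identity_gives_rho_one(self):
        rng = np.random.default_rng(0)
        M = rng.uniform(0.1, 1, (7, 7))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0)
        rho, p = matrix_correlation(self._dm(D), self._dm(D), n_perm=99,
                                    seed=0)
        assert rho == pytest.approx(1.0)
        assert p <= 0.05

    def test_reversed_ranks_give_minus_one(self):
        n = 6
        vals = np.arange(1, n * (n - 1) // 2 + 1, dtype=float)
        from scipy.spatial.distance import squareform
        D1 = squareform(vals)
        D2 = squareform(vals.max() + 1 - vals)
        rho, _ = matrix_correlation(self._dm(D1, "euclidean"),
                                    self._dm(D2, "euclidean"), n_perm=9,
                                    seed=0)
        assert rho == pytest.approx(-1.0)

    def test_hand_ranked_five_localities(self):
        rng = np.random.default_rng(5)
        M1 = rng.uniform(0, 1, (5, 5))
        M2 = rng.uniform(0, 1, (5, 5))
        D1 = (M1 + M1.T) / 2
        D2 = (M2 + M2.T) / 2
        np.fill_diagonal(D1, 0)
        np.fill_diagonal(D2, 0)
        from scipy.spatial.distance import squareform
        from scipy.stats import rankdata
        v1, v2 = squareform(D1, checks=False), squareform(D2, checks=False)
        r1, r2 = rankdata(v1), rankdata(v2)
        expected = np.corrcoef(r1, r2)[0, 1]
        rho, _ = matrix_correlation(self._dm(D1), self._dm(D2), n_perm=9,
                                    seed=0)
        assert rho == pytest.approx(expected)

    def test_statistic_matches_skbio_mantel(self):
        from skbio.stats.distance import DistanceMatrix, mantel
        cm1, _, _ = simulate.simulate_community(n_localities=10, seed=1)
        cm2, _, _ = simulate.simulate_community(n_localities=10, seed=2)
        D1 = dissimilarity(cm1, "sorensen")
        D2 = dissimilarity(cm2, "sorensen")
        rho, _ = matrix_correlation(D1, D2, n_perm=9, seed=0)
        ref, _, _ = mantel(DistanceMatrix(D1.matrix, D1.ids),
                           DistanceMatrix(D2.matrix, D2.ids),
                           method="spearman", permutations=0)
        assert rho == pytest.approx(float(ref))

    def test_index_mismatch_rejected(self):
        D = np.zeros((3, 3))
        a = DissimilarityMatrix(D, ["x", "y", "z"], "euclidean")
        b = DissimilarityMatrix(D, ["x", "y", "w"], "euclidean")
        with pytest.raises(CyanodelimError, match="mismatch"):
            matrix_correlation(a, b)


def test_significance_star_convention():
    assert [significance_stars(p) for p in (0.2, 0.04, 0.004, 0.0004)] == \
        ["n.s.", "*", "**", "***"]
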