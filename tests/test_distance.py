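"""Distance stage: scaling, PC truncation, patristic distances, regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from dmicontinuum.distance import (
    DistanceError,
    explained_variance_fractions,
    patristic_distances,
    reduce_and_distance,
    ri_distance_regression,
    scale_columns,
)
from dmicontinuum.synth import TraitSpec, make_traits


def check_distance_matrix(dm: pd.DataFrame):
    d = dm.to_numpy()
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0.0)
    assert (d >= -1e-12).all()
    n = d.shape[0]
    for i in range(n):
        for j in range(n):
            for k in range(n):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestScaleColumns:
    def test_hand_arithmetic(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, 10.0, 20.0]})
        out = scale_columns(m)
        assert np.allclose(out["a"], [-1.0, 0.0, 1.0])
        assert out.mean().abs().max() < 1e-12
        assert np.allclose(out.std(ddof=1), 1.0)

    def test_idempotent(self):
        m = pd.DataFrame(np.random.default_rng(0).normal(size=(6, 4)))
        once = scale_columns(m)
        twice = scale_columns(once)
        assert np.allclose(once, twice, atol=1e-12)

    def test_constant_column_named_in_error(self):
        m = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(DistanceError, match="flat"):
            scale_columns(m)


class TestReduceAndDistance:
    def test_full_variance_equals_plain_euclidean(self):
        m = make_traits(TraitSpec(n_pops=8, n_vars=12, latent_dims=3, seed=1))
        scaled = scale_columns(m)
        dm = reduce_and_distance(scaled, variance_target=1.0)
        direct = squareform(pdist(scaled.to_numpy()))
        assert np.allclose(dm.to_numpy(), direct, atol=1e-9)

    def test_identical_rows_have_zero_distance(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 0.5], [1.0, 2.0, 0.5], [3.0, -1.0, 2.0], [0.0, 1.0, 4.0]],
            index=list("ABCD"),
        )
        dm = reduce_and_distance(scale_columns(m), variance_target=1.0)
        assert dm.loc["A", "B"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_bruteforce_eigendecomposition(self):
        # 4 populations, exact 2-component structure: compare the truncated
        # projection distances against a hand-rolled eigendecomposition
        rng = np.random.default_rng(3)
        z = rng.normal(size=(4, 2)) * [4.0, 2.0]
        w = rng.normal(size=(2, 6))
        m = pd.DataFrame(z @ w, index=list("ABCD"))
        scaled = scale_columns(m)
        x = scaled.to_numpy() - scaled.to_numpy().mean(axis=0)
        evals, evecs = np.linalg.eigh(x @ x.T / (x.shape[0] - 1))
        order = np.argsort(evals)[::-1]
        # scores from the Gram matrix route: U * sqrt(lambda * (n-1))
        scores = evecs[:, order[:2]] * np.sqrt(np.maximum(evals[order[:2]], 0) * 3)
        expected = squareform(pdist(scores))
        dm = reduce_and_distance(scaled, axes_override=2)
        assert np.allclose(dm.to_numpy(), expected, atol=1e-8)

    def test_axis_override_bounds_checked(self):
        m = make_traits(TraitSpec(n_pops=5, n_vars=6, latent_dims=2, seed=2))
        with pytest.raises(DistanceError):
            reduce_and_distance(scale_columns(m), axes_override=9)

    def test_explained_variance_sums_to_one(self):
        m = make_traits(TraitSpec(n_pops=8, n_vars=10, latent_dims=4, seed=4))
        fractions = explained_variance_fractions(scale_columns(m))
        assert (fractions >= -1e-12).all()
        assert fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_output_is_a_valid_distance_matrix(self):
        m = make_traits(TraitSpec(n_pops=6, n_vars=9, latent_dims=3, seed=5))
        check_distance_matrix(reduce_and_distance(scale_columns(m), 0.95))


class TestPatristicDistances:
    def test_cherry(self):
        dm = patristic_distances("(A:1.0,B:2.0);", ["A", "B"])
        assert dm.loc["A", "B"] == pytest.approx(3.0)
        assert dm.loc["A", "A"] == 0.0

    def test_balanced_four_tip_unit_branches(self):
        newick = "((A:1,B:1):1,(C:1,D:1):1);"
        dm = patristic_distances(newick, ["A", "B", "C", "D"])
        assert dm.loc["A", "B"] == pytest.approx(2.0)
        assert dm.loc["C", "D"] == pytest.approx(2.0)
        for a in "AB":
            for b in "CD":
                assert dm.loc[a, b] == pytest.approx(4.0)
        check_distance_matrix(dm)

    def test_ultrametric_three_point_condition(self):
        newick = "((A:1,B:1):2,(C:2,D:2):1);"
        dm = patristic_distances(newick, ["A", "B", "C", "D"]).to_numpy()
        n = dm.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert dm[i, j] <= max(dm[i, k], dm[k, j]) + 1e-9

    def test_missing_tip_named(self):
        with pytest.raises(DistanceError, match="Z"):
            patristic_distances("(A:1,B:1);", ["A", "Z"])

    def test_negative_branch_length_rejected(self):
        with pytest.raises(DistanceError, match="negative"):
            patristic_distances("(A:1,B:-0.5);", ["A", "B"])


def _pair_frame(n_pairs, rng):
    pops = [f"P{i}" for i in range(n_pairs + 1)]
    pairs = [(pops[0], p) for p in pops[1:]]  # star: n_pairs pairs
    return pops, pairs


class TestRIDistanceRegression:
    @staticmethod
    def random_matrices(pops, rng):
        def dist(values):
            n = len(pops)
            d = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            d[iu] = values
            return pd.DataFrame(d + d.T, index=pops, columns=pops)

        n_off = len(pops) * (len(pops) - 1) // 2
        return dist(rng.uniform(1, 2, n_off)), dist(rng.uniform(0, 1, n_off))

    def test_exact_linear_relationship_recovered(self):
        pops = list("ABCDE")
        rng = np.random.default_rng(0)
        genetic, env = self.random_matrices(pops, rng)
        genetic.loc[:, :] = np.where(np.eye(5), 0.0, 1.0)  # constant off-diagonal
        rows = []
        for i, a in enumerate(pops):
            for b in pops[i + 1:]:
                rows.append({"pop_a": a, "pop_b": b, "ri": 0.1 + 0.5 * env.loc[a, b]})
        res = ri_distance_regression(pd.DataFrame(rows), genetic, env, "env")
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)
        assert res.coefficients["env"] == pytest.approx(0.5, abs=1e-9)

    def test_too_few_pairs_rejected(self):
        pops = list("ABC")
        genetic, env = self.random_matrices(pops, np.random.default_rng(1))
        rows = pd.DataFrame(
            {"pop_a": ["A", "A", "B"], "pop_b": ["B", "C", "C"], "ri": [0.1, 0.2, 0.3]}
        )
        with pytest.raises(DistanceError):
            ri_distance_regression(rows, genetic, env)

    def test_small_n_flag(self):
        pops = list("ABCD")
        rng = np.random.default_rng(2)
        genetic, env = self.random_matrices(pops, rng)
        rows = [
            {"pop_a": a, "pop_b": b, "ri": rng.uniform(-0.2, 0.6)}
            for i, a in enumerate(pops)
            for b in pops[i + 1:]
        ]
        res = ri_distance_regression(pd.DataFrame(rows), genetic, env)
        assert res.n_pairs == 6
        assert res.small_n

    def test_null_p_values_roughly_uniform(self):
        # RI independent of both distances: the sequential F p-value for the
        # second predictor should be uniform across generator seeds
        from scipy import stats

        pops = [f"P{i}" for i in range(7)]
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            genetic, env = self.random_matrices(pops, rng)
            rows = [
                {"pop_a": a, "pop_b": b, "ri": rng.normal(0.2, 0.1)}
                for i, a in enumerate(pops)
                for b in pops[i + 1:]
            ]
            res = ri_distance_regression(pd.DataFrame(rows), genetic, env, "env")
            pvals.append(res.p_values["env"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_effect_recovered_within_ci(self):
        pops = [f"P{i}" for i in range(6)]  # 15 pairs
        hits = 0
        n_seeds = 50
        beta = 0.5
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            genetic, env = self.random_matrices(pops, rng)
            rows = []
            for i, a in enumerate(pops):
                for b in pops[i + 1:]:
                    ri = 0.05 * genetic.loc[a, b] + beta * env.loc[a, b] + rng.normal(0, 0.05)
                    rows.append({"pop_a": a, "pop_b": b, "ri": ri})
            res = ri_distance_regression(pd.DataFrame(rows), genetic, env, "env")
            est = res.coefficients["env"]
            # 95% CI from the residual-based SE implied by the F statistic
            se = abs(est) / np.sqrt(res.f_statistics["env"]) if res.f_statistics["env"] > 0 else np.inf
            hits += abs(est - beta) <= 2.18 * se  # t_{.975, df=12}
        assert hits >= 0.9 * n_seeds
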