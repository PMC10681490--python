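"""Ordination core: fits against brute-force oracles, adjusted R^2,
permutation tests, forward selection, variance partitioning, outliers."""

import numpy as np
import pandas as pd
import pytest

from adaptscan.rda import (
    RDA,
    OrdinationResult,
    adjusted_r2,
    anova_axes,
    assign_outlier_axis,
    forward_select,
    outlier_snps,
    rda_fit,
    significant_axes,
    variance_partition,
)


def brute_force_constrained_eigs(Y, X, Z=None):
    """Independent oracle: explicit projection-matrix arithmetic."""
    n = Y.shape[0]
    ones = np.ones((n, 1))
    C = ones if Z is None else np.hstack([ones, Z])
    Pc = C @ np.linalg.pinv(C)
    Yr = Y - Pc @ Y
    Xr = X - Pc @ X
    Px = Xr @ np.linalg.pinv(Xr)
    Yhat = Px @ Yr
    eigs = np.linalg.eigvalsh(Yhat.T @ Yhat / (n - 1))[::-1]
    return eigs[eigs > 1e-12]


class TestRdaFit:
    def test_perfect_fit(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        res = rda_fit(x[:, None], x[:, None])
        assert res.r2 == pytest.approx(1.0)
        assert len(res.eigenvalues) == 1
        assert abs(res.loadings[0, 0]) == pytest.approx(1.0)

    def test_orthogonal_predictor_zero_r2(self):
        n = 8
        y = np.tile([1.0, -1], n // 2)
        x = np.tile([1.0, 1, -1, -1], n // 4)
        res = rda_fit(y[:, None], x[:, None])
        assert res.r2 == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("shape", [(6, 4, 2), (10, 20, 3)])
    def test_eigenvalues_match_bruteforce_oracle(self, shape):
        n, L, p = shape
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(n, L))
        X = rng.normal(size=(n, p))
        res = rda_fit(Y, X)
        oracle = brute_force_constrained_eigs(Y - Y.mean(axis=0), X)
        assert np.allclose(res.eigenvalues, oracle, atol=1e-8)

    def test_variance_conservation(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(15, 30))
        X = rng.normal(size=(15, 3))
        Z = rng.normal(size=(15, 2))
        res = rda_fit(Y, X, Z)
        total = (
            res.conditioned_variance
            + res.constrained_variance
            + res.residual_variance
        )
        assert total == pytest.approx(res.total_variance, abs=1e-8)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(3)
        res = rda_fit(rng.normal(size=(12, 25)), rng.normal(size=(12, 3)))
        G = res.loadings.T @ res.loadings
        assert np.allclose(G, np.eye(G.shape[0]), atol=1e-8)

    def test_empty_conditioning_equals_constant_column(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(10, 12))
        X = rng.normal(size=(10, 2))
        a = rda_fit(Y, X)
        b = rda_fit(Y, X, Z=np.zeros((10, 1)))
        assert np.allclose(a.eigenvalues, b.eigenvalues, atol=1e-10)

    def test_sklearn_get_params_roundtrip(self):
        est = RDA(scale=True, n_axes=2)
        clone_params = est.get_params()
        assert clone_params == {"scale": True, "n_axes": 2}
        est.set_params(scale=False)
        assert est.scale is False


class TestAdjustedR2:
    def test_closed_forms(self):
        assert adjusted_r2(0.5, 11, 2) == pytest.approx(0.375)
        assert adjusted_r2(1.0, 11, 2) == pytest.approx(1.0)
        assert adjusted_r2(0.0, 11, 2) == pytest.approx(-0.25)

    def test_monotone_decreasing_in_p(self):
        vals = [adjusted_r2(0.4, 30, p) for p in range(1, 10)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_small_n_errors(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.5, 3, 2)


class TestAnovaAxes:
    def test_maximal_signal_attains_minimum_p(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        Y = np.column_stack([x, 2 * x]) + 1e-9 * rng.normal(size=(20, 2))
        test = anova_axes(Y, x[:, None], n_perm=99, seed=1)
        assert test.p_values[0] == pytest.approx(1.0 / 100.0)

    def test_p_resolution(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(10, 5))
        X = rng.normal(size=(10, 1))
        test = anova_axes(Y, X, n_perm=49, seed=2)
        assert np.all(test.p_values * 50 == np.round(test.p_values * 50))

    def test_significant_axes_selection(self):
        test_obj = type("T", (), {})()
        from adaptscan.rda import AxisTest

        t = AxisTest(
            pseudo_f=np.array([5.0, 1.0]),
            p_values=np.array([0.01, 0.5]),
            n_perm=99,
        )
        assert significant_axes(t, alpha=0.05).tolist() == [0]


class TestForwardSelect:
    def test_causal_predictor_selected_first(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 40
            causal = rng.normal(size=n)
            P = pd.DataFrame(
                {
                    "causal": causal,
                    "n1": rng.normal(size=n),
                    "n2": rng.normal(size=n),
                }
            )
            Y = np.outer(causal, rng.normal(size=10)) + 0.5 * rng.normal(
                size=(n, 10)
            )
            path = forward_select(Y, P, n_perm=199, seed=seed)
            if len(path) and path.iloc[0]["predictor"] == "causal":
                hits += 1
        assert hits >= 19

    def test_duplicated_causal_single_selection(self):
        rng = np.random.default_rng(7)
        n = 30
        causal = rng.normal(size=n)
        P = pd.DataFrame({"a": causal, "b": causal.copy()})
        Y = np.outer(causal, rng.normal(size=8)) + 0.3 * rng.normal(size=(n, 8))
        path = forward_select(Y, P, n_perm=199, seed=0)
        assert len(path) == 1

    def test_pure_noise_rarely_selects(self):
        selected = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            Y = rng.normal(size=(25, 10))
            P = pd.DataFrame(rng.normal(size=(25, 2)), columns=["a", "b"])
            path = forward_select(Y, P, p_thresh=0.01, n_perm=199, seed=seed)
            selected += len(path) > 0
        assert selected <= 3  # nominal rate ~1% per candidate


class TestVariancePartition:
    def test_env_only_recovery(self):
        gaps = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 150
            env = rng.normal(size=(n, 2))
            geo = rng.normal(size=(n, 2))
            struct = rng.normal(size=(n, 2))
            Y = env @ rng.normal(size=(2, 20)) + 0.8 * rng.normal(size=(n, 20))
            part = variance_partition(Y, env, geo, struct, n_perm=29, seed=seed)
            gaps.append(
                (
                    part.full_adj_r2 - part.pure["env"],
                    part.pure["geo"],
                    part.pure["struct"],
                )
            )
        arr = np.array(gaps)
        assert np.all(np.abs(arr) < 0.05 + 1e-9)

    def test_partition_identity(self):
        rng = np.random.default_rng(11)
        Y = rng.normal(size=(30, 15))
        env, geo, struct = (rng.normal(size=(30, 2)) for _ in range(3))
        part = variance_partition(Y, env, geo, struct, n_perm=9, seed=0)
        recon = sum(part.pure.values()) + part.confounded
        assert recon == pytest.approx(part.full_adj_r2, abs=1e-8)
        frac = sum(part.pure_of_explainable.values())
        frac += part.confounded_of_explainable
        assert frac == pytest.approx(1.0, abs=1e-8)

    def test_duplicated_component_confounded(self):
        rng = np.random.default_rng(12)
        n = 40
        env = rng.normal(size=(n, 2))
        Y = env @ rng.normal(size=(2, 12)) + 0.5 * rng.normal(size=(n, 12))
        part = variance_partition(
            Y, env, env.copy(), rng.normal(size=(n, 2)), n_perm=9, seed=0
        )
        assert abs(part.pure["env"]) < 0.05
        assert abs(part.pure["geo"]) < 0.05
        assert part.confounded > 0.1

    def test_null_response(self):
        rng = np.random.default_rng(13)
        Y = rng.normal(size=(40, 20))
        part = variance_partition(
            Y, rng.normal(size=(40, 2)), rng.normal(size=(40, 2)),
            rng.normal(size=(40, 2)), n_perm=9, seed=0,
        )
        assert abs(part.full_adj_r2) < 0.05


class TestOutlierSnps:
    def _result_with_loadings(self, load):
        load = np.asarray(load, dtype=float)[:, None]
        return OrdinationResult(
            eigenvalues=np.array([1.0]), loadings=load,
            sample_scores=np.zeros((3, 1)), r2=0.5, adj_r2=0.4,
            total_variance=1.0, conditioned_variance=0.0,
            constrained_variance=0.5, residual_variance=0.5,
            rank=1, n_samples=3, n_predictors=1,
        )

    def test_forced_outlier_flagged(self):
        rng = np.random.default_rng(14)
        load = rng.normal(size=500)
        load = (load - load.mean()) / load.std()
        load[77] = 5.0
        res = self._result_with_loadings(load)
        out = outlier_snps(res, [0], k_sd=3.0)
        flagged = set(out["snp_idx"])
        assert 77 in flagged
        # chance flags bounded by a generous binomial envelope
        assert len(flagged) <= 1 + 8

    def test_infinite_threshold_empty(self):
        rng = np.random.default_rng(15)
        res = self._result_with_loadings(rng.normal(size=100))
        assert len(outlier_snps(res, [0], k_sd=np.inf)) == 0

    def test_axis_assignment_takes_largest_deviation(self):
        df = pd.DataFrame(
            {
                "snp_idx": [5, 5], "axis": [0, 1],
                "loading": [0.1, -0.2], "sd_units": [3.2, -4.1],
            }
        )
        uniq = assign_outlier_axis(df)
        assert len(uniq) == 1
        assert uniq.iloc[0]["axis"] == 1
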