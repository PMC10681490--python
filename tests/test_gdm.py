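"""GDM: dissimilarities, I-spline basis, fitting, raster transforms,
RGB composition and Procrustes comparison."""

import numpy as np
import pandas as pd
import pytest

from adaptscan.envgrid import Raster
from adaptscan.gdm import (
    GDM,
    build_site_pairs,
    genetic_dissimilarity,
    ispline_basis,
    pca_rgb,
    procrustes_residuals,
    transform_rasters,
)


class TestGeneticDissimilarity:
    def test_identical_samples(self):
        X = np.tile([1.0, 2.0, 0.0], (3, 1))
        with pytest.warns(UserWarning):
            D = genetic_dissimilarity(X)
        assert np.all(D == 0)

    def test_max_pair_scaled_to_one(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [3.0, 4.0]])
        D = genetic_dissimilarity(X)
        assert D.max() == pytest.approx(1.0)
        assert np.all(np.diag(D) == 0)

    def test_hand_computed_three_samples(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0]])
        D = genetic_dissimilarity(X)
        # raw distances: 2, 2, 2*sqrt(2); scaled by 2*sqrt(2)
        assert D[0, 1] == pytest.approx(2 / (2 * np.sqrt(2)))
        assert D[1, 2] == pytest.approx(1.0)


class TestIsplineBasis:
    knots = (0.0, 0.5, 1.0)

    def test_boundary_values(self):
        B0 = ispline_basis(np.array([0.0]), self.knots)
        B1 = ispline_basis(np.array([1.0]), self.knots)
        assert np.allclose(B0, 0.0)
        assert np.allclose(B1, 1.0)

    def test_clamping_outside_range(self):
        lo = ispline_basis(np.array([-5.0]), self.knots)
        hi = ispline_basis(np.array([7.0]), self.knots)
        assert np.allclose(lo, 0.0) and np.allclose(hi, 1.0)

    def test_monotone_non_decreasing(self):
        x = np.linspace(0, 1, 500)
        B = ispline_basis(x, self.knots)
        assert np.all(np.diff(B, axis=0) >= -1e-12)

    def test_matches_quadrature_of_derivative(self):
        # oracle: each I-spline equals the integral of its own derivative
        x = np.linspace(0, 1, 2001)
        B = ispline_basis(x, self.knots)
        for j in range(3):
            d = np.gradient(B[:, j], x)
            integ = np.concatenate(
                [[0.0], np.cumsum((d[1:] + d[:-1]) / 2 * np.diff(x))]
            )
            assert np.max(np.abs(integ - B[:, j])) < 1e-3

    def test_degenerate_knots_warn_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            B = ispline_basis(np.array([1.0, 2.0]), (3.0, 3.0, 3.0))
        assert np.all(B == 0.0)


def make_pairs(rng, n=25, causal="p1", n_noise=2):
    cols = {causal: rng.uniform(0, 2, n)}
    for i in range(n_noise):
        cols[f"noise{i}"] = rng.uniform(0, 2, n)
    P = pd.DataFrame(cols)
    coords = pd.DataFrame(
        {"x_km": rng.uniform(0, 100, n), "y_km": rng.uniform(0, 100, n)}
    )
    x = P[causal].to_numpy()
    D = 1 - np.exp(-np.abs(x[:, None] - x[None, :]))
    return build_site_pairs(P, coords, D)


class TestGdmFit:
    def test_constant_response_explained_by_intercept(self):
        rng = np.random.default_rng(0)
        pairs = make_pairs(rng)
        pairs["d"] = 0.4
        model = GDM().fit(pairs)
        assert model.deviance_explained_ == pytest.approx(0.0, abs=1e-6)

    def test_zero_eta_predicts_zero(self):
        rng = np.random.default_rng(1)
        pairs = make_pairs(rng)
        model = GDM().fit(pairs)
        model.intercept_ = 0.0
        for name in model.predictors_:
            model.coefs_[name] = np.zeros_like(model.coefs_[name])
        same = pairs.copy()
        assert np.allclose(model.predict(same), 0.0)

    def test_causal_predictor_recovered(self):
        rng = np.random.default_rng(2)
        pairs = make_pairs(rng).drop(columns="geo_km")
        model = GDM().fit(pairs)
        assert model.importance_["p1"] > 80.0
        assert model.deviance_explained_ > 90.0

    def test_fitted_values_in_link_range(self):
        rng = np.random.default_rng(3)
        pairs = make_pairs(rng)
        model = GDM().fit(pairs)
        pred = model.predict(pairs)
        assert np.all(pred >= 0.0) and np.all(pred < 1.0)

    def test_importance_sums_to_100(self):
        rng = np.random.default_rng(4)
        model = GDM().fit(make_pairs(rng))
        assert model.importance_.sum() == pytest.approx(100.0, abs=1e-6)

    def test_nested_model_deviance_non_decreasing(self):
        rng = np.random.default_rng(5)
        pairs = make_pairs(rng)
        sub = pairs[[c for c in pairs.columns
                     if c == "d" or c.startswith("p1")]]
        small = GDM().fit(sub)
        full = GDM().fit(pairs.drop(columns="geo_km"))
        assert full.deviance_explained_ >= small.deviance_explained_ - 1e-6

    def test_nonnegative_coefficients_and_monotone_partials(self):
        rng = np.random.default_rng(6)
        model = GDM().fit(make_pairs(rng))
        for name, coefs in model.coefs_.items():
            assert np.all(coefs >= 0.0)
            lo, _, hi = model.knots_[name]
            f = model.partial_function(name, np.linspace(lo, hi, 100))
            assert np.all(np.diff(f) >= -1e-10)


def layer(values):
    return Raster(values=np.asarray(values, dtype=float), xll=0.0, yll=0.0,
                  cellsize=10.0)


class TestTransformRasters:
    def _model(self):
        rng = np.random.default_rng(7)
        pairs = make_pairs(rng, causal="p1", n_noise=1).drop(columns="geo_km")
        return GDM().fit(pairs)

    def test_zero_coefficient_layer_is_zero(self):
        model = self._model()
        model.coefs_["noise0"] = np.zeros(3)
        rasters = {
            "p1": layer(np.random.default_rng(8).uniform(0, 2, (4, 4))),
            "noise0": layer(np.random.default_rng(9).uniform(0, 2, (4, 4))),
        }
        out = transform_rasters(model, rasters)
        assert np.allclose(out["noise0"].values, 0.0)

    def test_monotone_in_raw_values(self):
        model = self._model()
        grid_vals = np.linspace(0, 2, 16).reshape(4, 4)
        out = transform_rasters(model, {
            "p1": layer(grid_vals),
            "noise0": layer(grid_vals),
        })
        flat = out["p1"].values.ravel()
        assert np.all(np.diff(flat) >= -1e-10)

    def test_maximum_is_coefficient_sum(self):
        model = self._model()
        lo, _, hi = model.knots_["p1"]
        out = transform_rasters(model, {
            "p1": layer(np.full((2, 2), hi)),
            "noise0": layer(np.full((2, 2), 1.0)),
        })
        assert np.allclose(out["p1"].values, model.coefs_["p1"].sum())

    def test_missing_raster_errors(self):
        model = self._model()
        with pytest.raises(KeyError, match="noise0"):
            transform_rasters(model, {"p1": layer(np.ones((2, 2)))})


class TestPcaRgb:
    def test_identical_layers_rank_one(self):
        vals = np.random.default_rng(10).normal(size=(5, 5))
        stack = {f"l{i}": layer(vals) for i in range(3)}
        with pytest.warns(UserWarning, match="informative"):
            rgb, loadings, scores = pca_rgb(stack)
        assert np.all(rgb[:, :, 1] == rgb[0, 0, 1])
        assert np.all(rgb[:, :, 2] == rgb[0, 0, 2])

    def test_orthogonal_gradients_non_degenerate(self):
        n = 12
        x, y = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
        radial = np.hypot(x - n / 2, y - n / 2)
        stack = {"gx": layer(x), "gy": layer(y), "r": layer(radial)}
        rgb, loadings, scores = pca_rgb(stack)
        for c in range(3):
            assert rgb[:, :, c].min() == 0 and rgb[:, :, c].max() == 255

    def test_png_round_trip(self, tmp_path):
        from adaptscan.gdm import save_rgb_png

        n = 8
        x, y = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
        stack = {"gx": layer(x), "gy": layer(y), "r": layer(x * y)}
        rgb, _, _ = pca_rgb(stack)
        out = tmp_path / "turnover.png"
        save_rgb_png(rgb, out)
        assert out.stat().st_size > 0

    def test_nodata_transparent(self):
        vals = np.random.default_rng(11).normal(size=(4, 4))
        vals2 = vals.copy()
        vals2[0, 0] = np.nan
        stack = {"a": layer(vals), "b": layer(vals2),
                 "c": layer(vals**2)}
        rgb, _, _ = pca_rgb(stack)
        assert rgb[0, 0, 3] == 0
        assert np.all(rgb[1:, :, 3] == 255)


class TestProcrustes:
    def test_identity(self):
        A = np.random.default_rng(12).normal(size=(30, 3))
        res = procrustes_residuals(A, A)
        assert res.residuals.max() < 1e-12

    def test_rotation_and_scale_removed(self):
        rng = np.random.default_rng(13)
        A = rng.normal(size=(40, 3))
        th = 1.1
        R = np.array(
            [[np.cos(th), -np.sin(th), 0.0],
             [np.sin(th), np.cos(th), 0.0],
             [0.0, 0.0, 1.0]]
        )
        B = 2.0 * A @ R + np.array([3.0, -1.0, 0.5])
        res = procrustes_residuals(A, B)
        assert res.residuals.max() < 1e-8
        assert np.allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-10)

    def test_localized_perturbation_concentrates(self):
        rng = np.random.default_rng(14)
        A = rng.normal(size=(100, 3))
        B = A.copy()
        B[10:20] += 3.0
        res = procrustes_residuals(A, B)
        top_decile = np.argsort(res.residuals)[-10:]
        assert set(top_decile) == set(range(10, 20))

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError):
            procrustes_residuals(np.zeros((5, 3)), np.zeros((5, 2)))
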