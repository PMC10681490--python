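"""Population frequencies, covariance estimation, and Bayes factors."""

import numpy as np
import pandas as pd
import pytest

from adaptscan.popcov import (
    OmegaMatrix,
    PopFreqMatrix,
    bayes_factors,
    estimate_omega,
    pop_allele_freqs,
    run_gea,
    standardize_freqs,
)
from adaptscan.simdata import make_covariance, simulate_frequencies
from adaptscan.variants import thin_interleave
from conftest import make_table


class TestPopAlleleFreqs:
    def test_counting(self):
        t = make_table(np.array([[0.0, 1.0, 2.0]]))
        pfm = pop_allele_freqs(t)
        assert pfm.freqs[0, 0] == pytest.approx(0.5)

    def test_all_homref(self):
        t = make_table(np.zeros((2, 5)))
        assert np.all(pop_allele_freqs(t).freqs == 0.0)

    def test_against_bruteforce_loop(self):
        rng = np.random.default_rng(0)
        dose = rng.integers(0, 3, size=(20, 12)).astype(float)
        dose[dose > 1.5] = 2.0
        pops = ["a"] * 6 + ["b"] * 6
        t = make_table(dose, pops=pops)
        pfm = pop_allele_freqs(t)
        for j, pop in enumerate(pfm.populations):
            cols = [i for i, p in enumerate(pops) if p == pop]
            for l in range(20):
                count = sum(dose[l, c] for c in cols)
                assert pfm.freqs[j, l] == pytest.approx(count / (2 * len(cols)))

    def test_all_missing_pop_errors(self):
        dose = np.ones((1, 4))
        dose[0, :2] = np.nan
        t = make_table(dose, pops=["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="a"):
            pop_allele_freqs(t)


class TestStandardizeFreqs:
    def test_identical_freqs_zero_alpha(self):
        pfm = PopFreqMatrix(
            freqs=np.full((3, 2), 0.4), sizes=np.full((3, 2), 10.0),
            populations=["a", "b", "c"],
        )
        alpha, pi = standardize_freqs(pfm)
        assert np.allclose(alpha, 0.0)
        assert np.allclose(pi, 0.4)

    def test_two_pop_formula(self):
        pfm = PopFreqMatrix(
            freqs=np.array([[0.25], [0.75]]), sizes=np.full((2, 1), 10.0),
            populations=["a", "b"],
        )
        alpha, pi = standardize_freqs(pfm)
        assert pi[0] == pytest.approx(0.5)
        assert alpha[:, 0] == pytest.approx([-0.5, 0.5])

    def test_weighted_mean(self):
        pfm = PopFreqMatrix(
            freqs=np.array([[0.2], [0.6]]),
            sizes=np.array([[10.0], [30.0]]),
            populations=["a", "b"],
        )
        _, pi = standardize_freqs(pfm)
        assert pi[0] == pytest.approx(0.5)

    def test_monomorphic_errors(self):
        pfm = PopFreqMatrix(
            freqs=np.zeros((2, 1)), sizes=np.full((2, 1), 4.0),
            populations=["a", "b"],
        )
        with pytest.raises(ValueError, match="monomorphic"):
            standardize_freqs(pfm)


class TestEstimateOmega:
    def test_single_snp_outer_product(self):
        a = np.array([[0.3], [-0.1], [0.2]])
        om = estimate_omega(a, epsilon=1e-3)
        assert np.allclose(om.matrix, a @ a.T + 1e-3 * np.eye(3))

    def test_zero_alpha_gives_ridge(self):
        om = estimate_omega(np.zeros((3, 10)), epsilon=1e-3)
        assert np.allclose(om.matrix, 1e-3 * np.eye(3))

    def test_simulation_consistency(self):
        J = 4
        omega_true = make_covariance(
            [(0, 0), (500, 0), (0, 500), (500, 500)], decay=700.0
        )
        rng = np.random.default_rng(1)
        drift = 0.15
        p, pi = simulate_frequencies(omega_true, 20000, drift, rng)
        alpha = (p - pi[None, :]) / np.sqrt(pi * (1 - pi))[None, :]
        om = estimate_omega(alpha)
        target = drift**2 * omega_true
        off = ~np.eye(J, dtype=bool)
        r = np.corrcoef(om.matrix[off], target[off])[0, 1]
        assert r > 0.95
        assert np.all(
            np.abs(om.matrix[off] - target[off]) <= 0.1 * np.abs(target[off])
        )


class TestBayesFactors:
    def test_null_data_penalized_by_prior(self):
        z = np.array([-1.0, 1.0])
        z = z / z.std(ddof=0)
        alpha = np.zeros((2, 1))
        res = bayes_factors(alpha, z, np.eye(2), tau=1.0)
        assert res["bf_db"].iloc[0] < 0.0

    def test_unit_norm_closed_form(self):
        # z'z = 1, alpha = 0, Omega = I, tau = 1: BF = 1/sqrt(2)
        z = np.array([1.0, 0.0])
        res = bayes_factors(np.zeros((2, 1)), z, np.eye(2), tau=1.0)
        bf = 10 ** (res["bf_db"].iloc[0] / 10)
        assert bf == pytest.approx(2**-0.5, abs=1e-10)

    def test_sign_invariances(self):
        rng = np.random.default_rng(2)
        alpha = rng.normal(size=(4, 20))
        z = rng.normal(size=4)
        z = (z - z.mean()) / z.std(ddof=0)
        om = estimate_omega(rng.normal(size=(4, 100)))
        base = bayes_factors(alpha, z, om)
        flipped_allele = bayes_factors(-alpha, z, om)
        flipped_cov = bayes_factors(alpha, -z, om)
        assert np.allclose(base["bf_db"], flipped_allele["bf_db"])
        assert np.allclose(base["bf_db"], flipped_cov["bf_db"])
        assert np.allclose(base["beta_hat"], -flipped_cov["beta_hat"])
        assert np.allclose(base["beta_hat"], -flipped_allele["beta_hat"])

    def test_tau_to_zero_collapses_to_null(self):
        rng = np.random.default_rng(3)
        alpha = rng.normal(size=(3, 10))
        z = np.array([-1.0, 0.0, 1.0])
        z = (z - z.mean()) / z.std(ddof=0)
        res = bayes_factors(alpha, z, np.eye(3), tau=1e-8)
        assert np.allclose(res["bf_db"], 0.0, atol=1e-6)

    def test_grid_close_to_analytic(self):
        # fine normal-weighted grid approximates the normal prior's mass
        rng = np.random.default_rng(4)
        tau = 0.1
        for _ in range(20):
            alpha = 0.2 * rng.normal(size=(6, 5))
            z = rng.normal(size=6)
            z = (z - z.mean()) / z.std(ddof=0)
            om = estimate_omega(0.2 * rng.normal(size=(6, 200)))
            ana = bayes_factors(alpha, z, om, tau=tau)
            grd = bayes_factors(
                alpha, z, om, tau=tau, grid=(-4 * tau, 4 * tau, 401),
                grid_prior="normal",
            )
            bf_a = 10 ** (ana["bf_db"] / 10)
            bf_g = 10 ** (grd["bf_db"] / 10)
            assert np.all(np.abs(bf_g - bf_a) / bf_a < 0.05)

    def test_uniform_grid_same_order(self):
        # the flat-prior grid mirrors the original tool's support and
        # should agree with the analytic BF to leading order on null data
        res = bayes_factors(
            np.zeros((2, 1)), np.array([1.0, 0.0]), np.eye(2),
            grid=(-0.3, 0.3, 201),
        )
        assert res["bf_db"].iloc[0] < 0.0


class TestRunGea:
    def _toy(self):
        rng = np.random.default_rng(5)
        dose = rng.integers(0, 3, size=(120, 16)).astype(float)
        pops = [f"p{j}" for j in range(4) for _ in range(4)]
        t = make_table(dose, pops=pops)
        cov = pd.DataFrame(
            {"env": [-1.2, -0.4, 0.4, 1.2]},
            index=pd.Index([f"p{j}" for j in range(4)]),
        )
        cov["env"] = (cov["env"] - cov["env"].mean()) / cov["env"].std(ddof=0)
        alpha, _ = standardize_freqs(pop_allele_freqs(t))
        return t, cov, estimate_omega(alpha)

    def test_subset_identity(self):
        t, cov, om = self._toy()
        direct = run_gea(t, cov, om)["env"]
        split = run_gea(t, cov, om, subsets=thin_interleave(t, 10))["env"]
        assert np.allclose(direct["bf_db"], split["bf_db"])

    def test_output_length(self):
        t, cov, om = self._toy()
        tracks = run_gea(t, cov, om)
        assert all(len(tr) == t.n_sites for tr in tracks.values())

    def test_label_permutation_destroys_signal(self, small_dataset):
        from adaptscan.variants import maf_filter

        ds = small_dataset
        t = maf_filter(ds.genotypes)  # drop sites sampled monomorphic
        alpha, _ = standardize_freqs(pop_allele_freqs(t))
        om = estimate_omega(alpha)
        pops = list(t.samples["population"].unique())
        z = ds.truth.z[: len(pops)]
        cov = pd.DataFrame({"env_1": z}, index=pd.Index(pops))
        planted = np.isin(
            t.snp_ids.to_numpy(), [s for s, _, _ in ds.truth.adaptive_loci]
        )
        track = run_gea(t, cov, om)["env_1"]
        signal = track.loc[planted, "bf_db"].mean()
        rng = np.random.default_rng(6)
        null_means = []
        while len(null_means) < 5:
            perm = rng.permutation(len(z))
            if np.array_equal(perm, np.arange(len(z))):
                continue
            cov_perm = cov.copy()
            cov_perm["env_1"] = z[perm]
            tr = run_gea(t, cov_perm, om)["env_1"]
            null_means.append(tr.loc[planted, "bf_db"].mean())
        assert signal > np.median(null_means) + 3.0
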