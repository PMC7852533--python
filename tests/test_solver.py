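"""Tests for the eigen-reparameterized Gibbs sampler."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import metgp as mg


def single_env_table(y):
    # zero-padded IDs keep the sorted hybrid order aligned with y's order
    rec = pd.DataFrame({
        "env": "E1", "gid": [f"H{i:03d}" for i in range(len(y))], "value": y,
    })
    return mg.PhenotypeTable(rec)


def identity_term_set(y, model="EA"):
    ph = single_env_table(y)
    K = mg.KernelMatrix(np.eye(len(y)), ph.hybrids, "GB")
    return ph, mg.build_model(model, ph, K)


def random_psd(rng, n, jitter=0.1):
    A = rng.standard_normal((n, n + 2))
    K = A @ A.T / (n + 2) + jitter * np.eye(n)
    return 0.5 * (K + K.T)


class TestMcmcConfig:
    def test_invariants(self):
        with pytest.raises(ValueError):
            mg.McmcConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            mg.McmcConfig(thin=0)

    def test_saved_count(self):
        cfg = mg.McmcConfig(iterations=10_000, burn_in=1_000, thin=2)
        assert cfg.n_saved == 4_500


class TestEigendecompose:
    def test_identity(self):
        out = mg.eigendecompose_terms([("A", np.eye(5))])
        U, s = out["A"]
        np.testing.assert_allclose(s, 1.0)
        np.testing.assert_allclose(U.T @ U, np.eye(5), atol=1e-10)

    def test_rank_one(self, rng):
        v = rng.standard_normal(8)
        out = mg.eigendecompose_terms([("A", np.outer(v, v))])
        U, s = out["A"]
        assert s.size == 1

    def test_reconstruction(self, rng):
        K = random_psd(rng, 12)
        U, s = mg.eigendecompose_terms([("A", K)])["A"]
        np.testing.assert_allclose((U * s) @ U.T, K, atol=1e-8)

    def test_asymmetric_raises(self, rng):
        K = rng.standard_normal((4, 4))
        with pytest.raises(ValueError, match="symmetric"):
            mg.eigendecompose_terms([("A", K)])


class TestConjugacy:
    def test_scaled_inv_chi2_matches_scipy(self):
        # scaled-inv-chi2(df, s) == InvGamma(df/2, df*s/2)
        rng = np.random.default_rng(0)
        df, s = 12.0, 1.7
        draws = np.array([
            mg.draw_scaled_inv_chi2(rng, df, s) for _ in range(4000)
        ])
        ref = stats.invgamma(a=df / 2, scale=df * s / 2)
        ks = stats.kstest(draws, ref.cdf)
        assert ks.pvalue > 0.01


class TestGibbsFit:
    def test_reproducibility_bit_identical(self, quick_mcmc):
        rng = np.random.default_rng(1)
        ph, ts = identity_term_set(rng.standard_normal(30))
        f1 = mg.gibbs_fit(ph, ts, quick_mcmc)
        f2 = mg.gibbs_fit(ph, ts, quick_mcmc)
        for t in f1.var_samples:
            np.testing.assert_array_equal(f1.var_samples[t],
                                          f2.var_samples[t])
        np.testing.assert_array_equal(f1.fitted, f2.fitted)

    def test_fitted_self_consistency(self, small_dataset, quick_mcmc):
        d = small_dataset
        ts = mg.build_model("EADW", d["phenotypes"], d["K_A"], d["K_D"],
                            d["K_W"])
        fit = mg.gibbs_fit(d["phenotypes"], ts, quick_mcmc)
        recon = fit.fixed_part + sum(fit.effects.values())
        np.testing.assert_allclose(fit.fitted, recon, atol=1e-8)

    def test_variance_samples_positive(self, small_dataset, quick_mcmc):
        d = small_dataset
        ts = mg.build_model("EA", d["phenotypes"], d["K_A"])
        fit = mg.gibbs_fit(d["phenotypes"], ts, quick_mcmc)
        for t, draws in fit.var_samples.items():
            assert (draws > 0).all(), t

    def test_zero_signal_shrinks_genetic_variance(self):
        # y iid noise over hybrids replicated in 2 environments: the
        # hybrid-level variance is identified by replication and shrinks,
        # while residual variance tracks var(y)
        ratios = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            p = 60
            y = rng.standard_normal(2 * p)
            rec = pd.DataFrame({
                "env": ["E1"] * p + ["E2"] * p,
                "gid": [f"H{i:03d}" for i in range(p)] * 2,
                "value": y,
            })
            ph = mg.PhenotypeTable(rec)
            K = mg.KernelMatrix(np.eye(p), ph.hybrids, "GB")
            ts = mg.build_model("EA", ph, K)
            fit = mg.gibbs_fit(ph, ts, mg.McmcConfig(
                iterations=1500, burn_in=500, seed=seed))
            ratios.append(fit.var_means["A"] / fit.var_means["residual"])
            assert fit.var_means["residual"] == pytest.approx(
                float(np.var(y)), rel=0.5)
        assert np.mean(ratios) < 1.0

    def test_ridge_oracle_fixed_variances(self):
        # single term, K = I, variances fixed: posterior mean of u equals
        # the mixed-model-equations (ridge) solution
        rng = np.random.default_rng(7)
        n = 50
        y = rng.standard_normal(n) * 1.5 + 2.0
        ph, ts = identity_term_set(y)
        var_u, var_e = 1.0, 0.5
        lam = var_e / var_u
        cfg = mg.McmcConfig(iterations=22_000, burn_in=2_000, thin=1, seed=3,
                            fixed_variances={"A": var_u, "residual": var_e})
        fit = mg.gibbs_fit(ph, ts, cfg)
        mu_hat = fit.mu
        u_hat = fit.effects["A"]
        # oracle: direct MME solve at the fitted fixed effect
        u_ridge = np.linalg.solve(np.eye(n) * (1 + lam), y - mu_hat)
        assert np.max(np.abs(u_hat - u_ridge)) < 0.02

    def test_duplicated_records_halve_mu_uncertainty(self):
        rng = np.random.default_rng(11)
        n = 60
        y = rng.standard_normal(n)
        ph1, ts1 = identity_term_set(y)
        # duplicate every record as a pseudo-hybrid with an identical kernel row
        y2 = np.concatenate([y, y])
        rec = pd.DataFrame({
            "env": "E1",
            "gid": [f"H{i}" for i in range(n)] + [f"H{i}b" for i in range(n)],
            "value": y2,
        })
        ph2 = mg.PhenotypeTable(rec)
        K2 = mg.KernelMatrix(np.eye(2 * n), ph2.hybrids, "GB")
        ts2 = mg.build_model("EA", ph2, K2)
        cfg = mg.McmcConfig(iterations=6000, burn_in=1000, thin=1, seed=5,
                            fixed_variances={"A": 0.05, "residual": 1.0})
        v1 = mg.gibbs_fit(ph1, ts1, cfg).mu_samples.var()
        v2 = mg.gibbs_fit(ph2, ts2, cfg).mu_samples.var()
        assert v2 / v1 == pytest.approx(0.5, abs=0.15)

    def test_empty_training_set_raises(self, small_dataset, quick_mcmc):
        d = small_dataset
        ts = mg.build_model("EA", d["phenotypes"], d["K_A"])
        with pytest.raises(ValueError, match="empty training"):
            mg.gibbs_fit(d["phenotypes"], ts, quick_mcmc,
                         mask=np.zeros(d["phenotypes"].n, dtype=bool))


class TestEigenVsNaiveGibbs:
    """Transformed sampler against a direct full-covariance Gibbs oracle."""

    @staticmethod
    def naive_gibbs(y, K, iters, burn, seed, nu=5.0, sc=None):
        """Untransformed Gibbs for y = 1 mu + u + e, u ~ N(0, K s2u)."""
        rng = np.random.default_rng(seed)
        n = y.size
        sc = float(np.var(y)) / 2.0 if sc is None else sc
        K_inv = np.linalg.inv(K)
        var_u, var_e = sc, sc
        u = np.zeros(n)
        mu = 0.0
        keep = {"var_u": [], "var_e": [], "fitted": np.zeros(n), "mu": []}
        saved = 0
        for it in range(iters):
            mu = rng.normal((y - u).mean(), np.sqrt(var_e / n))
            # joint draw of u from its multivariate normal full conditional
            C = K_inv / var_u + np.eye(n) / var_e
            L = np.linalg.cholesky(C)
            rhs = (y - mu) / var_e
            mean = np.linalg.solve(C, rhs)
            z = rng.standard_normal(n)
            u = mean + np.linalg.solve(L.T, z)
            ssu = float(u @ K_inv @ u)
            var_u = (nu * sc + ssu) / rng.chisquare(nu + n)
            e = y - mu - u
            var_e = (nu * sc + float(e @ e)) / rng.chisquare(nu + n)
            if it >= burn:
                keep["var_u"].append(var_u)
                keep["var_e"].append(var_e)
                keep["mu"].append(mu)
                keep["fitted"] += mu + u
                saved += 1
        keep["fitted"] /= saved
        return keep

    def test_posterior_means_agree(self):
        rng = np.random.default_rng(21)
        n = 20
        K = random_psd(rng, n, jitter=0.3)
        w, V = np.linalg.eigh(K)
        u_true = V @ (np.sqrt(w) * rng.standard_normal(n))
        y = 1.0 + u_true + 0.5 * rng.standard_normal(n)

        sc = float(np.var(y)) / 2.0
        ph = single_env_table(y)
        ts = mg.build_model("EA", ph,
                            mg.KernelMatrix(K, ph.hybrids, "GB"))
        fit = mg.gibbs_fit(ph, ts, mg.McmcConfig(
            iterations=21_000, burn_in=1_000, thin=1, seed=2,
            scale_u=sc, scale_e=sc))
        ref = self.naive_gibbs(y, K, iters=21_000, burn=1_000, seed=4, sc=sc)

        assert fit.var_means["A"] == pytest.approx(
            np.mean(ref["var_u"]), abs=0.05 * max(1, np.mean(ref["var_u"])))
        assert fit.var_means["residual"] == pytest.approx(
            np.mean(ref["var_e"]), abs=0.05)
        assert np.max(np.abs(fit.fitted - ref["fitted"])) < 0.05


class TestPredict:
    def test_training_target_returns_fitted(self, small_dataset, quick_mcmc):
        d = small_dataset
        ts = mg.build_model("EA", d["phenotypes"], d["K_A"])
        fit = mg.gibbs_fit(d["phenotypes"], ts, quick_mcmc)
        target = d["phenotypes"].records.iloc[[0]][["env", "gid"]]
        out = mg.predict(fit, target)
        assert out["predicted"].iloc[0] == pytest.approx(fit.fitted[0])

    def test_unknown_hybrid_raises(self, small_dataset, quick_mcmc):
        d = small_dataset
        ts = mg.build_model("EA", d["phenotypes"], d["K_A"])
        fit = mg.gibbs_fit(d["phenotypes"], ts, quick_mcmc)
        target = pd.DataFrame({"env": ["E1"], "gid": ["NOPE"]})
        with pytest.raises(KeyError, match="unknown hybrid"):
            mg.predict(fit, target)

    def test_cv0_new_environment_ea_expansion(self, small_dataset, quick_mcmc):
        # under EA a new-environment prediction = mu + avg beta + additive
        # effect, and the additive effect matches the hybrid's training one
        d = small_dataset
        ph = d["phenotypes"]
        mask = (ph.records["env"] != "E1").to_numpy()
        ts = mg.build_model("EA", ph, d["K_A"])
        fit = mg.gibbs_fit(ph, ts, quick_mcmc, mask=mask)
        avg_beta = float(np.mean(list(fit.beta)))
        rec = ph.records
        for i in np.where(~mask)[0][:5]:
            gid = rec["gid"].iloc[i]
            j = rec.index[(rec["gid"] == gid) & mask][0]
            assert fit.effects["A"][i] == pytest.approx(
                fit.effects["A"][j], abs=1e-8)
            assert fit.fitted[i] == pytest.approx(
                fit.mu + avg_beta + fit.effects["A"][i], abs=1e-8)

    def test_allones_kw_makes_w_effect_constant(self, small_dataset,
                                                quick_mcmc):
        d = small_dataset
        ph = d["phenotypes"]
        K_W1 = mg.KernelMatrix(np.ones((ph.q, ph.q)), ph.environments, "GB")
        ts = mg.build_model("EADW", ph, d["K_A"], d["K_D"], K_W1)
        mask = (ph.records["env"] != "E1").to_numpy()
        fit = mg.gibbs_fit(ph, ts, quick_mcmc, mask=mask)
        w_eff = fit.effects["W"]
        assert np.ptp(w_eff) < 1e-8  # constant across all records


class TestVariancePartition:
    def test_sums_to_one(self, small_dataset, quick_mcmc):
        d = small_dataset
        ts = mg.build_model("EADW+GW", d["phenotypes"], d["K_A"], d["K_D"],
                            d["K_W"])
        fit = mg.gibbs_fit(d["phenotypes"], ts, quick_mcmc)
        parts = mg.variance_partition(fit)
        assert sum(parts.values()) == pytest.approx(1.0, abs=1e-10)
        assert set(parts) == {"A", "D", "W", "AW", "DW", "residual"}

    def test_pure_noise_residual_dominates(self):
        rng = np.random.default_rng(3)
        ph, ts = identity_term_set(rng.standard_normal(100))
        fit = mg.gibbs_fit(ph, ts, mg.McmcConfig(
            iterations=1500, burn_in=500, seed=1))
        parts = mg.variance_partition(fit)
        assert parts["residual"] > 0.5

    def test_half_heritability_recovery(self):
        cfg = mg.SimulationConfig(
            n_parents=30, n_hybrids=100, n_markers=200, n_environments=4,
            variance_components={"A": 1.0, "residual": 1.0}, seed=17,
        )
        g = mg.maf_filter(mg.simulate_genotypes(cfg))
        K_A = mg.gb_kernel(mg.additive_design(g), labels=g.hybrid_ids)
        ph, _ = mg.simulate_phenotypes(g, cfg, K_A=K_A)
        ts = mg.build_model("EA", ph, K_A)
        fit = mg.gibbs_fit(ph, ts, mg.McmcConfig(
            iterations=2000, burn_in=500, seed=2))
        parts = mg.variance_partition(fit)
        assert parts["A"] == pytest.approx(0.5, abs=0.15)
        assert parts["residual"] == pytest.approx(0.5, abs=0.15)
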