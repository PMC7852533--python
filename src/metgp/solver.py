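"""Eigen-reparameterized Gibbs sampler for kernel mixed models.

Each random-effect covariance is eigendecomposed on the training
observations, ``K = U S U'``, so the effect coefficients in the eigenbasis
have independent normal full conditionals ``b_i ~ N(0, sigma2_u s_i)``
against an iid residual.  Variance components carry scaled-inverse-chi-square
priors and are updated from their conjugate full conditionals.  Held-out
records contribute nothing to the likelihood; their effects are propagated
through the joint prior covariance (``u_test = K_test,train K_train^+
u_train`` per draw) and averaged over saved draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .models import EffectTermSet, PhenotypeTable

__all__ = [
    "McmcConfig",
    "FitResult",
    "draw_scaled_inv_chi2",
    "eigendecompose_terms",
    "gibbs_fit",
    "predict",
    "variance_partition",
]


@dataclass(frozen=True)
class McmcConfig:
    """Gibbs-sampler settings and scaled-inverse-chi-square priors.

    ``scale_u`` / ``scale_e`` default to ``var(y_train) / 2`` when left as
    None (weakly informative, data-driven).
    """

    iterations: int = 10_000
    burn_in: int = 1_000
    thin: int = 2
    seed: int = 0
    nu_u: float = 5.0
    nu_e: float = 5.0
    scale_u: float | None = None
    scale_e: float | None = None
    eig_tol: float = 1e-8
    #: optional {term or "residual": value} map pinning variances (no update)
    fixed_variances: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.iterations > self.burn_in >= 0:
            raise ValueError("need iterations > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_saved(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class FitResult:
    """Posterior summaries, fitted values and held-out predictions."""

    model: str
    term_names: tuple[str, ...]
    var_samples: dict[str, np.ndarray]
    var_means: dict[str, float]
    mu: float
    beta: pd.Series
    fitted: np.ndarray            # posterior-mean fitted value, training rows = index
    effects: dict[str, np.ndarray]  # posterior-mean effect per term, all n rows
    fixed_part: np.ndarray          # posterior-mean fixed part, all n rows
    predictions: pd.DataFrame       # masked records: env, gid, predicted
    mu_samples: np.ndarray
    train_mask: np.ndarray
    phenotypes: PhenotypeTable
    ess: dict[str, float] = field(default_factory=dict)
    split_rhat: dict[str, float] = field(default_factory=dict)
    retained_dims: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "variance_components": self.var_means,
            "mu": self.mu,
            "beta": self.beta.to_dict(),
            "ess": self.ess,
            "split_rhat": self.split_rhat,
            "retained_dims": self.retained_dims,
        }


def draw_scaled_inv_chi2(
    rng: np.random.Generator, df: float, scale: float
) -> float:
    """One draw from scaled-inverse-chi-square(df, scale) = df*scale/chi2_df."""
    return df * scale / rng.chisquare(df)


def eigendecompose_terms(
    terms: list[tuple[str, np.ndarray]], tol: float = 1e-8
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Eigendecompose each term covariance, keeping components above tolerance.

    Returns {name: (U_r, s_r)} with eigenvalues ``s_i > tol * max(s)``.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, K in terms:
        K = np.asarray(K, dtype=float)
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError(f"term {name}: covariance not symmetric")
        s, U = np.linalg.eigh(0.5 * (K + K.T))
        smax = max(s[-1], 0.0)
        keep = s > tol * smax if smax > 0 else np.zeros_like(s, bool)
        if not keep.any():
            raise ValueError(f"term {name}: covariance has no positive eigenvalues")
        out[name] = (U[:, keep], s[keep])
    return out


def _ess(x: np.ndarray) -> float:
    """Effective sample size via the initial-positive-sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = x.size
    x = x - x.mean()
    v = float(x @ x) / n
    if v == 0 or n < 4:
        return float(n)
    rho_sum = 0.0
    for lag in range(1, n // 2):
        rho = float(x[:-lag] @ x[lag:]) / (n * v)
        if rho <= 0:
            break
        rho_sum += rho
    return float(n / (1.0 + 2.0 * rho_sum))


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction on a single chain."""
    n = x.size // 2
    if n < 2:
        return float("nan")
    halves = np.stack([x[:n], x[x.size - n:]])
    w = halves.var(axis=1, ddof=1).mean()
    b = n * halves.mean(axis=1).var(ddof=1)
    if w == 0:
        return float("nan")
    return float(np.sqrt((w * (n - 1) / n + b / n) / w))


def _training_fixed_design(
    phenotypes: PhenotypeTable, train: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Reference-coded design restricted to environments seen in training."""
    envs = sorted(phenotypes.records.loc[train, "env"].unique())
    idx = {e: j for j, e in enumerate(envs)}
    n = phenotypes.n
    X = np.zeros((n, len(envs)))
    for i, e in enumerate(phenotypes.records["env"]):
        j = idx.get(e)
        if j is not None:
            X[i, j] = 1.0
    X = np.column_stack([np.ones(n), X[:, 1:]])
    return X, envs


def gibbs_fit(
    phenotypes: PhenotypeTable,
    term_set: EffectTermSet,
    config: McmcConfig = McmcConfig(),
    mask: np.ndarray | None = None,
) -> FitResult:
    """Fit an assembled model by Gibbs sampling.

    Parameters
    ----------
    phenotypes
        All records, training and held-out.
    term_set
        Model structure over the same records.
    config
        Sampler settings, priors and seed.
    mask
        Boolean length-n array, True = training record.  None fits all
        records.
    """
    n = phenotypes.n
    train = np.ones(n, dtype=bool) if mask is None else np.asarray(mask, bool)
    if train.shape != (n,):
        raise ValueError("mask must be a boolean vector over all records")
    if not train.any():
        raise ValueError("empty training set")
    test = ~train
    y = phenotypes.y
    y_tr = y[train]
    n_tr = int(train.sum())

    X_full, train_envs = _training_fixed_design(phenotypes, train)
    X = X_full[train]
    XtX = X.T @ X
    try:
        L_x = np.linalg.cholesky(XtX)
    except np.linalg.LinAlgError as exc:
        raise ValueError("numerically singular fixed design") from exc

    # eigendecompose each term covariance on the training rows
    eig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    proj: dict[str, np.ndarray] = {}  # test-row propagation, K_ts U S^-1
    retained: dict[str, int] = {}
    for name, K in term_set.terms:
        U, s = eigendecompose_terms(
            [(name, K[np.ix_(np.where(train)[0], np.where(train)[0])])],
            tol=config.eig_tol,
        )[name]
        eig[name] = (U, s)
        retained[name] = int(s.size)
        if test.any():
            K_ts = K[np.ix_(np.where(test)[0], np.where(train)[0])]
            proj[name] = (K_ts @ U) / s

    rng = np.random.default_rng(config.seed)
    sc_u = config.scale_u if config.scale_u is not None else float(np.var(y_tr)) / 2.0
    sc_e = config.scale_e if config.scale_e is not None else float(np.var(y_tr)) / 2.0
    sc_u = max(sc_u, 1e-12)
    sc_e = max(sc_e, 1e-12)

    names = term_set.term_names
    pinned = dict(config.fixed_variances or {})
    b = {t: np.zeros(eig[t][1].size) for t in names}
    u = {t: np.zeros(n_tr) for t in names}
    var_u = {t: pinned.get(t, sc_u) for t in names}
    var_e = pinned.get("residual", sc_e)
    beta = np.zeros(X.shape[1])

    n_saved = config.n_saved
    var_draws = {t: np.empty(n_saved) for t in names}
    var_draws["residual"] = np.empty(n_saved)
    mu_draws = np.empty(n_saved)
    beta_acc = np.zeros_like(beta)
    u_acc = {t: np.zeros(n_tr) for t in names}
    u_test_acc = {t: np.zeros(int(test.sum())) for t in names}
    saved = 0

    for it in range(1, config.iterations + 1):
        # fixed effects, flat prior
        w = y_tr - sum(u.values())
        mean_b = np.linalg.solve(L_x.T, np.linalg.solve(L_x, X.T @ w))
        z = rng.standard_normal(beta.size)
        beta = mean_b + np.sqrt(var_e) * np.linalg.solve(L_x.T, z)
        xb = X @ beta

        # random effects in each term's eigenbasis
        for t in names:
            U, s = eig[t]
            e = y_tr - xb
            for t2 in names:
                if t2 != t:
                    e -= u[t2]
            r = U.T @ e
            post_var = 1.0 / (1.0 / var_e + 1.0 / (var_u[t] * s))
            post_mean = post_var * r / var_e
            b[t] = post_mean + np.sqrt(post_var) * rng.standard_normal(s.size)
            u[t] = U @ b[t]
            # variance component, scaled-inv-chi2 full conditional
            if t not in pinned:
                ss = float(np.sum(b[t] ** 2 / s))
                df = config.nu_u + s.size
                var_u[t] = draw_scaled_inv_chi2(
                    rng, df, (config.nu_u * sc_u + ss) / df
                )

        resid = y_tr - xb - sum(u.values())
        if "residual" not in pinned:
            df_e = config.nu_e + n_tr
            var_e = draw_scaled_inv_chi2(
                rng, df_e, (config.nu_e * sc_e + float(resid @ resid)) / df_e
            )

        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            for t in names:
                var_draws[t][saved] = var_u[t]
                u_acc[t] += u[t]
                if test.any():
                    u_test_acc[t] += proj[t] @ b[t]
            var_draws["residual"][saved] = var_e
            mu_draws[saved] = beta[0]
            beta_acc += beta
            saved += 1

    assert saved == n_saved
    beta_mean = beta_acc / n_saved
    var_means = {t: float(var_draws[t].mean()) for t in var_draws}

    # posterior-mean effects mapped back to all n records
    effects = {}
    for t in names:
        full = np.zeros(n)
        full[train] = u_acc[t] / n_saved
        if test.any():
            full[test] = u_test_acc[t] / n_saved
        effects[t] = full

    # fixed part for every record; unseen environments get the average
    # training-environment effect (reference level counts as zero)
    env_effect = {train_envs[0]: 0.0}
    for j, e in enumerate(train_envs[1:]):
        env_effect[e] = float(beta_mean[1 + j])
    avg_env = float(np.mean(list(env_effect.values())))
    mu = float(beta_mean[0])
    fixed_part = np.array([
        mu + env_effect.get(e, avg_env) for e in phenotypes.records["env"]
    ])

    fitted = fixed_part + sum(effects.values())
    pred_records = phenotypes.records.loc[test, ["env", "gid"]].copy()
    pred_records["predicted"] = fitted[test]

    diag_series = {f"sigma2_{t}": var_draws[t] for t in var_draws}
    ess = {k: _ess(v) for k, v in diag_series.items()}
    rhat = {k: _split_rhat(v) for k, v in diag_series.items()}

    return FitResult(
        model=term_set.model,
        term_names=names,
        var_samples=var_draws,
        var_means=var_means,
        mu=mu,
        beta=pd.Series(env_effect, name="env_effect"),
        fitted=fitted,
        effects=effects,
        fixed_part=fixed_part,
        predictions=pred_records.reset_index(drop=True),
        mu_samples=mu_draws,
        train_mask=train,
        phenotypes=phenotypes,
        ess=ess,
        split_rhat=rhat,
        retained_dims=retained,
    )


def predict(
    fit: FitResult, target_records: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Predictions for (env, gid) targets.

    Targets that are training records return their fitted value; held-out
    records return their posterior-mean prediction.  Unknown hybrids raise.
    """
    ph = fit.phenotypes
    table = ph.records[["env", "gid"]].copy()
    table["predicted"] = fit.fitted
    if target_records is None:
        return table.loc[~fit.train_mask].reset_index(drop=True)
    known = set(ph.hybrids)
    out = []
    indexed = table.set_index(["env", "gid"])["predicted"]
    for _, row in target_records.iterrows():
        key = (str(row["env"]), str(row["gid"]))
        if key[1] not in known:
            raise KeyError(f"unknown hybrid {key[1]!r} (no kernel row)")
        if key not in indexed.index:
            raise KeyError(
                f"record {key} was not part of the fitted table; refit with "
                "the target included in the mask"
            )
        out.append({"env": key[0], "gid": key[1], "predicted": indexed[key]})
    return pd.DataFrame(out)


def variance_partition(fit: FitResult) -> dict[str, float]:
    """Posterior-mean variance components as proportions summing to 1."""
    total = sum(fit.var_means.values())
    return {t: v / total for t, v in fit.var_means.items()}
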