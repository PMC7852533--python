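"""Cross-validation schemes, predictive-ability statistics and the model grid.

Three schemes mirror common multi-environment prediction questions:

``CV1``
    untested hybrids — a hybrid's records are entirely train or test,
``CV2``
    sparse trials — records sampled uniformly,
``CV0``
    new environments — deterministic leave-one-environment-out.

Predictive ability (PA) is the Pearson correlation between observed and
predicted test values, summarized per fold and, for CV0, per left-out
environment and per hybrid across environments.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import (
    GenotypeTable,
    KernelMatrix,
    additive_design,
    build_kernel,
    dominance_design,
    select_bandwidth,
    select_layers,
)
from .models import MODEL_NAMES, PhenotypeTable, build_model
from .solver import McmcConfig, gibbs_fit

logger = logging.getLogger(__name__)

SCHEMES = ("CV1", "CV2", "CV0")

TYPOLOGY_BINS = (-np.inf, 0.0, 0.25, 0.50, 0.75, 1.0)
TYPOLOGY_LABELS = ("<=0", "(0,0.25]", "(0.25,0.50]", "(0.50,0.75]", "(0.75,1]")

__all__ = [
    "SCHEMES",
    "CVPlan",
    "CVResult",
    "make_folds",
    "predictive_ability",
    "genotype_level_pa",
    "standard_error",
    "pa_typology",
    "run_grid",
]


@dataclass(frozen=True)
class CVPlan:
    """Fold definitions for one cross-validation scheme."""

    scheme: str
    train_masks: tuple[np.ndarray, ...]
    fold_labels: tuple[str, ...]
    seed: int
    train_fraction: float

    @property
    def n_folds(self) -> int:
        return len(self.train_masks)


@dataclass
class CVResult:
    """Predictive-ability summary for one model/kernel/scheme cell."""

    model: str
    kernel: str
    scheme: str
    fold_pa: list[float]
    mean_pa: float
    se: float
    per_environment: dict[str, float] = field(default_factory=dict)
    per_hybrid: pd.Series | None = None
    typology: pd.DataFrame | None = None


def make_folds(
    phenotypes: PhenotypeTable,
    scheme: str,
    repetitions: int = 50,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> CVPlan:
    """Build train/test masks for CV1, CV2 or CV0.

    CV1 samples ``ceil(train_fraction * p)`` hybrids per repetition and
    trains on all their records; CV2 samples ``ceil(train_fraction * n)``
    records; CV0 enumerates environments deterministically (one fold per
    environment, ``repetitions`` ignored).
    """
    scheme = scheme.upper()
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; use one of {SCHEMES}")
    rng = np.random.default_rng(seed)
    n = phenotypes.n
    masks: list[np.ndarray] = []
    labels: list[str] = []

    if scheme == "CV0":
        if phenotypes.q < 2:
            raise ValueError("CV0 needs at least 2 environments")
        for env in phenotypes.environments:
            mask = (phenotypes.records["env"] != env).to_numpy()
            masks.append(mask)
            labels.append(env)
    elif scheme == "CV1":
        if phenotypes.p < 2:
            raise ValueError("CV1 needs at least 2 hybrids")
        n_train = math.ceil(train_fraction * phenotypes.p)
        hybrids = np.array(phenotypes.hybrids)
        for rep in range(repetitions):
            chosen = set(rng.choice(hybrids, size=n_train, replace=False))
            mask = phenotypes.records["gid"].isin(chosen).to_numpy()
            masks.append(mask)
            labels.append(f"rep{rep + 1}")
    else:  # CV2
        n_train = math.ceil(train_fraction * n)
        for rep in range(repetitions):
            idx = rng.choice(n, size=n_train, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[idx] = True
            masks.append(mask)
            labels.append(f"rep{rep + 1}")

    return CVPlan(scheme, tuple(masks), tuple(labels), seed, train_fraction)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def predictive_ability(
    observed: np.ndarray,
    predicted: np.ndarray,
    grouping: np.ndarray | None = None,
) -> float | pd.Series:
    """Pearson correlation of observed vs predicted, optionally per group.

    Groups with fewer than 3 records or zero variance yield NaN and are
    excluded from any averaging by the caller (logged).
    """
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must align")
    if grouping is None:
        return _pearson(observed, predicted)
    out = {}
    for g in pd.unique(np.asarray(grouping)):
        sel = np.asarray(grouping) == g
        if sel.sum() < 3:
            out[g] = float("nan")
            continue
        r = _pearson(observed[sel], predicted[sel])
        if np.isnan(r):
            logger.info("predictive_ability: group %r has zero variance", g)
        out[g] = r
    return pd.Series(out)


def genotype_level_pa(
    records: pd.DataFrame, observed_col: str = "value",
    predicted_col: str = "predicted",
) -> pd.Series:
    """Per-hybrid Pearson correlation across its environments."""
    out = {}
    for gid, sub in records.groupby("gid"):
        if len(sub) < 3:
            out[gid] = float("nan")
            continue
        out[gid] = _pearson(sub[observed_col].to_numpy(),
                            sub[predicted_col].to_numpy())
    return pd.Series(out, name="pa")


def standard_error(
    per_fold_pa: np.ndarray, n: int, n1: int, n2: int
) -> float:
    """Corrected resampling SE: SD(fold PAs) * sqrt(1/n + n2/n1)."""
    if n1 <= 0:
        raise ValueError("training size n1 must be positive")
    pa = np.asarray(per_fold_pa, float)
    pa = pa[~np.isnan(pa)]
    if pa.size < 2:
        raise ValueError("need at least 2 folds for a standard error")
    sd = float(pa.std(ddof=1))
    return sd * math.sqrt(1.0 / n + n2 / n1)


def pa_typology(per_hybrid_pa: pd.Series) -> pd.DataFrame:
    """Histogram of per-hybrid PA over {<=0, quarter-width bins up to 1}."""
    pa = per_hybrid_pa.dropna()
    cats = pd.cut(pa, bins=list(TYPOLOGY_BINS), labels=list(TYPOLOGY_LABELS))
    counts = cats.value_counts().reindex(list(TYPOLOGY_LABELS), fill_value=0)
    freq = counts / counts.sum() if counts.sum() else counts.astype(float)
    return pd.DataFrame({"count": counts, "frequency": freq})


def _fold_sizes(plan: CVPlan) -> tuple[int, int]:
    n1 = int(plan.train_masks[0].sum())
    n2 = int((~plan.train_masks[0]).sum())
    return n1, n2


def run_grid(
    genotypes: GenotypeTable,
    phenotypes: PhenotypeTable,
    W: np.ndarray | None = None,
    env_labels: list[str] | None = None,
    models: tuple[str, ...] = MODEL_NAMES,
    kernel_methods: tuple[str, ...] = ("GB", "GK", "DK"),
    schemes: tuple[str, ...] = SCHEMES,
    repetitions: int = 50,
    train_fraction: float = 0.7,
    mcmc: McmcConfig = McmcConfig(),
    h: float = 1.0,
    layers: int = 2,
    select_hyperparams: bool = False,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[str, str], CVResult]]:
    """Run the model x kernel x scheme grid and tabulate predictive ability.

    Returns a long-format results table (model, kernel, scheme, mean PA, SE,
    percent gain over the EA baseline of the same kernel and scheme) plus
    the full per-cell :class:`CVResult` objects keyed by (model+kernel,
    scheme).

    When ``select_hyperparams`` is true, the GK bandwidth and DK depth are
    chosen once per kernel matrix by marginal likelihood on per-hybrid mean
    phenotypes (a faster stand-in for per-fold re-selection).
    """
    X_A = additive_design(genotypes)
    X_D = dominance_design(genotypes)
    gids = list(genotypes.hybrid_ids)
    if W is not None and env_labels is None:
        env_labels = phenotypes.environments

    y_bar = (
        phenotypes.records.groupby("gid")["value"].mean()
        .reindex(gids).to_numpy()
    )

    results: dict[tuple[str, str], CVResult] = {}
    rows = []
    for method in kernel_methods:
        kw = {"h": h, "layers": layers}
        if select_hyperparams and method == "GK":
            kw["h"] = select_bandwidth(X_A, y_bar)
        if select_hyperparams and method == "DK":
            kw["layers"] = select_layers(X_A, y_bar, l_max=5)
        K_A = build_kernel(X_A, method, labels=gids, **kw)
        K_D = build_kernel(X_D, method, labels=gids, **kw)
        K_W = (build_kernel(W, method, labels=env_labels, **kw)
               if W is not None else None)

        for model in models:
            if model in ("EADW", "EADW+GW") and K_W is None:
                logger.warning("skipping %s: no envirotype matrix", model)
                continue
            term_set = build_model(model, phenotypes, K_A, K_D, K_W)
            for scheme in schemes:
                t0 = time.perf_counter()
                plan = make_folds(phenotypes, scheme, repetitions,
                                  train_fraction, seed=seed)
                fold_pa: list[float] = []
                cv0_pred = []
                for k, mask in enumerate(plan.train_masks):
                    cfg = McmcConfig(
                        iterations=mcmc.iterations, burn_in=mcmc.burn_in,
                        thin=mcmc.thin, seed=mcmc.seed + 7919 * k,
                        nu_u=mcmc.nu_u, nu_e=mcmc.nu_e,
                        scale_u=mcmc.scale_u, scale_e=mcmc.scale_e,
                        eig_tol=mcmc.eig_tol,
                    )
                    fit = gibbs_fit(phenotypes, term_set, cfg, mask)
                    test = ~mask
                    r = predictive_ability(
                        phenotypes.y[test], fit.fitted[test]
                    )
                    fold_pa.append(r)
                    if scheme == "CV0":
                        sub = phenotypes.records.loc[test, ["env", "gid",
                                                            "value"]].copy()
                        sub["predicted"] = fit.fitted[test]
                        cv0_pred.append(sub)

                valid = [r for r in fold_pa if not np.isnan(r)]
                mean_pa = float(np.mean(valid)) if valid else float("nan")
                n1, n2 = _fold_sizes(plan)
                se = (standard_error(np.array(fold_pa), phenotypes.n, n1, n2)
                      if len(valid) >= 2 else float("nan"))
                res = CVResult(model, method, scheme, fold_pa, mean_pa, se)
                if scheme == "CV0":
                    res.per_environment = dict(
                        zip(plan.fold_labels, fold_pa)
                    )
                    all_pred = pd.concat(cv0_pred, ignore_index=True)
                    res.per_hybrid = genotype_level_pa(all_pred)
                    res.typology = pa_typology(res.per_hybrid)
                results[(f"{model}|{method}", scheme)] = res
                logger.info("%s / %s / %s: PA=%.3f (%.1fs)", model, method,
                            scheme, mean_pa, time.perf_counter() - t0)
                rows.append({
                    "model": model, "kernel": method, "scheme": scheme,
                    "mean_pa": mean_pa, "se": se,
                    "n_folds": plan.n_folds,
                })

    table = pd.DataFrame(rows)
    if not table.empty:
        base = table[table["model"] == "EA"].set_index(["kernel", "scheme"])[
            "mean_pa"]

        def gain(row):
            key = (row["kernel"], row["scheme"])
            if key not in base.index or base[key] == 0:
                return float("nan")
            return 100.0 * (row["mean_pa"] - base[key]) / abs(base[key])

        table["pct_gain_vs_EA"] = table.apply(gain, axis=1)
    return table, results
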