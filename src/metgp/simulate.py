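"""Synthetic genotypes, weather and phenotypes for multi-environment trials.

Parents are simulated as fully inbred (homozygous) lines; F1 hybrid dosages
are the deterministic sum of the two parental alleles.  Weather is a
seasonal sinusoid plus an environment-specific offset and noise — minimal
structure that gives environments distinguishable envirotypes.  Phenotypes
are drawn from the generative model the fitting stage assumes: a grand mean,
fixed environment offsets, zero-mean Gaussian effect vectors with
covariance (term kernel) x (term variance), and iid residual noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .envirotyping import WEATHER_VARIABLES
from .kernels import GenotypeTable, KernelMatrix
from .models import (
    PhenotypeTable,
    env_main_cov,
    interaction_cov,
    main_effect_cov,
)

TERM_NAMES = ("A", "D", "W", "AE", "DE", "AW", "DW")

__all__ = [
    "SimulationConfig",
    "cross_parents",
    "simulate_genotypes",
    "simulate_weather",
    "simulate_phenotypes",
    "write_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for one synthetic multi-environment trial."""

    n_parents: int = 20
    n_hybrids: int = 50
    n_markers: int = 200
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_environments: int = 4
    days: int = 120
    variance_components: Mapping[str, float] = field(
        default_factory=lambda: {"A": 1.0, "residual": 1.0}
    )
    mu: float = 6.0
    env_fixed_effects: tuple[float, ...] | None = None
    weather_noise_sd: float = 1.0
    weather_offset_sd: float = 1.0
    epistasis_variance: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        max_crosses = self.n_parents * (self.n_parents - 1) // 2
        if self.n_hybrids > max_crosses:
            raise ValueError(
                f"{self.n_hybrids} hybrids requested but only {max_crosses} "
                f"distinct crosses exist for {self.n_parents} parents"
            )
        for term, v in self.variance_components.items():
            if term not in TERM_NAMES + ("residual",):
                raise ValueError(f"unknown variance term {term!r}")
            if v < 0:
                raise ValueError(f"variance for {term} must be >= 0")
        if self.variance_components.get("residual", 0.0) <= 0:
            raise ValueError("residual variance must be positive")
        if (self.env_fixed_effects is not None
                and len(self.env_fixed_effects) != self.n_environments):
            raise ValueError("env_fixed_effects length must equal n_environments")

    @property
    def environment_ids(self) -> list[str]:
        return [f"E{i + 1}" for i in range(self.n_environments)]


def cross_parents(
    parent_alleles: np.ndarray, pairs: np.ndarray
) -> np.ndarray:
    """F1 dosages from homozygous parents: the sum of the two parental alleles.

    ``parent_alleles`` is parents x markers in {0, 1} (the allele each fully
    inbred parent is fixed for); the result is hybrids x markers in {0,1,2}.
    """
    pairs = np.asarray(pairs)
    return (parent_alleles[pairs[:, 0]] + parent_alleles[pairs[:, 1]]).astype(float)


def simulate_genotypes(config: SimulationConfig) -> GenotypeTable:
    """Cross homozygous parents into F1 hybrids with dosages in {0, 1, 2}."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.maf_range
    freq = rng.uniform(lo, hi, size=config.n_markers)
    # parental alleles: 1 with probability freq, parents fully homozygous
    parent_alleles = (
        rng.random((config.n_parents, config.n_markers)) < freq
    ).astype(int)

    pairs = [(i, j) for i in range(config.n_parents)
             for j in range(i + 1, config.n_parents)]
    chosen = rng.choice(len(pairs), size=config.n_hybrids, replace=False)
    parents = np.array([pairs[c] for c in chosen])
    dosage = cross_parents(parent_alleles, parents)

    table = GenotypeTable(
        dosage=dosage,
        hybrid_ids=[f"H{p1 + 1:03d}x{p2 + 1:03d}" for p1, p2 in parents],
        marker_ids=[f"M{k + 1}" for k in range(config.n_markers)],
        parents=parents,
    )
    table.parent_alleles = parent_alleles  # kept for provenance checks
    return table


def simulate_weather(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Daily weather tables per environment: sinusoid + offset + noise."""
    rng = np.random.default_rng(config.seed + 1)
    days = np.arange(1, config.days + 1)
    base = rng.uniform(5.0, 25.0, size=len(WEATHER_VARIABLES))
    amplitude = rng.uniform(1.0, 5.0, size=len(WEATHER_VARIABLES))
    phase = rng.uniform(0.0, 2.0 * math.pi, size=len(WEATHER_VARIABLES))
    tables: dict[str, pd.DataFrame] = {}
    for env in config.environment_ids:
        offsets = config.weather_offset_sd * rng.standard_normal(
            len(WEATHER_VARIABLES)
        )
        data = {"day": days}
        for k, var in enumerate(WEATHER_VARIABLES):
            season = base[k] + amplitude[k] * np.sin(
                2.0 * math.pi * days / 365.0 + phase[k]
            )
            noise = config.weather_noise_sd * rng.standard_normal(len(days))
            data[var] = season + offsets[k] + noise
        tables[env] = pd.DataFrame(data)
    return tables


def _draw_mvn(rng: np.random.Generator, K: np.ndarray, variance: float,
              psd_tol: float = 1e-8) -> np.ndarray:
    w, V = np.linalg.eigh(0.5 * (K + K.T))
    scale = max(w[-1], 1e-300)
    if w[0] < -psd_tol * scale:
        raise ValueError(
            f"non-PSD term covariance (min eigenvalue {w[0]:.3e})"
        )
    w = np.clip(w, 0.0, None)
    z = rng.standard_normal(w.size)
    return V @ (np.sqrt(variance * w) * z)


def simulate_phenotypes(
    genotypes: GenotypeTable,
    config: SimulationConfig,
    K_A: KernelMatrix | None = None,
    K_D: KernelMatrix | None = None,
    K_W: KernelMatrix | None = None,
) -> tuple[PhenotypeTable, dict]:
    """Draw phenotypes for the full hybrid x environment grid.

    Only terms with positive configured variance are simulated; each needs
    its kernel (K_A for A/AE/AW, K_D for D/DE/DW, K_W for W/AW/DW).
    Returns the phenotype table and a ground-truth dict holding the true
    effect vectors, fixed effects and variances.
    """
    rng = np.random.default_rng(config.seed + 2)
    envs = config.environment_ids
    gids = genotypes.hybrid_ids
    grid = pd.DataFrame(
        [(e, g) for e in envs for g in gids], columns=["env", "gid"]
    )
    grid["value"] = 0.0
    ph = PhenotypeTable(grid)
    Z_E = ph.incidence_env(envs)
    Z_G = ph.incidence_geno(list(gids))

    active = {
        t: v for t, v in config.variance_components.items()
        if t != "residual" and v > 0
    }
    needs = {"A": "K_A", "AE": "K_A", "AW": "K_A",
             "D": "K_D", "DE": "K_D", "DW": "K_D", "W": "K_W"}
    kernels = {"K_A": K_A, "K_D": K_D, "K_W": K_W}
    for t in active:
        if kernels[needs[t]] is None:
            raise ValueError(f"term {t} has positive variance but {needs[t]} "
                             "was not supplied")
        if t in ("AW", "DW") and K_W is None:
            raise ValueError(f"term {t} requires K_W")

    def aligned(K: KernelMatrix, labels: list[str]) -> np.ndarray:
        pos = {lab: i for i, lab in enumerate(K.labels)}
        idx = np.array([pos[str(lab)] for lab in labels])
        return K.values[np.ix_(idx, idx)]

    A = aligned(K_A, list(gids)) if K_A is not None else None
    D = aligned(K_D, list(gids)) if K_D is not None else None
    W = aligned(K_W, envs) if K_W is not None else None
    q = config.n_environments

    effects: dict[str, np.ndarray] = {}
    for t, var in active.items():
        if t == "A":
            cov = main_effect_cov(A, Z_G)
        elif t == "D":
            cov = main_effect_cov(D, Z_G)
        elif t == "W":
            cov = env_main_cov(W, Z_E)
        elif t == "AE":
            cov = interaction_cov(np.eye(q), A, Z_E, Z_G)
        elif t == "DE":
            cov = interaction_cov(np.eye(q), D, Z_E, Z_G)
        elif t == "AW":
            cov = interaction_cov(W, A, Z_E, Z_G)
        else:  # DW
            cov = interaction_cov(W, D, Z_E, Z_G)
        effects[t] = _draw_mvn(rng, cov, var)

    beta = (np.asarray(config.env_fixed_effects, dtype=float)
            if config.env_fixed_effects is not None
            else np.zeros(q))
    fixed = config.mu + Z_E @ beta

    genetic_extra = np.zeros(len(grid))
    epi_info = None
    if config.epistasis_variance > 0:
        # nonlinear architecture: pairwise multiplicative marker interactions
        Xc = genotypes.dosage - 2.0 * genotypes.freq
        m = genotypes.n_markers
        n_pairs = min(500, m * (m - 1) // 2)
        i_idx = rng.integers(0, m, size=n_pairs)
        j_idx = rng.integers(0, m, size=n_pairs)
        coefs = rng.standard_normal(n_pairs)
        g_epi = (Xc[:, i_idx] * Xc[:, j_idx]) @ coefs
        sd = g_epi.std()
        if sd > 0:
            g_epi = (g_epi - g_epi.mean()) / sd * math.sqrt(
                config.epistasis_variance
            )
        genetic_extra = Z_G @ g_epi
        epi_info = g_epi

    resid_var = config.variance_components["residual"]
    eps = math.sqrt(resid_var) * rng.standard_normal(len(grid))
    y = fixed + sum(effects.values(), np.zeros(len(grid))) + genetic_extra + eps

    table = grid.copy()
    table["value"] = y
    truth = {
        "mu": config.mu,
        "beta": dict(zip(envs, beta.tolist())),
        "variances": dict(config.variance_components),
        "effects": effects,
        "residual": eps,
        "epistasis": epi_info,
    }
    return PhenotypeTable(table), truth


def write_dataset(
    outdir: str | Path,
    genotypes: GenotypeTable,
    phenotypes: PhenotypeTable,
    weather: Mapping[str, pd.DataFrame],
    truth: dict | None = None,
) -> None:
    """Write genotype/phenotype/weather CSVs and a ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genotypes.to_frame().to_csv(outdir / "genotypes.csv")
    phenotypes.records.to_csv(outdir / "phenotypes.csv", index=False)
    for env, table in weather.items():
        table.to_csv(outdir / f"weather_{env}.csv", index=False)
    if truth is not None:
        serializable = {
            "mu": truth["mu"],
            "beta": truth["beta"],
            "variances": truth["variances"],
            "effects": {t: v.tolist() for t, v in truth["effects"].items()},
        }
        (outdir / "ground_truth.json").write_text(
            json.dumps(serializable, indent=1)
        )

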