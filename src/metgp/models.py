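"""Assembly of multi-environment model structures.

Five model structures of increasing complexity are supported, named by the
effects they carry:

========  =============================================
name      random terms
========  =============================================
EA        A
EAD       A, D
EAD+GE    A, D, AE, DE
EADW      A, D, W
EADW+GW   A, D, W, AW, DW
========  =============================================

All random-effect covariances are expanded to the observation level with
incidence matrices (``Z K Z'``), which handles unbalanced/sparse trial data
uniformly; interaction terms are Hadamard products of an environmental and a
genomic expansion.  Fixed effects are an intercept plus reference-coded
environment indicators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import KernelMatrix

MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "EA": ("A",),
    "EAD": ("A", "D"),
    "EAD+GE": ("A", "D", "AE", "DE"),
    "EADW": ("A", "D", "W"),
    "EADW+GW": ("A", "D", "W", "AW", "DW"),
}

MODEL_NAMES = tuple(MODEL_TERMS)

__all__ = [
    "MODEL_TERMS",
    "MODEL_NAMES",
    "PhenotypeTable",
    "EffectTermSet",
    "main_effect_cov",
    "env_main_cov",
    "interaction_cov",
    "build_model",
]


@dataclass
class PhenotypeTable:
    """Phenotype records (environment, hybrid, value) with incidence maps."""

    records: pd.DataFrame
    environments: list[str] = field(init=False)
    hybrids: list[str] = field(init=False)

    def __post_init__(self) -> None:
        req = {"env", "gid", "value"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"phenotype records need columns {sorted(req)}")
        rec = self.records.reset_index(drop=True).copy()
        rec["env"] = rec["env"].astype(str)
        rec["gid"] = rec["gid"].astype(str)
        if rec.duplicated(["env", "gid"]).any():
            dup = rec[rec.duplicated(["env", "gid"])].iloc[0]
            raise ValueError(
                f"duplicate record for environment {dup['env']!r}, "
                f"hybrid {dup['gid']!r}"
            )
        self.records = rec
        self.environments = sorted(rec["env"].unique())
        self.hybrids = sorted(rec["gid"].unique())

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def q(self) -> int:
        return len(self.environments)

    @property
    def p(self) -> int:
        return len(self.hybrids)

    @property
    def y(self) -> np.ndarray:
        return self.records["value"].to_numpy(dtype=float)

    def incidence_env(self, environments: list[str] | None = None) -> np.ndarray:
        """n x q 0/1 incidence of observations onto environments."""
        envs = environments if environments is not None else self.environments
        idx = {e: j for j, e in enumerate(envs)}
        Z = np.zeros((self.n, len(envs)))
        for i, e in enumerate(self.records["env"]):
            Z[i, idx[e]] = 1.0
        return Z

    def incidence_geno(self, hybrids: list[str] | None = None) -> np.ndarray:
        """n x p 0/1 incidence of observations onto hybrids."""
        gids = hybrids if hybrids is not None else self.hybrids
        idx = {g: j for j, g in enumerate(gids)}
        Z = np.zeros((self.n, len(gids)))
        for i, g in enumerate(self.records["gid"]):
            if g not in idx:
                raise KeyError(f"hybrid {g!r} absent from genotype labels")
            Z[i, idx[g]] = 1.0
        return Z

    def fixed_design(self) -> np.ndarray:
        """Intercept + reference-coded environment indicators (n x q)."""
        Z_E = self.incidence_env()
        return np.column_stack([np.ones(self.n), Z_E[:, 1:]])


@dataclass
class EffectTermSet:
    """Fixed design plus the ordered random-effect covariances of one model."""

    model: str
    fixed: np.ndarray
    terms: list[tuple[str, np.ndarray]]
    phenotypes: PhenotypeTable

    def __post_init__(self) -> None:
        expected = MODEL_TERMS.get(self.model)
        if expected is None:
            raise ValueError(f"unknown model {self.model!r}")
        got = tuple(name for name, _ in self.terms)
        if got != expected:
            raise ValueError(
                f"model {self.model} requires terms {expected}, got {got}"
            )
        n = self.phenotypes.n
        for name, K in self.terms:
            if K.shape != (n, n):
                raise ValueError(f"term {name}: covariance is not {n} x {n}")
            if not np.allclose(K, K.T, atol=1e-8):
                raise ValueError(f"term {name}: covariance not symmetric")

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.terms)


def _align_kernel(K: KernelMatrix, labels: list[str], what: str) -> np.ndarray:
    """Reorder a labeled kernel to the requested label order."""
    pos = {lab: i for i, lab in enumerate(K.labels)}
    missing = [lab for lab in labels if lab not in pos]
    if missing:
        raise KeyError(f"{what} kernel lacks labels {missing[:5]}")
    idx = np.array([pos[lab] for lab in labels])
    return K.values[np.ix_(idx, idx)]


def main_effect_cov(K_geno: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Observation-level expansion Z K Z' of a genotype-indexed covariance.

    Equivalent to the ``J_q (x) K`` Kronecker structure for balanced data:
    the effect is shared across environments.
    """
    K_geno = np.asarray(K_geno, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if Z.shape[1] != K_geno.shape[0]:
        raise ValueError(
            f"incidence has {Z.shape[1]} columns but kernel is "
            f"{K_geno.shape[0]} x {K_geno.shape[0]}"
        )
    return Z @ K_geno @ Z.T


def env_main_cov(K_W: np.ndarray, Z_E: np.ndarray) -> np.ndarray:
    """Observation-level expansion Z_E K_W Z_E' of the environment covariance."""
    return main_effect_cov(K_W, Z_E)


def interaction_cov(
    env_part: np.ndarray,
    K_geno: np.ndarray,
    Z_E: np.ndarray,
    Z_G: np.ndarray,
) -> np.ndarray:
    """Hadamard interaction covariance (Z_E E Z_E') ⊙ (Z_G K Z_G').

    ``env_part`` is the q x q identity for plain GE interaction or the
    environmental kernel K_W for reaction-norm (GW) interaction.
    """
    return env_main_cov(env_part, Z_E) * main_effect_cov(K_geno, Z_G)


def build_model(
    name: str,
    phenotypes: PhenotypeTable,
    K_A: KernelMatrix,
    K_D: KernelMatrix | None = None,
    K_W: KernelMatrix | None = None,
) -> EffectTermSet:
    """Assemble the fixed design and random-term covariances for one model."""
    if name not in MODEL_TERMS:
        raise ValueError(
            f"unknown model {name!r}; choose one of {MODEL_NAMES}"
        )
    needed = MODEL_TERMS[name]
    if any(t in needed for t in ("D", "DE", "DW")) and K_D is None:
        raise ValueError(f"model {name} requires the dominance kernel K_D")
    if any(t in needed for t in ("W", "AW", "DW")) and K_W is None:
        raise ValueError(f"model {name} requires the environmental kernel K_W")

    Z_E = phenotypes.incidence_env()
    Z_G = phenotypes.incidence_geno(list(K_A.labels))
    A = _align_kernel(K_A, list(K_A.labels), "additive")
    q = phenotypes.q

    if q == 1 and ("AE" in needed or "DE" in needed):
        warnings.warn(
            "single environment: AE/DE covariances duplicate A/D",
            stacklevel=2,
        )

    terms: list[tuple[str, np.ndarray]] = []
    cov_A = main_effect_cov(A, Z_G)
    for term in needed:
        if term == "A":
            terms.append(("A", cov_A))
        elif term == "D":
            D = _align_kernel(K_D, list(K_A.labels), "dominance")
            terms.append(("D", main_effect_cov(D, Z_G)))
        elif term == "W":
            W = _align_kernel(K_W, phenotypes.environments, "environmental")
            terms.append(("W", env_main_cov(W, Z_E)))
        elif term in ("AE", "DE"):
            K = A if term == "AE" else _align_kernel(
                K_D, list(K_A.labels), "dominance")
            terms.append((term, interaction_cov(np.eye(q), K, Z_E, Z_G)))
        elif term in ("AW", "DW"):
            K = A if term == "AW" else _align_kernel(
                K_D, list(K_A.labels), "dominance")
            W = _align_kernel(K_W, phenotypes.environments, "environmental")
            terms.append((term, interaction_cov(W, K, Z_E, Z_G)))
    return EffectTermSet(name, phenotypes.fixed_design(), terms, phenotypes)
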