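"""Marker codings and relationship-kernel constructions.

Three kernel methods are supported for building relationship matrices from a
generic feature matrix ``X`` (marker codes or scaled environmental
covariables):

``GB``
    trace-normalized linear kernel ``XX' / (trace(XX')/nrow(X))``,
``GK``
    Gaussian kernel ``exp(-h * D^2 / Q)`` where ``D^2`` is the squared
    Euclidean distance matrix and ``Q`` the median of its off-diagonal
    entries,
``DK``
    recursive arc-cosine ("deep") kernel emulating a one-hidden-layer
    neural network, deepened by ``l`` recursion levels.

Hyperparameters (``h`` for GK, number of layers for DK) are selected by
maximizing the marginal likelihood of a single-kernel mixed model on a
candidate grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

DEFAULT_BANDWIDTH_GRID = (0.1, 0.25, 0.5, 1.0, 2.0, 5.0)

__all__ = [
    "GenotypeTable",
    "KernelMatrix",
    "maf_filter",
    "additive_design",
    "dominance_design",
    "gb_kernel",
    "gk_kernel",
    "dk_base",
    "dk_recurse",
    "dk_kernel",
    "select_bandwidth",
    "select_layers",
    "normalize_kernel",
    "build_kernel",
    "read_genotypes_csv",
    "read_genotypes_vcf",
]


# ---------------------------------------------------------------------------
# Genotype container
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Hybrid-by-marker dosage matrix with per-marker allele frequencies.

    Parameters
    ----------
    dosage
        ``(p, m)`` integer array of counted-allele dosages in {0, 1, 2}.
    hybrid_ids
        Length-``p`` labels.
    marker_ids
        Length-``m`` labels.
    parents
        Optional ``(p, 2)`` array of parent indices (synthetic crosses).
    """

    dosage: np.ndarray
    hybrid_ids: list[str]
    marker_ids: list[str]
    parents: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (hybrids x markers)")
        if np.isnan(self.dosage).any():
            raise ValueError(
                "dosage contains missing entries; impute before constructing "
                "a GenotypeTable (mean imputation is an explicit pre-step)"
            )
        if not np.isin(self.dosage, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2}")
        p, m = self.dosage.shape
        if len(self.hybrid_ids) != p or len(self.marker_ids) != m:
            raise ValueError("label lengths do not match dosage shape")

    @property
    def n_hybrids(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def freq(self) -> np.ndarray:
        """Frequency of the counted allele per marker, from hybrid dosages."""
        return self.dosage.mean(axis=0) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosage, index=self.hybrid_ids, columns=self.marker_ids
        )


# ---------------------------------------------------------------------------
# Kernel container
# ---------------------------------------------------------------------------

@dataclass
class KernelMatrix:
    """Labeled symmetric PSD relationship matrix with method metadata."""

    values: np.ndarray
    labels: list[str]
    method: str
    hyperparams: dict = field(default_factory=dict)
    psd_tolerance: float = 1e-8

    def __post_init__(self) -> None:
        K = np.asarray(self.values, dtype=float)
        n = K.shape[0]
        if K.ndim != 2 or K.shape[1] != n:
            raise ValueError("kernel must be square")
        if len(self.labels) != n:
            raise ValueError("label count does not match kernel size")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("kernel is not symmetric (tolerance 1e-10)")
        K = 0.5 * (K + K.T)
        self.values = _psd_repair(K, self.psd_tolerance)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _psd_repair(K: np.ndarray, rel_tol: float) -> np.ndarray:
    """Clip slightly negative eigenvalues; error if clearly indefinite."""
    w = np.linalg.eigvalsh(K)
    scale = max(w[-1], 1e-300)
    if w[0] < -rel_tol * scale:
        raise ValueError(
            f"kernel is not positive semidefinite: min eigenvalue {w[0]:.3e} "
            f"below -{rel_tol:.0e} * max eigenvalue {scale:.3e}"
        )
    if w[0] < 0:
        w_full, U = np.linalg.eigh(K)
        w_full = np.clip(w_full, 0.0, None)
        K = (U * w_full) @ U.T
        K = 0.5 * (K + K.T)
    return K


# ---------------------------------------------------------------------------
# Marker codings
# ---------------------------------------------------------------------------

def maf_filter(genotypes: GenotypeTable, threshold: float = 0.05) -> GenotypeTable:
    """Remove markers whose minor allele frequency is <= ``threshold``.

    The filter is strict at the boundary: a marker at exactly the threshold
    is removed.
    """
    f = genotypes.freq
    maf = np.minimum(f, 1.0 - f)
    keep = maf > threshold
    n_removed = int((~keep).sum())
    if not keep.any():
        raise ValueError(
            f"all {genotypes.n_markers} markers removed at MAF <= {threshold}"
        )
    if n_removed:
        logger.info("maf_filter: removed %d of %d markers", n_removed,
                    genotypes.n_markers)
    return GenotypeTable(
        dosage=genotypes.dosage[:, keep],
        hybrid_ids=list(genotypes.hybrid_ids),
        marker_ids=[m for m, k in zip(genotypes.marker_ids, keep) if k],
        parents=genotypes.parents,
    )


def additive_design(genotypes: GenotypeTable, center: bool = True) -> np.ndarray:
    """Additive marker coding: raw dosages, optionally centered by ``2 f_l``."""
    X = genotypes.dosage.astype(float)
    if center:
        X = X - 2.0 * genotypes.freq
    return X


def dominance_design(genotypes: GenotypeTable) -> np.ndarray:
    """Dominance-deviation coding per marker with counted-allele frequency f.

    dosage 2 -> -2(1-f)^2, dosage 1 -> 2f(1-f), dosage 0 -> -2f^2.
    The HWE-weighted mean of the three codes is zero for every f in (0, 1).
    """
    f = genotypes.freq
    if ((f <= 0.0) | (f >= 1.0)).any():
        bad = np.where((f <= 0.0) | (f >= 1.0))[0]
        raise ValueError(
            f"dominance deviation undefined for monomorphic markers at "
            f"indices {bad[:5].tolist()} (f in {{0,1}}); apply maf_filter first"
        )
    dos = genotypes.dosage
    D = np.empty_like(dos, dtype=float)
    D[dos == 0] = np.broadcast_to(-2.0 * f**2, dos.shape)[dos == 0]
    D[dos == 1] = np.broadcast_to(2.0 * f * (1.0 - f), dos.shape)[dos == 1]
    D[dos == 2] = np.broadcast_to(-2.0 * (1.0 - f) ** 2, dos.shape)[dos == 2]
    return D


# ---------------------------------------------------------------------------
# Kernel builders
# ---------------------------------------------------------------------------

def _labels_for(X: np.ndarray, labels: Sequence[str] | None) -> list[str]:
    if labels is None:
        return [str(i) for i in range(X.shape[0])]
    return list(labels)


def gb_kernel(X: np.ndarray, labels: Sequence[str] | None = None) -> KernelMatrix:
    """Trace-normalized linear kernel K = XX' / (trace(XX')/nrow(X))."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    G = X @ X.T
    tr = np.trace(G)
    if tr <= 0:
        raise ValueError("gb_kernel: trace(XX') is zero (all-zero input)")
    K = G / (tr / X.shape[0])
    return KernelMatrix(K, _labels_for(X, labels), "GB")


def _sq_distances(X: np.ndarray) -> np.ndarray:
    return squareform(pdist(X, metric="sqeuclidean"))


def gk_kernel(
    X: np.ndarray, h: float = 1.0, labels: Sequence[str] | None = None
) -> KernelMatrix:
    """Gaussian kernel K_ii' = exp(-h * D2_ii' / Q).

    ``D2`` is the squared Euclidean distance matrix and ``Q`` the median of
    its strictly off-diagonal entries, so the kernel is scale-free in the
    input units.  The diagonal is exactly 1.
    """
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("gk_kernel needs at least 2 rows")
    D2 = _sq_distances(X)
    off = D2[np.triu_indices_from(D2, k=1)]
    Q = float(np.median(off))
    if Q <= 0:
        raise ValueError(
            "gk_kernel: median off-diagonal squared distance is zero "
            "(degenerate distances: too many identical rows)"
        )
    K = np.exp(-h * D2 / Q)
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(K, _labels_for(X, labels), "GK",
                        {"h": float(h), "Q": Q})


def _j_theta(theta: np.ndarray) -> np.ndarray:
    return np.sin(theta) + (np.pi - theta) * np.cos(theta)


def dk_base(X: np.ndarray, labels: Sequence[str] | None = None) -> KernelMatrix:
    """Base arc-cosine kernel DK1(x, x') = (1/pi) ||x|| ||x'|| J(theta).

    ``theta`` is the angle between the two rows; ``J(theta) = sin(theta) +
    (pi - theta) cos(theta)``.  Satisfies ``DK1(x, x) = ||x||^2`` and
    ``DK1(x, -x) = 0``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        raise ValueError("dk_base: input has an all-zero row (zero norm)")
    cos = (X @ X.T) / np.outer(norms, norms)
    theta = np.arccos(np.clip(cos, -1.0, 1.0))
    K = (1.0 / np.pi) * np.outer(norms, norms) * _j_theta(theta)
    K = 0.5 * (K + K.T)
    return KernelMatrix(K, _labels_for(X, labels), "DK", {"layers": 1})


def dk_recurse(K_l: KernelMatrix, levels: int = 1) -> KernelMatrix:
    """Apply the arc-cosine layer recursion ``levels`` times.

    DK(l+1)(i,i') = (1/pi) sqrt(DK(l)(i,i) DK(l)(i',i')) J(theta(l)) with
    theta(l) the angle implied by the previous layer.  The diagonal is
    preserved exactly.
    """
    K = np.array(K_l.values, dtype=float)
    if (np.diag(K) <= 0).any():
        raise ValueError("dk_recurse: kernel diagonal must be positive")
    for _ in range(levels):
        d = np.sqrt(np.diag(K))
        denom = np.outer(d, d)
        theta = np.arccos(np.clip(K / denom, -1.0, 1.0))
        K = (1.0 / np.pi) * denom * _j_theta(theta)
        K = 0.5 * (K + K.T)
        np.fill_diagonal(K, d**2)
    layers = int(K_l.hyperparams.get("layers", 1)) + levels
    return KernelMatrix(K, list(K_l.labels), "DK", {"layers": layers})


def dk_kernel(
    X: np.ndarray, layers: int = 1, labels: Sequence[str] | None = None
) -> KernelMatrix:
    """Arc-cosine kernel at the requested depth (``layers`` >= 1)."""
    if layers < 1:
        raise ValueError("layers must be >= 1")
    K = dk_base(X, labels=labels)
    if layers > 1:
        K = dk_recurse(K, levels=layers - 1)
    return K


def normalize_kernel(K: KernelMatrix) -> KernelMatrix:
    """Rescale so the mean diagonal equals 1 (idempotent)."""
    tr = float(np.trace(K.values))
    if tr <= 0:
        raise ValueError("normalize_kernel: zero trace")
    scale = tr / K.n
    return KernelMatrix(K.values / scale, list(K.labels), K.method,
                        dict(K.hyperparams))


# ---------------------------------------------------------------------------
# Marginal-likelihood hyperparameter selection
# ---------------------------------------------------------------------------

def kernel_marginal_loglik(
    K: np.ndarray,
    y: np.ndarray,
    ratio_grid: Sequence[float] | None = None,
) -> float:
    """Profile REML-style marginal log-likelihood of y = 1*mu + u + e.

    ``u ~ N(0, K sigma2_u)``, ``e ~ N(0, I sigma2_e)``.  The mean is removed
    by centering; for each candidate variance ratio ``lambda = sigma2_u /
    sigma2_e`` on the grid, the total variance is profiled out analytically
    and the maximum over the grid is returned.
    """
    if ratio_grid is None:
        ratio_grid = np.geomspace(1e-3, 1e3, 41)
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    n = y.size
    w, U = np.linalg.eigh(0.5 * (K + K.T))
    w = np.clip(w, 0.0, None)
    z2 = (U.T @ yc) ** 2
    best = -np.inf
    for lam in ratio_grid:
        v = lam * w + 1.0  # marginal eigen-variances up to sigma2_e
        quad = float(np.sum(z2 / v))
        if quad <= 0:
            continue
        # profile sigma2_e = quad / n
        ll = -0.5 * (np.sum(np.log(v)) + n * np.log(quad / n) + n)
        best = max(best, ll)
    return best


def select_bandwidth(
    X: np.ndarray,
    y: np.ndarray,
    candidate_h: Sequence[float] = DEFAULT_BANDWIDTH_GRID,
) -> float:
    """Pick the GK bandwidth maximizing the single-kernel marginal likelihood.

    Ties break toward the smaller h.
    """
    candidates = sorted(float(h) for h in candidate_h)
    if not candidates:
        raise ValueError("empty candidate grid")
    if len(candidates) == 1:
        return candidates[0]
    best_h, best_ll = None, -np.inf
    for h in candidates:
        K = gk_kernel(X, h=h).values
        ll = kernel_marginal_loglik(K, y)
        if np.isfinite(ll) and ll > best_ll:
            best_h, best_ll = h, ll
    if best_h is None:
        raise ValueError("non-finite marginal likelihood for all candidates")
    return best_h


def select_layers(X: np.ndarray, y: np.ndarray, l_max: int = 10) -> int:
    """Pick the arc-cosine depth in 1..l_max maximizing the marginal likelihood.

    Ties break toward the smaller l.
    """
    if l_max < 1:
        raise ValueError("l_max must be >= 1")
    K = dk_base(X)
    best_l, best_ll = None, -np.inf
    for l in range(1, l_max + 1):
        if l > 1:
            K = dk_recurse(K, levels=1)
        ll = kernel_marginal_loglik(K.values, y)
        if np.isfinite(ll) and ll > best_ll:
            best_l, best_ll = l, ll
    if best_l is None:
        raise ValueError("non-finite marginal likelihood for all candidates")
    return best_l


def build_kernel(
    X: np.ndarray,
    method: str,
    labels: Sequence[str] | None = None,
    h: float = 1.0,
    layers: int = 1,
) -> KernelMatrix:
    """Dispatch to GB / GK / DK by method name."""
    method = method.upper()
    if method == "GB":
        return gb_kernel(X, labels=labels)
    if method == "GK":
        return gk_kernel(X, h=h, labels=labels)
    if method == "DK":
        return dk_kernel(X, layers=layers, labels=labels)
    raise ValueError(f"unknown kernel method {method!r}; use GB, GK or DK")


# ---------------------------------------------------------------------------
# Genotype IO
# ---------------------------------------------------------------------------

def read_genotypes_csv(path, sep: str = ",") -> GenotypeTable:
    """Read an IDs-by-markers dosage table (first column = hybrid ID)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        col_means = np.nanmean(values, axis=0)
        n_imp = int(np.isnan(values).sum())
        idx = np.where(np.isnan(values))
        values[idx] = np.round(col_means[idx[1]])
        logger.warning("read_genotypes_csv: mean-imputed %d missing entries",
                       n_imp)
    return GenotypeTable(values, [str(i) for i in df.index],
                         [str(c) for c in df.columns])


def read_genotypes_vcf(path) -> GenotypeTable:
    """Read diploid biallelic VCF genotypes as ALT-allele dosages.

    Multiallelic sites and sites with missing calls are skipped with a
    logged count.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("cyvcf2 is required for VCF input") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        gts = np.asarray(var.gt_types)  # 0 hom-ref, 1 het, 2 missing, 3 hom-alt
        if (gts == 2).any():
            skipped += 1
            continue
        dosage = np.where(gts == 3, 2, gts).astype(float)
        rows.append(dosage)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    if skipped:
        logger.info("read_genotypes_vcf: skipped %d sites", skipped)
    if not rows:
        raise ValueError("no usable biallelic records in VCF")
    return GenotypeTable(np.column_stack(rows), samples, ids)
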