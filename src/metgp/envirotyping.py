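"""Envirotype covariable construction from daily environmental tables.

Daily weather/management tables (one per environment, indexed by day of
cycle) are summarized into per-interval quantiles, centered and scaled
across environments, quality-controlled, and turned into an environmental
relationship kernel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .kernels import KernelMatrix, build_kernel

logger = logging.getLogger(__name__)

#: Daily environmental variables (weather schema used throughout).
WEATHER_VARIABLES: tuple[str, ...] = (
    "toa_insolation",
    "surface_insolation",
    "longwave_flux",
    "wind_speed_10m",
    "tmin_2m",
    "tmax_2m",
    "dewpoint_2m",
    "relative_humidity",
    "precipitation",
    "temp_rue_effect",
    "evapotranspiration",
    "water_deficit",
    "vapor_pressure_deficit",
    "svp_slope",
    "temp_range",
    "global_radiation",
)

#: Default crop-cycle phenology windows as (start_DAE, end_DAE, label).
DEFAULT_INTERVALS: tuple[tuple[int, int, str], ...] = (
    (0, 14, "emergence_V1"),
    (15, 35, "V1_V4"),
    (36, 65, "V4_VT"),
    (66, 90, "VT_R3"),
    (91, 120, "R3_maturity"),
)

DEFAULT_PERCENTILES: tuple[float, ...] = (0.25, 0.50, 0.75)

__all__ = [
    "WEATHER_VARIABLES",
    "DEFAULT_INTERVALS",
    "DEFAULT_PERCENTILES",
    "PhenologyIntervals",
    "EnvCovariableMatrix",
    "summarize_interval_percentiles",
    "append_management_covariables",
    "scale_and_qc",
    "env_kernel",
    "register_derived_variable",
    "apply_derived_variables",
]


@dataclass(frozen=True)
class PhenologyIntervals:
    """Ordered, contiguous, non-overlapping crop-cycle windows.

    The day-of-cycle convention is 1-based from emergence: an interval
    ``(start, end)`` covers days ``max(start, 1) .. end`` inclusive, so the
    first default window "0-14" means days 1-14.
    """

    intervals: tuple[tuple[int, int, str], ...] = DEFAULT_INTERVALS

    def __post_init__(self) -> None:
        prev_end = None
        for start, end, _label in self.intervals:
            if end < start:
                raise ValueError(f"interval ({start}, {end}) is decreasing")
            if prev_end is not None and start != prev_end + 1:
                raise ValueError(
                    f"intervals must be contiguous; gap/overlap at {start}"
                )
            prev_end = end

    def __iter__(self):
        return iter(self.intervals)

    def days(self, start: int, end: int) -> np.ndarray:
        return np.arange(max(start, 1), end + 1)

    @property
    def max_day(self) -> int:
        return self.intervals[-1][1]


@dataclass
class EnvCovariableMatrix:
    """Scaled envirotype covariable matrix (q environments x k covariables).

    ``values`` columns have mean 0 and SD 1; ``scaling`` records the
    pre-scaling mean/SD per retained column and ``dropped_columns`` logs the
    QC decisions.
    """

    values: pd.DataFrame
    scaling: pd.DataFrame
    dropped_columns: dict[str, str] = field(default_factory=dict)

    @property
    def n_environments(self) -> int:
        return self.values.shape[0]

    @property
    def n_covariables(self) -> int:
        return self.values.shape[1]

    @property
    def environments(self) -> list[str]:
        return [str(e) for e in self.values.index]

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def summarize_interval_percentiles(
    daily_tables: Mapping[str, pd.DataFrame],
    intervals: PhenologyIntervals | None = None,
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
) -> pd.DataFrame:
    """Summarize daily series into (variable, interval, percentile) covariables.

    Parameters
    ----------
    daily_tables
        Mapping environment -> table with a ``day`` column (1-based day of
        cycle) and one column per environmental variable.
    intervals
        Phenology windows; defaults to the five standard windows.
    percentiles
        Quantile levels computed per window (linear-interpolation type-7).

    Returns
    -------
    DataFrame
        Environments x covariables, columns named
        ``<variable>_<interval-label>_q<percent>``.
    """
    intervals = intervals or PhenologyIntervals()
    rows = {}
    for env, table in daily_tables.items():
        if "day" not in table.columns:
            raise ValueError(f"table for environment {env!r} lacks a 'day' column")
        variables = [c for c in table.columns if c != "day"]
        day = table["day"].to_numpy()
        record: dict[str, float] = {}
        for start, end, label in intervals:
            window = table.loc[(day >= max(start, 1)) & (day <= end)]
            if window.empty:
                raise ValueError(
                    f"environment {env!r}: interval {label} "
                    f"({start}-{end} DAE) is outside the data's day range"
                )
            for var in variables:
                series = window[var].to_numpy(dtype=float)
                for pq in percentiles:
                    col = f"{var}_{label}_q{int(round(pq * 100)):02d}"
                    record[col] = float(np.quantile(series, pq))
        rows[env] = record
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "env"
    return out


def append_management_covariables(
    raw_table: pd.DataFrame,
    management: Mapping[str, Mapping[str, float]] | Mapping[str, float],
    name: str = "management",
) -> pd.DataFrame:
    """Append per-environment management covariables (e.g. nitrogen applied).

    ``management`` maps column name -> {environment: value}.  A flat
    {environment: value} map is accepted as a single variable named
    ``name``.  Every environment in the table must appear in each map.
    """
    if management and not isinstance(next(iter(management.values())), Mapping):
        management = {name: management}  # type: ignore[dict-item]
    out = raw_table.copy()
    for name, env_map in management.items():
        if name in out.columns:
            raise ValueError(f"duplicate covariable column {name!r}")
        missing = [e for e in out.index if e not in env_map]
        if missing:
            raise ValueError(
                f"management variable {name!r} missing environments {missing}"
            )
        out[name] = [float(env_map[e]) for e in out.index]
    return out


def scale_and_qc(
    raw_table: pd.DataFrame, z_threshold: float = 3.0
) -> EnvCovariableMatrix:
    """Center/scale covariables across environments and drop QC failures.

    Zero-variance columns are dropped first; then any column with a
    standardized entry exceeding ``|z_threshold|`` is dropped.  Both are
    recorded in ``dropped_columns``.
    """
    if raw_table.shape[0] < 2:
        raise ValueError("scale_and_qc needs at least 2 environments")
    dropped: dict[str, str] = {}
    values = raw_table.to_numpy(dtype=float)
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    cols = list(raw_table.columns)

    keep = sds > 0
    for c, k in zip(cols, keep):
        if not k:
            dropped[c] = "zero variance"
    z = (values[:, keep] - means[keep]) / sds[keep]
    kept_cols = [c for c, k in zip(cols, keep) if k]

    outlier = np.abs(z).max(axis=0) > z_threshold
    for c, bad in zip(kept_cols, outlier):
        if bad:
            dropped[c] = f"|z| > {z_threshold}"
    final_cols = [c for c, bad in zip(kept_cols, outlier) if not bad]
    if not final_cols:
        raise ValueError("all covariable columns dropped by QC")
    z = z[:, ~outlier]

    scaling = pd.DataFrame(
        {"mean": means[keep][~outlier], "sd": sds[keep][~outlier]},
        index=final_cols,
    )
    if dropped:
        logger.info("scale_and_qc: dropped %d columns (%s)", len(dropped),
                    ", ".join(sorted(set(dropped.values()))))
    scaled = pd.DataFrame(z, index=raw_table.index, columns=final_cols)
    return EnvCovariableMatrix(scaled, scaling, dropped)


def env_kernel(
    W: EnvCovariableMatrix,
    method: str = "GB",
    h: float = 1.0,
    layers: int = 1,
) -> KernelMatrix:
    """Build the q x q environmental relationship kernel from scaled W."""
    return build_kernel(
        W.to_numpy(), method, labels=W.environments, h=h, layers=layers
    )


# ---------------------------------------------------------------------------
# Derived-variable hook
# ---------------------------------------------------------------------------

_DERIVED_REGISTRY: dict[str, Callable[[pd.DataFrame], pd.Series]] = {}


def register_derived_variable(
    name: str, fn: Callable[[pd.DataFrame], pd.Series]
) -> None:
    """Register a function deriving a daily variable from existing columns."""
    _DERIVED_REGISTRY[name] = fn


def apply_derived_variables(daily_table: pd.DataFrame) -> pd.DataFrame:
    """Append all registered derived variables as new daily columns."""
    out = daily_table.copy()
    for name, fn in _DERIVED_REGISTRY.items():
        out[name] = fn(out)
    return out
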