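"""Isocratic retention processing and pure-water extrapolation.

Retention times are converted to retention factors k = (t_r - t_0)/t_0,
replicates are averaged, and log10 k is regressed on the eluent composition:
the acetonitrile volume fraction for IAM and CHOL systems, or the micellized
surfactant concentration C_M = C - CMC for BMC systems.  The intercept of
that line is logkw, the retention factor extrapolated to a pure-water eluent
— a chromatographic lipophilicity index substitutable for logPow.

Replicates are averaged on the k scale before the log transform by default
(``aggregate="k"``); averaging the logs instead is available via
``aggregate="log"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import (
    ConfigurationError,
    DataQualityWarning,
    InsufficientDataError,
    SingularDesignError,
    ValidationError,
)
from .io import RetentionMeasurement

__all__ = [
    "BRIJ35_CMC",
    "RetentionSeries",
    "LinearFitResult",
    "LogkwResult",
    "retention_factor",
    "micellized_concentration",
    "build_series",
    "fit_logk_series",
    "extrapolate_logkw",
]

#: Documented default critical micelle concentration of Brij35 at 25 °C
#: (mol/dm³); override per run if a measured value is available.
BRIJ35_CMC = 9.0e-5


def retention_factor(t_r: float, t_0: float) -> float:
    """Dimensionless retention factor k = (t_r - t_0)/t_0 (times in minutes)."""
    if not t_0 > 0:
        raise ValidationError("t_0 must be > 0")
    if t_r < t_0:
        raise ValidationError(f"t_r {t_r} < t_0 {t_0}")
    return (t_r - t_0) / t_0


def micellized_concentration(c_total: float, cmc: float) -> float:
    """Micellized surfactant concentration C_M = C - CMC (mol/dm³)."""
    if cmc < 0:
        raise ValidationError("cmc must be >= 0")
    if c_total < cmc:
        raise ValidationError(f"total concentration {c_total} below the CMC {cmc}")
    return c_total - cmc


@dataclass
class RetentionSeries:
    """Replicate-averaged (level, k) points for one compound in one system.

    ``points`` is a list of (level, k, n_replicates) with strictly increasing
    levels; ``cmc`` (mol/dm³) is required for BMC series, where the fitting
    abscissa is C_M = level - cmc.
    """

    compound_id: str
    system: str
    points: list[tuple[float, float, int]]
    cmc: float | None = None

    def __post_init__(self) -> None:
        if self.system == "BMC" and self.cmc is None:
            raise ConfigurationError(
                f"{self.compound_id}: BMC series require the surfactant CMC "
                f"(e.g. BRIJ35_CMC = {BRIJ35_CMC})"
            )
        levels = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValidationError("levels must be strictly increasing")

    @property
    def levels(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def k(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    @property
    def abscissa(self) -> np.ndarray:
        """The regression abscissa: C_M for BMC, the raw level otherwise."""
        if self.system == "BMC":
            return np.array(
                [micellized_concentration(lv, self.cmc) for lv in self.levels]
            )
        return self.levels


@dataclass
class LinearFitResult:
    """OLS line summary: slope, intercept, R², residual sd, point count."""

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n_points: int

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValidationError(f"r_squared {self.r_squared} outside [0, 1]")
        self.r_squared = min(max(self.r_squared, 0.0), 1.0)

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass
class LogkwResult:
    """Pure-water extrapolation: logkw is the intercept of the logk-level line."""

    compound_id: str
    system: str
    logkw: float
    fit: LinearFitResult

    def summary(self) -> str:
        f = self.fit
        return (
            f"{self.compound_id} [{self.system}]: logkw = {self.logkw:.4f} "
            f"(slope {f.slope:+.4f}, R² {f.r_squared:.4f}, n {f.n_points})"
        )


def build_series(
    measurements: Iterable[RetentionMeasurement],
    cmc: float | None = None,
    aggregate: str = "k",
) -> list[RetentionSeries]:
    """Group measurements by (compound, system) into replicate-averaged series.

    Replicates at the same level are averaged on the k scale (``aggregate="k"``,
    default) or on the log10 k scale (``aggregate="log"``).  Levels whose
    averaged k is not positive are excluded with a warning, since they cannot
    be log-transformed.  ``cmc`` must be supplied when BMC measurements are
    present.
    """
    if aggregate not in ("k", "log"):
        raise ConfigurationError(f"unknown aggregate mode {aggregate!r}")
    groups: dict[tuple[str, str], dict[float, list[float]]] = {}
    for m in measurements:
        groups.setdefault((m.compound_id, m.system), {}).setdefault(m.level, []).append(
            retention_factor(m.t_r, m.t_0)
        )
    series: list[RetentionSeries] = []
    for (cid, system), by_level in sorted(groups.items()):
        points = []
        for level in sorted(by_level):
            ks = by_level[level]
            if len(ks) < 3:
                warnings.warn(
                    f"{cid} [{system}] level {level}: only {len(ks)} replicate(s); "
                    "at least three independent measurements are recommended",
                    DataQualityWarning,
                    stacklevel=2,
                )
            if aggregate == "k":
                k_avg = float(np.mean(ks))
            else:
                if any(k <= 0 for k in ks):
                    k_avg = 0.0
                else:
                    k_avg = float(10 ** np.mean(np.log10(ks)))
            if k_avg <= 0:
                warnings.warn(
                    f"{cid} [{system}] level {level}: averaged k <= 0, "
                    "excluded (cannot take log)",
                    DataQualityWarning,
                    stacklevel=2,
                )
                continue
            points.append((level, k_avg, len(ks)))
        series.append(
            RetentionSeries(
                compound_id=cid,
                system=system,
                points=points,
                cmc=cmc if system == "BMC" else None,
            )
        )
    return series


def _ols_line(x: np.ndarray, y: np.ndarray) -> LinearFitResult:
    n = len(x)
    if len(np.unique(x)) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct levels for a line fit, got {len(np.unique(x))}"
        )
    if np.ptp(x) == 0:
        raise SingularDesignError("zero variance in the composition level")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    residual_sd = float(np.sqrt(ss_res / (n - 2))) if n > 2 else 0.0
    return LinearFitResult(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        residual_sd=residual_sd,
        n_points=n,
    )


def fit_logk_series(series: RetentionSeries) -> LinearFitResult:
    """OLS of log10 k on the composition abscissa (volume fraction or C_M)."""
    k = series.k
    if np.any(k <= 0):
        raise ValidationError("all retention factors must be > 0 for the log transform")
    return _ols_line(series.abscissa, np.log10(k))


def extrapolate_logkw(fit: LinearFitResult, compound_id: str, system: str) -> LogkwResult:
    """Pure-water retention: the fitted line evaluated at level 0 (its intercept)."""
    return LogkwResult(compound_id=compound_id, system=system, logkw=fit.intercept, fit=fit)


def logkw_from_measurements(
    measurements: Iterable[RetentionMeasurement],
    cmc: float | None = None,
    aggregate: str = "k",
) -> list[LogkwResult]:
    """Convenience pipeline: measurements -> series -> line fits -> logkw."""
    results = []
    for s in build_series(measurements, cmc=cmc, aggregate=aggregate):
        fit = fit_logk_series(s)
        results.append(extrapolate_logkw(fit, s.compound_id, s.system))
    return results
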