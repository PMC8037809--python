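"""Analyte-micelle association from micellar retention (Foley analysis).

In bio-partitioning micellar chromatography the reciprocal retention factor
is linear in the micellized surfactant concentration:

    1/k = (K_MA / (P_SW * phi)) * C_M + 1 / (P_SW * phi)

where K_MA (dm³/mol) is the analyte-micelle association constant, P_SW the
analyte partition coefficient between the stationary phase and water, and
phi the stationary/mobile phase volume ratio of the column.  An unweighted
OLS of 1/k on C_M with slope a and intercept b therefore gives

    P_SW = 1 / (b * phi)        K_MA = a / b

Note K_MA is phi-free: the phase ratio only rescales P_SW.  log10 K_MA is
exposed as a BBB-permeation descriptor comparable to logBB.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import NonPhysicalFitError, NonPhysicalWarning, ValidationError
from .retention import LinearFitResult, RetentionSeries, _ols_line

__all__ = ["FoleyResult", "fit_foley", "kma_as_bbb_descriptor"]


@dataclass
class FoleyResult:
    """Fitted micelle-association parameters for one compound.

    ``linearization_fit`` is the OLS of 1/k on C_M; ``log_kma``/``log_psw``
    are log10 transforms, NaN when the underlying constant is not positive.
    """

    compound_id: str
    k_ma: float
    p_sw: float
    log_kma: float
    log_psw: float
    phase_ratio: float
    linearization_fit: LinearFitResult

    def predict_reciprocal_k(self, c_m):
        """The fitted 1/k line, reconstructed from (K_MA, P_SW, phi)."""
        b = 1.0 / (self.p_sw * self.phase_ratio)
        a = self.k_ma * b
        return a * np.asarray(c_m, dtype=float) + b

    def summary(self) -> str:
        f = self.linearization_fit
        return (
            f"{self.compound_id}: K_MA = {self.k_ma:.4g} dm³/mol "
            f"(logK_MA = {self.log_kma:.3f}), P_SW = {self.p_sw:.4g} "
            f"(phi = {self.phase_ratio}), R² = {f.r_squared:.4f}, n = {f.n_points}"
        )


def fit_foley(series: RetentionSeries, phase_ratio: float) -> FoleyResult:
    """Estimate (K_MA, P_SW) from a BMC retention series.

    Requires at least three distinct surfactant levels, all k > 0, and a
    positive column phase ratio (no default is shipped: the value is
    column-specific and must be chosen explicitly).  A non-positive fitted
    intercept has no physical solution and raises; a negative slope yields a
    negative K_MA, reported with an anti-binding warning rather than clipped.
    """
    if series.system != "BMC":
        raise ValidationError(f"Foley analysis requires a BMC series, got {series.system}")
    if not phase_ratio > 0:
        raise ValidationError("phase_ratio must be > 0")
    k = series.k
    if np.any(k <= 0):
        raise ValidationError("all retention factors must be > 0")
    fit = _ols_line(series.abscissa, 1.0 / k)
    a, b = fit.slope, fit.intercept
    if b <= 0:
        raise NonPhysicalFitError(
            f"{series.compound_id}: fitted 1/k intercept {b:.4g} <= 0 has no "
            "physical (P_SW > 0) solution"
        )
    k_ma = a / b
    p_sw = 1.0 / (b * phase_ratio)
    if k_ma < 0:
        warnings.warn(
            f"{series.compound_id}: negative K_MA = {k_ma:.4g} dm³/mol "
            "(reciprocal retention decreases with micelle concentration; "
            "anti-binding behaviour)",
            NonPhysicalWarning,
            stacklevel=2,
        )
    return FoleyResult(
        compound_id=series.compound_id,
        k_ma=k_ma,
        p_sw=p_sw,
        log_kma=math.log10(k_ma) if k_ma > 0 else float("nan"),
        log_psw=math.log10(p_sw) if p_sw > 0 else float("nan"),
        phase_ratio=phase_ratio,
        linearization_fit=fit,
    )


def kma_as_bbb_descriptor(results: list[FoleyResult]) -> pd.DataFrame:
    """Tabulate log10 K_MA per compound as a BBB-permeation descriptor.

    Compounds with non-positive K_MA carry no log and are excluded with a
    warning.  The resulting column is compared side by side with the logBB
    variants; the association constant is used as a correspondence, not
    converted through any calibration.
    """
    rows = []
    for r in results:
        if r.k_ma <= 0:
            warnings.warn(
                f"{r.compound_id}: K_MA = {r.k_ma:.4g} <= 0, excluded from the "
                "logK_MA descriptor table",
                NonPhysicalWarning,
                stacklevel=2,
            )
            continue
        rows.append({"compound_id": r.compound_id, "log_kma": r.log_kma})
    return pd.DataFrame(rows, columns=["compound_id", "log_kma"])
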