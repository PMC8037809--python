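"""Synthetic data generators mirroring the study's measurement designs.

Three generators cover the pipeline's inputs:

* :func:`simulate_retention` — isocratic IAM/CHOL-style series, linear in
  log10 k over the eluent composition with additive Gaussian noise on the
  log scale (the scale on which the model is linear).  Default levels are
  the four acetonitrile fractions used in the study (0.3-0.6 v/v) with
  triplicate measurements.
* :func:`simulate_micellar` — BMC series generated forward through the
  Foley relation, with multiplicative Gaussian noise on k, at the study's
  four total surfactant concentrations (0.075-0.15 mol/dm³).
* :func:`simulate_qsar_table` — a 40-compound descriptor table (30 train /
  10 test) with logBB generated from the published coefficient vector plus
  Gaussian noise at the published residual standard error (0.436).
  Descriptor ranges default to the span of the studied saponins' values.

Every generator is deterministic for a fixed seed, and each spec serialises
to a sidecar JSON so generated tables remain auditable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import RetentionMeasurement
from .qsar import TrainingTable
from .retention import BRIJ35_CMC, micellized_concentration

__all__ = [
    "RetentionSimSpec",
    "FoleySimSpec",
    "QSARSimSpec",
    "simulate_retention",
    "simulate_micellar",
    "simulate_qsar_table",
    "write_sidecar",
    "read_sidecar",
]

ACETONITRILE_LEVELS = (0.3, 0.4, 0.5, 0.6)          # v/v, isocratic IAM/CHOL design
SURFACTANT_LEVELS = (0.075, 0.1, 0.125, 0.15)       # mol/dm³ total Brij35, BMC design
PUBLISHED_BETA = (-0.114, -0.098, 0.278, 0.218)     # (intercept, dlogp, lipophilicity, e)
PUBLISHED_NOISE_SD = 0.436                          # residual SE of the published model


@dataclass
class RetentionSimSpec:
    """Generating parameters for a linear isocratic retention series."""

    logkw_true: float = 1.3
    slope_true: float = -3.0
    levels: tuple[float, ...] = ACETONITRILE_LEVELS
    noise_sd: float = 0.02
    t_0: float = 1.05
    n_replicates: int = 3
    seed: int = 0
    system: str = "IAM"
    compound_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not self.levels:
            raise ValidationError("levels must be nonempty")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.system not in ("IAM", "CHOL"):
            raise ValidationError("isocratic simulation covers IAM/CHOL systems")


@dataclass
class FoleySimSpec:
    """Generating parameters for a Foley-consistent micellar (BMC) series."""

    k_ma_true: float = 120.0
    p_sw_true: float = 40.0
    phase_ratio: float = 0.1
    cmc: float = BRIJ35_CMC
    levels: tuple[float, ...] = SURFACTANT_LEVELS
    noise_cv: float = 0.02
    t_0: float = 1.22
    n_replicates: int = 3
    seed: int = 0
    compound_id: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.p_sw_true > 0:
            raise ValidationError("p_sw_true must be > 0")
        if not self.phase_ratio > 0:
            raise ValidationError("phase_ratio must be > 0")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        for level in self.levels:
            if micellized_concentration(level, self.cmc) <= 0:
                raise ValidationError(
                    f"level {level} yields non-positive micellized concentration"
                )


@dataclass
class QSARSimSpec:
    """Generating parameters for a synthetic QSAR training table.

    Descriptor ranges default to the span observed across the four studied
    saponins (dlogp 1.17-21.0, logPow -3.7-5.2); the E range 1-8 is a
    documented order-of-magnitude choice for triterpenoid-sized solutes.
    """

    n_compounds: int = 40
    n_test: int = 10
    beta_true: tuple[float, float, float, float] = PUBLISHED_BETA
    descriptor_ranges: dict = field(
        default_factory=lambda: {
            "dlogp": (1.17, 21.0),
            "lipophilicity": (-3.7, 5.2),
            "e": (1.0, 8.0),
        }
    )
    noise_sd: float = PUBLISHED_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0 <= self.n_test < self.n_compounds:
            raise ValidationError("need 0 <= n_test < n_compounds")
        widths = [hi - lo for lo, hi in self.descriptor_ranges.values()]
        if all(w == 0 for w in widths):
            raise ValidationError("all descriptor ranges are degenerate (zero width)")


def simulate_retention(spec: RetentionSimSpec) -> list[RetentionMeasurement]:
    """Generate isocratic measurements: log10 k = logkw + slope*level + eps."""
    rng = np.random.default_rng(spec.seed)
    out: list[RetentionMeasurement] = []
    for level in spec.levels:
        log_k_clean = spec.logkw_true + spec.slope_true * level
        for rep in range(1, spec.n_replicates + 1):
            log_k = log_k_clean + rng.normal(0.0, spec.noise_sd)
            k = 10.0 ** log_k
            out.append(
                RetentionMeasurement(
                    compound_id=spec.compound_id,
                    system=spec.system,
                    level=level,
                    t_r=spec.t_0 * (1.0 + k),
                    t_0=spec.t_0,
                    replicate=rep,
                )
            )
    return out


def simulate_micellar(spec: FoleySimSpec) -> list[RetentionMeasurement]:
    """Generate BMC measurements forward through the Foley relation.

    1/k_clean = (K_MA/(P_SW*phi)) * C_M + 1/(P_SW*phi); multiplicative
    Gaussian noise of coefficient of variation ``noise_cv`` is applied to k.
    """
    rng = np.random.default_rng(spec.seed)
    b = 1.0 / (spec.p_sw_true * spec.phase_ratio)
    a = spec.k_ma_true * b
    out: list[RetentionMeasurement] = []
    for level in spec.levels:
        c_m = micellized_concentration(level, spec.cmc)
        k_clean = 1.0 / (a * c_m + b)
        for rep in range(1, spec.n_replicates + 1):
            k = k_clean * (1.0 + rng.normal(0.0, spec.noise_cv))
            if k <= 0:
                raise ValidationError(
                    "noise draw produced a non-positive retention factor; "
                    "reduce noise_cv"
                )
            out.append(
                RetentionMeasurement(
                    compound_id=spec.compound_id,
                    system="BMC",
                    level=level,
                    t_r=spec.t_0 * (1.0 + k),
                    t_0=spec.t_0,
                    replicate=rep,
                )
            )
    return out


def simulate_qsar_table(spec: QSARSimSpec) -> TrainingTable:
    """Generate a descriptor table with logBB from the affine model plus noise."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds
    cols = {}
    for name, (lo, hi) in spec.descriptor_ranges.items():
        cols[name] = rng.uniform(lo, hi, size=n)
    b0, b1, b2, b3 = spec.beta_true
    logbb = (
        b0
        + b1 * cols["dlogp"]
        + b2 * cols["lipophilicity"]
        + b3 * cols["e"]
        + rng.normal(0.0, spec.noise_sd, size=n)
    )
    split = np.array(["train"] * n, dtype=object)
    split[rng.choice(n, size=spec.n_test, replace=False)] = "test"
    df = pd.DataFrame(
        {
            "compound_id": [f"syn-{i + 1:03d}" for i in range(n)],
            "dlogp": cols["dlogp"],
            "lipophilicity": cols["lipophilicity"],
            "e": cols["e"],
            "logbb": logbb,
            "split": split,
        }
    )
    return TrainingTable(df)


def write_sidecar(spec, path) -> None:
    """Write the generating spec next to a generated table (``<path>.spec.json``)."""
    doc = {"spec_type": type(spec).__name__, **dataclasses.asdict(spec)}
    Path(str(path) + ".spec.json").write_text(json.dumps(doc, indent=2))


def read_sidecar(path):
    """Read a sidecar written by :func:`write_sidecar`; returns the spec object."""
    doc = json.loads(Path(str(path) + ".spec.json").read_text())
    kind = doc.pop("spec_type")
    cls = {s.__name__: s for s in (RetentionSimSpec, FoleySimSpec, QSARSimSpec)}[kind]
    for f in dataclasses.fields(cls):
        if f.name in doc and isinstance(doc[f.name], list):
            if f.name != "descriptor_ranges":
                doc[f.name] = tuple(doc[f.name])
    if "descriptor_ranges" in doc:
        doc["descriptor_ranges"] = {k: tuple(v) for k, v in doc["descriptor_ranges"].items()}
    return cls(**doc)
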