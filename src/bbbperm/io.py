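"""Tabular input/output.

Reads the three CSV schemas the pipeline consumes (compound descriptors,
in silico BBB profiles, isocratic retention measurements), serialises fitted
QSAR models to a JSON archive, and exposes the packaged reference tables for
the four studied triterpenoid saponins (arjunic acid, akebia saponin D,
bacoside A, platycodin D).

Dialect: UTF-8, comma-separated, ``.`` decimal, mandatory header row.  The
Unicode minus U+2212 is accepted everywhere an ASCII ``-`` is, because the
reference tables circulate in typeset form.  An in silico logBB reported only
as an upper bound (``<-2``) is stored as the bound value with an explicit
flag rather than as missing: downstream classification uses the bound, while
numeric averaging excludes it.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .exceptions import (
    ArchiveVersionError,
    DataQualityWarning,
    FormatError,
    ValidationError,
)
from .qsar import ADState, ModelDiagnostics, QSARModel

__all__ = [
    "CompoundDescriptors",
    "InSilicoBBBRecord",
    "RetentionMeasurement",
    "ModelArchive",
    "read_descriptor_table",
    "read_insilico_table",
    "read_retention_table",
    "write_model_archive",
    "read_model_archive",
    "load_reference_descriptors",
    "load_reference_insilico",
]

ARCHIVE_SCHEMA_VERSION = "1"

SYSTEMS = ("IAM", "CHOL", "BMC")


@dataclass(frozen=True)
class CompoundDescriptors:
    """Physicochemical descriptor vector for one compound.

    Units: ``mw`` g/mol, ``tpsa`` Å², ``polarizability`` 10⁻²⁴ cm³; the three
    partition coefficients are log10 values (n-octanol/water, heptane/water,
    cyclohexane/water).  ``e_excess_molar_refraction`` is the Abraham E
    descriptor and is optional.
    """

    compound_id: str
    logpow: float
    logphw: float
    logpcw: float
    mw: float
    tpsa: float
    polarizability: float
    e_excess_molar_refraction: float | None = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValidationError("compound_id must be nonempty")
        if not self.mw > 0:
            raise ValidationError(f"{self.compound_id}: mw must be > 0")
        if self.tpsa < 0:
            raise ValidationError(f"{self.compound_id}: tpsa must be >= 0")
        if self.polarizability < 0:
            raise ValidationError(f"{self.compound_id}: polarizability must be >= 0")


@dataclass(frozen=True)
class InSilicoBBBRecord:
    """In silico pharmacokinetic BBB profile for one compound.

    ``logbb_is_upper_bound`` marks a logBB reported only as an upper bound
    (printed ``<-2``); ``logbb`` then carries the bound value.
    """

    compound_id: str
    logbb: float | None
    logps: float
    logps_fubrain: float
    fu_plasma: float
    fb_brain: float
    logbb_is_upper_bound: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.fu_plasma <= 1.0:
            raise ValidationError(
                f"{self.compound_id}: fu_plasma {self.fu_plasma} outside [0, 1]"
            )
        if not 0.0 <= self.fb_brain <= 1.0:
            raise ValidationError(
                f"{self.compound_id}: fb_brain {self.fb_brain} outside [0, 1]"
            )
        if self.logbb_is_upper_bound and self.logbb is None:
            raise ValidationError("bound flag requires a logbb bound value")


@dataclass(frozen=True)
class RetentionMeasurement:
    """One isocratic retention measurement.

    ``level`` is the eluent composition: acetonitrile volume fraction in
    [0, 1] for IAM/CHOL, total surfactant concentration in mol/dm³ for BMC.
    Times are minutes.
    """

    compound_id: str
    system: str
    level: float
    t_r: float
    t_0: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.system not in SYSTEMS:
            raise FormatError(f"unknown chromatographic system {self.system!r}")
        if not self.t_0 > 0:
            raise ValidationError(f"{self.compound_id}: t_0 must be > 0")
        if self.t_r < self.t_0:
            raise ValidationError(
                f"{self.compound_id}: t_r {self.t_r} < t_0 {self.t_0}"
            )
        if self.level < 0:
            raise ValidationError(f"{self.compound_id}: level must be >= 0")
        if self.replicate < 1:
            raise ValidationError("replicate must be a positive integer")


@dataclass
class ModelArchive:
    """A serialised QSAR model plus provenance metadata."""

    model: QSARModel
    provenance: dict = field(default_factory=dict)
    schema_version: str = ARCHIVE_SCHEMA_VERSION


def _normalize_minus(text: str) -> str:
    return text.replace("−", "-")


def _parse_float(cell, row_label: str, column: str) -> float:
    if isinstance(cell, str):
        cell = _normalize_minus(cell).strip()
    try:
        value = float(cell)
    except (TypeError, ValueError):
        raise FormatError(
            f"non-numeric value {cell!r} in row {row_label!r}, column {column!r}"
        ) from None
    if math.isnan(value):
        raise FormatError(f"missing value in row {row_label!r}, column {column!r}")
    return value


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas detail
        raise FormatError(str(exc)) from exc


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_descriptor_table(path) -> list[CompoundDescriptors]:
    """Read a compound descriptor CSV.

    Expected columns ``compound_id,logPow,logPhw,logPcw,MW,TPSA,polarizability``
    with an optional ``E`` column (Abraham excess molar refraction).
    """
    df = _read_csv(path)
    _require_columns(
        df, ["compound_id", "logPow", "logPhw", "logPcw", "MW", "TPSA", "polarizability"], path
    )
    records: list[CompoundDescriptors] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        cid = str(row["compound_id"]).strip()
        if cid in seen:
            raise FormatError(f"duplicate compound_id {cid!r}")
        seen.add(cid)
        e_val = None
        if "E" in df.columns:
            raw = row["E"]
            if isinstance(raw, str) and raw.strip():
                e_val = _parse_float(raw, cid, "E")
        records.append(
            CompoundDescriptors(
                compound_id=cid,
                logpow=_parse_float(row["logPow"], cid, "logPow"),
                logphw=_parse_float(row["logPhw"], cid, "logPhw"),
                logpcw=_parse_float(row["logPcw"], cid, "logPcw"),
                mw=_parse_float(row["MW"], cid, "MW"),
                tpsa=_parse_float(row["TPSA"], cid, "TPSA"),
                polarizability=_parse_float(row["polarizability"], cid, "polarizability"),
                e_excess_molar_refraction=e_val,
            )
        )
    return records


def read_insilico_table(path) -> list[InSilicoBBBRecord]:
    """Read an in silico BBB profile CSV.

    Expected columns ``compound_id,logBB,logPS,logPS_Fubrain,Fu,Fb``.  A logBB
    cell of the form ``<x`` is parsed as an upper bound at ``x``.
    """
    df = _read_csv(path)
    _require_columns(df, ["compound_id", "logBB", "logPS", "logPS_Fubrain", "Fu", "Fb"], path)
    records: list[InSilicoBBBRecord] = []
    for _, row in df.iterrows():
        cid = str(row["compound_id"]).strip()
        raw = row["logBB"]
        logbb: float | None = None
        bound = False
        if isinstance(raw, str):
            raw = _normalize_minus(raw).strip()
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
            logbb = None
        elif isinstance(raw, str) and raw.startswith("<"):
            logbb = _parse_float(raw[1:], cid, "logBB")
            bound = True
        else:
            logbb = _parse_float(raw, cid, "logBB")
        records.append(
            InSilicoBBBRecord(
                compound_id=cid,
                logbb=logbb,
                logps=_parse_float(row["logPS"], cid, "logPS"),
                logps_fubrain=_parse_float(row["logPS_Fubrain"], cid, "logPS_Fubrain"),
                fu_plasma=_parse_float(row["Fu"], cid, "Fu"),
                fb_brain=_parse_float(row["Fb"], cid, "Fb"),
                logbb_is_upper_bound=bound,
            )
        )
    return records


def read_retention_table(path) -> list[RetentionMeasurement]:
    """Read an isocratic retention CSV.

    Expected columns ``compound_id,system,level,t_r,t_0,replicate``; ``system``
    restricted to IAM/CHOL/BMC.  Emits a :class:`DataQualityWarning` for any
    (compound, system, level) measured fewer than three times.
    """
    df = _read_csv(path)
    _require_columns(df, ["compound_id", "system", "level", "t_r", "t_0", "replicate"], path)
    measurements: list[RetentionMeasurement] = []
    seen: set[tuple] = set()
    for _, row in df.iterrows():
        cid = str(row["compound_id"]).strip()
        system = str(row["system"]).strip()
        m = RetentionMeasurement(
            compound_id=cid,
            system=system,
            level=_parse_float(row["level"], cid, "level"),
            t_r=_parse_float(row["t_r"], cid, "t_r"),
            t_0=_parse_float(row["t_0"], cid, "t_0"),
            replicate=int(_parse_float(row["replicate"], cid, "replicate")),
        )
        key = (m.compound_id, m.system, m.level, m.replicate)
        if key in seen:
            raise ValidationError(f"duplicate measurement {key}")
        seen.add(key)
        measurements.append(m)
    counts: dict[tuple, int] = {}
    for m in measurements:
        counts[(m.compound_id, m.system, m.level)] = (
            counts.get((m.compound_id, m.system, m.level), 0) + 1
        )
    low = [k for k, n in counts.items() if n < 3]
    if low:
        warnings.warn(
            f"{len(low)} (compound, system, level) group(s) have fewer than 3 "
            "replicates; retention factors are normally averaged over at least "
            "three independent measurements",
            DataQualityWarning,
            stacklevel=2,
        )
    return measurements


def write_measurements_csv(measurements: Iterable[RetentionMeasurement], path) -> None:
    """Write retention measurements in the schema :func:`read_retention_table` reads."""
    df = pd.DataFrame(
        [
            {
                "compound_id": m.compound_id,
                "system": m.system,
                "level": m.level,
                "t_r": m.t_r,
                "t_0": m.t_0,
                "replicate": m.replicate,
            }
            for m in measurements
        ]
    )
    df.to_csv(path, index=False)


# -- model archive ---------------------------------------------------------


def write_model_archive(model: QSARModel, path, provenance: dict | None = None) -> None:
    """Serialise a fitted QSAR model to a JSON archive (lossless round trip)."""
    doc = {
        "schema_version": ARCHIVE_SCHEMA_VERSION,
        "intercept": model.intercept,
        "coefficients": {
            "dlogp": model.coef_dlogp,
            "lipophilicity": model.coef_lipophilicity,
            "e": model.coef_e,
        },
        "n_train": model.n_train,
        "diagnostics": dataclasses.asdict(model.diagnostics) if model.diagnostics else None,
        "ad": model.ad_state.to_dict() if model.ad_state else None,
        "provenance": provenance or {},
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_model_archive(path) -> ModelArchive:
    """Read a model archive written by :func:`write_model_archive`."""
    doc = json.loads(Path(path).read_text())
    version = str(doc.get("schema_version"))
    if version != ARCHIVE_SCHEMA_VERSION:
        raise ArchiveVersionError(
            f"unsupported model archive schema_version {version!r} "
            f"(supported: {ARCHIVE_SCHEMA_VERSION!r})"
        )
    diag = doc.get("diagnostics")
    ad = doc.get("ad")
    model = QSARModel(
        intercept=doc["intercept"],
        coef_dlogp=doc["coefficients"]["dlogp"],
        coef_lipophilicity=doc["coefficients"]["lipophilicity"],
        coef_e=doc["coefficients"]["e"],
        n_train=doc.get("n_train"),
        diagnostics=ModelDiagnostics(**diag) if diag else None,
        ad_state=ADState.from_dict(ad) if ad else None,
    )
    return ModelArchive(model=model, provenance=doc.get("provenance", {}), schema_version=version)


# -- packaged reference tables ---------------------------------------------


def _data_path(name: str):
    return resources.files("bbbperm.data").joinpath(name)


def load_reference_descriptors() -> list[CompoundDescriptors]:
    """Physicochemical descriptors of the four studied saponins."""
    with resources.as_file(_data_path("saponin_descriptors.csv")) as p:
        return read_descriptor_table(p)


def load_reference_insilico() -> list[InSilicoBBBRecord]:
    """In silico BBB pharmacokinetic profiles of the four studied saponins."""
    with resources.as_file(_data_path("saponin_insilico_bbb.csv")) as p:
        return read_insilico_table(p)
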