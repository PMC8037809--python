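"""Per-compound BBB permeation profiles and cross-method comparison.

A :class:`BBBProfile` collects, for one compound, every available logBB
variant — the in silico estimate, the QSAR prediction from logPow, and the
three biomimetic predictions obtained by substituting logkw-IAM, logkw-CHOL
or logkw-BMC for logPow — together with logK_MA, the in silico
pharmacokinetic descriptors (logPS, logPS_Fubrain, Fu, Fb) and the basic
physicochemical parameters.  On top of that the module computes the summary
statistics, pairwise method discrepancies and a qualitative permeability
call.

Classification uses a representative logBB: the in silico value when present
(a bound-flagged value participates at its bound), otherwise the mean of the
available variants.  Defaults follow the common logBB conventions: a
representative value <= -1 is called non-permeant and >= 0 permeant, with
everything between left uncertain.  A topological polar surface area of
90 Å² or more is appended as supporting evidence against CNS penetration
(the TPSA < 90 Å² rule of thumb) but never overrides the logBB rule, and the
molecular weight and logPow are annotated the same way.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, ValidationError
from .io import CompoundDescriptors, InSilicoBBBRecord

__all__ = [
    "BBBProfile",
    "PermeabilityCall",
    "mean_descriptor",
    "extreme_fraction",
    "absolute_error",
    "compare_methods",
    "classify_permeability",
    "build_profiles",
    "profiles_table",
]

#: logBB variant attribute -> display label
VARIANT_LABELS = {
    "logbb_insilico": "logBB-in-silico",
    "logbb_qsar": "logBB-QSAR",
    "logbb_iam": "logBB-IAM",
    "logbb_chol": "logBB-CHOL",
    "logbb_bmc": "logBB-BMC",
}

NON_PERMEANT_THRESHOLD = -1.0
PERMEANT_THRESHOLD = 0.0
TPSA_CNS_LIMIT = 90.0


@dataclass
class BBBProfile:
    """All permeation evidence gathered for one compound."""

    compound_id: str
    logbb_insilico: float | None = None
    logbb_insilico_is_upper_bound: bool = False
    logbb_qsar: float | None = None
    logbb_iam: float | None = None
    logbb_chol: float | None = None
    logbb_bmc: float | None = None
    log_kma: float | None = None
    logps: float | None = None
    logps_fubrain: float | None = None
    fu_plasma: float | None = None
    fb_brain: float | None = None
    tpsa: float | None = None
    mw: float | None = None
    logpow: float | None = None

    def variants(self, include_bounds: bool = True) -> dict[str, float]:
        """Present logBB variants as label -> value.

        With ``include_bounds=False`` a bound-flagged in silico value is
        omitted (a bound is not a point estimate and is kept out of means).
        """
        out: dict[str, float] = {}
        for attr, label in VARIANT_LABELS.items():
            value = getattr(self, attr)
            if value is None:
                continue
            if (
                attr == "logbb_insilico"
                and self.logbb_insilico_is_upper_bound
                and not include_bounds
            ):
                continue
            out[label] = value
        return out

    def mean_logbb(self) -> float | None:
        """Mean over present point-estimate variants (bounds excluded)."""
        values = list(self.variants(include_bounds=False).values())
        if not values:
            return None
        return float(np.mean(values))


@dataclass
class PermeabilityCall:
    """Qualitative BBB permeability call with its supporting evidence."""

    compound_id: str
    call: str  # permeant | non_permeant | uncertain
    evidence: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.call not in ("permeant", "non_permeant", "uncertain"):
            raise ValidationError(f"unknown call {self.call!r}")
        if not self.evidence:
            raise ValidationError("a permeability call requires at least one evidence item")


def mean_descriptor(values: Sequence[float], round_to: int | None = None) -> float:
    """Arithmetic mean, optionally rounded half-up to ``round_to`` decimals.

    Half-up here means ties round away from zero, matching how reported
    descriptor averages are conventionally printed.
    """
    if len(values) == 0:
        raise InsufficientDataError("cannot average an empty list")
    mean = float(np.mean(np.asarray(values, dtype=float)))
    if round_to is None:
        return mean
    q = Decimal(1).scaleb(-round_to)
    return float(Decimal(repr(mean)).quantize(q, rounding=ROUND_HALF_UP))


def extreme_fraction(
    records: Sequence[InSilicoBBBRecord], fraction: str, direction: str
) -> tuple[str, float]:
    """Compound attaining the max/min of ``fu_plasma`` or ``fb_brain``.

    Ties are broken by first occurrence.
    """
    if fraction not in ("fu_plasma", "fb_brain"):
        raise ValidationError(f"unknown fraction field {fraction!r}")
    if direction not in ("max", "min"):
        raise ValidationError(f"direction must be 'max' or 'min', got {direction!r}")
    if not records:
        raise InsufficientDataError("no records to scan")
    pick = max if direction == "max" else min
    best = pick(records, key=lambda r: getattr(r, fraction))
    return best.compound_id, getattr(best, fraction)


def absolute_error(a: float, b: float) -> float:
    """|a - b|; the discrepancy measure used between logBB variants."""
    return abs(float(a) - float(b))


def compare_methods(profile: BBBProfile) -> pd.DataFrame:
    """All pairwise absolute discrepancies between the profile's estimates.

    The scan covers every present logBB variant plus logK_MA (compared as an
    equivalent descriptor).  Returns a DataFrame with one row per unordered
    pair, sorted by discrepancy; the first and last rows are the most and
    least concordant method pairs.
    """
    entries = dict(profile.variants(include_bounds=True))
    if profile.log_kma is not None:
        entries["logK_MA"] = profile.log_kma
    if len(entries) < 2:
        raise InsufficientDataError(
            f"{profile.compound_id}: need >= 2 estimates to compare, have {len(entries)}"
        )
    rows = [
        {
            "compound_id": profile.compound_id,
            "method_a": la,
            "method_b": lb,
            "value_a": va,
            "value_b": vb,
            "abs_error": absolute_error(va, vb),
        }
        for (la, va), (lb, vb) in itertools.combinations(entries.items(), 2)
    ]
    return (
        pd.DataFrame(rows)
        .sort_values("abs_error", kind="stable")
        .reset_index(drop=True)
    )


def classify_permeability(profile: BBBProfile) -> PermeabilityCall:
    """Qualitative permeability call from the representative logBB.

    The representative value is the in silico logBB when present (bounds
    participate at their bound value), otherwise the mean of the available
    variants.  Physicochemical notes (TPSA, MW, logPow) are evidence only.
    """
    if profile.logbb_insilico is not None:
        rep = profile.logbb_insilico
        source = "in silico logBB"
        if profile.logbb_insilico_is_upper_bound:
            source += " (upper bound)"
    else:
        rep = profile.mean_logbb()
        source = "mean of available logBB variants"
    if rep is None:
        raise InsufficientDataError(
            f"{profile.compound_id}: no logBB estimate available for classification"
        )
    evidence = [f"representative logBB = {rep:.3g} ({source})"]
    if rep <= NON_PERMEANT_THRESHOLD:
        call = "non_permeant"
        evidence.append(f"logBB rule: {rep:.3g} <= {NON_PERMEANT_THRESHOLD}")
    elif rep >= PERMEANT_THRESHOLD:
        call = "permeant"
        evidence.append(f"logBB rule: {rep:.3g} >= {PERMEANT_THRESHOLD}")
    else:
        call = "uncertain"
        evidence.append(
            f"logBB rule: {NON_PERMEANT_THRESHOLD} < {rep:.3g} < {PERMEANT_THRESHOLD}"
        )
    if profile.tpsa is not None and profile.tpsa >= TPSA_CNS_LIMIT:
        evidence.append(
            f"TPSA = {profile.tpsa} Å² >= {TPSA_CNS_LIMIT} Å² (CNS rule of thumb "
            "disfavours penetration)"
        )
    if profile.mw is not None and profile.mw > 500:
        evidence.append(f"MW = {profile.mw} g/mol > 500 (large molecule)")
    if profile.logpow is not None and profile.logpow < 0:
        evidence.append(f"logPow = {profile.logpow} < 0 (hydrophilic)")
    return PermeabilityCall(compound_id=profile.compound_id, call=call, evidence=evidence)


def build_profiles(
    insilico: Iterable[InSilicoBBBRecord] = (),
    descriptors: Iterable[CompoundDescriptors] = (),
    logbb_qsar: dict[str, float] | None = None,
    logbb_iam: dict[str, float] | None = None,
    logbb_chol: dict[str, float] | None = None,
    logbb_bmc: dict[str, float] | None = None,
    log_kma: dict[str, float] | None = None,
) -> list[BBBProfile]:
    """Merge the per-method outputs into one profile per compound."""
    profiles: dict[str, BBBProfile] = {}

    def get(cid: str) -> BBBProfile:
        return profiles.setdefault(cid, BBBProfile(compound_id=cid))

    for rec in insilico:
        p = get(rec.compound_id)
        p.logbb_insilico = rec.logbb
        p.logbb_insilico_is_upper_bound = rec.logbb_is_upper_bound
        p.logps = rec.logps
        p.logps_fubrain = rec.logps_fubrain
        p.fu_plasma = rec.fu_plasma
        p.fb_brain = rec.fb_brain
    for d in descriptors:
        p = get(d.compound_id)
        p.tpsa = d.tpsa
        p.mw = d.mw
        p.logpow = d.logpow
    for attr, mapping in (
        ("logbb_qsar", logbb_qsar),
        ("logbb_iam", logbb_iam),
        ("logbb_chol", logbb_chol),
        ("logbb_bmc", logbb_bmc),
        ("log_kma", log_kma),
    ):
        for cid, value in (mapping or {}).items():
            setattr(get(cid), attr, value)
    return list(profiles.values())


def profiles_table(profiles: Iterable[BBBProfile]) -> pd.DataFrame:
    """One row per compound: all variants, the mean logBB, call and evidence."""
    rows = []
    for p in profiles:
        call = classify_permeability(p)
        row = {
            "compound_id": p.compound_id,
            "logbb_insilico": p.logbb_insilico,
            "logbb_insilico_is_upper_bound": p.logbb_insilico_is_upper_bound,
            "logbb_qsar": p.logbb_qsar,
            "logbb_iam": p.logbb_iam,
            "logbb_chol": p.logbb_chol,
            "logbb_bmc": p.logbb_bmc,
            "log_kma": p.log_kma,
            "mean_logbb": p.mean_logbb(),
            "logps": p.logps,
            "logps_fubrain": p.logps_fubrain,
            "fu_plasma": p.fu_plasma,
            "fb_brain": p.fb_brain,
            "tpsa": p.tpsa,
            "mw": p.mw,
            "logpow": p.logpow,
            "call": call.call,
            "evidence": "; ".join(call.evidence),
        }
        rows.append(row)
    return pd.DataFrame(rows)
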