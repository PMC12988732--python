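"""Deterministic dietary risk metrics for heavy metals in eggs.

The chain of metrics, per population group and sampling area:

* EDI  = C × (FIR/1000) / BW                       (mg/kg body weight/day)
* THQ  = (EF × ED × (FIR/1000) × C) / (RfD × BW × AT)   (dimensionless)
* HI   = Σ_metals THQ
* CR   = EDI × SF          (per carcinogen: Cr, Cd, Pb)
* TCR  = CR_Cr + CR_Cd + CR_Pb

C is the area-level summary concentration (arithmetic mean by default) in
mg/kg; FIR is in g/person/day and is divided by 1000 exactly once, here.
When EF×ED = AT the THQ reduces algebraically to EDI/RfD.

Decision thresholds: HI (or THQ) ≥ 1 flags potential non-carcinogenic
effects; CR/TCR < 1e-6 is negligible, 1e-6–1e-4 acceptable, ≥ 1e-4
potentially unacceptable. Boundary values are classified into the
flagged/higher band (a cell printed as 1.0e-4 is a flag).

All kernels accept scalars or numpy arrays in ``c`` and are exactly
homogeneous of degree 1 in concentration; the Monte Carlo engine reuses
them unchanged, so point-mass simulations reproduce these values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import (
    CARCINOGENS,
    ConcentrationRecord,
    ExposureProfile,
    ToxicityReference,
    ValidationError,
    records_to_frame,
)

__all__ = [
    "DomainError",
    "RiskResult",
    "edi",
    "thq",
    "hazard_index",
    "cancer_risk",
    "total_cancer_risk",
    "classify_hi",
    "classify_cr",
    "assess",
    "results_to_frame",
    "HI_THRESHOLD",
    "CR_NEGLIGIBLE",
    "CR_UNACCEPTABLE",
]

HI_THRESHOLD = 1.0
CR_NEGLIGIBLE = 1e-6
CR_UNACCEPTABLE = 1e-4

_SUMMARIES = ("mean", "median", "max")


class DomainError(ValueError):
    """An argument is outside the domain of a risk equation."""


def edi(c, profile: ExposureProfile):
    """Estimated daily intake, mg/kg bw/day, for concentration ``c`` (mg/kg)."""
    return c * (profile.fir / 1000.0) / profile.bw


def thq(c, profile: ExposureProfile, rfd: float):
    """Target hazard quotient: chronic exposure over the oral reference dose."""
    if rfd is None or rfd <= 0:
        raise DomainError(f"rfd must be > 0, got {rfd!r}")
    return (profile.ef * profile.ed * (profile.fir / 1000.0) * c) / (
        rfd * profile.bw * profile.at
    )


def hazard_index(thqs: Mapping[str, float]) -> float:
    """Cumulative non-carcinogenic hazard: the sum of per-metal THQs.

    An empty map is a domain error — the hazard index of nothing is
    undefined, not zero.
    """
    if not thqs:
        raise DomainError("hazard index of an empty THQ map is undefined")
    bad = {m: v for m, v in thqs.items() if np.any(np.asarray(v) < 0)}
    if bad:
        raise DomainError(f"negative THQ values: {bad}")
    return sum(thqs.values())


def cancer_risk(e, sf: float | None, metal: str | None = None):
    """Incremental lifetime cancer risk: EDI × slope factor."""
    if sf is None:
        raise DomainError(f"no slope factor available for metal {metal or '<unknown>'}")
    if sf < 0:
        raise DomainError(f"sf must be >= 0, got {sf}")
    return e * sf


def total_cancer_risk(crs: Mapping[str, float]) -> float:
    """Sum of the carcinogen risks; requires exactly the keys Cr, Cd, Pb."""
    if set(crs) != set(CARCINOGENS):
        missing = set(CARCINOGENS) - set(crs)
        extra = set(crs) - set(CARCINOGENS)
        raise DomainError(
            f"total cancer risk needs exactly {CARCINOGENS}; "
            f"missing={sorted(missing)} extra={sorted(extra)}"
        )
    return crs["Cr"] + crs["Cd"] + crs["Pb"]


def classify_hi(hi: float) -> str:
    """``no_concern`` below 1, ``potential_adverse`` at or above 1."""
    if hi < 0:
        raise DomainError(f"hi must be >= 0, got {hi}")
    return "no_concern" if hi < HI_THRESHOLD else "potential_adverse"


def classify_cr(cr: float) -> str:
    """Carcinogenic-risk band: <1e-6 negligible, 1e-6–1e-4 acceptable,
    >=1e-4 potentially unacceptable."""
    if cr < 0:
        raise DomainError(f"cr must be >= 0, got {cr}")
    if cr < CR_NEGLIGIBLE:
        return "negligible"
    if cr < CR_UNACCEPTABLE:
        return "acceptable"
    return "potentially_unacceptable"


@dataclass(frozen=True)
class RiskResult:
    """Full deterministic risk profile for one (area, population group)."""

    area: str
    group: str
    edi_by_metal: dict[str, float]
    thq_by_metal: dict[str, float]
    hi: float
    cr_by_metal: dict[str, float]
    tcr: float
    hi_class: str
    cr_class_by_metal: dict[str, str]
    tcr_class: str


def assess(
    records: Sequence[ConcentrationRecord],
    profiles: Sequence[ExposureProfile],
    toxicity: Sequence[ToxicityReference],
    summary: str = "mean",
) -> list[RiskResult]:
    """Compute one :class:`RiskResult` per (area, population group).

    The area-level concentration entering the equations is the per-metal
    ``summary`` statistic ("mean" by default; "median" and "max" are
    alternatives) over that area's samples. A metal absent from an area is
    omitted from that area's HI with a warning; every metal used must have
    an RfD.
    """
    if summary not in _SUMMARIES:
        raise ValueError(f"summary must be one of {_SUMMARIES}, got {summary!r}")
    if not records:
        raise ValidationError([("dataset", "no concentration records")])
    tox = {t.metal: t for t in toxicity}
    df = records_to_frame(list(records))
    # numpy reductions (not pandas aggregates) so the Monte Carlo engine's
    # point-mass degenerate case reproduces these values bit-exactly
    reduce = {"mean": np.mean, "median": np.median, "max": np.max}[summary]
    cell: dict[tuple[str, str], float] = {
        key: float(reduce(g["concentration"].to_numpy()))
        for key, g in df.groupby(["area", "metal"], sort=True)
    }
    all_metals = sorted(df["metal"].unique())
    missing_rfd = [m for m in all_metals if m not in tox]
    if missing_rfd:
        raise ValidationError(
            [(m, "no oral reference dose configured") for m in missing_rfd]
        )

    results: list[RiskResult] = []
    for area in sorted(df["area"].unique()):
        conc = {m: v for (a, m), v in cell.items() if a == area}
        absent = sorted(set(all_metals) - set(conc))
        if absent:
            warnings.warn(
                f"area {area!r} has no records for {', '.join(absent)}; "
                "HI computed over the available metals",
                stacklevel=2,
            )
        for profile in profiles:
            edis = {m: float(edi(c, profile)) for m, c in conc.items()}
            thqs = {m: float(thq(c, profile, tox[m].rfd)) for m, c in conc.items()}
            hi = float(hazard_index(thqs))
            crs = {
                m: float(cancer_risk(edis[m], tox[m].sf, m))
                for m in CARCINOGENS
                if m in edis
            }
            if set(crs) == set(CARCINOGENS):
                tcr = float(total_cancer_risk(crs))
            else:  # pragma: no cover - only when a carcinogen is absent
                tcr = float(sum(crs.values()))
                warnings.warn(
                    f"area {area!r} lacks {sorted(set(CARCINOGENS) - set(crs))}; "
                    "TCR computed over available carcinogens",
                    stacklevel=2,
                )
            results.append(
                RiskResult(
                    area=area,
                    group=profile.group,
                    edi_by_metal=edis,
                    thq_by_metal=thqs,
                    hi=hi,
                    cr_by_metal=crs,
                    tcr=tcr,
                    hi_class=classify_hi(hi),
                    cr_class_by_metal={m: classify_cr(v) for m, v in crs.items()},
                    tcr_class=classify_cr(tcr),
                )
            )
    return results


def results_to_frame(results: Sequence[RiskResult]) -> pd.DataFrame:
    """Long-format export: one row per (area, group, metric[, metal])."""
    rows = []
    for r in results:
        for m, v in r.edi_by_metal.items():
            rows.append((r.area, r.group, "EDI", m, v, ""))
        for m, v in r.thq_by_metal.items():
            rows.append((r.area, r.group, "THQ", m, v, ""))
        rows.append((r.area, r.group, "HI", "", r.hi, r.hi_class))
        for m, v in r.cr_by_metal.items():
            rows.append((r.area, r.group, "CR", m, v, r.cr_class_by_metal[m]))
        rows.append((r.area, r.group, "TCR", "", r.tcr, r.tcr_class))
    return pd.DataFrame(
        rows, columns=["area", "group", "metric", "metal", "value", "classification"]
    )
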