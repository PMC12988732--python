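"""Domain types, unit conventions, and table readers/writers.

All concentrations are carried in mg/kg on the measurement basis declared in
the input file (``basis`` metadata, dry by default; the pipeline never
converts between dry and fresh mass). Dietary intake rates (FIR) are stored
in g/person/day and converted to kg/day exactly once, inside the risk
equations.

Concentration tables are long-format CSV: one measurement (one metal on one
egg sample) per row. Exposure profiles, toxicity references and regulatory
limits live in a single hierarchical YAML file; a USEPA-sourced example
ships with the package (:func:`example_reference_path`).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "METALS",
    "CARCINOGENS",
    "PRODUCTION_SYSTEMS",
    "MINING_CLASSES",
    "GROUPS",
    "AUTHORITIES",
    "ConcentrationRecord",
    "ExposureProfile",
    "ToxicityReference",
    "RegulatoryLimit",
    "SchemaError",
    "ValidationError",
    "read_concentration_table",
    "write_concentration_table",
    "records_to_frame",
    "frame_to_records",
    "substitute_lod",
    "read_reference_tables",
    "dataset_to_json",
    "example_reference_path",
]

#: The ten trace elements routinely assayed in whole-egg digests.
METALS: tuple[str, ...] = ("Cr", "Mn", "Co", "Ni", "Cu", "Zn", "As", "Se", "Cd", "Pb")

#: Probable human carcinogens carrying an oral cancer slope factor.
CARCINOGENS: tuple[str, ...] = ("Cr", "Cd", "Pb")

PRODUCTION_SYSTEMS: tuple[str, ...] = ("free_range", "commercial")
MINING_CLASSES: tuple[str, ...] = ("mining", "non_mining")
GROUPS: tuple[str, ...] = ("male", "female", "child")
AUTHORITIES: tuple[str, ...] = ("GB2762", "FAO_WHO", "EC", "user")

#: Below-detection-limit substitution conventions.
LOD_POLICIES: tuple[str, ...] = ("half", "sqrt2", "full", "zero")

_REQUIRED_COLUMNS = (
    "sample_id",
    "area",
    "production_system",
    "mining_class",
    "metal",
    "concentration",
)


class SchemaError(ValueError):
    """A table is structurally unusable (missing column, wrong unit, ...)."""


class ValidationError(ValueError):
    """One or more rows/values violate an invariant.

    ``errors`` holds ``(location, message)`` pairs; ``location`` is a
    1-based data-row number for tabular input or a dotted key path for
    config input.
    """

    def __init__(self, errors: Sequence[tuple[object, str]]):
        self.errors = list(errors)
        lines = "; ".join(f"[{loc}] {msg}" for loc, msg in self.errors)
        super().__init__(f"{len(self.errors)} validation error(s): {lines}")


@dataclass(frozen=True)
class ConcentrationRecord:
    """One metal measurement on one egg sample.

    ``below_lod`` records carry the detection limit itself as
    ``concentration`` (never 0); a substitution convention is applied
    explicitly via :func:`substitute_lod`.
    """

    sample_id: str
    area: str
    production_system: str
    mining_class: str
    metal: str
    concentration: float
    below_lod: bool = False
    basis: str = "dry"

    def __post_init__(self) -> None:
        errs = _validate_record_fields(self)
        if errs:
            raise ValidationError([(self.sample_id, m) for m in errs])


def _validate_record_fields(r: "ConcentrationRecord | object") -> list[str]:
    errs: list[str] = []
    if r.production_system not in PRODUCTION_SYSTEMS:
        errs.append(
            f"unknown production_system {r.production_system!r}; "
            f"allowed: {', '.join(PRODUCTION_SYSTEMS)}"
        )
    if r.mining_class not in MINING_CLASSES:
        errs.append(
            f"unknown mining_class {r.mining_class!r}; allowed: {', '.join(MINING_CLASSES)}"
        )
    if r.metal not in METALS:
        errs.append(f"unknown metal symbol {r.metal!r}; allowed: {', '.join(METALS)}")
    c = r.concentration
    if not isinstance(c, (int, float)) or not math.isfinite(float(c)):
        errs.append(f"concentration must be a finite number, got {c!r}")
    elif float(c) < 0:
        errs.append(f"concentration must be >= 0, got {c}")
    elif getattr(r, "below_lod", False) and float(c) == 0:
        errs.append("below_lod records must carry the LOD value, not 0")
    if getattr(r, "basis", "dry") not in ("dry", "fresh"):
        errs.append(f"basis must be 'dry' or 'fresh', got {r.basis!r}")
    return errs


@dataclass(frozen=True)
class ExposureProfile:
    """Per-population-group ingestion exposure parameters.

    BW kg; FIR g/person/day; EF days/year; ED years; AT days.
    """

    group: str
    bw: float
    fir: float
    ef: float
    ed: float
    at: float

    def __post_init__(self) -> None:
        errs = []
        for name in ("bw", "fir", "ef", "ed", "at"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(float(v)) and v > 0):
                errs.append(f"{name} must be strictly positive, got {v!r}")
        if isinstance(self.ef, (int, float)) and self.ef > 366:
            errs.append(f"ef must be <= 366 days/year, got {self.ef}")
        if errs:
            raise ValidationError([(self.group, m) for m in errs])


@dataclass(frozen=True)
class ToxicityReference:
    """Oral reference dose (mg/kg/day) and, for carcinogens, the cancer
    slope factor ((mg/kg/day)^-1) of one metal."""

    metal: str
    rfd: float
    sf: float | None = None

    def __post_init__(self) -> None:
        errs = []
        if self.metal not in METALS:
            errs.append(f"unknown metal symbol {self.metal!r}")
        if not (isinstance(self.rfd, (int, float)) and self.rfd > 0):
            errs.append(f"rfd must be > 0, got {self.rfd!r}")
        if self.sf is not None:
            if self.metal not in CARCINOGENS:
                errs.append(
                    f"slope factor given for {self.metal}, but only "
                    f"{', '.join(CARCINOGENS)} are assessed as carcinogens"
                )
            elif not (isinstance(self.sf, (int, float)) and self.sf >= 0):
                errs.append(f"sf must be >= 0, got {self.sf!r}")
        if errs:
            raise ValidationError([(self.metal, m) for m in errs])


@dataclass(frozen=True)
class RegulatoryLimit:
    """Maximum permitted level (mg/kg) for one metal under one authority."""

    metal: str
    authority: str
    limit: float

    def __post_init__(self) -> None:
        errs = []
        if self.metal not in METALS:
            errs.append(f"unknown metal symbol {self.metal!r}")
        if self.authority not in AUTHORITIES:
            errs.append(f"unknown authority {self.authority!r}; allowed: {', '.join(AUTHORITIES)}")
        if not (isinstance(self.limit, (int, float)) and self.limit > 0):
            errs.append(f"limit must be > 0, got {self.limit!r}")
        if errs:
            raise ValidationError([(f"{self.metal}/{self.authority}", m) for m in errs])


# ---------------------------------------------------------------------------
# concentration tables


def read_concentration_table(path: str | Path) -> list[ConcentrationRecord]:
    """Read a long-format concentration CSV into validated records.

    Required columns: sample_id, area, production_system, mining_class,
    metal, concentration. Optional: below_lod (bool-ish), unit (must read
    mg/kg), basis (dry|fresh, default dry).

    Raises :class:`SchemaError` for structural problems and
    :class:`ValidationError` listing every offending row (1-based data-row
    numbers) otherwise. No silent drops.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if "unit" in df.columns:
        bad_units = sorted(set(df["unit"]) - {"mg/kg", ""})
        if bad_units:
            raise SchemaError(
                f"unit column must read mg/kg, found: {', '.join(map(repr, bad_units))}"
            )

    records: list[ConcentrationRecord] = []
    errors: list[tuple[object, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowdict = row._asdict()
        try:
            conc = float(rowdict["concentration"])
        except ValueError:
            errors.append((i, f"concentration {rowdict['concentration']!r} is not numeric"))
            continue
        below = _parse_bool(rowdict.get("below_lod", ""), default=False)
        if below is None:
            errors.append((i, f"below_lod {rowdict['below_lod']!r} is not a boolean"))
            continue
        candidate = dataclasses.make_dataclass("_Row", rowdict.keys())(**rowdict)
        candidate.concentration = conc
        candidate.below_lod = below
        candidate.basis = rowdict.get("basis", "") or "dry"
        row_errs = _validate_record_fields(candidate)
        if row_errs:
            errors.extend((i, m) for m in row_errs)
            continue
        records.append(
            ConcentrationRecord(
                sample_id=str(rowdict["sample_id"]),
                area=str(rowdict["area"]),
                production_system=str(rowdict["production_system"]),
                mining_class=str(rowdict["mining_class"]),
                metal=str(rowdict["metal"]),
                concentration=conc,
                below_lod=below,
                basis=candidate.basis,
            )
        )
    errors.extend(_check_area_consistency(records))
    if errors:
        raise ValidationError(errors)
    return records


def _parse_bool(v: object, default: bool) -> bool | None:
    s = str(v).strip().lower()
    if s == "":
        return default
    if s in ("1", "true", "t", "yes", "y"):
        return True
    if s in ("0", "false", "f", "no", "n"):
        return False
    return None


def _check_area_consistency(records: Iterable[ConcentrationRecord]) -> list[tuple[object, str]]:
    """An area must carry a single (production_system, mining_class) label."""
    errors = []
    seen: dict[str, tuple[str, str]] = {}
    for r in records:
        label = (r.production_system, r.mining_class)
        prev = seen.setdefault(r.area, label)
        if prev != label:
            errors.append(
                (r.sample_id, f"area {r.area!r} labeled both {prev} and {label}")
            )
    return errors


def records_to_frame(records: Sequence[ConcentrationRecord]) -> pd.DataFrame:
    """Records as a long-format DataFrame (the package's working container)."""
    cols = [f.name for f in dataclasses.fields(ConcentrationRecord)]
    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=cols)


def frame_to_records(df: pd.DataFrame) -> list[ConcentrationRecord]:
    cols = [f.name for f in dataclasses.fields(ConcentrationRecord)]
    present = [c for c in cols if c in df.columns]
    return [ConcentrationRecord(**row) for row in df[present].to_dict("records")]


def write_concentration_table(records: Sequence[ConcentrationRecord], path: str | Path) -> None:
    """Write records as CSV; floats use 12 significant digits so a
    write/read round trip is value-exact for such decimals."""
    df = records_to_frame(records)
    df.to_csv(path, index=False, float_format="%.12g")


def substitute_lod(
    records: Sequence[ConcentrationRecord], policy: str = "half"
) -> list[ConcentrationRecord]:
    """Replace below-LOD concentrations per ``policy``.

    half → LOD/2 (default convention), sqrt2 → LOD/√2, full → LOD, zero → 0.
    Records keep their ``below_lod`` tag so provenance is never lost.
    """
    if policy not in LOD_POLICIES:
        raise ValueError(f"unknown LOD policy {policy!r}; allowed: {', '.join(LOD_POLICIES)}")
    factor = {"half": 0.5, "sqrt2": 1 / math.sqrt(2), "full": 1.0}.get(policy)
    out = []
    for r in records:
        if not r.below_lod:
            out.append(r)
        elif policy == "zero":
            # bypass the carry-the-LOD invariant deliberately: substituted value
            out.append(dataclasses.replace(r, concentration=0.0, below_lod=False))
        else:
            out.append(dataclasses.replace(r, concentration=r.concentration * factor))
    return out


# ---------------------------------------------------------------------------
# reference tables (exposure / toxicity / limits)


def read_reference_tables(
    path: str | Path,
) -> tuple[list[ExposureProfile], list[ToxicityReference], list[RegulatoryLimit]]:
    """Read the hierarchical YAML reference file.

    Layout::

        exposure_profiles:
          male: {bw: 65.0, fir: 40.0, ef: 365, ed: 70, at: 25550}
        toxicity:
          Cr: {rfd: 0.003, sf: 0.5}
          Mn: {rfd: 0.14}
        limits:
          GB2762: {Pb: 0.2, Cd: 0.05}

    A missing ``sf`` for a non-carcinogen is not an error; all type
    invariants are enforced and every violation is reported with its key
    path.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"reference file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise SchemaError("reference file must be a mapping")
    for section in ("exposure_profiles", "toxicity", "limits"):
        if section not in raw:
            raise SchemaError(f"missing section {section!r}")

    errors: list[tuple[object, str]] = []
    profiles: list[ExposureProfile] = []
    for group, params in raw["exposure_profiles"].items():
        try:
            profiles.append(ExposureProfile(group=group, **{k.lower(): v for k, v in params.items()}))
        except ValidationError as e:
            errors.extend((f"exposure_profiles.{group}", msg) for _, msg in e.errors)
        except TypeError as e:
            errors.append((f"exposure_profiles.{group}", str(e)))

    toxicity: list[ToxicityReference] = []
    for metal, params in raw["toxicity"].items():
        try:
            toxicity.append(
                ToxicityReference(metal=metal, rfd=params.get("rfd"), sf=params.get("sf"))
            )
        except ValidationError as e:
            errors.extend((f"toxicity.{metal}", msg) for _, msg in e.errors)

    limits: list[RegulatoryLimit] = []
    seen: set[tuple[str, str]] = set()
    for authority, table in (raw["limits"] or {}).items():
        for metal, limit in (table or {}).items():
            key = (metal, authority)
            if key in seen:
                errors.append((f"limits.{authority}.{metal}", "duplicate (metal, authority) limit"))
                continue
            seen.add(key)
            try:
                limits.append(RegulatoryLimit(metal=metal, authority=authority, limit=limit))
            except ValidationError as e:
                errors.extend((f"limits.{authority}.{metal}", msg) for _, msg in e.errors)

    if errors:
        raise ValidationError(errors)
    return profiles, toxicity, limits


def dataset_to_json(
    records: Sequence[ConcentrationRecord], path: str | Path | None = None
) -> str:
    """Export a validated dataset as JSON (list of objects); returns the
    string and optionally writes it."""
    payload = json.dumps([dataclasses.asdict(r) for r in records], indent=2)
    if path is not None:
        Path(path).write_text(payload + "\n")
    return payload


def example_reference_path() -> Path:
    """Path of the packaged example exposure/toxicity/limit YAML file."""
    return Path(resources.files("eggrisk").joinpath("data/example_reference.yaml"))
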