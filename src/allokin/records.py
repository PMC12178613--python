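"""Reading, validating, unit-standardising and anomaly-filtering kinetic records.

A :class:`KineticRecord` is one literature observation of chemotroph (or
phototroph) uptake kinetics: a dry-weight-specific maximum uptake rate
``vmax_dw`` (mol S g^-1 DW h^-1) and/or a half-saturation constant ``km``
(mol S L^-1), tagged with the organism and its energy-source reaction group.

Canonical internal units are fixed (mol, g DW, L, h); all conversion happens
here at the I/O boundary and never mid-pipeline.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .allometry import AllometryConstants, weight_from_volume

__all__ = [
    "KineticRecord",
    "RecordSet",
    "AnomalyFilterConfig",
    "UnitConversion",
    "UnitError",
    "RecordValidationError",
    "read_records",
    "standardize_units",
    "express_in_unit",
    "filter_anomalies",
]

# Consistency constant between a normal MAD and sd: 1/Phi^-1(3/4).
_MAD_TO_SD = 1.4826
_IQR_TO_SD = 1.349


class UnitError(ValueError):
    """Unrecognised or unconvertible unit string."""


class RecordValidationError(ValueError):
    """A record (or CSV row) violating the schema invariants."""


@dataclass(frozen=True)
class KineticRecord:
    organism_name: str
    functional_group: str
    trophic_mode: str = "chemotroph"
    vmax_dw: Optional[float] = None  # mol S g^-1 DW h^-1
    km: Optional[float] = None  # mol S L^-1
    source_id: str = ""
    raw_value: Optional[float] = None
    raw_unit: Optional[str] = None

    def __post_init__(self) -> None:
        if self.vmax_dw is None and self.km is None:
            raise RecordValidationError(
                f"record for {self.organism_name!r} has neither vmax_dw nor km"
            )
        for name in ("vmax_dw", "km"):
            v = getattr(self, name)
            if v is not None and not (v > 0 and math.isfinite(v)):
                raise RecordValidationError(
                    f"{name} must be positive and finite, got {v!r} "
                    f"({self.organism_name!r})"
                )
        if not self.functional_group:
            raise RecordValidationError(
                f"record for {self.organism_name!r} has empty functional_group"
            )


@dataclass
class RecordSet:
    """A validated collection of kinetic records with provenance."""

    records: list[KineticRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[KineticRecord]:
        return iter(self.records)

    def vmax_dw_values(self) -> np.ndarray:
        return np.array([r.vmax_dw for r in self.records if r.vmax_dw is not None])

    def km_values(self) -> np.ndarray:
        return np.array([r.km for r in self.records if r.km is not None])

    def paired_values(self) -> tuple[np.ndarray, np.ndarray]:
        """(vmax_dw, km) arrays over records reporting both variables."""
        pairs = [
            (r.vmax_dw, r.km)
            for r in self.records
            if r.vmax_dw is not None and r.km is not None
        ]
        if not pairs:
            return np.empty(0), np.empty(0)
        v, k = zip(*pairs)
        return np.array(v), np.array(k)

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.functional_group, None)
        return list(seen)

    def counts_by_group(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.functional_group] = out.get(r.functional_group, 0) + 1
        return out

    def subset(self, group: Optional[str] = None, trophic_mode: Optional[str] = None):
        recs = [
            r
            for r in self.records
            if (group is None or r.functional_group == group)
            and (trophic_mode is None or r.trophic_mode == trophic_mode)
        ]
        return RecordSet(recs, provenance=self.provenance)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "organism": [r.organism_name for r in self.records],
                "functional_group": [r.functional_group for r in self.records],
                "trophic_mode": [r.trophic_mode for r in self.records],
                "vmax_dw": [r.vmax_dw for r in self.records],
                "km": [r.km for r in self.records],
                "source": [r.source_id for r in self.records],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "RecordSet":
        records = []
        for _, row in df.iterrows():
            records.append(
                KineticRecord(
                    organism_name=str(row.get("organism", "")),
                    functional_group=str(row.get("functional_group", "")),
                    trophic_mode=str(row.get("trophic_mode", "chemotroph")),
                    vmax_dw=_opt_float(row.get("vmax_dw")),
                    km=_opt_float(row.get("km")),
                    source_id=str(row.get("source", "")),
                )
            )
        return cls(records, provenance=provenance)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _opt_float(x) -> Optional[float]:
    if x is None:
        return None
    try:
        v = float(x)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(v) else v


# --------------------------------------------------------------------------
# Unit standardisation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitConversion:
    """Knobs the unit dialects need.

    protein_to_dw       : g protein per g dry weight (default 0.55), used for
                          per-protein rate units.
    dry_weight_per_cell : g DW per cell, used for per-cell rate units.
    cell_volume         : um^3; fallback route to dry weight via the
                          weight-volume allometry when dry weight is absent.
    constants           : allometry constants for the volume->weight map.
    """

    protein_to_dw: float = 0.55
    dry_weight_per_cell: Optional[float] = None
    cell_volume: Optional[float] = None
    constants: AllometryConstants = field(default_factory=AllometryConstants)

    def weight_per_cell(self) -> float:
        if self.dry_weight_per_cell is not None:
            return self.dry_weight_per_cell
        if self.cell_volume is not None:
            return weight_from_volume(self.cell_volume, self.constants)
        raise UnitError(
            "per-cell unit conversion needs dry_weight_per_cell or cell_volume"
        )


_AMOUNT_MOL = {"mol": 1.0, "mmol": 1e-3, "umol": 1e-6, "nmol": 1e-9, "pmol": 1e-12}
# factor turning "per <time unit>" into "per hour"
_PER_TIME = {
    "h": 1.0, "hr": 1.0, "hour": 1.0,
    "min": 60.0, "minute": 60.0,
    "s": 3600.0, "sec": 3600.0, "second": 3600.0,
    "d": 1.0 / 24.0, "day": 1.0 / 24.0,
}
# factor turning "per <mass unit>" into "per gram"
_PER_MASS = {"g": 1.0, "mg": 1e3, "ug": 1e6}
_MOLARITY = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "nm": 1e-9}


def _normalize_unit(unit: str) -> list[str]:
    u = unit.strip().lower()
    u = u.replace("μ", "u").replace("µ", "u")
    u = u.replace("⁻¹", "-1").replace("−", "-")
    u = re.sub(r"[()\[\]]", " ", u)
    u = u.replace("/", " / ")
    # "g-1" -> "g -1" so inversion markers are their own tokens
    u = re.sub(r"([a-z]+)\s*\^?\s*-\s*1", r"\1 -1", u)
    tokens = [t for t in u.split() if t not in {"s", "substrate"}]
    return tokens


def _parse_rate_unit(unit: str):
    """Parse a V_max unit into (mol factor, basis, per-gram factor, per-hour factor).

    basis is one of "dw", "protein", "cell".
    """
    tokens = _normalize_unit(unit)
    amount = None
    basis = None
    mass_factor = 1.0
    time_factor = None
    i = 0
    per_next = False
    while i < len(tokens):
        t = tokens[i]
        if t == "/":
            per_next = True
            i += 1
            continue
        inverted = per_next or (i + 1 < len(tokens) and tokens[i + 1] == "-1")
        if t in _PER_MASS and not inverted:
            # "(mg protein)-1" tokenises with the marker on the qualifier
            j = i + 1
            if j < len(tokens) and tokens[j] in {"dw", "dry", "protein"}:
                inverted = j + 1 < len(tokens) and tokens[j + 1] == "-1"
        if t in _AMOUNT_MOL and not inverted and amount is None:
            amount = _AMOUNT_MOL[t]
        elif t in _PER_MASS and inverted:
            mass_factor = _PER_MASS[t]
            # look ahead for the basis qualifier (dw / protein)
            j = i + 1
            while j < len(tokens) and tokens[j] == "-1":
                j += 1
            if j < len(tokens) and tokens[j] in {"dw", "dry", "protein"}:
                basis = "protein" if tokens[j] == "protein" else "dw"
            else:
                basis = "dw"
        elif t in {"dw", "dry", "weight", "protein"}:
            if t == "protein":
                basis = "protein"
        elif t in {"cell", "cells"} and inverted:
            basis = "cell"
        elif t in _PER_TIME and inverted:
            time_factor = _PER_TIME[t]
        elif t == "-1":
            pass
        else:
            raise UnitError(
                f"unrecognised token {t!r} in rate unit {unit!r}; supported: "
                "mol/mmol/umol/nmol S per g|mg (DW|protein) or per cell, "
                "per h|min|s|day"
            )
        per_next = False
        i += 1
    if amount is None or basis is None or time_factor is None:
        raise UnitError(
            f"could not parse rate unit {unit!r} (need amount, mass-or-cell "
            "basis and time)"
        )
    return amount, basis, mass_factor, time_factor


def _rate_factor(unit: str, conversion: UnitConversion) -> float:
    amount, basis, mass_factor, time_factor = _parse_rate_unit(unit)
    factor = amount * mass_factor * time_factor
    if basis == "protein":
        factor *= conversion.protein_to_dw
    elif basis == "cell":
        factor /= conversion.weight_per_cell()
    return factor


def _conc_factor(unit: str) -> float:
    tokens = _normalize_unit(unit)
    if len(tokens) == 1 and tokens[0] in _MOLARITY:
        return _MOLARITY[tokens[0]]
    amount = None
    per_litre = False
    per_next = False
    for i, t in enumerate(tokens):
        if t == "/":
            per_next = True
            continue
        inverted = per_next or (i + 1 < len(tokens) and tokens[i + 1] == "-1")
        if t in _AMOUNT_MOL and not inverted:
            amount = _AMOUNT_MOL[t]
        elif t in {"l", "litre", "liter"} and inverted:
            per_litre = True
        elif t == "-1":
            pass
        else:
            raise UnitError(f"unrecognised token {t!r} in concentration unit {unit!r}")
        per_next = False
    if amount is None or not per_litre:
        raise UnitError(f"could not parse concentration unit {unit!r}")
    return amount


def standardize_units(
    raw_value: float,
    raw_unit: str,
    conversion: UnitConversion = UnitConversion(),
    variable: str = "vmax",
) -> float:
    """Convert a reported value to canonical units.

    ``variable="vmax"`` targets mol S g^-1 DW h^-1 (per-protein values are
    scaled by the protein:DW mass ratio; per-cell values divided by the dry
    weight per cell); ``variable="km"`` targets mol S L^-1.
    """
    if variable == "vmax":
        return raw_value * _rate_factor(raw_unit, conversion)
    if variable == "km":
        return raw_value * _conc_factor(raw_unit)
    raise ValueError(f"variable must be 'vmax' or 'km', got {variable!r}")


def express_in_unit(
    canonical_value: float,
    unit: str,
    conversion: UnitConversion = UnitConversion(),
    variable: str = "vmax",
) -> float:
    """Inverse of :func:`standardize_units`: express a canonical value in `unit`."""
    if variable == "vmax":
        return canonical_value / _rate_factor(unit, conversion)
    if variable == "km":
        return canonical_value / _conc_factor(unit)
    raise ValueError(f"variable must be 'vmax' or 'km', got {variable!r}")


# --------------------------------------------------------------------------
# CSV ingest
# --------------------------------------------------------------------------

#: default column-name mapping; override entries via ``read_records(column_map=...)``
DEFAULT_COLUMNS = {
    "organism": "organism",
    "group": "functional_group",
    "trophic_mode": "trophic_mode",
    "vmax_dw": "vmax_dw",
    "km": "km",
    "value": "value",
    "unit": "unit",
    "variable": "variable",
    "source": "source",
}


def read_records(
    path,
    conversion: UnitConversion = UnitConversion(),
    column_map: Optional[dict] = None,
) -> RecordSet:
    """Read a records CSV into a validated :class:`RecordSet`.

    Two schemas are accepted and detected from the header:

    * wide — columns ``vmax_dw`` and/or ``km`` already in canonical units;
      a row may report one or both variables;
    * long — columns ``value``, ``unit``, ``variable`` (vmax|km); each row is
      standardised to canonical units and becomes a single-variable record.

    Rows failing validation raise :class:`RecordValidationError` naming the
    row, so bad data is reported rather than silently dropped.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise RecordValidationError(f"cannot read records CSV {path}: {exc}") from exc
    if df.empty:
        raise RecordValidationError(f"records CSV {path} has no data rows")

    have = set(df.columns)
    wide = cols["vmax_dw"] in have or cols["km"] in have
    long = {cols["value"], cols["unit"], cols["variable"]} <= have
    if not (wide or long):
        raise RecordValidationError(
            f"records CSV {path} lacks required columns: need "
            f"{cols['vmax_dw']!r}/{cols['km']!r} (wide) or "
            f"{cols['value']!r},{cols['unit']!r},{cols['variable']!r} (long)"
        )
    for required in ("organism", "group"):
        if cols[required] not in have:
            raise RecordValidationError(
                f"records CSV {path} is missing required column {cols[required]!r}"
            )

    records = []
    for idx, row in df.iterrows():
        common = dict(
            organism_name=str(row[cols["organism"]]),
            functional_group=str(row[cols["group"]]),
            trophic_mode=str(row.get(cols["trophic_mode"], "chemotroph")),
            source_id=str(row.get(cols["source"], "")),
        )
        try:
            if wide:
                rec = KineticRecord(
                    vmax_dw=_opt_float(row.get(cols["vmax_dw"])),
                    km=_opt_float(row.get(cols["km"])),
                    **common,
                )
            else:
                value = float(row[cols["value"]])
                variable = str(row[cols["variable"]]).strip().lower()
                canonical = standardize_units(
                    value, str(row[cols["unit"]]), conversion, variable=variable
                )
                rec = KineticRecord(
                    vmax_dw=canonical if variable == "vmax" else None,
                    km=canonical if variable == "km" else None,
                    raw_value=value,
                    raw_unit=str(row[cols["unit"]]),
                    **common,
                )
        except (RecordValidationError, UnitError, ValueError) as exc:
            raise RecordValidationError(f"row {idx} of {path}: {exc}") from exc
        records.append(rec)
    return RecordSet(records, provenance=str(path))


# --------------------------------------------------------------------------
# Anomaly filtering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnomalyFilterConfig:
    """Robust-z outlier filter on log10 values.

    A record is flagged when |log10(x) - median| / (1.4826 * MAD) exceeds
    `threshold` for the configured variable(s).  `apply_on` is one of
    "log10_vmax_dw", "log10_km" or "both" (flag if either variable flags).
    With method "none" nothing is removed.
    """

    method: str = "robust_z"
    threshold: float = 3.5
    apply_on: str = "both"

    def __post_init__(self) -> None:
        if self.method not in {"robust_z", "none"}:
            raise ValueError(f"unknown anomaly filter method {self.method!r}")
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")
        if self.apply_on not in {"log10_vmax_dw", "log10_km", "both"}:
            raise ValueError(f"unknown apply_on {self.apply_on!r}")


def robust_z_scores(values: np.ndarray) -> np.ndarray:
    """|x - median| / (1.4826 * MAD); falls back to IQR/1.349 when MAD = 0,
    then to the ordinary standard deviation when the IQR is also degenerate
    (e.g. a heavy majority of identical values).

    All-identical input returns all-zero scores (nothing can be flagged).
    """
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    scale = _MAD_TO_SD * mad
    if scale == 0:
        q1, q3 = np.percentile(values, [25, 75])
        scale = (q3 - q1) / _IQR_TO_SD
    if scale == 0:
        scale = np.std(values, ddof=1) if values.size > 1 else 0.0
    if scale == 0:
        return np.zeros_like(values)
    return np.abs(values - med) / scale


def filter_anomalies(
    rs: RecordSet, cfg: AnomalyFilterConfig = AnomalyFilterConfig()
) -> tuple[RecordSet, RecordSet]:
    """Split `rs` into (kept, removed); kept + removed always partition rs.

    Scores are computed per variable over the records that report it; a
    record missing a variable cannot be flagged on that variable.
    """
    if len(rs) == 0:
        raise ValueError("cannot filter an empty RecordSet")
    if cfg.method == "none":
        return RecordSet(list(rs.records), rs.provenance), RecordSet([], rs.provenance)

    flag = np.zeros(len(rs), dtype=bool)
    variables = []
    if cfg.apply_on in {"log10_vmax_dw", "both"}:
        variables.append("vmax_dw")
    if cfg.apply_on in {"log10_km", "both"}:
        variables.append("km")
    for attr in variables:
        idx = [i for i, r in enumerate(rs.records) if getattr(r, attr) is not None]
        if len(idx) < 2:
            continue
        logs = np.log10([getattr(rs.records[i], attr) for i in idx])
        scores = robust_z_scores(logs)
        for i, z in zip(idx, scores):
            if z > cfg.threshold:
                flag[i] = True
    kept = [r for r, f in zip(rs.records, flag) if not f]
    removed = [r for r, f in zip(rs.records, flag) if f]
    return RecordSet(kept, rs.provenance), RecordSet(removed, rs.provenance)
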