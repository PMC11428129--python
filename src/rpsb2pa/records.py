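"""Structure x method spectroscopy records and tabular I/O.

One :class:`SpectroscopyRecord` holds the seven scalar properties of a
single RPSB5 structure computed with a single electronic-structure method:
the S0->S1 excitation energy, the two-photon transition strength and cross
section, and the transition/permanent dipole magnitudes. A packaged data
table provides all 35 rows (7 structures x 5 methods) of the reference
dataset; user data in the same schema loads from CSV or JSON.

The schema is fixed (header required)::

    method,structure,dE_eV,delta2pa_au,sigma2pa_GM,mu01_D,dmu_D,mu00_D,mu11_D

Units are fixed by the column names (eV, au, GM, D) and never auto-detected.
"""

from __future__ import annotations

import csv
import importlib.resources
import io
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errors import InputError, InvariantViolation

logger = logging.getLogger(__name__)

#: canonical structure tokens -> (is_planar, methyl positions)
KNOWN_STRUCTURES: dict[str, tuple[bool, frozenset[int]]] = {
    "9,13-dimethyl": (True, frozenset({9, 13})),
    "9-methyl": (True, frozenset({9})),
    "13-methyl": (True, frozenset({13})),
    "9,10-dimethyl (Cs)": (True, frozenset({9, 10})),
    "9,10-dimethyl (twist)": (False, frozenset({9, 10})),
    "9,10,13-trimethyl (Cs)": (True, frozenset({9, 10, 13})),
    "9,10,13-trimethyl (twist)": (False, frozenset({9, 10, 13})),
}

KNOWN_METHODS = ("RI-CC2", "M11", "MN15", "CAM-B3LYP", "BHandHLYP")

#: native precision per property (decimals) as printed in the reference table
PROPERTY_DECIMALS = {
    "dE": 3,
    "delta2pa": 0,
    "sigma2pa": 1,
    "mu01": 3,
    "dmu": 3,
    "mu00": 3,
    "mu11": 3,
}

PROPERTY_UNITS = {
    "dE": "eV",
    "delta2pa": "au",
    "sigma2pa": "GM",
    "mu01": "D",
    "dmu": "D",
    "mu00": "D",
    "mu11": "D",
}

CSV_COLUMNS = (
    "method",
    "structure",
    "dE_eV",
    "delta2pa_au",
    "sigma2pa_GM",
    "mu01_D",
    "dmu_D",
    "mu00_D",
    "mu11_D",
)

_COLUMN_TO_FIELD = {
    "dE_eV": "dE",
    "delta2pa_au": "delta2pa",
    "sigma2pa_GM": "sigma2pa",
    "mu01_D": "mu01",
    "dmu_D": "dmu",
    "mu00_D": "mu00",
    "mu11_D": "mu11",
}


def _normalize(token: str) -> str:
    return " ".join(token.split())


@dataclass(frozen=True)
class StructureLabel:
    """A chromophore structure identity (methylation pattern + planarity)."""

    name: str
    is_planar: bool
    methyl_positions: frozenset[int]

    @classmethod
    def parse(cls, name: str, strict: bool = False) -> "StructureLabel":
        """Resolve a structure token case-insensitively and whitespace-trimmed.

        Unknown names are admitted with empty methyl positions (and a logged
        warning) unless ``strict`` is set.
        """
        cleaned = _normalize(name)
        for canonical, (planar, positions) in KNOWN_STRUCTURES.items():
            if cleaned.lower() == canonical.lower():
                return cls(canonical, planar, positions)
        if strict:
            raise InputError(f"unknown structure name {name!r}")
        logger.warning("unknown structure name %r admitted without metadata", name)
        return cls(cleaned, "(twist)" not in cleaned.lower(), frozenset())


@dataclass(frozen=True)
class MethodLabel:
    """An electronic-structure method identity (e.g. the CC2 reference)."""

    name: str
    hf_exchange_note: str = ""

    @classmethod
    def parse(cls, name: str) -> "MethodLabel":
        cleaned = _normalize(name)
        for canonical in KNOWN_METHODS:
            if cleaned.lower() == canonical.lower():
                return cls(canonical)
        return cls(cleaned)


@dataclass(frozen=True)
class SpectroscopyRecord:
    """All seven scalar spectroscopic properties for one structure x method.

    dE [eV], delta2pa [au], sigma2pa [GM], mu01/dmu/mu00/mu11 [D].
    """

    structure: StructureLabel
    method: MethodLabel
    dE: float
    delta2pa: float
    sigma2pa: float
    mu01: float
    dmu: float
    mu00: float
    mu11: float

    @property
    def key(self) -> tuple[str, str]:
        return (self.structure.name, self.method.name)


def validate_record(r: SpectroscopyRecord) -> list[str]:
    """Check a record against the domain invariants.

    Returns a list of human-readable violation descriptors (empty when the
    record is valid). Violations are data, not exceptions.
    """
    out: list[str] = []
    if not r.dE > 0:
        out.append(f"positivity: dE must be > 0, got {r.dE}")
    for name in ("delta2pa", "sigma2pa", "mu01", "dmu", "mu00", "mu11"):
        v = getattr(r, name)
        if v < 0:
            out.append(f"positivity: {name} must be >= 0, got {v}")
    # |mu00 - mu11| <= |Δμ| <= mu00 + mu11 follows from Δμ being a vector
    # difference of the two permanent dipoles; small slack for printed rounding
    tol = 5e-3
    lo, hi = abs(r.mu00 - r.mu11), r.mu00 + r.mu11
    if not (lo - tol <= r.dmu <= hi + tol):
        out.append(
            "triangle inequality: require |mu00-mu11| <= dmu <= mu00+mu11, "
            f"got |{r.mu00}-{r.mu11}|={lo:.3f} <= {r.dmu} <= {hi:.3f}"
        )
    return out


@dataclass
class RecordSet:
    """A keyed collection of records; (structure, method) pairs are unique."""

    records: list[SpectroscopyRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for r in self.records:
            if r.key in seen:
                raise InvariantViolation(f"duplicate (structure, method) pair {r.key}")
            seen.add(r.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SpectroscopyRecord]:
        return iter(self.records)

    def get(self, structure: str, method: str) -> SpectroscopyRecord:
        skey = _normalize(structure).lower()
        mkey = _normalize(method).lower()
        for r in self.records:
            if r.structure.name.lower() == skey and r.method.name.lower() == mkey:
                return r
        raise KeyError(f"no record for ({structure!r}, {method!r})")

    @property
    def methods(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.method.name not in out:
                out.append(r.method.name)
        return out

    @property
    def structures(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.structure.name not in out:
                out.append(r.structure.name)
        return out

    def subset(self, method: str) -> "RecordSet":
        mkey = _normalize(method).lower()
        return RecordSet(
            [r for r in self.records if r.method.name.lower() == mkey],
            provenance=f"{self.provenance} [subset {method}]",
        )


def _record_from_mapping(row: dict, rownum: int, strict_structures: bool) -> SpectroscopyRecord:
    missing = [c for c in CSV_COLUMNS if c not in row or row[c] in (None, "")]
    if missing:
        raise InputError(f"row {rownum}: missing field(s) {', '.join(missing)}")
    values = {}
    for col, fname in _COLUMN_TO_FIELD.items():
        try:
            v = float(row[col])
        except (TypeError, ValueError):
            raise InputError(
                f"row {rownum}: field {col!r} is not numeric: {row[col]!r}"
            ) from None
        if math.isnan(v):
            raise InputError(f"row {rownum}: field {col!r} is NaN")
        values[fname] = v
    return SpectroscopyRecord(
        structure=StructureLabel.parse(str(row["structure"]), strict=strict_structures),
        method=MethodLabel.parse(str(row["method"])),
        **values,
    )


def _records_from_rows(
    rows: Iterable[dict], provenance: str, strict_structures: bool = False
) -> RecordSet:
    records: list[SpectroscopyRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(rows, start=1):
        rec = _record_from_mapping(row, i, strict_structures)
        if rec.key in seen:
            raise InputError(f"row {i}: duplicate (structure, method) pair {rec.key}")
        seen.add(rec.key)
        records.append(rec)
    return RecordSet(records, provenance=provenance)


def load_records(path: str | Path, format: str | None = None) -> RecordSet:
    """Load a RecordSet from a CSV or JSON file in the fixed schema.

    ``format`` is "csv" or "json"; inferred from the suffix when omitted.
    Malformed rows raise :class:`InputError` naming the row and field;
    duplicate (structure, method) pairs are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or set(CSV_COLUMNS) - set(reader.fieldnames):
                raise InputError(
                    f"{path}: CSV header must contain columns {','.join(CSV_COLUMNS)}"
                )
            return _records_from_rows(reader, provenance=str(path))
    if fmt == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise InputError(f"{path}: invalid JSON: {exc}") from None
        if not isinstance(data, list):
            raise InputError(f"{path}: JSON input must be an array of objects")
        return _records_from_rows(data, provenance=str(path))
    raise InputError(f"unsupported format {fmt!r} (expected csv or json)")


def save_records(rs: RecordSet, path: str | Path, format: str | None = None) -> None:
    """Write a RecordSet to CSV or JSON in the fixed schema."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    rows = [
        {
            "method": r.method.name,
            "structure": r.structure.name,
            "dE_eV": r.dE,
            "delta2pa_au": r.delta2pa,
            "sigma2pa_GM": r.sigma2pa,
            "mu01_D": r.mu01,
            "dmu_D": r.dmu,
            "mu00_D": r.mu00,
            "mu11_D": r.mu11,
        }
        for r in rs
    ]
    if fmt == "csv":
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=list(CSV_COLUMNS))
        writer.writeheader()
        writer.writerows(rows)
        path.write_text(buf.getvalue())
        return
    if fmt == "json":
        path.write_text(json.dumps(rows, indent=1) + "\n")
        return
    raise InputError(f"unsupported format {fmt!r} (expected csv or json)")


def builtin_table1() -> RecordSet:
    """The packaged reference dataset: 35 records, 7 structures x 5 methods.

    Method-comparison aggregate rows (MAEs) are never stored; the benchmark
    module recomputes them.
    """
    text = (
        importlib.resources.files("rpsb2pa").joinpath("data/table1.csv").read_text()
    )
    reader = csv.DictReader(io.StringIO(text))
    rs = _records_from_rows(reader, provenance="packaged reference table", strict_structures=True)
    assert len(rs) == 35, "packaged table must hold 7 structures x 5 methods"
    return rs
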