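"""Method-comparison layer: MAEs, factor ranges, trend orderings, correlations.

Compares each method block of a RecordSet against a reference method
(RI-CC2 by default): unweighted mean absolute errors per property,
reference/method ratio ranges (the "underestimation factor"), percent
changes of every structure against the native chromophore, descending
property orderings, and the Pearson correlation between the quadratic-
response two-photon strengths and the collinear two-state estimate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import pearsonr

from .constants import convert_units
from .errors import InputError
from .fewstate import two_state_delta
from .records import (
    PROPERTY_DECIMALS,
    PROPERTY_UNITS,
    MethodLabel,
    RecordSet,
    StructureLabel,
)

logger = logging.getLogger(__name__)

PROPERTIES = tuple(PROPERTY_DECIMALS)

#: the native chromophore used as the baseline for relative changes
NATIVE_STRUCTURE = "9,13-dimethyl"


def _method_name(method) -> str:
    return method.name if isinstance(method, MethodLabel) else str(method)


def _structure_name(structure) -> str:
    return structure.name if isinstance(structure, StructureLabel) else str(structure)


def _block(rs: RecordSet, method) -> dict[str, object]:
    name = _method_name(method)
    block = {r.structure.name: r for r in rs if r.method.name == name}
    if not block:
        raise InputError(f"method {name!r} not present in record set")
    return block


def _paired(rs: RecordSet, method, reference):
    b1, b2 = _block(rs, method), _block(rs, reference)
    if set(b1) != set(b2):
        only1 = sorted(set(b1) - set(b2))
        only2 = sorted(set(b2) - set(b1))
        raise InputError(
            f"structure sets differ between {_method_name(method)!r} and "
            f"{_method_name(reference)!r}: only in former {only1}, only in latter {only2}"
        )
    structures = sorted(b1)
    return structures, b1, b2


def mae(rs: RecordSet, method, reference, property: str) -> float:
    """Unweighted mean absolute deviation of ``method`` from ``reference``.

    Returned unrounded; the property's native printed precision lives in
    :data:`rpsb2pa.records.PROPERTY_DECIMALS` for reporting.
    """
    if property not in PROPERTIES:
        raise InputError(f"unknown property {property!r}")
    structures, b1, b2 = _paired(rs, method, reference)
    diffs = [abs(getattr(b1[s], property) - getattr(b2[s], property)) for s in structures]
    return float(np.mean(diffs))


def ratio_range(rs: RecordSet, method, reference, property: str) -> tuple[float, float]:
    """(min, max) of reference/method value ratios over the shared structures.

    The raw extrema are returned; the reporting layer rounds to 1 decimal.
    """
    structures, b1, b2 = _paired(rs, method, reference)
    ratios = []
    for s in structures:
        denom = getattr(b1[s], property)
        if denom == 0:
            raise InputError(f"zero {property} for {s!r} under {_method_name(method)!r}")
        ratios.append(getattr(b2[s], property) / denom)
    return float(min(ratios)), float(max(ratios))


def relative_change(rs: RecordSet, method, structure, baseline, property: str) -> float:
    """Percent change of ``structure`` vs ``baseline`` under one method."""
    block = _block(rs, method)
    sname, bname = _structure_name(structure), _structure_name(baseline)
    for n in (sname, bname):
        if n not in block:
            raise InputError(f"structure {n!r} missing under {_method_name(method)!r}")
    v, v0 = getattr(block[sname], property), getattr(block[bname], property)
    if v0 == 0:
        raise InputError(f"zero baseline {property} for {bname!r}")
    return 100.0 * (v - v0) / v0


def ordering(rs: RecordSet, method, property: str) -> list[str]:
    """Structures ranked by ``property`` in descending order (ties: alphabetical)."""
    block = _block(rs, method)
    values = {s: getattr(r, property) for s, r in block.items()}
    if len(set(values.values())) < len(values):
        logger.info("ties in %s ordering broken alphabetically", property)
    return sorted(values, key=lambda s: (-values[s], s))


def two_state_estimate(record) -> float:
    """Collinear two-state δ [au] built from a record's printed magnitudes.

    Uses |μ01|² |Δμ|² / (ΔE/2)² with the package's averaging normalization;
    collinearity is assumed because only magnitudes are recorded (quasi-linear
    charge-transfer chromophore).
    """
    mu01_au = convert_units(record.mu01, "D", "au")
    dmu_au = convert_units(record.dmu, "D", "au")
    omega_f = convert_units(record.dE, "eV", "hartree")
    return two_state_delta(
        np.array([0.0, 0.0, mu01_au]), np.array([0.0, 0.0, dmu_au]), omega_f
    )


def two_state_correlation(rs: RecordSet, method) -> float:
    """Pearson r between recorded δ and the collinear two-state estimate."""
    block = _block(rs, method)
    if len(block) < 3:
        raise InputError(
            f"need at least 3 structures for a correlation, got {len(block)}"
        )
    structures = sorted(block)
    delta = [block[s].delta2pa for s in structures]
    est = [two_state_estimate(block[s]) for s in structures]
    return float(pearsonr(delta, est).statistic)


@dataclass
class BenchmarkReport:
    """Aggregated method-comparison results against one reference method."""

    reference: str
    per_method: dict[str, dict] = field(default_factory=dict)
    relative_changes: dict[str, dict[str, float]] = field(default_factory=dict)
    correlations: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "reference": self.reference,
            "per_method": self.per_method,
            "relative_changes": self.relative_changes,
            "correlations": self.correlations,
            "warnings": self.warnings,
        }
        text = json.dumps(obj, indent=1, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def mae_row(self, method: str) -> dict[str, float]:
        """MAE per property, rounded at each property's native precision."""
        raw = self.per_method[method]["mae"]
        return {
            p: round(raw[p], PROPERTY_DECIMALS[p]) if PROPERTY_DECIMALS[p] else
               float(int(round(raw[p])))
            for p in PROPERTIES
        }

    def to_text(self, rs: RecordSet | None = None) -> str:
        """Aligned-column text report mirroring the reference table's layout."""
        lines: list[str] = []
        header = f"{'structure':28s}" + "".join(
            f"{p + ' [' + PROPERTY_UNITS[p] + ']':>16s}" for p in PROPERTIES
        )
        if rs is not None:
            for method in rs.methods:
                lines.append(method)
                lines.append(header)
                for r in (rec for rec in rs if rec.method.name == method):
                    lines.append(
                        f"{r.structure.name:28s}" + "".join(
                            f"{getattr(r, p):>16.{PROPERTY_DECIMALS[p]}f}"
                            for p in PROPERTIES
                        )
                    )
                if method != self.reference and method in self.per_method:
                    row = self.mae_row(method)
                    lines.append(
                        f"{'MAE':28s}" + "".join(
                            f"{row[p]:>16.{PROPERTY_DECIMALS[p]}f}" for p in PROPERTIES
                        )
                    )
                lines.append("")
        lines.append(f"reference method: {self.reference}")
        for method, data in sorted(self.per_method.items()):
            rmin, rmax = data["ratio_rounded"]["delta2pa"]
            smin, smax = data["ratio_rounded"]["sigma2pa"]
            lines.append(
                f"{method}: reference/method delta2pa factor {rmin:.1f}-{rmax:.1f}, "
                f"sigma2pa factor {smin:.1f}-{smax:.1f}"
            )
        for method, r in sorted(self.correlations.items()):
            lines.append(f"{method}: two-state correlation r = {r:.4f}")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines) + "\n"


def build_report(rs: RecordSet, reference="RI-CC2") -> BenchmarkReport:
    """Full deterministic benchmark of every method against ``reference``."""
    ref = _method_name(reference)
    if ref not in rs.methods:
        raise InputError(f"reference method {ref!r} not present in record set")
    report = BenchmarkReport(reference=ref)
    ref_structures = set(_block(rs, ref))
    for method in rs.methods:
        if method == ref:
            continue
        if set(_block(rs, method)) != ref_structures:
            report.warnings.append(
                f"method {method!r} skipped: structure set differs from reference"
            )
            continue
        maes = {p: mae(rs, method, ref, p) for p in PROPERTIES}
        ratios = {}
        ratios_rounded = {}
        for p in ("delta2pa", "sigma2pa"):
            lo, hi = ratio_range(rs, method, ref, p)
            ratios[p] = [lo, hi]
            ratios_rounded[p] = [round(lo, 1), round(hi, 1)]
        report.per_method[method] = {
            "mae": maes,
            "ratio": ratios,
            "ratio_rounded": ratios_rounded,
            "ordering": {p: ordering(rs, method, p) for p in PROPERTIES},
        }
    if len(rs.methods) == 1:
        report.warnings.append("single-method record set: no comparisons computed")
    baseline_block = _block(rs, ref)
    if NATIVE_STRUCTURE in baseline_block:
        for method in rs.methods:
            block = _block(rs, method)
            if NATIVE_STRUCTURE not in block:
                continue
            changes = {}
            for s in sorted(block):
                if s == NATIVE_STRUCTURE:
                    continue
                changes[s] = {
                    p: relative_change(rs, method, s, NATIVE_STRUCTURE, p)
                    for p in ("delta2pa", "sigma2pa")
                }
            report.relative_changes[method] = changes
    for method in rs.methods:
        if len(_block(rs, method)) >= 3:
            report.correlations[method] = two_state_correlation(rs, method)
    return report
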