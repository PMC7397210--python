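"""Compound registry, regulatory reference values, classification schemes and sample-table I/O.

The registry covers the 16 US-EPA priority polycyclic aromatic hydrocarbons
(PAHs), from naphthalene (2 rings) to benzo[ghi]perylene (6 rings).  For each
compound it stores the reference constants used by the screening risk indexes:

* ``mpc_pl`` — maximum permissible concentration under Polish soil
  regulations (µg kg⁻¹); only 10 of the 16 compounds are regulated, so the
  field is ``None`` for the other six.  Used for hazard quotients (HQ/HI).
* ``mpc_nl`` — maximum permissible concentration under Dutch regulations
  (µg kg⁻¹), available for all 16; used as the effect level for toxic
  pressure (TP/TPm).
* ``pnec`` — predicted no-effect concentration (µg kg⁻¹), the level below
  which unacceptable effects on soil organisms are unlikely; used for toxic
  units (TU/TUm).
* ``tef`` — toxic equivalency factor relative to benzo[a]pyrene
  (dimensionless, order-of-magnitude potency estimate); used for the
  benzo[a]pyrene-equivalent concentration (TEQ).

Classification schemes map index values to ordinal risk/contamination
classes.  All schemes use left-closed intervals: a value equal to a
breakpoint falls in the *upper* class.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "CompoundRecord",
    "SampleRecord",
    "ClassificationScheme",
    "COMPOUND_ORDER",
    "builtin_registry",
    "lookup",
    "builtin_schemes",
    "get_scheme",
    "read_sample_table",
    "write_sample_table",
    "reference_report",
    "SampleTableError",
]


@dataclass(frozen=True)
class CompoundRecord:
    """One priority PAH with its reference constants."""

    abbreviation: str
    full_name: str
    n_rings: int
    mpc_pl: float | None  # Polish MPC, µg/kg; None for unregulated compounds
    mpc_nl: float  # Dutch MPC, µg/kg
    pnec: float  # µg/kg
    tef: float  # dimensionless, relative to BaPyr
    is_carcinogenic: bool
    is_4em: bool  # one of the four air-emission-monitored PAHs


# Canonical US-EPA order; readers accept any column order but writers use this.
_REGISTRY: tuple[CompoundRecord, ...] = (
    CompoundRecord("Napht", "naphthalene", 2, 100.0, 690.0, 1000.0, 0.001, False, False),
    CompoundRecord("Acyn", "acenaphthylene", 3, None, 170.0, 290.0, 0.001, False, False),
    CompoundRecord("Acen", "acenaphthene", 3, None, 680.0, 38.0, 0.001, False, False),
    CompoundRecord("Flu", "fluorene", 3, None, 1600.0, 1000.0, 0.001, False, False),
    CompoundRecord("Phen", "phenanthrene", 3, None, 3600.0, 1800.0, 0.001, False, False),
    CompoundRecord("Anth", "anthracene", 3, 200.0, 340.0, 130.0, 0.01, False, False),
    CompoundRecord("Fln", "fluoranthene", 4, None, 4800.0, 1500.0, 0.001, False, False),
    CompoundRecord("Pyr", "pyrene", 4, None, 1800.0, 1000.0, 0.001, False, False),
    CompoundRecord("BaA", "benzo[a]anthracene", 4, 100.0, 190.0, 79.0, 0.1, True, False),
    CompoundRecord("Ch", "chrysene", 4, 200.0, 1600.0, 550.0, 0.01, True, False),
    CompoundRecord("BbF", "benzo[b]fluoranthene", 5, 100.0, 790.0, 280.0, 0.1, True, True),
    CompoundRecord("BkF", "benzo[k]fluoranthene", 5, 100.0, 790.0, 270.0, 0.1, True, True),
    CompoundRecord("BaPyr", "benzo[a]pyrene", 5, 100.0, 160.0, 53.0, 1.0, True, True),
    CompoundRecord("IndPyr", "indeno[1,2,3-cd]pyrene", 6, 200.0, 380.0, 130.0, 0.1, True, True),
    CompoundRecord("DahA", "dibenz[a,h]anthracene", 5, 100.0, 180.0, 54.0, 1.0, True, False),
    CompoundRecord("BPer", "benzo[ghi]perylene", 6, 200.0, 490.0, 170.0, 0.01, False, False),
)

COMPOUND_ORDER: tuple[str, ...] = tuple(c.abbreviation for c in _REGISTRY)

_BY_ABBREV: dict[str, CompoundRecord] = {c.abbreviation: c for c in _REGISTRY}

#: Abbreviations of the 10 compounds regulated under Polish soil guidelines.
REGULATED_PL: tuple[str, ...] = tuple(
    c.abbreviation for c in _REGISTRY if c.mpc_pl is not None
)


def builtin_registry() -> tuple[CompoundRecord, ...]:
    """Return the 16 priority-PAH records in canonical US-EPA order."""
    return _REGISTRY


def lookup(abbreviation: str) -> CompoundRecord:
    """Return the registry record for ``abbreviation``.

    Raises
    ------
    KeyError
        If the abbreviation is not one of the 16 priority PAHs.
    """
    try:
        return _BY_ABBREV[abbreviation]
    except KeyError:
        raise KeyError(
            f"unknown PAH abbreviation {abbreviation!r}; "
            f"expected one of {', '.join(COMPOUND_ORDER)}"
        ) from None


# ---------------------------------------------------------------------------
# Classification schemes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassificationScheme:
    """Ordered breakpoints partitioning [0, inf) into labelled classes.

    Intervals are closed on the left and open on the right, so a value equal
    to a breakpoint is assigned to the upper class (e.g. HI = 10 counts as
    "moderate risk").
    """

    scheme_id: str
    breakpoints: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.breakpoints) + 1:
            raise ValueError(
                f"scheme {self.scheme_id!r}: need exactly "
                f"{len(self.breakpoints) + 1} labels, got {len(self.labels)}"
            )
        if any(nxt <= prev for prev, nxt in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError(
                f"scheme {self.scheme_id!r}: breakpoints must be strictly increasing"
            )

    def class_index(self, value: float) -> int:
        """Zero-based class index for ``value`` (left-closed intervals)."""
        if not math.isfinite(value) or value < 0:
            raise ValueError(
                f"scheme {self.scheme_id!r}: value must be finite and >= 0, got {value}"
            )
        return bisect_right(self.breakpoints, value)

    def classify(self, value: float) -> str:
        """Label for ``value``."""
        return self.labels[self.class_index(value)]


def _schemes() -> dict[str, ClassificationScheme]:
    return {
        # Σ16PAH contamination status of agricultural soils, µg/kg.
        "contamination": ClassificationScheme(
            "contamination",
            (200.0, 600.0, 1000.0, 5000.0, 10000.0),
            (
                "background (class 0)",
                "non-contaminated (class 1)",
                "moderately contaminated (class 2)",
                "contaminated (class 3)",
                "heavily contaminated (class 4)",
                "very heavily contaminated (class 5)",
            ),
        ),
        # Hazard index of the regulated mixture; >10 flags possible risk.
        "hi": ClassificationScheme(
            "hi",
            (1.0, 10.0, 100.0),
            ("negligible risk", "low risk", "moderate risk", "high risk"),
        ),
        # Toxic units of the 16-PAH mixture (Persoone hazard rating).
        "tum": ClassificationScheme(
            "tum",
            (1.0, 10.0, 100.0),
            ("no toxicity", "low toxicity", "high toxicity", "very high toxicity"),
        ),
        # Toxic pressure, single compound or mixture (Dagnino rating).
        "tp": ClassificationScheme(
            "tp",
            (0.25, 0.50, 0.75),
            ("no risk", "low risk", "moderate risk", "high risk"),
        ),
        # BaPyr-equivalent concentration against a ladder of national soil
        # guideline values for human-health protection, µg/kg.
        "teq": ClassificationScheme(
            "teq",
            (15.0, 100.0, 200.0, 600.0, 1000.0, 2000.0, 4000.0, 10000.0),
            (
                "<15",
                "15-100",
                "100-200",
                "200-600",
                "600-1000",
                "1000-2000",
                "2000-4000",
                "4000-10000",
                ">10000",
            ),
        ),
    }


_SCHEMES = _schemes()


def builtin_schemes() -> dict[str, ClassificationScheme]:
    """Return the built-in classification schemes keyed by scheme id."""
    return dict(_SCHEMES)


def get_scheme(scheme_id: str) -> ClassificationScheme:
    try:
        return _SCHEMES[scheme_id]
    except KeyError:
        raise KeyError(
            f"unknown scheme {scheme_id!r}; expected one of {', '.join(_SCHEMES)}"
        ) from None


# ---------------------------------------------------------------------------
# Sample records and table I/O
# ---------------------------------------------------------------------------

_OPTIONAL_COLUMNS = ("sand", "silt", "clay", "ph_kcl", "c_org", "tn", "x", "y")


@dataclass
class SampleRecord:
    """One soil sample: per-compound PAH concentrations plus optional properties.

    Concentrations are in µg kg⁻¹ dry soil; texture fractions in percent;
    ``c_org`` (total organic carbon) and ``tn`` (total nitrogen) in g kg⁻¹.
    """

    sample_id: str
    concentrations: dict[str, float]
    sand: float | None = None
    silt: float | None = None
    clay: float | None = None
    ph_kcl: float | None = None
    c_org: float | None = None
    tn: float | None = None
    x: float | None = None
    y: float | None = None

    def __post_init__(self) -> None:
        missing = [a for a in COMPOUND_ORDER if a not in self.concentrations]
        if missing:
            raise ValueError(
                f"sample {self.sample_id!r}: missing concentrations for {', '.join(missing)}"
            )
        for abbr, c in self.concentrations.items():
            if abbr not in _BY_ABBREV:
                raise ValueError(f"sample {self.sample_id!r}: unknown compound {abbr!r}")
            if not math.isfinite(c) or c < 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: concentration of {abbr} must be "
                    f"finite and >= 0, got {c}"
                )
        texture = (self.sand, self.silt, self.clay)
        if all(t is not None for t in texture):
            total = sum(texture)  # type: ignore[arg-type]
            if abs(total - 100.0) > 0.5:
                raise ValueError(
                    f"sample {self.sample_id!r}: sand+silt+clay = {total:.2f}, "
                    "expected 100 ± 0.5"
                )

    def total_pah(self) -> float:
        """Σ16PAH in µg kg⁻¹."""
        return sum(self.concentrations[a] for a in COMPOUND_ORDER)


class SampleTableError(ValueError):
    """Malformed concentration table (reported with row/column context)."""


def read_sample_table(path: str | Path) -> list[SampleRecord]:
    """Read soil samples from a concentration CSV.

    The file must have a ``sample_id`` column and one column per compound
    abbreviation (all 16, any order).  Optional property columns
    (``sand, silt, clay, ph_kcl, c_org, tn, x, y``) are picked up when
    present; empty cells in them yield absent fields.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise SampleTableError(f"{path}: missing required column 'sample_id'")
    missing = [a for a in COMPOUND_ORDER if a not in df.columns]
    if missing:
        raise SampleTableError(f"{path}: missing compound column(s) {', '.join(missing)}")
    dupes = df.columns[df.columns.duplicated()].tolist()
    if dupes:
        raise SampleTableError(f"{path}: duplicated column(s) {', '.join(map(str, dupes))}")

    records: list[SampleRecord] = []
    for i, row in df.iterrows():
        conc: dict[str, float] = {}
        for abbr in COMPOUND_ORDER:
            raw = row[abbr]
            try:
                val = float(raw)
            except (TypeError, ValueError):
                raise SampleTableError(
                    f"{path}: row {i + 1}, column {abbr}: non-numeric value {raw!r}"
                ) from None
            if math.isnan(val):
                raise SampleTableError(f"{path}: row {i + 1}, column {abbr}: missing value")
            if val < 0:
                raise SampleTableError(
                    f"{path}: row {i + 1}, column {abbr}: negative concentration {val}"
                )
            conc[abbr] = val
        extras: dict[str, float | None] = {}
        for col in _OPTIONAL_COLUMNS:
            if col in df.columns:
                val = row[col]
                extras[col] = None if pd.isna(val) else float(val)
        try:
            records.append(SampleRecord(str(row["sample_id"]), conc, **extras))
        except ValueError as exc:
            raise SampleTableError(f"{path}: row {i + 1}: {exc}") from exc
    return records


def write_sample_table(records: Iterable[SampleRecord], path: str | Path) -> None:
    """Write samples to CSV in canonical compound order (lossless round trip)."""
    records = list(records)
    rows = []
    present_optional = [
        col for col in _OPTIONAL_COLUMNS
        if any(getattr(r, col) is not None for r in records)
    ]
    for r in records:
        row: dict[str, object] = {"sample_id": r.sample_id}
        row.update({a: r.concentrations[a] for a in COMPOUND_ORDER})
        for col in present_optional:
            row[col] = getattr(r, col)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def reference_report() -> str:
    """Plain-text dump of the registry and schemes for auditability."""
    lines = ["# PAH registry (concentrations in ug/kg)"]
    header = f"{'abbr':8}{'rings':>6}{'MPC_PL':>8}{'MPC_NL':>8}{'PNEC':>8}{'TEF':>8}  flags"
    lines.append(header)
    for c in _REGISTRY:
        flags = "".join(("C" if c.is_carcinogenic else "-", "E" if c.is_4em else "-"))
        mpc_pl = f"{c.mpc_pl:.0f}" if c.mpc_pl is not None else "-"
        lines.append(
            f"{c.abbreviation:8}{c.n_rings:>6}{mpc_pl:>8}{c.mpc_nl:>8.0f}"
            f"{c.pnec:>8.0f}{c.tef:>8.3f}  {flags}"
        )
    lines.append("flags: C carcinogenic, E emission-monitored quartet")
    lines.append("")
    lines.append("# Classification schemes (left-closed intervals)")
    for s in _SCHEMES.values():
        bp = ", ".join(f"{b:g}" for b in s.breakpoints)
        lines.append(f"{s.scheme_id}: breakpoints [{bp}]")
        for lab in s.labels:
            lines.append(f"  - {lab}")
    return "\n".join(lines) + "\n"
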