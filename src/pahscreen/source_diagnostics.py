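"""Diagnostic isomer ratios for PAH source apportionment.

Pairs of PAH isomers with similar physicochemical properties keep a roughly
constant proportion between emission and deposition, so the normalised ratio
a/(a+b) points at the emission source.  Three of the most stable ratios are
used: Fln/(Fln+Pyr), BaA/(BaA+Ch) and IndPyr/(IndPyr+BPer).

The threshold sets are the conventional literature scheme; they are
config-overridable because boundary placement differs slightly between
authors (in particular the 0.4 lower bound for Fln/(Fln+Pyr) petrogenic
sources is a conventional choice rather than a universal constant).
Boundary values fall in the upper category (left-closed convention, as for
the risk classification schemes).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Mapping

from .reference_data import SampleRecord

__all__ = [
    "RatioResult",
    "RATIO_DEFS",
    "DEFAULT_THRESHOLDS",
    "isomer_ratio",
    "diagnose_sources",
]

#: ratio_id -> (numerator compound, other isomer)
RATIO_DEFS: dict[str, tuple[str, str]] = {
    "FlnPyr": ("Fln", "Pyr"),
    "BaACh": ("BaA", "Ch"),
    "IndBPer": ("IndPyr", "BPer"),
}

#: ratio_id -> (breakpoints, labels, coarse categories); labels partition [0, 1].
DEFAULT_THRESHOLDS: dict[str, tuple[tuple[float, ...], tuple[str, ...], tuple[str, ...]]] = {
    "FlnPyr": (
        (0.4, 0.5),
        ("petrogenic", "liquid fossil fuel combustion", "coal/biomass combustion"),
        ("petrogenic", "combustion", "combustion"),
    ),
    "BaACh": (
        (0.2, 0.35),
        ("petrogenic", "mixed", "combustion"),
        ("petrogenic", "mixed", "combustion"),
    ),
    "IndBPer": (
        (0.2, 0.5),
        ("petrogenic", "liquid fossil fuel combustion", "coal/biomass combustion"),
        ("petrogenic", "combustion", "combustion"),
    ),
}


@dataclass(frozen=True)
class RatioResult:
    """One diagnostic ratio: value in [0, 1] (None when undefined) + label."""

    ratio_id: str
    value: float | None
    source_label: str  # "undefined" when the denominator is zero
    category: str  # coarse verdict class: petrogenic / combustion / mixed


def isomer_ratio(
    sample: SampleRecord,
    ratio_id: str,
    thresholds: Mapping[str, tuple] | None = None,
) -> RatioResult:
    """Compute one diagnostic ratio a/(a+b) and its source label.

    A zero denominator yields ``value=None`` and label ``"undefined"``.
    """
    if ratio_id not in RATIO_DEFS:
        raise KeyError(
            f"unknown ratio {ratio_id!r}; expected one of {', '.join(RATIO_DEFS)}"
        )
    num_abbr, den_abbr = RATIO_DEFS[ratio_id]
    a = sample.concentrations[num_abbr]
    b = sample.concentrations[den_abbr]
    if a + b == 0:
        return RatioResult(ratio_id, None, "undefined", "undefined")
    value = a / (a + b)
    breaks, labels, categories = (thresholds or DEFAULT_THRESHOLDS)[ratio_id]
    idx = bisect_right(breaks, value)
    return RatioResult(ratio_id, value, labels[idx], categories[idx])


def diagnose_sources(
    sample: SampleRecord,
    thresholds: Mapping[str, tuple] | None = None,
) -> tuple[dict[str, RatioResult], str]:
    """All three ratios plus a combined verdict.

    The verdict is the majority coarse category (petrogenic / combustion /
    mixed) over the defined ratios; ties — or all ratios undefined — give
    ``"mixed"``.
    """
    results = {rid: isomer_ratio(sample, rid, thresholds) for rid in RATIO_DEFS}
    counts: dict[str, int] = {}
    for r in results.values():
        if r.value is not None:
            counts[r.category] = counts.get(r.category, 0) + 1
    if not counts:
        return results, "mixed"
    best = max(counts.values())
    winners = [cat for cat, n in counts.items() if n == best]
    verdict = winners[0] if len(winners) == 1 else "mixed"
    return results, verdict
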