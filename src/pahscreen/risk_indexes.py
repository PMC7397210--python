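"""Single-compound and mixture risk indexes for PAH-contaminated soils.

Four index families are computed from measured concentrations:

* **HQ / HI** — hazard quotient HQ = C / MPC_PL per regulated compound and
  the hazard index HI = Σ HQ over the 10 compounds with Polish soil
  screening values.  The most conservative (screening) approach.
* **TU / TUm** — toxic unit TU = C / PNEC per compound and the
  concentration-addition mixture sum TUm = Σ TU over all 16 PAHs, which
  assumes a shared toxic mode of action (narcosis for PAHs).
* **TP / TPm** — toxic pressure of a single compound, bounded to [0, 1],
  combined by response addition TPm = 1 − Π(1 − TPᵢ), which assumes
  dissimilar modes of action.  The single-compound form is configurable
  because only the effect level (the Dutch MPC) is fixed by convention:
  the default is the capped ratio min(C/MPC_NL, 1); a log-logistic
  potentially-affected-fraction curve is available as an alternative.
* **TEQ** — benzo[a]pyrene-equivalent concentration TEQ = Σ (C × TEF),
  a human-health-oriented potency-weighted sum over all 16 PAHs.

All indexes assume total measured concentrations are 100% bioavailable —
deliberately conservative, as appropriate for a first screening tier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reference_data import (
    COMPOUND_ORDER,
    REGULATED_PL,
    SampleRecord,
    builtin_registry,
    get_scheme,
    lookup,
)

__all__ = [
    "RiskProfile",
    "hazard_quotient",
    "hazard_index",
    "toxic_unit",
    "toxic_units_mixture",
    "toxic_pressure_single",
    "toxic_pressure_mixture",
    "teq",
    "classify",
    "ring_group_sums",
    "compute_profile",
    "compute_profiles",
    "profiles_to_frame",
    "summarize",
]


def hazard_quotient(c: float, mpc: float) -> float:
    """Hazard quotient C/MPC (both µg kg⁻¹); HQ > 1 flags possible risk."""
    if mpc <= 0:
        raise ValueError(f"MPC must be > 0, got {mpc}")
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    return c / mpc


def hazard_index(sample: SampleRecord) -> tuple[dict[str, float], float]:
    """Per-compound hazard quotients and their sum (HI).

    Covers exactly the 10 compounds with Polish screening values; the six
    unregulated compounds contribute nothing.
    """
    hq = {
        abbr: hazard_quotient(sample.concentrations[abbr], lookup(abbr).mpc_pl)
        for abbr in REGULATED_PL
    }
    return hq, sum(hq.values())


def toxic_unit(c: float, pnec: float) -> float:
    """Toxic unit C/PNEC (both µg kg⁻¹); TU > 1 flags likely effects."""
    if pnec <= 0:
        raise ValueError(f"PNEC must be > 0, got {pnec}")
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    return c / pnec


def toxic_units_mixture(sample: SampleRecord) -> tuple[dict[str, float], float]:
    """Per-compound toxic units and the concentration-addition sum TUm."""
    tu = {
        abbr: toxic_unit(sample.concentrations[abbr], lookup(abbr).pnec)
        for abbr in COMPOUND_ORDER
    }
    return tu, sum(tu.values())


def toxic_pressure_single(
    c: float,
    mpc_nl: float,
    form: str = "ratio_capped",
    beta: float | None = None,
) -> float:
    """Toxic pressure of one compound, in [0, 1].

    Parameters
    ----------
    form:
        ``"ratio_capped"`` (default): min(C / MPC_NL, 1).
        ``"log_logistic"``: 1 / (1 + (MPC_NL / C)^(1/beta)), a saturating
        potentially-affected-fraction curve with TP = 0.5 at C = MPC_NL;
        ``beta`` is its log-scale slope (default 0.4).
    """
    if mpc_nl <= 0:
        raise ValueError(f"MPC_NL must be > 0, got {mpc_nl}")
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    if form == "ratio_capped":
        return min(c / mpc_nl, 1.0)
    if form == "log_logistic":
        b = 0.4 if beta is None else beta
        if b <= 0:
            raise ValueError(f"beta must be > 0, got {b}")
        if c == 0:
            return 0.0
        return 1.0 / (1.0 + (mpc_nl / c) ** (1.0 / b))
    raise ValueError(f"unknown TP form {form!r}")


def toxic_pressure_mixture(tp: Sequence[float] | Mapping[str, float]) -> float:
    """Response-addition combination TPm = 1 − Π(1 − TPᵢ)."""
    values = list(tp.values()) if isinstance(tp, Mapping) else list(tp)
    survival = 1.0
    for i, t in enumerate(values):
        if not (0.0 <= t <= 1.0):
            raise ValueError(f"TP[{i}] = {t} outside [0, 1]")
        survival *= 1.0 - t
    return 1.0 - survival


def teq(sample: SampleRecord) -> tuple[dict[str, float], float]:
    """Per-compound BaPyr-equivalents (C × TEF, µg kg⁻¹) and their sum."""
    per = {
        abbr: sample.concentrations[abbr] * lookup(abbr).tef
        for abbr in COMPOUND_ORDER
    }
    return per, sum(per.values())


def classify(value: float, scheme_id: str) -> str:
    """Class label of ``value`` under a built-in scheme (left-closed bins)."""
    return get_scheme(scheme_id).classify(value)


def ring_group_sums(sample: SampleRecord) -> dict[str, float]:
    """Concentration sums over ring-number and flag partitions (µg kg⁻¹).

    Returns keys ``2-ring`` … ``6-ring``, ``PAH_Carcin`` (the 7 carcinogens),
    ``PAH_4em`` (the emission-monitored quartet) and ``S16PAH``.
    """
    out = {f"{n}-ring": 0.0 for n in range(2, 7)}
    out["PAH_Carcin"] = 0.0
    out["PAH_4em"] = 0.0
    for rec in builtin_registry():
        c = sample.concentrations[rec.abbreviation]
        out[f"{rec.n_rings}-ring"] += c
        if rec.is_carcinogenic:
            out["PAH_Carcin"] += c
        if rec.is_4em:
            out["PAH_4em"] += c
    out["S16PAH"] = sum(out[f"{n}-ring"] for n in range(2, 7))
    return out


@dataclass
class RiskProfile:
    """All index values and class labels for one sample."""

    sample_id: str
    hq: dict[str, float]
    hi: float
    tu: dict[str, float]
    tum: float
    tp: dict[str, float]
    tpm: float
    teq: dict[str, float]
    teq_total: float
    total_pah: float
    tp_form: str
    labels: dict[str, str] = field(default_factory=dict)


def compute_profile(
    sample: SampleRecord,
    tp_form: str = "ratio_capped",
    beta: float | None = None,
) -> RiskProfile:
    """Compute every index and class label for one sample."""
    hq, hi = hazard_index(sample)
    tu, tum = toxic_units_mixture(sample)
    tp = {
        abbr: toxic_pressure_single(
            sample.concentrations[abbr], lookup(abbr).mpc_nl, form=tp_form, beta=beta
        )
        for abbr in COMPOUND_ORDER
    }
    tpm = toxic_pressure_mixture(tp)
    teq_map, teq_total = teq(sample)
    total = sample.total_pah()
    labels = {
        "contamination": classify(total, "contamination"),
        "hi": classify(hi, "hi"),
        "tum": classify(tum, "tum"),
        "tpm": classify(tpm, "tp"),
        "teq": classify(teq_total, "teq"),
    }
    return RiskProfile(
        sample_id=sample.sample_id,
        hq=hq,
        hi=hi,
        tu=tu,
        tum=tum,
        tp=tp,
        tpm=tpm,
        teq=teq_map,
        teq_total=teq_total,
        total_pah=total,
        tp_form=tp_form,
        labels=labels,
    )


def compute_profiles(
    samples: Iterable[SampleRecord],
    tp_form: str = "ratio_capped",
    beta: float | None = None,
) -> list[RiskProfile]:
    return [compute_profile(s, tp_form=tp_form, beta=beta) for s in samples]


def profiles_to_frame(profiles: Iterable[RiskProfile], ndigits: int | None = None) -> pd.DataFrame:
    """Tabulate profiles: per-compound columns, mixture scalars, class labels.

    ``ndigits`` optionally rounds numeric columns for reporting; full
    precision is the default.
    """
    rows = []
    for p in profiles:
        row: dict[str, object] = {"sample_id": p.sample_id}
        for abbr in REGULATED_PL:
            row[f"HQ_{abbr}"] = p.hq[abbr]
        for abbr in COMPOUND_ORDER:
            row[f"TU_{abbr}"] = p.tu[abbr]
        for abbr in COMPOUND_ORDER:
            row[f"TP_{abbr}"] = p.tp[abbr]
        for abbr in COMPOUND_ORDER:
            row[f"TEQ_{abbr}"] = p.teq[abbr]
        row["S16PAH"] = p.total_pah
        row["HI"] = p.hi
        row["TUm"] = p.tum
        row["TPm"] = p.tpm
        row["TEQ_total"] = p.teq_total
        row["tp_form"] = p.tp_form
        for scheme, label in p.labels.items():
            row[f"class_{scheme}"] = label
        rows.append(row)
    df = pd.DataFrame(rows)
    if ndigits is not None:
        num = df.select_dtypes("number").columns
        df[num] = df[num].round(ndigits)
    return df


def summarize(values: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Descriptive statistics table: Min, LQ, Mean, Median, UQ, Max, CoV,
    Skewness, Kurtosis — one row per variable.

    Quartiles use linear interpolation between order statistics; CoV is
    100·sd/mean with the n−1 sample standard deviation; skewness and excess
    kurtosis are the standard moment ratios g1 and g2.
    """
    rows = []
    for name, vals in values.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise ValueError(f"variable {name!r}: need at least 2 observations")
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1))
        rows.append(
            {
                "variable": name,
                "min": float(arr.min()),
                "lq": float(np.percentile(arr, 25)),
                "mean": mean,
                "median": float(np.median(arr)),
                "uq": float(np.percentile(arr, 75)),
                "max": float(arr.max()),
                "cov": 100.0 * sd / mean if mean > 0 else math.nan,
                "skewness": float(stats.skew(arr)),
                "kurtosis": float(stats.kurtosis(arr)),
            }
        )
    return pd.DataFrame(rows)
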