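"""VIS-NIR spectra: container, acquisition conventions and preprocessing.

Spectra are diffuse reflectance factors over 350-2500 nm.  Acquisition
conventions mirrored here: replicate scans of one sample are averaged and
the native (variable-resolution) grid is linearly interpolated to 1 nm
steps, giving 2151 channels.

Preprocessing operators:

* moving average (``ma``) — centred window mean, default segment 5; edge
  points use the window truncated to the grid so the grid is preserved.
* standard normal variate (``snv``) — per-spectrum standardisation to mean
  0 / sd 1 (n-1 denominator); removes multiplicative scatter and baseline
  offsets.
* Savitzky-Golay first derivative (``sg``) — local polynomial fit, default
  window 11 / order 2, derivative in reflectance units per nm; edges use a
  polynomial fit on the truncated window (scipy's ``mode="interp"``).
* ``log1r`` — optional log10(1/R) absorbance transform, off by default:
  the screening workflow operates on reflectance as acquired.

Operators act on reflectance arrays and are deterministic pure transforms;
a :class:`PreprocessChain` serialises an ordered pipeline to and from a
compact text form (e.g. ``"ma:5|snv"``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "Spectrum",
    "PreprocessChain",
    "GRID_1NM",
    "average_replicates",
    "resample_to_1nm",
    "moving_average",
    "snv",
    "savitzky_golay_first_derivative",
    "log_one_over_r",
    "read_spectra",
    "write_spectra",
    "SpectraFormatError",
]

WAVELENGTH_MIN = 350.0
WAVELENGTH_MAX = 2500.0
#: target acquisition grid: 350..2500 nm at 1 nm, 2151 channels
GRID_1NM = np.arange(WAVELENGTH_MIN, WAVELENGTH_MAX + 1.0)


@dataclass(frozen=True)
class Spectrum:
    """Reflectance factor over a strictly increasing wavelength grid (nm).

    Values above 1 are possible relative to the white reference, hence the
    (0, 1.5] validity range.  Derived quantities (SNV output, derivatives)
    are carried in the same container with validation relaxed via
    ``validate=False``.
    """

    sample_id: str
    wavelengths: np.ndarray
    reflectance: np.ndarray
    replicate_id: int | None = None
    validate: bool = True

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        rf = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", rf)
        if wl.ndim != 1 or rf.shape != wl.shape:
            raise ValueError(
                f"spectrum {self.sample_id!r}: wavelengths and reflectance must be "
                f"1-D and equal length (got {wl.shape} vs {rf.shape})"
            )
        if wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError(
                f"spectrum {self.sample_id!r}: wavelengths must be strictly increasing"
            )
        if not np.all(np.isfinite(rf)):
            raise ValueError(f"spectrum {self.sample_id!r}: non-finite reflectance")
        if self.validate and (np.any(rf <= 0) or np.any(rf > 1.5)):
            raise ValueError(
                f"spectrum {self.sample_id!r}: reflectance outside (0, 1.5]"
            )

    def with_values(self, reflectance: np.ndarray, validate: bool | None = None) -> "Spectrum":
        return replace(
            self,
            reflectance=np.asarray(reflectance, dtype=float),
            validate=self.validate if validate is None else validate,
        )


def average_replicates(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise mean of replicate scans of one sample."""
    if not spectra:
        raise ValueError("no replicates to average")
    first = spectra[0]
    for s in spectra[1:]:
        if s.wavelengths.shape != first.wavelengths.shape or not np.array_equal(
            s.wavelengths, first.wavelengths
        ):
            raise ValueError(
                f"sample {first.sample_id!r}: replicate grids do not match"
            )
        if s.sample_id != first.sample_id:
            raise ValueError(
                f"cannot average across samples {first.sample_id!r} and {s.sample_id!r}"
            )
    mean = np.mean([s.reflectance for s in spectra], axis=0)
    return Spectrum(first.sample_id, first.wavelengths, mean, replicate_id=None,
                    validate=first.validate)


def resample_to_1nm(spectrum: Spectrum) -> Spectrum:
    """Linear interpolation onto the integer 350..2500 nm grid."""
    wl = spectrum.wavelengths
    if wl[0] > WAVELENGTH_MIN or wl[-1] < WAVELENGTH_MAX:
        raise ValueError(
            f"spectrum {spectrum.sample_id!r}: grid [{wl[0]}, {wl[-1]}] does not "
            f"cover [{WAVELENGTH_MIN}, {WAVELENGTH_MAX}]"
        )
    values = np.interp(GRID_1NM, wl, spectrum.reflectance)
    return replace(spectrum, wavelengths=GRID_1NM.copy(), reflectance=values)


def _moving_average_values(values: np.ndarray, segment: int) -> np.ndarray:
    # mean over the window intersected with the grid (shrunken edge windows)
    n = values.size
    half = segment // 2
    csum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def moving_average(spectrum: Spectrum, segment: int = 5) -> Spectrum:
    """Centred moving-average smoothing; default segment size 5."""
    if segment % 2 == 0 or segment < 3:
        raise ValueError(f"segment must be odd and >= 3, got {segment}")
    if segment > spectrum.wavelengths.size:
        raise ValueError(
            f"segment {segment} exceeds grid length {spectrum.wavelengths.size}"
        )
    return spectrum.with_values(_moving_average_values(spectrum.reflectance, segment))


def snv(spectrum: Spectrum) -> Spectrum:
    """Standard normal variate: per-spectrum mean 0, sd 1 (n-1 denominator)."""
    values = spectrum.reflectance
    if np.ptp(values) == 0:
        raise ValueError(
            f"spectrum {spectrum.sample_id!r}: constant spectrum, SNV undefined"
        )
    sd = values.std(ddof=1)
    return spectrum.with_values((values - values.mean()) / sd, validate=False)


def savitzky_golay_first_derivative(
    spectrum: Spectrum, window: int = 11, polyorder: int = 2
) -> Spectrum:
    """Savitzky-Golay first derivative (units: reflectance per nm).

    Requires a uniform grid (apply :func:`resample_to_1nm` first if needed).
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if not (1 <= polyorder < window):
        raise ValueError(f"polyorder must satisfy 1 <= polyorder < window, got {polyorder}")
    steps = np.diff(spectrum.wavelengths)
    if not np.allclose(steps, steps[0]):
        raise ValueError(
            f"spectrum {spectrum.sample_id!r}: Savitzky-Golay needs a uniform grid"
        )
    deriv = savgol_filter(
        spectrum.reflectance, window, polyorder, deriv=1, delta=steps[0], mode="interp"
    )
    return spectrum.with_values(deriv, validate=False)


def log_one_over_r(spectrum: Spectrum) -> Spectrum:
    """Apparent absorbance log10(1/R)."""
    if np.any(spectrum.reflectance <= 0):
        raise ValueError(f"spectrum {spectrum.sample_id!r}: R must be > 0 for log(1/R)")
    return spectrum.with_values(-np.log10(spectrum.reflectance), validate=False)


# ---------------------------------------------------------------------------
# Preprocessing chains
# ---------------------------------------------------------------------------

_OPERATORS = {
    "ma": (moving_average, ("segment",), (5,)),
    "snv": (snv, (), ()),
    "sg": (savitzky_golay_first_derivative, ("window", "polyorder"), (11, 2)),
    "resample": (resample_to_1nm, (), ()),
    "log1r": (log_one_over_r, (), ()),
}


@dataclass(frozen=True)
class PreprocessChain:
    """Ordered, serialisable pipeline of preprocessing operators.

    Text form: steps separated by ``|``, integer parameters after ``:``,
    e.g. ``"ma:5|snv"`` or ``"ma:5|sg:11:2"``.
    """

    steps: tuple[tuple[str, tuple[int, ...]], ...]

    @classmethod
    def parse(cls, text: str) -> "PreprocessChain":
        steps: list[tuple[str, tuple[int, ...]]] = []
        text = text.strip()
        if text:
            for part in text.split("|"):
                tokens = part.strip().split(":")
                name = tokens[0]
                if name not in _OPERATORS:
                    raise ValueError(
                        f"unknown preprocessing operator {name!r}; "
                        f"expected one of {', '.join(_OPERATORS)}"
                    )
                _, param_names, defaults = _OPERATORS[name]
                params = tuple(int(t) for t in tokens[1:])
                if len(params) > len(param_names):
                    raise ValueError(f"operator {name!r}: too many parameters in {part!r}")
                params = params + defaults[len(params):]
                steps.append((name, params))
        return cls(tuple(steps))

    def serialise(self) -> str:
        return "|".join(
            name if not params else name + ":" + ":".join(str(p) for p in params)
            for name, params in self.steps
        )

    def apply(self, spectrum: Spectrum) -> Spectrum:
        out = spectrum
        for name, params in self.steps:
            func, _, _ = _OPERATORS[name]
            out = func(out, *params)
        return out

    def apply_matrix(self, wavelengths: np.ndarray, X: np.ndarray) -> np.ndarray:
        """Apply the chain row-wise to a samples × wavelengths matrix."""
        rows = []
        for i, row in enumerate(np.atleast_2d(X)):
            s = Spectrum(f"row{i}", wavelengths, row, validate=False)
            rows.append(self.apply(s).reflectance)
        return np.asarray(rows)


# ---------------------------------------------------------------------------
# I/O — wide and long CSV dialects
# ---------------------------------------------------------------------------


class SpectraFormatError(ValueError):
    """Malformed spectra CSV."""


def read_spectra(path: str | Path) -> list[Spectrum]:
    """Read spectra from CSV; the dialect is auto-detected from the header.

    Wide: ``sample_id[,replicate]`` then one column per wavelength (numeric
    header names).  Long: ``sample_id,replicate,wavelength,reflectance``.
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    if "wavelength" in cols and "reflectance" in cols:
        return _read_long(df, path)
    return _read_wide(df, path)


def _read_long(df: pd.DataFrame, path: str | Path) -> list[Spectrum]:
    for col in ("sample_id", "wavelength", "reflectance"):
        if df[col].isna().any():
            row = int(df[col].isna().idxmax()) + 1
            raise SpectraFormatError(f"{path}: row {row}: missing value in column {col!r}")
    has_rep = "replicate" in df.columns
    spectra = []
    keys = ["sample_id", "replicate"] if has_rep else ["sample_id"]
    for key, grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("wavelength")
        sid = str(key[0]) if isinstance(key, tuple) else str(key)
        rep = int(key[1]) if has_rep and isinstance(key, tuple) else None
        spectra.append(
            Spectrum(sid, grp["wavelength"].to_numpy(float),
                     grp["reflectance"].to_numpy(float), replicate_id=rep)
        )
    return spectra


def _read_wide(df: pd.DataFrame, path: str | Path) -> list[Spectrum]:
    if "sample_id" not in df.columns:
        raise SpectraFormatError(f"{path}: missing 'sample_id' column")
    meta_cols = ["sample_id"] + (["replicate"] if "replicate" in df.columns else [])
    wl_cols = [c for c in df.columns if c not in meta_cols]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError:
        bad = next(c for c in wl_cols if not _is_number(c))
        raise SpectraFormatError(
            f"{path}: non-numeric wavelength column {bad!r}"
        ) from None
    if np.any(np.diff(wavelengths) <= 0):
        raise SpectraFormatError(f"{path}: wavelength columns not strictly increasing")
    spectra = []
    for i, row in df.iterrows():
        values = row[wl_cols].to_numpy(float)
        if np.isnan(values).any():
            bad = wl_cols[int(np.isnan(values).argmax())]
            raise SpectraFormatError(f"{path}: row {i + 1}: missing value at {bad} nm")
        rep = int(row["replicate"]) if "replicate" in meta_cols and not pd.isna(row.get("replicate")) else None
        spectra.append(Spectrum(str(row["sample_id"]), wavelengths, values, replicate_id=rep))
    return spectra


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


def write_spectra(spectra: Iterable[Spectrum], path: str | Path, dialect: str = "wide") -> None:
    """Write spectra to CSV in the wide (default) or long dialect."""
    spectra = list(spectra)
    if dialect == "wide":
        grids = {tuple(s.wavelengths) for s in spectra}
        if len(grids) > 1:
            raise ValueError("wide dialect requires a common wavelength grid")
        has_rep = any(s.replicate_id is not None for s in spectra)
        rows = []
        for s in spectra:
            row: dict[str, object] = {"sample_id": s.sample_id}
            if has_rep:
                row["replicate"] = s.replicate_id
            row.update({f"{wl:g}": v for wl, v in zip(s.wavelengths, s.reflectance)})
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
    elif dialect == "long":
        frames = []
        for s in spectra:
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": s.sample_id,
                        "replicate": s.replicate_id if s.replicate_id is not None else 0,
                        "wavelength": s.wavelengths,
                        "reflectance": s.reflectance,
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
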