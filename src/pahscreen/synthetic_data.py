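"""Synthetic soil datasets with paired VIS-NIR spectra.

No concentration or spectral data were published with the survey this
package's workflow is modelled on, so testing the full pipeline requires a
generator that reproduces the *statistical structure* the analysis
exploits:

* Σ16PAH is log-normal and spans roughly 3×10² to 3×10⁵ µg kg⁻¹, with the
  bulk of samples between a few hundred and a few thousand;
* the compound composition is dominated by high-molecular-weight (≥4-ring)
  PAHs, with diagnostic isomer ratios centred near (0.58, 0.43, 0.52) —
  a combustion-type profile;
* organic carbon is positively correlated with Σ16PAH on the log-log scale
  (default correlation 0.9, i.e. r² ≈ 0.8);
* spectra are flat, sandy-soil reflectance curves that darken with organic
  carbon and PAH content, with absorption features at 1400/1900 nm (water),
  2210 nm (clay-bound water) and a hydrocarbon-scaled band inside
  1600–1800 nm; replicate scans differ by multiplicative scatter and
  additive noise.

The mechanism is deliberately simple (Dirichlet-perturbed composition,
Gaussian absorption bands): it is *not* a physical radiative-transfer
simulation, only the structure the screening analysis assumes.

Seeding: one global seed drives sample generation; each sample's spectra
use a seed derived from (global seed, sample id), so extending a dataset
does not reshuffle existing spectra.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .reference_data import COMPOUND_ORDER, SampleRecord, write_sample_table
from .risk_indexes import compute_profiles, profiles_to_frame
from .spectral_processing import GRID_1NM, Spectrum, average_replicates, write_spectra

__all__ = [
    "SpectralConfig",
    "GeneratorConfig",
    "DEFAULT_COMPOSITION",
    "generate_samples",
    "generate_spectrum",
    "spectra_matrix",
    "make_fixture",
]

# Mean mass-fraction profile of the 16 compounds (normalised at use).  The
# relative weights reproduce a combustion-dominated, HMW-heavy profile with
# isomer-ratio centres Fln/(Fln+Pyr) ≈ 0.57, BaA/(BaA+Ch) ≈ 0.43,
# IndPyr/(IndPyr+BPer) ≈ 0.52.
DEFAULT_COMPOSITION: dict[str, float] = {
    "Napht": 61.0,
    "Acyn": 5.8,
    "Acen": 12.2,
    "Flu": 10.0,
    "Phen": 126.0,
    "Anth": 11.7,
    "Fln": 240.0,
    "Pyr": 180.0,
    "BaA": 69.5,
    "Ch": 93.5,
    "BbF": 131.6,
    "BkF": 54.0,
    "BaPyr": 96.5,
    "IndPyr": 72.8,
    "DahA": 14.0,
    "BPer": 68.0,
}


@dataclass(frozen=True)
class SpectralConfig:
    """Parameters of the spectral forward model.

    Reflectance model per sample::

        R(λ) = [ baseline(λ) · (1 − darkening) − Σ bands(λ) ] · scatter + noise

    with ``baseline(λ) = baseline_low + baseline_rise·(1 − exp(−(λ−350)/baseline_scale_nm))``
    (a flat, sandy-soil curve rising through the VIS), fractional darkening
    ``corg_darkening·z_Corg + pah_darkening·z_PAH`` where the z's are the
    log-scaled contents normalised to [0, 1], Gaussian water/clay bands, and
    a hydrocarbon band at 1700 nm whose depth scales with PAH content.
    Replicates share the shape and differ by multiplicative scatter
    (sd ``scatter_sd``) and additive noise (sd ``noise_sd``).
    """

    baseline_low: float = 0.12
    baseline_rise: float = 0.38
    baseline_scale_nm: float = 900.0
    corg_darkening: float = 0.30  # fractional darkening at z_Corg = 1
    pah_darkening: float = 0.25  # fractional darkening at z_PAH = 1
    water_band_depth_1400: float = 0.04
    water_band_depth_1900: float = 0.08
    clay_band_depth_2210: float = 0.03
    hc_band_center: float = 1700.0  # hydrocarbon overtone band, nm
    hc_band_width: float = 40.0
    hc_band_depth: float = 0.015  # depth at z_PAH = 1; 3x the default noise sd
    noise_sd: float = 0.005
    scatter_sd: float = 0.02
    replicates: int = 5


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic soil dataset."""

    n_samples: int = 74
    seed: int = 0
    log10_total_mean: float = 3.1  # log10 Σ16PAH, µg/kg (median ≈ 1250)
    log10_total_sd: float = 0.8  # ±3 sd spans ≈ 10² to 3×10⁵
    corg_pah_correlation: float = 0.9  # corr(log C_org, log Σ16PAH)
    log10_corg_mean: float = 1.07  # log10 C_org, g/kg (median ≈ 12)
    log10_corg_sd: float = 0.35
    composition_profile: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    dirichlet_concentration: float = 600.0  # spread of per-sample composition
    spectral: SpectralConfig = field(default_factory=SpectralConfig)

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if not -1.0 < self.corg_pah_correlation < 1.0:
            raise ValueError("corg_pah_correlation must be in (-1, 1)")
        profile = self.composition_profile
        if set(profile) != set(COMPOUND_ORDER):
            raise ValueError("composition_profile must cover exactly the 16 compounds")
        if any(v < 0 for v in profile.values()) or sum(profile.values()) <= 0:
            raise ValueError("composition fractions must be >= 0 with positive sum")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be > 0")
        if self.spectral.replicates < 1:
            raise ValueError("replicates must be >= 1")


def generate_samples(config: GeneratorConfig) -> list[SampleRecord]:
    """Draw soil samples: concentrations, texture, pH, C_org, TN.

    Σ16PAH is log-normal; per-compound concentrations are the total times a
    Dirichlet-perturbed composition profile; log C_org is drawn jointly with
    log Σ16PAH at the configured correlation; texture stays in loamy-sand
    ranges.
    """
    fractions = np.array([config.composition_profile[a] for a in COMPOUND_ORDER])
    fractions = fractions / fractions.sum()
    alpha = config.dirichlet_concentration * fractions
    rho = config.corg_pah_correlation

    samples = []
    for i in range(config.n_samples):
        # per-sample stream: extending the dataset leaves earlier samples intact
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, i]))
        z1, z2 = rng.standard_normal(2)
        log_total = config.log10_total_mean + config.log10_total_sd * z1
        log_corg = config.log10_corg_mean + config.log10_corg_sd * (
            rho * z1 + np.sqrt(1.0 - rho**2) * z2
        )
        total = 10.0**log_total
        corg = 10.0**log_corg
        comp = rng.dirichlet(alpha)
        sand = float(np.clip(rng.normal(71.8, 8.0), 49.0, 90.6))
        clay = float(np.clip(rng.normal(1.9, 1.2), 0.0, 6.0))
        ph = float(np.clip(rng.normal(5.2, 0.6), 3.8, 7.8))
        tn = corg * float(np.clip(rng.normal(0.075, 0.015), 0.02, 0.15))
        conc = {
            abbr: float(total * comp[j]) for j, abbr in enumerate(COMPOUND_ORDER)
        }
        samples.append(
            SampleRecord(
                sample_id=f"S{i + 1:03d}",
                concentrations=conc,
                sand=sand,
                silt=100.0 - sand - clay,
                clay=clay,
                ph_kcl=ph,
                c_org=float(corg),
                tn=float(tn),
            )
        )
    return samples


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # per-sample stream derived from (global seed, stable id hash); the
    # constant 2 keeps it disjoint from the sample-generation streams
    return np.random.default_rng(
        np.random.SeedSequence([seed, 2, zlib.crc32(sample_id.encode())])
    )


def spectrum_shape(sample: SampleRecord, config: GeneratorConfig) -> np.ndarray:
    """Noise-free reflectance shape for one sample on the 1 nm grid."""
    if sample.c_org is None:
        raise ValueError(f"sample {sample.sample_id!r}: C_org required for spectra")
    sp = config.spectral
    wl = GRID_1NM
    total = sample.total_pah()
    z_pah = float(np.clip((np.log10(max(total, 1.0)) - 2.5) / 3.0, 0.0, 1.0))
    z_corg = float(np.clip((np.log10(max(sample.c_org, 0.1)) - 0.7) / 1.5, 0.0, 1.0))
    clay_scale = 0.3 + 0.7 * (sample.clay / 6.0 if sample.clay is not None else 0.3)

    baseline = sp.baseline_low + sp.baseline_rise * (
        1.0 - np.exp(-(wl - wl[0]) / sp.baseline_scale_nm)
    )
    darkening = sp.corg_darkening * z_corg + sp.pah_darkening * z_pah
    bands = (
        sp.water_band_depth_1400 * _gauss(wl, 1400.0, 25.0)
        + sp.water_band_depth_1900 * _gauss(wl, 1900.0, 35.0)
        + sp.clay_band_depth_2210 * clay_scale * _gauss(wl, 2210.0, 18.0)
        + sp.hc_band_depth * z_pah * _gauss(wl, sp.hc_band_center, sp.hc_band_width)
    )
    return baseline * (1.0 - darkening) - bands


def generate_spectrum(
    sample: SampleRecord, config: GeneratorConfig, seed: int | None = None
) -> list[Spectrum]:
    """Replicate scans for one sample (multiplicative scatter + noise)."""
    sp = config.spectral
    rng = _sample_rng(config.seed if seed is None else seed, sample.sample_id)
    shape = spectrum_shape(sample, config)
    spectra = []
    for rep in range(1, sp.replicates + 1):
        scatter = 1.0 + sp.scatter_sd * rng.standard_normal()
        noise = sp.noise_sd * rng.standard_normal(shape.size)
        values = np.clip(shape * scatter + noise, 1e-4, 1.5)
        spectra.append(Spectrum(sample.sample_id, GRID_1NM.copy(), values, replicate_id=rep))
    return spectra


def spectra_matrix(
    samples: Sequence[SampleRecord], config: GeneratorConfig, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate-averaged spectra as (wavelengths, samples × channels)."""
    rows = [
        average_replicates(generate_spectrum(s, config, seed)).reflectance
        for s in samples
    ]
    return GRID_1NM.copy(), np.asarray(rows)


def make_fixture(
    config: GeneratorConfig, outdir: str | Path, tp_form: str = "ratio_capped"
) -> dict[str, Path]:
    """Write a self-consistent three-file bundle to ``outdir``.

    ``concentrations.csv`` (samples + soil properties), ``spectra.csv``
    (replicated scans, wide dialect) and ``indexes.csv`` (ground-truth risk
    indexes recomputed from the generated concentrations).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = generate_samples(config)
    paths = {
        "concentrations": outdir / "concentrations.csv",
        "spectra": outdir / "spectra.csv",
        "indexes": outdir / "indexes.csv",
    }
    write_sample_table(samples, paths["concentrations"])
    all_spectra: list[Spectrum] = []
    for s in samples:
        all_spectra.extend(generate_spectrum(s, config))
    write_spectra(all_spectra, paths["spectra"])
    profiles = compute_profiles(samples, tp_form=tp_form)
    profiles_to_frame(profiles).to_csv(paths["indexes"], index=False)
    return paths


# ---------------------------------------------------------------------------
# Flat key=value config files (CLI)
# ---------------------------------------------------------------------------

_SPECTRAL_PREFIX = "spectral."


def config_to_text(config: GeneratorConfig) -> str:
    """Serialise a config to flat ``key = value`` lines."""
    lines = []
    for key, value in asdict(config).items():
        if key == "spectral":
            for sk, sv in value.items():
                lines.append(f"{_SPECTRAL_PREFIX}{sk} = {sv}")
        elif key == "composition_profile":
            for abbr in COMPOUND_ORDER:
                lines.append(f"composition.{abbr} = {value[abbr]}")
        else:
            lines.append(f"{key} = {value}")
    return "\n".join(lines) + "\n"


def config_from_text(text: str) -> GeneratorConfig:
    """Parse a flat ``key = value`` config; missing keys keep defaults."""
    base: dict[str, object] = {}
    spectral: dict[str, object] = {}
    composition: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key.startswith(_SPECTRAL_PREFIX):
            spectral[key[len(_SPECTRAL_PREFIX):]] = _coerce(value)
        elif key.startswith("composition."):
            composition[key.split(".", 1)[1]] = float(value)
        else:
            base[key] = _coerce(value)
    config = GeneratorConfig(
        **base,  # type: ignore[arg-type]
        **({"composition_profile": composition} if composition else {}),
    )
    if spectral:
        config = replace(config, spectral=replace(config.spectral, **spectral))  # type: ignore[arg-type]
    return config


def _coerce(value: str) -> object:
    try:
        f = float(value)
    except ValueError:
        return value
    return int(f) if f.is_integer() and "." not in value and "e" not in value.lower() else f
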