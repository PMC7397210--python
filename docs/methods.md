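# Methods

This note documents the models, conventions and design choices behind
`pahscreen`, in the order the pipeline runs them.

## Risk indexes

All indexes operate on total measured concentrations of the 16 US-EPA
priority PAHs in µg kg⁻¹ dry soil and assume 100% bioavailability.  That
is deliberately conservative: the package implements a *first* screening
tier whose job is to rule areas out, not to quantify site-specific risk.

**Hazard quotient / index.**  `HQ_i = C_i / MPC_i` with the Polish soil
screening values (100 µg kg⁻¹ for Napht, BaA, BbF, BkF, BaPyr, DahA;
200 µg kg⁻¹ for Anth, Ch, IndPyr, BPer).  `HI` sums HQ over exactly these
10 regulated compounds — the six unregulated PAHs never contribute, by
hard rule rather than option.

**Toxic units.**  `TU_i = C_i / PNEC_i` with per-compound predicted
no-effect concentrations (assessment-factor-derived, most-sensitive-species
values taken as given constants; their derivation is out of scope).
`TUm = Σ TU_i` over all 16 compounds is the concentration-addition mixture
model, appropriate because PAH toxicity to soil organisms is dominated by
a shared narcotic mode of action.

**Toxic pressure.**  The response-addition combination
`TPm = 1 − Π(1 − TP_i)` needs per-compound pressures bounded to [0, 1],
with the Dutch maximum permissible concentrations (MPC_NL) as the effect
level.  The exact single-compound transfer function is a genuine free
choice, and the package exposes two:

* `ratio_capped` (default): `TP_i = min(C_i / MPC_NL_i, 1)` — the simplest
  bounded reading of "screening value as the effect level".  It saturates
  linearly and is the most conservative of the two.
* `log_logistic`: `TP_i = 1 / (1 + (MPC_NL_i / C_i)^(1/β))` with β = 0.4
  by default — a saturating potentially-affected-fraction curve of the
  kind used in species-sensitivity-distribution frameworks, with
  `TP = 0.5` at `C = MPC_NL` and `TP(0) = 0`.

The chosen form is recorded in every output row (`tp_form` column).  With
the capped-ratio default, TPm saturates quickly for multi-compound
contamination: a sample can be "low toxicity" by TUm and "high risk" by
TPm.  This is a property of the response-addition model under a
conservative per-compound form, not a bug; the log-logistic form gives
lower mixture pressures at the same concentrations.

**Toxic equivalents.**  `TEQ = Σ C_i · TEF_i` with the standard
benzo[a]pyrene-relative potency factors (TEF = 1 for BaPyr and DahA, then
order-of-magnitude steps 0.1 / 0.01 / 0.001).  TEQ is screened against a
ladder of guideline values (15, 100, 200, 600, 1000, 2000, 4000,
10 000 µg kg⁻¹) drawn from different national frameworks; 600 µg kg⁻¹ is
the human-health safety value used for the headline binary screen.  The
4000 µg kg⁻¹ rung is carried in the ladder as conventionally printed even
though no single named guideline anchors it.

**Classification.**  Every scheme is a strictly increasing breakpoint list
with one label per interval.  Intervals are closed on the left and open on
the right, so `HI = 10` is "moderate risk" and `TPm = 0.25` is "low risk".
The underlying rating tables print overlapping range labels ("1–10",
"10–100") without resolving ties, so a single documented convention was
required; left-closed was chosen so that a value *reaching* a threshold
always escalates.

**Below-detection values** are accepted as given numbers.  No LoD/2
substitution is applied by default because no substitution rule is part of
the index definitions; callers can preprocess the table if their QC policy
differs.

**Descriptive statistics** (`summarize`) report Min, LQ, Mean, Median, UQ,
Max, CoV, skewness and kurtosis per variable.  Quartiles use linear
interpolation between order statistics; CoV is `100·sd/mean` with the
n−1 sample standard deviation; skewness and kurtosis are the standard
moment ratios (g1, excess g2).  These conventions are fixed so summaries
are reproducible; other quartile rules differ by at most a few percent at
n ≈ 74.

## Source diagnostics

Three stable isomer ratios are computed as `a/(a+b)`: Fln/(Fln+Pyr),
BaA/(BaA+Ch), IndPyr/(IndPyr+BPer).  Threshold sets follow the
conventional literature scheme: petrogenic below 0.4 / 0.2 / 0.2,
combustion above 0.5 / 0.35 / 0.5, with liquid-fossil-fuel (or "mixed" for
BaA/Ch) bands in between.  The 0.4 lower bound for Fln/(Fln+Pyr) is a
conventional assumption rather than a universal constant; all thresholds
are overridable per call.  Boundary values go to the upper category (same
left-closed convention as the risk schemes).  The per-sample verdict is
the majority coarse category (petrogenic / combustion / mixed) over the
defined ratios; ties report "mixed"; a zero denominator marks that ratio
"undefined" and drops it from the vote.

## Spectral processing

Spectra are reflectance factors on 350–2500 nm.  Acquisition conventions:
replicate scans (default 5) are averaged pointwise; variable-resolution
instrument grids are linearly interpolated to the integer 1 nm grid (2151
channels).  Values slightly above 1 are legal (white-reference panels are
not perfect reflectors); the container accepts (0, 1.5].

Preprocessing operators and their conventions:

* **Moving average**, default segment 5.  Edge points use the window
  truncated to the grid (shrunken windows) so every operator is
  grid-preserving and spectra stay aligned across samples.
* **SNV**: per-spectrum standardisation to mean 0 / sd 1 with the n−1
  denominator; exactly invariant to affine transforms of the spectrum, so
  it removes multiplicative scatter and offset.
* **Savitzky-Golay first derivative**, default window 11 / polynomial
  order 2 — standard soil-spectroscopy practice; the defaults are
  config-exposed and recorded in model metadata because no single
  convention exists.  Units are reflectance per nm; edges use a polynomial
  fit on the truncated window.
* Operators act on reflectance as acquired.  An optional log10(1/R)
  apparent-absorbance transform exists but is off by default; the
  screening models are trained on reflectance.

Chains serialise to a compact text form (`"ma:5|snv"`) that round-trips
losslessly and is stored beside every trained model, so prediction always
re-applies the training preprocessing.

## Chemometrics

**PCA** is plain mean-centred SVD (scikit-learn backend) used for
exploration; on realistic soil spectra PC-1 carries almost all variance
because broadband albedo dominates.

**PLS class prediction.**  Index values are first mapped to ordinal class
numbers under their scheme; PLS regression (scikit-learn NIPALS,
no scaling) then treats the class number as a numeric target.  Continuous
predictions are rounded to the nearest whole number — halves away from
zero, a documented choice where "nearest" is ambiguous — then clipped to
the classes present in training (a prediction falling on a class absent
from training snaps to the nearest present class; exact ties snap down).
Binary models use 0/1 encoding, which puts the decision point at 0.5 after
rounding.  Regressing an ordinal code and rounding is statistically
unconventional (ordinal logistic regression would be the textbook tool)
but is retained as a fidelity choice: it is the procedure screening
practitioners actually run in chemometrics packages, and the point of the
pipeline is to evaluate that procedure.

**Validation** is full cross-validation, interpreted as leave-one-out (its
standard meaning in chemometrics software): every sample is predicted by a
model fitted on the remaining n−1.  When the latent-variable count is not
forced, it is chosen by minimum RMSECV over 1…10; the cap is a
config-exposed default and the per-count RMSECV curve is kept on the
model.  Model fitting is deterministic; only data generation and
permutation controls take seeds.

**Important wavelengths** are reported as maximal contiguous intervals
where |regression coefficient| exceeds the q-quantile of all
|coefficients| (default q = 0.9).  With sparse coefficient vectors a zero
quantile would flag the whole grid, so the zero-coefficient channels are
excluded in that degenerate case; q = 0 explicitly returns the full grid.

**TEQ threshold suite**: one independent binary model per guideline rung;
rungs that leave one side of the split empty are skipped with a logged
notice and reported "n/a".

## Synthetic data

The generator reproduces the statistical structure the analysis exploits,
not soil physics:

* `log10 Σ16PAH ~ N(3.1, 0.8)` — median ≈ 1250 µg kg⁻¹, and the
  ~3×10² … 3×10⁵ µg kg⁻¹ range observed in heavily pressured agricultural
  regions sits within ±3 sd.  Exact quantile matching is not attempted.
* Per-compound concentrations are `total × fractions`, with fractions
  drawn from a Dirichlet around a fixed combustion-type mean profile
  (concentration parameter 600).  This single mechanism fixes both the
  HMW dominance (≈80% of mass in ≥4-ring compounds) and the isomer-ratio
  centres (0.58 / 0.43 / 0.52, with spreads comparable to field
  variability).  Independent per-compound log-normals were rejected
  because they cannot control the ratios.
* `log10 C_org` is drawn jointly with `log10 Σ16PAH` at correlation 0.9
  (r² ≈ 0.8 on the log-log scale), around a median of ≈12 g kg⁻¹.
* Texture is loamy sand (sand ≈ 72 ± 8%, clay ≤ 6%), pH_KCl ≈ 5.2 ± 0.6,
  TN proportional to C_org.
* Spectra: a flat sandy-soil baseline rising from ≈0.12 to ≈0.47,
  multiplied by `(1 − 0.30·z_Corg − 0.25·z_PAH)` (log-scaled contents
  normalised to [0, 1]) — the broadband darkening with organic carbon and
  contamination; minus Gaussian absorption bands at 1400 and 1900 nm
  (water), 2210 nm (clay-scaled), and a hydrocarbon band at 1700 nm whose
  depth is `0.015·z_PAH` — three times the additive noise sd (0.005), the
  signal-to-noise regime the recovery tests assume.  Replicates share the
  shape and differ by ±2% multiplicative scatter plus noise.

Seeding: sample i is drawn from a stream keyed `(seed, 1, i)`, so
extending a dataset leaves earlier samples bit-identical; spectra use
streams keyed `(seed, 2, crc32(sample_id))`, so they depend on the sample
but not on how many samples exist.

**What passing tests do and do not show.**  The generator's spectra carry
the PAH signal through exactly two mechanisms (broadband darkening and one
overtone band).  Real spectra entangle texture, iron oxides, moisture and
instrument effects, and their PAH signal is indirect (via organic matter).
Synthetic-recovery accuracies (&ge;90% for the binary TUm and TEQ screens at
signal-to-noise 3, collapse to the majority rate with the signal removed)
therefore validate the *pipeline* — preprocessing, model fitting,
validation and reporting — not the field performance of VIS-NIR screening,
which can only be established on real paired data.

## Problem sizes and numerical choices

The default study size is 74 samples with 5 replicate scans, matching the
survey design the package emulates; tests and the acceptance script use
that size, with smaller n only for I/O smoke tests.  Leave-one-out
selection over 10 latent-variable counts on a 74 × 2151 matrix fits in a
few seconds.  Mixture sums are plain sequential summation (16 terms;
compensated summation would be noise here).  The response-addition product
accumulates in float64 and is exact to ~1e-15 for 16 factors.  Degenerate
inputs fail loudly: zero-variance targets, constant spectra under SNV,
single-class binary fits and empty replicate sets all raise with context.

## Known limitations

* The capped-ratio TP default makes TPm saturate faster than
  SSD-based toxic-pressure implementations; per-compound class shares are
  sensitive to this choice, which is why the form is configurable and
  recorded in outputs.
* No bioavailability correction, no probabilistic SSD fitting, no
  instrument transfer or splice correction, no spatial interpolation —
  all are beyond the screening tier this package implements.
* Multiclass accuracy on ordinal targets degrades when middle classes are
  thin; the binary screens are the recommended deliverable, matching how
  the method performs in practice.
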