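# Methods

## Dose-rate model and fitting

Each tissue's absorbed-dose rate after a ¹⁷⁷Lu-DOTATATE infusion is modelled
as a biexponential Ḋ(t) = C₁e^{at} + C₂e^{bt} with both rate constants
negative, in hours post injection. The model captures the three observed
morphologies: an uptake phase that peaks at a finite time (tumour,
C₂ < 0, fast component more negative), a rapid early washout superimposed
on a slow component (bone marrow) and near-monoexponential clearance
(kidney). Only effective kinetics are modelled — no decomposition into
physical decay and biological clearance.

Fitting four parameters to four samples is exactly determined and strongly
multimodal, so the optimiser runs from a deterministic grid of decay-pair
starts (nine magnitudes geometric between 1/(10·t_max) and 10/t_min, all
pairs, amplitudes by linear solve for each pair), refines each with bounded
least squares (scipy `least_squares`, trust-region reflective) and keeps the
best optimum. Shape constraints are built into the parametrisation: washout
uses C₁, C₂ ≥ 0; the uptake shape uses C₂ = −v·C₁ with v ∈ [0, 1] (so
Ḋ(0) ≥ 0) and b = a − e^q < a. Fits are canonicalised slow-component-first
(a ≥ b). A fit with relative residual below 1e−8 is treated as an exact
interpolant and stops the start scan. Residuals are unweighted by default
(a relative-weighting option exists); the reported fit statistic is the
Pearson correlation r between fitted and observed sample values. There is
no wall-clock or RNG dependence anywhere in the fit, so identical series
give identical fits.

Tie-breaks and degenerate inputs: a pure monoexponential is representable
either by C₂ ≈ 0 or by b ≈ a; both reproduce the curve and no attempt is
made to prefer one. All-zero series and series shorter than four points are
rejected.

## Quantification

* **Concentration to dose rate.** Local absorption of the mean emitted
  electron energy (Eₑ = 147 keV/decay, absorbed fraction φₑ = 1, photons
  neglected): Ḋ = C·φₑ·Eₑ·k, where k = 10⁶ · 1.602176634e−16 · 3600 · 1000
  converts (MBq/g)(keV/decay) to Gy/h; 1 MBq/g ≈ 0.08479 Gy/h. k is derived
  from SI constants and is not configurable.
* **Recovery coefficient.** RC(d) = 1/(1+(a/d)^b) fitted by nonlinear least
  squares to measured/true concentration ratios of phantom spheres
  (default diameters 10–31 mm). The fit needs at least two distinct
  diameters and non-constant ratios; the start value of a is the diameter
  whose ratio is closest to 0.5 (the sigmoid's fixed point RC(a) = 1/2).
* **Hybrid tumour quantification.** C(t) = C_SPECT,24h/RC(d) ·
  A_net(t)/A_net(24 h): the partial-volume-corrected SPECT concentration
  anchors the absolute scale and the background-subtracted planar
  activities supply the shape. Because a small object's measured
  concentration *underestimates* the truth by the factor RC < 1, the
  correction divides by RC; a `pve_mode="multiply"` compatibility flag
  applies the multiplicative form instead for pipelines that fold RC into
  the calibration the other way. Background subtraction scales the
  background ROI activity by the ROI-size ratio and clamps negative net
  activities to zero with a warning (noise can push a faint tumour
  negative; failing hard would discard usable series).
* **Bone marrow.** Two-compartment model: Ḋ_BM(t) = A_low/m_low·φₑEₑ·CF·k +
  A_low·S_BM←low + A_high·S_BM←high — a concentration-based self-dose term
  from the low-uptake planar area (calibration factor CF, default 3.2) plus
  S-value cross-dose terms from the low- and high-uptake areas. m_low and
  the two S-values are study-specific and enter as mandatory inputs; the
  synthetic generator's defaults (m_low = 10 kg, S_BM←low = 5e−6,
  S_BM←high = 5e−5 Gy/(MBq·h)) are plausible magnitudes only.

## Interval doses and enhancement

Interval doses use the exact antiderivative per component with
e^{λ·∞} = 0; infinity is symbolic, never a large number, so partition
additivity holds to floating precision. "28 d" is fixed at exactly 672 h —
the interval bookkeeping mixes hours and days and a single canonical hour
scale avoids drift. Intervals are half-open [t₁, t₂) by convention
(irrelevant to the integrals).

A radiosensitizer window W with a scalar RBE gives the enhancement dose
ED = D(0,∞) + (RBE−1)·D(W); TNED = ED_tu/ED_nt. ED is affine in RBE with
slope D(W), hence TNED/TND = (1+(RBE_tu−1)f_tu)/(1+(RBE_nt−1)f_nt) with f
the window dose fraction — the package verifies this identity against the
three-integral route on random instances. Cohort summaries default to the
median of per-patient ratios; the ratio of cohort medians is a different
statistic (91 vs ~67 for the total-dose TND of marrow at the default
calibration) and is never silently substituted. Default RBE scenarios:
tumour 2, normal tissue ∈ {1, 1.5, 2}; default window grids: starts
{0, 6, 24} h, stops {28 d, ∞}. RBE < 1 is rejected unless explicitly
allowed (a sensitizer is not expected to protect tissue). A degenerate
(zero-width) window in a scan returns TNED = TND.

No biologically effective dose (BED/EQD2) or cell-survival modelling is
attempted: RBE is a plain scalar multiplier on absorbed dose.

## Synthetic cohort

The generator emulates ROI/VOI-level measurement records, not images. The
default median kinetics are solved analytically from the cohort summary
targets (median totals 0.30 / 4.5 / 27.3 Gy per 7.4 GBq; tumour uptake
peaking near 12 h with ≈86% of its dose in 24 h–28 d; marrow 62% and kidney
76% after 24 h; ≥98.5% of every tissue's dose within 28 d):

| tissue | shape | a (1/h) | b (1/h) | slow fraction | total (Gy) |
|---|---|---|---|---|---|
| tumour | uptake (C₂ = −C₁) | −0.00625 | −0.35 | — | 27.3 |
| bone marrow | washout | −0.009 | −0.20 | 0.76712 | 0.30 |
| kidney | washout | −0.0105 | −0.08 | 0.97268 | 4.5 |

Patient variation is log-normal around these medians (σ_log of the total
dose 0.55 / 0.20 / 0.30 for tumour / marrow / kidney, matching the
published order-of-magnitude ranges; σ_log = 0.12 on the rate constants),
and measurement noise is multiplicative log-normal with configured CV
(default 5%) — both keep samples strictly positive, as imaging
quantification errors are proportional. Planar records embed the true net
activity plus a size-scaled background with its own slow clearance, so
background subtraction recovers the net exactly at zero noise; the SPECT
record is the true 24 h concentration suppressed by the true recovery
coefficient; the marrow activity series are constructed so the
two-compartment formula reproduces the true dose rate. With zero noise the
full pipeline therefore round-trips the ground-truth kinetics to numerical
tolerance, which the tests exercise.

What the generator does **not** emulate: spill-in/spill-over between
regions, organ overlap in planar projections, deadtime, reconstruction
artefacts, patient motion, or inter-time-point registration error. Passing
tests demonstrate the correctness of the quantification → fit → integrate →
enhance chain under the assumed kinetic model and proportional noise; they
do not validate the model against real acquisitions.

## Problem sizes and numerics

Default runs use 17-patient cohorts at the grid {2, 24, 48, 168} h; the
cohort-calibration check uses 200 patients; fit-quality statistics use 100
seeded replicates; property checks compare the closed-form integrals with
adaptive quadrature on 1000 random curves. All randomness flows through
numpy `SeedSequence` children of a single seed. The window-fraction curve
constructors solve for the slow rate with Brent's method on a bracketing
grid (the window fraction is unimodal in the rate, so the slow-side root is
taken); fractions above the unimodal maximum (e.g. >0.852 for a
monoexponential in 24 h–672 h) are correctly reported as unreachable.

## Known limitations

* Kidney concentration series are taken as input; no conjugate-view planar
  quantification is included.
* Only the left-kidney-style single concentration series is modelled; no
  organ-mass individualisation beyond what the input series already embeds.
* The two-compartment marrow constants are not identifiable from the
  package's inputs; results in absolute marrow dose scale directly with
  them.
* Four-point fits interpolate noise exactly (r ≈ 1 by construction); the
  fit statistic is a consistency check, not evidence of model adequacy.
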