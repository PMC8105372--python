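# Methods

This note documents the models implemented in `ins2p`, the conventions and
defaults they use, and what the synthetic test bed does and does not show.

## Exposure dosimetry

**Footprint geometry.** The fiber output (core diameter 105 µm, NA 0.15,
1470 nm) is modelled as a cone of half-angle `asin(NA / n)` in each medium.
The beam propagates from the tip through immersion gel and the cranial
window, refracting at flat interfaces parallel to the brain surface by
Snell's law; Fresnel losses and scattering are neglected. The beam diameter
where it meets the surface is the minor axis of the elliptical footprint;
obliquity stretches the major axis by `1 / sin(θ)`, where θ is the beam's
incidence angle (to the surface plane) *in the medium just above the
surface*. With the package defaults — incidence 35°, tip-to-surface
distance 150 µm, gel n = 1.34, window n = 1.51 and 100 µm thick, tissue
n = 1.36 — the model gives a 244.5 × 167.9 µm ellipse. Tip distance,
window thickness and refractive indices are configuration parameters: their
true experimental values are not fully determined, so the footprint
reproduces the reported 246 × 168 µm ellipse approximately (here within
1%), not exactly. The exposed area is `π·major·minor/4`; radiant exposure
(J cm⁻²) times area gives the per-pulse energy in µJ.

**Water absorption and penetration depth.** The packaged table
`water_extinction_synthetic.csv` is a coarse digitization of the water
extinction spectrum k(λ) between 1300 and 2000 nm, assembled for this
package from widely tabulated absorption-coefficient values (it is a
synthetic stand-in for the classic tabulations, accurate to a few percent
near 1470 and 1875 nm). k is interpolated log-linearly in λ and converted
to the Lambert absorption coefficient `α = 4πk/λ` (cm⁻¹). A value printed
elsewhere as "24,815 cm⁻¹" for water at 1470 nm is read with a European
decimal comma, i.e. 24.815 cm⁻¹ — the only reading consistent with the
≈400 µm penetration depth quoted alongside it, since the 1/e penetration
depth is `10⁴/α` µm (403 µm for α = 24.815 cm⁻¹; 372 µm for 26.875 cm⁻¹ at
1875 nm).

**Fluence field.** One pulse's energy is spread over the surface as an
elliptical Gaussian whose 1/e² diameters equal the footprint axes — a
stated convention, since the relation between the reported ellipse and the
beam profile is not defined elsewhere — normalized so the plane integral
equals the pulse energy (peak fluence `2E/(π wₓ w_y)`, exactly twice the
nominal average radiant exposure). Depth attenuation is Beer–Lambert,
`exp(−αz)`. Immersion-gel absorption is deliberately *not* subtracted,
matching how the nominal surface energy densities were defined. The field
conserves energy at every depth (checked by quadrature in the tests) and is
monotone along each principal axis and in depth.

## Trace analysis

**Normalization.** ΔF/F₀ = (F − F₀)/F₀ per trial, with F₀ the mean raw
fluorescence over the absolute window [3.0, 4.5) s (stimulus at 5 s). A
time t maps to frame `floor(t × rate)`; windows are half-open on the right,
so at 30.9375 Hz the baseline covers the 47 frames 92–138. The five trials
of an energy are averaged pointwise; the peak is the maximum of the
averaged trace in the response window, default [onset, onset + 2 s) — the
response-window length is a package convention (transients begin at onset
and decay within ~2 s) since no value is stated elsewhere. No smoothing is
applied before peak extraction.

**Responder criterion and the σF convention.** A cell is a responder at an
energy iff SNR = peak/σF strictly exceeds k = 3. Two readings of σF are
implemented:

- `pooled` (default): σF is the pooled standard deviation of the
  *single-trial* ΔF/F₀ baselines. The threshold then reflects single-trial
  noise while the peak is read from the n-trial average, so averaging
  tightens the criterion by √n.
- `averaged`: σF is the baseline SD of the averaged trace itself.

The choice matters more than it looks. The `averaged` reading is
scale-free: peak and σF shrink together under trial averaging, so on pure
noise the maximum over a ~62-frame response window exceeds 3σ for ~8–12% of
ROIs *regardless of the noise level* (Monte-Carlo at 10,000 ROIs: ≈0.12;
pinned as a regression value in the tests). A criterion with a 12%
intrinsic false-positive rate cannot produce responder fractions as low as
the few percent observed at sub-threshold doses, and it would swamp
ground-truth recovery on synthetic data. The pooled reading has a
negligible false-positive rate at the same settings and is therefore the
default; the averaged reading remains available behind
`sigma_mode="averaged"`. Which convention produced the original published
counts cannot be determined from the text; the package documents its
default rather than asserting it.

Degenerate cases are explicit: σF = 0 raises (never silently classifying),
a single trial yields a zero SD with a degeneracy flag, and F₀ ≤ 0 is an
error. Frame-rate presets 30.9375 Hz (default) and 30.25 Hz are both
accepted; they differ by <0.1 s across a recording and do not move any
window by more than one frame.

**Baseline stability and outliers.** Baseline time courses normalize each
recording's mean F₀ (across ROIs) to the first recording, with SEM
propagated on the same scale; the first entry is exactly 1. Outlier removal
for amplitude aggregation uses the boxplot rule with Tukey hinges (median
of each half, the overall median included in both halves when n is odd) and
1.5×IQR fences; with fewer than four values the rule is a no-op with a
warning.

## Population statistics

Responder fractions are percentages per experiment; cross-experiment
summaries are unweighted means ± SEM (each experiment is one observation).
Multiplicity partitions responders into cells responding to exactly one,
exactly two, or three-to-four energies; cells missing a call at any energy
are excluded listwise with a warning. The amplitude dose–response uses the
highly responsive subset (cells responding to all of 0.47/0.58/0.70
J cm⁻², regardless of the lowest dose), reports mean peak ΔF/F₀ ± SEM per
energy and normalizes to the highest energy (100%).

Hypothesis tests: a pooled-variance two-sample t-test (Welch behind a
flag; zero-variance inputs give t = 0, p = 1 for equal means and an
infinite-t flag otherwise), and a one-way repeated-measures ANOVA computed
from the within-subject sum-of-squares decomposition with df
(k−1, (k−1)(n−1)), followed by paired t-tests with Bonferroni correction
(p multiplied by the number of performed comparisons — adjacent dose pairs
by default — capped at 1). The RM-ANOVA is cross-checked in the tests
against `statsmodels` `AnovaRM` and against the F = t² identity for two
conditions; the t-test's type-I error is calibrated on 10,000 null
simulations.

## Spatial mapping

Fields of view are aligned by shifting each experiment so the spatial
distribution maximum of its multiple (3×+4×) responders sits at the origin.
"Maximum" is operationalized as the per-axis fitted normal mean (mode =
mean for a normal); a kernel-density mode is available behind
`center_mode="kde"`. No rotation is applied, mirroring a fixed horizontal
fiber orientation. Per-axis fits report μ, sample SD σ and
FWHM = 2√(2 ln 2)·σ ≈ 2.3548σ. The central region is the
exposure-footprint-sized ellipse (246 × 168 µm, horizontal, boundary counts
as inside); coordinates are µm in the image convention (origin top-left, y
downward). Depth is carried through but the membership test is planar.
Whether published FWHM summaries are per-experiment means or pooled-fit
values is ambiguous; both are computable here (the pipeline reports pooled
fits of the aligned overlay; per-experiment fits are one `groupby` away).

## Synthetic data generator

The generator emulates the study design: by default 250 cells uniform in a
300 × 300 µm FoV at depths 96–255 µm, a 246 × 168 µm Gaussian footprint
centered in the FoV (configurable offset per experiment), four energy
densities × 5 trials, 30 s recordings at 30.9375 Hz with the stimulus at
5 s. Each cell draws an activation threshold θ from a log-normal
distribution; it responds at an energy iff the local fluence (surface
Gaussian × Beer–Lambert at its depth) reaches θ — which makes responder
sets nested across energies by construction — with peak amplitude
`A_max(1 − exp(−(f − θ)/s))` (A_max = 0.30, s = 0.15 J cm⁻²). Transients
are double-exponential, τ_rise = 0.08 s, τ_decay = 0.4 s (GCaMP6f-like
convention; no kinetics are claimed from data), normalized to unit peak so
the configured amplitude *is* the true peak ΔF/F₀ up to frame sampling
(sampled-peak factor 0.9997 at the default rate). Raw fluorescence is
`F₀·bleach·(1 + A·g(t))` plus Gaussian noise of SD `noise_sd·F₀`
(σF ≈ 0.01 by default; Poisson mode available); bleaching is an optional
per-recording exponential on F₀, off by default. Everything is
deterministic under the seed, and every generated quantity is kept as
ground truth.

**Calibration and its limits.** The threshold distribution (median
0.17 J cm⁻², log-SD 0.5) was calibrated once against the published
recruitment ladder, and the limits of that calibration are worth stating.
Under a pure Gaussian-beam threshold model the recruitment gain per unit
log-energy is bounded by the beam-to-FoV area ratio
(`π wₓ w_y / 2A_FoV`), so across a 2× energy range no parameter choice
reproduces a rise from ~4% to ~40% of the FoV while also keeping the
spatial patterns: the published steepness implies recruitment physics
beyond static beam fluence (e.g. lateral heat diffusion), which is exactly
the future-work boundary of this package's scope. The defaults give a
monotone, saturating ladder (≈18/23/27/30% in expectation), central-vs-
peripheral responsiveness of roughly 80% vs a few percent, central-share
ordering 3×+4× > 2× > 1×, and a multiple-responder FWHM of ≈125 µm. Tests
and the acceptance script therefore validate *recovery of the generator's
own ground truth* and the qualitative figure-level patterns, never the
published percentages themselves.

What the generator does not emulate: motion artifacts, neuropil
contamination, hemodynamic occlusion, temperature effects on indicator
brightness, glial waves, or spatially correlated noise. Passing tests show
the analysis is correct under the stated model, not that the model captures
every property of real recordings.

**Movie rendering.** Cells can be rendered as Gaussian blobs into a
16-bit multi-page TIFF with a label-image ROI mask; each blob is scaled so
the mean over its own mask pixels equals the cell's fluorescence, making
mean-over-mask extraction the exact inverse up to quantization (and blob
overlap for nearly touching cells). Out-of-range intensities clamp with a
warning.

## Numerical conventions

- Sample SDs use ddof = 1 throughout (two points [−10, 10] → σ = 14.142,
  FWHM = 33.30).
- Strict inequality at the SNR threshold: a peak at exactly 3σ is a
  non-responder.
- Ellipse membership is closed (boundary inside).
- Frame windows are half-open; indices floor(t × rate).
- All lengths µm, areas cm², exposures J cm⁻², energies µJ, α cm⁻¹.

## Problem sizes used in validation

The test suite and the acceptance script run the full pipeline at the
default study scale (250 cells × 4 energies × 5 trials × 928 frames, a few
seconds per experiment), use 10,000-ROI Monte-Carlo runs for false-positive
and type-I calibration, and a 20,000-cell noise-free recruitment run for
population-shape checks — sizes at which the sampling error of the checked
quantities is small compared to the asserted margins.

## Known limitations

- The footprint model is geometric (no Fresnel losses, no scattering, no
  Monte-Carlo photon transport); its defaults are fitted, not measured.
- The water table is a synthetic digitization; α values inherit a few
  percent of digitization uncertainty.
- The recruitment model cannot reproduce the steepness of the published
  dose–response (see calibration above) and carries no temperature or
  time-course physics.
- RM-ANOVA assumes sphericity (no correction is applied), matching the
  simple within-subject decomposition it implements.
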