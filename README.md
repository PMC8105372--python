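# ins2p

Dosimetry and calcium-response analysis for **infrared neural stimulation
(INS)** experiments imaged with two-photon GCaMP microscopy.

INS excites neural tissue with trains of pulsed infrared light (here
1470 nm, 250 µs pulses at 200 Hz for 500 ms) absorbed by tissue water — a
photothermal mechanism that needs no exogenous chromophore. When such
stimulation is combined with in-vivo two-photon imaging of a fluorescent
calcium indicator (GCaMP6f) in cortical Layer 2/3, each recording yields
per-cell fluorescence time series from which one wants to know: *which
cells responded, how strongly, at which radiant exposures, and where in the
beam path?* `ins2p` is the analysis pipeline for that question, written for
experimenters running INS dose–response studies and for anyone who wants to
reproduce or stress-test this class of analysis without access to raw
recordings.

## What it computes

**Trace analysis.** Raw fluorescence F is normalized per trial to
ΔF/F₀ = (F − F₀)/F₀, with F₀ the mean over a fixed pre-stimulus window
([3.0, 4.5) s for a stimulus at 5 s). Trials are averaged, and a cell is a
**responder** at an energy density when

    SNR = (ΔF/F₀)_peak / σ_F > 3,

with the peak taken over a 2 s post-onset window and σ_F the baseline noise
SD (pooled over single-trial baselines by default; see `docs/methods.md`
for why that convention matters).

**Dosimetry.** The oblique, divergent fiber output is projected through
gel and cranial window onto the brain surface (cone + Snell refraction),
giving an elliptical footprint (≈246 × 168 µm, area ≈3.25 × 10⁻⁴ cm²),
per-pulse energies (radiant exposure × area), the water absorption
coefficient α(λ) = 4πk/λ interpolated from a packaged extinction table, the
1/e penetration depth 10⁴/α µm, and a 3-D fluence field (surface elliptical
Gaussian × Beer–Lambert in depth).

**Population results.** Responder fractions per energy density with
cross-experiment mean ± SEM; multiplicity (cells responding to 1, 2, or
3–4 of the four energies); amplitude dose–response of the highly
responsive subset normalized to the top dose; two-sample t-tests and
one-way repeated-measures ANOVA with Bonferroni post-hocs; boxplot-rule
outlier removal.

**Spatial mapping.** Fields of view aligned on the distribution maxima of
multiple responders, per-axis normal fits with FWHM = 2√(2 ln 2)·σ, and
central-vs-peripheral classification against the exposure ellipse.

**Synthetic experiments.** A generator with full ground truth — cells with
log-normal activation thresholds recruited wherever local fluence reaches
threshold (responder sets are nested across energies by construction),
GCaMP6f-like transients, noise, optional bleaching, optional rendering to
TIFF movies + ROI masks — so every stage is testable with no downloads.

## Worked example

```python
from ins2p import SyntheticConfig, simulate_experiment, analyze_trace_array
from ins2p.dose_response import responder_fractions, normalized_dose_response

sim = simulate_experiment(SyntheticConfig(seed=42))      # 250 cells, 4 doses x 5 trials
calls = analyze_trace_array(sim.traces, sim.energies,
                            roi_ids=sim.cells["roi_id"].to_numpy())
calls.insert(0, "experiment_id", "demo")

_, fractions = responder_fractions(calls)
print(fractions.to_string(index=False))
```

```
 energy_density  mean_pct  sem_pct  n_experiments
           0.35      17.2      0.0              1
           0.47      23.2      0.0              1
           0.58      26.4      0.0              1
           0.70      29.6      0.0              1
```

17.2% of cells cross the 3σ criterion at 0.35 J cm⁻², rising monotonically
and saturating toward 29.6% at 0.70 J cm⁻² — within sampling error of this
simulation's ground-truth recruitment (18.4/24.8/27.2/31.6%). The amplitude
dose–response of the cells responding to all three upper doses:

```python
print(normalized_dose_response(calls, remove_outliers=True).round(4).to_string(index=False))
```

```
 energy_density  mean_peak    sem  n_cells  normalized_pct
           0.35     0.1095 0.0115       58         44.9607
           0.47     0.1722 0.0103       58         70.7041
           0.58     0.2131 0.0083       58         87.4757
           0.70     0.2436 0.0065       57        100.0000
```

i.e. mean peak ΔF/F₀ grows with dose and is expressed as a percentage of
the top-dose response (100%).

The same stages are available from the shell:

```sh
ins2p dosimetry --fiber-core 105 --na 0.15 --wavelength 1470 --angle 35
ins2p simulate --seed 42 --out run/          # traces.csv, cells.csv, ground_truth.csv
ins2p analyze run/traces.csv --out run/calls.csv
ins2p run --seed 42 --out-dir run/           # all stages + report.json
```

## Layout

| Module | Contents |
| --- | --- |
| `ins2p.dosimetry` | fiber/path specs, footprint projection, absorption, fluence field |
| `ins2p.traces` | ΔF/F₀, trial averaging, 3σ classification, baseline stability, outliers |
| `ins2p.dose_response` | fractions, multiplicity, normalized curves, t-tests, RM-ANOVA |
| `ins2p.spatial` | FoV alignment, normal fits/FWHM, ellipse membership |
| `ins2p.synth` | synthetic experiments with ground truth, movie rendering |
| `ins2p.pipeline` / `ins2p.cli` / `ins2p.config` | orchestration, YAML config, CLI |

`docs/methods.md` documents the models, conventions, calibration choices
and their limits.
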