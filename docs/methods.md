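# Methods

`omiflim` implements a label-free optical metabolic imaging (OMI) analysis
for fluorescence-lifetime microscopy of macrophages, together with a
synthetic TCSPC data generator so that every stage can be exercised and
validated without microscope data. This note records the models, the
defaults and their rationale, the numerical choices, and what the synthetic
data does and does not emulate.

## Decay model and forward simulation

Each pixel of a TCSPC acquisition is a histogram of photon arrival times,
modeled as a two-component exponential decay convolved with the instrument
response function (IRF):

    I(t) = alpha1 * exp(-t/tau1) + alpha2 * exp(-t/tau2) + C,
    alpha1 + alpha2 = 1,  tau1 < tau2.

For NAD(P)H the short component is the free coenzyme and the long component
the protein-bound form; for FAD the assignment is reversed. C is a constant
background per bin (ambient light, dark counts); no richer detector model
is used.

**Time axis.** 256 bins spanning a 12.5 ns window (80 MHz laser repetition,
typical of femtosecond Ti:sapphire-class sources), i.e. ~48.8 ps/bin. Both
are configurable; the acquisition literature rarely reports the bin width,
so the window is an explicit, documented choice rather than a measured
value.

**IRF.** A Gaussian kernel parametrized by FWHM (default 260 ps, the
measured width of a typical second-harmonic reference) and peak position
(bin 25). The kernel is normalized to unit sum and its interpolated FWHM
matches the construction parameter to within one bin.

**Normalization convention.** `model_decay` scales the IRF-convolved decay
so that the decay-component counts *collected within the measurement
window* sum exactly to the `amplitude` parameter. Simple truncation of the
linear convolution would silently lose ~1% of the tail at tau2 = 2.5 ns;
renormalizing makes amplitude the expected in-window photon count, an
exactly conserved quantity that the noiseless-rendering tests check to
machine precision.

**Incomplete decay.** By default no periodic wrap-around is applied: with
tau2 <= 6 ns and a 12.5 ns window the wrapped tail is below 1% of
amplitude. A `wrap` option adds a single-period fold-back in both the
renderer and the fitter; the two must be set consistently.

**Photon noise.** Rendered cubes draw independent Poisson counts per bin
with the model expectation as mean. Index-of-dispersion tests confirm
variance/mean within [0.9, 1.1] over 1000+ pixels.

## Synthetic scenes and cohorts

Cells are non-overlapping disks (uniform radius in a configurable range)
on a dark background. The mCherry reporter renders as a filled mask —
the membrane-localized appearance of a CAAX-tagged reporter is *not*
emulated, which is acceptable because segmentation operates on intensity
only. GFP renders only inside TNF-alpha-positive cells. Optional Gaussian
noise around a background level (default mean 10, SD 2 on a signal of
1000) is added to both reporter channels.

Each cell draws true decay parameters per channel from group
distributions. Baseline (TNF-alpha-negative) means: NAD(P)H tau1 = 0.4 ns,
tau2 = 2.5 ns, alpha1 = 0.7, 5000 photons/pixel; FAD tau1 = 0.4 ns,
tau2 = 2.0 ns, alpha1 = 0.6, 2500 photons/pixel — literature-typical
free/bound values, giving a baseline redox ratio of ~0.67. TNF-alpha-
positive cells shift the NAD(P)H distribution in the directions observed
for proinflammatory macrophages: tau1 and tau2 x0.85, alpha1 x1.15, and
NAD(P)H photon budget x0.65 (so the redox ratio drops ~15%). FAD endpoints
are left unshifted, matching the absence of a consistent FAD change in
that comparison. The 15% magnitudes are free parameters with these
documented defaults, not measured values.

**Cohort structure.** Cells are nested in larvae nested in experiment
days. All systematic effects act multiplicatively on the endpoint
distribution means — equivalently, additively on the log scale:

    log mean_icl = log base + log treat_mult + day_d + b_l + c_i,

with day shifts `day_d ~ N(0, day_sd)` (default 0.03), larva random
effects `b_l ~ N(0, larva_sd)` (default 0.05) shared by both lifetimes and
photon budgets, a whole-cell factor `c_i ~ N(0, cell_sd)` (default 0.05)
shared by a cell's lifetimes, plus independent per-parameter jitter
(`component_cv`, default 0.03). This single log-additive structure means a
log-transformed Gaussian GLM is correctly specified for the generated
data, and the intraclass correlation of log endpoints within a larva has
the closed form larva_sd^2 / (larva_sd^2 + cell_sd^2), exact when the
per-parameter jitter is zero. Because the larva factor multiplies both
channels' budgets equally it cancels in the redox ratio; larva-level
clustering of the redox ratio therefore comes only through segmentation
and fitting noise. Draws are clipped to the fitter's parameter bounds;
with the default means and SDs clipping essentially never binds.

One master seed drives everything; each field of view gets a child seed
recorded in its metadata sidecar, and rendering seeds derive from the
field seed.

## Per-pixel fitting

The fitter recovers (amplitude, alpha1, tau1, tau2, offset) per pixel by
weighted least squares against the IRF-convolved model, with Neyman
weights 1/max(count, 1) — the weighting classic TCSPC packages use. A
Poisson maximum-likelihood objective is available as an option and serves
as an independent cross-check in tests.

Numerical strategy: amplitude and offset enter the model linearly, so they
are solved exactly (weighted normal equations, clipped nonnegative) for
every trial shape, and a bounded trust-region-reflective solver optimizes
only (alpha1, tau1, tau2). This separable formulation minimizes the same
objective as the full five-parameter problem but converges in far fewer
iterations; a brute-force grid oracle in the test suite confirms the
solver's objective beats every grid point. Convolutions run through a
cached FFT. Tolerances: 1e-8 on objective and step, at most 400 residual
evaluations.

Defaults (all configurable):

- bounds tau1 in [0.05, 1.0] ns, tau2 in [1.0, 6.0] ns, alpha1 in [0, 1],
  amplitude and offset >= 0 — the disjoint lifetime ranges enforce the
  tau1 < tau2 convention by construction;
- initialization tau1 = 0.4 ns, tau2 = 2.5 ns (NAD(P)H) or 2.0 ns (FAD),
  alpha1 = 0.7; offset from the mean of the 10 pre-peak bins; amplitude
  from the residual total count;
- background exclusion at >= 500 total photons per (binned) pixel — a
  stand-in for the per-image manual threshold an operator would choose;
- spatial binning off by default; odd k x k sum-binning pools neighboring
  photons before fitting while reporting on the original grid (field edges
  are zero-padded, so a one-pixel border loses part of its pool);
- non-convergent pixels are marked invalid and excluded from per-cell
  averages, mirroring manual quality control.

Recovery at the default photon budgets: noiseless 10^6-photon pixels
return all shape parameters to better than 1%; at 5000 photons with the
260 ps IRF the median relative error of tau_m is ~4-5%. A single
exponential fit with the two-component model leaves the component split
degenerate; tau_m remains identifiable and accurate.

## Segmentation and TNF-alpha classification

The in vivo whole-cell path is implemented: rescale the mCherry image by
its brightest pixel, threshold at 0.15, fill holes, label 8-connected
components, remove components under 25 pixels, relabel consecutively.
Rescale-by-max makes the result invariant to global intensity scaling.
The interactive steps of the original workflow (object declumping, manual
mask edits, the nucleus-propagation cytoplasm pipeline for cultured cells)
are deliberately replaced by these explicit, reproducible rules; touching
cells are not split. A user-supplied label image can override the
automatic masks. For infected-wound fields, a bacteria mask (threshold
default 0.6 x image max, bacteria being the brightest mCherry objects) is
subtracted from every cell before relabeling.

A cell is TNF-alpha-positive if any pixel inside it exceeds the GFP
detection threshold. "Any signal" needs a numeric detection floor: the
default is median + 5 x MAD (normal-consistent) of the background pixels.
A 3-sigma floor would be exceeded by ~0.1% of pure-background pixels, so
an any-pixel rule at 3 sigma would miscall essentially every cell in a
large field; 5 sigma keeps the expected number of false pixels per field
near zero while still detecting single-pixel true signal (reporter signal
is ~500 sigma above background). The proportional-area variant reports
|pixels above both GFP and mCherry thresholds| / |pixels above the
mCherry threshold|.

## Optical endpoints

- Redox ratio per pixel: ORR = I_N / (I_N + I_F), using the *fitted
  decay-component counts* (amplitude) as intensity, so the background
  offset does not contaminate the ratio. ORR is computed per pixel and
  then averaged per cell; this differs from a ratio of cell-summed
  intensities and is the documented choice.
- Per-cell endpoints: arithmetic means over the valid fitted pixels of
  each cell for ORR and both channels' tau_m, tau1, tau2, alpha1. Cells
  with zero valid pixels are dropped with a warning; cells with fewer than
  a handful of valid pixels are retained (the statistics layer can filter
  on `n_valid_pixels`).
- OMI index per cell: ORR_i/<ORR> + tauM_N_i/<tauM_N> - tauM_F_i/<tauM_F>,
  with <.> arithmetic means over a declared normalization group (default:
  all cells pooled across the compared conditions; configurable, and
  recorded in the output metadata). The group mean of the OMI index is 1
  by construction, which the suite checks to 1e-12.

## Cohort statistics

Every data point is a cell. Endpoints are analyzed with Gaussian general
linear models: treatment indicators, experiment day as a fixed blocking
factor, and an interaction when two experimental factors are present.
Inference uses CR1 cluster-robust standard errors clustered by larva —
sandwich covariance with cluster-summed scores, small-sample factor
G/(G-1) x (n-1)/(n-k), and a t reference on G-1 degrees of freedom, where
G is the number of larvae. With every cell its own cluster this reduces
exactly to HC1. Estimated group means are computed at balanced day weights
(each day weighted equally) with 95% CIs; pairwise group contrasts are
reported as differences, or as fold-change ratios with back-transformed
CIs when the endpoint was natural-log transformed. Whether to log an
endpoint is a recorded per-run choice guided by the residual diagnostics
(residual-vs-fitted and normal-quantile tables; a gross-heteroskedasticity
flag trips when the residual SD doubles across fitted-value quartiles).
No multiplicity adjustment is applied anywhere. Mixed/random-effects
models are out of scope; larva-level outcomes can be analyzed with the
same fixed-block GLM without clustering.

Calibration at the defaults: nominal 95% intervals for an injected
fold-change of 0.85 achieve ~95% empirical coverage over 500 simulated
cohorts of 16 larvae x 30 cells, and the robust SE exceeds the classical
SE essentially always at intraclass correlation 0.5.

## Problem sizes used in the checks

The test suite and examples run on scaled-down scenes chosen to exercise
every code path at desk scale: 64-96 pixel fields, 6-10 cells of radius
3-5 px, 2 days x 3 larvae x 10 cells for full-pipeline cohorts, and
table-level (geometry-free) simulation for the 500-replicate coverage
studies. Full-scale 256 x 256 fields with hundreds of cells per condition
run through exactly the same code, only slower.

## What passing tests do and do not show

The generator emulates the statistical skeleton the analysis assumes:
Poisson photon counting under an IRF-convolved bi-exponential, disk-shaped
cells with group-shifted endpoint distributions, and the day/larva/cell
nesting. It does not emulate scattering or depth attenuation, spectral
bleed-through, membrane-localized reporter morphology, cell motion or
overlap, afterpulsing beyond a constant offset, or autofluorescent
confounders such as elastin and lipofuscin. Passing tests therefore
demonstrate that the pipeline is a faithful, well-calibrated
implementation of the stated analysis — that it recovers what was injected
— not that the analysis is robust to every complication of real tissue
imaging. Group-difference magnitudes from real experiments are not
reproduced here; only the directions of the injected effects are
meaningful, and those are free parameters of the generator.
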