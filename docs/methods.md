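# Methods

`qlisa` models a bead-based multiplex immunoassay read out in a
variable-height microfluidic channel, together with the image analysis
and statistics needed to go from micrographs to concentrations.  This
note records the models, their assumptions, the tunable parameters, and
the design choices made where more than one reasonable option existed.

## 1. The device model

A variable-height channel is a wide shallow slit (width w ≈ 3 mm,
length L ≈ 20 mm, heights of a few µm) whose ceiling height h(x)
decreases monotonically from inlet to outlet.  A bead of diameter d
travels until h(x) = d and traps there, so bead populations of distinct
diameters sort passively into distinct detection bands, one analyte per
band.

**Height profile.** The default profile is linear between the inlet and
outlet heights; this is the minimal monotone model and makes trap
positions analytically invertible,

x(d) = L · (h_in − d) / (h_in − h_out).

Profilometer traces can be supplied instead (`kind="measured"`), in
which case heights are interpolated piecewise-linearly and inverted the
same way.  Tie rule at the boundaries: d ≥ h_in is excluded at the
inlet; d ≤ h_out passes through — both comparisons inclusive toward
non-trapping, since a bead exactly equal to the local height cannot
enter (respectively always fits).

**Flow.** With width ≫ height the lubrication (Hele-Shaw/wide-slit)
approximation applies, and the channel's hydraulic resistance is

R = 12 μ ∫₀ᴸ dx / (w·h(x)³),  Q = ΔP / R.

For a linear profile the integral has the closed form
(L/(h_in−h_out))·(1/h_out² − 1/h_in²)/2, which the tests verify against
adaptive quadrature to 1e−9 relative; a uniform slit reduces exactly to
plane Poiseuille Q = w h³ ΔP/(12 μ L).  Because the integrand goes as
h⁻³, the resistance concentrates where the channel is shallowest: the
flow rate is governed almost entirely by the outlet height, and raising
the inlet height does little.  The package encodes the resulting design
rule — outlet height ≥ 1.5 µm, below which band formation becomes
impractically slow and beads aggregate — as `design_check`.  No
particle transport or band-formation kinetics are modelled.

**Capacity.** Bands are ~500 µm wide and need ≥ 500 µm of clear channel
between them, so a channel of length L holds
⌊L / (band_width + separation)⌋ bands — 20 for the default 20 mm
channel.  This assumes one band plus one gap per analyte; denser
packings (e.g. no trailing gap) would give one more band and are not
used.

## 2. The synthetic imaging model

No raw instrument images are available, so all image-level code is
validated against a generative model with exact ground truth.  One field
of view (default 1344 × 1100 px, 0.454 µm/px — a 1.4 MP monochrome
camera behind a 10× objective) consists of an epi-illuminated frame and
one fluorescence frame per detection channel.

* **Beads** — truncated-normal diameters (±3 sd) with configurable mean
  and CV (defaults 4.5/2.8/1.0 µm at 3–5% CV, the three assay bead
  populations), placed uniformly at random without overlap, ~200 per
  FOV.  Disks are rendered with an area-preserving antialiased rim
  (`edge_width_px`, default 0.25 px).  The narrow rim reflects that no
  optical PSF is modelled; it keeps the masked statistic within ~2% of
  the generative per-bead intensity at this bead size.
* **Epi frame** — beads attenuate a bright background
  (1000 − 400·coverage), under a smooth multiplicative illumination
  field (default tilt of +20%/−15% across x/y) and Gaussian read noise
  (sd 10).  Bead polarity (dark on bright) is configurable.
* **Fluorescence frames** — each bead carries a concentration-dependent
  quantum-dot signal given by a Hill/Langmuir response
  r(c) = baseline + r_max·c^hill/(k_half^hill + c^hill)
  (defaults: baseline 50, r_max 2000, k_half 2000 pg/mL, hill 1 — a
  simple saturating sandwich-assay response; the real curve shape is
  unknown, and any monotone saturating form serves the same purpose).
  The fluorophore's emission is distributed over detection channels by a
  crossover matrix (own-channel gain 1.0, 2% bleed elsewhere), plus
  bead-type-specific autofluorescence (the 2.8 µm beads contribute
  80 RFU in the 525 nm channel, emulating their strong autofluorescence
  there), background 20 and Gaussian noise sd 5 (optional Poisson shot
  noise via `poisson_gain`).
* **Biological/technical variation** — multiplicative log-normal
  factors: per bead (CV 10%), per FOV (CV 5%) and per replicate run
  (CV 5%).  These set the realistic scale of the intra-assay CVs (~3–6%
  at high signal) and of the blank spread that determines the LOD.
* **Artifacts** — untethered debris (Poisson-many bright specks, mean
  30/FOV, intensity 200–2000, radius 1–3 px) appear only in the
  fluorescence frames, never in the epi frame: exactly the off-mask
  signal the masked statistic must ignore.  Physical carryover places
  smaller bead types in an upstream band with expectation
  `carryover_fraction` (default 5%) of the band's bead count; carryover
  beads carry their own analyte's true signal and autofluorescence.
* **Determinism** — every run derives sub-seeds from the master seed
  through `SeedSequence([seed, kind, index, replicate])` counters, so
  any subset of a run is independently reproducible and identical
  configs give bit-identical images.

What the generator does *not* emulate: diffraction/PSF blur, spectral
emission curves (the crossover matrix abstracts them), bead stacking or
aggregation, flow dynamics during band formation, and matrix effects
beyond the noise/attenuation knobs.  Passing tests therefore demonstrate
the correctness and robustness of the *pipeline*, not instrument-level
accuracy on real micrographs.

## 3. Image quantification

The per-FOV statistic is RFU/Bead Area = f/b, where B′ is the binary
bead mask from the epi frame, b = ΣB′, and f = Σ(B′ ⊙ F) with F the
background-corrected fluorescence frame.  Only bead-tethered signal
contributes; off-mask debris changes the statistic by exactly zero.

Steps and defaults:

1. **Pseudo-flat-field** the epi frame: divide by an estimate of the
   illumination surface, then rescale to the original mean.  The default
   estimator is a least-squares degree-2 polynomial surface, which
   removes smooth gradients essentially exactly including at the image
   borders; the classical large-sigma Gaussian-blur estimator
   (sigma = min(H, W)/4) is available as `method="gaussian"` but is
   biased within ~sigma of the borders, where any symmetric blur
   flattens a ramp.
2. **Binarize** with Otsu's global threshold by default
   (`polarity="beads_dark"`); a local-mean threshold (window radius
   15 px, offset 0) is available for uneven scenes but will speckle on
   pure background, so it should be combined with size filtering.
3. **Background-correct** each fluorescence frame by subtracting the
   median of off-mask pixels (or of the lowest-decile pixels when no
   mask is supplied), clamped at zero.  Median-of-off-mask makes the
   statistic exactly linear in fluorescence gain.
4. **Aggregate** per band: per-FOV statistics averaged, SEM = sd/√n
   across FOVs, and — when a 0 pg/mL control run is supplied — the
   control band mean subtracted channelwise *after* per-FOV averaging.
   Negative control-subtracted values are preserved so downstream
   statistics remain unbiased.

An empty mask raises an explicit error rather than returning NaN.

## 4. Bead sizing

Confocal stacks are reduced by maximum-intensity projection, thresholded
with a local-mean filter, labelled with 8-connectivity, filtered by
minimum area and border exclusion, and summarized as equivalent-circle
diameters d = 2√(area/π) with sample (n−1) sd and CV.  The local-mean
window radius must exceed the particle radius (beads at confocal
sampling of 0.1 µm/px are ~14–23 px in radius, so radius 40–45 px is
used in the analyses); a window smaller than the bead hollows out the
particle interiors.  The exact histogram heuristic of common "default"
auto-thresholds is not reproduced — local mean is equivalent in effect
on high-contrast bead images and is parameterized.  Touching beads are
not watershed-split; the simulated fields place beads with clearance
instead.

## 5. Assay statistics

* **Standard curve** — four-parameter logistic
  r(c) = d + (a−d)/(1+(c/c₀)^b) fitted by least squares (slope b > 0
  bounded; a fit with d ≤ a, i.e. non-increasing response, is refused),
  with linear-in-log10 fallback for short series.  The inverse is the
  closed-form 4PL inverse; signals at or beyond the asymptotes return
  explicit below/above-range markers rather than extrapolating.
* **LOD** — blank mean + 3 × sample sd (10 blanks by convention; a
  warning is issued otherwise), converted to concentration through the
  inverse curve.
* **CVs** — intra-assay: sample sd/mean of same-day replicates (n = 3
  convention); inter-assay: arithmetic mean of daily CVs.  Sample
  (n−1) sd is used throughout; with n = 3 the n-vs-(n−1) choice
  matters, and the sample convention is the conservative one.
* **Crossover t-test** — two-sample two-tailed Student's t with pooled
  variance by default (Welch optional), applied to per-FOV band values
  of an analyte at 0 pg/mL with vs without a second analyte present.
* **Method comparison** — OLS trend of test vs reference plus mean bias
  against the identity line.

## 6. Reagent design

Reagent amounts follow the fixed molar-ratio chain used for every assay
in the panel: capture antibody 5×, detection antibody 10× the maximum
analyte moles, quantum dots 2× the detection moles, with
analyte moles = c_max · V / MW.  Antibody molar mass defaults to 150 kDa
(whole IgG) when unspecified and the output flags the assumption.

## 7. Problem sizes and numerical choices

The analyses and acceptance checks run at full camera resolution
(1344 × 1100) with 200 beads/FOV, 3 FOVs per measurement, 3 replicates
and 10 blanks for calibration runs (≈ 1 min on one CPU), 6 FOVs per arm
for the carryover t-test, and n = 300 beads per population for sizing.
Unit and property tests use reduced fields (160 × 200, ~25 beads) for
speed; the rendering model is scale-free so nothing but statistical
power changes with field size.

Tolerances: closed-form vs quadrature flow resistance 1e−9 relative;
band-position/height round trip 1e−9 µm; 4PL self-recovery on exact data
1e−6 relative; duplicate-bead resolution 0.01 µm.  The local-threshold
comparisons use a 1e−9·range tolerance against the mean filter's own
float error, which otherwise selects exactly-flat background.

## 8. Known limitations

* The flow model is quasi-static lubrication theory; it says nothing
  about how long bands take to form beyond the monotone dependence of Q
  on geometry.
* The generator's crossover gains, autofluorescence levels and noise
  parameters are plausible defaults, not calibrated instrument values.
* Bead trapping is treated as deterministic at the diameter-matching
  position; band width in the simulator is a per-FOV abstraction, not a
  packing model.
* Real epi/fluorescence frames may be misregistered; the pipeline
  assumes they share a field of view exactly.
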