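# Methods

## Model

A broad-band MT Z-spectrum is modeled as the sum of two symmetric spectral
components centered at zero offset:

    y(x) = (1 − F_r) · S_f(x; LW_f) + F_r · S_r(x; LW_r)

with `y` the normalized *saturation amount* — 1 on resonance, approaching 0
at ±30 kHz — and `S` a Lorentzian `LW²/(LW² + 4x²)` by default (a Gaussian
`exp(−4 ln2 · x²/LW²)` with the same FWHM convention is available per pool
for model selection, so the comparison varies shape rather than width
parameterization). The constraint `F_f + F_r = 1` is substituted rather than
fitted, leaving three independent variables `(F_r, LW_f, LW_r)`. Apparent
relaxation times follow from `T2 = 1/(π·LW)`; they are reported in µs.

Assumptions worth keeping in mind:

- **No exchange kinetics.** The model is phenomenological; the fitted `T2`
  values absorb exchange rates, T1, and the saturation-pulse bandwidth, and
  so differ from multi-echo T2 measurements (the free-pool value especially,
  since the ~400 Hz pulse bandwidth floors the fittable narrow linewidth).
- **Symmetry.** `y(x) = y(−x)`; B0-shift asymmetries are out of scope.
- **Labeling convention.** The model is invariant under exchanging the two
  components, so the broader fitted component is *always* reported as the
  restricted pool. Without this rule, maps could swap pool identity voxel to
  voxel. An equal-width optimum is flagged as degenerate (the fractions are
  then unidentifiable even though their sum is still 1).

## Offset schedule

The default schedule has 53 points spanning ±30 kHz, symmetric about 0, with
increments shrinking from 3000 Hz at the outer limits to 50 Hz near
resonance. The exact interior layout is a design choice; we build it from
banded increments (outer edge → step, stepped inward until the next band):
30000→3000, 12000→2000, 4000→1000, 2000→400, 800→100, 300→50, plus 0. The
constructor asserts the 53-point count. The fit is insensitive to the
precise interior layout: a 31-point symmetric subsample chosen
log-uniformly in |x| (always retaining 0 and ±30 kHz) reproduces noiseless
maps to well under 1% — the basis of the reduced-sampling claim, and the
reason subsampling uses log spacing (the two linewidths span roughly two
decades).

## Normalization

Measured stacks are converted voxel-wise to `y(x) = 1 − S(x)/S_ref`. Two
references are supported:

- `outermost` (default for measured data): mean of the two ±30 kHz volumes,
  where MT perturbation is minimal. Documented bias: the model predicts
  `y(30 kHz) ≈ 0.05–0.08 · F_r > 0`, so this reference slightly compresses
  fitted `F_r`.
- `separate`: an unsaturated reference volume. The synthetic pipelines
  (round-trip recovery, cohorts) use the phantom's noise-free baseline `s0`
  as this reference, because the outermost-reference bias would otherwise
  dominate the ≤1e−4 recovery checks by construction.

Normalized values are clipped to [−0.05, 1.05] with the clipped count
reported in QC; voxels with non-positive reference are excluded from the
mask.

## Fitting

Bounded trust-region least squares (`scipy.optimize.least_squares`, `trf`)
with analytic Jacobian. Bounds: `F_r ∈ [0, 0.6]` (brain tissue),
`LW_f ∈ [50, 5000]` Hz (lower bound = schedule resolution floor),
`LW_r ∈ [2000, 100000]` Hz. Tolerances `ftol = xtol = gtol = 1e−12`,
`max_nfev = 200`; parameter scales (0.1, 100, 10⁴) match the disparate
magnitudes. Initialization is data-driven: `F_r⁰` is read off the spectrum
near |x| = 5 kHz (free peak decayed, broad component not), each linewidth
starts at twice the |x| where `y` first crosses the corresponding
half-maximum level, falling back to (0.2, 400 Hz, 16 kHz). This avoids
swap-label local minima; an adversarial label-swapped start still converges
to the correctly labeled optimum. Non-convergence never raises — the voxel
is recorded in QC with best-so-far parameters.

Goodness of fit is NRMSD = RMS residual / range(y_meas). Range was chosen
as the normalizer because it reproduces the expected magnitude (a few
percent) for unit-range spectra; mean- or RMS-normalization would be
equally defensible conventions.

Lineshape selection fits all four {L,G}×{L,G} pairs from the same
initialization and ranks by SSE (non-converged → ∞). On
Lorentzian-generated brain-like spectra with σ = 0.01 noise the
Lorentzian–Lorentzian pair wins essentially always.

## Synthetic data

Phantoms assign each labeled voxel a tissue preset and generate
`S(x) = s0·(1 − y(x)) + ε`, `ε ~ N(0, σ·s0)`, deterministically from a seed.
Presets cover healthy GM/WM group means, deep gray structures, and
lymphoma/glioma tissue, stored as `(F_r, T2,f, T2,r)` and converted to
linewidths. CSF is MT-inactive: flat `y` except direct saturation near
resonance, modeled as a single Lorentzian of width 400 Hz (the pulse
bandwidth). Built-in geometries: `two-disc` (GM annulus around WM disc) and
`cohort-slice` (GM ribbon, WM core, paired CSF ventricles, optional tumor
insert), default 64×64; tests and the acceptance script use 12–32 px
matrices, which keeps the full loops to seconds without changing any
per-voxel property.

Noise is Gaussian on signal, not Rician: at the SNR of averaged ROI spectra
the difference is negligible and Gaussian keeps least squares correctly
specified.

Cohorts emulate an aging study: WM `F_r = 0.355 − 0.00165·age` plus
per-subject scatter, GM parameters age-independent, ages defaulting to the
nine reference-cohort ages (33–71, mean 47.3; tiled for multiples of nine,
uniform otherwise), sexes cycling the 7M/2F pattern with no modeled sex
effect. The scatter default `subject_sd = 0.0155` is derived once from the
reference regression regime: with the nine reference ages, residual SD
≈ 0.0155 is what makes R² ≈ 0.66. Draws outside (0, 0.6) are resampled.

What the phantoms do **not** emulate: partial-volume mixing at tissue
boundaries, B0/B1 inhomogeneity, motion/ghosting artifacts, left–right
asymmetries, or anatomically realistic geometry. Passing round-trip tests
therefore shows the estimator is correct and stable under the stated noise
model, not that acquisition-physics confounds are handled.

## Statistics

Tissue summaries use the arithmetic mean and sample SD (n−1), which matches
the published summary-cell convention. The age regression is ordinary least
squares with the classical two-sided t test (n−2 df) for the slope p-value.
Derived quantities: the WM/GM ratio of mean `F_r`, and the ratio of
regression-predicted `F_r` at two ages (70 vs 35 by default). Internal
values stay full precision; rounding (fractions 2 dp, T2 3 significant
figures) is applied only at the reporting layer.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run phantoms at 12–32 px, 50
model-selection replicates, 100-replicate Monte-Carlo checks, and cohorts of
9 and 90 subjects; every stochastic step is seeded (package default
20150313) and the acceptance script derives all sub-seeds from its `--seed`
argument. At n = 90 with the default per-subject scatter the regression
slope estimate carries ≈ 8% sampling error (one SE), so single-seed slope
values scatter accordingly; the intercept is much tighter.

## Known limitations

- Free-pool T2 is apparent only; it is compressed toward the schedule's
  resolution floor and should be interpreted relatively, not absolutely.
- The outermost-offset normalization slightly compresses `F_r`; use a
  separate unsaturated reference when one was acquired.
- Voxels where the two fitted widths coincide are degenerate for the
  fraction split and are only flagged, not regularized.
- No spatial regularization, partial-volume unmixing, or field-map
  correction.
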