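# zapped

Two-pool Lorentzian Z-spectrum fitting for quantitative magnetization-transfer
(MT) MRI of brain.

## The problem

Off-resonance saturation transfers magnetization between mobile ("free") water
protons and motion-restricted protons bound to macromolecules such as myelin.
Recording the on-resonance signal while stepping a saturation pulse over a
broad, symmetric range of offsets (±30 kHz) traces out a *Z-spectrum* whose
shape carries the relative sizes and apparent relaxation properties of both
proton pools — including the ultra-short-T2 restricted pool that is invisible
to conventional MR spectroscopy.

`zapped` fits each normalized Z-spectrum `y(x)` to a phenomenological
two-component model with three independent variables:

```
y(x) = F_f · LW_f² / (LW_f² + 4x²)  +  F_r · LW_r² / (LW_r² + 4x²),    F_f + F_r = 1
```

where `x` is the offset in Hz, `F_f`/`F_r` are the free/restricted pool
fractions, and `LW_f`/`LW_r` are the component full widths at half maximum.
Linewidths convert to apparent spin–spin relaxation times via
`T2 = 1/(π·LW)`. Exchange kinetics are deliberately not modeled; the fitted
T2 values are *apparent* (they fold in exchange rates, T1, and the ~400 Hz
saturation bandwidth, which floors the fittable free-pool width).

The package is for MR physicists and image analysts who want voxel-wise maps
of `F_f`, `F_r`, `T2,f`, `T2,r` (plus an NRMSD goodness-of-fit map) from 4-D
offset stacks, tissue-ROI estimates, lineshape model selection
(Lorentzian/Gaussian per pool), and cohort-level statistics such as the WM/GM
restricted-fraction ratio and the age regression of white-matter `F_r`.
Because scanner data cannot ship with the package, a synthetic-phantom module
generates signal stacks, tissue labels, and multi-subject aging cohorts with
known ground truth.

## Worked example

```python
import numpy as np
from zapped import (PoolParams, default_schedule, forward_zspectrum, fit_zspectrum,
                    make_cohort, CohortSpec, build_cohort_table, summarize_tissue,
                    fraction_ratio, age_regression, regression_age_ratio)

# fit one noisy white-matter spectrum on the 53-point ±30 kHz schedule
schedule = default_schedule()
wm = PoolParams.from_t2(0.28, 672.0, 23.4)          # F_r, T2,f [µs], T2,r [µs]
z = forward_zspectrum(wm, schedule)
z.values += np.random.default_rng(20150313).normal(0, 0.005, len(z))
fit = fit_zspectrum(z)
p = fit.params
print(f"F_r = {p.f_restricted:.3f}   T2,f = {p.t2_free_us:.0f} us   "
      f"T2,r = {p.t2_restricted_us:.1f} us   NRMSD = {fit.nrmsd:.3f}")

# simulate a nine-subject healthy cohort and summarize it
cohort = make_cohort(CohortSpec(seed=20150313), schedule)
table = build_cohort_table(cohort, schedule)
print(f"R (WM/GM)       = {fraction_ratio(table, 'WM', 'GM'):.2f}")
reg = age_regression(table, "WM")
print(f"F_r(age)        = {reg.intercept:.3f} {reg.slope:+.5f}*age   "
      f"(R^2 = {reg.r_squared:.2f}, p = {reg.p_value:.3f})")
print(f"F_r(70)/F_r(35) = {regression_age_ratio(reg, 70, 35):.2f}")
```

Output:

```
F_r = 0.278   T2,f = 667 us   T2,r = 23.0 us   NRMSD = 0.005
R (WM/GM)       = 1.65
F_r(age)        = 0.352 -0.00150*age   (R^2 = 0.74, p = 0.003)
F_r(70)/F_r(35) = 0.82
```

The single-spectrum fit recovers the generating white-matter parameters
(`F_r` 0.278 vs 0.28; apparent T2s within a few percent at this noise level).
The cohort summary reproduces the healthy-adult picture the model was built
around: restricted fraction roughly 1.65× higher in white than gray matter,
and a white-matter `F_r` that declines with age (the fitted slope scatters
around the generating −0.00165/year at n = 9).

## Command line

```bash
zapped simulate --geometry two-disc --preset GM-healthy,WM-healthy \
                --sigma 0.005 --seed 7 --out phantom/
zapped fit --stack phantom/stack.nii.gz --offsets phantom/offsets.csv \
           --labels phantom/labels.nii.gz --out maps/
zapped summarize --table cohort.csv --tissue WM
```

`zapped fit` writes one 3-D NIfTI per parameter map plus a mask and a QC
JSON (non-converged and clipped-voxel counts).

## Layout

- `zapped.model` — forward model, lineshapes, LW↔T2 conversions
- `zapped.sampling` — banded offset schedules, subsampling, CSV I/O
- `zapped.fitting` — normalization, bounded least-squares fits, maps, NRMSD
- `zapped.phantom` — synthetic phantoms, tissue presets, aging cohorts
- `zapped.stats` — tissue summaries, ratios, age regression, reports
- `zapped.reference` — published healthy-cohort reference values
- `zapped.io` / `zapped.cli` — NIfTI + sidecar I/O, command line

See `docs/methods.md` for the model assumptions, parameter defaults, and
numerical choices.
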