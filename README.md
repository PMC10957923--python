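# eisassay

Analysis pipeline for impedimetric biosensor assays: from electrochemical
impedance spectra, through Randles-equivalent-circuit fitting that extracts
the charge-transfer resistance (Rct), to the statistics that turn Rct into an
analyte concentration — semi-log calibration, limits of detection and
quantification, apparent binding constant, inter-electrode repeatability and
selectivity panels. A seeded synthetic-data generator replaces the
potentiostat, so the whole pipeline runs and is tested without instrument
files.

## The science

A faradaic impedimetric biosensor reads out target binding as an increase in
the charge-transfer resistance of a redox probe (ferro/ferricyanide) at the
electrode: bound analyte hinders the probe's access to the surface, and the
Nyquist semicircle grows. Spectra measured over 100 kHz–0.1 Hz (10 mV AC,
0.2 V DC) are modelled by a Randles circuit — solution resistance Rs in
series with the parallel combination of a constant phase element (CPE, the
non-ideal double layer) and the faradaic branch Rct + Z_W (Warburg diffusion):

```
Z(ω) = Rs + [ Z_CPE(ω)⁻¹ + (Rct + Z_W(ω))⁻¹ ]⁻¹
Z_CPE = 1/(Q(jω)ⁿ)        Z_W = W·coth(s)/s,  s = (jωτ)^φ   (bounded "open" form)
```

Parameters are estimated by complex nonlinear least squares (real and
imaginary residuals jointly, modulus weighting 1/|Z|²). Rct — the only
parameter proportional to analyte concentration — then feeds the assay
statistics:

* **Calibration**: ordinary least squares of Rct on log10(concentration),
  `Rct = slope·log10(c) + intercept`, with R² over a stated linear range.
* **LOD/LOQ**: either invert the blank-mean + 3·SD signal threshold through
  the calibration, or apply 3.3·σ_blank/slope in the log-concentration
  domain; LOQ = 3·LOD in both conventions.
* **Binding**: Langmuir isotherm `Rct(c) = R₀ + ΔR_max·c/(K_app + c)`; the
  half-saturation concentration K_app is the apparent (surface-density
  dependent) binding constant.
* **Repeatability**: inter-electrode RSD = 100·SD/mean (sample SD, n−1).
* **Selectivity**: per-condition means flagged against the blank + 3·SD
  threshold.

## Worked example

```python
import numpy as np
from eisassay import (RandlesParameters, ScenarioConfig, fit_randles, fit_semilog,
                      lod_blank_plus_3sd, simulate_dose_response, simulate_spectrum,
                      default_frequency_grid)
from eisassay.simulate import INTEGRIN_SEMILOG

# one noisy spectrum (1% proportional noise) and its circuit fit
params = RandlesParameters(rs=200, rct=11835, q=5e-6, n=0.9, w_r=2000, w_tau=10)
spec = simulate_spectrum(params, default_frequency_grid(10), noise_sigma=0.01, seed=42)
print(fit_randles(spec).summary())

# a simulated dose-response campaign: calibration and detection limit
cfg = ScenarioConfig(response=INTEGRIN_SEMILOG, concentrations=(1, 2, 4, 5, 10, 20),
                     replicates=3, n_blanks=3, noise_sigma=0.01, sigma_e=0.05, seed=7)
series, _ = simulate_dose_response(cfg)
cal = fit_semilog(series)
print(cal.summary())
lod = lod_blank_plus_3sd(series.blanks, cal)
print(f"LOD = {lod.lod:.2f} {lod.unit}, LOQ = {lod.loq:.2f} {lod.unit}")
```

prints

```
Randles circuit fit (CNLS)
  variant    : open_bounded
  weighting  : modulus
  converged  : True  (`ftol` termination condition is satisfied.)
  chi2 / dof : 0.00573481 / 116
  param        estimate        std err
  rs            199.362       0.300829
  rct             11876        34.6949
  q         5.02349e-06    2.65439e-08
  n            0.899286    0.000897264
  w_r           1340.68        283.279
  w_tau         5.54921        2.35208
  w_phi             0.5            nan

Semi-log calibration (ng/mL): Rct = 10867.2 * log10(c) + 3979.86  (R^2 = 0.9826, range 1-20 ng/mL, 18 points)
LOD = 0.67 ng/mL, LOQ = 2.02 ng/mL
```

The fitted Rct (11 876 ± 35 Ω) recovers the generating value (11 835 Ω plus
the 1% spectral noise); with 5% inter-electrode variability the refitted
calibration line (slope 10 867 Ω/decade, intercept 3 980 Ω) sits within 1%
of the generating line (10 944, 3 940), and the detection limit lands below
the 1 ng/mL low end of the linear range, as it should for usable assays.

The same operations are available from the shell:

```bash
eisassay simulate --config scenario.json --out run/ --full-spectra
eisassay fit --spectrum run/spectrum_c5_r0.csv --out fit.json
eisassay calibrate --doseresponse run/dose_response.csv --out cal.json
eisassay lod --doseresponse run/dose_response.csv --calibration cal.json --out lod.json
```

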