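# Methods

## Circuit model

The forward model is the Randles equivalent circuit of a faradaic
impedimetric sensor: electrolyte resistance `Rs` in series with the parallel
combination of a constant phase element and the faradaic branch
`Rct + Z_W`,

    Z(ω) = Rs + [ Z_CPE(ω)⁻¹ + (Rct + Z_W(ω))⁻¹ ]⁻¹ ,  ω = 2πf.

`Z_CPE = 1/(Q(jω)ⁿ)` models the double layer of an inhomogeneous
(screen-printed, nanoparticle-coated) electrode; `n = 1` recovers an ideal
capacitor. Two Warburg variants are implemented, because the circuit is
conventionally described with an "open" (bounded, reflective) element while
the low-frequency behaviour of such sensors is often summarised as a 45°
line, which is the semi-infinite signature:

* `open_bounded` (default): `Z_W = W·coth(s)/s`, `s = (jωτ)^φ`. Blocks at
  DC. Evaluated through `1/tanh`, which cannot overflow because
  `arg(s) = 90φ° ≤ 45°` keeps `Re(s) > 0`; for `|s| < 10⁻⁴` the Laurent
  series `coth(s)/s = 1/s² + 1/3 − s²/45` avoids 0/0.
* `semi_infinite`: `Z_W = W·(2πf)^(−1/2)(1 − j)`, constant −45° phase.

The Warburg exponent `φ` is fixed at 0.5 (the diffusive value) and excluded
from fitting unless explicitly freed; a free `φ` is rarely identifiable
together with a CPE exponent. Which variant a given instrument's fitting
software used is generally not reported, so neither variant claims to
reproduce any particular instrument's internal model; the variant is
recorded in every fit result.

Conventions: frequencies in Hz (descending, sweep order), impedance stored
as measured (`Im Z ≤ 0` in the capacitive region), ohms throughout (kΩ only
at display). The default grid spans exactly 100 kHz–0.1 Hz (the standard
protocol, 0.2 V DC / 10 mV AC), log-spaced with `points_per_decade` points
per decade plus the final endpoint (10/decade → 61 points).

## Parameter estimation (CNLS)

`RandlesModel.fit()` minimises the jointly weighted squared real and
imaginary residuals (2N entries — magnitude/phase stacking is avoided as
non-smooth near the real axis):

    chi²(θ) = Σ_k w_k [(ReZ_k − ReẐ_k)² + (ImZ_k − ImẐ_k)²]

with weights `modulus` (1/|Z_k|², default — equalises points across the
decades of |Z| a sweep spans), `unit`, or `proportional` (element-wise
1/value²). Optimisation uses `scipy.optimize.least_squares` (trust-region
reflective) with box bounds (`rs ∈ [0, 10⁵] Ω`, `rct ∈ [1, 10⁸] Ω`,
`q ∈ [10⁻¹², 10⁻¹]`, `n ∈ [0.5, 1]`, `w_r ∈ [0, 10⁸]`,
`w_tau ∈ [10⁻⁴, 10⁴] s`); `rct`, `q` and `w_tau` are optimised as log10
values, which conditions the problem across their many-decade ranges. The
`n ≥ 0.5` floor stops the CPE from absorbing the Warburg branch
(identifiability, not physics). Relative convergence tolerances default to
10⁻¹⁰; all tolerances (xtol/ftol/gtol) are set equal.

The starting point is geometric: `rs` from the high-frequency real
intercept, `rct` from the −Im apex (at the apex `Re Z − rs = rct/2` for an
ideal semicircle), `q` from the apex frequency via `ω_peak = 1/(rct·q)`,
`n = 0.9`, Warburg magnitude from the residual low-frequency real extent and
`τ = 1/(2πf_min)`. Apex detection applies a 3-point moving average and
requires candidate peaks to exceed 5% of the spectrum's real-axis span:
without this, 1% measurement noise can fake an interior −Im maximum at high
frequency where −Im is tiny, and the fit starts from garbage. A spectrum
with no qualifying interior maximum (flat, monotone, or semicircle fully
merged into the blocking tail) raises a degenerate-spectrum error rather
than guessing.

Optional multistart (`FitOptions.multistart > 1`) draws log-uniform ×[1/3, 3]
jitters around the start from a seeded generator and keeps the best chi² —
deterministic under a fixed seed. Non-convergence is recorded in the result
(`converged = False`), never raised silently; `extract_rct` refuses
non-converged fits.

Standard errors are asymptotic: the Jacobian at the optimum gives
`cov = (JᵀJ)⁻¹ · chi²/dof` with `dof = 2N − p`, mapped from log10 space by
the delta method (`se(p) = p·ln10·se(u)`). Reported ± values on published
fitted quantities may instead be across-electrode SDs; the package reports
both (fit stderr per spectrum, replicate SD per condition) and does not
claim to reproduce any publication's error bars.

### Identifiability limits

Not every parameter set is recoverable from a 100 kHz–0.1 Hz sweep, and the
recovery tests draw from the shapes the assay actually produces (clear
semicircle plus visible diffusion tail) rather than from the full bound box:

* if the bounded-Warburg transition `1/(2πτ)` lies below 0.1 Hz, only
  `W/√τ` is constrained by in-band data (`coth(s)/s ≈ 1/s` throughout);
* if the semicircle apex frequency `1/(2πrct·q)` falls at or below the
  Warburg transition, the two features merge and −Im has no interior
  maximum;
* if `W` is a percent-level fraction of `rct`, the chi² valley along the
  Warburg directions is flat and single-start convergence to 0.1% is not a
  meaningful demand.

The test draw keeps `τ ≤ ~1.4 s`, the apex ≥ ~30× the Warburg transition
frequency, and `W ∈ [0.1, 1]·rct`.

## Assay statistics

* **Semi-log calibration**: OLS of Rct on log10(c); every replicate enters
  as its own point (no pre-averaging), so replicate scatter is reflected in
  R². Blanks (c = 0) are never log-transformed and never enter the
  regression; they feed only LOD and panel thresholds. Zero/negative
  concentrations are rejected at construction.
* **LOD, blank + 3SD method**: threshold = mean(blanks) + 3·sd(blanks)
  (sample SD, n−1; ≥ 3 blanks required), inverted through the calibration:
  `LOD = 10^((threshold − intercept)/slope)`.
* **LOD, 3.3σ/slope method**: with a slope in Ω per *decade*, the literal
  quotient `3.3·σ_blank/slope` is an increment in log10-concentration, not
  a concentration — the formula is dimensionally ambiguous on a semi-log
  calibration. The least-assumptive reading is adopted: the increment is
  anchored at the lower edge of the linear range,
  `LOD = c_min · 10^(3.3σ/slope)`, and every result carries a note saying
  so. LOQ is stored as exactly `3·LOD` for both methods.
* **Langmuir binding**: weighted least squares of
  `Rct(c) = R₀ + ΔR_max·c/(K + c)` with `K` in log10 space; blanks enter as
  c = 0 points and pin the baseline. `K_app` is flagged as an extrapolation
  when the data do not span saturation. Whether a published apparent
  constant came from a Langmuir fit or another isotherm is usually
  unstated; Langmuir is the default reading here and no alternative
  isotherm is implemented.
* **Repeatability**: sample mean, SD (n−1), RSD = 100·SD/mean. The exact
  quotient is reported — e.g. moments 39.5 ± 4 kΩ give 10.13%, which
  publications may round to "ca. 11%"; the package never forces the rounded
  figure.
* **Condition panels**: per-group mean, SD, fold-over-blank, and a
  `detected` flag = mean > blank mean + 3·blank SD — deliberately the same
  3-SD rule as the LOD, for internal consistency. No hypothesis testing is
  performed (none is claimed by the assay design).

## Synthetic data

The generator emulates the statistical structure of the recorded assay, not
electrode physics (no binding kinetics, probe density or diffusion-layer
simulation):

* **Spectrum noise**: `Z_k·(1 + ε_k)`, `ε_k` complex Gaussian with i.i.d.
  components N(0, σ²/2); default σ = 0.01 (1%), instrument-like.
* **Electrode variability**: Rct multiplied by `exp(N(0, σ_e²))`; default
  σ_e = 0.10, matching the ~10–11% inter-electrode RSD of hand-made
  screen-printed strips. Only the aggregate RSD is observable, so the
  σ/σ_e split is a modelling choice, defaulted σ_e-dominated.
* **Response laws**: the printed semi-log calibration lines
  (10944·log10 c + 3940 for the integrin scenario; 5860·log10 c + 11400 for
  the vesicle scenario) and the Langmuir isotherm (K = 5.3 ng/mL,
  ΔR_max = 45 000 Ω, baseline 3 000 Ω) are the generating truths, so
  analysis closes the loop on the published equations.
* **Blanks**: the semi-log line does not extend to zero analyte, so the
  blank Rct is a separate config field, defaulting to half the response at
  the lowest calibrated concentration — low enough that the 3-SD threshold
  lands near the bottom of the linear range. No published blank Rct values
  exist; synthetic blanks make the detection limits order-of-magnitude
  plausible, not numerically reproducible. Absolute published LODs and R²
  values depend on unprinted blank SDs and raw scatter and are therefore
  exercised only as properties (monotonicity, method contracts), never as
  numeric targets.
* **Determinism**: every draw comes from a substream keyed by
  (seed, operation name, index) via `SeedSequence`, so outputs are
  bit-reproducible and independent of call order.
* **Base circuit**: Rs = 200 Ω, Rct = 2 kΩ (blank), Q = 5 µS·sⁿ, n = 0.9,
  W = 2 kΩ, τ = 10 s — kilo-ohm-scale Rct and a visible diffusion tail,
  the regime of ferro/ferricyanide on carbon screen-printed electrodes.

Passing tests on these data show the *analysis* is correct under the stated
noise model; they cannot show robustness to drift, matrix effects in real
biofluids, electrode aging, or non-Gaussian artefacts, which the generator
does not emulate.

## Problem sizes

Tests and the acceptance script use 61-point spectra (10 points/decade),
dose-response campaigns of 4–7 levels × 1–8 replicates, 40–100-seed
Monte-Carlo loops for noise-robustness medians, and a 500×500 brute-force
grid as the independent oracle for the two-parameter fit — sizes at which
every check runs in seconds while keeping Monte-Carlo medians stable.

## Known limitations

* Single-time-constant Randles topology only; no inductive elements, no
  Kramers–Kronig validation, no automatic model selection.
* Asymptotic standard errors; no bootstrap or posterior sampling.
* The 3.3σ/slope LOD anchoring is one defensible reading of a dimensionally
  ambiguous convention (see above); results carry the note.
* CSV dialects only (documented open format with comma/semicolon sniffing);
  proprietary potentiostat exports are out of scope, with the reader kept
  small enough to extend.
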