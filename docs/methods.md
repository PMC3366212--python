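# Methods

## Problem setting

During haemodialysis, uremic solutes cleared from the patient's blood leave
the dialyser dissolved in the spent dialysate. Because several of these
solutes absorb in the ultraviolet, the UV absorbance of spent dialysate —
measured against pure, pre-session dialysate as the blank — tracks solute
removal without drawing blood. Uric acid (UA) is a particularly favourable
target: its chromophore has a characteristic absorbance maximum near 294 nm
and a trough near 265 nm, and in the 280–310 nm window it dominates the
total absorbance of the dialysate mixture. `dialyspec` implements the full
estimation pipeline: spectra are optionally smoothed or differentiated with
a Savitzky-Golay filter, and UA concentration is predicted by a linear
model

    Y = a + b1·x1 + b2·x2 + … + bk·xk

where each `x_i` is the spectrum value (absorbance, AU, or first
derivative, AU/nm) at one selected wavelength and Y is in µmol/L.

## Synthetic spent-dialysate spectra

No clinical spectra ship with the package; the simulator produces datasets
with the structure the analysis assumes, so every downstream stage is
testable end to end.

**Mixture model.** Spectra are Beer-Lambert sums over a small chromophore
library: `A(λ, t) = Σ_j ε_j(λ)·c_j(t)·l` with path length `l = 1 cm`.
Each chromophore's extinction `ε_j(λ)` is a sum of Gaussian bands
(centre, sigma, peak amplitude in AU per (µmol/L)·cm) plus a flat
non-negative floor. Gaussians are the simplest shape that reproduces the
qualitative landmarks the method relies on; no claim is made that real
uremic chromophores are Gaussian.

**Default library.**

| chromophore | bands (centre nm, σ nm, amplitude) | role |
|---|---|---|
| `uric_acid` | (235, 14, 0.0105), (294, 15, 0.0126) | target; 294 nm max, ~263 nm local min |
| `uv_low`    | (225, 16, 0.009)                    | strong short-wavelength interferent |
| `broad`     | (275, 50, 0.0018)                   | weak broad interferent overlapping the UA window |

The UA amplitude at 294 nm matches uric acid's molar absorptivity
(≈1.26×10⁴ L·mol⁻¹·cm⁻¹, i.e. 0.0126 AU per (µmol/L)·cm), so simulated
absorbances land on a physically plausible scale (~1 AU near 294 nm at
100 µmol/L). The two interferents guarantee that no single wavelength is a
perfect UA probe, which is what makes multi-wavelength calibration
worthwhile. At representative concentrations UA contributes ~90% of the
280–310 nm absorbance, comfortably above the 0.5 dominance threshold the
dominance check asserts.

**Kinetics.** Each chromophore's dialysate concentration decays
mono-exponentially, `c(t) = c0·exp(−k·t)`, emulating intradialytic solute
washout; defaults are k = 0.005 /min for UA, 0.006 for `uv_low`, 0.003
for `broad`. One pool per solute suffices for desk-scale testing; two-pool
kinetics and dialyser mass-transfer physics are out of scope.

**Sampling design.** Default sampling times are 10, 60, 120, 180 and
240 minutes after session start (a common mid-length schedule; other
schedules can be passed per profile). Initial UA is drawn uniformly on
30–160 µmol/L per session, spanning the clinical spread; interferent
initials are uniform on 50–250 (`uv_low`) and 20–120 (`broad`) µmol/L.

**Noise.** Two components, both optional: i.i.d. additive Gaussian noise
on absorbance (default SD 0.005 AU, a realistic bench-spectrophotometer
level) and a per-spectrum constant baseline offset (default SD 0.01 AU)
representing an imperfect blank reference. The offset is what gives
derivative models their edge: a constant shifts absorbance at every
wavelength but vanishes under d/dλ.

**Splits.** `cal_count` of `n_sessions` sessions (defaults 75 of 188,
the published design) are assigned to the calibration split at random,
seeded; all samples of a session share one label, mirroring a split by
dialysis procedure rather than by sample.

**What the simulator does not emulate** — and hence what passing tests do
not show about clinical data: real chromophore line shapes and pH
dependence, correlated inter-solute kinetics, machine self-test artifacts,
detector nonlinearity and stray light, and inter-patient covariance
structure. Error magnitudes on synthetic data are therefore not comparable
to clinically reported ones; only structural and directional behaviour is.

## Savitzky-Golay filtering

The filter is implemented from its defining least-squares problem rather
than from tabulated convolutes: within a window of odd length `w` a
polynomial of degree `p` is fitted, and the output is the fitted
polynomial's value or `d`-th derivative at the window centre. Row `d` of
the Vandermonde pseudo-inverse gives the convolution weights, scaled by
`d!/Δλ^d` so derivatives are per nm (AU/nm). Defaults are the classic
9-point quadratic convolute (`w=9, p=2`), with `d=1` for first-derivative
spectra; smoothing and differentiation are a single pass, which is the
mathematically standard convolute.

Edge handling: the first and last `(w−1)/2` points are produced by
refitting the same local polynomial one-sidedly on the first/last full
window and evaluating at the edge position — no padding, no fabricated
data — and are flagged in the output's `edge_mask`. For polynomial inputs
of degree ≤ p the one-sided fit is still exact, so polynomial-exactness
holds at every point, not just the interior.

The derivative normalisation convention matters when applying the
published derivative-model coefficients: they are interpreted here as
acting on per-nm derivatives on a 1 nm grid (where per-point and per-nm
scaling coincide). The processing software originally used to derive them
does not document its convention, so exact re-derivation of those
coefficients is not attempted.

## Calibration

`fit_mlr` is ordinary least squares of UA concentration on the spectrum
values at a fixed wavelength set, with intercept, solved by
`numpy.linalg.lstsq`; a rank-deficient design raises a collinearity error
naming the wavelengths.

`forward_stepwise` searches all 191 grid wavelengths. At each step it adds
the candidate minimising calibration RMSE (equivalent to maximising the R²
gain for nested OLS), with two guards: candidates pushing the design
matrix condition number above 1e10 are skipped (neighbouring wavelengths
on smooth spectra are nearly collinear), and RMSE ties break toward the
lower wavelength so selection is deterministic. Selection stops either at
`max_steps` (default 3) or when a paired two-sided t-test on *absolute*
residuals (new model vs previous, α = 0.05) fails to reject — absolute
residuals because raw OLS residuals have mean zero for every
intercept-containing model, which would make a raw paired test degenerate.
When the test fails to reject, the last accepted model is returned.

Six published models (three absorbance: 294/312/266 nm; three derivative:
300/270/222 nm) ship as packaged JSON fixtures and are loaded by name
through `published_model`.

## Validation statistics

Residuals use the convention e = predicted − observed, so a model reading
low has negative BIAS. The metrics are

* BIAS = Σe/N,
* SE = sqrt(Σ(e − BIAS)²/(N−1)),
* RMSE = sqrt(Σe²/N),

which satisfy RMSE² = BIAS² + SE²·(N−1)/N exactly. R² is the squared
Pearson correlation between laboratory and calculated values — not
1 − SSE/SST; the two differ off the 45° line. Bland-Altman agreement
reports mean difference and mean ± 1.96 SD limits on
predicted − observed. Model pairs are compared with a paired two-sided
t-test on absolute residuals; the significance flag uses strict p < α.

## Numerical choices and degenerate inputs

* Identical residual vectors in a paired comparison return t = 0, p = 1
  rather than a 0/0 failure.
* Negative concentration predictions are returned unclipped with a
  warning, preserving the linear model's algebra.
* R² is refused for constant vectors (undefined correlation), SE for
  N < 2, stepwise for an empty calibration split.
* All simulation randomness flows from one `numpy` Generator seeded from
  the config, so datasets are bit-reproducible.

## Problem sizes

Tests and the acceptance script run at desk scale: 14–60 sessions for
stepwise and directional checks (60 sessions × 5 samples ≈ 300 records),
20 seeds for stochastic trend assertions, 188 sessions only where the
published 75/113 split itself is asserted. These sizes were chosen so the
full suite completes in well under a minute while leaving the stochastic
assertions comfortable margins.

## Known limitations

* The simulator's error magnitudes are not calibrated to clinical
  reporting; only directional conclusions (derivative ≤ absorbance RMSE,
  more wavelengths ≤ fewer) transfer.
* The stepwise entry criterion (minimum calibration RMSE) and stopping
  test (paired t on absolute residuals) are declared package choices; the
  statistical software originally used for the published models does not
  document its own entry/removal rules, so selected wavelengths need not
  coincide with the published ones on real data.
* No exclusion logic for machine self-test artifacts is implemented
  beyond input validation.
* Non-uniform wavelength grids are rejected, not resampled.
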