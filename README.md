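# dialyspec

Optical estimation of uric-acid (UA) concentration in spent dialysate from
UV absorbance spectra.

During haemodialysis the spent dialysate carries the solutes removed from
the patient's blood, and its UV absorbance — referenced against pure
dialysate — tracks solute removal without blood sampling. Uric acid, a
uremic solute and cardiovascular risk marker, absorbs characteristically
near 294 nm and dominates the mixture's absorbance in the 280–310 nm
window, so its concentration can be read from the spectrum with a small
linear model. `dialyspec` is aimed at people developing or studying such
optical dialysis-adequacy monitors: it implements the whole pipeline as a
tested Python library plus CLI.

The core model is multi-wavelength linear regression

&nbsp;&nbsp;&nbsp;&nbsp;*Y = a + b₁x₁ + b₂x₂ + ⋯ + b_k x_k*

with *Y* the UA concentration (µmol/L) and *x_i* the absorbance (AU) or
first-derivative (AU/nm) value at a selected wavelength. Wavelengths are
chosen by forward stepwise selection over the full 190–380 nm grid
(minimum calibration RMSE per step; paired t-test on absolute residuals as
the stopping rule), coefficients by ordinary least squares on a
session-level calibration split. Models are validated with BIAS, SE, RMSE,
R² and Bland-Altman limits of agreement. The package includes:

* a synthetic spent-dialysate spectra simulator (Beer-Lambert chromophore
  mixtures, mono-exponential intradialytic washout, additive and
  baseline-offset noise, seeded session-level calibration/validation
  splits),
* a Savitzky-Golay filter implemented from its least-squares definition
  (9-point quadratic default, per-nm derivatives, one-sided edge fits),
* six published prediction models (three on absorbance at 294/312/266 nm,
  three on derivative spectra at 300/270/222 nm) shipped as JSON fixtures,
* the validation-statistics suite and paired model comparisons.

See `docs/methods.md` for the model details and assumptions.

## Worked example

Simulate 188 sessions (75 calibration, 113 validation), differentiate,
calibrate a 3-wavelength derivative model, and evaluate it:

```sh
dialyspec simulate   --sessions 188 --cal-count 75 --seed 42 -o spectra.csv
dialyspec preprocess --deriv 1 -i spectra.csv -o deriv.csv
dialyspec calibrate  --signal deriv --max-steps 3 -i deriv.csv -o model.json
dialyspec evaluate   --model model.json -i deriv.csv -o eval.csv --bland-altman ba.json
```

The calibrate step logs its selection trace to stderr:

```
... [calibrate] signal=deriv steps=3 stop=max_steps wavelengths=280.0,309.0,287.0 out=model.json
```

and `eval.csv` contains:

```
method,split,N,mean_pred,sd_pred,R2,BIAS,SE,RMSE
stepwise_3WL,calibration,375,54.50,30.64,0.9995,0.00,0.70,0.70
stepwise_3WL,validation,565,55.59,31.55,0.9993,-0.00,0.82,0.82
```

Reading: the fitted model predicts a mean UA of 54.5 ± 30.6 µmol/L on the
375 calibration samples with calibration BIAS exactly 0.00 (an algebraic
property of OLS with intercept) and generalises to the 565 held-out
validation samples with RMSE 0.82 µmol/L and R² 0.999 — high because
synthetic noise is mild; clinical data would be harsher. The Bland-Altman
summary in `ba.json` gives the matching limits of agreement
(−1.62 to +1.61 µmol/L).

The published models can be applied directly, e.g. in Python:

```python
from dialyspec import published_model, apply_model
m = published_model("UVa_3WL")   # -1.55 + 75.38·A294 - 62.27·A312 - 7.36·A266
```

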