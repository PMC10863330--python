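# fielddose

Voxel finite-element dosimetry for small-electrode tDCS and nonlinear
mixed-model dose-response analysis of motor-evoked potentials (MEPs).

Weak transcranial direct current stimulation polarizes cortex, but the
dose that matters physiologically is the electric field actually reaching
the target neurons, which varies strongly between heads for the same
stimulation current.  `fielddose` implements the full computational chain
used to ask whether the individually modeled field predicts excitability
changes better than the current does:

1. **Volume conductor** — multi-tissue head phantoms on a regular voxel
   grid (synthetic stand-ins for MRI segmentations), per-element
   conductivities with partial-volume mixing at selected tissue
   boundaries, and rubber/paste/needle models of 2 cm disc electrodes.
2. **Field solvers** — first-order hexahedral FEM for the tDCS scalar
   potential (`∇·σ∇φ = 0`, Dirichlet electrodes, solution scaled to the
   injected current) and for the TMS source problem
   (`∇·σ∇φ = −∇·σ ∂A/∂t`) with a figure-eight coil.
3. **Dose measures** — at the cortical FDI site 2 mm below the pial
   surface: the signed normal component `E_FDI`, the strength `|E|_FDI`,
   the 3 cm regional mean `E_sphere`, and the TMS-hotspot mean `E_TMS`.
4. **Synthetic MEP experiments** — 21 participants × 5 currents (0–2 mA)
   × 2 TMS directions × 4 time points with log-normal MEP sizes,
   participant random intercepts/slopes, a cubic field effect peaking at
   a configurable `E*`, baseline-normalization regression to the mean,
   and latency drift; ground truth embedded for recovery studies.
5. **Inference** — maximum-likelihood linear mixed models (independent
   variance components, equal random SDs across current levels), GESD
   outlier screening, likelihood-ratio tests with BH-FDR, partial
   dependence with cluster-bootstrap BCa intervals, permutation variable
   importance, and extraction of the optimal field `E_opt` and its
   normalized-MEP gain ΔNMEP over sham.

The core statistical model for the field effect is

```
log(MEP / MEP_baseline) ~ Σ_k β_k P_k(E_FDI) + direction + timepoint
                          + gender + time-of-day + log baseline + session
                          + (interactions with each P_k)
                          + (1 | participant) + independent slopes
```

with `P_1..P_3` polynomials orthonormal with respect to the observed
`E_FDI` values.  `E_opt` maximizes the fitted partial dependence
`g(E)`; `ΔNMEP = 100·(exp(g(E_opt) − g(0)) − 1)` percent.

## Worked example

```python
from fielddose import dose, mep

# simulate the study: 21 participants, truth peak at 0.44 V/m (+27%)
ds = mep.generate_dataset(mep.StudyDesign(), mep.TruthParams(seed=7))

df, prep = dose.prepare_analysis_table(ds, "field_nmep")
fit = dose.fit_lmm(dose.build_spec("field_nmep"), df, prep)
red = dose.fit_lmm(dose.drop_term_group(fit.spec, "field"), fit.data, prep,
                   screen_outliers=False)
lr = dose.lr_test(fit, red, "field")
opt = dose.optimal_field(fit)
print(f"field LR test: chi2({lr.df}) = {lr.chi2:.1f}, p = {lr.p:.2g}")
print(f"E_opt = {opt['E_opt']:.2f} V/m, dNMEP = {opt['delta_nmep_pct']:+.0f}%")
```

prints

```
field LR test: chi2(3) = 67.4, p = 1.6e-14
E_opt = 0.47 V/m, dNMEP = +22%
```

i.e. on this 21-participant draw the three orthonormal field polynomials
jointly improve the fit (a nonlinear dose-response), and the fitted
response peaks near the generating optimum of 0.44 V/m — with the
sampling error expected at n = 21 (other seeds land between p ≈ 0.1 and
p ≈ 1e-14; at n = 200 the recovery is within the partial-dependence grid
resolution).

A field-dosimetry run on a phantom:

```python
from fielddose.experiments import run_phantom_study

study = run_phantom_study(spacing_mm=2.0, current_A=1e-3, with_tms=True)
print(study.E_FDI, study.absE_FDI, study.E_sphere, study.E_TMS)
```

The command-line interface mirrors the library:
`fielddose phantom`, `conduct`, `solve`, `metrics`, `simulate`,
`analyze` (see `fielddose --help`).

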