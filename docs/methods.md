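# Methods

`fielddose` models the chain from stimulation hardware to behavioral
statistics for anodal small-electrode tDCS of the hand motor cortex: a
volume-conductor model of the head, the quasi-static electric field it
implies, scalar dose measures read at the cortical representation of the
FDI muscle, and a nonlinear mixed-effects analysis of how that dose
modulates normalized motor-evoked-potential (MEP) size.  Everything is
exercised end to end on synthetic sphere phantoms and simulated MEP
experiments with known ground truth.

## Volume conductor

The head is a regular hexahedral voxel grid of integer tissue labels.
Sphere phantoms stand in for MRI-derived segmentations: concentric
shells (scalp, compact bone, CSF, gray matter, white matter by default),
optionally with a sinusoidally modulated pial radius emulating cortical
folding.  The default grid spacing is 2 mm; resolution is a parameter,
and the shell-volume and solver-oracle tests run the same geometry at 4,
2 and 1 mm.  A 1 mm dura layer thinner than the grid spacing is not
represented as whole voxels; boundary mixing (below) is the mechanism
intended for sub-voxel laminae.

Element conductivities (S/m): GM 0.2, WM 0.14, CSF 1.8, blood 0.7, dura
0.16, compact bone 0.008, cancellous bone 0.027, scalp 0.08, fat 0.08,
muscle 0.16, eye 1.5, electrode rubber 28.3, electrode paste 0.504.  A
second table for TMS differs slightly (GM 0.215, WM 0.142, CSF 1.79,
dura 0.18, compact bone 0.009, cancellous 0.034, scalp 0.43, fat 0.15,
muscle 0.18).  Sensitivity variants scale CSF by ±10% and both bone
compartments by ±50%.

Elements straddling one of the listed tissue boundary pairs — WM–GM,
GM–CSF, CSF–dura, dura–compact bone, scalp–paste, paste–rubber,
paste–air, rubber–air — receive the volume-fraction-weighted average of
the two conductivities; all other mixed elements take their dominant
tissue's value (staircase rule).  Volume fractions are estimated by
sub-voxel point sampling (default 4³ points per element against the
analytic phantom geometry; the convergence of this estimator in the
sampling factor is tested).

Electrodes are 2 cm diameter conductive-rubber discs on a 2 mm layer of
electrode paste whose radius is 1 mm larger than the rubber; the paste
conforms to the voxelized scalp by filling the air gap between the flat
rubber underside and the scalp surface.  Current enters through a
needle-shaped connector (default: a single axial needle of radius
0.5 mm through the rubber center — the needle dimensions are not
constrained by the source hardware description, so they are parameters);
every element the needle penetrates becomes a Dirichlet block whose
nodes carry the boundary condition.

## Field solvers

tDCS: `div(sigma grad phi) = 0` with Dirichlet values ±0.5 on the two
connector node sets and natural boundary conditions elsewhere,
discretized with first-order (trilinear) hexahedral elements and
element-wise constant conductivity.  The solution is rescaled so the
discrete reaction current entering at the anode equals the target
stimulation current (current is the controlled quantity, not voltage).
A target of 0 A is sham: no solve, identically zero field.

TMS: `div(sigma grad phi) = -div(sigma dA/dt)` with the natural
condition `n.(grad phi + dA/dt) = 0`; the total field is
`E = -grad phi - dA/dt`.  The pure-Neumann gauge is fixed by a zero-mean
constraint over active nodes.  The figure-eight coil is two coplanar
counter-wound 70 mm loops whose centers sit one wing radius to either
side of the coil center along the lateral axis, so the induced field
under the center runs along the handle; each wing is discretized as a
sheet of magnetic dipoles (default 256), which converges to the exact
loop vector potential and is cross-checked against the elliptic-integral
loop formula.  Only the shape of the ≥70%-of-maximum field region
matters downstream, which is invariant to dI/dt.

Linear systems are solved with Jacobi-preconditioned conjugate
gradients to a relative residual of 1e-6 (sparse direct factorization
below 20k unknowns).  The iterative path is verified against a dense
direct solve to 1e-8 on small grids, and the assembled potential against
the Legendre-series solution for cap-electrode current injection on a
concentric multi-shell sphere (relative L2 error ≤ 5% at 2 mm on the
three-shell configuration).  E is evaluated at element centers as the
gradient of the trilinear interpolant.

## Dose measures

Read from the field at the cortical FDI site — placed 2 mm below the
pial surface along the outward normal of a smoothed signed-distance
field, at a declared anchor direction standing in for the FreeSurfer
mapping of the MNI coordinate (default [-43,-11,60]; the alternative
[-41,-7,63] is accepted — both appear in the source material and are
deliberately not reconciled):

* `E_FDI`: signed normal component, positive when the field points into
  the cortex (anodal-facilitatory).  The sign convention is a
  configuration flag.
* `absE_FDI`: field strength at the site (trilinear interpolation from
  element centers).
* `E_sphere`: unweighted mean strength over precentral-gyrus GM within a
  3 cm ball around the site (the phantom's "precentral" mask is the GM
  patch within that ball).
* `E_TMS`: mean tDCS strength over GM where the TMS field exceeds 70% of
  its GM maximum.

All four are exactly linear in the stimulation current.

The phantom study ensemble used for reporting fixes the montage —
anode and TMS coil centered on the scalp at the hand-knob direction,
cathode at a contralateral-orbit direction, coil handle 45° off the
midline — and reads the measures at a ring of site anchors around the
nominal rFDI direction (13 mm of arc from the montage axis), emulating
participants whose activation site falls at arbitrary positions of their
folding pattern.  On this smooth sphere the hotspot mean and the site
strength coincide to within a few percent rather than showing the
crown-versus-site gap of real, deeply folded cortex; the corresponding
ordering check documents this as a known phantom limitation.

## Synthetic MEP experiments

The generator reproduces the study design: 21 participants × 5 sessions
(sham, 0.5, 1.0, 1.5, 2.0 mA, Latin-square order) × 2 TMS directions
(PA/AP) × 4 time points (baseline, 0, 15, 30 min), 20 trials per cell,
12 male / 9 female, morning/afternoon sessions at the observed 49:56
ratio.  Per-participant field efficacy (EFDI per mA) is log-normal with
mean 0.56 and SD 0.20 V/m.

Log MEP size is built from: a log-normal baseline level (mean 409 µV,
SD 234 µV) shared within participant/session/direction; a participant
random intercept (SD 0.35 — deliberately the dominant term); a cubic
field effect with stationary points at `peak_E` (default 0.44 V/m,
height log 1.27 ≈ +27%) and a trough beyond the observed range, so the
response rises to the peak and declines thereafter; a participant
field-sensitivity slope (SD 0.25 per V/m); per-cell measurement noise
(SD 0.18, the 20-trial mean) and residual noise (SD 0.15).  Because the
baseline measurement shares the session level but has its own noise,
normalization to baseline induces regression to the mean — the fitted
log-baseline coefficient is negative without being injected directly.
Latencies drift monotonically (+0.4 ms at 30 min) with a +0.7 ms AP
offset.  Trial-level EMG traces (3 kHz, Gabor-like biphasic waveform)
exercise peak-to-peak sizing, the 13500/4444 amplifier-scaling
correction and cross-correlation latency estimation; the default
pipeline generates cell-level sizes directly.

What the generator does not emulate: anatomically realistic field
distributions (phantom fields are smooth), physiological MEP
variability structure beyond log-normality, session-order carryover,
and any hardware drift.  Passing recovery tests therefore show the
inference machinery is consistent under the assumed data-generating
process, not that the process matches real recordings.

## Dose-response inference

All models are linear mixed-effects fits by maximum likelihood.  The
fixed designs are built from explicit dummy and product columns so LR
tests remove exactly the named columns: the current model carries the
five-level current factor, direction, time point, their full
interactions, gender, time of day, session number, log baseline and the
current interactions with each; the field model replaces current by
first- to third-order polynomials of EFDI orthonormalized against the
observed values (each polynomial interacts with direction, time point,
direction×time point, gender, time of day and centered log baseline —
nine columns per order).  Absolute-size models include the baseline time
point; the latency model uses the latency difference from the PA
baseline and contains no intercept terms.  Random effects are
independent variance components per participant: intercept, one shared
variance across the five current levels (equal-SD constraint by
construction), direction, time point, time of day, log baseline, and —
in field models — a linear EFDI slope.  No random correlations are
estimated.

Numerical notes: statsmodels' quasi-Newton optimizer alone stalls short
of the ML optimum on these variance-component models, which inflates LR
statistics; every fit is therefore polished with Powell and Nelder–Mead
restarts and the best log-likelihood kept.  Simulation studies
(type-I error, power, recovery) use a lean field family — polynomials,
direction, time point, log baseline, with intercept + current + field
random components — at 200 null replicates and 20 power replicates;
problem sizes chosen so the whole suite remains desk-scale.  Dropping
the current variance component is not an option: the field varies only
between sessions, and without a session-level component the 3-df field
test's type-I error roughly doubles.

Residuals of every initial fit are screened with the generalized
extreme Studentized deviate test (α = 0.05, at most 5% of rows); flagged
rows are excluded and the model refitted once.  LR p-values across term
groups are flagged with Benjamini–Hochberg FDR at 0.05.  Partial
dependence pins a source variable to grid values, rebuilds the design
and averages fixed-effect predictions over the observed covariate rows;
participant curves add the estimated random effects.  `E_opt` maximizes
the field partial dependence on a 0.005 V/m grid over the observed
range (boundary optima are flagged), and ΔNMEP = 100·(exp(g(E_opt) −
g(0)) − 1).  Bootstrap confidence intervals are BCa with jackknife
acceleration, resampling participants as clusters (relabeled so
duplicated clusters stay distinct); row-level resampling is available
for comparison.  Permutation importance permutes a predictor's source
column (rebuilding interactions), or reassigns a random term's estimated
effects among participants, and reports the mean drop in R² over the
permutations without refitting.

## Known limitations

* Spherical phantoms cannot reproduce gyral-crown field concentration;
  the hotspot-vs-site-strength ordering seen in real heads does not
  emerge (measured hotspot/site ratio ≈ 0.95–0.96 at 2 mm, stable under
  discretization refinement).
* The deposited experimental dataset is loadable through a
  column-mapping loader but is not bundled; analyses here run on
  synthetic data only.
* No anisotropic conductivity, no capacitive effects, no electrode
  interface impedance, no REML or small-sample df corrections (ML and
  χ² reference distributions throughout, as in the modeled analysis).
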