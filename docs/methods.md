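# Methods

This note documents the models implemented in `aortaflow`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
fixtures do and do not establish about real data.

## Blood rheology

Blood is a generalized Newtonian fluid with Carreau–Yasuda apparent
viscosity η(γ̇) = η∞ + (η0 − η∞)[1 + (λγ̇)^a]^((n−1)/a). Parameters are
carried in centipoise with SI converters because rheometry of blood is
conventionally reported in cP. The defaults (η∞ = 2 cP, η0 = 11 cP,
λ = 1.5 s, a = 0.2, n = 0.71) describe healthy blood. Note that with
a = 0.2 the high-shear plateau is approached very slowly: η is still
≈2.02 cP at γ̇ = 10⁹ s⁻¹ and reaches 2 ± 0.001 cP only beyond
γ̇ ≈ 3×10¹³ s⁻¹; plateau checks therefore evaluate far out on the tail.
The λ and the transition-time symbol that sometimes appears as μ in
typeset versions of this model are the same constant — the bracket λγ̇ must
be dimensionless.

## Three-element Windkessel

Each outlet carries proximal resistance R, compliance C and distal
resistance r (units mmHg·s/μL and μL/mmHg, which keep mouse-scale values
O(0.1–1)). The outlet pressure solves
dp/dt + p/(rC) = (Q/C)(1 + R/r) + R·dQ/dt.

*Waveform representation.* The sampled inflow (typically 15 frames/cycle)
is fit with a truncated trigonometric series by least squares, which
handles non-uniform sampling and interpolates exactly whenever
2·modes + 1 ≥ samples. The mode count defaults to 20, capped at the Nyquist
limit of the sample count (7 for 15 samples). An alternative reading of an
"N-node" interpolation — resampling to N uniform points before
re-interpolating — is exposed via `interpret="points"`. The interpolant's
analytic derivative supplies R·dQ/dt; finite-differencing 15 noisy samples
would be markedly worse.

*Integration.* Classical RK4 with dt = T/200 by default (the integrator
requires dt < T/20). Cycles repeat until the maximum cycle-to-cycle
pressure change is below 0.1 mmHg, with at least 8 cycles and a 50-cycle
cap. Grid-refinement and periodicity checks in the test suite confirm the
expected convergence order.

*Tuning.* The success criterion is that systolic, diastolic, mean arterial
(MAP) and pulse pressures all fall within a relative tolerance (5% default)
of their targets. The tuning loop is a damped fixed point built on the
dominant sensitivities — total resistance R + r sets the pressure level
(update by the target/achieved MAP ratio), compliance sets the pulse
amplitude (update by the achieved/target amplitude ratio) — with the
proximal fraction R/(R + r) initialized at 0.09, a characteristic-impedance-
like value. The fixed point has no knob for the systolic/diastolic split,
so if those remain outside tolerance a Nelder–Mead polish over
(log(R + r), log C, logit fraction) minimizes the maximum relative error.
Initialization: R + r = MAP/mean(Q); C from matching the diastolic decay
exp(−t/(rC)) over roughly two thirds of a cycle.

*MAP target.* `PressureTargets.map` may be left unset, in which case the
mean-pressure criterion is self-consistent: MAP is read as the cycle
average of the achieved trace (its defining integral), and the reported
maximum error covers the remaining three summaries. When a measured MAP is
supplied it is enforced like the others.

*Outlet flow split.* When distributing a total flow over several outlets
the package uses a Murray-type rule, flows ∝ area^(3/2). This is a
documented modeling assumption, not a measured quantity.

## HGO constitutive model

The wall is the generalized-structure-tensor dispersion model: neo-Hookean
matrix c/2(I₁ − 3) plus two symmetric fiber families at ±α from the
circumferential axis with dispersion κ ∈ [0, 1/3], energy
k₁/(2k₂)[exp(k₂E²) − 1] per family, E = κ(I₁ − 3) + (1 − 3κ)(I₄ − 1),
active only in tension (E > 0). For planar biaxial states both families
share the same invariant.

Biaxial kinematics enforce incompressibility exactly
(λr = 1/(λθλz)) and plane stress, so Cauchy stresses reduce to
σᵢ = λᵢ ∂Ψ/∂λᵢ; the test suite verifies this against direct numerical
differentiation of the energy. The ν = 0.49 Poisson ratio is carried as
metadata for 3D solver hand-off only. Residuals are formed on Cauchy
stresses (the second Piola–Kirchhoff alternative would change fitted values
slightly; Cauchy is the convention adopted here).

Fitting uses bounded trust-region least squares over (c, k₁, k₂, κ, α)
with 5 seeded starts, because k₂ and α are weakly identifiable from planar
protocols. On noiseless synthetic data spanning an equibiaxial and two
constant-axial-stretch protocols over stretches 1.0–1.4, recovery is exact
to machine precision; the acceptance suite requires 1% (and 1° for α)
across 20 random truths.

The incremental modulus is defined as the analytic tangent
dσθ/dλθ at a given (λθ, λz) state with the axial stretch held fixed — the
stiffness linearization used to initialize mesh elasticity at diastole. At
the reference state with k₁ = 0 it equals 4c, the incompressible
plane-stress neo-Hookean value.

## Centerline geometry

The centerline is an ordered polyline with named landmarks; idealized
fixtures auto-register `aortic_root` and `iliac_bifurcation` at the ends.
AER = arc length / chord between those landmarks.

Maximum inner diameter: at stations every 0.15 mm (the nominal isotropic
imaging resolution; exposed as a parameter) the mesh is cut by the plane
normal to the local tangent. Tangents come from central differences on a
window-3 moving-average smoothing of the polyline, since raw polyline
tangents tilt the cutting plane. A plane can cut an arched vessel twice, so
intersection segments are grouped into connected loops and the loop nearest
the station is kept. The contour is fit with an algebraic (Kåsa)
least-squares circle — closed-form and robust for near-circular sections —
and the diameter is 2R of the fitted circle, not an area-equivalent
diameter. Stations within one step of the open tube ends are trimmed
because the cut there is incomplete; empty cuts are skipped with a warning.

Region partition: three ordered internal boundaries (arc-length fractions
or landmarks) split the centerline into ASC/DSC/SAB/IAB; each mesh vertex
takes the region of its nearest centerline station, and a station exactly
on a boundary belongs to the proximal region.

## Wall shear metrics

TAWSS, OSI, ECAP and RRT follow their defining cycle integrals, computed
per vertex by the trapezoid rule with the periodic wrap frame appended.
The OSI numerator uses the magnitude of the vector time integral. Stagnant
vertices (magnitude integral below a 10⁻⁶ Pa floor) take OSI = 0 by
convention. ECAP and RRT are undefined (NaN) where their denominators fall
below the floor — flow stagnation for ECAP, the OSI → 0.5 singularity for
RRT — and such vertices are excluded from regional means rather than
propagating infinities. Regional means are vertex-area-weighted
(barycentric areas, one third of each incident triangle) for
mesh-resolution independence; uniform weighting is available for
comparison. Von Mises stress is computed from the full symmetric tensor
with no thin-wall assumption. The Robin support traction is
t = −ks·u − cs·∂u/∂t − p0·n with defaults ks = 10³ Pa/mm, cs = 0.1 Pa·s/mm,
p0 = 0, the perivascular support values used for the mouse aorta.

## Porosity

Porosity is the percent image area above (default polarity) a threshold,
Otsu by default with a fixed-cut override; images are expected
pore-highlighted (bright = elastin void), and `polarity="below"` inverts
the convention. A constant image defeats Otsu and falls back to the fixed
cut with a warning. The exact thresholding recipe of the original
histology protocol is not reproducible here; Otsu is a parameter-free,
reproducible default.

## Cohort statistics

*Spearman.* Rho uses average ranks for ties; p-values are exact
(full permutation enumeration) for groups below 10 observations — the
regime of small animal cohorts — and the t-approximation otherwise. Groups
with fewer than 3 pairs or zero variance are flagged, not reported. No
multiple-testing correction is applied by default.

*WT normalization.* Every row in an (age, sex) cell is divided by that
cell's wild-type mean, so WT cell means are exactly 1 and mutant values are
expressed as fold-of-control. A cell lacking WT rows raises an error naming
the cell.

*Tobit.* Lifespan regression with right-censoring at the study endpoint
(120 days ≈ 4 months at 30 days/month; the bound is whatever censored rows
carry). Uncensored rows contribute the Gaussian density, censored rows the
upper-tail probability. The MLE is found by BFGS on (intercept, slope,
log scale) from the OLS start — which is already the exact optimum when
nothing is censored — with a Nelder–Mead polish if the line search stalls
on flat likelihoods. Standard errors come from the inverse numerical
Hessian. Pseudo-R² is McFadden's 1 − ℓ_model/ℓ_null (Cox–Snell available),
clamped to [0, 1]. A constant predictor returns slope 0 and pseudo-R² 0 by
definition. When mice carry repeated measurements, the measurement at the
last available age feeds the fit — an explicit selection rule.

*LMM/ANOVA.* Age (categorical), sex and genotype with all interactions
under sum-to-zero coding, random intercept per mouse, fit by REML via
statsmodels MixedLM. Per-term Wald F statistics are formed from the
fixed-effect covariance with residual denominator degrees of freedom
n − p; at the zero-variance boundary of a balanced design these equal
classical three-way ANOVA F values exactly, which the test suite checks to
1e-6. Rank-deficient designs (empty cells) are handled by dropping
collinear design columns in order, as lme4 does. Estimated-marginal-mean
contrasts are reported for genotype within each sex × age cell and sex
within each genotype × age cell, with normal-approximation p-values;
contrasts touching an empty cell are flagged unestimable rather than
extrapolated.

## Synthetic fixtures: what they emulate

The generators provide ground truth, not realism:

- **Waveform** — a half-sinusoid systolic ejection over the first third of
  the cycle on a diastolic plateau, parameterized by period (0.12 s
  default), mean flow (100 μL/s) and pulsatility (peak/mean, 3.0), with
  seeded low-order shape jitter and the cycle mean rescaled exactly. The
  true murine inlet waveform shape is not prescribed by the study design
  this emulates; the half-sinusoid is a stand-in that is fully specified by
  three numbers.
- **Tube meshes** — straight or circular-arc centerlines with a Gaussian
  fusiform bulge, r(s) = r₀ + A·exp(−(s−s₀)²/2w²); outward normals,
  right-handed winding, millimeters. Real aneurysmal geometries are
  asymmetric and branched; these are not.
- **WSS fields** — per-vertex tangent-plane vectors
  m·[(1−f)e₁ + f·sin(2πt/T + φ)e₂] with seeded magnitude/phase jitter.
  The reversal fraction f maps monotonically onto OSI with exact endpoints
  (f = 0 → OSI 0, f = 1 → OSI 0.5).
- **Biaxial data** — exact forward HGO stresses plus i.i.d. Gaussian noise.
- **Cohort tables** — per-mouse latent severity; mutant lifespan =
  150 d − effect·severity + N(0, 15 d), censored at 120 d; wild types
  survive to the endpoint. Measurements exist only for survived ages
  (1–4 months at 30 d/month). The driver metric is a constant per-mouse
  severity level rather than a progressive one, so the
  last-available-measurement rule does not mechanically couple the
  measured metric to death age under a null effect; progressive growth
  enters only through the wild-type age trajectory. Defaults (6 mice per
  sex × genotype cell, ~half of mutants dying early) mirror a small
  two-set murine study.
- **En-face images** — a Gaussian random field thresholded at the quantile
  matching the requested white fraction, mapped through a steep sigmoid so
  the known cut is 0.5 and the image is bimodal enough for Otsu.

Passing tests on these fixtures demonstrates correctness of the
computations and estimators under known ground truth; they do not
demonstrate that real murine MR, biaxial or imaging data satisfy the
generative assumptions (Gaussian noise, idealized geometry, administrative
censoring only).

## Problem sizes

The test and acceptance workloads are desk-scale by design: 10k-vertex
meshes, 15–512 frame shear series, 20 random constitutive truths, 200
Tobit replicates at n = 100, 120 null ANOVA simulations, and 20 seeded
tuning problems. These sizes give Monte-Carlo error comfortably inside the
asserted tolerances while keeping the full suite around two minutes.

## Known limitations

- No 3D CFD/FSI solves, no prestress equilibrium, no centerline extraction
  or image segmentation: inputs are assumed already reduced to meshes,
  centerlines, wall vectors and tables.
- The Windkessel tuner terminates at the first parameter set satisfying the
  tolerance criterion; it returns *a* feasible (R, C, r), not a unique one.
- Tobit inference uses asymptotic (Hessian) standard errors; for very small
  or heavily censored cohorts profile-likelihood intervals would be more
  faithful.
- The mixed-model F-tests use residual denominator degrees of freedom
  rather than Satterthwaite/Kenward–Roger corrections; for the balanced or
  near-balanced designs targeted here the difference is small.
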