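# Methods

This note records the models implemented in `starbrush`, the conventions
and numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the known limitations.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Disordered-chain model

Isolated disordered chains are described by the extended Guinier form
factor

    I(q) = I0 * exp{ -(q Rg)^2 / 3 + 0.0479 (nu - 0.212) (q Rg)^4 },

a low-q expansion of the form factor of a swollen-chain ensemble whose
quartic coefficient carries the Flory exponent.  At nu = 0.212 the
quartic term vanishes and the plain Guinier law is recovered; the
expansion is trusted only up to q·Rg ≈ 2 and grows unphysically beyond
q·Rg ≈ 2.5 (the quartic term eventually dominates), which is why the
generator truncates chain curves at q·Rg = 2.5 and `chain_intensity`
warns outside the validity window.

Rg and nu are linked through

    Rg = sqrt[ gamma(gamma+1) / (2(gamma+2nu)(gamma+2nu+1)) ] * b * N^nu

with gamma = 1.615 and a per-residue segment length b = 0.55 nm.  The
inverse map nu(Rg) is a bracketed Brent search on nu in [1/3, 1]
(xtol 1e-13); inputs outside the attainable [Rg(1/3), Rg(1)] raise a
domain error that names the bracket.

### Chain fitting

`fit_chain` performs weighted (sigma^-2) nonlinear least squares with
bounds I0 > 0, Rg > 0, nu in [1/3, 1].  The fit window 0.7 < q·Rg < 2 is
self-consistent: a plain Guinier fit (itself iterated on q·Rg < 1.3,
seeded from the lowest-q fifth of the curve) provides the starting Rg,
and the window is recomputed from each fitted Rg until the in-window
point set stops changing, or both window edges move by less than half
the local q-spacing (20 iterations maximum; the lower bound 0.7 is
applied strictly).  Parameter errors are 1-sigma values from the fit
covariance at the stated absolute uncertainties.  A flat or rising curve
has no finite Guinier radius and raises a fit error; series fitting
contains per-curve failures instead of aborting.

## Star-like (decorated core) model

Aggregated curves are modelled as Z chains grafted to a small dense
core:

    F(q) = Z^2 b_c^2 F_c + Z b_t^2 F_t + 2 Z^2 b_c b_t S_ct
           + Z(Z-1) b_t^2 S_tt,      I(q) = scale * F(q) + background.

* F_c — core self-term.  Sphere: Phi(x)^2 with
  Phi = 3(sin x - x cos x)/x^3, x = qR.  Cylinder: orientation average
  of the squared cylinder amplitude (2J1/x radial term times a sinc
  axial term), computed by 64-point Gauss–Legendre quadrature over the
  tilt angle.  Series expansions replace all 0/0 forms below argument
  1e-4.
* F_t — Debye function of one Gaussian tail, x = (q Rg_tail)^2.
* S_ct, S_tt — the standard decorated-micelle cross terms with tails
  anchored on a shell a distance d·Rg_tail (d = 1 by default) outside
  the core surface: psi(x) = (1 - e^-x)/x,
  S_ct = Phi(qR) psi sinc(q r_a), S_tt = [psi sinc(q r_a)]^2,
  r_a = R + d·Rg_tail.  For cylindrical cores the cross terms use the
  equal-volume sphere radius while F_c keeps the true orientation
  average; an amplitude-correlated alternative was evaluated and did not
  improve shape sensitivity at the relevant core sizes, so the simpler
  canonical form is kept.  The q→0 limit is the exact identity
  scale·Z²(b_c + b_t)² + background.

Vesicle and lamellar form factors were considered for aggregated curves
and rejected for this system (no bilayer or planar signature); they are
recorded in `EXCLUDED_FORM_FACTORS` and deliberately not implemented.

### Star fitting

`fit_star` is bounded weighted least squares (lmfit, trust-region
reflective).  Free parameters: Z (continuous in [1, 50], also reported
rounded), Rg_tail, scale, background (non-negative; can be held at zero
for background-free synthetic data), and the core dimensions unless held
fixed.  The excess scattering lengths b_c and b_t are always fixed
inputs: they are exactly degenerate with `scale`, and fixing them at,
say, twice their nominal values simply rescales `scale` by 1/4 without
moving Z (tested).  Cylindrical-core fits first rebin the curve into 100
logarithmic bins to keep the orientation quadrature affordable.
Optimisation uses one heuristic central start plus a seeded
latin-hypercube multi-start (5 starts by default); for free cylindrical
cores every fit is additionally refit from the conjugate geometry
branches described below.

An optional constrained mode (`fix_n`) imposes the core residue count
and derives the core radius from Z instead of fitting it, for comparing
against fits with a forced larger core.

Derived quantities and their errors follow the standard propagation
conventions for this analysis:

* tail height h = 2·Rg_tail; nu from inverting Rg(nu) at the full chain
  length (N = 146 by default), with
  d_nu = ln(1 + dRg/Rg) / ln N;
* core volume V (4πR³/3 or πR²L) with dV/V = sqrt(3 (dR/R)²);
* core residues per chain n = V/(phi_aa·Z), with the mean amino-acid
  partial volume phi_aa a configuration scalar (default 0.135 nm³, a
  literature-typical stand-in — it rescales n only);
* grafting distance rho = R sqrt(4π/Z), defined on the spherical core
  surface (cylindrical geometries raise an unsupported-geometry error;
  callers may use the equal-volume sphere radius explicitly);
* brush-regime ratio h/rho with a configurable threshold (default 1).

### Cylinder branch degeneracy and replicate reconciliation

Over a q-range that ends before the first core form-factor minimum
(q_max·R ≈ 3 here), two cylinders sharing volume V = πR²L and core
radius of gyration G = R²/2 + L²/12 are nearly indistinguishable: their
lengths are roots of L³/12 − G·L + V/(2π) = 0.  For the small cores of
interest (R ≈ 0.9 nm, L ≈ 1.2 nm versus the conjugate R ≈ 0.76 nm,
L ≈ 1.65 nm) the residual chi-square separation at 1% relative noise is
only ~0.2 per curve — below single-curve resolution.  This is why
production analyses fix the core dimensions after determining them once.

`fit_star_replicates` implements that practice for replicate curves of
one sample: each curve is fit freely, refit from the conjugate branch of
its own solution, and the branch whose per-replicate minima sum to the
lower total chi-square is selected for all replicates.  With ~25
replicates at 1% noise the selection statistic has z ≈ 1, so the correct
branch is chosen in most but not all noise realisations; conditional on
the correct branch the recovered R and L are accurate to ~1%.  This
residual ambiguity is a property of the measurement conditions, not of
the optimiser.

`compare_core_models` fits a list of candidate core shapes and ranks
them by reduced chi-square, breaking ties (equal to within 1e-9
relative) toward the model with fewer free parameters.

## Zimm analysis and extrapolation

`guinier_I0` fits ln I vs q² on a self-consistent q·Rg < 1.3 window; an
upward-curving region (positive quadratic coefficient beyond 2 sigma)
attaches an aggregation warning without suppressing the result.

`zimm_fit` implements the first-order Zimm law
C/I(0,C) = (1/KM)(1 + 2 A2 M C).  Per curve, 1/I is fit linearly in q²
over the low-q run, which is extended point by point while the next
point's standardized residual stays below 3 and a Wald–Wolfowitz runs
test on the in-window residuals keeps p > 0.01 (the operational meaning
of "until the curve stops being linear"); the intercept gives I(0,C).
C/I(0,C) is then fit linearly in C and A2 = slope/(2·intercept).  In
relative intensity units the reported A2 is the virial product A2·M up
to the instrument constant, which cancels in the ratio; an absolute
calibration constant can be supplied to convert.  The Zimm-plot
spreading constant alpha (default 0.01) only shifts the plot abscissa
(q² + alpha·C) and never enters a regression.  Plot-only binning is
likewise never applied before regression.

`extrapolate_zero_conc` is an error-weighted straight line in C whose
covariance is evaluated at the stated absolute errors (no residual
rescaling), so two points give the exact line with errors propagated
from the inputs.

## Scaling-theory overlays

The closed forms of the brush and screened-chain theories exist in
several conventions; the implementations guarantee the properties the
analysis actually uses and keep every convention in `BrushTheoryParams`
so exact literature forms can be substituted.

* Salted-brush height: h = c_brush · N · b · (sigma_g · w_eff / b)^(1/3)
  with w_eff = b/kappa_s² the screened-electrostatic effective excluded
  volume, kappa_s the inverse Debye length of the (monovalent) salt
  (lambda_D = 0.304 nm/sqrt(I[M]); a buffer contribution can be added to
  the ionic strength via `buffer_mM`), and sigma_g = 1/rho² the grafting
  density, modelled as a fitted linear function of salinity.  At fixed
  sigma_g the law d ln h/d ln Cs = −1/3 is exact; a linear sigma_g(Cs)
  adds the analytic sigma_g^(1/3) correction.  Defaults: c_brush = 0.33,
  b = 0.38 nm, N = 146, sigma_g = 0.44 nm⁻² (rho ≈ 1.5 nm).  Heights
  convert to an apparent exponent via h = b N^nu.
* Polyelectrolyte chain: a two-parameter crossover-swelling model,
  nu = c_poly · ln(sqrt(N)(1+z)^{1/5})/ln N with total dimensionless
  excluded volume z = z_neutral + s_el/(kappa_s b)², so the curve is
  monotone decreasing in salinity, approaches the neutral-chain plateau
  as Cs → ∞, and is scaled linearly by the prefactor c_poly = 1.24.
  z_neutral = 0.3 and s_el = 0.45 were chosen once so the 20–520 mM
  window spans the extended-chain range (nu ≈ 0.73 → 0.64 at N = 104);
  they are presentation conventions of the overlay, not fit results.

## Synthetic data

`SyntheticSpec` freezes a complete generative description: forward model
(chain or star), true parameters, q-grid (default 0.05–3.5 nm⁻¹, 400
log-spaced points, matching a typical synchrotron bio-SAXS window),
noise, concentrations, and seed; `save_with_spec` writes a YAML sidecar
from which the curve regenerates byte-for-byte.

The noise model is relative Gaussian: sigma(q) = f·I(q) + floor, with
f = 1.5% and floor = 1e-4 of the forward intensity by default (chosen as
a realistic synchrotron figure; the sigma column records the exact noise
scale used).  A noiseless request keeps a nominal relative sigma of
1e-6·I so downstream weighted fits remain defined, and adds no noise.
Concentration series follow exactly the first-order Zimm law the
analysis inverts, with the instrument constant fixed to 1 in relative
units.  Salinity sweeps drive any parameter through user-supplied trend
functions and record the truth per curve for recovery scoring.

What the generator does **not** emulate: interparticle structure factors
beyond the first-order virial, polydispersity in Z or core size,
q-resolution smearing, buffer-subtraction artefacts, and radiation
damage.  Passing recovery tests therefore demonstrate the correctness
and statistical calibration of the estimators under the stated model,
not robustness to every artefact of measured data.

## Reference recovery studies

`validation.star_cylinder_recovery` regenerates the low-salt star-brush
conditions (Z = 2, cylindrical core R = 0.89 nm, L = 1.19 nm, tails at
nu = 0.73 for N = 146, domain-split scattering lengths b_c : b_t =
50 : 96, 1% relative noise, 25 replicates) and reports the modal rounded
Z and mean core dimensions from free-core fits with replicate branch
reconciliation.  `validation.chain_recovery` regenerates 50 chain curves
at the high-salt infinite-dilution exponent (nu = 0.62, N = 104, 1.5%
noise) and reports the mean recovered exponent.  Problem sizes (25 and
50 replicates, 400-point curves) keep each study under a minute on one
CPU while the Monte-Carlo means are stable to well inside the quoted
tolerances.

## Known limitations

* The cylinder (R, L) split is fundamentally weakly identified without
  the form-factor minimum in range (see above); report V and h/rho when
  branch selection is uncertain.
* A2 is reported in relative units unless an absolute calibration is
  provided; comparisons across instruments require calibration.
* The theory overlays are scaling laws with order-unity prefactors; they
  support trend comparisons, not absolute structure determination.
* Tails are Gaussian (Debye) inside the star model; excluded-volume tail
  statistics enter only through the a-posteriori h → nu conversion.
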