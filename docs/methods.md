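# Methods

## Model

The package integrates a five-variable compartment model of a well-mixed
tumor microenvironment (TME). Cancer cells are split into a non-stem pool `C`
and a stem pool `S` (volumes, mm³); active T cells, IFN-γ, and protons are
tracked as extensive totals (`E·V` cells, `I·V` pg, `H·V` mol, with
`V = C + S`). Writing the dynamics in extensive form keeps the equations in
the products that the biology specifies (influx proportional to volume,
decay proportional to totals) and avoids quotient-rule errors; densities are
derived on demand as `E = EV/V` etc., which is why the model is undefined at
`V = 0` and every integration carries a terminal elimination event.

Assumptions, in brief: logistic tumor growth with carrying capacity `K`;
stem cells divide asymmetrically with probability σ (the asymmetric branch
produces a non-stem cell) and are killed only by T cells, while non-stem
cells also undergo apoptosis at rate `n`; T-cell killing is proportional to
T-cell *density* rather than count, so a stem-cell-rich tumor dilutes the
attack on non-stem cells; PD-1/PD-L1 engagement (PD-1⁺ fraction `p`, PD-L1
fraction `L = α + β I/(ζ+I)` with constitutive and IFN-γ-driven parts)
anergizes T cells; protons come from metabolism (δ) and from CAIX (`q`),
exchange with the physiological baseline at rate `v`, and kill T cells at
rate `η·max(1 − H_thresh/H, 0)` once the pH drops below 6.7. Treatment is a
piecewise-constant triple `(d₁, d₂, d₃)`: anti-PD-1 scales `p` by `(1−d₁)`,
anti-CTLA-4 scales T-cell influx by `(1+d₂)`, anti-CAIX scales `q` by
`(1−d₃)`. No pharmacokinetics: effects are constant inside a window and zero
outside (half-open `[t_start, t_end)` convention).

pH conversion uses the mol/mm³ → mol/L factor 10⁶; this is the only reading
under which the packaged proton thresholds (`H_thresh = 2e-13` mol/mm³ ↔ pH
6.7, `H₀ = 3.98e-14` mol/mm³ ↔ pH 7.4) are internally consistent.

## Parameters and the growth-rate recalibration

`ModelParameters` defaults reproduce the published tables: literature
constants plus the fitted free parameters (`a* = a·m·μ = 834.16`,
`b* = b·μ = 5821`, `η = 2485`, `n = 0.799`, `q = 7.6258e-13`; per-cohort
inoculation fractions; stem fraction `3.083e-5`). Only the composites are
primitive — the individual factors were never separately fitted — but
configuration files may supply `a, m, mu, b` and the loader multiplies them.
Validation is strict at construction: all rates non-negative, fractions in
[0, 1], and `β ≤ 1 − α` (the PD-L1⁺ fraction must remain a fraction) is a
hard error.

The printed maximal growth rate φ = 2417.2 day⁻¹ is dynamically inconsistent
with the rest of the published results: at that rate the logistic transient
saturates in hours, every tumor sits at ≈ K regardless of immune pressure
(knockout and control plateaus both ≈ 1200 mm³ instead of ≈ 759 vs
1179 mm³), and the reduced model's knockout case retains a positive steady
state instead of collapsing to the origin. `recalibrate_phi()` therefore
refits φ — and φ only — by bounded least squares on scaled residuals of the
three published long-horizon anchors (control maximum 1179 mm³ at
inoculation fraction 0.1; knockout plateau 759 mm³ at 0.336; control plateau
1179 mm³ at 0.210), restarted from a log-spaced grid so the result is
deterministic. The fit gives φ ≈ 1.4097 day⁻¹ with anchor residuals
(−3.7%, +0.7%, −3.7%); no single φ does better simultaneously, because the
control anchor alone prefers φ ≈ 4.4 while the knockout anchor prefers
φ ≈ 1.4. With the recalibrated rate the control trajectory is monotone, so
its maximum is the plateau itself (reached near day 100 rather than day 40).
`fitted_parameters()` caches this per process; the printed value remains the
raw default so the discrepancy stays visible.

## Numerics

Forward simulation uses `scipy.integrate.solve_ivp` with LSODA (rate
constants span thirteen orders of magnitude; explicit solvers stall), an
analytic Jacobian, `rtol = 1e-8`, and per-component absolute tolerances
`(1e-12, 1e-12, 1e-7, 1e-10, 1e-22)` for `(C, S, EV, IV, HV)` — roughly
1e-12 relative to each variable's working magnitude (volumes ~10³ mm³,
T cells ~10⁵, protons ~10⁻¹⁰ mol). Time is split at treatment-window
boundaries so the solver never crosses a discontinuous right-hand side. The
elimination event fires when `V` drops below 10⁻⁶ mm³ (well under one cell
volume, 6.2×10⁻⁶ mm³); elimination is absorbing and no post-elimination
states are reported. Halving the tolerances moves the day-200 control volume
by < 0.1%.

The acidosis term has a kink at `H = H_thresh`; the Jacobian uses the
one-sided derivative (zero below threshold). Near total collapse the density
`E = EV/V` is singular as `V → 0⁺`, which is exactly why integration stops
at the elimination threshold.

## Steady-state analysis

For the reduced model, the T-cell nullcline condition is a quadratic in
`x = E·S` with coefficients `A = (r/ω)(d_eff + a*p′(α+β))`,
`B = b*′ r/ω − d_eff ζ − a*p′αζ`, `C = b*′ζ`, where `p′ = p(1−d₁)`,
`b*′ = b*(1+d₂)`, and `d_eff = d + η·max(1 − H_thresh/H*, 0)` folds the acid
death at the quasi-steady proton level `H* = (δ + q(1−d₃) + vH₀)/v`. Since
`A, C > 0`, the discriminant is positive and the roots have opposite signs;
the positive root is the nullcline slope `c₁`. The tumor nullcline
coefficient `c₂ = φ/(a*·vc (1 − p′L))` depends on the PD-L1 fraction at the
equilibrium T-cell density: on the T-cell nullcline that density is exactly
`E = x/S = c₁`, so the package evaluates `L` at `I = r·c₁/ω`, which makes
the closed form `S* = (1 − c₁/c₂)K`, `ES* = c₁S*` exact (verified against a
brute-force 2-D root solve to 1e-8 relative). The origin is a boundary limit
point of the density formulation rather than an interior equilibrium; it is
labelled attracting exactly when the positive equilibrium does not exist
(near `S = 0` the reduced tumor equation grows like `φ(1 − c₁/c₂)S`), and
the positive equilibrium's stability is read from the eigenvalues of a
central-difference Jacobian.

The packaged phase-portrait settings (`b* = 3×10⁴`, `η = 10⁶`) represent an
immunotherapy-boosted immune response and use the recalibrated φ — with the
printed rate `c₂ ≈ 5×10⁵` dwarfs any `c₁` and the knockout collapse cannot
occur.

## Calibration

The loss is the scaled sum of squares `Σᵢ ((yᵢ − ŷᵢ)/yᵢ)²` pooled over all
cohorts (30 points in the default design). The optimizer is bounded
trust-region least squares (`scipy.optimize.least_squares`) on the scaled
residual vector, multistarted from points sampled uniformly within the
published bounds; all parameters are shared across cohorts except the
per-cohort inoculation fraction. Knockout cohorts set `q = 0`; untreated
cohorts zero their effect flags; treatment (where active) spans the whole
observation window from inoculation, since no dosing calendar is published
and effects are constant by assumption.

Numerical choices specific to fitting:

- Residuals are evaluated through a low-overhead path
  (`scipy.integrate.odeint` with a numba-compiled right-hand side and
  Jacobian, rtol 1e-6) that agrees with the reference integrator to ≤ 2e-7
  relative on the design cohorts and falls back to it on the rare
  pathological parameter corners where the regularized integration fails.
- The fitting elimination threshold is 0.01 mm³ (≈ 1600 cells), far below
  caliper resolution: random starts frequently visit collapsing tumors, and
  resolving the near-singular approach to `V = 0` at every residual
  evaluation dominates cost without changing any residual measurably.
  Volumes below threshold predict as zero (flagged), so an eliminated
  prediction against positive data contributes a unit scaled residual.
- Finite-difference steps use `diff_step = 1e-3` (relative), well above the
  integration noise floor.
- Inoculation-fraction lower bounds are clipped to 1e-6 because the model is
  undefined at zero initial volume.
- Multistart strategy: the published procedure optimizes every start
  (`polish_top=None`, default, with `n_starts = 1000`). For desk-scale runs
  a prescreen-and-polish alternative evaluates the loss once at every sampled start and
  fully optimizes only the `polish_top` most promising, each with up to
  `polish_rounds` trust-region restarts — restarting resets the trust region
  and reliably escapes premature `xtol` stalls on this problem. An optional
  `loss_tol` stops refinement once the loss is far below any practical
  convergence requirement (tests use 5e-7 for noise-free data).

On noise-free synthetic data the refit reaches loss < 1e-6, but not all
parameters are identifiable from 30 points: at the fitted dose magnitudes
(`d₁ = 0.028`, `d₂ = 0.011`) the checkpoint effects are near-flat directions
and their recovered values are meaningless even at near-zero loss. The
recovery report therefore returns per-parameter relative errors alongside a
local loss-curvature flag per parameter, and tests assert recovery only for
the identifiable subset (infiltration `b*`, apoptosis `n`, CAIX production
`q`, and the inoculation fractions).

## Synthetic data

The generator emulates the murine design: six cohorts (control, CAIX
knockout, treatment-free vehicle, anti-CAIX, ICI, anti-CAIX+ICI), five
measurement days each — (6, 8, 11, 13, 15) for the control/knockout growth
comparison, (10, 12, 14, 17, 19) for the treatment cohorts — with true
parameters defaulting to the fitted set (recalibrated φ, so curves evolve on
realistic multi-week scales). Noise is multiplicative Gaussian,
`V·(1 + ε)`, `ε ~ N(0, CV²)` with CV = 10% by default, truncated at 0.1% of
the noise-free value to keep volumes positive (the loss divides by data);
replicates are averaged, and per-day SEMs are attached when replicates > 1.
The proportional noise model follows from the loss itself, which scales
residuals by the data; the published experiments report only cohort means,
so the synthetic SEMs describe generator spread, not the original animals.
What passing tests show: the pipeline (generate → fit → compare) is
self-consistent under the model's own dynamics and noise. What they do not
show: robustness to real-data features — per-animal heterogeneity, dropout,
caliper bias, or model misspecification.

## Problem sizes used by the test suite

Oracle and property checks run at full published scale (100 equilibrium
parameter sets against the brute-force root solve, 1000 draws for the
discriminant/Vieta properties). Calibration studies run at desk scale as the
package's own choice: the noise-free loop closure uses 50 starts with
top-5 polishing, and the CV-10% replicate study uses three replicate fits of
eight starts each; the full 1000-start procedure remains available through
`FitSpec(n_starts=1000, polish_top=None)`.

## Known limitations

- The model is undefined without a tumor; post-elimination dynamics
  (immune contraction, dormancy, re-challenge) are out of scope.
- No drug pharmacokinetics: treatment effects switch on and off
  instantaneously at window boundaries.
- Single well-mixed compartment — no spatial gradients of pH or infiltrate.
- The recalibrated φ is a compromise across the three published anchors; the
  control-side anchors are reproduced at −3.7% rather than exactly, and the
  published "maximum on day 40" is realized as a monotone approach to the
  plateau rather than a transient peak.
- Calibration identifiability is limited at the published dose magnitudes;
  interpret fitted `d₁`, `d₂` (and to a lesser degree `a*`, η,
  stem fraction) through the curvature flags, not at face value.
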