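# Methods

## Model

The lung is `m = 2^n` terminal compartments at the leaves of a dichotomous
airway tree with `n` generations. Airway `(j, k)` (generation `j`, index
`k = 1..2^j`) carries resistance `R_{j,k}` (cmH2O·s/l) and serves the
compartment block picked out by the 0/1 structure vector `Z_{j,k}` (entries
`(k−1)2^{n−j}+1 .. k·2^{n−j}`). Summing the per-path pressure balances gives
the vector state equation `R x' + C(x) x = p(t) e` with
`R = Σ R_{j,k} Z_{j,k} Z_{j,k}ᵀ`; `R` is symmetric positive definite for
positive resistances, so the flow map `x' = R⁻¹(p e − C(x) x)` is always
well defined. Entry `(i, i')` of `R` equals the summed resistance of the
airways shared by the tracheal paths of compartments `i` and `i'`, which is
the independent oracle the construction is tested against.

Each compartment's compliance `c(x)` is piecewise linear in its volume: a
rising limb `a1 + b1 x` (recruitment, `b1 > 0`), a plateau `a2`, and a
falling limb `a3 + b3 x` (overdistension, `b3 < 0`), with breakpoints
`x1 < x2` and stated domain `[0, v_cap]`. The solvers use a C-infinity
approximation in which each kink is replaced by a sigmoidal ramp of
sharpness `beta_smooth` (default 30 l⁻¹); the ramp anchors are the volumes
where the rising/falling limbs extrapolate to zero compliance and to the
plateau value. Beyond the stated domain the piecewise form extends the
falling limb affinely and the smooth form follows its natural sigmoid
extension; both are floored at 1e-6 l/cmH2O through a smooth positive-part
`(c + √(c² + 4f²))/2` so the elastance `1/c` and its derivative remain
finite and smooth everywhere (relative distortion where `c ≫ f` is below
1e-9). The reference inspiratory parameter set is discontinuous at `x2`
(falling-limb value 0.2484 vs plateau 0.025 l/cmH2O); parameters are stored
exactly as given and a warning is emitted when the jump exceeds 1% of the
plateau. Breakpoint ties resolve to the left-closed segment. An exact
constant-compliance mode covers the single-compartment linear special case.

## Optimal inspiration (closed form)

`J_in = ∫ x''ᵀx'' + α₁ p_in eᵀx' dt` with rest-to-rest boundary conditions
`x(0) = V₀`, `x(T_in) = V₀+V_T`, `x'(0) = x'(T_in) = 0`. Substituting the
state equation for `p_in e` splits the work term into a resistive quadratic
`x'ᵀR_in x'` and a compliance term `xᵀC(x)x'` whose time integral is a pure
function of the endpoint volumes; the criterion is therefore strictly convex
in the trajectory and its stationarity condition is the linear equation
`x'''' = α₁ R_in x''` — the optimum is independent of the compliance.

With `R_in = QΛQᵀ` and modal rates `μ_i = √(α₁λ_i)`, each mode is solved in
the basis `{1, s, (cosh(μs)−1)/μ², (sinh(μs)−μs)/μ³}`, which limits smoothly
to the cubic basis `{1, s, s²/2, s³/6}` as `α₁ → 0`; the boundary system
reduces to one well-conditioned 2×2 solve per mode for any `μ`, avoiding
both the overflow of `exp(μT)` and the cancellation of the exponential
coefficients at small `α₁` (the `α₁ = 1e-8` solution matches the `α₁ = 0`
cubic to 6e-11 sup-norm). The equivalent `d₁ + d₂t + e^{At}d₃ + e^{−At}d₄`
coefficients (`A = √α₁ R_in^{1/2}`, the unique SPD square root) are reported
for inspection but never used for evaluation. For `α₁ = 0` the solution is
the cubic `d₁ = V₀`, `d₂ = 0`, `d₃ = 3V_T/T_in²`, `d₄ = −2V_T/T_in³`.

## Optimal expiration (collocation BVP)

`J_ex = ∫ x''ᵀx'' + α₂ p_ex² eᵀe dt` with the mirrored rest-to-rest
conditions. Eliminating `p_ex e = R_ex x' + C_ex(x)x` makes the integrand
`x''ᵀx'' + α₂‖R_ex x' + C_ex(x)x‖²`; stationarity yields a fourth-order
equation containing `C_ex(x)`, its derivative `C'_ex = diag(d(1/c_i)/dx_i)`
(always the analytic smoothed form) and `X = diag(x_i)`. For `α₂ > 0` the
first-order reduction `y = (x, x', x'', x''')` (dimension 4m, 2m boundary
conditions per end) is solved with `scipy.integrate.solve_bvp` at tolerance
1e-8 and up to 20000 mesh nodes, starting from the `α₂ = 0` Hermite cubic;
if the direct solve fails, continuation in `α₂` over four steps is used
(the reference configurations solve directly in ~1 s). Stationarity
residuals are evaluated at the interpolant's collocation points (mesh nodes
and interval midpoints); converged solves sit near 1e-8. For `α₂ = 0` the
equation collapses to `x'''' = 0` and the exact Hermite cubic is returned.

The printed reference coefficients for the `α₂ = 0` cubic (kept verbatim in
`remark4_coefficients`, flagged `as_printed`) satisfy the start conditions
and the terminal zero-flow condition but not the terminal volume (they end
0.634 l above `V₀` for the reference timing), so they cannot be the
boundary-consistent cubic; `solve_expiration` returns the Hermite cubic,
which is the unique minimiser of `∫x''ᵀx''` under the four conditions.

For a single compartment with constant compliance the equation is linear
with constant coefficients; its solution family changes character at the
discriminant threshold `α₂ = 4C_ex²/R_ex⁴` (`classify_linear_regime`), and
the collocation solution matches the characteristic-root solution of the
linear BVP to ~1e-11.

## Pressures, criteria, cycles

Per-compartment driving pressures are reconstructed as rows of
`R x' + C(x) x`. For heterogeneous compartments the optimum need not be
realisable by a single airway pressure, so the mean across compartments
(*consensus*) and the maximum deviation from it (*spread*) are always
reported; identical compartments give spread at roundoff level. The
criteria are integrated by composite Simpson quadrature on the trajectory
grid (smooth integrands; doubling the grid moves values by <1e-8 relative).
`run_cycle` chains the two solvers through the shared boundary data, so the
assembled trajectory is continuous at `T_in` and periodic by construction.
`limit_cycle_analysis` iterates forward-simulated cycles (LSODA, rtol 1e-8,
atol 1e-10) and returns the fixed point of the cycle map with the distance
sequence; under the reference waveforms (ramp `20t+5`, passive zero) the
map is strongly contracting and converges in two cycles.

## Independent verification

Two oracles share no code with the solvers. (1) *Direct transcription*:
each phase criterion is discretised on a uniform grid with central
differences, the zero-flow boundary conditions built into the stencils by
ghost-point reflection, and trapezoid quadrature weights. Trapezoid, not
Simpson, is deliberate: Simpson's alternating 4/2 weights admit even/odd
grid oscillations that lower the discrete curvature cost by ~11% without
moving the trajectory, an artifact absent with uniform weights. The
expiratory discrete functional is an exact weighted sum of squares and is
minimised by a damped Gauss–Newton iteration on sparse banded normal
equations; the inspiratory one is quadratic plus the near-constant
compliance potential and is minimised by Newton steps with the exact
quadratic Hessian. Gradients are fully analytic. At N = 641 (with multigrid
warm starts) the transcription minimiser agrees with the collocation
solution to ≤7e-4 l sup-norm and ≤0.4% in criterion value across the tested
weights; the agreement tightens monotonically with N. (2) *Manufactured
solutions*: the expiratory stationarity operator is applied to a random
trigonometric trajectory twice — analytic derivatives vs pure
finite-difference derivatives of the sampled volumes — using 6th-order
stencils at step 0.02 s, chosen because the fourth-difference quotient hits
its double-precision roundoff floor near 1e-2 at fine steps and the steep
elastance derivative amplifies first-derivative errors by ~1e4; the two
evaluations agree to ~2e-8.

## Reference configurations

`paper_2comp` is the two-compartment configuration used throughout:
compliance parameters as printed for both phases (`a2 = 0.025` inspiratory
/ `0.038` expiratory l/cmH2O plateaus, breakpoints 0.3/0.48 and 0.23/0.43 l,
`v_cap = 0.6` l, `beta_smooth = 30`), `T_in = 2` s, `T_ex = 3` s,
`α₁ = 2.0`, `α₂ = 0.1`, summed end-expiratory volume 0.2 l and summed tidal
volume 1.2 l split equally across compartments (0.1/0.6 l each; the split
is not dictated by the totals and is overridable). The absolute airway
resistances behind the published figures are cited to tabulated
physiological values but not printed, so documented defaults are used:
parent airway 1.0 cmH2O·s/l, each generation-j airway `0.5·2^j`, and
expiratory resistances 2.5× inspiratory. `paper_4comp` uses `n = 2` with
the same compliance curves per compartment (hence `v_cap` stays 0.6 l even
though the per-compartment tidal split is 0.3 l) and the same totals.
`random` draws seeded, breakpoint-continuous curves (`b1 > 0`, `b3 < 0`)
and positive resistances for property tests. Default output grids are 401
points per phase; solver tolerances are rtol 1e-8 / atol 1e-10 (forward),
1e-8 (collocation), chosen so trajectories can feed fourth-derivative
residual checks.

## A model finding, and limitations

Under the reference parameters the per-compartment end-inspiratory volume
(0.7 l) lies beyond the zero-crossing of the printed expiratory falling
limb (`a3 + b3 x = 0` at 0.683 l), so at the start of expiration the
smoothed compliance is ~0.0024 l/cmH2O and the implied static recoil
pressure ~296 cmH2O. The squared-pressure term then makes it optimal to
leave this region fast: the expiratory optimum has a deep early flow trough
(−3.0 l/s summed at `α₂ = 0.1`) and *undershoots* the end-expiratory volume
(minimum summed volume ≈ −0.02 l, transiently negative) before returning to
`V₀` at `T_in + T_ex`. This is a property of the minimiser, not a solver
artifact — the independent transcription oracle reproduces it and assigns
the non-monotone trajectory a criterion value an order of magnitude below
the monotone cubic's. Monotone decreasing expiration, often taken for
granted for this criterion family, therefore fails for parameter sets whose
tidal range exhausts the expiratory compliance curve; with resistances or
volume splits that keep `x_i` inside the compliant range the computed
optima are monotone. The trough-in-first-half and trough-steepens-with-`α₂`
properties hold regardless.

Other limitations: trees are strictly dichotomous with volume-independent
resistances; expiration is passive (no muscle pressure, no intrinsic PEEP);
the four closed-form solution families of the linear single-compartment
case are classified but not constructed; the synthetic `random`
configurations exercise code paths, not physiological variability — passing
property tests shows correctness of the mathematics on those inputs, not
calibration to real patient data. Volumes are not constrained to be
nonnegative, which is exactly what makes the undershoot observable rather
than hidden by a constraint the criterion does not contain.
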