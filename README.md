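# lungflow

Optimal respiratory airflow patterns for a nonlinear multicompartment lung
mechanics model.

`lungflow` is aimed at researchers in respiratory physiology and mechanical
ventilation who need clinically plausible *reference breathing patterns* for
ventilator control design. It models the lung as `m = 2^n` compartments fed
through a dichotomous airway tree, with volume-dependent (piecewise-linear,
sigmoidally smoothed) compliance, and computes the inspiratory and expiratory
volume trajectories that minimise classical breathing-effort criteria by
calculus of variations.

## Model

During each phase the compartment volumes `x(t) ∈ R^m` obey the pressure
balance

```
R x'(t) + C(x(t)) x(t) = p(t) e,
```

where `R = Σ_{j,k} R_{j,k} Z_{j,k} Z_{j,k}^T` is the symmetric
positive-definite resistance matrix assembled from the per-airway resistances
`R_{j,k}` (cmH2O·s/l) and the airway structure vectors `Z_{j,k}`,
`C(x) = diag(1/c_i(x_i))` is the diagonal elastance matrix built from the
per-compartment compliance curves `c_i` (l/cmH2O), `p(t)` is the airway
opening pressure and `e` the all-ones vector. Separate resistance and
compliance parameter sets are used for inspiration and expiration.

**Inspiration** minimises volume acceleration plus work of breathing,

```
J_in(x) = ∫₀^T_in [ x''ᵀx'' + α₁ p_in(t) eᵀx' ] dt ,
```

over trajectories running from rest at the end-expiratory volume `V₀` to rest
at `V₀ + V_T` (tidal volume `V_T`). The Euler–Lagrange equation is the
*linear* fourth-order system `x'''' − α₁ R_in x'' = 0` — independent of the
compliance — solved in closed form (a cubic when `α₁ = 0`, otherwise
`d₁ + d₂t + e^{At}d₃ + e^{−At}d₄` with `A = √α₁ R_in^{1/2}`).

**Expiration** minimises acceleration plus the integral square of the driving
pressure (an elastic-potential/oxygen-cost surrogate),

```
J_ex(x) = ∫_{T_in}^{T_in+T_ex} [ x''ᵀx'' + α₂ p_ex²(t) eᵀe ] dt ,
```

whose stationarity condition is a genuinely nonlinear fourth-order two-point
boundary-value problem in `C_ex(x)` and its derivative; it is solved by
collocation on the first-order system of dimension `4m`.

The package also reconstructs per-compartment driving pressures from any
trajectory, evaluates the criteria by quadrature, iterates breathing cycles
to their limit cycle under prescribed pressures, and cross-checks both
solvers against an independent direct-transcription minimiser.

## Worked example

```python
import numpy as np
from lungflow import make_fixture, run_cycle

model, spec = make_fixture("paper_2comp")   # two compartments, T_in=2 s,
                                            # T_ex=3 s, alpha1=2.0, alpha2=0.1
bundle = run_cycle(model, spec)

print(f"J_in  = {bundle.report.J_in:8.3f}")
print(f"J_ex  = {bundle.report.J_ex:8.3f}")
tot = bundle.trajectory.total("x")
print("summed volume at t=0, T_in, T_in+T_ex:",
      f"{tot[0]:.3f}, {bundle.inspiration.total('x')[-1]:.3f}, {tot[-1]:.3f} l")
print(f"peak inspiratory flow  = {bundle.inspiration.total('dx').max():.3f} l/s")
flow = bundle.expiration.total("dx")
i = np.argmin(flow)
print(f"expiratory flow trough = {flow[i]:.3f} l/s at t = {bundle.expiration.t[i]:.3f} s")
print(f"pressure spread (max)  = {bundle.pressure_in.max_spread:.2e} cmH2O")
```

prints

```
J_in  =   42.663
J_ex  =  568.114
summed volume at t=0, T_in, T_in+T_ex: 0.200, 1.400, 0.200 l
peak inspiratory flow  = 0.832 l/s
expiratory flow trough = -3.022 l/s at t = 2.075 s
pressure spread (max)  = 7.11e-15 cmH2O
```

The cycle runs from the summed end-expiratory volume 0.2 l up to 1.4 l and
back, with the boundary conditions met exactly. The inspiratory flow is
symmetric about `T_in/2` and flattens as `α₁` grows; the expiratory flow is
asymmetric with a deep trough early in expiration that steepens with `α₂`.
The near-zero pressure spread confirms that, for identical compartments, the
optimum is realisable by a single airway-opening pressure. Note the early
expiratory trough here is extreme (−3 l/s): at the end-inspiratory volume
the expiratory compliance curve is almost exhausted, so the squared-pressure
term forces a fast initial emptying that briefly undershoots the
end-expiratory level — see `docs/methods.md` for a discussion.

A command-line interface mirrors the library:

```
lungflow fixture paper_2comp -o model.json
lungflow solve --config model.json --phase cycle -o run
lungflow validate --config model.json -o validation.json
```

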