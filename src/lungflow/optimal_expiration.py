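"""Optimal expiratory trajectory: a nonlinear fourth-order boundary-value problem.

The expiratory criterion weighs squared volume acceleration against the
integral square of the driving pressure (a surrogate for the elastic
potential energy stored in the lung),

    J_ex(x) = int_{T_in}^{T_in+T_ex} [ x''^T x'' + alpha2 * p_ex^2(t) e^T e ] dt,

with rest-to-rest boundary conditions x(T_in) = V0 + VT, x(T_in+T_ex) = V0
and zero flow at both ends.  Eliminating the pressure via the expiratory
state equation gives the Euler–Lagrange equation

    x'''' - alpha2 R_ex^2 x'' + alpha2 C_ex^2(x) x
      + alpha2 [ C_ex R_ex x' - R_ex C_ex x' + X C_ex' R_ex x'
                 - R_ex C_ex' X x' + X C_ex' C_ex x ] = 0,

where C_ex(x) = diag(1/c_i(x_i)), C_ex'(x) = diag(d/dx_i 1/c_i) and
X = diag(x_i).  The compliance nonlinearity makes this genuinely nonlinear,
so for alpha2 > 0 it is solved by collocation as a first-order system of
dimension 4m with 2m boundary conditions at each end; for alpha2 = 0 it
collapses to x'''' = 0, whose unique solution is the rest-to-rest Hermite
cubic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_bvp

from .forward_dynamics import Trajectory
from .lung_model import LungModel, ModelError
from .optimal_inspiration import BreathSpec, ClosedFormCoefficients, hermite_cubic

__all__ = ["BvpSolution", "solve_expiration", "expiration_el_residual",
           "classify_linear_regime", "remark4_coefficients", "BvpError"]


class BvpError(RuntimeError):
    """Collocation failure; carries the residual history of the attempts."""

    def __init__(self, message, history):
        super().__init__(message)
        self.history = history


@dataclass
class BvpSolution:
    """Converged collocation (or closed-form) solution of the expiratory problem."""

    trajectory: Trajectory
    mesh: np.ndarray
    max_residual: float
    converged: bool
    diagnostics: dict = field(default_factory=dict)
    coefficients: ClosedFormCoefficients | None = None


def _el_rhs(model: LungModel, alpha2: float, R: np.ndarray, R2: np.ndarray,
            x: np.ndarray, dx: np.ndarray, ddx: np.ndarray) -> np.ndarray:
    """x'''' from the Euler–Lagrange equation; arrays shaped (m, K)."""
    el = model.elastance_vector(x, "expiration")
    elp = model.elastance_derivative_vector(x, "expiration")
    Rdx = R @ dx
    bracket = (el * Rdx - R @ (el * dx)
               + x * elp * Rdx - R @ (elp * x * dx)
               + x * elp * el * x)
    return alpha2 * (R2 @ ddx - el ** 2 * x - bracket)


def solve_expiration(model: LungModel, spec: BreathSpec, n_grid: int = 401,
                     tol: float = 1e-8, max_nodes: int = 20000,
                     n_mesh: int = 81) -> BvpSolution:
    """Solve the expiratory two-point boundary-value problem.

    For ``alpha2 > 0`` the fourth-order Euler–Lagrange equation is reduced to
    the first-order system y = (x, x', x'', x''') and solved by collocation,
    starting from the rest-to-rest cubic and, if the direct solve fails,
    continuing in alpha2 over four steps.  For ``alpha2 = 0`` the exact
    Hermite cubic is returned.
    """
    if spec.m != model.m:
        raise ModelError("boundary vectors do not match the compartment count")
    m = model.m
    t0, t1 = spec.T_in, spec.T_in + spec.T_ex
    x_start, x_end = spec.V0 + spec.VT, spec.V0
    cubic = hermite_cubic(t0, spec.T_ex, x_start, x_end)
    t = np.linspace(t0, t1, n_grid)

    if spec.alpha2 == 0.0:
        traj = _traj_from_coeffs(cubic, t)
        return BvpSolution(trajectory=traj, mesh=t, max_residual=0.0,
                           converged=True, coefficients=cubic,
                           diagnostics={"iterations": 0, "method": "closed-form"})

    R = model.R_ex
    R2 = R @ R

    def make_fun(a2):
        def fun(tt, y):
            x, dx, ddx, d3x = y[:m], y[m:2 * m], y[2 * m:3 * m], y[3 * m:]
            return np.vstack([dx, ddx, d3x,
                              _el_rhs(model, a2, R, R2, x, dx, ddx)])
        return fun

    def bc(ya, yb):
        return np.concatenate([ya[:m] - x_start, ya[m:2 * m],
                               yb[:m] - x_end, yb[m:2 * m]])

    def guess_from(coeffs_like, mesh):
        return np.vstack([coeffs_like.derivatives(mesh, k).T for k in range(4)])

    mesh = np.linspace(t0, t1, n_mesh)
    history = []
    sol = solve_bvp(make_fun(spec.alpha2), bc, mesh, guess_from(cubic, mesh),
                    tol=tol, max_nodes=max_nodes)
    history.append(("direct", spec.alpha2, sol.status, float(sol.rms_residuals.max())))
    if sol.status != 0:
        # continuation in alpha2 from the cubic end of the family
        y = guess_from(cubic, mesh)
        tt = mesh
        for a2 in np.linspace(spec.alpha2 / 4, spec.alpha2, 4):
            sol = solve_bvp(make_fun(a2), bc, tt, y, tol=tol,
                            max_nodes=max_nodes)
            history.append(("continuation", a2, sol.status,
                            float(sol.rms_residuals.max())))
            if sol.status != 0:
                raise BvpError(
                    f"collocation failed at alpha2={a2:.4g}: {sol.message}",
                    history)
            tt, y = sol.x, sol.y
    yg = sol.sol(t)
    x, dx, ddx, d3x = (yg[:m].T, yg[m:2 * m].T, yg[2 * m:3 * m].T, yg[3 * m:].T)
    d4x = _el_rhs(model, spec.alpha2, R, R2, yg[:m], yg[m:2 * m],
                  yg[2 * m:3 * m]).T
    traj = Trajectory(t=t, x=x, dx=dx, ddx=ddx, phase="expiration",
                      label="optimal",
                      extras={"d3x": d3x, "d4x": d4x,
                              "spline": sol.sol, "mesh": sol.x})
    bvp = BvpSolution(
        trajectory=traj, mesh=sol.x,
        max_residual=float(sol.rms_residuals.max()), converged=True,
        diagnostics={"iterations": int(sol.niter), "mesh_size": sol.x.size,
                     "history": history, "method": "collocation"})
    bvp.max_residual = expiration_el_residual(traj, model, spec.alpha2)
    return bvp


def expiration_el_residual(traj: Trajectory, model: LungModel,
                           alpha2: float) -> float:
    """Max-norm residual of the full expiratory Euler–Lagrange equation.

    For a collocation solution the residual is evaluated at the interior
    mesh nodes and interval midpoints (the collocation points) using the
    solver's interpolant; otherwise the trajectory's stored analytic fourth
    derivative is used (finite-differenced third derivative as a fallback).
    """
    m = traj.m
    vcaps = [c.v_cap for c in model.compliance_ex if not c.constant]
    if vcaps and traj.x.max() > max(vcaps) + 1e-12:
        warnings.warn("trajectory leaves the compliance domain; "
                      "affine/sigmoid extension in effect", stacklevel=2)
    R = model.R_ex
    if "spline" in traj.extras:
        mesh = traj.extras.get("mesh", traj.t)
        pts = np.union1d(mesh, 0.5 * (mesh[:-1] + mesh[1:]))[1:-1]
        y = traj.extras["spline"](pts)
        x4 = traj.extras["spline"].derivative()(pts)[3 * m:]
        rhs = _el_rhs(model, alpha2, R, R @ R, y[:m], y[m:2 * m],
                      y[2 * m:3 * m])
        return float(np.max(np.abs(x4 - rhs)))
    if "d4x" in traj.extras:
        x4 = traj.extras["d4x"]
    elif "d3x" in traj.extras:
        x4 = np.gradient(traj.extras["d3x"], traj.t, axis=0)
    else:
        raise ModelError("trajectory carries no third/fourth derivative data")
    rhs = _el_rhs(model, alpha2, R, R @ R, traj.x.T, traj.dx.T, traj.ddx.T).T
    return float(np.max(np.abs((x4 - rhs)[1:-1])))


def classify_linear_regime(alpha2: float, R_ex: float, C_ex: float) -> str:
    """Character of the single-compartment constant-compliance problem.

    With scalar resistance ``R_ex`` and constant elastance coefficient
    ``C_ex`` (the reciprocal compliance), the Euler–Lagrange equation is the
    linear constant-coefficient ODE x'''' - alpha2 R^2 x'' + alpha2 C^2 x = 0,
    whose solution family changes character at the discriminant threshold
    ``alpha2 = 4 C_ex^2 / R_ex^4``.  Returns one of ``"zero"``,
    ``"subcritical"``, ``"critical"``, ``"supercritical"``.
    """
    if R_ex <= 0 or C_ex <= 0:
        raise ModelError("R_ex and C_ex must be positive")
    if alpha2 < 0:
        raise ModelError("alpha2 must be nonnegative")
    if alpha2 == 0:
        return "zero"
    crit = 4.0 * C_ex ** 2 / R_ex ** 4
    if abs(alpha2 - crit) <= 1e-12 * crit:
        return "critical"
    return "subcritical" if alpha2 < crit else "supercritical"


def remark4_coefficients(spec: BreathSpec) -> ClosedFormCoefficients:
    """The printed reference coefficients of the alpha2 = 0 expiratory cubic.

    Returned exactly as printed (in absolute time), flagged ``as_printed``.
    These coefficients match the start-of-expiration conditions but not the
    end-of-expiration ones (see :meth:`ClosedFormCoefficients.boundary_report`);
    the Euler–Lagrange-consistent alpha2 = 0 solution is the Hermite cubic
    that :func:`solve_expiration` returns.
    """
    Ti, Te = spec.T_in, spec.T_ex
    beta_cubic = 1.0 / (3 * Te ** 3 + 12 * Te ** 2 * Ti
                        + 12 * Te * Ti ** 2 + 4 * Ti ** 3)
    VT = spec.VT
    d1 = spec.V0 + VT + 3 * beta_cubic * Ti ** 2 * Te * VT \
        + 2 * beta_cubic * Ti ** 3 * VT
    d2 = -beta_cubic * (6 * Ti ** 2 * VT + 6 * Te * Ti * VT)
    d3 = beta_cubic * (3 * Te * VT + 6 * Ti * VT)
    d4 = -2 * beta_cubic * VT
    out = ClosedFormCoefficients(d1=d1, d2=d2, d3=d3, d4=d4, branch="cubic",
                                 t0=0.0, as_printed=True)
    out.beta_cubic = beta_cubic
    return out


def _traj_from_coeffs(coeffs: ClosedFormCoefficients, t: np.ndarray) -> Trajectory:
    return Trajectory(
        t=t, x=coeffs.derivatives(t, 0), dx=coeffs.derivatives(t, 1),
        ddx=coeffs.derivatives(t, 2), phase="expiration", label="optimal",
        extras={"d3x": coeffs.derivatives(t, 3),
                "d4x": coeffs.derivatives(t, 4),
                "coefficients": coeffs})
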