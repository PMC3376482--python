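"""Closed-form optimal inspiratory volume trajectory.

The inspiratory criterion weighs squared volume acceleration against the
mechanical work of breathing,

    J_in(x) = int_0^T_in [ x''(t)^T x''(t) + alpha1 * p_in(t) e^T x'(t) ] dt,

subject to x(0) = V0, x(T_in) = V0 + VT and zero flow at both endpoints.
Eliminating the pressure through the state equation, the work term splits
into a resistive quadratic and a pure endpoint (potential) term, so the
stationarity condition is the linear fourth-order equation

    x'''' - alpha1 * R_in * x'' = 0,

whose solution is available in closed form: a cubic polynomial when
alpha1 = 0, and d1 + d2 t + exp(A t) d3 + exp(-A t) d4 with
A = sqrt(alpha1) * R_in^(1/2) otherwise.  Notably the optimum does not
depend on the (nonlinear) compliance at all.

The boundary system is solved per eigenmode of R_in in a cosh/sinh
parametrisation, which stays well conditioned when exp(A T_in) is large.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward_dynamics import Trajectory
from .lung_model import LungModel, ModelError

__all__ = ["BreathSpec", "ClosedFormCoefficients", "solve_inspiration",
           "inspiration_el_residual"]


@dataclass(frozen=True, eq=False)
class BreathSpec:
    """Timing, boundary volumes and criterion weights for one breathing cycle.

    ``V0`` (l) is the per-compartment end-expiratory volume, ``VT`` (l) the
    per-compartment tidal volume; ``alpha1`` weighs work of breathing in the
    inspiratory criterion and ``alpha2`` the squared driving pressure in the
    expiratory one.
    """

    T_in: float
    T_ex: float
    V0: np.ndarray
    VT: np.ndarray
    alpha1: float = 0.0
    alpha2: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "V0", np.atleast_1d(np.asarray(self.V0, float)))
        object.__setattr__(self, "VT", np.atleast_1d(np.asarray(self.VT, float)))
        if self.T_in <= 0 or self.T_ex <= 0:
            raise ModelError("phase durations must be positive")
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ModelError("criterion weights must be nonnegative")
        if np.any(self.V0 < 0) or np.any(self.VT <= 0):
            raise ModelError("need V0 >= 0 and VT > 0 componentwise")
        if self.V0.shape != self.VT.shape:
            raise ModelError("V0 and VT must have the same length")

    @property
    def m(self) -> int:
        return self.V0.size

    def replace(self, **kw) -> "BreathSpec":
        d = {"T_in": self.T_in, "T_ex": self.T_ex, "V0": self.V0,
             "VT": self.VT, "alpha1": self.alpha1, "alpha2": self.alpha2}
        d.update(kw)
        return BreathSpec(**d)


@dataclass
class ClosedFormCoefficients:
    """Coefficient vectors of a closed-form branch solution.

    ``branch == "cubic"``:        x(s) = d1 + d2 s + d3 s^2 + d4 s^3,
    ``branch == "exponential"``:  x(s) = d1 + d2 s + exp(A s) d3 + exp(-A s) d4,

    with ``s = t - t0`` the time since the start of the phase (the printed
    expiratory reference coefficients use absolute time, ``t0 = 0``).
    """

    d1: np.ndarray
    d2: np.ndarray
    d3: np.ndarray
    d4: np.ndarray
    branch: str
    t0: float = 0.0
    A: np.ndarray | None = None
    # eigen data (Q, mu, E) for stable evaluation of the exponential branch:
    # modal coefficients E in the basis {1, s, (cosh(mu s)-1)/mu^2,
    # (sinh(mu s)-mu s)/mu^3}, which limits smoothly to {1, s, s^2/2, s^3/6}
    _eig: tuple | None = field(default=None, repr=False)
    as_printed: bool = False

    def derivatives(self, t, order: int = 0) -> np.ndarray:
        """k-th time derivative, shape (K, m)."""
        s = np.atleast_1d(np.asarray(t, float)) - self.t0
        if self.branch == "cubic":
            coef = [self.d1, self.d2, self.d3, self.d4]
            out = np.zeros((s.size, self.d1.size))
            for p in range(order, 4):
                fac = np.prod(np.arange(p - order + 1, p + 1)) if order else 1.0
                out += fac * np.outer(s ** (p - order), coef[p])
            return out
        Q, mu, E = self._eig
        z = np.outer(s, mu)                         # (K, m)
        e1, e2, e3, e4 = E
        ch = np.cosh(z)
        shm = s[:, None] * _sinhc(z)                # sinh(mu s)/mu
        f3 = 0.5 * s[:, None] ** 2 * _coshc2(z)     # (cosh(mu s)-1)/mu^2
        f4 = s[:, None] ** 3 / 6.0 * _sinhc3(z)     # (sinh(mu s)-mu s)/mu^3
        if order == 0:
            y = e1 + np.outer(s, np.ones_like(mu)) * e2 + e3 * f3 + e4 * f4
        elif order == 1:
            y = np.broadcast_to(e2, z.shape) + e3 * shm + e4 * f3
        elif order == 2:
            y = e3 * ch + e4 * shm
        elif order == 3:
            y = e3 * mu ** 2 * shm + e4 * ch
        elif order == 4:
            y = mu ** 2 * (e3 * ch + e4 * shm)
        else:
            raise ValueError("derivatives up to order 4 are available")
        return y @ Q.T

    def boundary_report(self, spec: BreathSpec, phase: str) -> dict:
        """Residuals of the four boundary conditions for the given phase."""
        if phase == "inspiration":
            t0, t1 = 0.0, spec.T_in
            x0, x1 = spec.V0, spec.V0 + spec.VT
        else:
            t0, t1 = spec.T_in, spec.T_in + spec.T_ex
            x0, x1 = spec.V0 + spec.VT, spec.V0
        return {
            "x_start": np.max(np.abs(self.derivatives(t0, 0)[0] - x0)),
            "dx_start": np.max(np.abs(self.derivatives(t0, 1)[0])),
            "x_end": np.max(np.abs(self.derivatives(t1, 0)[0] - x1)),
            "dx_end": np.max(np.abs(self.derivatives(t1, 1)[0])),
        }


def _sinhc(z):
    """sinh(z)/z, stable at z = 0."""
    small = np.abs(z) < 1e-4
    zs = np.where(small, 1.0, z)
    return np.where(small, 1.0 + z * z / 6.0, np.sinh(zs) / zs)


def _coshc2(z):
    """2 (cosh(z) - 1)/z^2, stable at z = 0 (uses cosh-1 = 2 sinh^2(z/2))."""
    small = np.abs(z) < 1e-4
    zs = np.where(small, 1.0, z)
    return np.where(small, 1.0 + z * z / 12.0,
                    4.0 * np.sinh(zs / 2.0) ** 2 / zs ** 2)


def _sinhc3(z):
    """6 (sinh(z) - z)/z^3, stable at z = 0."""
    small = np.abs(z) < 1e-2
    zs = np.where(small, 1.0, z)
    return np.where(small, 1.0 + z * z / 20.0 * (1.0 + z * z / 42.0),
                    6.0 * (np.sinh(zs) - zs) / zs ** 3)


def hermite_cubic(t0: float, T: float, x_start: np.ndarray,
                  x_end: np.ndarray) -> ClosedFormCoefficients:
    """The unique cubic joining two rest states (zero end flows) over [t0, t0+T]."""
    x_start = np.atleast_1d(np.asarray(x_start, float))
    delta = np.atleast_1d(np.asarray(x_end, float)) - x_start
    return ClosedFormCoefficients(
        d1=x_start, d2=np.zeros_like(x_start),
        d3=3.0 * delta / T ** 2, d4=-2.0 * delta / T ** 3,
        branch="cubic", t0=t0)


def solve_inspiration(model: LungModel, spec: BreathSpec, n_grid: int = 401
                      ) -> tuple[Trajectory, ClosedFormCoefficients]:
    """Optimal inspiratory trajectory on [0, T_in] in closed form.

    Returns the trajectory sampled on ``n_grid`` uniform points together with
    the closed-form coefficients.  Flows and accelerations are analytic; the
    third and fourth derivatives are stored in ``Trajectory.extras`` for
    residual diagnostics.
    """
    if spec.m != model.m:
        raise ModelError("boundary vectors do not match the compartment count")
    T = spec.T_in
    if spec.alpha1 == 0.0:
        coeffs = hermite_cubic(0.0, T, spec.V0, spec.V0 + spec.VT)
    else:
        R = model.R_in
        lam, Q = np.linalg.eigh(R)
        if lam.min() <= 0:
            raise ModelError("R_in is not positive definite")
        mu = np.sqrt(spec.alpha1 * lam)
        v0 = Q.T @ spec.V0
        vt = Q.T @ spec.VT
        # modal solution in the stable basis {1, s, f3, f4} with
        # f3 = (cosh(mu s)-1)/mu^2, f4 = (sinh(mu s)-mu s)/mu^3, which tends
        # to the cubic basis as alpha1 -> 0.  y(0) = v0 and y'(0) = 0 give
        # e1 = v0, e2 = 0; the end conditions a 2x2 system per mode.
        z = mu * T
        f3T = 0.5 * T ** 2 * _coshc2(z)
        f4T = T ** 3 / 6.0 * _sinhc3(z)
        shmT = T * _sinhc(z)
        det = f3T ** 2 - f4T * shmT
        e3 = f3T * vt / det
        e4 = -shmT * vt / det
        E = np.stack([v0, np.zeros_like(v0), e3, e4])
        # equivalent exp(+/-A t) coefficient vectors (cancellative for tiny
        # mu; reported for inspection, not used for evaluation)
        d1 = Q @ (v0 - e3 / mu ** 2)
        d2 = Q @ (-e4 / mu ** 2)
        d3 = Q @ (e3 / (2 * mu ** 2) + e4 / (2 * mu ** 3))
        d4 = Q @ (e3 / (2 * mu ** 2) - e4 / (2 * mu ** 3))
        A = (Q * mu) @ Q.T
        coeffs = ClosedFormCoefficients(d1=d1, d2=d2, d3=d3, d4=d4,
                                        branch="exponential", t0=0.0,
                                        A=A, _eig=(Q, mu, E))
    bc = coeffs.boundary_report(spec, "inspiration")
    if max(bc.values()) > 1e-9:
        raise ModelError(f"boundary system left residual {bc}")
    t = np.linspace(0.0, T, n_grid)
    traj = Trajectory(
        t=t, x=coeffs.derivatives(t, 0), dx=coeffs.derivatives(t, 1),
        ddx=coeffs.derivatives(t, 2), phase="inspiration", label="optimal",
        extras={"d3x": coeffs.derivatives(t, 3),
                "d4x": coeffs.derivatives(t, 4),
                "coefficients": coeffs})
    return traj, coeffs


def inspiration_el_residual(traj: Trajectory, model: LungModel,
                            alpha1: float) -> float:
    """Max-norm residual of x'''' - alpha1 R_in x'' over interior grid points.

    Uses the analytic derivatives stored by :func:`solve_inspiration` when
    present, otherwise central finite differences on the (uniform) grid.
    """
    if traj.t.size < 5:
        raise ModelError("need at least 5 grid points for the residual")
    if "d4x" in traj.extras:
        x2 = traj.ddx
        x4 = traj.extras["d4x"]
        res = x4[1:-1] - alpha1 * (x2[1:-1] @ model.R_in.T)
        return float(np.max(np.abs(res)))
    h = traj.t[1] - traj.t[0]
    if not np.allclose(np.diff(traj.t), h):
        raise ModelError("finite-difference residual needs a uniform grid")
    x = traj.x
    x4 = (x[:-4] - 4 * x[1:-3] + 6 * x[2:-2] - 4 * x[3:-1] + x[4:]) / h ** 4
    x2 = (x[1:-3] - 2 * x[2:-2] + x[3:-1]) / h ** 2
    return float(np.max(np.abs(x4 - alpha1 * (x2 @ model.R_in.T))))
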