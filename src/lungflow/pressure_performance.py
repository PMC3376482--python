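"""Driving-pressure reconstruction, performance functionals and cycle orchestration.

Given any volume trajectory, the per-compartment driving pressure follows
from the pressure balance ``p_i(t) = row_i( R x'(t) + C(x(t)) x(t) )``.  For
a trajectory realisable by a single airway-opening pressure all rows agree;
the *consensus* pressure (mean over compartments) and the *spread* (max
deviation from consensus) are reported so that heterogeneous cases, where
the optimum is not exactly realisable by one scalar pressure, are flagged
rather than silently averaged.

The inspiratory and expiratory criteria are evaluated in their eliminated
forms (pressure removed through the state equation):

    L_in = x''^T x'' + alpha1 [ x'^T R_in x' + x^T C_in(x) x' ],
    L_ex = x''^T x'' + alpha2 |R_ex x' + C_ex(x) x|^2 ,

integrated by composite Simpson quadrature on the trajectory grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, simpson

from .forward_dynamics import PressureWaveform, Trajectory, simulate_phase
from .lung_model import LungModel, ModelError
from .optimal_expiration import BvpSolution, solve_expiration
from .optimal_inspiration import BreathSpec, solve_inspiration

__all__ = ["PressureTrace", "PerformanceReport", "CycleBundle",
           "reconstruct_pressure", "performance_inspiration",
           "performance_expiration", "run_cycle", "simulate_cycle",
           "limit_cycle_analysis", "compare_performance", "LimitCycleError"]


@dataclass
class PressureTrace:
    """Reconstructed driving pressures along a trajectory (cmH2O)."""

    t: np.ndarray
    per_compartment: np.ndarray   # (K, m)
    consensus: np.ndarray         # (K,) mean across compartments
    spread: np.ndarray            # (K,) max |p_i - consensus|
    phase: str

    @property
    def max_spread(self) -> float:
        return float(self.spread.max())

    def to_frame(self):
        import pandas as pd
        K, m = self.per_compartment.shape
        return pd.DataFrame({
            "time_s": np.repeat(self.t, m),
            "compartment": np.tile(np.arange(1, m + 1), K),
            "pressure_cmH2O": self.per_compartment.ravel(),
            "consensus": np.repeat(self.consensus, m),
            "spread": np.repeat(self.spread, m),
        })


@dataclass
class PerformanceReport:
    """Values of the breathing-effort criteria along a cycle."""

    J_in: float
    J_ex: float
    label: str = ""
    t: np.ndarray | None = None
    cumulative: np.ndarray | None = None

    @property
    def J_total(self) -> float:
        return self.J_in + self.J_ex


@dataclass
class CycleBundle:
    """One solved or simulated breathing cycle."""

    inspiration: Trajectory
    expiration: Trajectory
    pressure_in: PressureTrace
    pressure_ex: PressureTrace
    report: PerformanceReport
    bvp: BvpSolution | None = None
    coefficients: object | None = None

    @property
    def trajectory(self) -> Trajectory:
        return self.inspiration.concat(self.expiration)


def reconstruct_pressure(traj: Trajectory, model: LungModel,
                         phase: str) -> PressureTrace:
    """Per-compartment driving pressure ``R x' + C(x) x`` with consensus/spread."""
    R = model.resistance(phase)
    elast = model.elastance_vector(traj.x.T, phase).T
    p = traj.dx @ R.T + elast * traj.x
    consensus = p.mean(axis=1)
    spread = np.abs(p - consensus[:, None]).max(axis=1)
    return PressureTrace(t=traj.t, per_compartment=p, consensus=consensus,
                         spread=spread, phase=phase)


def _integrand_inspiration(traj, model, alpha1):
    el = model.elastance_vector(traj.x.T, "inspiration").T
    quad = np.einsum("ki,ij,kj->k", traj.dx, model.R_in, traj.dx)
    return (traj.ddx ** 2).sum(axis=1) + alpha1 * (
        quad + (traj.x * el * traj.dx).sum(axis=1))


def _integrand_expiration(traj, model, alpha2):
    el = model.elastance_vector(traj.x.T, "expiration").T
    q = traj.dx @ model.R_ex.T + el * traj.x
    return (traj.ddx ** 2).sum(axis=1) + alpha2 * (q ** 2).sum(axis=1)


def performance_inspiration(traj: Trajectory, model: LungModel,
                            alpha1: float) -> float:
    """J_in by composite Simpson quadrature of the eliminated integrand."""
    if "inspiration" not in traj.phase:
        raise ModelError(f"expected an inspiratory trajectory, got {traj.phase!r}")
    return float(simpson(_integrand_inspiration(traj, model, alpha1), x=traj.t))


def performance_expiration(traj: Trajectory, model: LungModel,
                           alpha2: float) -> float:
    """J_ex by composite Simpson quadrature of the eliminated integrand."""
    if "expiration" not in traj.phase:
        raise ModelError(f"expected an expiratory trajectory, got {traj.phase!r}")
    return float(simpson(_integrand_expiration(traj, model, alpha2), x=traj.t))


def _bundle(model, spec, insp, exp, bvp=None, coeffs=None, label=""):
    J_in = performance_inspiration(insp, model, spec.alpha1)
    J_ex = performance_expiration(exp, model, spec.alpha2)
    t = np.concatenate([insp.t, exp.t])
    L = np.concatenate([_integrand_inspiration(insp, model, spec.alpha1),
                        _integrand_expiration(exp, model, spec.alpha2)])
    # cumulative criterion over the cycle (trapezoid; seam duplicated point
    # contributes zero width)
    cum = cumulative_trapezoid(L, t, initial=0.0)
    report = PerformanceReport(J_in=J_in, J_ex=J_ex, label=label,
                               t=t, cumulative=cum)
    return CycleBundle(
        inspiration=insp, expiration=exp,
        pressure_in=reconstruct_pressure(insp, model, "inspiration"),
        pressure_ex=reconstruct_pressure(exp, model, "expiration"),
        report=report, bvp=bvp, coefficients=coeffs)


def run_cycle(model: LungModel, spec: BreathSpec, n_grid: int = 401,
              **bvp_kwargs) -> CycleBundle:
    """Solve the optimal inspiration and expiration of one breathing cycle.

    The phases share their boundary data: inspiration runs from V0 to
    V0 + VT, expiration back down, both starting and ending at rest, so the
    assembled trajectory is continuous at T_in and periodic by construction.
    """
    insp, coeffs = solve_inspiration(model, spec, n_grid=n_grid)
    bvp = solve_expiration(model, spec, n_grid=n_grid, **bvp_kwargs)
    return _bundle(model, spec, insp, bvp.trajectory, bvp=bvp, coeffs=coeffs,
                   label="optimal")


def simulate_cycle(model: LungModel, spec: BreathSpec,
                   p_in: PressureWaveform, p_ex: PressureWaveform,
                   x0, n_grid: int = 401) -> CycleBundle:
    """Forward-simulate one cycle under prescribed pressure waveforms."""
    insp = simulate_phase(model, "inspiration", p_in, x0, n_grid=n_grid)
    exp = simulate_phase(model, "expiration", p_ex, insp.x[-1], n_grid=n_grid)
    return _bundle(model, spec, insp, exp, label="reference")


class LimitCycleError(RuntimeError):
    def __init__(self, message, distances):
        super().__init__(message)
        self.distances = distances


def limit_cycle_analysis(model: LungModel, pressures, x0, max_cycles: int = 50,
                         tol: float = 1e-6, n_grid: int = 201):
    """Iterate the breathing-cycle map to its fixed point.

    Simulates inspiration then expiration under the given waveform pair,
    feeding each cycle's end-expiratory state into the next cycle, until
    successive end-expiratory states differ by less than ``tol`` (max-norm).
    Returns ``(x_fixed, distances)`` with the per-cycle distance sequence.
    """
    p_in, p_ex = pressures
    x = np.atleast_1d(np.asarray(x0, float))
    distances = []
    for _ in range(max_cycles):
        insp = simulate_phase(model, "inspiration", p_in, x, n_grid=n_grid)
        exp = simulate_phase(model, "expiration", p_ex, insp.x[-1],
                             n_grid=n_grid)
        x_new = exp.x[-1]
        distances.append(float(np.max(np.abs(x_new - x))))
        x = x_new
        if distances[-1] < tol:
            return x, np.asarray(distances)
    raise LimitCycleError(
        f"no limit cycle within {max_cycles} cycles (last distance "
        f"{distances[-1]:.3g})", np.asarray(distances))


def compare_performance(optimal: CycleBundle, reference: CycleBundle
                        ) -> tuple[PerformanceReport, PerformanceReport]:
    """Side-by-side criterion comparison of two cycle bundles.

    Returns the two reports; each carries its cumulative criterion curve.
    If the bundles live on different grids the reference curve is resampled
    onto the optimal grid (with a warning) so the curves are comparable.
    """
    a, b = optimal.report, reference.report
    if a.t.shape != b.t.shape or not np.allclose(a.t, b.t):
        warnings.warn("cycle grids differ; resampling reference cumulative "
                      "curve onto the optimal grid", stacklevel=2)
        b = PerformanceReport(
            J_in=b.J_in, J_ex=b.J_ex, label=b.label, t=a.t.copy(),
            cumulative=np.interp(a.t, b.t, b.cumulative))
    return a, b
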