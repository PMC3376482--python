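"""Forward integration of the compartment state equations.

During either phase the volumes obey the pressure balance
``R x'(t) + C(x(t)) x(t) = p(t) e`` with ``R`` the phase's resistance matrix,
``C(x)`` the diagonal elastance matrix and ``e`` the all-ones vector, so the
flows are ``x' = R^{-1} (p(t) e - C(x) x)``.  This module integrates that
system under an arbitrary applied pressure waveform and packages the result
as a :class:`Trajectory` carrying volumes, flows and accelerations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .lung_model import LungModel, ModelError, _check_phase

__all__ = ["PressureWaveform", "Trajectory", "simulate_phase",
           "reference_pressures", "IntegrationError"]


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails; carries the last valid state."""

    def __init__(self, message: str, t_last: float, x_last: np.ndarray):
        super().__init__(message)
        self.t_last = t_last
        self.x_last = x_last


@dataclass(frozen=True)
class PressureWaveform:
    """Applied airway-opening pressure p(t) (cmH2O) on a phase interval."""

    func: Callable[[float], float]
    t_start: float
    t_end: float
    label: str = ""

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < self.t_start - 1e-12) or np.any(t > self.t_end + 1e-12):
            raise ValueError(
                f"pressure {self.label!r} evaluated outside "
                f"[{self.t_start}, {self.t_end}]")
        out = self.func(t)
        return np.broadcast_to(np.asarray(out, dtype=float), t.shape).copy() \
            if t.ndim else float(out)


@dataclass
class Trajectory:
    """Time-sampled per-compartment volumes, flows and accelerations.

    ``x``, ``dx``, ``ddx`` have shape ``(K, m)`` on the strictly increasing
    time grid ``t`` (shape ``(K,)``); units l, l/s, l/s².
    """

    t: np.ndarray
    x: np.ndarray
    dx: np.ndarray
    ddx: np.ndarray
    phase: str
    label: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        for name in ("x", "dx", "ddx"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim == 1:
                arr = arr[:, None]
            setattr(self, name, arr)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.x.shape[0] != self.t.size:
            raise ValueError("grid/volume shape mismatch")

    @property
    def m(self) -> int:
        return self.x.shape[1]

    def total(self, which: str = "x") -> np.ndarray:
        """Summed-over-compartments volume/flow/acceleration e^T x(t)."""
        return getattr(self, which).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: time_s, compartment, volume_l, flow_l_per_s, accel_l_per_s2, phase."""
        K, m = self.x.shape
        return pd.DataFrame({
            "time_s": np.repeat(self.t, m),
            "compartment": np.tile(np.arange(1, m + 1), K),
            "volume_l": self.x.ravel(),
            "flow_l_per_s": self.dx.ravel(),
            "accel_l_per_s2": self.ddx.ravel(),
            "phase": self.phase,
        })

    def concat(self, other: "Trajectory") -> "Trajectory":
        """Join two consecutive phases, dropping the duplicated seam point."""
        drop = 1 if np.isclose(other.t[0], self.t[-1]) else 0
        return Trajectory(
            t=np.concatenate([self.t, other.t[drop:]]),
            x=np.vstack([self.x, other.x[drop:]]),
            dx=np.vstack([self.dx, other.dx[drop:]]),
            ddx=np.vstack([self.ddx, other.ddx[drop:]]),
            phase=f"{self.phase}+{other.phase}",
            label=self.label or other.label)


def _flow(model: LungModel, phase: str, R_inv: np.ndarray, p: float,
          x: np.ndarray) -> np.ndarray:
    return R_inv @ (p - model.elastance_vector(x, phase) * x)


def simulate_phase(model: LungModel, phase: str, pressure: PressureWaveform,
                   x0, t_span=None, n_grid: int = 401,
                   rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Integrate ``R x' + C(x) x = p(t) e`` over one phase.

    Flows on the output grid are recomputed from the state equation (exact
    given the volumes); accelerations come from differentiating the state
    equation analytically, ``x'' = R^{-1}(p' e - C x' - C'(x) X' x)``, using
    the smoothed-compliance derivative.
    """
    _check_phase(phase)
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if np.any(x0 < 0):
        raise ModelError("initial volumes must be nonnegative")
    if t_span is None:
        t_span = (pressure.t_start, pressure.t_end)
    R = model.resistance(phase)
    R_inv = np.linalg.inv(R)
    t_eval = np.linspace(t_span[0], t_span[1], n_grid)

    def rhs(t, x):
        return _flow(model, phase, R_inv, pressure(t), x)

    sol = solve_ivp(rhs, t_span, x0, t_eval=t_eval, rtol=rtol, atol=atol,
                    method="LSODA", dense_output=False)
    if not sol.success:
        t_last = float(sol.t[-1]) if sol.t.size else t_span[0]
        x_last = sol.y[:, -1] if sol.t.size else x0
        raise IntegrationError(
            f"integration failed at t={t_last:.4g}: {sol.message}",
            t_last, x_last)

    x = sol.y.T  # (K, m)
    p = np.array([pressure(t) for t in t_eval])
    elast = model.elastance_vector(x.T, phase).T      # (K, m)
    dx = (R_inv @ (p[:, None] - elast * x).T).T
    # dp/dt by central differences of the waveform (exact for linear/constant)
    h = (t_span[1] - t_span[0]) / (10 * (n_grid - 1))
    tp = np.clip(t_eval + h, t_span[0], t_span[1])
    tm = np.clip(t_eval - h, t_span[0], t_span[1])
    dp = (np.array([pressure(u) for u in tp])
          - np.array([pressure(u) for u in tm])) / (tp - tm)
    delast = model.elastance_derivative_vector(x.T, phase).T
    ddx = (R_inv @ (dp[:, None] - elast * dx - delast * dx * x).T).T
    return Trajectory(t=t_eval, x=x, dx=dx, ddx=ddx, phase=phase,
                      label=pressure.label, extras={"pressure": p})


def reference_pressures(T_in: float, T_ex: float) -> tuple[PressureWaveform,
                                                           PressureWaveform]:
    """The non-optimal comparison waveforms: ramp 20t+5 then passive release.

    Inspiration is driven by the linear pressure ``p_in(t) = 20 t + 5`` cmH2O
    on ``[0, T_in]``; expiration is passive at atmospheric (gauge zero)
    pressure on ``[T_in, T_in + T_ex]``.
    """
    if T_in <= 0 or T_ex <= 0:
        raise ValueError("phase durations must be positive")
    p_in = PressureWaveform(lambda t: 20.0 * t + 5.0, 0.0, T_in,
                            label="ramp 20t+5")
    p_ex = PressureWaveform(lambda t: 0.0 * t, T_in, T_in + T_ex,
                            label="passive 0")
    return p_in, p_ex
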