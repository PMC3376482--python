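"""Dichotomous airway-tree lung model with volume-dependent compliance.

The lung is represented as ``m = 2**n`` terminal compartments fed through a
binary (dichotomous) airway tree of ``n`` generations.  Each compartment has a
nonlinear compliance curve — piecewise linear in volume, with an optional
smooth sigmoidal approximation — and each airway a flow resistance.  Separate
parameter sets are kept for the inspiratory and expiratory phases of the
breathing cycle, because airway calibre and tissue recoil differ between them.

The central objects are :class:`ComplianceCurve`, :class:`AirwayTree` and
:class:`LungModel`; the module-level functions build the structure vectors and
the symmetric positive-definite resistance matrices that turn the per-airway
pressure balances into the vector state equation ``R x' + C(x) x = p(t) e``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ComplianceCurve",
    "AirwayTree",
    "LungModel",
    "path_indices",
    "structure_vector",
    "build_resistance_matrix",
    "compliance_value",
    "inv_compliance_derivative",
    "compliance_matrix",
]

#: floor (l/cmH2O) applied to compliance so 1/c stays finite for any volume
COMPLIANCE_FLOOR = 1e-6


class ModelError(ValueError):
    """Domain error in lung-model construction or evaluation."""


# ---------------------------------------------------------------------------
# compliance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplianceCurve:
    """Volume-dependent compliance of a single lung compartment.

    The curve is piecewise linear in compartment volume ``x`` (l):

    * ``a1 + b1*x``  rising segment on ``[0, x1]``  (``b1 > 0``),
    * ``a2``         plateau on ``(x1, x2]``,
    * ``a3 + b3*x``  falling segment for ``x > x2`` (``b3 < 0``),

    extended affinely beyond ``v_cap`` and floored at a small positive value
    so the elastance ``1/c`` stays finite.  A smooth C-infinity approximation
    replaces each kink by a sigmoidal ramp of sharpness ``beta_smooth``; the
    smooth form is what the integrators and the expiratory Euler–Lagrange
    equation use, since the latter needs ``d/dx (1/c)``.

    Parameters are in l/cmH2O for the intercepts ``a1, a2, a3``, per-litre for
    the slopes ``b1, b3``, and litres for the breakpoints ``x1, x2`` and the
    domain cap ``v_cap``.
    """

    a1: float
    b1: float
    a2: float
    a3: float
    b3: float
    x1: float
    x2: float
    v_cap: float
    beta_smooth: float = 30.0
    phase: str = "inspiration"
    constant: bool = False

    def __post_init__(self) -> None:
        if self.constant:
            if self.a2 <= 0:
                raise ModelError("constant compliance must be positive")
            return
        if not (self.b1 > 0 and self.b3 < 0):
            raise ModelError(
                f"compliance slopes must satisfy b1 > 0 and b3 < 0, "
                f"got b1={self.b1}, b3={self.b3}")
        if not (0 < self.x1 < self.x2 <= self.v_cap):
            raise ModelError(
                f"breakpoints must satisfy 0 < x1 < x2 <= v_cap, "
                f"got x1={self.x1}, x2={self.x2}, v_cap={self.v_cap}")
        if self.beta_smooth <= 0:
            raise ModelError("beta_smooth must be positive")
        a, b, c, d = self.sigmoid_anchors()
        if not all(map(math.isfinite, (a, b, c, d))):
            raise ModelError("sigmoid anchors are not finite")
        if not (a < b and d < c):
            raise ModelError(
                f"sigmoid anchors must satisfy a < b and d < c, "
                f"got a={a}, b={b}, c={c}, d={d}")
        gap = abs((self.a3 + self.b3 * self.x2) - self.a2)
        if gap > 0.01 * abs(self.a2):
            warnings.warn(
                f"compliance curve discontinuous at x2={self.x2}: "
                f"segment-3 value {self.a3 + self.b3 * self.x2:.4g} vs "
                f"plateau {self.a2:.4g}", stacklevel=2)

    @classmethod
    def constant_curve(cls, c: float, phase: str = "inspiration") -> "ComplianceCurve":
        """Exactly constant compliance ``c`` (single-compartment/linear cases)."""
        return cls(a1=c, b1=0.0, a2=c, a3=c, b3=0.0, x1=0.0, x2=0.0,
                   v_cap=math.inf, phase=phase, constant=True)

    def sigmoid_anchors(self) -> tuple[float, float, float, float]:
        """Anchor volumes ``(a, b, c, d)`` of the two sigmoidal ramps.

        ``a`` is where the rising segment extrapolates to zero compliance and
        ``b`` where it reaches the plateau ``a2``; ``c``/``d`` are the same
        for the falling segment (``d < c`` since ``b3 < 0``).
        """
        a = -self.a1 / self.b1
        b = self.a2 / self.b1 + a
        c = -self.a3 / self.b3
        d = self.a2 / self.b3 + c
        return a, b, c, d

    # -- evaluation ---------------------------------------------------------

    def value(self, x, mode: str = "smoothed"):
        """Compliance (l/cmH2O) at volume ``x`` (scalar or array, l).

        The piecewise form is defined for nonnegative volumes only; the
        smoothed form extends naturally (and floored) to all real volumes,
        which keeps solver iterates evaluable if they overshoot zero.
        """
        x = np.asarray(x, dtype=float)
        if mode == "piecewise" and np.any(x < 0):
            raise ModelError("volume must be nonnegative")
        if self.constant:
            return np.full_like(x, self.a2) if x.ndim else float(self.a2)
        if mode == "piecewise":
            seg3 = np.maximum(self.a3 + self.b3 * x, COMPLIANCE_FLOOR)
            out = np.where(x <= self.x1, self.a1 + self.b1 * x,
                           np.where(x <= self.x2, self.a2, seg3))
        elif mode == "smoothed":
            out = self._smooth_floor(self._smooth_raw(x))
        else:
            raise ModelError(f"unknown compliance mode {mode!r}")
        return out if out.ndim else float(out)

    def _smooth_raw(self, x):
        a, b, c, d = self.sigmoid_anchors()
        beta = self.beta_smooth
        return self.a2 * (_ramp(x, a, b, beta) - _ramp(x, d, c, beta))

    @staticmethod
    def _smooth_floor(c):
        # smooth positive-part: ~c for c >> floor, -> floor as c -> 0
        f = COMPLIANCE_FLOOR
        return 0.5 * (c + np.sqrt(c * c + 4.0 * f * f))

    def derivative(self, x):
        """dc/dx of the smoothed (floored) compliance."""
        x = np.asarray(x, dtype=float)
        if self.constant:
            return np.zeros_like(x) if x.ndim else 0.0
        a, b, c, d = self.sigmoid_anchors()
        beta = self.beta_smooth
        raw = self._smooth_raw(x)
        draw = self.a2 * (_ramp_prime(x, a, b, beta) - _ramp_prime(x, d, c, beta))
        f = COMPLIANCE_FLOOR
        dfloor = 0.5 * (1.0 + raw / np.sqrt(raw * raw + 4.0 * f * f))
        out = draw * dfloor
        return out if out.ndim else float(out)

    def inv_derivative(self, x):
        """d/dx of the elastance 1/c(x) (cmH2O/l^2), smoothed mode."""
        x = np.asarray(x, dtype=float)
        if self.constant:
            return np.zeros_like(x) if x.ndim else 0.0
        cval = self._smooth_floor(self._smooth_raw(x))
        out = -self.derivative(x) / (cval * cval)
        return out if out.ndim else float(out)


def _softplus(z):
    return np.logaddexp(0.0, z)


def _ramp(x, lo, hi, beta):
    """Smooth ramp: 0 below ``lo``, slope 1/(hi-lo) between, 1 above ``hi``."""
    return (_softplus(beta * (x - lo)) - _softplus(beta * (x - hi))) / (beta * (hi - lo))


def _ramp_prime(x, lo, hi, beta):
    from scipy.special import expit
    return (expit(beta * (x - lo)) - expit(beta * (x - hi))) / (hi - lo)


def compliance_value(curve: ComplianceCurve, x, mode: str = "piecewise"):
    """Functional form of :meth:`ComplianceCurve.value` (nonnegative volumes)."""
    if np.any(np.asarray(x, dtype=float) < 0):
        raise ModelError("volume must be nonnegative")
    return curve.value(x, mode=mode)


def inv_compliance_derivative(curve: ComplianceCurve, x):
    """Functional form of :meth:`ComplianceCurve.inv_derivative` (x >= 0)."""
    if np.any(np.asarray(x, dtype=float) < 0):
        raise ModelError("volume must be nonnegative")
    return curve.inv_derivative(x)


# ---------------------------------------------------------------------------
# airway tree / resistance matrices
# ---------------------------------------------------------------------------

def path_indices(i: int, n: int) -> list[int]:
    """Airway indices ``k_0..k_n`` on the path from the trachea to compartment ``i``.

    ``k_j`` is the index (1-based) of the generation-``j`` airway that feeds
    compartment ``i`` of an ``n``-generation dichotomous tree; defined by the
    downward floor recursion ``k_j = floor((k_{j+1}-1)/2) + 1`` with
    ``k_n = i``.
    """
    if not (isinstance(i, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ModelError("compartment index and generation count must be integers")
    if n < 0 or not (1 <= i <= 2 ** n):
        raise ModelError(f"compartment index {i} out of range for n={n}")
    ks = [0] * (n + 1)
    ks[n] = int(i)
    for j in range(n - 1, -1, -1):
        ks[j] = (ks[j + 1] - 1) // 2 + 1
    return ks


def structure_vector(j: int, k: int, n: int) -> np.ndarray:
    """0/1 vector marking the compartments served by airway ``(j, k)``.

    Element ``l`` (1-based) is 1 exactly for
    ``l = (k-1)*2**(n-j)+1 .. k*2**(n-j)``.
    """
    if not (0 <= j <= n) or not (1 <= k <= 2 ** j):
        raise ModelError(f"airway (j={j}, k={k}) out of range for n={n}")
    z = np.zeros(2 ** n)
    width = 2 ** (n - j)
    z[(k - 1) * width: k * width] = 1.0
    return z


@dataclass(frozen=True, eq=False)
class AirwayTree:
    """Per-airway flow resistances of an ``n``-generation dichotomous tree.

    ``resistances[j]`` holds the ``2**j`` resistances (cmH2O·s/l) of
    generation ``j``, for ``j = 0..n``; generation 0 is the single parent
    (tracheal) airway.
    """

    n: int
    resistances: tuple = field()  # tuple of ndarray, resistances[j] shape (2**j,)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ModelError("generation count must be >= 0")
        if len(self.resistances) != self.n + 1:
            raise ModelError(
                f"expected {self.n + 1} generations, got {len(self.resistances)}")
        for j, r in enumerate(self.resistances):
            r = np.asarray(r, dtype=float)
            if r.shape != (2 ** j,):
                raise ModelError(
                    f"generation {j} must have {2 ** j} airways, got {r.shape}")
            if np.any(r <= 0) or not np.all(np.isfinite(r)):
                raise ModelError(f"generation {j} has nonpositive resistance")

    @classmethod
    def from_table(cls, n: int, table) -> "AirwayTree":
        """Build from ``[[j, k, value], ...]`` rows covering every airway."""
        res = [np.full(2 ** j, np.nan) for j in range(n + 1)]
        for j, k, val in table:
            j, k = int(j), int(k)
            if not (0 <= j <= n) or not (1 <= k <= 2 ** j):
                raise ModelError(f"resistance entry [{j}, {k}] out of range")
            res[j][k - 1] = float(val)
        for j, r in enumerate(res):
            missing = np.nonzero(np.isnan(r))[0]
            if missing.size:
                raise ModelError(
                    f"missing resistance entry [{j}, {int(missing[0]) + 1}]")
        return cls(n=n, resistances=tuple(res))

    @classmethod
    def uniform_generations(cls, n: int, values) -> "AirwayTree":
        """Same resistance for every airway of a generation; ``values[j]`` per j."""
        return cls(n=n, resistances=tuple(
            np.full(2 ** j, float(values[j])) for j in range(n + 1)))

    def scaled(self, factor: float) -> "AirwayTree":
        return AirwayTree(n=self.n, resistances=tuple(
            np.asarray(r) * factor for r in self.resistances))

    def resistance(self, j: int, k: int) -> float:
        return float(self.resistances[j][k - 1])

    def to_table(self) -> list[list[float]]:
        return [[j, k + 1, float(self.resistances[j][k])]
                for j in range(self.n + 1) for k in range(2 ** j)]


def build_resistance_matrix(tree: AirwayTree) -> np.ndarray:
    """Assemble the m×m resistance matrix ``R = sum_{j,k} R_{j,k} Z_{j,k} Z_{j,k}^T``.

    Entry ``(i, i')`` equals the summed resistance of the airways shared by
    the paths from the trachea to compartments ``i`` and ``i'``; the matrix is
    symmetric positive definite for strictly positive resistances.
    """
    m = 2 ** tree.n
    R = np.zeros((m, m))
    for j in range(tree.n + 1):
        width = 2 ** (tree.n - j)
        for k in range(1, 2 ** j + 1):
            sl = slice((k - 1) * width, k * width)
            R[sl, sl] += tree.resistance(j, k)
    return R


# ---------------------------------------------------------------------------
# assembled model
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class LungModel:
    """A ``2**n``-compartment lung: airway trees and compliances for both phases."""

    tree_in: AirwayTree
    tree_ex: AirwayTree
    compliance_in: tuple  # ComplianceCurve per compartment
    compliance_ex: tuple

    def __post_init__(self) -> None:
        if self.tree_in.n != self.tree_ex.n:
            raise ModelError("inspiratory/expiratory trees must share n")
        m = 2 ** self.tree_in.n
        if len(self.compliance_in) != m or len(self.compliance_ex) != m:
            raise ModelError(f"need one compliance curve per compartment ({m})")
        for R in (self.R_in, self.R_ex):
            if np.linalg.eigvalsh(R).min() <= 0:
                raise ModelError("resistance matrix is not positive definite")

    @property
    def n(self) -> int:
        return self.tree_in.n

    @property
    def m(self) -> int:
        return 2 ** self.tree_in.n

    @property
    def R_in(self) -> np.ndarray:
        return build_resistance_matrix(self.tree_in)

    @property
    def R_ex(self) -> np.ndarray:
        return build_resistance_matrix(self.tree_ex)

    def resistance(self, phase: str) -> np.ndarray:
        return self.R_in if _check_phase(phase) == "inspiration" else self.R_ex

    def curves(self, phase: str) -> tuple:
        return (self.compliance_in if _check_phase(phase) == "inspiration"
                else self.compliance_ex)

    # -- vector/matrix evaluation ------------------------------------------

    def compliance_vector(self, x, phase: str, mode: str = "smoothed") -> np.ndarray:
        """Per-compartment compliance c_i(x_i); x shape (m,) or (m, K)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return np.stack([crv.value(x[i], mode=mode)
                         for i, crv in enumerate(self.curves(phase))])

    def elastance_vector(self, x, phase: str, mode: str = "smoothed") -> np.ndarray:
        """Per-compartment 1/c_i(x_i) (cmH2O/l)."""
        c = self.compliance_vector(x, phase, mode=mode)
        bad = np.nonzero(c == 0)
        if len(bad[0]):
            raise ModelError(
                f"zero compliance in compartment {int(bad[0][0]) + 1}")
        return 1.0 / c

    def elastance_derivative_vector(self, x, phase: str) -> np.ndarray:
        """Per-compartment d/dx_i (1/c_i(x_i)), smoothed mode."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return np.stack([crv.inv_derivative(x[i])
                         for i, crv in enumerate(self.curves(phase))])

    def compliance_matrix(self, x, phase: str, mode: str = "smoothed") -> np.ndarray:
        """Diagonal elastance matrix C(x) = diag(1/c_i(x_i)) for a volume vector."""
        return np.diag(self.elastance_vector(x, phase, mode=mode))


def compliance_matrix(model: LungModel, x, phase: str,
                      mode: str = "smoothed") -> np.ndarray:
    """Functional form of :meth:`LungModel.compliance_matrix`."""
    return model.compliance_matrix(x, phase, mode=mode)


def _check_phase(phase: str) -> str:
    if phase not in ("inspiration", "expiration"):
        raise ModelError(f"unknown phase {phase!r}")
    return phase
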