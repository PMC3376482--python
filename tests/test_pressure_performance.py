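"""Pressure reconstruction, criterion evaluation, cycles and limit cycles."""

import numpy as np
import pytest

from lungflow import (AirwayTree, ComplianceCurve, LungModel, ModelError,
                      PressureWaveform, Trajectory, compare_performance,
                      limit_cycle_analysis, performance_expiration,
                      performance_inspiration, reconstruct_pressure,
                      reference_pressures, simulate_cycle, simulate_phase)
from lungflow.optimal_inspiration import hermite_cubic


def single_compartment(R=1.5, c=0.04):
    tree = AirwayTree.uniform_generations(0, [R])
    return LungModel(
        tree_in=tree, tree_ex=tree.scaled(2.5),
        compliance_in=(ComplianceCurve.constant_curve(c),),
        compliance_ex=(ComplianceCurve.constant_curve(c, "expiration"),))


def cubic_trajectory(t0, T, x0, x1, phase, n=401):
    cub = hermite_cubic(t0, T, x0, x1)
    t = np.linspace(t0, t0 + T, n)
    return Trajectory(t=t, x=cub.derivatives(t, 0), dx=cub.derivatives(t, 1),
                      ddx=cub.derivatives(t, 2), phase=phase)


# ---------------------------------------------------------------------------
# pressure reconstruction
# ---------------------------------------------------------------------------

def test_reconstruction_inverts_forward_simulation(paper2):
    model, spec = paper2
    p_in, _ = reference_pressures(spec.T_in, spec.T_ex)
    traj = simulate_phase(model, "inspiration", p_in, spec.V0)
    trace = reconstruct_pressure(traj, model, "inspiration")
    assert np.max(np.abs(trace.consensus - (20 * traj.t + 5))) <= 1e-6
    assert trace.max_spread <= 1e-6


def test_single_compartment_consensus_is_exact_balance():
    model = single_compartment()
    traj = cubic_trajectory(0.0, 2.0, np.array([0.1]), np.array([0.5]),
                            "inspiration")
    trace = reconstruct_pressure(traj, model, "inspiration")
    exact = 1.5 * traj.dx[:, 0] + traj.x[:, 0] / 0.04
    assert np.allclose(trace.consensus, exact, atol=1e-12)
    assert trace.max_spread == 0.0


def test_identical_compartments_have_zero_spread(cycle2):
    assert cycle2.pressure_in.max_spread <= 1e-8
    assert cycle2.pressure_ex.max_spread <= 1e-8


# ---------------------------------------------------------------------------
# performance functionals
# ---------------------------------------------------------------------------

def test_inspiratory_criterion_of_cubic_matches_closed_form(paper2):
    """alpha1=0 reduces to int ||x''||^2 = 12 VT^2/T^3 per compartment."""
    model, spec = paper2
    traj = cubic_trajectory(0.0, spec.T_in, spec.V0, spec.V0 + spec.VT,
                            "inspiration")
    J = performance_inspiration(traj, model, 0.0)
    expected = model.m * 12 * 0.6 ** 2 / 2.0 ** 3     # 0.54 per compartment
    assert J == pytest.approx(expected, rel=1e-10)


def test_expiratory_criterion_of_cubic_matches_closed_form(paper2):
    model, spec = paper2
    traj = cubic_trajectory(spec.T_in, spec.T_ex, spec.V0 + spec.VT, spec.V0,
                            "expiration")
    J = performance_expiration(traj, model, 0.0)
    assert J == pytest.approx(model.m * 12 * 0.6 ** 2 / 3.0 ** 3, rel=1e-10)


def test_static_trajectory_reduces_to_pressure_squared_term():
    """x'' = x' = 0 leaves only alpha2 * m * p^2 with p the static pressure."""
    model = single_compartment()
    x_eq, alpha2, T = 0.3, 0.25, 3.0
    t = np.linspace(2.0, 2.0 + T, 301)
    traj = Trajectory(t=t, x=np.full((301, 1), x_eq),
                      dx=np.zeros((301, 1)), ddx=np.zeros((301, 1)),
                      phase="expiration")
    J = performance_expiration(traj, model, alpha2)
    p = x_eq / 0.04
    assert J == pytest.approx(alpha2 * p ** 2 * T, rel=1e-12)


def test_zero_motion_inspiration_costs_nothing():
    model = single_compartment()
    t = np.linspace(0, 2, 101)
    traj = Trajectory(t=t, x=np.full((101, 1), 0.2), dx=np.zeros((101, 1)),
                      ddx=np.zeros((101, 1)), phase="inspiration")
    assert performance_inspiration(traj, model, 0.0) == 0.0


def test_phase_mismatch_raises(paper2):
    model, spec = paper2
    traj = cubic_trajectory(0.0, 2.0, spec.V0, spec.V0 + spec.VT,
                            "inspiration")
    with pytest.raises(ModelError):
        performance_expiration(traj, model, 0.1)


def test_quadrature_grid_convergence(paper2, insp2):
    model, spec = paper2
    traj, coeffs = insp2
    J1 = performance_inspiration(traj, model, spec.alpha1)
    t2 = np.linspace(0, spec.T_in, 2 * traj.t.size - 1)
    fine = Trajectory(t=t2, x=coeffs.derivatives(t2, 0),
                      dx=coeffs.derivatives(t2, 1),
                      ddx=coeffs.derivatives(t2, 2), phase="inspiration")
    J2 = performance_inspiration(fine, model, spec.alpha1)
    assert abs(J1 - J2) <= 1e-8 * abs(J1)


# ---------------------------------------------------------------------------
# optimality spot checks
# ---------------------------------------------------------------------------

def admissible_perturbations(t, m, n_pert, scale, seed):
    """Smooth bumps vanishing with their first derivatives at both endpoints."""
    rng = np.random.default_rng(seed)
    T = t[-1] - t[0]
    s = (t - t[0]) / T
    for _ in range(n_pert):
        q = rng.normal(size=(4, m)) * scale
        # delta(s) = s^2 (1-s)^2 * poly(s); derivatives by polynomial algebra
        base = np.polynomial.Polynomial([0, 0, 1, -2, 1])   # s^2(1-s)^2
        d = np.zeros((t.size, m))
        dd = np.zeros((t.size, m))
        ddd = np.zeros((t.size, m))
        for i in range(m):
            poly = base * np.polynomial.Polynomial(q[:, i])
            d[:, i] = poly(s)
            dd[:, i] = poly.deriv(1)(s) / T
            ddd[:, i] = poly.deriv(2)(s) / T ** 2
        yield d, dd, ddd


@pytest.mark.parametrize("phase", ["inspiration", "expiration"])
def test_optimum_beats_random_admissible_competitors(paper2, insp2, bvp2,
                                                     phase):
    model, spec = paper2
    if phase == "inspiration":
        traj = insp2[0]
        J_star = performance_inspiration(traj, model, spec.alpha1)
        evaluate = lambda tr: performance_inspiration(tr, model, spec.alpha1)
    else:
        traj = bvp2.trajectory
        J_star = performance_expiration(traj, model, spec.alpha2)
        evaluate = lambda tr: performance_expiration(tr, model, spec.alpha2)
    worse = 0
    for d, dd, ddd in admissible_perturbations(traj.t, model.m, 100, 0.01,
                                               seed=42):
        pert = Trajectory(t=traj.t, x=traj.x + d, dx=traj.dx + dd,
                          ddx=traj.ddx + ddd, phase=phase)
        worse += evaluate(pert) >= J_star - 1e-9 * abs(J_star)
    assert worse == 100


# ---------------------------------------------------------------------------
# cycles
# ---------------------------------------------------------------------------

def test_cycle_continuity_and_periodicity(cycle2, paper2):
    _, spec = paper2
    insp, exp = cycle2.inspiration, cycle2.expiration
    assert np.allclose(insp.x[-1], exp.x[0], atol=1e-9)
    assert np.allclose(insp.x[0], spec.V0, atol=1e-9)
    assert np.allclose(exp.x[-1], spec.V0, atol=1e-7)
    tot = cycle2.trajectory.total("x")
    assert tot.max() == pytest.approx(float((spec.V0 + spec.VT).sum()),
                                      abs=1e-7)
    assert tot[0] == pytest.approx(float(spec.V0.sum()), abs=1e-9)
    assert tot[-1] == pytest.approx(float(spec.V0.sum()), abs=1e-7)


def test_comparison_against_reference_cycle(cycle2, paper2):
    model, spec = paper2
    p_in, p_ex = reference_pressures(spec.T_in, spec.T_ex)
    ref = simulate_cycle(model, spec, p_in, p_ex, spec.V0)
    rep_opt, rep_ref = compare_performance(cycle2, ref)
    assert rep_opt.J_total < rep_ref.J_total
    # optimal vs itself: identical curves
    a, b = compare_performance(cycle2, cycle2)
    assert np.array_equal(a.cumulative, b.cumulative)


def test_cumulative_curve_nondecreasing_for_optimal(cycle2):
    assert np.all(np.diff(cycle2.report.cumulative) >= -1e-12)


# ---------------------------------------------------------------------------
# limit cycle
# ---------------------------------------------------------------------------

def test_limit_cycle_of_reference_pressures(paper2):
    model, spec = paper2
    pair = reference_pressures(spec.T_in, spec.T_ex)
    fixed, dist = limit_cycle_analysis(model, pair, spec.V0, tol=1e-6)
    assert len(dist) <= 20
    assert np.all(np.diff(dist) < 0)
    assert dist[-1] < 1e-6
    # already on the cycle: a single iteration suffices
    _, dist2 = limit_cycle_analysis(model, pair, fixed, tol=1e-6)
    assert len(dist2) == 1


def test_limit_cycle_fixed_point_matches_affine_map_analysis():
    """n=0 constant compliance: the cycle map is affine with a known fixed point."""
    R, c = 1.5, 0.04
    model = single_compartment(R, c)
    T_in, T_ex = 2.0, 3.0
    pair = reference_pressures(T_in, T_ex)
    fixed, _ = limit_cycle_analysis(model, pair, [0.2], tol=1e-10)
    # inspiration: x' = (20t+5 - x/c)/R, solved exactly; expiration decays
    tau_in, tau_ex = R * c, 2.5 * R * c
    # particular solution for p = 20t+5: x_p = c(20 t + 5) - 20 R c^2
    def insp_end(x0):
        xp0 = 5 * c - 20 * R * c ** 2
        xpT = c * (20 * T_in + 5) - 20 * R * c ** 2
        return xpT + (x0 - xp0) * np.exp(-T_in / tau_in)
    M = np.exp(-T_in / tau_in) * np.exp(-T_ex / tau_ex)
    b = insp_end(0.0) * np.exp(-T_ex / tau_ex)
    x_star = b / (1 - M)
    assert fixed[0] == pytest.approx(x_star, abs=1e-7)
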