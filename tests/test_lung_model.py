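"""Airway-tree structure, resistance assembly and compliance curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungflow import (AirwayTree, ComplianceCurve, LungModel, ModelError,
                      build_resistance_matrix, compliance_matrix,
                      compliance_value, inv_compliance_derivative,
                      path_indices, structure_vector)
from lungflow.fixtures import _COMPLIANCE_EX, _COMPLIANCE_IN


def random_tree(rng, n):
    return AirwayTree(n=n, resistances=tuple(
        rng.uniform(0.1, 5.0, size=2 ** j) for j in range(n + 1)))


# ---------------------------------------------------------------------------
# tree indexing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("i, n, expected", [
    (3, 2, [1, 2, 3]),      # path through airways (0,1), (1,2), (2,3)
    (1, 0, [1]),            # single compartment
    (4, 2, [1, 2, 4]),
    (1, 3, [1, 1, 1, 1]),
    (8, 3, [1, 2, 4, 8]),
])
def test_path_indices(i, n, expected):
    assert path_indices(i, n) == expected


@pytest.mark.parametrize("i, n", [(0, 2), (5, 2), (2, 0), (-1, 1)])
def test_path_indices_out_of_range(i, n):
    with pytest.raises(ModelError):
        path_indices(i, n)


@pytest.mark.parametrize("j, k, n, expected", [
    (0, 1, 2, [1, 1, 1, 1]),    # root airway feeds all compartments
    (1, 2, 2, [0, 0, 1, 1]),    # airway (1,2) serves compartments 3, 4
    (2, 3, 2, [0, 0, 1, 0]),
])
def test_structure_vector(j, k, n, expected):
    assert structure_vector(j, k, n).tolist() == expected


@pytest.mark.parametrize("j, k, n", [(3, 1, 2), (1, 3, 2), (0, 0, 1)])
def test_structure_vector_out_of_range(j, k, n):
    with pytest.raises(ModelError):
        structure_vector(j, k, n)


@given(st.integers(0, 4), st.integers(0, 4))
@settings(max_examples=40, derandomize=True)
def test_structure_vectors_partition_compartments(n, j):
    """For each generation the airway supports tile the compartments."""
    j = min(j, n)
    total = sum(structure_vector(j, k, n) for k in range(1, 2 ** j + 1))
    assert np.array_equal(total, np.ones(2 ** n))


@given(st.integers(0, 4), st.integers(1, 16))
@settings(max_examples=60, derandomize=True)
def test_path_consistent_with_structure(n, i):
    """Compartment i lies in the support of every airway on its path."""
    i = (i - 1) % (2 ** n) + 1
    ks = path_indices(i, n)
    for j, k in enumerate(ks):
        assert structure_vector(j, k, n)[i - 1] == 1


# ---------------------------------------------------------------------------
# resistance matrix
# ---------------------------------------------------------------------------

def shared_ancestor_matrix(tree):
    """Brute-force oracle: entry (i, i') sums resistances of shared path airways."""
    m = 2 ** tree.n
    R = np.zeros((m, m))
    for i in range(1, m + 1):
        ki = path_indices(i, tree.n)
        for i2 in range(1, m + 1):
            ki2 = path_indices(i2, tree.n)
            R[i - 1, i2 - 1] = sum(
                tree.resistance(j, ki[j])
                for j in range(tree.n + 1) if ki[j] == ki2[j])
    return R


def test_resistance_matrix_single_airway():
    tree = AirwayTree.uniform_generations(0, [2.7])
    assert build_resistance_matrix(tree).tolist() == [[2.7]]


def test_resistance_matrix_four_compartment_row():
    """Row 3 reproduces the pressure-balance coefficient pattern."""
    tree = AirwayTree.from_table(2, [[0, 1, 1.0], [1, 1, 2.0], [1, 2, 3.0],
                                     [2, 1, 4.0], [2, 2, 5.0], [2, 3, 6.0],
                                     [2, 4, 7.0]])
    R = build_resistance_matrix(tree)
    # compartment 3: R_{2,3}+R_{1,2}+R_{0,1} on its own flow,
    # R_{1,2}+R_{0,1} on sibling 4, R_{0,1} on 1 and 2
    assert R[2].tolist() == [1.0, 1.0, 6.0 + 3.0 + 1.0, 3.0 + 1.0]
    assert np.allclose(R, R.T)


@pytest.mark.parametrize("n", range(5))
def test_resistance_matrix_matches_shared_ancestor_oracle(n):
    rng = np.random.default_rng(100 + n)
    for _ in range(40):
        tree = random_tree(rng, n)
        Z = build_resistance_matrix(tree)
        assert np.allclose(Z, shared_ancestor_matrix(tree), atol=1e-12)
        assert np.linalg.eigvalsh(Z).min() > 0


def test_airway_tree_validation():
    with pytest.raises(ModelError):
        AirwayTree(n=1, resistances=(np.array([1.0]), np.array([1.0])))
    with pytest.raises(ModelError):
        AirwayTree(n=0, resistances=(np.array([-1.0]),))
    with pytest.raises(ModelError, match=r"\[1, 2\]"):
        AirwayTree.from_table(1, [[0, 1, 1.0], [1, 1, 1.0]])


# ---------------------------------------------------------------------------
# compliance
# ---------------------------------------------------------------------------

def curve_in(**kw):
    with pytest.warns(UserWarning):
        return ComplianceCurve(phase="inspiration", **{**_COMPLIANCE_IN, **kw})


def curve_ex(**kw):
    return ComplianceCurve(phase="expiration", **{**_COMPLIANCE_EX, **kw})


def test_piecewise_values():
    c = curve_in()
    assert compliance_value(c, 0.4, "piecewise") == pytest.approx(0.025)
    # breakpoint ties resolve to the left-closed segment
    assert compliance_value(c, c.x1, "piecewise") == pytest.approx(
        c.a1 + c.b1 * c.x1)
    assert compliance_value(c, 0.0, "piecewise") == pytest.approx(c.a1)
    with pytest.raises(ModelError):
        compliance_value(c, -0.1, "piecewise")


def test_printed_inspiratory_curve_warns_discontinuity():
    """The printed segment-3 parameters jump at x2; the model flags it."""
    with pytest.warns(UserWarning, match="discontinuous"):
        ComplianceCurve(**_COMPLIANCE_IN)


def test_slope_sign_validation():
    with pytest.raises(ModelError):
        ComplianceCurve(**{**_COMPLIANCE_EX, "b1": -0.01})
    with pytest.raises(ModelError):
        ComplianceCurve(**{**_COMPLIANCE_EX, "b3": 0.01})
    with pytest.raises(ModelError):
        ComplianceCurve(**{**_COMPLIANCE_EX, "x1": 0.5})  # x1 > x2


def test_smoothed_close_to_piecewise_away_from_breakpoints():
    """beta=30 sigmoid approximation within 5% at >=0.05 l from breakpoints."""
    c = curve_ex()
    xs = np.linspace(0.0, 0.6, 601)
    keep = (np.abs(xs - c.x1) >= 0.05) & (np.abs(xs - c.x2) >= 0.05)
    pw = c.value(xs[keep], mode="piecewise")
    sm = c.value(xs[keep], mode="smoothed")
    assert np.max(np.abs(sm - pw) / pw) < 0.05


@pytest.mark.parametrize("beta_lo, beta_hi", [(30, 100), (100, 300)])
def test_smoothed_converges_with_beta(beta_lo, beta_hi):
    """Sharper sigmoids approach the piecewise curve pointwise."""
    xs = np.linspace(0.0, 0.6, 241)
    keep = (np.abs(xs - _COMPLIANCE_EX["x1"]) >= 0.02) & \
           (np.abs(xs - _COMPLIANCE_EX["x2"]) >= 0.02)
    pw = curve_ex().value(xs[keep], mode="piecewise")
    err = [np.max(np.abs(curve_ex(beta_smooth=b).value(xs[keep]) - pw))
           for b in (beta_lo, beta_hi)]
    assert err[1] < err[0]


def test_inv_compliance_derivative_matches_central_difference():
    c = curve_ex()
    xs = np.linspace(0.05, 0.6, 112)
    h = 1e-5
    fd = (1 / c.value(xs + h) - 1 / c.value(xs - h)) / (2 * h)
    an = inv_compliance_derivative(c, xs)
    assert np.max(np.abs(an - fd) / np.maximum(np.abs(fd), 1e-8)) < 1e-4


def test_inv_derivative_degenerate_cases():
    const = ComplianceCurve.constant_curve(0.03)
    assert inv_compliance_derivative(const, 0.4) == 0.0
    # nearly-hard plateau: derivative ~ 0 mid-plateau
    sharp = curve_ex(beta_smooth=300)
    assert abs(inv_compliance_derivative(sharp, 0.33)) < 1e-6


def test_compliance_matrix_values(paper2):
    model, _ = paper2
    C = compliance_matrix(model, np.array([0.4, 0.4]), "inspiration")
    assert np.allclose(C, np.diag([40.0, 40.0]), rtol=2e-3)
    assert C[0, 1] == 0.0 and C[1, 0] == 0.0


def test_compliance_matrix_single_constant():
    tree = AirwayTree.uniform_generations(0, [1.0])
    model = LungModel(
        tree_in=tree, tree_ex=tree,
        compliance_in=(ComplianceCurve.constant_curve(0.05),),
        compliance_ex=(ComplianceCurve.constant_curve(0.05, "expiration"),))
    assert compliance_matrix(model, [0.2], "inspiration").tolist() == [[20.0]]


def test_lung_model_validation():
    t0 = AirwayTree.uniform_generations(0, [1.0])
    t1 = AirwayTree.uniform_generations(1, [1.0, 1.0])
    c = (ComplianceCurve.constant_curve(0.05),)
    with pytest.raises(ModelError):
        LungModel(tree_in=t0, tree_ex=t1, compliance_in=c, compliance_ex=c)
    with pytest.raises(ModelError):
        LungModel(tree_in=t1, tree_ex=t1.scaled(2.0), compliance_in=c,
                  compliance_ex=c)


def test_paper_fixture_resistances_positive_definite(paper2, paper4):
    for model, _ in (paper2, paper4):
        for R in (model.R_in, model.R_ex):
            assert np.linalg.eigvalsh(R).min() > 0
        assert np.allclose(model.R_ex, 2.5 * model.R_in)
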