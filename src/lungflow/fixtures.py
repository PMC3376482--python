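"""Reference model configurations and randomized model generation.

``paper_2comp`` and ``paper_4comp`` reproduce the published two- and
four-compartment parameter sets: piecewise-linear compliance curves for both
breathing phases, a 2.5x inspiratory-to-expiratory resistance factor, breath
timing T_in = 2 s / T_ex = 3 s, and criterion weights alpha1 = 2.0,
alpha2 = 0.1.  The absolute airway resistances behind the published runs are
not printed, so documented defaults are used (parent airway 1.0 cmH2O·s/l,
generation-j airways 0.5 * 2**j) — overridable through ``overrides``.

The summed end-expiratory volume e^T V0 = 0.2 l and summed tidal volume
e^T VT = 1.2 l are split equally across compartments.
"""

from __future__ import annotations

import numpy as np

from .lung_model import AirwayTree, ComplianceCurve, LungModel, ModelError
from .optimal_inspiration import BreathSpec

__all__ = ["make_fixture", "fixture_config", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("paper_2comp", "paper_4comp", "random")

# piecewise compliance parameters of the reference compartment (identical for
# every compartment), in l/cmH2O (a), 1/l-scaled slopes (b) and l (x, v_cap)
_COMPLIANCE_IN = dict(a1=0.018, b1=0.0233, a2=0.025, a3=0.2532, b3=-0.01,
                      x1=0.3, x2=0.48, v_cap=0.6)
_COMPLIANCE_EX = dict(a1=0.02, b1=0.078, a2=0.038, a3=0.1025, b3=-0.15,
                      x1=0.23, x2=0.43, v_cap=0.6)

_TOTAL_V0 = 0.2   # l, summed end-expiratory volume
_TOTAL_VT = 1.2   # l, summed tidal volume


def _default_resistances(n: int) -> list[float]:
    """Per-generation inspiratory resistance (cmH2O·s/l): 1.0 root, 0.5*2**j."""
    return [1.0] + [0.5 * 2 ** j for j in range(1, n + 1)]


def fixture_config(name: str, seed: int | None = None,
                   overrides: dict | None = None) -> dict:
    """Plain-dict configuration for a named fixture (see :func:`make_fixture`)."""
    overrides = dict(overrides or {})
    if name == "random":
        if seed is None:
            raise ModelError("random fixture requires a seed")
        cfg = _random_config(seed)
    elif name in ("paper_2comp", "paper_4comp"):
        n = 1 if name == "paper_2comp" else 2
        m = 2 ** n
        beta = overrides.pop("beta_smooth", 30.0)
        gen = _default_resistances(n)
        cfg = {
            "name": name,
            "n": n,
            "resistances_in": [[j, k, gen[j]] for j in range(n + 1)
                               for k in range(1, 2 ** j + 1)],
            "resistances_ex": {"factor": 2.5},
            "compliance_in": [dict(_COMPLIANCE_IN) for _ in range(m)],
            "compliance_ex": [dict(_COMPLIANCE_EX) for _ in range(m)],
            "beta_smooth": beta,
            "breath": {
                "T_in": 2.0, "T_ex": 3.0,
                "V0": [_TOTAL_V0 / m] * m, "VT": [_TOTAL_VT / m] * m,
                "alpha1": 2.0, "alpha2": 0.1,
            },
        }
    else:
        raise ModelError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    for key, val in overrides.items():
        if key not in cfg and key not in cfg["breath"]:
            raise ModelError(f"unknown override key {key!r}")
        (cfg if key in cfg else cfg["breath"])[key] = val
    return cfg


def _random_config(seed: int) -> dict:
    rng = np.random.default_rng(seed)
    n = int(rng.integers(0, 3))
    m = 2 ** n
    res_in = [[j, k, float(rng.uniform(0.3, 3.0))]
              for j in range(n + 1) for k in range(1, 2 ** j + 1)]
    factor = float(rng.uniform(2.0, 3.0))

    def curve():
        a2 = float(rng.uniform(0.02, 0.05))
        b1 = float(rng.uniform(0.02, 0.1))
        b3 = -float(rng.uniform(0.05, 0.3))
        x1 = float(rng.uniform(0.15, 0.35))
        x2 = float(rng.uniform(x1 + 0.1, 0.55))
        # continuous at the breakpoints: a1 = a2 - b1*x1, a3 = a2 - b3*x2
        return dict(a1=a2 - b1 * x1, b1=b1, a2=a2, a3=a2 - b3 * x2, b3=b3,
                    x1=x1, x2=x2, v_cap=0.6)

    return {
        "name": "random", "seed": seed, "n": n,
        "resistances_in": res_in,
        "resistances_ex": {"factor": factor},
        "compliance_in": [curve() for _ in range(m)],
        "compliance_ex": [curve() for _ in range(m)],
        "beta_smooth": 30.0,
        "breath": {
            "T_in": float(rng.uniform(1.5, 2.5)),
            "T_ex": float(rng.uniform(2.5, 3.5)),
            "V0": [float(rng.uniform(0.05, 0.15))] * m,
            "VT": [float(rng.uniform(0.2, 0.4))] * m,
            "alpha1": float(rng.uniform(0.5, 4.0)),
            "alpha2": float(rng.uniform(0.02, 0.2)),
        },
    }


def model_from_config(cfg: dict) -> tuple[LungModel, BreathSpec]:
    """Instantiate the model and breath specification from a config dict."""
    try:
        n = int(cfg["n"])
        m = 2 ** n
        tree_in = AirwayTree.from_table(n, cfg["resistances_in"])
        res_ex = cfg["resistances_ex"]
        if isinstance(res_ex, dict) and "factor" in res_ex:
            tree_ex = tree_in.scaled(float(res_ex["factor"]))
        else:
            tree_ex = AirwayTree.from_table(n, res_ex)
        beta = float(cfg.get("beta_smooth", 30.0))

        def curves(blocks, phase):
            if len(blocks) != m:
                raise ModelError(
                    f"need {m} compliance blocks for phase {phase}, "
                    f"got {len(blocks)}")
            return tuple(ComplianceCurve(beta_smooth=beta, phase=phase, **blk)
                         for blk in blocks)

        model = LungModel(
            tree_in=tree_in, tree_ex=tree_ex,
            compliance_in=curves(cfg["compliance_in"], "inspiration"),
            compliance_ex=curves(cfg["compliance_ex"], "expiration"))
        b = cfg["breath"]
        spec = BreathSpec(T_in=float(b["T_in"]), T_ex=float(b["T_ex"]),
                          V0=np.asarray(b["V0"], float),
                          VT=np.asarray(b["VT"], float),
                          alpha1=float(b["alpha1"]),
                          alpha2=float(b["alpha2"]))
    except KeyError as exc:
        raise ModelError(f"missing configuration key {exc.args[0]!r}") from exc
    if spec.m != model.m:
        raise ModelError("breath boundary vectors do not match compartments")
    return model, spec


def make_fixture(name: str, seed: int | None = None,
                 overrides: dict | None = None) -> tuple[LungModel, BreathSpec]:
    """Build a named fixture model: ``paper_2comp``, ``paper_4comp`` or ``random``."""
    return model_from_config(fixture_config(name, seed=seed, overrides=overrides))
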