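"""Configuration files and tabular output.

Model configurations are JSON documents with the keys ``n``,
``resistances_in`` (rows ``[j, k, value]``), ``resistances_ex`` (rows or
``{"factor": f}``), ``compliance_in``/``compliance_ex`` (per-compartment
parameter blocks), ``beta_smooth`` and ``breath`` (timing, boundary volumes,
weights).  Trajectories and pressure traces are written as tidy CSV,
reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import _version
from .forward_dynamics import Trajectory
from .fixtures import model_from_config
from .lung_model import LungModel, ModelError
from .optimal_inspiration import BreathSpec

__all__ = ["load_config", "save_config", "canonical_json", "config_from_model",
           "write_trajectory", "read_trajectory", "write_report"]


def canonical_json(cfg: dict) -> str:
    """Canonical serialisation (sorted keys) so round trips are byte-stable."""
    return json.dumps(cfg, indent=2, sort_keys=True) + "\n"


def save_config(cfg: dict, path) -> None:
    cfg = dict(cfg)
    cfg.setdefault("format_version", _version.__version__)
    Path(path).write_text(canonical_json(cfg))


def load_config(path) -> tuple[LungModel, BreathSpec]:
    """Load and validate a model configuration file."""
    try:
        cfg = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelError(f"malformed configuration {path}: {exc}") from exc
    return model_from_config(cfg)


def config_from_model(model: LungModel, spec: BreathSpec,
                      name: str = "custom") -> dict:
    """Serialisable configuration dict reproducing a model + breath spec."""
    def blocks(curves):
        return [{"a1": c.a1, "b1": c.b1, "a2": c.a2, "a3": c.a3, "b3": c.b3,
                 "x1": c.x1, "x2": c.x2, "v_cap": c.v_cap} for c in curves]
    return {
        "name": name,
        "n": model.n,
        "resistances_in": model.tree_in.to_table(),
        "resistances_ex": model.tree_ex.to_table(),
        "compliance_in": blocks(model.compliance_in),
        "compliance_ex": blocks(model.compliance_ex),
        "beta_smooth": model.compliance_in[0].beta_smooth,
        "breath": {"T_in": spec.T_in, "T_ex": spec.T_ex,
                   "V0": list(map(float, spec.V0)),
                   "VT": list(map(float, spec.VT)),
                   "alpha1": spec.alpha1, "alpha2": spec.alpha2},
    }


def write_trajectory(traj: Trajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False)


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    t = np.sort(df["time_s"].unique())
    piv = {col: df.pivot_table(index="time_s", columns="compartment",
                               values=col, sort=True).to_numpy()
           for col in ("volume_l", "flow_l_per_s", "accel_l_per_s2")}
    phase = str(df["phase"].iloc[0])
    return Trajectory(t=t, x=piv["volume_l"], dx=piv["flow_l_per_s"],
                      ddx=piv["accel_l_per_s2"], phase=phase)


def write_report(report, path) -> None:
    """Write a report (dict or object with __dict__ of scalars/arrays) as JSON."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return {k: v for k, v in vars(o).items() if not k.startswith("_")}
    Path(path).write_text(json.dumps(report, indent=2, default=default,
                                     sort_keys=True) + "\n")
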