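"""YAML/JSON design configuration shared by the CLI subcommands.

Schema (all sections optional unless a subcommand needs them)::

    recruitment: {model: fixed|increasing|decreasing, N: 188, T_R: 8}
    schedule:    {d: [1, 2, 4]}
    allocation:  {phi: 0.5}
    correlation: {kind: uniform|exponential, param: 0.5}
                 # or: {kind: exponential, reference: {rho: 0.5, between: [1, 3]}}
    covariance:  {sigma: [12, 12, 12]}   # or a scalar
    design:      {tau: [...], I_max: 0.326, lower: [...], upper: [...]}
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .correlation import CorrelationSpec, CovarianceSpec, gamma_from_reference
from .gsd import GsdDesign
from .recruitment import RecruitmentSpec
from .schedule import AllocationSpec, FollowUpSchedule

__all__ = ["load_config", "build_objects"]


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def build_objects(cfg: dict) -> dict:
    """Instantiate domain objects from a parsed configuration mapping."""
    out: dict = {}
    if "schedule" in cfg:
        out["sched"] = FollowUpSchedule(cfg["schedule"]["d"])
    if "recruitment" in cfg:
        r = cfg["recruitment"]
        out["rec"] = RecruitmentSpec(model=r["model"], N=float(r["N"]), T_R=float(r["T_R"]))
    if "allocation" in cfg:
        out["alloc"] = AllocationSpec(float(cfg["allocation"]["phi"]))
    if "correlation" in cfg:
        c = cfg["correlation"]
        if "reference" in c:
            ref = c["reference"]
            sched = out["sched"]
            r, rp = ref["between"]
            param = gamma_from_reference(
                float(ref["rho"]), float(sched.d[r - 1]), float(sched.d[rp - 1])
            )
        else:
            param = float(c["param"])
        out["corr"] = CorrelationSpec(c["kind"], param)
    if "covariance" in cfg:
        out["cov"] = CovarianceSpec(cfg["covariance"]["sigma"])
    if "design" in cfg:
        d = cfg["design"]
        upper = [np.inf if str(u).lower() in ("inf", ".inf", "+inf") else float(u) for u in d["upper"]]
        out["design"] = GsdDesign(
            tau=np.asarray(d["tau"], dtype=float),
            I_max=float(d["I_max"]),
            lower=np.asarray(d["lower"], dtype=float),
            upper=np.asarray(upper, dtype=float),
        )
    return out
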