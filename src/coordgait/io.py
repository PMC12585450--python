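"""Reading and writing trial files and result tables.

A trial on disk is a directory with two delimited text files and a JSON
sidecar:

* ``kinematics.csv`` — columns ``time_s, hip_deg, knee_deg, ankle_deg``
* ``grf.csv`` — columns ``time_s, grf_N``
* ``trial.json`` — sampling rates, subject/group/time labels, and (for
  generated trials) the simulation config and seed

All angles are degrees and forces newtons; round trips are stable to the
10-significant-digit text precision used on write.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GaitSimConfig, JointWaveform, MocapTrial

__all__ = ["write_trial", "read_trial", "write_results"]

KINEMATIC_COLUMNS = ["time_s", "hip_deg", "knee_deg", "ankle_deg"]
GRF_COLUMNS = ["time_s", "grf_N"]


def _config_to_jsonable(config: GaitSimConfig) -> dict:
    d = asdict(config)
    d["joint_waveforms"] = {
        j: {"offset_deg": wf.offset_deg, "harmonics": [list(h) for h in wf.harmonics]}
        for j, wf in config.joint_waveforms.items()
    }
    if math.isinf(d["coupling_noise_kappa"]):
        d["coupling_noise_kappa"] = "inf"
    return d


def config_from_jsonable(d: dict) -> GaitSimConfig:
    d = dict(d)
    if "joint_waveforms" in d:
        d["joint_waveforms"] = {
            j: JointWaveform(w["offset_deg"], tuple(tuple(h) for h in w["harmonics"]))
            for j, w in d["joint_waveforms"].items()
        }
    if d.get("coupling_noise_kappa") == "inf":
        d["coupling_noise_kappa"] = math.inf
    return GaitSimConfig(**d)


def write_trial(trial: MocapTrial, out_dir: str | Path) -> Path:
    """Write one trial as the kinematics/GRF/sidecar file triplet."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    kin = pd.DataFrame({"time_s": trial.angle_times})
    for joint in ("hip", "knee", "ankle"):
        if joint not in trial.angles:
            raise ValueError(f"trial lacks required angle channel '{joint}'")
        kin[f"{joint}_deg"] = trial.angles[joint]
    kin.to_csv(out / "kinematics.csv", index=False, float_format="%.10g")

    grf = pd.DataFrame({"time_s": trial.grf_times, "grf_N": trial.grf})
    grf.to_csv(out / "grf.csv", index=False, float_format="%.10g")

    meta = {
        "kinematic_rate_hz": trial.kinematic_rate,
        "grf_rate_hz": trial.grf_rate,
        "subject": trial.meta.get("subject"),
        "group": trial.meta.get("group"),
        "time": trial.meta.get("time"),
    }
    if isinstance(trial.meta.get("config"), GaitSimConfig):
        meta["sim_config"] = _config_to_jsonable(trial.meta["config"])
    (out / "trial.json").write_text(json.dumps(meta, indent=2))
    return out


def _read_numeric(path: Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {missing}")
    for c in columns:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path.name}: non-numeric value in column '{c}' at data row {row}"
            )
        df[c] = coerced
    t = df["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path.name}: time_s must be strictly increasing")
    if abs(t[0]) > 1e-9:
        raise ValueError(f"{path.name}: time_s must start at 0")
    return df


def read_trial(trial_dir: str | Path) -> MocapTrial:
    """Read a trial directory written by :func:`write_trial`."""
    d = Path(trial_dir)
    kin = _read_numeric(d / "kinematics.csv", KINEMATIC_COLUMNS)
    grf = _read_numeric(d / "grf.csv", GRF_COLUMNS)
    meta = json.loads((d / "trial.json").read_text())

    kin_rate = float(meta["kinematic_rate_hz"])
    grf_rate = float(meta["grf_rate_hz"])
    trial_meta = {k: meta.get(k) for k in ("subject", "group", "time")}
    if "sim_config" in meta:
        trial_meta["config"] = config_from_jsonable(meta["sim_config"])
    return MocapTrial(
        angles={
            "hip": kin["hip_deg"].to_numpy(),
            "knee": kin["knee_deg"].to_numpy(),
            "ankle": kin["ankle_deg"].to_numpy(),
        },
        kinematic_rate=kin_rate,
        grf=grf["grf_N"].to_numpy(),
        grf_rate=grf_rate,
        meta=trial_meta,
    )


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> Path:
    """Write each named results table as ``<name>.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False, float_format="%.10g")
    return out
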