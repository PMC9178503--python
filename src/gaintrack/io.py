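"""Session serialization: plain CSV/JSON/YAML, no binary vendor formats.

A session directory contains:

    trajectory.csv    time_s, lab_angle_deg_unwrapped, speed_cm_s
    spikes_unit<k>.csv   one column, time_s
    lfp.csv           time_s, value
    pulses_a.csv / pulses_b.csv   one column, onset_s
    profile.yaml      the gain schedule
    truth.json        ground-truth cell specs, behavior config, format tag
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .frames import AngularTrajectory, GainProfile
from .simulate import (
    LFP,
    BehaviorConfig,
    PlaceCellSpec,
    PulseTrain,
    SyntheticSession,
)

__all__ = ["write_session", "read_session", "FORMAT_VERSION"]

FORMAT_VERSION = "1.0"

_TRAJ_COLS = ["time_s", "lab_angle_deg_unwrapped", "speed_cm_s"]


def write_session(session: SyntheticSession, directory) -> Path:
    """Write a session to a directory of plain-text files."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    traj = session.trajectory
    pd.DataFrame(
        {
            "time_s": traj.time,
            "lab_angle_deg_unwrapped": traj.lab_angle_unwrapped,
            "speed_cm_s": traj.linear_speed,
        }
    ).to_csv(d / "trajectory.csv", index=False)
    for uid, times in session.spike_trains.items():
        pd.DataFrame({"time_s": times}).to_csv(
            d / f"spikes_unit{uid}.csv", index=False
        )
    if session.lfp is not None:
        pd.DataFrame(
            {"time_s": session.lfp.time, "value": session.lfp.values}
        ).to_csv(d / "lfp.csv", index=False)
    for name, train in (("pulses_a", session.pulses_a), ("pulses_b", session.pulses_b)):
        if train is not None:
            pd.DataFrame({"onset_s": train.onsets}).to_csv(
                d / f"{name}.csv", index=False
            )
    with open(d / "profile.yaml", "w") as fh:
        yaml.safe_dump(session.profile.to_dict(), fh)
    truth = {
        "format_version": FORMAT_VERSION,
        "track_radius_cm": traj.track_radius,
        "lfp_rate_hz": session.lfp.rate if session.lfp is not None else None,
        "pulse_width_s": (
            session.pulses_a.pulse_width if session.pulses_a is not None else None
        ),
        "cell_specs": {
            str(uid): {
                **asdict(spec),
                "active_lap_range": (
                    list(spec.active_lap_range)
                    if spec.active_lap_range is not None
                    else None
                ),
            }
            for uid, spec in session.cell_specs.items()
        },
        "behavior": asdict(session.behavior) if session.behavior else None,
        "pulse_correspondence": (
            [list(p) for p in session.pulse_correspondence]
            if session.pulse_correspondence is not None
            else None
        ),
    }
    with open(d / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return d


def read_session(directory) -> SyntheticSession:
    """Read a session directory written by :func:`write_session`."""
    d = Path(directory)
    traj_path = d / "trajectory.csv"
    if not traj_path.exists():
        raise FileNotFoundError(f"missing trajectory.csv in {d}")
    tdf = pd.read_csv(traj_path)
    missing = [c for c in _TRAJ_COLS if c not in tdf.columns]
    if missing:
        raise ValueError(f"trajectory.csv missing columns {missing}")
    extra = [c for c in tdf.columns if c not in _TRAJ_COLS]
    if extra:
        warnings.warn(f"trajectory.csv has extra columns {extra}; preserved")

    truth = {}
    truth_path = d / "truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = json.load(fh)

    traj = AngularTrajectory(
        time=tdf["time_s"].to_numpy(),
        lab_angle_unwrapped=tdf["lab_angle_deg_unwrapped"].to_numpy(),
        linear_speed=tdf["speed_cm_s"].to_numpy(),
        track_radius=truth.get("track_radius_cm", 75.0),
    )

    profile = GainProfile()
    prof_path = d / "profile.yaml"
    if prof_path.exists():
        with open(prof_path) as fh:
            profile = GainProfile.from_dict(yaml.safe_load(fh))

    spike_trains: dict[int, np.ndarray] = {}
    for p in sorted(d.glob("spikes_unit*.csv")):
        m = re.match(r"spikes_unit(\d+)\.csv", p.name)
        if m:
            spike_trains[int(m.group(1))] = pd.read_csv(p)["time_s"].to_numpy()

    lfp = None
    if (d / "lfp.csv").exists():
        ldf = pd.read_csv(d / "lfp.csv")
        t = ldf["time_s"].to_numpy()
        rate = truth.get("lfp_rate_hz")
        if rate is None:
            rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 250.0
        lfp = LFP(values=ldf["value"].to_numpy(), rate=float(rate), time=t)

    pulse_width = truth.get("pulse_width_s") or 1.0
    trains = {}
    for name in ("pulses_a", "pulses_b"):
        p = d / f"{name}.csv"
        trains[name] = (
            PulseTrain(
                onsets=pd.read_csv(p)["onset_s"].to_numpy(),
                pulse_width=pulse_width,
            )
            if p.exists()
            else None
        )

    cell_specs = {
        int(uid): PlaceCellSpec(
            **{
                **spec,
                "active_lap_range": (
                    tuple(spec["active_lap_range"])
                    if spec.get("active_lap_range") is not None
                    else None
                ),
            }
        )
        for uid, spec in truth.get("cell_specs", {}).items()
    }
    behavior = (
        BehaviorConfig(**truth["behavior"]) if truth.get("behavior") else None
    )
    corr = (
        [tuple(p) for p in truth["pulse_correspondence"]]
        if truth.get("pulse_correspondence")
        else None
    )
    return SyntheticSession(
        trajectory=traj,
        profile=profile,
        spike_trains=spike_trains,
        cell_specs=cell_specs,
        lfp=lfp,
        pulses_a=trains["pulses_a"],
        pulses_b=trains["pulses_b"],
        pulse_correspondence=corr,
        behavior=behavior,
    )
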