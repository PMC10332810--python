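"""Readers and writers for the pipeline's on-disk containers.

Imaging data live in a hierarchical HDF5 container with groups
``/fluorescence`` (cell x frame x trial values plus acquisition attributes),
``/schedule`` (per-trial epoch table) and optionally ``/ground_truth``
(per-cell latent amplitudes from the synthetic generator). Trajectories are
tidy CSV (run_id, fly_id, frame, t_s, x_mm, y_mm); arena geometry and
quadrant layout travel as a small YAML document.
"""
from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .behavior import QuadrantLayout
from .synth import Arena
from .types import Epoch, StimulusSchedule, TrialTensor

__all__ = [
    "save_imaging_dataset",
    "load_imaging_dataset",
    "save_trajectories",
    "load_trajectories",
    "save_arena_layout",
    "load_arena_layout",
]

TRAJ_COLUMNS = ["run_id", "fly_id", "frame", "t_s", "x_mm", "y_mm"]


def save_imaging_dataset(
    path,
    tensor: TrialTensor,
    schedule: StimulusSchedule,
    ground_truth: dict | None = None,
) -> None:
    """Write a trial tensor, its schedule and optional generator ground truth."""
    with h5py.File(path, "w") as f:
        g = f.create_group("fluorescence")
        g.create_dataset("values", data=tensor.values, compression="gzip")
        g.attrs["frame_rate_hz"] = tensor.frame_rate_hz
        g.attrs["kind"] = tensor.kind
        g.attrs["background"] = tensor.background
        g.attrs["background_subtracted"] = tensor.background_subtracted

        rows = [
            (t, i, ep.role, ep.onset_s, ep.offset_s)
            for t, epochs in enumerate(schedule.trials)
            for i, ep in enumerate(epochs)
        ]
        s = f.create_group("schedule")
        s.create_dataset("trial", data=[r[0] for r in rows])
        s.create_dataset("epoch", data=[r[1] for r in rows])
        s.create_dataset(
            "role", data=np.array([r[2] for r in rows], dtype="S16")
        )
        s.create_dataset("onset_s", data=[r[3] for r in rows])
        s.create_dataset("offset_s", data=[r[4] for r in rows])
        s.create_dataset(
            "trial_labels", data=np.array(schedule.labels, dtype="S32")
        )

        if ground_truth is not None:
            gt = f.create_group("ground_truth")
            for key in ("amplitudes", "second_pulse_amplitudes"):
                if key in ground_truth:
                    df = ground_truth[key]
                    sub = gt.create_group(key)
                    sub.create_dataset("values", data=df.to_numpy())
                    sub.create_dataset(
                        "columns", data=np.array(df.columns, dtype="S32")
                    )


def load_imaging_dataset(path) -> tuple[TrialTensor, StimulusSchedule, dict]:
    """Read a container written by :func:`save_imaging_dataset` (or user data
    in the same schema). Ground truth may be absent (empty dict)."""
    with h5py.File(path, "r") as f:
        g = f["fluorescence"]
        labels = [b.decode() for b in f["schedule/trial_labels"][()]]
        tensor = TrialTensor(
            values=g["values"][()],
            frame_rate_hz=float(g.attrs["frame_rate_hz"]),
            kind=str(g.attrs["kind"]),
            trial_labels=labels,
            background=float(g.attrs["background"]),
            background_subtracted=bool(g.attrs["background_subtracted"]),
        )
        trial_idx = f["schedule/trial"][()]
        roles = [b.decode() for b in f["schedule/role"][()]]
        onsets = f["schedule/onset_s"][()]
        offsets = f["schedule/offset_s"][()]
        trials: list[list[Epoch]] = [[] for _ in range(len(labels))]
        for t, role, a, b in zip(trial_idx, roles, onsets, offsets):
            trials[int(t)].append(Epoch(role, float(a), float(b)))
        schedule = StimulusSchedule(
            trials=[tuple(eps) for eps in trials], labels=labels
        )
        ground_truth: dict = {}
        if "ground_truth" in f:
            for key, sub in f["ground_truth"].items():
                cols = [b.decode() for b in sub["columns"][()]]
                ground_truth[key] = pd.DataFrame(
                    sub["values"][()],
                    columns=cols,
                    index=pd.RangeIndex(sub["values"].shape[0], name="cell"),
                )
    return tensor, schedule, ground_truth


def save_trajectories(path, traj: pd.DataFrame) -> None:
    traj[TRAJ_COLUMNS].to_csv(path, index=False)


def load_trajectories(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
    return df


def save_arena_layout(path, arena: Arena, layout: QuadrantLayout) -> None:
    doc = {
        "arena": {
            "radius_mm": arena.radius,
            "center_mm": list(arena.center),
            "frame_rate_hz": arena.frame_rate_hz,
        },
        "layout": {
            "rotation_deg": layout.rotation_deg,
            "odor_map": {int(k): v for k, v in layout.odor_map.items()},
        },
    }
    Path(path).write_text(yaml.safe_dump(doc))


def load_arena_layout(path) -> tuple[Arena, QuadrantLayout]:
    doc = yaml.safe_load(Path(path).read_text())
    arena = Arena(
        radius=float(doc["arena"]["radius_mm"]),
        center=tuple(doc["arena"]["center_mm"]),
        frame_rate_hz=float(doc["arena"]["frame_rate_hz"]),
    )
    layout = QuadrantLayout(
        rotation_deg=float(doc["layout"]["rotation_deg"]),
        odor_map={int(k): v for k, v in doc["layout"]["odor_map"].items()},
    )
    return arena, layout
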