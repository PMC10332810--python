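"""Circular-arena behavioral statistics.

Quadrant occupancy and the Performance Index (PI) quantify the quadrant
choice assay: PI(t) = (N_paired - N_unpaired) / N_total per video frame,
summarized as the mean over the final 30 s of the test. Discrimination
experiments average PIs over reciprocally trained groups; generalization
experiments subtract an unpaired control after baseline-correcting both.
Upwind displacement quantifies odor attraction in the flooded-arena assay:
the increase in each fly's distance from the arena center relative to its
location at stimulus onset, averaged across the flies of an arena.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import Arena

__all__ = [
    "QuadrantLayout",
    "PIResult",
    "UpwindResult",
    "quadrant_counts",
    "occupancy_series",
    "performance_index_series",
    "reciprocal_pi",
    "generalization_score",
    "upwind_displacement",
    "radial_position_at",
]


@dataclass
class QuadrantLayout:
    """Four quadrants of the arena disk and their odor assignment.

    Quadrant q covers polar angles [rotation + 90q, rotation + 90(q+1))
    degrees about the arena center; the half-open intervals make boundary
    ties deterministic (a fly exactly on a boundary belongs to the
    counter-clockwise-adjacent quadrant). ``odor_map`` assigns each quadrant
    'paired' or 'unpaired'; opposing quadrants must share an odor.
    """

    rotation_deg: float = 0.0
    odor_map: dict[int, str] = field(
        default_factory=lambda: {0: "paired", 1: "unpaired", 2: "paired", 3: "unpaired"}
    )

    def __post_init__(self):
        if sorted(self.odor_map) != [0, 1, 2, 3]:
            raise ValueError("odor_map must cover quadrants 0..3")
        if self.odor_map[0] != self.odor_map[2] or self.odor_map[1] != self.odor_map[3]:
            raise ValueError("opposing quadrants must share an odor")

    def quadrants_for(self, role: str) -> list[int]:
        return [q for q, r in self.odor_map.items() if r == role]


@dataclass
class PIResult:
    pi_series: np.ndarray
    pi_scalar: float
    baseline_pi: float
    design: str = "reciprocal"


@dataclass
class UpwindResult:
    t_s: np.ndarray
    per_fly: pd.DataFrame  # fly x frame displacement (mm)
    arena_series: np.ndarray
    summary: float


def _quadrant_of(x: np.ndarray, y: np.ndarray, layout: QuadrantLayout, arena: Arena) -> np.ndarray:
    ang = np.degrees(np.arctan2(y - arena.center[1], x - arena.center[0]))
    return (np.floor(((ang - layout.rotation_deg) % 360.0) / 90.0)).astype(int)


def quadrant_counts(
    positions: np.ndarray, layout: QuadrantLayout, arena: Arena
) -> np.ndarray:
    """Count centroids per quadrant for one frame; counts sum to the number
    of flies."""
    positions = np.asarray(positions, dtype=float)
    q = _quadrant_of(positions[:, 0], positions[:, 1], layout, arena)
    return np.bincount(q, minlength=4)


def occupancy_series(
    traj: pd.DataFrame, layout: QuadrantLayout, arena: Arena
) -> np.ndarray:
    """Per-frame quadrant occupancy counts (frames x 4) from a trajectory
    table with columns fly_id, frame, x_mm, y_mm."""
    q = _quadrant_of(
        traj["x_mm"].to_numpy(), traj["y_mm"].to_numpy(), layout, arena
    )
    frames = traj["frame"].to_numpy()
    n_frames = int(frames.max()) + 1
    counts = np.zeros((n_frames, 4), dtype=int)
    np.add.at(counts, (frames, q), 1)
    return counts


def performance_index_series(
    counts: np.ndarray,
    layout: QuadrantLayout,
    frame_rate_hz: float,
    odor_onset_s: float | None = None,
    final_window_s: float = 30.0,
    design: str = "reciprocal",
) -> PIResult:
    """PI per frame plus the final-window scalar and pre-odor baseline.

    The scalar is the mean PI over [T_end - final_window_s, T_end); the
    baseline is the mean over all frames before ``odor_onset_s`` (NaN when no
    pre-odor period exists).
    """
    counts = np.asarray(counts)
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("no flies counted in at least one frame")
    paired = counts[:, layout.quadrants_for("paired")].sum(axis=1)
    unpaired = counts[:, layout.quadrants_for("unpaired")].sum(axis=1)
    pi = (paired - unpaired) / totals
    n = len(pi)
    lo = max(0, n - int(round(final_window_s * frame_rate_hz)))
    scalar = float(pi[lo:n].mean())
    if odor_onset_s is not None and odor_onset_s > 0:
        onset_frame = int(np.floor(odor_onset_s * frame_rate_hz))
        baseline = float(pi[:onset_frame].mean()) if onset_frame > 0 else float("nan")
    else:
        baseline = float("nan")
    return PIResult(pi_series=pi, pi_scalar=scalar, baseline_pi=baseline, design=design)


def reciprocal_pi(pi_run1: float, pi_run2: float) -> float:
    """Average the summary PIs of two reciprocally trained groups."""
    return 0.5 * (pi_run1 + pi_run2)


def generalization_score(pi_test: PIResult, pi_control: PIResult) -> float:
    """Generalization PI corrected by the unpaired control, both
    baseline-corrected for initial quadrant-occupancy bias."""
    for name, res in (("test", pi_test), ("control", pi_control)):
        if not np.isfinite(res.baseline_pi):
            raise ValueError(f"{name} PI carries no pre-odor baseline")
    return (pi_test.pi_scalar - pi_test.baseline_pi) - (
        pi_control.pi_scalar - pi_control.baseline_pi
    )


def _radii(traj: pd.DataFrame, arena: Arena) -> pd.DataFrame:
    r = np.hypot(
        traj["x_mm"].to_numpy() - arena.center[0],
        traj["y_mm"].to_numpy() - arena.center[1],
    )
    return traj.assign(r_mm=r)


def upwind_displacement(
    traj: pd.DataFrame,
    arena: Arena,
    onset_s: float,
    window_s: float = 30.0,
) -> UpwindResult:
    """Per-fly increase in distance from the arena center relative to the
    position at stimulus onset, with the arena (across-fly) mean series and
    its mean over the stimulus window as summary.

    Flies with missing frames inside the window are excluded with a warning.
    """
    rate = arena.frame_rate_hz
    onset_f = int(np.floor(onset_s * rate))
    end_f = int(np.floor((onset_s + window_s) * rate))
    if onset_f < 0 or onset_f > traj["frame"].max():
        raise ValueError("stimulus onset outside the recording")
    end_f = min(end_f, int(traj["frame"].max()) + 1)

    df = _radii(traj, arena)
    df = df[(df["frame"] >= onset_f) & (df["frame"] < end_f)]
    wide = df.pivot_table(index="fly_id", columns="frame", values="r_mm")
    complete = wide.notna().all(axis=1)
    if not complete.all():
        lost = list(wide.index[~complete])
        warnings.warn(f"flies with missing frames excluded: {lost}")
        wide = wide[complete]
    if wide.empty:
        raise ValueError("no fly has complete frames in the stimulus window")
    disp = wide.sub(wide.iloc[:, 0], axis=0)
    arena_series = disp.mean(axis=0).to_numpy()
    t_s = (disp.columns.to_numpy() - onset_f) / rate
    return UpwindResult(
        t_s=t_s,
        per_fly=disp,
        arena_series=arena_series,
        summary=float(arena_series.mean()),
    )


def radial_position_at(
    traj: pd.DataFrame, arena: Arena, t_s: float
) -> tuple[pd.Series, float]:
    """Per-fly distance from the arena center at time t, plus the arena mean."""
    frame = int(np.floor(t_s * arena.frame_rate_hz))
    df = _radii(traj, arena)
    at = df[df["frame"] == frame]
    if at.empty:
        raise ValueError("time outside the recording")
    per_fly = at.set_index("fly_id")["r_mm"].sort_index()
    return per_fly, float(per_fly.mean())
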