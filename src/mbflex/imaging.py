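"""Fluorescence quantification: background subtraction, dF/F, response
amplitudes, transition contrast, and descriptive summaries.

Quantification always operates on unfiltered dF/F; :func:`boxcar_filter` is
reserved for plotted traces. dF/F is computed per cell and per trial against
the mean fluorescence of a baseline window immediately preceding the first
odor onset of that same trial:  dF/F_i = (F_i - F_0) / F_0.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .types import ResponseWindow, StimulusSchedule, TrialTensor, window_frames

__all__ = [
    "subtract_background",
    "compute_dff",
    "boxcar_filter",
    "response_amplitude",
    "mean_amplitudes",
    "transition_contrast",
    "trial_average_sorted",
    "pca_project",
    "odor_response_correlation",
]


def subtract_background(t: TrialTensor) -> TrialTensor:
    """Subtract the field's scalar background fluorescence (PMT offset plus
    autofluorescence) from a raw tensor. Refuses dff tensors and refuses to
    run twice."""
    if t.kind != "raw":
        raise ValueError("background subtraction applies to raw fluorescence only")
    if t.background_subtracted:
        raise ValueError("background already subtracted from this tensor")
    if not np.isfinite(t.background):
        raise ValueError("background must be finite")
    if t.background >= t.values.min():
        warnings.warn(
            "background exceeds minimum fluorescence somewhere; "
            "negative fluorescence values will result"
        )
    return t.replace(values=t.values - t.background, background_subtracted=True)


def compute_dff(
    t: TrialTensor,
    schedule: StimulusSchedule,
    baseline_window_s: float = 8.0,
) -> TrialTensor:
    """Convert a background-subtracted raw tensor to dF/F.

    F_0 is, per cell and per trial, the mean fluorescence over the
    ``baseline_window_s`` seconds immediately preceding that trial's first
    odor onset. Raises if any F_0 is non-positive, listing the offenders.
    """
    if t.kind != "raw":
        raise ValueError("input is already dF/F")
    if not t.background_subtracted:
        raise ValueError("subtract background before computing dF/F")
    if schedule.n_trials != t.n_trials:
        raise ValueError("schedule and tensor disagree on trial count")

    dff = np.empty_like(t.values)
    offenders = []
    for trial in range(t.n_trials):
        onset = schedule.first_onset(trial)
        lo, hi = window_frames(
            onset - baseline_window_s, onset, t.frame_rate_hz, t.n_frames
        )
        f0 = t.values[:, lo:hi, trial].mean(axis=1)
        bad = np.flatnonzero(f0 <= 0)
        if bad.size:
            offenders.extend((int(c), trial) for c in bad)
            continue
        dff[:, :, trial] = (t.values[:, :, trial] - f0[:, None]) / f0[:, None]
    if offenders:
        raise ValueError(
            f"non-positive baseline F0 for (cell, trial) pairs: {offenders[:10]}"
            + (" ..." if len(offenders) > 10 else "")
        )
    return t.replace(values=dff, kind="dff", background=0.0)


def boxcar_filter(
    trace: np.ndarray, frame_rate_hz: float, width_s: float = 0.2
) -> np.ndarray:
    """Centered moving average over ``width_s`` for plotting, applied along
    the last axis; edge windows shrink to the available frames.

    Plot-only by convention: all quantification uses unfiltered dF/F.
    """
    if width_s < 1.0 / frame_rate_hz:
        raise ValueError("width_s must cover at least one frame interval")
    trace = np.asarray(trace, dtype=float)
    w = max(1, int(round(width_s * frame_rate_hz)))
    n = trace.shape[-1]
    out = np.empty_like(trace)
    for i in range(n):
        lo = max(0, i - w // 2)
        hi = min(n, i - w // 2 + w)
        out[..., i] = trace[..., lo:hi].mean(axis=-1)
    return out


def response_amplitude(
    t: TrialTensor,
    schedule: StimulusSchedule,
    epoch: int | str = "first",
    window: ResponseWindow = ResponseWindow(),
    trials: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean dF/F over a window anchored at the selected epoch's onset.

    Returns a tidy table with one row per (cell, trial): columns
    ``cell, trial, stimulus, amplitude``. For single-ROI data there is one
    cell (index 0). Trials lacking the selected epoch raise ``ValueError``.
    """
    if t.kind != "dff":
        raise ValueError("response amplitudes are quantified on dF/F data")
    sel = np.arange(t.n_trials) if trials is None else np.asarray(trials)
    rows = []
    for trial in sel:
        ep = schedule.epoch(int(trial), epoch)
        lo, hi = window_frames(
            ep.onset_s + window.start_s,
            ep.onset_s + window.start_s + window.duration_s,
            t.frame_rate_hz,
            t.n_frames,
        )
        amps = t.values[:, lo:hi, trial].mean(axis=1)
        lab = schedule.labels[trial]
        rows.append(
            pd.DataFrame(
                {
                    "cell": np.arange(t.n_cells),
                    "trial": int(trial),
                    "stimulus": lab,
                    "amplitude": amps,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def mean_amplitudes(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot an amplitude table to per-cell trial-mean amplitudes
    (cells x stimuli)."""
    return table.pivot_table(index="cell", columns="stimulus", values="amplitude")


def transition_contrast(
    t: TrialTensor,
    schedule: StimulusSchedule,
    trial: int,
    cell: int = 0,
    signed: bool = True,
) -> float:
    """Contrast score of an odor transition for one ROI and trial:
    max dF/F during the second-pulse epoch minus min dF/F during the first.

    Quantifies how detectable the odor boundary is; invariant to adding a
    constant to the whole trace. ``signed=False`` returns the absolute value.
    """
    if t.kind != "dff":
        raise ValueError("transition contrast is quantified on dF/F data")
    if not schedule.is_transition(trial):
        raise ValueError(f"trial {trial} ({schedule.labels[trial]!r}) is not a transition")
    first = schedule.epoch(trial, "first")
    second = schedule.epoch(trial, "second")
    lo1, hi1 = window_frames(first.onset_s, first.offset_s, t.frame_rate_hz, t.n_frames)
    lo2, hi2 = window_frames(second.onset_s, second.offset_s, t.frame_rate_hz, t.n_frames)
    contrast = float(
        t.values[cell, lo2:hi2, trial].max() - t.values[cell, lo1:hi1, trial].min()
    )
    return contrast if signed else abs(contrast)


def trial_average_sorted(
    t: TrialTensor,
    schedule: StimulusSchedule,
    sort_stimulus: str,
    window: ResponseWindow | None = None,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Trial-averaged traces per stimulus, rows sorted by descending response
    to ``sort_stimulus`` (ties broken by original cell index; stable).

    Returns ``(averages, order)`` where ``averages[stim]`` is a
    cell x frame matrix with rows in sorted order and ``order`` maps sorted
    rows back to original cell indices.
    """
    if t.kind != "dff":
        raise ValueError("trial averages are computed on dF/F data")
    if window is None:
        trial0 = int(schedule.trials_for(sort_stimulus)[0])
        ep = schedule.epoch(trial0, "first")
        window = ResponseWindow(start_s=0.0, duration_s=ep.offset_s - ep.onset_s)
    table = response_amplitude(
        t, schedule, "first", window, trials=schedule.trials_for(sort_stimulus)
    )
    sort_amp = table.groupby("cell")["amplitude"].mean().to_numpy()
    order = np.argsort(-sort_amp, kind="stable")
    averages = {}
    for stim in schedule.stimuli:
        idx = schedule.trials_for(stim)
        averages[stim] = t.values[:, :, idx].mean(axis=2)[order]
    return averages, order


def pca_project(features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project a trial x cell response matrix onto its first two principal
    axes (mean-centered). Each axis is oriented so its largest-magnitude
    loading is positive. Returns ``(coords, components)`` with coords of
    shape (trials, 2).

    With fewer than two non-degenerate directions the second coordinate is
    all zeros (with a warning).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need at least 3 trials and 2 cells")
    Xc = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    comps = vt[:2].copy()
    rank_ok = s.size > 1 and s[1] > 1e-12 * max(s[0], 1.0)
    if not rank_ok:
        warnings.warn("feature matrix has rank < 2; second PC set to zero")
        comps[1] = 0.0
    for k in range(2):
        if comps[k].any():
            j = np.argmax(np.abs(comps[k]))
            if comps[k][j] < 0:
                comps[k] = -comps[k]
    return Xc @ comps.T, comps


def odor_response_correlation(
    amp_x: np.ndarray, amp_y: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of per-cell mean amplitudes
    between two odors over all pooled cells."""
    x = np.asarray(amp_x, dtype=float)
    y = np.asarray(amp_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("amplitude vectors must be 1-D and equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pooled cells")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in an amplitude vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
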