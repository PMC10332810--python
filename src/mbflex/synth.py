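"""Seeded synthetic datasets with the statistical structure the analyses assume.

Four generators provide ground-truth-known inputs for every pipeline stage:

* :func:`gen_kc_dataset` — sparse Kenyon-cell (KC) population responses to
  single odor pulses and odor transitions. Similar odors (A, A') activate
  strongly overlapping responder sets with correlated per-cell amplitudes;
  the dissimilar odor (B) activates a nearly disjoint set. Transition trials
  carry the second odor's single-pulse response plus a small, fixed,
  order-dependent perturbation, so transition order is decodable only when
  that perturbation dominates trial noise.
* :func:`gen_mbon_dataset` — a single mushroom-body output neuron (MBON) ROI
  imaged before and after pairing, with learning-induced depression of both
  similar odors in isolation but an order-asymmetric recovery when the
  unpaired similar odor follows the paired odor in a transition.
* :func:`gen_synapse_counts` — heavy-tailed KC->MBON synapse counts used for
  connectome-style weight initialization.
* :func:`gen_arena_trajectories` — group random-walk trajectories of flies in
  a circular arena with stimulus-conditioned upwind (radially outward) drift
  and quadrant occupancy bias.

All generators are deterministic given their config seed and return the
latent parameters they used, so downstream modules can be tested for
ground-truth recovery.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import Epoch, StimulusSchedule, TrialTensor, parse_stimulus

__all__ = [
    "KcSynthConfig",
    "MbonSynthConfig",
    "ArenaSynthConfig",
    "SynapseCountModel",
    "ArenaEpoch",
    "ArenaTimeline",
    "Arena",
    "make_schedule",
    "gen_kc_dataset",
    "gen_mbon_dataset",
    "gen_synapse_counts",
    "gen_arena_trajectories",
]

# Stimulus sets used throughout: three single pulses and the two
# similar-odor transition orders; MBON experiments add a B-containing control.
PULSE_STIMULI = ("A", "A_prime", "B")
TRANSITION_STIMULI = ("A>A_prime", "A_prime>A")
MBON_STIMULI = PULSE_STIMULI + TRANSITION_STIMULI + ("A>B",)


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass
class KcSynthConfig:
    """Configuration for the KC population generator.

    responder_fraction is the probability that a cell responds to any one
    odor; overlap_AAprime / overlap_B are the fractions of A-responders also
    responding to A' / B. amplitude_corr_target is the pooled per-cell
    Pearson correlation between A and A' mean amplitudes the generator
    calibrates itself to. order_effect_eps scales the fixed order-dependent
    perturbation added to the second pulse of transition trials.
    """

    n_cells: int = 500
    responder_fraction: float = 0.1
    overlap_AAprime: float = 0.85
    overlap_B: float = 0.05
    amplitude_corr_target: float = 0.74
    trial_noise_sd: float = 0.1
    n_trials_per_stim: int = 8
    frame_rate_hz: float = 10.0
    pulse_s: float = 5.0
    gap_s: float = 0.0
    baseline_s: float = 10.0
    tail_s: float = 5.0
    order_effect_eps: float = 0.5
    tau_rise_s: float = 0.3
    tau_decay_s: float = 1.0
    stimuli: tuple[str, ...] = PULSE_STIMULI + TRANSITION_STIMULI
    seed: int = 0

    def validate(self) -> None:
        for name in ("responder_fraction", "overlap_AAprime", "overlap_B"):
            _check_fraction(name, getattr(self, name))
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        if self.n_trials_per_stim < 2:
            raise ValueError("n_trials_per_stim must be at least 2")
        for name in ("pulse_s", "baseline_s", "frame_rate_hz", "tau_rise_s", "tau_decay_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.trial_noise_sd < 0 or self.order_effect_eps < 0:
            raise ValueError("noise and perturbation scales must be non-negative")


@dataclass
class MbonSynthConfig:
    """Configuration for the single-ROI MBON pre/post-pairing generator.

    depression_factor_* are the multiplicative post/pre response scales for
    isolated pulses of the paired (A) and similar unpaired (A') odors.
    transition_recovery is the scale applied to the A' response when it
    follows A in a transition (1.0 restores the pre-pairing level).
    """

    depression_factor_A: float = 0.3
    depression_factor_Aprime: float = 0.3
    transition_recovery: float = 1.0
    base_amplitude: float = 2.0
    tau_rise_s: float = 0.2
    tau_decay_s: float = 1.0
    noise_sd: float = 0.05
    f0: float = 100.0
    background: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "depression_factor_A",
            "depression_factor_Aprime",
            "transition_recovery",
        ):
            _check_fraction(name, getattr(self, name))
        if not self.base_amplitude > 0:
            raise ValueError("pre-pairing responses must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SynapseCountModel:
    """Lognormal KC->MBON synapse-count model, rounded to integers >= 1.

    Defaults target the connectome-scale mean of ~8.8 synapses per KC
    (2959 synapses across 336 alpha'/beta' KCs onto one MBON).
    """

    n_kcs: int = 336
    mean_count: float = 2959 / 336
    sigma: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_kcs < 1:
            raise ValueError("n_kcs must be positive")
        if not self.mean_count > 0 or not self.sigma > 0:
            raise ValueError("distribution parameters must be positive")


@dataclass
class ArenaSynthConfig:
    """Configuration for the circular-arena trajectory generator.

    upwind_drift (mm/s) is the radially outward drift applied while an odor
    stimulus is on; quadrant_bias is the relative stationary occupancy weight
    of paired-odor quadrants during choice epochs (1 = no preference).
    """

    n_flies: int = 15
    arena_radius: float = 50.0
    frame_rate_hz: float = 30.0
    step_sd: float = 1.0
    upwind_drift: float = 0.5
    quadrant_bias: float = 1.0
    init_radius: float | None = None
    init_mode: str = "disk"
    seed: int = 0

    def validate(self) -> None:
        if self.n_flies < 1:
            raise ValueError("n_flies must be positive")
        if not self.arena_radius > 0 or not self.frame_rate_hz > 0:
            raise ValueError("arena_radius and frame_rate_hz must be positive")
        if self.step_sd < 0:
            raise ValueError("step_sd must be non-negative")
        if not self.quadrant_bias > 0:
            raise ValueError("quadrant_bias must be positive")
        if self.init_radius is not None and not 0 < self.init_radius <= self.arena_radius:
            raise ValueError("init_radius must lie in (0, arena_radius]")
        if self.init_mode not in ("disk", "ring"):
            raise ValueError("init_mode must be 'disk' or 'ring'")


@dataclass(frozen=True)
class ArenaEpoch:
    """One epoch of the arena stimulus timeline.

    kind is ``"air"`` (pure random walk), ``"odor"`` (upwind drift on) or
    ``"choice"`` (quadrant bias on). drift_mm_s / bias override the config
    defaults for this epoch when given.
    """

    kind: str
    start_s: float
    end_s: float
    drift_mm_s: float | None = None
    bias: float | None = None

    def __post_init__(self):
        if self.kind not in ("air", "odor", "choice"):
            raise ValueError(f"unknown arena epoch kind {self.kind!r}")
        if not self.start_s < self.end_s:
            raise ValueError("epoch start must precede end")


@dataclass
class ArenaTimeline:
    """Stimulus timeline for an arena run (epochs may leave gaps = air)."""

    duration_s: float
    epochs: list[ArenaEpoch] = field(default_factory=list)

    def state_at(self, t: float) -> ArenaEpoch | None:
        for ep in self.epochs:
            if ep.start_s <= t < ep.end_s:
                return ep
        return None


@dataclass(frozen=True)
class Arena:
    """Circular arena geometry."""

    radius: float = 50.0
    center: tuple[float, float] = (0.0, 0.0)
    frame_rate_hz: float = 30.0


def make_schedule(
    stimuli,
    n_trials_per_stim: int,
    baseline_s: float,
    pulse_s: float,
    gap_s: float = 0.0,
) -> StimulusSchedule:
    """Build a trial-aligned schedule for a list of stimulus labels.

    Single pulses occupy [baseline, baseline+pulse); transitions append the
    second odor immediately after (or after ``gap_s`` of clean air, in which
    case the trial is an interrupted transition rather than a true one).
    """
    trials, labels = [], []
    for stim in stimuli:
        roles = parse_stimulus(stim)
        t0 = baseline_s
        epochs = [Epoch(roles[0], t0, t0 + pulse_s)]
        if len(roles) == 2:
            t1 = t0 + pulse_s + gap_s
            epochs.append(Epoch(roles[1], t1, t1 + pulse_s))
        for _ in range(n_trials_per_stim):
            trials.append(tuple(epochs))
            labels.append(stim)
    return StimulusSchedule(trials=trials, labels=labels)


def _relax_trace(
    targets: np.ndarray, frame_rate_hz: float, tau_rise_s: float, tau_decay_s: float
) -> np.ndarray:
    """First-order relaxation of (cells x frames) targets: rise toward larger
    targets with tau_rise, decay toward smaller with tau_decay."""
    dt = 1.0 / frame_rate_hz
    a_rise = 1.0 - np.exp(-dt / tau_rise_s)
    a_decay = 1.0 - np.exp(-dt / tau_decay_s)
    out = np.zeros_like(targets)
    x = np.zeros(targets.shape[0])
    for k in range(targets.shape[1]):
        tgt = targets[:, k]
        alpha = np.where(tgt > x, a_rise, a_decay)
        x = x + (tgt - x) * alpha
        out[:, k] = x
    return out


def _designed_trace(
    epochs,
    epoch_amps,
    n_frames: int,
    frame_rate_hz: float,
    tau_rise_s: float,
    tau_decay_s: float,
) -> np.ndarray:
    """Noise-free dF/F trace (cells x frames) for one trial.

    Dynamics are linear in the amplitude vectors, so window-mean response
    amplitudes scale exactly with the configured depression factors.
    """
    n_cells = len(epoch_amps[0])
    targets = np.zeros((n_cells, n_frames))
    for ep, amp in zip(epochs, epoch_amps):
        lo = int(np.floor(ep.onset_s * frame_rate_hz))
        hi = int(np.floor(ep.offset_s * frame_rate_hz))
        targets[:, lo:hi] = np.asarray(amp)[:, None]
    return _relax_trace(targets, frame_rate_hz, tau_rise_s, tau_decay_s)


def _calibrate_similar_amplitudes(
    amp_a: np.ndarray,
    amp_ap_indep: np.ndarray,
    shared: np.ndarray,
    target: float,
) -> tuple[np.ndarray, float, float]:
    """Mix the A' amplitudes on shared responders toward the A amplitudes so
    the pooled per-cell Pearson r hits the target, by bisection on the mixing
    coefficient. Returns (amplitudes, realized r, mix)."""

    def realized(mix: float) -> tuple[np.ndarray, float]:
        ap = amp_ap_indep.copy()
        ap[shared] = mix * amp_a[shared] + (1.0 - mix) * amp_ap_indep[shared]
        r = np.corrcoef(amp_a, ap)[0, 1]
        return ap, float(r)

    lo_amp, r_lo = realized(0.0)
    hi_amp, r_hi = realized(1.0)
    if target <= r_lo:
        warnings.warn(
            f"amplitude_corr_target {target:.2f} below reachable minimum {r_lo:.2f}; "
            "using uncoupled amplitudes"
        )
        return lo_amp, r_lo, 0.0
    if target >= r_hi:
        warnings.warn(
            f"amplitude_corr_target {target:.2f} above reachable maximum {r_hi:.2f} "
            "for this responder overlap; using fully coupled amplitudes"
        )
        return hi_amp, r_hi, 1.0
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        _, r_mid = realized(mid)
        if r_mid < target:
            lo = mid
        else:
            hi = mid
    mix = 0.5 * (lo + hi)
    amp, r = realized(mix)
    return amp, r, mix


def gen_kc_dataset(
    config: KcSynthConfig,
) -> tuple[TrialTensor, StimulusSchedule, dict]:
    """Generate a raw-fluorescence KC trial tensor, its schedule, and ground truth.

    The returned tensor is raw fluorescence (background and per-cell baseline
    included) so the full imaging chain — background subtraction, dF/F — can
    be exercised. Ground truth includes per-cell responder sets, mean dF/F
    amplitudes per odor, the transition second-pulse amplitude vectors, the
    order perturbations, and the realized A–A' amplitude correlation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cells

    n_resp = int(round(config.responder_fraction * n))
    if n_resp == 0:
        raise ValueError("degenerate code: responder set empty for every odor")
    n_shared_ap = int(round(config.overlap_AAprime * n_resp))
    n_shared_b = int(round(config.overlap_B * n_resp))
    needed = n_resp + (n_resp - n_shared_ap) + (n_resp - n_shared_b)
    if needed > n:
        raise ValueError(
            "overlap fractions inconsistent with responder_fraction: "
            f"{needed} distinct responder cells required but only {n} cells"
        )

    perm = rng.permutation(n)
    idx_a = perm[:n_resp]
    idx_ap = np.concatenate(
        [rng.choice(idx_a, size=n_shared_ap, replace=False),
         perm[n_resp : 2 * n_resp - n_shared_ap]]
    ).astype(int)
    idx_b = np.concatenate(
        [rng.choice(idx_a, size=n_shared_b, replace=False),
         perm[2 * n_resp - n_shared_ap : needed]]
    ).astype(int)

    def draw_amps(idx: np.ndarray) -> np.ndarray:
        amp = np.zeros(n)
        amp[idx] = rng.gamma(shape=2.0, scale=0.5, size=idx.size)
        return amp

    amp_a = draw_amps(idx_a)
    amp_ap_indep = draw_amps(idx_ap)
    amp_b = draw_amps(idx_b)
    shared_mask = np.zeros(n, dtype=bool)
    shared_mask[np.intersect1d(idx_a, idx_ap)] = True
    amp_ap, realized_r, mix = _calibrate_similar_amplitudes(
        amp_a, amp_ap_indep, shared_mask, config.amplitude_corr_target
    )
    amplitudes = {"A": amp_a, "A_prime": amp_ap, "B": amp_b}

    # Order-dependent transition perturbations: fixed across trials on the
    # union of the two odors' responders, signed by order, scale = eps.
    perturbations: dict[str, np.ndarray] = {}
    second_pulse_amps: dict[str, np.ndarray] = {}
    for stim in config.stimuli:
        roles = parse_stimulus(stim)
        if len(roles) != 2:
            continue
        first, second = roles
        support = np.union1d(np.flatnonzero(amplitudes[first]),
                             np.flatnonzero(amplitudes[second]))
        pert = np.zeros(n)
        pert[support] = rng.normal(0.0, 1.0, size=support.size)
        perturbations[stim] = pert
        second_pulse_amps[stim] = np.clip(
            amplitudes[second] + config.order_effect_eps * pert, 0.0, None
        )

    schedule = make_schedule(
        config.stimuli, config.n_trials_per_stim, config.baseline_s,
        config.pulse_s, config.gap_s,
    )
    duration_s = config.baseline_s + 2 * config.pulse_s + config.gap_s + config.tail_s
    n_frames = int(round(duration_s * config.frame_rate_hz))

    designed: dict[str, np.ndarray] = {}
    for stim in config.stimuli:
        roles = parse_stimulus(stim)
        trial0 = schedule.trials_for(stim)[0]
        epochs = schedule.epochs(trial0)
        if len(roles) == 1:
            amps = [amplitudes[roles[0]]]
        else:
            amps = [amplitudes[roles[0]], second_pulse_amps[stim]]
        designed[stim] = _designed_trace(
            epochs, amps, n_frames, config.frame_rate_hz,
            config.tau_rise_s, config.tau_decay_s,
        )

    dff = np.empty((n, n_frames, schedule.n_trials))
    for t, lab in enumerate(schedule.labels):
        noise = rng.normal(0.0, config.trial_noise_sd, size=(n, n_frames)) \
            if config.trial_noise_sd > 0 else 0.0
        dff[:, :, t] = designed[lab] + noise

    f0 = rng.uniform(80.0, 120.0, size=n)
    background = 10.0
    raw = background + f0[:, None, None] * (1.0 + dff)
    tensor = TrialTensor(
        values=raw, frame_rate_hz=config.frame_rate_hz, kind="raw",
        trial_labels=list(schedule.labels), background=background,
    )
    responders = pd.DataFrame(
        {odor: amplitudes[odor] > 0 for odor in amplitudes},
        index=pd.RangeIndex(n, name="cell"),
    )
    ground_truth = {
        "amplitudes": pd.DataFrame(amplitudes, index=pd.RangeIndex(n, name="cell")),
        "responders": responders,
        "second_pulse_amplitudes": pd.DataFrame(
            second_pulse_amps, index=pd.RangeIndex(n, name="cell")
        ),
        "perturbations": pd.DataFrame(
            perturbations, index=pd.RangeIndex(n, name="cell")
        ),
        "realized_corr_AAprime": realized_r,
        "amplitude_mix": mix,
        "f0": f0,
        "designed_traces": designed,
        "config": config,
    }
    return tensor, schedule, ground_truth


def _mbon_epoch_amp(
    role: str, position: str, prev_role: str | None, config: MbonSynthConfig, post: bool
) -> float:
    """Designed epoch amplitude for the MBON ROI (pre- or post-pairing)."""
    a = config.base_amplitude
    if not post:
        return a
    if role == "B":
        return a
    if role == "A":
        return config.depression_factor_A * a
    # role == A_prime
    if position == "second" and prev_role == "A":
        return config.transition_recovery * a
    return config.depression_factor_Aprime * a


def gen_mbon_dataset(
    config: MbonSynthConfig, schedule: StimulusSchedule
) -> tuple[TrialTensor, TrialTensor, dict]:
    """Generate pre- and post-pairing MBON trial tensors for a schedule.

    The schedule must contain the three single pulses, both similar-odor
    transition orders, and at least one B-containing transition control.
    Post-pairing pulse amplitudes scale by the depression factors; the A'
    response when second in an A->A' transition scales by transition_recovery
    instead; B responses are unchanged.
    """
    config.validate()
    present = set(schedule.stimuli)
    required = set(PULSE_STIMULI + TRANSITION_STIMULI)
    missing = sorted(required - present)
    has_b_control = any(
        "B" in parse_stimulus(s) and len(parse_stimulus(s)) == 2 for s in present
    )
    if missing or not has_b_control:
        if not has_b_control:
            missing.append("<B-containing transition>")
        raise ValueError(f"schedule missing required stimulus types: {missing}")

    rng = np.random.default_rng(config.seed)
    frame_rate = 10.0
    duration_s = max(e.offset_s for tr in schedule.trials for e in tr) + 10.0
    n_frames = int(round(duration_s * frame_rate))

    tensors = []
    gt_amps: dict[str, dict[str, list[float]]] = {"pre": {}, "post": {}}
    for phase in ("pre", "post"):
        post = phase == "post"
        dff = np.empty((1, n_frames, schedule.n_trials))
        for t, lab in enumerate(schedule.labels):
            epochs = schedule.epochs(t)
            amps = []
            prev = None
            for i, ep in enumerate(epochs):
                pos = "first" if i == 0 else "second"
                amps.append(
                    np.array([_mbon_epoch_amp(ep.role, pos, prev, config, post)])
                )
                prev = ep.role
            gt_amps[phase][lab] = [float(a[0]) for a in amps]
            trace = _designed_trace(
                epochs, amps, n_frames, frame_rate,
                config.tau_rise_s, config.tau_decay_s,
            )
            noise = rng.normal(0.0, config.noise_sd, size=trace.shape) \
                if config.noise_sd > 0 else 0.0
            dff[:, :, t] = trace + noise
        raw = config.background + config.f0 * (1.0 + dff)
        tensors.append(
            TrialTensor(
                values=raw, frame_rate_hz=frame_rate, kind="raw",
                trial_labels=list(schedule.labels), background=config.background,
            )
        )
    ground_truth = {
        "epoch_amplitudes": gt_amps,
        "config": config,
        "frame_rate_hz": frame_rate,
    }
    return tensors[0], tensors[1], ground_truth


def gen_synapse_counts(model: SynapseCountModel) -> np.ndarray:
    """Sample per-KC synapse counts: lognormal rounded to integers >= 1."""
    model.validate()
    rng = np.random.default_rng(model.seed)
    mu = np.log(model.mean_count) - 0.5 * model.sigma**2
    counts = np.round(rng.lognormal(mean=mu, sigma=model.sigma, size=model.n_kcs))
    return np.maximum(counts, 1).astype(int)


def _reflect_into_disk(pos: np.ndarray, radius: float) -> np.ndarray:
    """Reflect positions radially across the circle back into the disk."""
    r = np.linalg.norm(pos, axis=1)
    outside = r > radius
    if np.any(outside):
        r_new = 2 * radius - r[outside]
        r_new = np.clip(r_new, 0.0, radius)
        pos[outside] *= (r_new / r[outside])[:, None]
    return pos


def _quadrant(pos: np.ndarray, rotation_deg: float = 0.0) -> np.ndarray:
    ang = np.degrees(np.arctan2(pos[:, 1], pos[:, 0]))
    return (np.floor(((ang - rotation_deg) % 360.0) / 90.0)).astype(int)


def gen_arena_trajectories(
    config: ArenaSynthConfig,
    timeline: ArenaTimeline,
    run_id: int = 0,
    paired_quadrants: tuple[int, int] = (0, 2),
) -> tuple[pd.DataFrame, Arena]:
    """Simulate a group of flies as a biased random walk in a circular arena.

    Flies take i.i.d. Gaussian steps (sd = ``step_sd`` mm/frame) and are
    reflected at the arena wall. During ``odor`` epochs an outward radial
    drift of ``upwind_drift`` mm/s is added. During ``choice`` epochs steps
    are Metropolis-filtered so the stationary occupancy weight of the
    ``paired_quadrants`` relative to the others equals ``quadrant_bias``.

    Returns a tidy trajectory table (run_id, fly_id, frame, t_s, x_mm, y_mm)
    and the :class:`Arena` geometry.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    R = config.arena_radius
    dt = 1.0 / config.frame_rate_hz
    n_frames = int(round(timeline.duration_s * config.frame_rate_hz))
    nf = config.n_flies

    # area-uniform over the disk of init_radius, or on that radius exactly
    if config.init_mode == "ring":
        r0 = np.full(nf, config.init_radius or R)
    else:
        r0 = (config.init_radius or R) * np.sqrt(rng.uniform(size=nf))
    th0 = rng.uniform(0, 2 * np.pi, size=nf)
    pos = np.column_stack([r0 * np.cos(th0), r0 * np.sin(th0)])

    paired_set = np.zeros(4, dtype=bool)
    for q in paired_quadrants:
        paired_set[q] = True

    traj = np.empty((n_frames, nf, 2))
    for k in range(n_frames):
        t = k * dt
        ep = timeline.state_at(t)
        step = rng.normal(0.0, config.step_sd, size=(nf, 2))
        if ep is not None and ep.kind == "odor":
            drift = (ep.drift_mm_s if ep.drift_mm_s is not None
                     else config.upwind_drift) * dt
            r = np.linalg.norm(pos, axis=1)
            unit = np.where(r[:, None] > 1e-9, pos / np.maximum(r, 1e-9)[:, None], 0.0)
            step = step + drift * unit
        proposal = _reflect_into_disk(pos + step, R)
        if ep is not None and ep.kind == "choice":
            bias = ep.bias if ep.bias is not None else config.quadrant_bias
            w_old = np.where(paired_set[_quadrant(pos)], bias, 1.0)
            w_new = np.where(paired_set[_quadrant(proposal)], bias, 1.0)
            accept = rng.uniform(size=nf) < np.minimum(1.0, w_new / w_old)
            pos = np.where(accept[:, None], proposal, pos)
        else:
            pos = proposal
        traj[k] = pos

    frames = np.arange(n_frames)
    df = pd.DataFrame(
        {
            "run_id": run_id,
            "fly_id": np.tile(np.arange(nf), n_frames),
            "frame": np.repeat(frames, nf),
            "t_s": np.repeat(frames * dt, nf),
            "x_mm": traj[:, :, 0].ravel(),
            "y_mm": traj[:, :, 1].ravel(),
        }
    )
    arena = Arena(radius=R, center=(0.0, 0.0), frame_rate_hz=config.frame_rate_hz)
    return df, arena
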