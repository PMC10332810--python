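"""End-to-end orchestration: synthesize -> quantify -> decode -> behavioral
metrics -> statistics -> report.

Each experiment function reproduces one analysis family on synthetic data
with known ground truth:

* :func:`run_kc_experiment` — per-fly KC datasets, pooled per-cell odor
  response correlations, PCA projections, sorted trial-average maps and
  per-odor LOOCV decoder accuracies.
* :func:`run_protocol_experiment` — the two pulse/transition transfer
  protocols and the weight-response correlation.
* :func:`run_mbon_experiment` — pre/post response-amplitude ratios and
  transition contrast scores with paired signed-rank statistics.
* :func:`run_choice_experiment` / :func:`run_transition_experiment` /
  :func:`run_drift_recovery` — arena PI (reciprocal and unpaired-control
  designs), upwind displacement around odor transitions, and planted-drift
  recovery with a matched-null difference estimator.

:func:`run_all` executes the stage DAG from a :class:`RunConfig`, writes a
machine-readable ``results.json``, tidy CSV tables and figure panels, and
logs seeds. All stages are deterministic given the global seed.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, imaging
from .decoding import (
    FitSettings,
    init_weights_connectome,
    loocv_odor_accuracy,
    protocol_mbon_emulation,
    protocol_transition_trained,
    weight_response_correlation,
)
from .stats import (
    StatResult,
    apply_family_correction,
    independent_rank_sum,
    paired_signed_rank,
)
from .synth import (
    MBON_STIMULI,
    PULSE_STIMULI,
    TRANSITION_STIMULI,
    ArenaEpoch,
    ArenaSynthConfig,
    ArenaTimeline,
    KcSynthConfig,
    MbonSynthConfig,
    SynapseCountModel,
    gen_arena_trajectories,
    gen_kc_dataset,
    gen_mbon_dataset,
    gen_synapse_counts,
    make_schedule,
)
from .types import ResponseWindow

log = logging.getLogger("mbflex")

__all__ = [
    "RunConfig",
    "run_kc_experiment",
    "run_protocol_experiment",
    "run_mbon_experiment",
    "run_choice_experiment",
    "run_transition_experiment",
    "run_drift_recovery",
    "run_all",
    "sem",
]


def sem(x) -> float:
    """Standard error of the mean: sample SD / sqrt(n)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return float("nan")
    return float(x.std(ddof=1) / np.sqrt(x.size))


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive n reproducible sub-seeds (< 2**31) from a global seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


@dataclass
class BehaviorAssayConfig:
    """Study conditions for the arena experiments.

    The choice test floods opposing quadrants with the two odors for
    ``test_s`` seconds after a ``baseline_s`` air period; trained groups
    occupy the paired quadrants with stationary weight ``trained_bias``
    (< 1: conditioned avoidance of the paired odor). The transition assay
    delivers two 30 s odor pulses back to back with order-dependent upwind
    drift on the second pulse.
    """

    n_runs: int = 12
    baseline_s: float = 30.0
    test_s: float = 150.0
    trained_bias: float = 0.5
    pulse_s: float = 30.0
    drift_first: float = 0.5
    drift_second_similar_after_paired: float = 0.8
    drift_second_paired_after_similar: float = 0.2


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    kc: KcSynthConfig = field(default_factory=KcSynthConfig)
    mbon: MbonSynthConfig = field(default_factory=MbonSynthConfig)
    arena: ArenaSynthConfig = field(default_factory=ArenaSynthConfig)
    assay: BehaviorAssayConfig = field(default_factory=BehaviorAssayConfig)
    fit: FitSettings = field(default_factory=FitSettings)
    synapse_model: SynapseCountModel = field(default_factory=SynapseCountModel)
    window: ResponseWindow = field(default_factory=ResponseWindow)
    lam_decoding: float = 1.0
    n_imaging_flies: int = 3
    n_mbon_flies: int = 8
    stages: tuple[str, ...] = ("kc", "protocols", "mbon", "behavior")
    make_plots: bool = True
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        kwargs = {}
        nested = {
            "kc": KcSynthConfig,
            "mbon": MbonSynthConfig,
            "arena": ArenaSynthConfig,
            "assay": BehaviorAssayConfig,
            "fit": FitSettings,
            "synapse_model": SynapseCountModel,
            "window": ResponseWindow,
        }
        for key, value in doc.items():
            if key in nested:
                if key == "kc" and "stimuli" in value:
                    value = {**value, "stimuli": tuple(value["stimuli"])}
                kwargs[key] = nested[key](**value)
            elif key == "stages":
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def kc_feature_tables(tensor, schedule, window: ResponseWindow):
    """dF/F the tensor and build per-stimulus feature matrices.

    Pulse features are per-cell mean dF/F over the window at odor onset;
    transition features use the window anchored at the second-pulse onset.
    Returns (dff tensor, features dict, pulse amplitude table).
    """
    dff = imaging.compute_dff(imaging.subtract_background(tensor), schedule)
    pulse_table = imaging.response_amplitude(
        dff, schedule, "first", window,
        trials=np.concatenate([schedule.trials_for(s) for s in PULSE_STIMULI]),
    )
    features: dict[str, np.ndarray] = {}
    for stim in schedule.stimuli:
        trials = schedule.trials_for(stim)
        epoch = "second" if ">" in stim else "first"
        tab = imaging.response_amplitude(dff, schedule, epoch, window, trials=trials)
        features[stim] = (
            tab.pivot_table(index="trial", columns="cell", values="amplitude")
            .to_numpy()
        )
    return dff, features, pulse_table


def run_kc_experiment(
    kc_config: KcSynthConfig,
    n_flies: int = 3,
    lam: float = 1.0,
    settings: FitSettings | None = None,
    window: ResponseWindow | None = None,
    synapse_model: SynapseCountModel | None = None,
    seed: int = 0,
) -> dict:
    """Per-fly KC decoding plus pooled response-correlation summaries."""
    window = window or ResponseWindow()
    seeds = child_seeds(seed, n_flies)
    counts = gen_synapse_counts(synapse_model or SynapseCountModel(seed=seed))

    acc_rows = []
    pooled_amps = []
    first_fly = {}
    for fly, s in enumerate(seeds):
        cfg = dataclasses.replace(kc_config, seed=s)
        tensor, schedule, gt = gen_kc_dataset(cfg)
        dff, features, pulse_table = kc_feature_tables(tensor, schedule, window)
        mean_amp = imaging.mean_amplitudes(pulse_table)
        pooled_amps.append(mean_amp)

        pulse_trials = np.concatenate(
            [schedule.trials_for(s_) for s_ in PULSE_STIMULI]
        )
        X = np.vstack([features[s_] for s_ in PULSE_STIMULI])
        labels = np.concatenate(
            [[s_] * len(features[s_]) for s_ in PULSE_STIMULI]
        )
        theta0 = init_weights_connectome(counts, X.shape[1], seed=s)
        for odor in PULSE_STIMULI:
            res = loocv_odor_accuracy(
                X, labels, odor, lam=lam, theta0=theta0, settings=settings
            )
            acc_rows.append(
                {"fly": fly, "odor": odor, "accuracy": res.accuracy,
                 "n_folds": res.n_folds_evaluated}
            )
        if fly == 0:
            coords, _ = imaging.pca_project(X)
            averages, order = imaging.trial_average_sorted(dff, schedule, "A")
            first_fly = {
                "pca_coords": coords,
                "pca_labels": labels,
                "sorted_averages": averages,
                "sort_order": order,
                "ground_truth": gt,
                "schedule": schedule,
                "dff": dff,
            }
        del tensor, dff, features
    accuracies = pd.DataFrame(acc_rows)

    pooled = pd.concat(pooled_amps, ignore_index=True)
    corr = {}
    for pair in (("A", "A_prime"), ("A", "B"), ("A_prime", "B")):
        r, p = imaging.odor_response_correlation(
            pooled[pair[0]].to_numpy(), pooled[pair[1]].to_numpy()
        )
        corr["-".join(pair)] = {"r": r, "p": p, "n_cells": len(pooled)}

    fam = [
        paired_signed_rank(
            accuracies.query("odor == @odor").sort_values("fly")["accuracy"],
            accuracies.query("odor == 'B'").sort_values("fly")["accuracy"],
        )
        for odor in ("A", "A_prime")
    ]
    apply_family_correction(fam, "decoder-accuracy-vs-B")
    return {
        "accuracies": accuracies,
        "correlations": corr,
        "accuracy_stats": fam,
        "fly0": first_fly,
        "synapse_counts": counts,
    }


def run_protocol_experiment(
    kc_config: KcSynthConfig,
    settings: FitSettings | None = None,
    window: ResponseWindow | None = None,
    seed: int = 0,
) -> dict:
    """Fit the pulse-trained and transition-trained transfer protocols."""
    cfg = dataclasses.replace(kc_config, seed=child_seeds(seed, 1)[0])
    tensor, schedule, gt = gen_kc_dataset(cfg)
    _, features, pulse_table = kc_feature_tables(
        tensor, schedule, window or ResponseWindow()
    )
    pulse_trained = protocol_mbon_emulation(features, settings=settings, lam=0.0)
    transition_trained = protocol_transition_trained(
        features, settings=settings, lam=0.0
    )
    mean_amp = imaging.mean_amplitudes(pulse_table)
    w_corr = weight_response_correlation(
        pulse_trained.mean_theta, mean_amp["A"].to_numpy()
    )
    return {
        "pulse_trained": pulse_trained,
        "transition_trained": transition_trained,
        "weight_response_corr_A": w_corr,
        "ground_truth": gt,
    }


def run_mbon_experiment(
    mbon_config: MbonSynthConfig,
    n_flies: int = 8,
    window: ResponseWindow | None = None,
    n_trials_per_stim: int = 2,
    seed: int = 0,
) -> dict:
    """Pre/post amplitude ratios and transition contrast across flies."""
    window = window or ResponseWindow()
    schedule = make_schedule(MBON_STIMULI, n_trials_per_stim, 10.0, 5.0)
    rows = []
    contrast_rows = []
    for fly, s in enumerate(child_seeds(seed, n_flies)):
        cfg = dataclasses.replace(mbon_config, seed=s)
        pre_raw, post_raw, gt = gen_mbon_dataset(cfg, schedule)
        for phase, raw in (("pre", pre_raw), ("post", post_raw)):
            dff = imaging.compute_dff(imaging.subtract_background(raw), schedule)
            for stim in PULSE_STIMULI:
                tab = imaging.response_amplitude(
                    dff, schedule, "first", window,
                    trials=schedule.trials_for(stim),
                )
                rows.append(
                    {"fly": fly, "phase": phase, "stimulus": stim,
                     "epoch": "pulse", "amplitude": tab["amplitude"].mean()}
                )
            for stim in TRANSITION_STIMULI:
                trials = schedule.trials_for(stim)
                tab = imaging.response_amplitude(
                    dff, schedule, "second", window, trials=trials
                )
                rows.append(
                    {"fly": fly, "phase": phase, "stimulus": stim,
                     "epoch": "second", "amplitude": tab["amplitude"].mean()}
                )
                if phase == "post":
                    cs = np.mean([
                        imaging.transition_contrast(dff, schedule, int(t))
                        for t in trials
                    ])
                    contrast_rows.append(
                        {"fly": fly, "stimulus": stim, "contrast": cs}
                    )
    amplitudes = pd.DataFrame(rows)
    contrasts = pd.DataFrame(contrast_rows)

    wide = amplitudes.pivot_table(
        index=["fly", "stimulus", "epoch"], columns="phase", values="amplitude"
    ).reset_index()
    wide["post_pre_ratio"] = wide["post"] / wide["pre"]

    fam = []
    for stim in PULSE_STIMULI:
        sub = wide.query("stimulus == @stim and epoch == 'pulse'")
        fam.append(paired_signed_rank(sub["pre"], sub["post"]))
    apply_family_correction(fam, "mbon-pre-vs-post")
    c_wide = contrasts.pivot_table(index="fly", columns="stimulus", values="contrast")
    contrast_stat = paired_signed_rank(
        c_wide["A>A_prime"], c_wide["A_prime>A"]
    )
    return {
        "amplitudes": amplitudes,
        "ratios": wide,
        "contrasts": contrasts,
        "amplitude_stats": fam,
        "contrast_stat": contrast_stat,
    }


def _choice_timeline(assay: BehaviorAssayConfig, bias: float) -> ArenaTimeline:
    return ArenaTimeline(
        duration_s=assay.baseline_s + assay.test_s,
        epochs=[
            ArenaEpoch(
                "choice", assay.baseline_s, assay.baseline_s + assay.test_s,
                bias=bias,
            )
        ],
    )


def run_choice_experiment(
    arena_config: ArenaSynthConfig,
    assay: BehaviorAssayConfig | None = None,
    seed: int = 0,
    paired_control: bool = False,
) -> dict:
    """Quadrant choice assay: reciprocal trained PIs plus the
    unpaired-control generalization score.

    ``paired_control=True`` reuses each trained run's seed for its control
    run (common random numbers): pre-odor baselines cancel exactly, which
    sharpens planted-bias recovery. Independent controls (default) mimic the
    real assay, where control cohorts are different flies.
    """
    assay = assay or BehaviorAssayConfig()
    layout = behavior.QuadrantLayout()
    n = assay.n_runs
    seeds = child_seeds(seed, 2 * n)
    if paired_control:
        seeds = seeds[:n] * 2

    def run_pi(s: int, bias: float) -> behavior.PIResult:
        cfg = dataclasses.replace(arena_config, seed=s)
        traj, arena = gen_arena_trajectories(cfg, _choice_timeline(assay, bias))
        counts = behavior.occupancy_series(traj, layout, arena)
        return behavior.performance_index_series(
            counts, layout, arena.frame_rate_hz, odor_onset_s=assay.baseline_s
        )

    trained = [run_pi(s, assay.trained_bias) for s in seeds[:n]]
    control = [run_pi(s, 1.0) for s in seeds[n:]]

    # reciprocal design: average summary PIs pairwise across trained runs
    trained_pis = [r.pi_scalar for r in trained]
    reciprocal = [
        behavior.reciprocal_pi(a, b)
        for a, b in zip(trained_pis[0::2], trained_pis[1::2])
    ]
    gen_scores = [
        behavior.generalization_score(t, c) for t, c in zip(trained, control)
    ]
    stat = independent_rank_sum(trained_pis, [r.pi_scalar for r in control])
    return {
        "trained_pi": np.asarray(trained_pis),
        "control_pi": np.asarray([r.pi_scalar for r in control]),
        "reciprocal_pi": np.asarray(reciprocal),
        "generalization_scores": np.asarray(gen_scores),
        "pi_stat": stat,
    }


def run_transition_experiment(
    arena_config: ArenaSynthConfig,
    assay: BehaviorAssayConfig | None = None,
    seed: int = 0,
) -> dict:
    """Flooded-arena odor-transition assay: upwind displacement during the
    first and second pulses for both transition orders, with the
    radial-starting-position control."""
    assay = assay or BehaviorAssayConfig()
    n = assay.n_runs
    seeds = child_seeds(seed, 2 * n)
    onset1 = assay.baseline_s
    onset2 = assay.baseline_s + assay.pulse_s

    def run_order(s: int, second_drift: float):
        timeline = ArenaTimeline(
            duration_s=onset2 + assay.pulse_s + 5.0,
            epochs=[
                ArenaEpoch("odor", onset1, onset2, drift_mm_s=assay.drift_first),
                ArenaEpoch("odor", onset2, onset2 + assay.pulse_s,
                           drift_mm_s=second_drift),
            ],
        )
        cfg = dataclasses.replace(arena_config, seed=s)
        traj, arena = gen_arena_trajectories(cfg, timeline)
        first = behavior.upwind_displacement(traj, arena, onset1, assay.pulse_s)
        second = behavior.upwind_displacement(traj, arena, onset2, assay.pulse_s)
        _, r_at_onset2 = behavior.radial_position_at(traj, arena, onset2)
        return first, second, r_at_onset2

    rows = []
    series: dict[str, list[np.ndarray]] = {}
    for order, drift, batch in (
        ("A>A_prime", assay.drift_second_similar_after_paired, seeds[:n]),
        ("A_prime>A", assay.drift_second_paired_after_similar, seeds[n:]),
    ):
        series[order] = []
        for s in batch:
            first, second, r0 = run_order(s, drift)
            rows.append(
                {"order": order, "first_pulse": first.summary,
                 "second_pulse": second.summary, "radius_at_onset2": r0}
            )
            series[order].append(second.arena_series)
    table = pd.DataFrame(rows)
    a = table.query("order == 'A>A_prime'")
    b = table.query("order == 'A_prime>A'")
    fam = [
        independent_rank_sum(a["first_pulse"], b["first_pulse"]),
        independent_rank_sum(a["second_pulse"], b["second_pulse"]),
    ]
    apply_family_correction(fam, "upwind-displacement")
    start_stat = independent_rank_sum(a["radius_at_onset2"], b["radius_at_onset2"])
    return {
        "table": table,
        "second_pulse_series": {k: np.asarray(v) for k, v in series.items()},
        "stats": {"first": fam[0], "second": fam[1], "start_radius": start_stat},
    }


def run_drift_recovery(
    arena_config: ArenaSynthConfig | None = None,
    n_runs: int = 48,
    drift: float = 1.0,
    window_s: float = 10.0,
    seed: int = 0,
) -> dict:
    """Recover a planted upwind drift with a matched-null difference
    estimator.

    A reflected random walk started away from its stationary law inflates
    the mean radial displacement even without drift (a diffusive radial gain
    of order step_sd^2 / 2r per frame), so the estimator subtracts matched
    drift-off runs: v_hat = (mean end displacement with drift - without
    drift) / window. Cohorts start on a mid-arena ring so the diffusive term
    is matched between groups and the wall rarely censors the drift.
    """
    base = arena_config or ArenaSynthConfig(
        step_sd=0.3, init_radius=20.0, init_mode="ring", upwind_drift=drift
    )
    seeds = child_seeds(seed, 2 * n_runs)
    onset = 2.0

    def endpoint(s: int, v: float) -> tuple[float, float]:
        timeline = ArenaTimeline(
            duration_s=onset + window_s,
            epochs=[ArenaEpoch("odor", onset, onset + window_s, drift_mm_s=v)],
        )
        cfg = dataclasses.replace(base, seed=s)
        traj, arena = gen_arena_trajectories(cfg, timeline)
        res = behavior.upwind_displacement(traj, arena, onset, window_s)
        return float(res.arena_series[-1]), float(res.t_s[-1])

    on = [endpoint(s, drift) for s in seeds[:n_runs]]
    off = [endpoint(s, 0.0) for s in seeds[n_runs:]]
    t_last = on[0][1]
    estimate = (np.mean([e for e, _ in on]) - np.mean([e for e, _ in off])) / t_last
    return {
        "drift_planted": drift,
        "drift_estimate": float(estimate),
        "n_runs": n_runs,
        "endpoint_on": np.asarray([e for e, _ in on]),
        "endpoint_off": np.asarray([e for e, _ in off]),
    }


def _stat_to_dict(s: StatResult) -> dict:
    return {
        "test": s.test, "n1": s.n1, "n2": s.n2, "statistic": s.statistic,
        "p": s.p, "p_adjusted": s.p_adjusted, "family": s.family,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, StatResult):
        return _jsonable(_stat_to_dict(obj))
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_all(config: RunConfig, outdir) -> dict:
    """Execute the configured stage DAG and write results to ``outdir``.

    Emits ``results.json`` (summary scalars and statistics), tidy CSVs per
    stage, figure panels (PNG) when ``make_plots`` is set, and a run log
    with the seeds used. Any stage error aborts with a stage-tagged message.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("run_all seed=%d stages=%s", config.seed, config.stages)
    config.to_yaml(outdir / "config.yaml")

    stage_seeds = dict(zip(("kc", "protocols", "mbon", "behavior"),
                           child_seeds(config.seed, 4)))
    results: dict = {"seed": config.seed}
    raw: dict = {}
    try:
        if "kc" in config.stages:
            kc = run_kc_experiment(
                config.kc, config.n_imaging_flies, config.lam_decoding,
                config.fit, config.window, config.synapse_model,
                seed=stage_seeds["kc"],
            )
            raw["kc"] = kc
            kc["accuracies"].to_csv(outdir / "decoder_accuracies.csv", index=False)
            results["kc"] = {
                "correlations": kc["correlations"],
                "mean_accuracy": kc["accuracies"].groupby("odor")["accuracy"]
                .mean().to_dict(),
                "accuracy_sem": kc["accuracies"].groupby("odor")["accuracy"]
                .apply(sem).to_dict(),
                "accuracy_stats": [_stat_to_dict(s) for s in kc["accuracy_stats"]],
            }
        if "protocols" in config.stages:
            pr = run_protocol_experiment(
                config.kc, config.fit, config.window, seed=stage_seeds["protocols"]
            )
            raw["protocols"] = pr
            results["protocols"] = {
                "pulse_trained_mean_outputs": {
                    s: pr["pulse_trained"].mean_output(s)
                    for s in pr["pulse_trained"].outputs
                },
                "transition_trained_mean_outputs": {
                    s: pr["transition_trained"].mean_output(s)
                    for s in pr["transition_trained"].outputs
                },
                "weight_response_corr_A": pr["weight_response_corr_A"],
            }
        if "mbon" in config.stages:
            mb = run_mbon_experiment(
                config.mbon, config.n_mbon_flies, config.window,
                seed=stage_seeds["mbon"],
            )
            raw["mbon"] = mb
            mb["ratios"].to_csv(outdir / "mbon_ratios.csv", index=False)
            mb["contrasts"].to_csv(outdir / "mbon_contrasts.csv", index=False)
            pulse_ratios = mb["ratios"].query("epoch == 'pulse'")
            results["mbon"] = {
                "post_pre_ratio": pulse_ratios.groupby("stimulus")["post_pre_ratio"]
                .mean().to_dict(),
                "contrast_mean": mb["contrasts"].groupby("stimulus")["contrast"]
                .mean().to_dict(),
                "amplitude_stats": [_stat_to_dict(s) for s in mb["amplitude_stats"]],
                "contrast_stat": _stat_to_dict(mb["contrast_stat"]),
            }
        if "behavior" in config.stages:
            bseeds = child_seeds(stage_seeds["behavior"], 3)
            ch = run_choice_experiment(config.arena, config.assay, seed=bseeds[0])
            tr = run_transition_experiment(config.arena, config.assay, seed=bseeds[1])
            dr = run_drift_recovery(seed=bseeds[2])
            raw["behavior"] = {"choice": ch, "transition": tr, "drift": dr}
            tr["table"].to_csv(outdir / "upwind_displacement.csv", index=False)
            results["behavior"] = {
                "trained_pi_mean": float(np.mean(ch["trained_pi"])),
                "control_pi_mean": float(np.mean(ch["control_pi"])),
                "reciprocal_pi_mean": float(np.mean(ch["reciprocal_pi"])),
                "generalization_score_mean": float(
                    np.mean(ch["generalization_scores"])
                ),
                "pi_stat": _stat_to_dict(ch["pi_stat"]),
                "upwind_second_pulse_mean": tr["table"]
                .groupby("order")["second_pulse"].mean().to_dict(),
                "upwind_stats": {k: _stat_to_dict(v) for k, v in tr["stats"].items()},
                "drift_recovery": {
                    "planted": dr["drift_planted"],
                    "estimate": dr["drift_estimate"],
                },
            }
        if config.make_plots:
            _make_figures(raw, outdir)
    except Exception as exc:
        log.error("stage failure: %s", exc)
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()

    (outdir / "results.json").write_text(
        json.dumps(_jsonable(results), indent=2)
    )
    return results


def _make_figures(raw: dict, outdir: Path) -> None:
    """Figure-style panels; traces are boxcar-filtered for plotting only."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)

    if "kc" in raw:
        fly0 = raw["kc"]["fly0"]
        averages = fly0["sorted_averages"]
        rate = fly0["dff"].frame_rate_hz
        fig, axes = plt.subplots(1, len(PULSE_STIMULI), figsize=(10, 4), sharey=True)
        for ax, stim in zip(np.atleast_1d(axes), PULSE_STIMULI):
            filtered = imaging.boxcar_filter(averages[stim], rate)
            im = ax.imshow(filtered, aspect="auto", cmap="magma",
                           vmin=0, vmax=np.percentile(filtered, 99))
            ax.set_title(stim)
            ax.set_xlabel("frame")
        np.atleast_1d(axes)[0].set_ylabel("cell (sorted by A response)")
        fig.colorbar(im, ax=axes, label="dF/F")
        fig.savefig(figdir / "kc_sorted_heatmaps.png", dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(5, 4))
        coords, labels = fly0["pca_coords"], fly0["pca_labels"]
        for stim in PULSE_STIMULI:
            pts = coords[labels == stim]
            ax.scatter(pts[:, 0], pts[:, 1], label=stim, s=25)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend()
        fig.tight_layout()
        fig.savefig(figdir / "kc_pca.png", dpi=120)
        plt.close(fig)

        acc = raw["kc"]["accuracies"]
        fig, ax = plt.subplots(figsize=(5, 4))
        for i, odor in enumerate(PULSE_STIMULI):
            vals = acc.query("odor == @odor")["accuracy"]
            ax.scatter(np.full(len(vals), i), vals, color="gray", alpha=0.7)
            ax.errorbar(i, vals.mean(), yerr=sem(vals), fmt="ko", capsize=4)
        ax.set_xticks(range(len(PULSE_STIMULI)), PULSE_STIMULI)
        ax.set_ylabel("decoder accuracy")
        ax.set_ylim(0, 1.05)
        fig.tight_layout()
        fig.savefig(figdir / "decoder_accuracy.png", dpi=120)
        plt.close(fig)

    if "protocols" in raw:
        fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
        for ax, key, title in (
            (axes[0], "pulse_trained", "trained on pulses"),
            (axes[1], "transition_trained", "trained with transitions"),
        ):
            res = raw["protocols"][key]
            stims = list(res.outputs)
            for i, s in enumerate(stims):
                out = res.outputs[s]
                ax.scatter(np.full(out.size, i), out, s=8, color="k", alpha=0.3)
                ax.errorbar(i, out.mean(), yerr=sem(out), fmt="ro", capsize=3)
            ax.axhline(0.5, ls="--", color="gray")
            ax.set_xticks(range(len(stims)), stims, rotation=45)
            ax.set_title(title)
        axes[0].set_ylabel("model output")
        fig.tight_layout()
        fig.savefig(figdir / "model_outputs.png", dpi=120)
        plt.close(fig)

    if "mbon" in raw:
        wide = raw["mbon"]["ratios"].query("epoch == 'pulse'")
        fig, ax = plt.subplots(figsize=(5, 4))
        for i, stim in enumerate(PULSE_STIMULI):
            sub = wide.query("stimulus == @stim")
            for _, row in sub.iterrows():
                ax.plot([i - 0.15, i + 0.15], [row["pre"], row["post"]],
                        "o-", color="gray", alpha=0.6, ms=4)
        ax.set_xticks(range(len(PULSE_STIMULI)), PULSE_STIMULI)
        ax.set_ylabel("response amplitude (dF/F)")
        ax.set_title("pre vs post pairing")
        fig.tight_layout()
        fig.savefig(figdir / "mbon_amplitudes.png", dpi=120)
        plt.close(fig)

    if "behavior" in raw:
        ch = raw["behavior"]["choice"]
        tr = raw["behavior"]["transition"]
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        axes[0].boxplot(
            [ch["trained_pi"], ch["control_pi"]], tick_labels=["trained", "control"]
        )
        axes[0].axhline(0, color="gray", ls=":")
        axes[0].set_ylabel("performance index")
        for order, arr in tr["second_pulse_series"].items():
            mean = arr.mean(axis=0)
            err = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
            t = np.arange(mean.size)
            axes[1].plot(t, mean, label=order)
            axes[1].fill_between(t, mean - err, mean + err, alpha=0.3)
        axes[1].set_xlabel("frame from second-pulse onset")
        axes[1].set_ylabel("upwind displacement (mm)")
        axes[1].legend()
        fig.tight_layout()
        fig.savefig(figdir / "behavior.png", dpi=120)
        plt.close(fig)
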