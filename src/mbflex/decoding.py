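"""Logistic-regression population decoding of Kenyon-cell activity.

The decoder is the linear model h = 1 / (1 + exp(-X @ theta)) with no
intercept, fitted by minimizing binary cross-entropy with an optional
quadratic penalty:

    cost = -(1/m) * sum_i [ y_i log h_i + (1 - y_i) log(1 - h_i) ]
           + (lambda / 2m) * sum_j theta_j^2

where X is the m x n matrix of per-trial per-cell response features, y the
binary trial targets and theta the n weights. Fitting is deterministic
full-batch gradient descent with step halving, so identical inputs always
give identical weights.

Two weight initializations are provided: all-ones, and uniform resampling
from connectome synapse counts normalized to the maximum observed count.
Leave-one-out cross-validation (LOOCV) reports per-odor decoding accuracy,
and two transfer protocols emulate MBON-style readouts: training on isolated
odor pulses only (targets A: 0, A': 0, B: 1) and evaluating on transitions,
or training with the added requirement that the two transition orders be
discriminated (A->A': 1, A'->A: 0).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FitSettings",
    "DecoderModel",
    "LoocvResult",
    "ProtocolResult",
    "predict",
    "cost",
    "gradient",
    "fit",
    "init_weights_ones",
    "init_weights_connectome",
    "loocv_odor_accuracy",
    "protocol_mbon_emulation",
    "protocol_transition_trained",
    "weight_response_correlation",
]

_CLIP = 1e-12  # probability floor inside the cost, avoids log(0)


@dataclass(frozen=True)
class FitSettings:
    learning_rate: float = 0.1
    max_iter: int = 10_000
    cost_tolerance: float = 1e-8

    def __post_init__(self):
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if not self.cost_tolerance > 0:
            raise ValueError("cost_tolerance must be positive")


@dataclass
class DecoderModel:
    """Fitted weights plus regularization, threshold and fit diagnostics."""

    theta: np.ndarray
    lam: float = 0.0
    threshold: float = 0.5
    init_scheme: str = "custom"
    final_cost: float = float("nan")
    n_iter: int = 0
    converged: bool = False
    cost_history: np.ndarray | None = None  # cost after each accepted step

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("theta must be finite")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


def _theta_of(model) -> np.ndarray:
    return model.theta if isinstance(model, DecoderModel) else np.asarray(model, float)


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be m x n and y length m")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("targets must be binary {0, 1}")
    return X, y


def predict(model, X: np.ndarray) -> np.ndarray:
    """Elementwise logistic of X @ theta."""
    theta = _theta_of(model)
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != theta.shape[0]:
        raise ValueError(
            f"dimension mismatch: X has {X.shape[-1]} cells, theta has {theta.shape[0]}"
        )
    z = X @ theta
    # numerically stable logistic
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))


def cost(model, X: np.ndarray, y: np.ndarray, lam: float | None = None) -> float:
    """Binary cross-entropy plus (lambda/2m) * ||theta||^2."""
    theta = _theta_of(model)
    lam = (model.lam if isinstance(model, DecoderModel) else 0.0) if lam is None else lam
    X, y = _check_xy(X, y)
    m = X.shape[0]
    h = np.clip(predict(theta, X), _CLIP, 1.0 - _CLIP)
    ce = -(y @ np.log(h) + (1.0 - y) @ np.log(1.0 - h)) / m
    return float(ce + lam / (2.0 * m) * theta @ theta)


def gradient(model, X: np.ndarray, y: np.ndarray, lam: float | None = None) -> np.ndarray:
    """Analytic gradient of :func:`cost`: (1/m) X^T (h - y) + (lambda/m) theta."""
    theta = _theta_of(model)
    lam = (model.lam if isinstance(model, DecoderModel) else 0.0) if lam is None else lam
    X, y = _check_xy(X, y)
    m = X.shape[0]
    h = predict(theta, X)
    return X.T @ (h - y) / m + lam / m * theta


def fit(
    X: np.ndarray,
    y: np.ndarray,
    theta0: np.ndarray,
    lam: float = 0.0,
    settings: FitSettings | None = None,
    init_scheme: str = "custom",
    threshold: float = 0.5,
) -> DecoderModel:
    """Deterministic full-batch gradient descent from ``theta0``.

    Steps that would increase the cost are rejected and the step size halved,
    so the cost is non-increasing across accepted iterations. Stops when the
    cost change drops below ``cost_tolerance`` or ``max_iter`` is reached.
    """
    settings = settings or FitSettings()
    X, y = _check_xy(X, y)
    if not (np.any(y == 0) and np.any(y == 1)):
        raise ValueError("both target classes must be present for fitting")
    theta = np.asarray(theta0, dtype=float).copy()
    if theta.shape != (X.shape[1],):
        raise ValueError("theta0 length must equal the number of cells")

    m = X.shape[0]

    def _logistic(z):
        return np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)),
                        np.exp(z) / (1.0 + np.exp(z)))

    def _cost_of(h, th):
        hc = np.clip(h, _CLIP, 1.0 - _CLIP)
        ce = -(y @ np.log(hc) + (1.0 - y) @ np.log(1.0 - hc)) / m
        return float(ce + lam / (2.0 * m) * th @ th)

    lr0 = settings.learning_rate
    lr = lr0
    h = _logistic(X @ theta)
    c = _cost_of(h, theta)
    if not np.isfinite(c):
        raise ValueError("cost diverged at theta0; try a smaller learning_rate")
    n_iter = 0
    converged = False
    history = [c]
    for n_iter in range(1, settings.max_iter + 1):
        g = X.T @ (h - y) / m + lam / m * theta
        if np.max(np.abs(g)) < 1e-12:
            converged = True
            break
        accepted = False
        while lr > 1e-15:
            cand = theta - lr * g
            h_new = _logistic(X @ cand)
            c_new = _cost_of(h_new, cand)
            if np.isfinite(c_new) and c_new <= c:
                accepted = True
                break
            lr *= 0.5
        if not accepted:
            # no admissible step left: at numerical optimum
            converged = True
            break
        theta, delta, c, h = cand, c - c_new, c_new, h_new
        history.append(c)
        lr = min(lr * 1.5, lr0)  # recover after backtracking
        # a zero change can be a clipped-probability plateau, not convergence
        if 0.0 < delta < settings.cost_tolerance:
            converged = True
            break
    if not np.all(np.isfinite(theta)):
        raise ValueError("fit diverged; try a smaller learning_rate")
    return DecoderModel(
        theta=theta, lam=lam, threshold=threshold, init_scheme=init_scheme,
        final_cost=c, n_iter=n_iter, converged=converged,
        cost_history=np.asarray(history),
    )


def init_weights_ones(n: int) -> np.ndarray:
    """All-ones initialization (used for the pulse-transfer protocols)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    return np.ones(n)


def init_weights_connectome(counts: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """Initialize weights by uniform resampling from connectome synapse
    counts normalized to the maximum observed count (values in (0, 1])."""
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("counts must be non-empty")
    if np.any(counts <= 0):
        raise ValueError("synapse counts must be positive")
    support = counts / counts.max()
    rng = np.random.default_rng(seed)
    return rng.choice(support, size=n, replace=True)


@dataclass
class LoocvResult:
    odor: str
    accuracy: float
    folds: pd.DataFrame
    n_folds_evaluated: int
    n_folds_skipped: int
    mean_theta: np.ndarray


def loocv_odor_accuracy(
    X: np.ndarray,
    labels,
    odor: str,
    lam: float = 1.0,
    theta0: np.ndarray | None = None,
    settings: FitSettings | None = None,
    threshold: float = 0.5,
    mode: str = "hit",
) -> LoocvResult:
    """One-vs-rest LOOCV decoding of a target odor.

    Every trial is held out exactly once; the model is fitted on all
    remaining trials (all classes) with targets 1 for the target odor and 0
    otherwise. Folds whose training set lacks a class are skipped with a
    warning. ``mode='hit'`` (default) scores the fraction of held-out
    target-odor trials with h >= threshold; ``mode='balanced'`` averages that
    hit rate with the correct-rejection rate on held-out non-target trials.
    """
    labels = np.asarray(labels)
    X = np.asarray(X, dtype=float)
    y = (labels == odor).astype(float)
    if y.sum() < 2:
        raise ValueError("need at least 2 trials of the target odor")
    if (y == 0).sum() < 1:
        raise ValueError("need at least 1 trial of another odor")
    if theta0 is None:
        theta0 = init_weights_ones(X.shape[1])

    rows = []
    thetas = []
    skipped = 0
    for i in range(X.shape[0]):
        mask = np.ones(X.shape[0], dtype=bool)
        mask[i] = False
        if not (np.any(y[mask] == 0) and np.any(y[mask] == 1)):
            warnings.warn(f"fold {i}: a class is absent from the training set; skipped")
            skipped += 1
            continue
        model = fit(X[mask], y[mask], theta0, lam=lam, settings=settings,
                    threshold=threshold)
        h = float(predict(model, X[i]))
        thetas.append(model.theta)
        rows.append(
            {
                "fold": i,
                "stimulus": labels[i],
                "target": y[i],
                "output": h,
                "positive": h >= threshold,
            }
        )
    folds = pd.DataFrame(rows)
    pos = folds[folds["target"] == 1.0]
    hit_rate = float(pos["positive"].mean()) if len(pos) else float("nan")
    if mode == "hit":
        accuracy = hit_rate
    elif mode == "balanced":
        neg = folds[folds["target"] == 0.0]
        cr_rate = float((~neg["positive"]).mean()) if len(neg) else float("nan")
        accuracy = 0.5 * (hit_rate + cr_rate)
    else:
        raise ValueError("mode must be 'hit' or 'balanced'")
    return LoocvResult(
        odor=odor, accuracy=accuracy, folds=folds,
        n_folds_evaluated=len(folds), n_folds_skipped=skipped,
        mean_theta=np.mean(thetas, axis=0),
    )


@dataclass
class ProtocolResult:
    """Cross-validated model outputs per stimulus class plus mean weights."""

    outputs: dict[str, np.ndarray]
    mean_theta: np.ndarray
    targets: dict[str, float]
    n_folds: int

    def mean_output(self, stimulus: str) -> float:
        return float(np.mean(self.outputs[stimulus]))


def _run_protocol(
    features: dict[str, np.ndarray],
    targets: dict[str, float],
    settings: FitSettings | None,
    lam: float,
    threshold: float,
) -> ProtocolResult:
    missing = sorted(set(targets) - set(features))
    if missing:
        raise ValueError(f"missing stimulus classes in features: {missing}")
    train_stims = list(targets)
    X_train = np.vstack([features[s] for s in train_stims])
    y_train = np.concatenate(
        [np.full(len(features[s]), targets[s]) for s in train_stims]
    )
    stim_train = np.concatenate(
        [np.full(len(features[s]), s, dtype=object) for s in train_stims]
    )
    held_out_only = [s for s in features if s not in targets]

    theta0 = init_weights_ones(X_train.shape[1])
    outputs: dict[str, list[float]] = {s: [] for s in features}
    thetas = []
    for i in range(X_train.shape[0]):
        mask = np.ones(X_train.shape[0], dtype=bool)
        mask[i] = False
        model = fit(X_train[mask], y_train[mask], theta0, lam=lam,
                    settings=settings, threshold=threshold,
                    init_scheme="ones")
        thetas.append(model.theta)
        outputs[stim_train[i]].append(float(predict(model, X_train[i])))
        for s in held_out_only:
            outputs[s].extend(np.atleast_1d(predict(model, features[s])).tolist())
    return ProtocolResult(
        outputs={s: np.asarray(v) for s, v in outputs.items()},
        mean_theta=np.mean(thetas, axis=0),
        targets=dict(targets),
        n_folds=X_train.shape[0],
    )


def protocol_mbon_emulation(
    features: dict[str, np.ndarray],
    settings: FitSettings | None = None,
    lam: float = 0.0,
    threshold: float = 0.5,
) -> ProtocolResult:
    """Train on isolated pulses only (A: 0, A': 0, B: 1; weights initialized
    at 1, no regularization) and evaluate transition features held out.

    ``features`` maps stimulus labels to trial x cell response matrices;
    transition features are the second-pulse-window responses. Requires pulse
    trials for all three odors and both similar-odor transition orders.
    """
    for s in ("A>A_prime", "A_prime>A"):
        if s not in features:
            raise ValueError(f"missing transition features for {s!r}")
    return _run_protocol(
        features, {"A": 0.0, "A_prime": 0.0, "B": 1.0}, settings, lam, threshold
    )


def protocol_transition_trained(
    features: dict[str, np.ndarray],
    settings: FitSettings | None = None,
    lam: float = 0.0,
    threshold: float = 0.5,
) -> ProtocolResult:
    """As :func:`protocol_mbon_emulation` but with the transitions added to
    the training set and required to be discriminated (A->A': 1, A'->A: 0)."""
    targets = {"A": 0.0, "A_prime": 0.0, "B": 1.0, "A>A_prime": 1.0, "A_prime>A": 0.0}
    return _run_protocol(features, targets, settings, lam, threshold)


def weight_response_correlation(model, amplitudes: np.ndarray) -> float:
    """Pearson correlation between decoder weights and per-cell mean
    responses to an odor."""
    theta = _theta_of(model)
    amp = np.asarray(amplitudes, dtype=float)
    if amp.shape != theta.shape:
        raise ValueError("amplitude vector length must equal the weight count")
    if np.ptp(theta) == 0 or np.ptp(amp) == 0:
        raise ValueError("zero variance in weights or amplitudes")
    return float(np.corrcoef(theta, amp)[0, 1])
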