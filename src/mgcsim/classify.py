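"""Ratiometric detection core: nearest-mean-trajectory classification.

A class is represented by the trial-averaged population trajectory (its
template); an unseen trial is scored against template ``x`` by the
time-averaged Euclidean distance up to the decision time ``T``,

    D_x(T) = (1/T) * integral_0^T || r_unseen(t) - r_template_x(t) || dt,

discretised as the mean of per-step Euclidean norms, and assigned to the
class minimising ``D_x``.  Sweeping ``T`` under leave-one-trial-out
cross-validation yields the probability of correct classification as a
function of decision time: the earlier the curve rises above chance
(1/n_classes), the faster the representation resolves the blend ratio.

The same machinery applies to both the model's PN-population rate
trajectories and the normalised raw sensor trajectories, which is how the
spiking-network readout is benchmarked against direct classification of the
chemosensor transients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .readout import TrajectorySet

__all__ = [
    "ClassTemplate",
    "DecisionCurve",
    "mean_class_trajectory",
    "trajectory_distance",
    "classify_nearest",
    "classification_curve",
    "normalize_trajectories",
    "greedy_select",
]


@dataclass
class ClassTemplate:
    """Trial-mean trajectory of one class: shape (n_steps, n_channels)."""

    label: str
    mean: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        if self.n_trials < 1:
            raise ValueError("a template needs at least one trial")


@dataclass
class DecisionCurve:
    """P_classification as a function of decision time."""

    times_ms: np.ndarray
    p_correct: np.ndarray
    n_trials: int
    n_classes: int
    cv: str = "leave-one-out"

    @property
    def chance(self) -> float:
        return 1.0 / self.n_classes

    def binomial_se(self) -> np.ndarray:
        p = self.p_correct
        return np.sqrt(np.clip(p * (1 - p), 0, None) / self.n_trials)

    def first_above_chance(self, n_se: float = 2.0) -> float | None:
        """Earliest decision time with P > chance + n_se binomial s.e. of chance."""
        se = np.sqrt(self.chance * (1 - self.chance) / self.n_trials)
        above = self.p_correct > self.chance + n_se * se
        idx = np.nonzero(above)[0]
        return float(self.times_ms[idx[0]]) if idx.size else None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"T_ms": self.times_ms, "P_classification": self.p_correct,
             "n": self.n_trials}
        )


def mean_class_trajectory(trials: TrajectorySet, label: str) -> ClassTemplate:
    """Pointwise arithmetic mean across the trials of one class."""
    idx = [i for i, lab in enumerate(trials.labels) if lab == label]
    if not idx:
        raise ValueError(f"no trials of class {label!r}")
    return ClassTemplate(
        label=label,
        mean=trials.trajectories[idx].mean(axis=0),
        n_trials=len(idx),
    )


def _steps_for_T(T: float, delta: float, n_steps: int) -> int:
    if T <= 0:
        raise ValueError("decision time must be positive")
    n = int(round(T / delta))
    if n > n_steps:
        raise ValueError(f"decision time {T} ms exceeds trajectory span")
    return max(1, n)


def trajectory_distance(
    unseen: np.ndarray, template: ClassTemplate, T: float, delta: float = 1.0
) -> float:
    """Time-averaged Euclidean distance between trajectories over [0, T]."""
    unseen = np.asarray(unseen, dtype=float)
    n = _steps_for_T(T, delta, min(unseen.shape[0], template.mean.shape[0]))
    diff = unseen[:n] - template.mean[:n]
    return float(np.linalg.norm(diff, axis=1).mean())


def classify_nearest(
    unseen: np.ndarray,
    templates: list[ClassTemplate],
    T: float,
    delta: float = 1.0,
) -> str:
    """Label of the nearest mean trajectory at decision time ``T``.

    Ties break to the template whose label sorts first.
    """
    if not templates:
        raise ValueError("empty template set")
    ordered = sorted(templates, key=lambda t: t.label)
    dists = [trajectory_distance(unseen, t, T, delta) for t in ordered]
    return ordered[int(np.argmin(dists))].label


def classification_curve(
    trials: TrajectorySet,
    times_ms: np.ndarray | None = None,
    n_times: int = 25,
    seed: int | None = None,
    shuffle_labels: bool = False,
) -> DecisionCurve:
    """Leave-one-trial-out decision-time sweep.

    For each held-out trial, class templates are rebuilt from the remaining
    trials and the trial is classified at every decision time; the curve is
    the fraction classified correctly.  ``shuffle_labels`` permutes the labels
    first (seeded) — the resulting curve estimates the chance level.

    Every class must contribute at least two trials (a singleton class has no
    template once held out).
    """
    labels = list(trials.labels)
    if shuffle_labels:
        rng = np.random.default_rng(seed)
        labels = [labels[i] for i in rng.permutation(len(labels))]

    classes = sorted(set(labels))
    n_classes = len(classes)
    if n_classes < 2:
        raise ValueError("need at least two classes")
    counts = {cl: labels.count(cl) for cl in classes}
    thin = [cl for cl, n in counts.items() if n < 2]
    if thin:
        raise ValueError(f"classes with a single trial cannot be held out: {thin}")

    x = trials.trajectories
    n_trials, n_steps, _ = x.shape
    delta = trials.grid.delta
    if times_ms is None:
        times_ms = np.linspace(n_steps * delta / n_times, n_steps * delta, n_times)
    times_ms = np.asarray(times_ms, dtype=float)
    cut_steps = np.array([_steps_for_T(t, delta, n_steps) for t in times_ms])

    lab_idx = np.array([classes.index(lab) for lab in labels])
    sums = np.stack([x[lab_idx == ci].sum(axis=0) for ci in range(n_classes)])
    ns = np.array([counts[cl] for cl in classes])

    correct = np.zeros((times_ms.size, n_trials), dtype=bool)
    for y in range(n_trials):
        own = lab_idx[y]
        # per-class cumulative mean distance, LOO-corrected for the own class
        dist_t = np.empty((n_classes, n_steps))
        for ci in range(n_classes):
            if ci == own:
                tmpl = (sums[ci] - x[y]) / (ns[ci] - 1)
            else:
                tmpl = sums[ci] / ns[ci]
            dist_t[ci] = np.linalg.norm(x[y] - tmpl, axis=1)
        cums = np.cumsum(dist_t, axis=1)
        d = cums[:, cut_steps - 1] / cut_steps[None, :]  # (classes, times)
        pred = np.argmin(d, axis=0)  # ties -> lowest class index
        correct[:, y] = pred == own
    return DecisionCurve(
        times_ms=times_ms,
        p_correct=correct.mean(axis=1),
        n_trials=n_trials,
        n_classes=n_classes,
    )


def normalize_trajectories(
    trials: TrajectorySet, reference: TrajectorySet | None = None
) -> TrajectorySet:
    """Per-channel max-absolute scaling (scale learned on ``reference``).

    Used to put raw sensor trajectories on a common footing before the
    nearest-mean comparison; the scale comes from the training split when
    given, otherwise from ``trials`` itself.
    """
    src = reference if reference is not None else trials
    scale = np.abs(src.trajectories).max(axis=(0, 1))
    scale = np.where(scale == 0, 1.0, scale)
    return TrajectorySet(
        trajectories=trials.trajectories / scale,
        labels=list(trials.labels),
        grid=trials.grid,
        meta={**trials.meta, "normalized": True},
    )


def greedy_select(
    candidates: list,
    trajectory_fn,
    times_ms: np.ndarray | None = None,
    seed: int | None = None,
):
    """Scan a candidate pool and keep the connectome with the best accuracy.

    ``trajectory_fn(candidate) -> TrajectorySet`` maps each candidate model
    (plasticity disabled) to its training-set trajectories; the score is the
    decision-time-averaged leave-one-out accuracy.  Returns
    ``(best_candidate, scores)``; the first-encountered maximiser wins ties.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    scores = []
    for cand in candidates:
        ts = trajectory_fn(cand)
        curve = classification_curve(ts, times_ms=times_ms, seed=seed)
        scores.append(float(curve.p_correct.mean()))
    best = int(np.argmax(scores))
    return candidates[best], np.asarray(scores)
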