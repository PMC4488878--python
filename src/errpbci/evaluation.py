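"""Run records and the analysis machinery for closed-loop experiments.

Covers the task metrics (steps to the first target, targets reached),
the moving-average error rate that tracks learning progress, label
quality of the self-calibration against ground truth with ten-fold
cross-validated decoder accuracies, the incremental-calibration plateau
analysis, and the simulated supervised-control comparison (calibrate
first, then drive the calibrated filter with held-out signals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .decoder import (
    CORRECT,
    ERROR,
    DecoderParams,
    ShrinkageGaussianDecoder,
    fit_llr_calibration,
)
from .gridworld import (
    Action,
    GridState,
    GridTask,
    TransitionModel,
    optimal_actions,
    step,
)
from .planner import greedy_action
from .task_inference import (
    History,
    HistoryTriplet,
    TaskPosterior,
    calibrated_update,
    uniform_posterior,
)

__all__ = [
    "StepRecord",
    "GoalEvent",
    "RunRecord",
    "task_metrics",
    "instantaneous_error_rate",
    "label_quality",
    "calibration_curve",
    "simulated_supervised_control",
]


@dataclass
class StepRecord:
    """One logged step of a closed-loop run.

    ``true_label`` is the policy label under the user's intended task
    (was the device action objectively correct); ``emitted_label`` the
    class the user's assessment actually produced (equal to
    ``true_label`` unless the simulated user mis-assessed);
    ``learned_label`` the label the self-calibration assigned when the
    segment's target was identified (``None`` for unfinished segments).
    """

    index: int
    state: GridState
    action: Action
    mode: str  # "explore" | "exploit" | "calibrated"
    true_label: int
    emitted_label: int
    w_max: float
    decided: bool
    learned_label: Optional[int] = None
    target_index: int = 0


@dataclass
class GoalEvent:
    step_index: int
    reached: GridState
    intended: GridState

    @property
    def correct(self) -> bool:
        return GridState(*self.reached) == GridState(*self.intended)


@dataclass
class RunRecord:
    """Full log of one experiment: per-step records, goal events, features."""

    steps: list[StepRecord] = field(default_factory=list)
    goal_events: list[GoalEvent] = field(default_factory=list)
    features: Optional[np.ndarray] = None  # (n_steps, d), row i = steps[i]
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        idx = [s.index for s in self.steps]
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError("step indices must be contiguous from 1")
        for ev in self.goal_events:
            s = self.steps[ev.step_index - 1]
            if s.action != Action.GOAL_REACHED:
                raise ValueError("goal event without a goal-reached action")


def task_metrics(run: RunRecord) -> dict:
    """Steps to the first target and counts of correct/incorrect reaches."""
    events = run.goal_events
    steps_first = events[0].step_index if events else None
    n_correct = sum(ev.correct for ev in events)
    return {
        "steps_to_first_target": steps_first,
        "n_correct_targets": n_correct,
        "n_incorrect_targets": len(events) - n_correct,
    }


def instantaneous_error_rate(
    run: RunRecord, window: int = 10, until_first_goal: bool = False
) -> np.ndarray:
    """Moving-average error rate of the device's actions.

    At step ``i >= window`` the fraction of erroneous actions (policy
    labels w.r.t. the intended task) among the last ``window`` steps;
    earlier steps average the available prefix.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    steps = run.steps
    if until_first_goal and run.goal_events:
        steps = steps[: run.goal_events[0].step_index]
    errs = np.array([s.true_label == ERROR for s in steps], dtype=float)
    if errs.size == 0:
        return errs
    csum = np.concatenate([[0.0], np.cumsum(errs)])
    out = np.empty(errs.size)
    for i in range(errs.size):
        lo = max(0, i + 1 - window)
        out[i] = (csum[i + 1] - csum[lo]) / (i + 1 - lo)
    return out


def _tenfold_accuracy(
    X: np.ndarray,
    y_train: np.ndarray,
    y_eval: np.ndarray,
    params: DecoderParams,
    seed: int,
) -> float:
    """Stratified 10-fold CV accuracy: train on ``y_train`` labels, score
    predictions against ``y_eval`` on each test fold."""
    skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=seed)
    hits, total = 0, 0
    for tr, te in skf.split(X, y_eval):
        clf = ShrinkageGaussianDecoder(params.shrinkage_lambda, params.class_priors)
        clf.fit(X[tr], y_train[tr])
        hits += int(np.sum(clf.predict(X[te]) == y_eval[te]))
        total += te.size
    return hits / total


def label_quality(
    run: RunRecord,
    params: DecoderParams = DecoderParams(),
    seed: int = 0,
) -> dict:
    """Self-calibration label quality on the finished segments of a run.

    ``pct_labels_correct`` compares the labels the self-calibration
    assigned (the decided task's policy labels) with the labels the
    *intended* task's policy prescribes — the ground truth an experimenter
    can observe; it falls below 100 exactly for the segments whose target
    was misidentified.  ``pct_labels_match_signal_class`` additionally
    compares with the class the signal was actually generated from, which
    differs whenever the simulated user mis-assessed.  The ten-fold
    decoder accuracies (stratified, fixed seed) are trained under the
    ground-truth and the learned labelling respectively, both scored
    against the signal classes on the test folds.
    """
    if run.features is None:
        raise ValueError("run record carries no features")
    mask = np.array([s.learned_label is not None for s in run.steps])
    if not mask.any():
        raise ValueError("run has no finished (decided) target segment")
    X = run.features[mask]
    y_policy = np.array([s.true_label for s, m in zip(run.steps, mask) if m])
    y_signal = np.array([s.emitted_label for s, m in zip(run.steps, mask) if m])
    y_learned = np.array([s.learned_label for s, m in zip(run.steps, mask) if m])
    counts = [np.sum(y_signal == k) for k in (CORRECT, ERROR)]
    if min(counts) < 10:
        raise ValueError("need at least 10 samples per class for ten-fold CV")
    acc_true = _tenfold_accuracy(X, y_signal, y_signal, params, seed)
    acc_learned = _tenfold_accuracy(X, y_learned, y_signal, params, seed)
    return {
        "pct_labels_correct": 100.0 * float(np.mean(y_policy == y_learned)),
        "pct_labels_match_signal_class": 100.0 * float(np.mean(y_signal == y_learned)),
        "acc_cv_true": acc_true,
        "acc_cv_learned": acc_learned,
        "n_labeled": int(mask.sum()),
    }


def _plateau_index(acc: np.ndarray, tol: float, run_length: int = 5) -> Optional[int]:
    """First index from which the accuracy stays within ``tol`` of the
    curve's maximum for ``run_length`` consecutive points.

    Anchoring on the global maximum (the plateau level itself) rather
    than the running maximum matters for slowly rising curves: against a
    running maximum, a curve that gains slightly less than ``tol`` per
    increment would qualify as plateaued long before it stops improving.
    """
    level = acc.max() - tol
    for i in range(len(acc) - run_length + 1):
        if (acc[i : i + run_length] >= level).all():
            return i
    return None


def calibration_curve(
    X: np.ndarray,
    y: np.ndarray,
    train_size: int = 300,
    test_size: int = 200,
    n_shuffles: int = 10,
    n_min: int = 10,
    step: int = 5,
    plateau_tol: float = 0.01,
    params: DecoderParams = DecoderParams(),
    seed: int = 0,
) -> dict:
    """Incremental-calibration analysis.

    The data are split into a training pool and a fixed test set; a
    supervised decoder is trained on the first ``n`` pool trials for
    increasing ``n`` and scored on the test set, repeated over
    ``n_shuffles`` reshuffles.  The number of calibration trials is the
    first ``n`` at which the mean accuracy stays within ``plateau_tol``
    (one percentage point by default) of its running maximum for five
    consecutive increments.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    if X.shape[0] < train_size + test_size:
        raise ValueError("dataset smaller than train_size + test_size")
    rng = np.random.default_rng(seed)
    sizes = np.arange(n_min, train_size + 1, step)
    accs = np.empty((n_shuffles, sizes.size))
    for s in range(n_shuffles):
        order = rng.permutation(X.shape[0])
        pool, test = order[:train_size], order[train_size : train_size + test_size]
        Xte, yte = X[test], y[test]
        for j, n in enumerate(sizes):
            sub = pool[:n]
            if np.unique(y[sub]).size < 2:
                accs[s, j] = 0.5  # degenerate split: chance level
                continue
            clf = ShrinkageGaussianDecoder(params.shrinkage_lambda, params.class_priors)
            clf.fit(X[sub], y[sub])
            accs[s, j] = float(np.mean(clf.predict(Xte) == yte))
    mean_acc = accs.mean(axis=0)
    idx = _plateau_index(mean_acc, plateau_tol)
    return {
        "n_train": sizes,
        "accuracy_mean": mean_acc,
        "accuracy_std": accs.std(axis=0),
        "n_plateau": None if idx is None else int(sizes[idx]),
        "plateau_accuracy": None if idx is None else float(mean_acc[idx]),
    }


def calibrated_control_action(
    state: GridState,
    posterior: TaskPosterior,
    beta: float = 0.9,
) -> Action:
    """Greedy action of the calibrated controller with gated commitment.

    The device moves toward the most likely goal; the goal-reached action
    is committed only while that goal's pairwise confidence exceeds
    ``beta`` — otherwise the device keeps disambiguating by moving toward
    the runner-up goal, so a freshly reset (near-uniform) posterior can
    never trigger an instant degenerate reach at the current cell.
    """
    order = np.argsort(posterior.log_corrected)[::-1]
    map_task = posterior.tasks[int(order[0])]
    action = greedy_action(state, map_task)
    if action == Action.GOAL_REACHED and posterior.confidence[int(order[0])] <= beta:
        runner_up = posterior.tasks[int(order[1])]
        return greedy_action(state, runner_up)
    return action


def simulated_supervised_control(
    X: np.ndarray,
    y: np.ndarray,
    n_calib: int,
    model: TransitionModel,
    goal_sequence: Sequence[GridState],
    n_runs: int = 100,
    step_budget: int = 500,
    start: Optional[GridState] = None,
    params: DecoderParams = DecoderParams(),
    beta: float = 0.9,
    seed: int = 0,
) -> list[dict]:
    """Replay calibrated control using recorded/held-out labelled signals.

    A decoder is trained on ``n_calib`` trials; the remaining trials form
    a pool from which, at each simulated step, the next unused signal of
    the required true label is consumed.  Control is the calibrated
    recursive filter plus greedy movement toward the most likely goal,
    with the goal-reached commitment gated on the confidence threshold
    ``beta``.  Steps to the first target include the ``n_calib``
    calibration trials.  Returns per-run metric dicts (with a
    ``truncated`` flag when a run exhausts its signal pool).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    if n_calib >= X.shape[0]:
        raise ValueError("n_calib leaves no held-out signals")
    rng = np.random.default_rng(seed)
    tasks = model.tasks()
    results = []
    for _ in range(n_runs):
        order = rng.permutation(X.shape[0])
        calib, pool = order[:n_calib], order[n_calib:]
        if np.unique(y[calib]).size < 2:
            raise ValueError("calibration set must contain both classes")
        clf = ShrinkageGaussianDecoder(params.shrinkage_lambda, params.class_priors)
        clf.fit(X[calib], y[calib])
        models = clf.models_
        llr_scale = fit_llr_calibration(X[calib], y[calib], params, seed=seed)
        queues = {k: list(pool[y[pool] == k]) for k in (CORRECT, ERROR)}
        state = GridState(*(start or GridState(model.height // 2, model.width // 2)))
        posterior = uniform_posterior(tasks)
        target_idx = 0
        intended = GridState(*goal_sequence[0])
        events: list[GoalEvent] = []
        truncated = False
        budget = step_budget - n_calib
        for i in range(1, max(budget, 0) + 1):
            map_task = posterior.map_task()
            action = calibrated_control_action(state, posterior, beta)
            true_label = (
                CORRECT
                if action in optimal_actions(state, GridTask(intended))
                else ERROR
            )
            if not queues[true_label]:
                truncated = True
                break
            sig = X[queues[true_label].pop(0)]
            triplet = HistoryTriplet(state, action, sig, i)
            posterior = calibrated_update(
                posterior, triplet, models, params, llr_scale=llr_scale
            )
            if action == Action.GOAL_REACHED and state == map_task.goal:
                events.append(GoalEvent(i, state, intended))
                target_idx += 1
                intended = GridState(*goal_sequence[target_idx % len(goal_sequence)])
                posterior = uniform_posterior(tasks)
            state = step(state, action, model)
        metrics = {
            "steps_to_first_target": (
                events[0].step_index + n_calib if events else None
            ),
            "n_correct_targets": sum(ev.correct for ev in events),
            "n_incorrect_targets": sum(not ev.correct for ev in events),
            "truncated": truncated,
        }
        results.append(metrics)
    return results


def plot_error_rate(run: RunRecord, path, window: int = 10) -> None:
    """Write the moving-average error-rate figure for the first target."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    series = instantaneous_error_rate(run, window=window, until_first_goal=True)
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(np.arange(1, series.size + 1), 100 * series)
    ax.set_xlabel("step")
    ax.set_ylabel(f"% errors (last {window})")
    ax.set_ylim(0, 100)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
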