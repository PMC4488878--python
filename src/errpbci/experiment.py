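"""Closed-loop experiment orchestration.

``run_selfcal_experiment`` assembles the whole self-calibrating loop:
plan an action (uncertainty-driven while undecided, greedy once a goal
hypothesis clears the confidence threshold), execute it, collect the
simulated user's assessment signal, update the power-corrected task
posterior, and — on reaching a target — label the segment's signals with
the identified goal's policy, bank them as prior data for subsequent
targets, advance the goal sequence and reset the posterior.

``run_calibrated_experiment`` is the supervised baseline: fit the
shrinkage Gaussian decoder on labelled data, then run the calibrated
recursive filter with greedy control.

All randomness flows from the single configured seed.  Inter-action
timing of the original protocol (3–3.5 s between actions, rest breaks)
is operation metadata with no effect on the simulation and is recorded
in ``RunRecord.meta`` only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .decoder import CORRECT, ERROR, DecoderParams, ShrinkageGaussianDecoder
from .evaluation import GoalEvent, RunRecord, StepRecord
from .gridworld import (
    Action,
    GridState,
    GridTask,
    TransitionModel,
    error_label_array,
    optimal_actions,
    step,
)
from .planner import (
    PlannerConfig,
    select_action,
    signal_uncertainty_reward,
)
from .synthetic import SignalGeneratorConfig, SimulatedUser, assess
from .task_inference import (
    History,
    HistoryTriplet,
    InferenceConfig,
    LabeledSignals,
    _task_labels,
    calibrated_update,
    corrected_posterior,
    decide,
    task_class_summaries,
    uniform_posterior,
)

__all__ = [
    "ExperimentConfig",
    "default_goal_sequence",
    "run_selfcal_experiment",
    "run_calibrated_experiment",
    "save_run",
    "load_run",
]

#: fixed, documented goal sequence (cycled when more targets are reached);
#: consecutive goals are distinct so a new target never starts satisfied.
DEFAULT_GOAL_SEQUENCE: tuple[tuple[int, int], ...] = (
    (0, 3),
    (4, 1),
    (1, 0),
    (3, 4),
    (0, 0),
    (2, 4),
    (4, 4),
    (1, 2),
    (3, 0),
    (0, 2),
    (4, 3),
    (2, 1),
)


def default_goal_sequence(model: TransitionModel) -> list[GridState]:
    """The default sequence clipped into the given grid."""
    seq = [
        GridState(min(r, model.height - 1), min(c, model.width - 1))
        for r, c in DEFAULT_GOAL_SEQUENCE
    ]
    # drop consecutive duplicates created by clipping into small grids
    out: list[GridState] = []
    for s in seq:
        if not out or out[-1] != s:
            out.append(s)
    return out


@dataclass
class ExperimentConfig:
    """Closed-loop experiment configuration."""

    width: int = 5
    height: int = 5
    goal_sequence: Optional[Sequence[tuple[int, int]]] = None
    step_budget: int = 500
    beta: float = 0.9
    decoder: DecoderParams = field(default_factory=DecoderParams)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    planner: Optional[PlannerConfig] = None
    generator: Optional[SignalGeneratorConfig] = None
    seed: int = 0
    start: Optional[tuple[int, int]] = None
    max_targets: Optional[int] = None  # stop early after this many reaches
    inter_action_interval_s: tuple[float, float] = (3.0, 3.5)  # metadata only

    def __post_init__(self) -> None:
        if self.step_budget < 1:
            raise ValueError("step_budget must be positive")
        if not 0.5 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0.5, 1]")
        if self.planner is None:
            self.planner = PlannerConfig(beta=self.beta)
        if self.generator is None:
            self.generator = SignalGeneratorConfig()

    @property
    def model(self) -> TransitionModel:
        return TransitionModel(width=self.width, height=self.height)

    def goals(self) -> list[GridState]:
        model = self.model
        if self.goal_sequence is None:
            return default_goal_sequence(model)
        goals = [GridState(*g) for g in self.goal_sequence]
        for g in goals:
            if not model.contains(g):
                raise ValueError(f"goal {g} outside the grid")
        return goals


def _start_state(cfg: ExperimentConfig) -> GridState:
    if cfg.start is not None:
        s = GridState(*cfg.start)
        if not cfg.model.contains(s):
            raise ValueError(f"start {s} outside the grid")
        return s
    return GridState(cfg.height // 2, cfg.width // 2)


def run_selfcal_experiment(cfg: ExperimentConfig) -> RunRecord:
    """Run the self-calibrating closed loop; returns the full run record."""
    model = cfg.model
    tasks = model.tasks()
    goals = cfg.goals()
    rng = np.random.default_rng(cfg.seed)
    state = _start_state(cfg)
    user = SimulatedUser(GridTask(goals[0]), cfg.generator)
    history = History(d=cfg.generator.d)
    prior = LabeledSignals()
    posterior = uniform_posterior(tasks)
    decided: Optional[GridTask] = None
    target_idx = 0
    segment_start = 0  # step list offset of the current target's first step

    run = RunRecord(
        features=None,
        meta={
            "kind": "self-calibration",
            "seed": cfg.seed,
            "beta": cfg.beta,
            "grid": [cfg.height, cfg.width],
            "inter_action_interval_s": list(cfg.inter_action_interval_s),
        },
    )
    feats: list[np.ndarray] = []

    for i in range(1, cfg.step_budget + 1):
        if decided is None and len(history) >= 2:
            # signal-space uncertainty reward once class models exist
            means, var0 = task_class_summaries(
                history, tasks, prior, model, cfg.inference, kappa=2.0
            )
            reward = signal_uncertainty_reward(posterior, model, means, var0)
            if cfg.planner.exploit_blend > 0:
                p_correct = np.zeros_like(reward)
                for task, wgt in zip(tasks, posterior.scores):
                    p_correct += wgt * (1 - error_label_array(task, model))
                reward = reward + cfg.planner.exploit_blend * p_correct
        else:
            reward = None  # label-entropy fallback inside select_action
        action = select_action(state, posterior, decided, model, cfg.planner, reward)
        emitted, sig = assess(user, state, action, rng)
        true_label = (
            CORRECT
            if action in optimal_actions(state, user.intended_task)
            else ERROR
        )
        history.append(state, action, sig)
        feats.append(sig)
        posterior = corrected_posterior(history, tasks, prior, model, cfg.inference)
        # the decision is re-examined every step: the task is considered
        # identified only while its confidence stays above beta, so a
        # transient noise crossing is revoked by the next signals.
        decided = decide(posterior, cfg.beta)
        run.steps.append(
            StepRecord(
                index=i,
                state=state,
                action=action,
                mode="exploit" if decided is not None else "explore",
                true_label=true_label,
                emitted_label=emitted,
                w_max=float(posterior.confidence.max()),
                decided=decided is not None,
                target_index=target_idx,
            )
        )
        if (
            decided is not None
            and action == Action.GOAL_REACHED
            and state == decided.goal
        ):
            run.goal_events.append(GoalEvent(i, state, user.intended_task.goal))
            # prior transfer: label the segment with the identified goal's
            # policy and bank the signals; labels are never revised.
            labels = _task_labels(history, decided, model)
            prior.extend(history.feature_matrix(), labels)
            for off, lab in enumerate(labels):
                run.steps[segment_start + off].learned_label = int(lab)
            history.clear()
            posterior = uniform_posterior(tasks)
            decided = None
            segment_start = len(run.steps)
            target_idx += 1
            user = SimulatedUser(
                GridTask(goals[target_idx % len(goals)]), cfg.generator
            )
            if cfg.max_targets is not None and target_idx >= cfg.max_targets:
                state = step(state, action, model)
                break
        state = step(state, action, model)

    run.features = np.array(feats).reshape(len(feats), -1)
    run.validate()
    return run


def run_calibrated_experiment(
    cfg: ExperimentConfig,
    train_features: np.ndarray,
    train_labels: np.ndarray,
) -> RunRecord:
    """Supervised baseline: fit the decoder, then filter + greedy control."""
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels, dtype=int).ravel()
    if X.size == 0:
        raise ValueError("empty training set")
    clf = ShrinkageGaussianDecoder(
        cfg.decoder.shrinkage_lambda, cfg.decoder.class_priors
    )
    clf.fit(X, y)
    models = clf.models_
    from .decoder import fit_llr_calibration

    llr_scale = fit_llr_calibration(X, y, cfg.decoder, seed=cfg.seed)

    model = cfg.model
    tasks = model.tasks()
    goals = cfg.goals()
    rng = np.random.default_rng(cfg.seed)
    state = _start_state(cfg)
    user = SimulatedUser(GridTask(goals[0]), cfg.generator)
    posterior = uniform_posterior(tasks)
    target_idx = 0
    run = RunRecord(
        meta={"kind": "calibrated", "seed": cfg.seed, "grid": [cfg.height, cfg.width]}
    )
    feats: list[np.ndarray] = []
    from .evaluation import calibrated_control_action

    for i in range(1, cfg.step_budget + 1):
        map_task = posterior.map_task()
        action = calibrated_control_action(state, posterior, cfg.beta)
        emitted, sig = assess(user, state, action, rng)
        true_label = (
            CORRECT
            if action in optimal_actions(state, user.intended_task)
            else ERROR
        )
        triplet = HistoryTriplet(state, action, sig, i)
        posterior = calibrated_update(
            posterior, triplet, models, cfg.decoder, model, llr_scale=llr_scale
        )
        feats.append(sig)
        run.steps.append(
            StepRecord(
                index=i,
                state=state,
                action=action,
                mode="calibrated",
                true_label=true_label,
                emitted_label=emitted,
                w_max=float(posterior.confidence.max()),
                decided=False,
                target_index=target_idx,
            )
        )
        if action == Action.GOAL_REACHED and state == map_task.goal:
            run.goal_events.append(GoalEvent(i, state, user.intended_task.goal))
            posterior = uniform_posterior(tasks)
            target_idx += 1
            user = SimulatedUser(
                GridTask(goals[target_idx % len(goals)]), cfg.generator
            )
            if cfg.max_targets is not None and target_idx >= cfg.max_targets:
                state = step(state, action, model)
                break
        state = step(state, action, model)
    run.features = np.array(feats).reshape(len(feats), -1)
    run.validate()
    return run


# ---------------------------------------------------------------------------
# run log I/O (delimited text + feature CSV)


def save_run(run: RunRecord, out_dir: str | Path) -> Path:
    """Write a run as plain text: steps.tsv, events.tsv, features.csv, meta.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "step": s.index,
            "row": s.state.row,
            "col": s.state.col,
            "action": s.action.name,
            "mode": s.mode,
            "true_label": s.true_label,
            "emitted_label": s.emitted_label,
            "learned_label": "" if s.learned_label is None else s.learned_label,
            "w_max": s.w_max,
            "decided": int(s.decided),
            "target_index": s.target_index,
        }
        for s in run.steps
    ]
    pd.DataFrame(rows).to_csv(out / "steps.tsv", sep="\t", index=False, float_format="%.17g")
    ev = [
        {
            "step": e.step_index,
            "reached_row": e.reached.row,
            "reached_col": e.reached.col,
            "intended_row": e.intended.row,
            "intended_col": e.intended.col,
            "correct": int(e.correct),
        }
        for e in run.goal_events
    ]
    pd.DataFrame(ev, columns=["step", "reached_row", "reached_col", "intended_row", "intended_col", "correct"]).to_csv(
        out / "events.tsv", sep="\t", index=False
    )
    if run.features is not None:
        from .features import write_features

        write_features(out / "features.csv", run.features)
    (out / "meta.json").write_text(json.dumps(run.meta, indent=2))
    return out


def load_run(run_dir: str | Path) -> RunRecord:
    run_dir = Path(run_dir)
    steps_df = pd.read_csv(run_dir / "steps.tsv", sep="\t")
    steps = [
        StepRecord(
            index=int(r.step),
            state=GridState(int(r.row), int(r.col)),
            action=Action[str(r.action)],
            mode=str(r.mode),
            true_label=int(r.true_label),
            emitted_label=int(r.emitted_label),
            learned_label=None if pd.isna(r.learned_label) else int(r.learned_label),
            w_max=float(r.w_max),
            decided=bool(r.decided),
            target_index=int(r.target_index),
        )
        for r in steps_df.itertuples()
    ]
    ev_df = pd.read_csv(run_dir / "events.tsv", sep="\t")
    events = [
        GoalEvent(
            int(r.step),
            GridState(int(r.reached_row), int(r.reached_col)),
            GridState(int(r.intended_row), int(r.intended_col)),
        )
        for r in ev_df.itertuples()
    ]
    features = None
    fpath = run_dir / "features.csv"
    if fpath.exists():
        from .features import read_features

        features, _ = read_features(fpath)
    meta = {}
    mpath = run_dir / "meta.json"
    if mpath.exists():
        meta = json.loads(mpath.read_text())
    run = RunRecord(steps=steps, goal_events=events, features=features, meta=meta)
    run.validate()
    return run
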