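"""Action selection: uncertainty-driven exploration, greedy exploitation.

While no goal hypothesis has been identified with confidence, the device
plans to *reduce uncertainty* rather than to reach a goal: every
(state, action) pair is assigned an uncertainty reward and the resulting
MDP is solved by value iteration.  Once some hypothesis's confidence
``W^t`` exceeds the threshold ``beta``, the device switches to pure
exploitation: the decided goal's optimal policy, ignoring uncertainty.

Two uncertainty rewards are provided.  ``uncertainty_reward`` is the
label-space approximation: the binary entropy of the posterior-mixture
label distribution at each pair.  It is simple but blind to labelling
symmetries — two hypothesis groups whose labelings are exact class swaps
of each other keep maximal label entropy at pairs that carry no
information about which group is right, and the planner can stall there.
``signal_uncertainty_reward`` measures uncertainty on the *signal*
space: the expected information gain about the task from observing one
signal at the pair, i.e. the mixture entropy of the task-conditioned
signal predictives minus their mean entropy, approximated in closed form
through pairwise Bhattacharyya distances between the (shared-variance)
class predictives.  Swap-symmetric pairs then earn zero reward while
goal-reached actions — which break the symmetry — earn positive reward,
so the closed loop uses the signal-space reward whenever class models
exist and falls back to label entropy before that.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .gridworld import (
    Action,
    GridState,
    GridTask,
    TransitionModel,
    error_label_array,
    optimal_actions,
    step,
)
from .task_inference import TaskPosterior

__all__ = [
    "PlannerConfig",
    "uncertainty_reward",
    "signal_uncertainty_reward",
    "value_iteration",
    "select_action",
    "greedy_action",
]

#: documented deterministic tie-break: first action in this order wins.
ACTION_ORDER = tuple(Action)


@dataclass(frozen=True)
class PlannerConfig:
    """Planner hyperparameters.

    Discount 0.95 and a 1e-6 value-iteration tolerance are package
    defaults (the stopping rule is a sup-norm change below the
    tolerance).  ``beta`` is the confidence threshold of the
    explore/exploit switch.  ``exploit_blend`` adds a small bonus equal to
    the posterior probability that a pair is assessed as correct: it
    resolves ties between equally informative actions toward the current
    goal estimate, so the device's error exposure falls as the posterior
    concentrates (information itself is label-symmetric and cannot prefer
    the correct-labelled of two equally discriminating pairs).
    ``n_label_samples = 0`` disables the sampled signal-space reward term.
    """

    discount: float = 0.95
    vi_tolerance: float = 1e-6
    beta: float = 0.9
    exploit_blend: float = 0.05
    n_label_samples: int = 0
    max_iterations: int = 100_000

    def __post_init__(self) -> None:
        if not 0.0 < self.discount < 1.0:
            raise ValueError("discount must be in (0, 1)")
        if self.vi_tolerance <= 0:
            raise ValueError("vi_tolerance must be positive")
        if not 0.5 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0.5, 1]")


def _binary_entropy(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 0.0, 1.0)
    out = np.zeros_like(p)
    inner = (p > 0) & (p < 1)
    q = p[inner]
    out[inner] = -q * np.log(q) - (1.0 - q) * np.log1p(-q)
    return out


def uncertainty_reward(
    posterior: TaskPosterior,
    model: TransitionModel,
    n_label_samples: int = 0,
    signal_sampler: Optional[Callable[[int, np.random.Generator], np.ndarray]] = None,
    label_scorer: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Exploration reward per (state, action): entropy of the mixed label.

    ``reward[row, col, action] = H(q)`` with ``q`` the posterior-weighted
    probability that the action is correct there.  The reward vanishes
    wherever all (posterior-supported) hypotheses agree, and peaks
    (``ln 2``) where they split evenly.

    When ``n_label_samples > 0`` and a ``signal_sampler`` /
    ``label_scorer`` pair is supplied, a sampled signal-space term is
    added: for each pair, signals are drawn from the predictive mixture
    (label sampled from ``q``, then a feature draw for that label) and
    the mean entropy of their decoded label posterior is averaged in.
    """
    p_correct = np.zeros((model.height, model.width, len(Action)))
    for task, w in zip(posterior.tasks, posterior.scores):
        p_correct += w * (1 - error_label_array(task, model))
    total = float(posterior.scores.sum())
    if total > 0:
        p_correct /= total
    reward = _binary_entropy(p_correct)
    if n_label_samples > 0 and signal_sampler is not None and label_scorer is not None:
        rng = rng or np.random.default_rng()
        extra = np.zeros_like(reward)
        flat_q = p_correct.reshape(-1)
        for idx, q in enumerate(flat_q):
            if reward.reshape(-1)[idx] == 0.0:
                continue  # agreed pairs stay at zero reward
            labels = (rng.random(n_label_samples) > q).astype(int)
            draws = np.stack([signal_sampler(int(l), rng) for l in labels])
            p = np.clip(label_scorer(draws), 1e-12, 1 - 1e-12)
            extra.reshape(-1)[idx] = float(
                np.mean(-p * np.log(p) - (1 - p) * np.log1p(-p))
            )
        reward = 0.5 * (reward + extra)
    return reward


def signal_uncertainty_reward(
    posterior: TaskPosterior,
    model: TransitionModel,
    class_means: np.ndarray,
    var0: np.ndarray,
) -> np.ndarray:
    """Expected information gain about the task per (state, action) pair.

    Task ``t`` predicts a signal at pair ``(s, a)`` from the class model
    its labelling assigns there; the reward is the Jensen-Shannon-style
    information the signal carries about the task,

        I(s,a) = H( sum_t w_t p_t ) - sum_t w_t H(p_t),

    evaluated with the standard pairwise-Bhattacharyya approximation of
    Gaussian-mixture entropy using the shared pooled variance
    (``I = -sum_t w_t log sum_x w_x exp(-D_B(t,x))``).  Pairs where all
    (posterior-supported) hypotheses predict the same signal distribution
    — including label-swap-symmetric pairs — earn zero reward.

    ``class_means`` is the ``(T, 2, d)`` array from
    :func:`~errpbci.task_inference.task_class_summaries`.
    """
    T = len(posterior.tasks)
    w = posterior.scores
    d = class_means.shape[2]
    # Bhattacharyya distances between all task-class models (shared
    # diagonal covariance): D_B = ||mu_i - mu_j||^2_Sigma / 8
    flat = (class_means / np.sqrt(var0)[None, None, :]).reshape(2 * T, d)
    sq = (flat**2).sum(axis=1)
    D = np.clip((sq[:, None] + sq[None, :] - 2.0 * flat @ flat.T) / 8.0, 0.0, None)
    # model index chosen by each task at each (state, action) pair
    ids = np.empty((model.height, model.width, len(Action), T), dtype=int)
    for j, task in enumerate(posterior.tasks):
        err = error_label_array(task, model)  # 0 correct, 1 error
        ids[..., j] = 2 * j + err
    P = model.height * model.width * len(Action)
    ids_flat = ids.reshape(P, T)
    D_sub = D[ids_flat[:, :, None], ids_flat[:, None, :]]  # (P, T, T)
    mix = np.exp(-D_sub) @ w  # (P, T): sum_x w_x exp(-D(t,x))
    info = -(w[None, :] * np.log(np.clip(mix, 1e-300, None))).sum(axis=1)
    return np.clip(info, 0.0, None).reshape(model.height, model.width, len(Action))


def value_iteration(
    reward: np.ndarray,
    model: TransitionModel,
    cfg: PlannerConfig = PlannerConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the finite MDP with per-(state, action) reward.

    Returns ``(policy, value)`` with ``policy[row, col]`` an ``Action``
    index (greedy, ties broken by the documented action order) and
    ``value`` within ``vi_tolerance`` of the Bellman fixed point.
    """
    H, W, A = model.height, model.width, len(Action)
    if reward.shape != (H, W, A):
        raise ValueError(f"reward must have shape {(H, W, A)}")
    # successor lookup: next_idx[s, a] over flattened states
    n = H * W
    next_idx = np.empty((n, A), dtype=int)
    for s in model.states():
        i = model.state_index(s)
        for a in Action:
            nxt = step(s, a, model)
            next_idx[i, int(a)] = model.state_index(nxt)
    r = reward.reshape(n, A)
    v = np.zeros(n)
    # ||V_k - V*|| <= gamma/(1-gamma) * ||V_k - V_{k-1}||, so this stopping
    # rule guarantees the returned value is within vi_tolerance of the
    # Bellman fixed point.
    stop = cfg.vi_tolerance * (1.0 - cfg.discount) / cfg.discount
    for _ in range(cfg.max_iterations):
        qv = r + cfg.discount * v[next_idx]
        v_new = qv.max(axis=1)
        delta = np.max(np.abs(v_new - v))
        v = v_new
        if delta <= stop:
            break
    else:
        raise RuntimeError("value iteration did not converge within the iteration cap")
    qv = r + cfg.discount * v[next_idx]
    policy = qv.argmax(axis=1)  # argmax returns the first (documented) tie-break
    return policy.reshape(H, W), v.reshape(H, W)


def greedy_action(state: GridState, task: GridTask) -> Action:
    """Deterministic optimal action for a task (documented tie-break)."""
    opts = optimal_actions(state, task)
    for a in ACTION_ORDER:
        if a in opts:
            return a
    raise RuntimeError("optimal action set is never empty")  # pragma: no cover


def select_action(
    state: GridState,
    posterior: TaskPosterior,
    decided: Optional[GridTask],
    model: TransitionModel,
    cfg: PlannerConfig = PlannerConfig(),
    reward: Optional[np.ndarray] = None,
) -> Action:
    """Explore/exploit action choice.

    With a decided task, return its optimal action at ``state``;
    otherwise plan on the uncertainty reward (recomputed from the
    posterior unless supplied) and follow the value-iteration policy.
    """
    state = GridState(*state)
    if decided is not None:
        return greedy_action(state, decided)
    if reward is None:
        reward = uncertainty_reward(posterior, model)
    policy, _ = value_iteration(reward, model, cfg)
    return Action(int(policy[state.row, state.col]))
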