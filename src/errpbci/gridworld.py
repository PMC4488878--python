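"""Discrete grid-world environment for ErrP-based cursor control.

The device moves a cursor on a ``width x height`` grid using five
instantaneous actions (one-step moves plus an explicit goal-reached
action).  Each cell of the grid is one *task hypothesis*: "the user's
intended goal is this cell".  A task induces an optimal policy (move
toward the goal along the shortest Manhattan path, and signal
goal-reached when on it) and therefore a binary label — correct or
erroneous — for every (state, action) pair.  These policy-induced label
maps are the task constraint that makes unsupervised decoder calibration
possible.

Conventions (fixed, documented):

* 0-based ``(row, col)`` coordinates, row 0 at the top; ``UP`` decreases
  the row index.
* Moves that would leave the grid clamp (the state is unchanged) so a
  planner may evaluate all five actions everywhere.
* Label probabilities are hard 0/1: robustness to occasional user
  mis-assessments is the job of the heavy-tailed signal likelihood, not
  of label softening.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np

__all__ = [
    "Action",
    "GridState",
    "GridTask",
    "TransitionModel",
    "step",
    "optimal_actions",
    "label_probability",
    "error_label_array",
]


class Action(enum.IntEnum):
    """The five device actions.  Order is the documented tie-break order."""

    UP = 0
    DOWN = 1
    LEFT = 2
    RIGHT = 3
    GOAL_REACHED = 4


#: (drow, dcol) displacement of each action.
_MOVES: dict[Action, tuple[int, int]] = {
    Action.UP: (-1, 0),
    Action.DOWN: (1, 0),
    Action.LEFT: (0, -1),
    Action.RIGHT: (0, 1),
    Action.GOAL_REACHED: (0, 0),
}

MOVEMENT_ACTIONS = (Action.UP, Action.DOWN, Action.LEFT, Action.RIGHT)


class GridState(NamedTuple):
    """A cell of the grid (0-based row/col, row 0 at the top)."""

    row: int
    col: int


@dataclass(frozen=True)
class GridTask:
    """One goal hypothesis: the user intends to reach ``goal``."""

    goal: GridState

    def __post_init__(self) -> None:
        object.__setattr__(self, "goal", GridState(*self.goal))


@dataclass(frozen=True)
class TransitionModel:
    """Deterministic transition model of a ``width x height`` grid."""

    width: int = 5
    height: int = 5

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be positive")

    @property
    def n_states(self) -> int:
        return self.width * self.height

    def contains(self, state: GridState) -> bool:
        return 0 <= state[0] < self.height and 0 <= state[1] < self.width

    def states(self) -> Iterator[GridState]:
        for r in range(self.height):
            for c in range(self.width):
                yield GridState(r, c)

    def tasks(self) -> list[GridTask]:
        """All ``width*height`` goal hypotheses, row-major order."""
        return [GridTask(s) for s in self.states()]

    def state_index(self, state: GridState) -> int:
        return state[0] * self.width + state[1]


def _validate(state: GridState, model: TransitionModel) -> GridState:
    state = GridState(*state)
    if not model.contains(state):
        raise ValueError(f"state {state} outside {model.height}x{model.width} grid")
    return state


def step(state: GridState, action: Action, model: TransitionModel) -> GridState:
    """Deterministic successor state; off-grid moves clamp.

    ``GOAL_REACHED`` never changes the state.
    """
    state = _validate(state, model)
    dr, dc = _MOVES[Action(action)]
    nxt = GridState(state.row + dr, state.col + dc)
    return nxt if model.contains(nxt) else state


def optimal_actions(state: GridState, task: GridTask) -> frozenset[Action]:
    """Actions the user assesses as correct in ``state`` under ``task``.

    On the goal cell the single correct action is ``GOAL_REACHED``;
    elsewhere every movement action that strictly decreases the
    Manhattan distance to the goal is correct (one or two actions).
    """
    state = GridState(*state)
    goal = task.goal
    if state == goal:
        return frozenset({Action.GOAL_REACHED})
    acts: set[Action] = set()
    if state.row > goal.row:
        acts.add(Action.UP)
    elif state.row < goal.row:
        acts.add(Action.DOWN)
    if state.col > goal.col:
        acts.add(Action.LEFT)
    elif state.col < goal.col:
        acts.add(Action.RIGHT)
    return frozenset(acts)


def label_probability(
    state: GridState, action: Action, task: GridTask
) -> tuple[float, float]:
    """Hard label distribution ``(p_correct, p_error)`` of an action.

    Determined entirely by the task's optimal policy.
    """
    if Action(action) in optimal_actions(state, task):
        return (1.0, 0.0)
    return (0.0, 1.0)


def error_label_array(task: GridTask, model: TransitionModel) -> np.ndarray:
    """Dense label map: ``labels[row, col, action] = 1`` iff erroneous.

    Vectorised lookup table used by the inference engine and the planner.
    """
    labels = np.ones((model.height, model.width, len(Action)), dtype=np.int8)
    for s in model.states():
        for a in optimal_actions(s, task):
            labels[s.row, s.col, int(a)] = 0
    return labels
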