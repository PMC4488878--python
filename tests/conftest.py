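import numpy as np
import pytest

from errpbci.gridworld import Action, GridState, GridTask, TransitionModel


@pytest.fixture
def grid5() -> TransitionModel:
    return TransitionModel(width=5, height=5)


@pytest.fixture
def grid3() -> TransitionModel:
    return TransitionModel(width=3, height=3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_history(model, rng, n_steps, d, signal=None):
    """Random (state, action) visits with signals; returns a History."""
    from errpbci.task_inference import History

    states = list(model.states())
    h = History(d=d)
    for _ in range(n_steps):
        s = states[rng.integers(len(states))]
        a = Action(rng.integers(len(Action)))
        e = rng.standard_normal(d) if signal is None else signal(s, a, rng)
        h.append(s, a, e)
    return h
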