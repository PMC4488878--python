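"""Synthetic ErrP-like signals and a simulated user for closed-loop runs.

The generator instantiates the statistical assumptions the decoder makes:
one multivariate Gaussian per class in feature space, with the error
class carrying a higher mean signal power (squared norm) than the
correct class — the asymmetry that lets the power correction break
label-symmetric ambiguities.  A simulated user assesses every device
action against the optimal policy of the intended goal, with an optional
mis-assessment rate flipping the emitted label.

The reference construction places the correct-class mean at the origin
and the error-class mean at distance ``delta`` along a fixed direction,
with equal identity covariances, where ``delta = 2 * Phi^{-1}(acc)``
yields a target Bayes-optimal single-trial accuracy ``acc`` (default
0.75, the middle of the 60–80 % range typical of single-trial ErrP
decoding).  The implied power ratio is then ``1 + delta^2 / d > 1`` by
construction.

A waveform mode synthesises three-channel epochs whose error condition
carries a biphasic deflection (positive peak near 400 ms, negative near
600 ms), so the raw-epoch feature-extraction path can be exercised end
to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .decoder import CORRECT, ERROR
from .features import FeatureConfig, RawEpoch, extract_features
from .gridworld import Action, GridState, GridTask, label_probability

__all__ = [
    "SignalGeneratorConfig",
    "SimulatedUser",
    "WaveformGeneratorConfig",
    "sample_signal",
    "assess",
    "separability_to_accuracy",
    "sample_waveform_epoch",
    "generate_labeled_dataset",
]


@dataclass
class SignalGeneratorConfig:
    """Two-class Gaussian feature generator.

    ``assessment_error_rate`` is the probability that the simulated
    user's assessment (and hence the emitted signal class) is flipped;
    it must stay below 0.5.
    """

    d: int = 57
    mu_c: np.ndarray = None
    mu_w: np.ndarray = None
    cov_c: np.ndarray = None
    cov_w: np.ndarray = None
    assessment_error_rate: float = 0.05
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mu_c is None:
            self.mu_c = np.zeros(self.d)
        if self.mu_w is None:
            # default separation targets 0.75 Bayes accuracy
            delta = 2.0 * stats.norm.ppf(0.75)
            self.mu_w = np.full(self.d, delta / np.sqrt(self.d))
        if self.cov_c is None:
            self.cov_c = np.eye(self.d)
        if self.cov_w is None:
            self.cov_w = np.eye(self.d)
        self.mu_c = np.asarray(self.mu_c, dtype=float).ravel()
        self.mu_w = np.asarray(self.mu_w, dtype=float).ravel()
        self.cov_c = np.atleast_2d(np.asarray(self.cov_c, dtype=float))
        self.cov_w = np.atleast_2d(np.asarray(self.cov_w, dtype=float))
        if not (self.mu_c.size == self.mu_w.size == self.d):
            raise ValueError("class means must have length d")
        if not 0.0 <= self.assessment_error_rate < 0.5:
            raise ValueError("assessment_error_rate must be in [0, 0.5)")
        if self.power_gap <= 1.0:
            raise ValueError(
                "the error class must have higher expected power than the "
                "correct class (power_gap > 1)"
            )
        self._chol_c = np.linalg.cholesky(self.cov_c)
        self._chol_w = np.linalg.cholesky(self.cov_w)

    @classmethod
    def from_accuracy(
        cls,
        accuracy: float = 0.75,
        d: int = 57,
        assessment_error_rate: float = 0.05,
        seed: Optional[int] = None,
    ) -> "SignalGeneratorConfig":
        """Generator at a target Bayes-optimal single-trial accuracy.

        Equal identity covariances; the error mean sits at Mahalanobis
        distance ``2 * Phi^{-1}(accuracy)`` from the origin along the
        uniform direction, so the implied power gap is ``1 + delta^2/d``.
        """
        if not 0.5 < accuracy < 1.0:
            raise ValueError("accuracy must be in (0.5, 1)")
        delta = 2.0 * stats.norm.ppf(accuracy)
        mu_w = np.full(d, delta / np.sqrt(d))
        return cls(
            d=d,
            mu_c=np.zeros(d),
            mu_w=mu_w,
            cov_c=np.eye(d),
            cov_w=np.eye(d),
            assessment_error_rate=assessment_error_rate,
            seed=seed,
        )

    @property
    def power_gap(self) -> float:
        """Expected-power ratio E[e'e | error] / E[e'e | correct]."""
        e_c = float(self.mu_c @ self.mu_c + np.trace(self.cov_c))
        e_w = float(self.mu_w @ self.mu_w + np.trace(self.cov_w))
        return e_w / e_c


def sample_signal(
    label: int, cfg: SignalGeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw one feature vector from the class Gaussian."""
    if label == CORRECT:
        mu, chol = cfg.mu_c, cfg._chol_c
    elif label == ERROR:
        mu, chol = cfg.mu_w, cfg._chol_w
    else:
        raise ValueError(f"unknown label {label!r}")
    return mu + chol @ rng.standard_normal(cfg.d)


@dataclass
class SimulatedUser:
    """A user with a fixed intended goal and a signal generator.

    The intended task stays fixed until the device reaches a target (the
    protocol's assumption; mid-reach goal switching is out of scope).
    """

    intended_task: GridTask
    generator: SignalGeneratorConfig


def assess(
    user: SimulatedUser,
    state: GridState,
    action: Action,
    rng: np.random.Generator,
) -> tuple[int, np.ndarray]:
    """Simulated assessment of a device action.

    The policy-true label comes from the intended task's optimal policy;
    with probability ``assessment_error_rate`` the user mis-assesses and
    the emitted label flips.  The signal is drawn from the *emitted*
    label's class.  Returns ``(emitted_label, features)``.
    """
    p_correct, _ = label_probability(state, action, user.intended_task)
    label = CORRECT if p_correct == 1.0 else ERROR
    if user.generator.assessment_error_rate > 0 and (
        rng.random() < user.generator.assessment_error_rate
    ):
        label = ERROR if label == CORRECT else CORRECT
    return label, sample_signal(label, user.generator, rng)


def separability_to_accuracy(
    cfg: SignalGeneratorConfig,
    n_samples: int = 20_000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Monte-Carlo Bayes-optimal single-trial accuracy of the generator.

    Draws balanced samples and classifies with the true class densities
    (the likelihood-ratio rule), so the estimate upper-bounds what any
    decoder can reach on this generator.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    half = n_samples // 2
    correct = 0
    rv_c = stats.multivariate_normal(cfg.mu_c, cfg.cov_c)
    rv_w = stats.multivariate_normal(cfg.mu_w, cfg.cov_w)
    for label, rv_true, rv_other in ((CORRECT, rv_c, rv_w), (ERROR, rv_w, rv_c)):
        X = rv_true.rvs(size=half, random_state=rng).reshape(half, cfg.d)
        correct += int(np.sum(rv_true.logpdf(X) >= rv_other.logpdf(X)))
    return correct / (2 * half)


def generate_labeled_dataset(
    n_per_class: int,
    cfg: SignalGeneratorConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced labelled feature set (supervised baselines, calibration curves)."""
    rng = rng or np.random.default_rng(cfg.seed)
    X = np.empty((2 * n_per_class, cfg.d))
    y = np.empty(2 * n_per_class, dtype=int)
    order = rng.permutation(2 * n_per_class)
    labels = np.repeat([CORRECT, ERROR], n_per_class)[order]
    for i, lab in enumerate(labels):
        X[i] = sample_signal(int(lab), cfg, rng)
        y[i] = lab
    return X, y


# ---------------------------------------------------------------------------
# waveform mode


@dataclass(frozen=True)
class WaveformGeneratorConfig:
    """Three-channel epoch synthesiser for the raw-feature path.

    Error epochs add a biphasic difference wave (positive Gaussian bump
    near 400 ms, negative near 600 ms) on top of white noise; correct
    epochs are noise only.  Epochs span [-200, 1000] ms around the onset
    at the configured sampling rate.
    """

    sampling_rate: float = 256.0
    channels: tuple[str, ...] = ("Fz", "FCz", "Cz")
    noise_sd: float = 1.0
    peak_amplitude: float = 2.0
    pre_ms: float = 200.0
    post_ms: float = 1000.0


def sample_waveform_epoch(
    label: int, cfg: WaveformGeneratorConfig, rng: np.random.Generator
) -> RawEpoch:
    fs = cfg.sampling_rate
    n_pre = int(round(cfg.pre_ms / 1000.0 * fs))
    n_post = int(round(cfg.post_ms / 1000.0 * fs))
    n = n_pre + n_post
    t_ms = (np.arange(n) - n_pre) / fs * 1000.0
    data = cfg.noise_sd * rng.standard_normal((len(cfg.channels), n))
    if label == ERROR:
        bump = cfg.peak_amplitude * (
            np.exp(-0.5 * ((t_ms - 400.0) / 50.0) ** 2)
            - np.exp(-0.5 * ((t_ms - 600.0) / 50.0) ** 2)
        )
        data += bump[None, :]
    elif label != CORRECT:
        raise ValueError(f"unknown label {label!r}")
    return RawEpoch(data, fs, t0_index=n_pre, channel_names=cfg.channels)


def waveform_features(
    label: int,
    wcfg: WaveformGeneratorConfig,
    fcfg: FeatureConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Convenience: synthesise an epoch and run the feature pipeline."""
    return extract_features(sample_waveform_epoch(label, wcfg, rng), fcfg)
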