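"""Goal inference from unlabeled (or labeled) ErrP signals.

Two regimes are implemented.

**Calibrated filter.**  With a trained decoder, the task posterior is a
recursive Bayes filter: after executing action ``a`` in state ``s`` and
observing signal ``e``, each goal hypothesis ``t`` is reweighted by the
class density of ``e`` under the label that ``t``'s optimal policy
assigns to ``(s, a)``.

**Self-calibration pseudo-likelihood.**  Without calibration the decoder
itself is unknown.  For each goal hypothesis the history of triplets
``(s_i, a_i, e_i)`` is labelled by that hypothesis's optimal policy, and
the hypothesis is scored by a leave-one-out product: each signal's
Jeffreys-predictive density under the class models fitted on all *other*
signals (with the hypothesis's labels).  Marginalising the Gaussian
parameters under the Jeffreys prior yields heavy-tailed Student-t
predictives, keeping the score robust to user mis-assessments.

Label-symmetric hypotheses (two goals whose policies assign exactly
opposite labels to every visited pair) tie under the pseudo-likelihood.
The tie is broken by the *power ratio*: error-class EEG responses carry
higher average power, so each hypothesis's score is multiplied by the
ratio of the responsibility-weighted mean signal power of its error
class over its correct class.

A decision is made when the confidence ``W^t`` — the minimum pairwise
normalised likelihood of ``t`` against every rival — exceeds a threshold
``beta`` in (0.5, 1]; at most one hypothesis can exceed any such
threshold.

Implementation note: the leave-one-out product is evaluated exactly but
in closed form, using rank-one downdates of each class's scatter matrix
(Sherman–Morrison for the Mahalanobis term and a determinant-lemma update
for the log determinant), so a step costs two Cholesky factorisations
per hypothesis instead of ``M`` refits.  A naive refit path is kept as an
internal cross-check and agrees to round-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.linalg import solve_triangular
from scipy.special import gammaln, logsumexp

from . import decoder as dec
from .gridworld import (
    Action,
    GridState,
    GridTask,
    TransitionModel,
    error_label_array,
    label_probability,
)

__all__ = [
    "HistoryTriplet",
    "History",
    "LabeledSignals",
    "InferenceConfig",
    "TaskPosterior",
    "uniform_posterior",
    "task_class_summaries",
    "calibrated_update",
    "pseudo_loglikelihood",
    "power_ratio",
    "corrected_posterior",
    "confidence",
    "decide",
]

CORRECT, ERROR = dec.CORRECT, dec.ERROR


@dataclass(frozen=True)
class HistoryTriplet:
    """One step of operation: where the device was, what it did, what the
    user's brain said about it."""

    state: GridState
    action: Action
    features: np.ndarray
    index: int


class History:
    """Ordered (state, action, features) triplets of the current target."""

    def __init__(self, d: Optional[int] = None):
        self._states: list[GridState] = []
        self._actions: list[int] = []
        self._features: list[np.ndarray] = []
        self._d = d

    def append(self, state: GridState, action: Action, features: np.ndarray) -> None:
        features = np.asarray(features, dtype=float).ravel()
        if self._d is None:
            self._d = features.size
        elif features.size != self._d:
            raise ValueError("inconsistent feature dimensionality")
        self._states.append(GridState(*state))
        self._actions.append(int(action))
        self._features.append(features)

    def __len__(self) -> int:
        return len(self._states)

    @property
    def d(self) -> int:
        if self._d is None:
            raise ValueError("empty history has no dimensionality")
        return self._d

    def triplets(self) -> list[HistoryTriplet]:
        return [
            HistoryTriplet(s, Action(a), f, i + 1)
            for i, (s, a, f) in enumerate(
                zip(self._states, self._actions, self._features)
            )
        ]

    def feature_matrix(self) -> np.ndarray:
        return np.array(self._features, dtype=float).reshape(len(self), -1)

    def state_action_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        rows = np.array([s.row for s in self._states], dtype=int)
        cols = np.array([s.col for s in self._states], dtype=int)
        acts = np.array(self._actions, dtype=int)
        return rows, cols, acts

    @classmethod
    def from_triplets(cls, triplets: Sequence[HistoryTriplet]) -> "History":
        h = cls()
        for t in triplets:
            h.append(t.state, t.action, t.features)
        return h

    def clear(self) -> None:
        self._states.clear()
        self._actions.clear()
        self._features.clear()


class LabeledSignals:
    """Signals with fixed labels (prior transfer between targets).

    Once a target has been identified and reached, its history is labelled
    by the identified goal's optimal policy and kept as supervised data
    for all subsequent targets; the labels are never revised.
    """

    def __init__(self, features: Optional[np.ndarray] = None, labels: Optional[np.ndarray] = None):
        if features is None:
            self.features = np.zeros((0, 0))
            self.labels = np.zeros(0, dtype=int)
        else:
            self.features = np.atleast_2d(np.asarray(features, dtype=float))
            self.labels = np.asarray(labels, dtype=int).ravel()
            if self.labels.shape[0] != self.features.shape[0]:
                raise ValueError("one label per signal required")

    def __len__(self) -> int:
        return self.features.shape[0]

    def extend(self, features: np.ndarray, labels: np.ndarray) -> None:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        labels = np.asarray(labels, dtype=int).ravel()
        if len(self) == 0:
            self.features, self.labels = features, labels
        else:
            self.features = np.vstack([self.features, features])
            self.labels = np.concatenate([self.labels, labels])

    def class_stats(self, d: int) -> list[tuple[float, np.ndarray, np.ndarray]]:
        """Per-class (n, sum, raw second moment) with zero defaults."""
        out = []
        for k in (CORRECT, ERROR):
            if len(self) and self.features.shape[1] == d:
                Xk = self.features[self.labels == k]
            else:
                Xk = np.zeros((0, d))
            out.append((float(Xk.shape[0]), Xk.sum(axis=0), Xk.T @ Xk))
        return out


@dataclass(frozen=True)
class InferenceConfig:
    """Self-calibration inference options.

    ``shrinkage_lambda`` regularises the Gaussian responsibility models of
    the power ratio.  ``confidence_uses_power`` selects whether the
    decision confidence is computed from the power-corrected scores.

    ``confidence_method`` selects the likelihood behind the decision
    confidence ``W^t``:

    * ``"prequential"`` (default) — each signal is scored under the class
      model fitted on the signals that came *before* it (plus any
      prior-labelled data).  No score is ever revised, so a rival
      labelling cannot inflate its evidence by re-fitting class means
      around past noise; under the true hypothesis a rival's gap is a
      supermartingale and the probability that it ever falsely exceeds
      ``log(beta/(1-beta))`` is bounded.  This is the statistic safe to
      threshold sequentially.
    * ``"loo"`` — ``W^t`` from the leave-one-out scores themselves.  The
      leave-one-out product re-fits every class model each step, which
      makes it the best *estimator* of the labelling (it backs the
      posterior and the planner) but lets the best-fitting wrong
      partition carry transient multi-nat noise leads in high dimension.
    * ``"plugin"`` — a single decoder fitted with the leading
      hypothesis's labels scores all hypotheses.
    * ``"combined"`` — the elementwise minimum of the prequential and
      leave-one-out confidences: the device commits only when the
      accumulated (never-revised) evidence and its cross-validated
      re-evaluation agree that the leader dominates every rival.

    ``anchor_pseudo_count`` (nu0) and ``mean_pseudo_count`` (kappa0) set
    the empirical-Bayes anchor of the predictive at the pooled statistics
    of all available signals: an (inverse-Wishart, diagonal) scale prior
    worth ``nu0`` pseudo-observations of the pooled per-dimension
    variance, and a conjugate mean prior worth ``kappa0`` pseudo-signals
    at the pooled mean.  The pure Jeffreys predictive is undefined for
    class counts n <= d, its scale estimate is extremely noisy near
    n = d, and in high dimension a flat mean prior lets tiny classes
    chase chance clusterings, producing spurious multi-nat evidence.
    Anchored at the pooled statistics — nuisances shared by both classes
    — a nearly empty class predicts like the pooled model, so rival goal
    hypotheses tie until genuine class structure accumulates.  The
    default ``kappa0`` corresponds to a prior scale of about a tenth of a
    pooled standard deviation for per-dimension class-mean offsets —
    deliberately conservative relative to the offsets a typical
    single-trial decoder implies, because a premature confident
    commitment costs far more operation time than the extra signals the
    anchor demands.  In anchored mode the predictive's scale is the
    pooled per-dimension variance itself (``nu0`` only parameterises the
    non-default conjugate paths); ``nu0 = kappa0 = 0`` recovers the pure
    Jeffreys rules.
    """

    shrinkage_lambda: float = 0.5
    power_correction: bool = True
    confidence_uses_power: bool = True
    confidence_method: str = "prequential"
    anchor_pseudo_count: float = 8.0
    mean_pseudo_count: float = 192.0

    def __post_init__(self) -> None:
        if self.confidence_method not in ("prequential", "loo", "plugin", "combined"):
            raise ValueError("unknown confidence_method")


@dataclass
class TaskPosterior:
    """Normalised per-task scores with diagnostics.

    ``log_pseudolik`` is the raw leave-one-out log pseudo-likelihood,
    ``log_corrected`` includes the log power ratio, ``scores`` is the
    normalised posterior (uniform task prior) and ``confidence`` holds
    ``W^t`` per task.
    """

    tasks: list[GridTask]
    log_pseudolik: np.ndarray
    log_corrected: np.ndarray
    scores: np.ndarray
    confidence: np.ndarray

    def __post_init__(self) -> None:
        T = len(self.tasks)
        for name in ("log_pseudolik", "log_corrected", "scores", "confidence"):
            arr = np.asarray(getattr(self, name), dtype=float).ravel()
            if arr.shape[0] != T:
                raise ValueError(f"{name} must have one entry per task")
            setattr(self, name, arr)

    def map_task(self) -> GridTask:
        return self.tasks[int(np.argmax(self.log_corrected))]


def uniform_posterior(tasks: Sequence[GridTask]) -> TaskPosterior:
    T = len(tasks)
    zeros = np.zeros(T)
    return TaskPosterior(
        tasks=list(tasks),
        log_pseudolik=zeros.copy(),
        log_corrected=zeros.copy(),
        scores=np.full(T, 1.0 / T),
        confidence=np.full(T, 0.5) if T > 1 else np.ones(T),
    )


# ---------------------------------------------------------------------------
# label maps


def _task_labels(history: History, task: GridTask, model: Optional[TransitionModel] = None) -> np.ndarray:
    """Hard labels the task's optimal policy assigns to each history step."""
    if model is None:
        rows, cols, _ = history.state_action_arrays()
        h = int(max(rows.max(initial=0), task.goal.row)) + 1
        w = int(max(cols.max(initial=0), task.goal.col)) + 1
        model = TransitionModel(width=w, height=h)
    lut = error_label_array(task, model)
    rows, cols, acts = history.state_action_arrays()
    return lut[rows, cols, acts].astype(int)


# ---------------------------------------------------------------------------
# exact closed-form leave-one-out predictive terms
#
# Two regimes, dispatched per task hypothesis.
#
# Cold start (either class too small for a scatter estimate): each signal
# is scored by a heavy-tailed Student t with *fixed* degrees of freedom
# and the *shared* pooled per-dimension scale, centred on the class mean
# anchored by ``kappa0`` pseudo-signals at the pooled mean m0.  Because
# the dof and scale are identical for every class and labelling, the
# normalisation cancels exactly between rival hypotheses and the
# evidence flows only through the class-mean residuals; without this,
# the predictive's class-size-dependent dof/scale factors bias the
# pseudo-likelihood by several nats toward particular labelling balances
# in high dimension — far more than the per-signal evidence itself.
#
# Estimated regime (both classes hold at least d + 2 real signals): the
# exact conjugate multivariate-t predictive with the class mean anchored
# as above and the scatter anchored by an inverse-Wishart prior worth
# ``nu0`` pseudo-observations of the pooled variance,
#
#   t_df( x | mean_a,  (Psi0 + S_a) (n_a+1) / (n_a df) ),  df = nu0 + n - d
#
# where ``_a`` marks kappa0-augmented statistics (n_a = n + kappa0) and n
# counts real class members: mean pseudo-signals tighten the location
# but add no scale degrees of freedom, as in conjugate
# normal-inverse-Wishart updating.  With nu0 = kappa0 = 0 the original
# Jeffreys rules (full -> diagonal -> pooled fallbacks) apply instead.
# nu0 = kappa0 = 0 recovers the pure Jeffreys predictive of the decoder
# module.  The anchor is constant across the leave-one-out sweep, so
# removing one real point stays a rank-one downdate of the scatter and
# the whole sweep costs a single Cholesky factorisation per class.

_VAR_FLOOR = 1e-30

#: fixed dof of the cold-start predictive: heavy tails for robustness to
#: mis-assessed signals, identical across classes so that the
#: normalisation cancels between rival labelings.
_EARLY_DF = 10.0


def _early_logdens(
    Xk: np.ndarray,
    s1_real: np.ndarray,
    n_real: float,
    kappa0: float,
    m0: np.ndarray,
    var0: np.ndarray,
) -> np.ndarray:
    """Cold-start scoring of each row of ``Xk`` against its own class.

    ``s1_real``/``n_real`` are the real-member statistics of the class
    including the evaluated rows; the leave-one-out anchored mean is
    ``(s1 - x + kappa0 m0) / (n - 1 + kappa0)``.
    """
    denom = n_real - 1.0 + kappa0
    if denom > 0:
        mean_loo = (s1_real[None, :] - Xk + kappa0 * m0[None, :]) / denom
    else:  # a memberless class without a mean anchor scores against m0
        mean_loo = np.broadcast_to(m0, Xk.shape)
    z2 = (Xk - mean_loo) ** 2 / var0[None, :]
    df = _EARLY_DF
    per_dim = (
        gammaln((df + 1.0) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * math.log(df * math.pi)
        - 0.5 * np.log(var0[None, :])
        - 0.5 * (df + 1.0) * np.log1p(z2 / df)
    )
    return per_dim.sum(axis=1)


def _student_t_terms(z2: np.ndarray, log_scale2_sum: np.ndarray, df: float, d: int) -> np.ndarray:
    """Multivariate/diagonal Student-t log density from quadratic forms.

    ``z2`` is the Mahalanobis form w.r.t. the scale matrix and
    ``log_scale2_sum`` its log determinant.
    """
    return (
        gammaln((df + d) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * d * math.log(df * math.pi)
        - 0.5 * log_scale2_sum
        - 0.5 * (df + d) * np.log1p(z2 / df)
    )


def _diag_loo_logdens(
    Xk: np.ndarray,
    n: float,
    s1: np.ndarray,
    s2_diag: np.ndarray,
    nu0: float,
    var0: np.ndarray,
    kappa0: float = 0.0,
) -> np.ndarray:
    """Per-dimension anchored predictives after removing each row of ``Xk``.

    ``n, s1, s2_diag`` describe the full *augmented* class (kappa0
    pseudo-signals included) with each row of ``Xk`` still present; the
    degrees of freedom count only real members.
    """
    n_loo = n - 1.0
    df = nu0 + (n_loo - kappa0) - 1.0
    if df <= 0 or n_loo < 1:
        raise ValueError("too few class members for the diagonal predictive")
    mean = s1 / n
    U = Xk - mean
    c = n / (n - 1.0)
    a = np.clip(s2_diag - s1 * s1 / n, 0.0, None)  # per-dim scatter
    a_loo = np.clip(a[None, :] - c * U**2, 0.0, None)
    resid = c * U  # x_i minus the leave-one-out mean
    scale2 = np.clip(
        (nu0 * var0[None, :] + a_loo) * (n_loo + 1.0) / (n_loo * df), _VAR_FLOOR, None
    )
    z2 = resid**2 / scale2
    per_dim = (
        gammaln((df + 1.0) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * math.log(df * math.pi)
        - 0.5 * np.log(scale2)
        - 0.5 * (df + 1.0) * np.log1p(z2 / df)
    )
    return per_dim.sum(axis=1)


def _full_loo_logdens(
    Xk: np.ndarray,
    n: float,
    s1: np.ndarray,
    s2: np.ndarray,
    nu0: float,
    var0: np.ndarray,
    kappa0: float = 0.0,
) -> Optional[np.ndarray]:
    """Closed-form LOO multivariate-t log densities for all class members.

    Returns ``None`` when the full-covariance path is unavailable
    (singular anchored scatter); the caller falls back to the diagonal
    restriction.  Degrees of freedom count only real members.
    """
    d = Xk.shape[1]
    n_loo = n - 1.0
    df = nu0 + (n_loo - kappa0) - d
    if df < 2 or n_loo - kappa0 < d + 2:
        return None
    A = s2 - np.outer(s1, s1) / n
    B = A + nu0 * np.diag(var0)  # anchored scatter
    try:
        L = np.linalg.cholesky(B)
    except np.linalg.LinAlgError:
        return None
    mean = s1 / n
    U = Xk - mean
    c = n / (n - 1.0)
    Z = solve_triangular(L, U.T, lower=True)
    q_full = (Z**2).sum(axis=0)
    cq = np.clip(c * q_full, None, 1.0 - 1e-12)
    logdet_B = 2.0 * np.log(np.diag(L)).sum()
    logdet_loo = logdet_B + np.log1p(-cq)
    q_loo = c * cq / (1.0 - cq)  # Sherman-Morrison Mahalanobis downdate
    f = (n_loo + 1.0) / (n_loo * df)  # scale = (B - c u u') * f
    return _student_t_terms(q_loo / f, logdet_loo + d * math.log(f), df, d)


def _pooled_diag_stats(
    X: np.ndarray, prior_stats: list[tuple[float, np.ndarray, np.ndarray]]
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Pooled (label-free) count, sum, per-dim second moment and variance."""
    n_pool = X.shape[0] + prior_stats[0][0] + prior_stats[1][0]
    s1_pool = X.sum(axis=0) + prior_stats[0][1] + prior_stats[1][1]
    s2d_pool = (
        (X**2).sum(axis=0) + np.diag(prior_stats[0][2]) + np.diag(prior_stats[1][2])
    )
    if n_pool > 1:
        var0 = np.clip(
            (s2d_pool - s1_pool**2 / n_pool) / (n_pool - 1.0), _VAR_FLOOR, None
        )
    else:  # pragma: no cover - excluded by the M >= 2 precondition
        var0 = np.ones(X.shape[1])
    return n_pool, s1_pool, s2d_pool, var0


def _pseudo_terms(
    X: np.ndarray,
    labels: np.ndarray,
    prior_stats: list[tuple[float, np.ndarray, np.ndarray]],
    nu0: float = 0.0,
    kappa0: float = 0.0,
) -> np.ndarray:
    """Per-signal LOO predictive log densities for one task hypothesis."""
    M, d = X.shape
    out = np.empty(M)
    n_pool, s1_pool, s2d_pool, var0 = _pooled_diag_stats(X, prior_stats)
    m0 = s1_pool / n_pool

    anchored = nu0 > 0 or kappa0 > 0

    for k in (CORRECT, ERROR):
        idx = np.flatnonzero(labels == k)
        if idx.size == 0:
            continue
        Xk = X[idx]
        n0, s1_0, s2_0 = prior_stats[k]
        n_k = n0 + idx.size  # real members
        if anchored:
            # shared-scale scoring throughout: class sizes differ between
            # rival labelings, and any class-size-dependent normalisation
            # (the t's dof, scale factors, log-determinants) would make
            # scores incomparable across hypotheses.
            s1_real = s1_0 + Xk.sum(axis=0)
            out[idx] = _early_logdens(Xk, s1_real, n_k, kappa0, m0, var0)
            continue
        # augment the class with kappa0 pseudo-signals at the pooled mean
        n = n_k + kappa0
        s1 = s1_0 + Xk.sum(axis=0) + kappa0 * m0
        n_loo = n - 1
        n_real_loo = n_loo - kappa0
        if n_real_loo >= d + 2 and nu0 + n_real_loo - d >= 2:
            s2 = s2_0 + Xk.T @ Xk + kappa0 * np.outer(m0, m0)
            vals = _full_loo_logdens(Xk, n, s1, s2, nu0, var0, kappa0)
            if vals is None:
                s2diag = np.diag(s2_0) + (Xk**2).sum(axis=0) + kappa0 * m0**2
                vals = _diag_loo_logdens(Xk, n, s1, s2diag, nu0, var0, kappa0)
            out[idx] = vals
        elif nu0 + n_real_loo - 1 > 0 and n_loo >= 1:
            s2diag = np.diag(s2_0) + (Xk**2).sum(axis=0) + kappa0 * m0**2
            out[idx] = _diag_loo_logdens(Xk, n, s1, s2diag, nu0, var0, kappa0)
        elif nu0 + (n_pool - 1) - 1 > 0 and n_pool - 1 >= (1 if nu0 > 0 else 2):
            # cold start: the class carries no usable signals of its own,
            # so the predictive pools all available data (task-independent)
            out[idx] = _diag_loo_logdens(Xk, n_pool, s1_pool, s2d_pool, nu0, var0)
        else:
            # degenerate start (a single other signal, no anchor): unit
            # variance at the remaining pooled mean; task-independent.
            mean_loo = (s1_pool[None, :] - Xk) / (n_pool - 1.0)
            r = Xk - mean_loo
            out[idx] = -0.5 * d * math.log(2.0 * math.pi) - 0.5 * (r**2).sum(axis=1)
    return out


def _prequential_loglikelihood(
    X: np.ndarray,
    labels: np.ndarray,
    prior_stats: list[tuple[float, np.ndarray, np.ndarray]],
    config: InferenceConfig,
) -> float:
    """Prequential (predict-then-observe) log likelihood of one labelling.

    Signal ``i`` is scored under the cold-start predictive (fixed-dof t,
    shared pooled scale, anchored mean) of its class fitted on signals
    ``1..i-1`` plus prior-labelled data; terms are never revised.  The
    pooled mean/scale are taken from all current data — they are shared
    by every hypothesis, so they cancel from the pairwise confidences
    this statistic feeds.
    """
    M, d = X.shape
    kappa0 = config.mean_pseudo_count
    _, s1_pool, _, var0 = _pooled_diag_stats(X, prior_stats)
    n_pool = M + prior_stats[0][0] + prior_stats[1][0]
    m0 = s1_pool / n_pool
    total = 0.0
    log_var_term = 0.5 * np.log(var0).sum()
    const = d * (
        gammaln((_EARLY_DF + 1.0) / 2.0)
        - gammaln(_EARLY_DF / 2.0)
        - 0.5 * math.log(_EARLY_DF * math.pi)
    )
    # running real-member stats per class, seeded with the prior signals
    n_k = [prior_stats[0][0], prior_stats[1][0]]
    s1_k = [prior_stats[0][1].copy(), prior_stats[1][1].copy()]
    for i in range(M):
        k = int(labels[i])
        denom = n_k[k] + kappa0
        mean = (s1_k[k] + kappa0 * m0) / denom if denom > 0 else m0
        z2 = (X[i] - mean) ** 2 / var0
        total += (
            const
            - log_var_term
            - 0.5 * (_EARLY_DF + 1.0) * np.log1p(z2 / _EARLY_DF).sum()
        )
        n_k[k] += 1.0
        s1_k[k] = s1_k[k] + X[i]
    return float(total)


def _naive_pseudo_loglikelihood(
    X: np.ndarray,
    labels: np.ndarray,
    prior: LabeledSignals,
    nu0: float,
    kappa0: float = 0.0,
) -> float:
    """Reference path: explicit refit and density per left-out signal."""
    M, d = X.shape
    pool_rows = [X] + ([prior.features] if len(prior) else [])
    pool_all = np.vstack(pool_rows)
    var0 = (
        pool_all.var(axis=0, ddof=1) if pool_all.shape[0] > 1 else np.ones(d)
    )
    var0 = np.clip(var0, _VAR_FLOOR, None)
    m0 = pool_all.mean(axis=0)

    def anchored_logpdf(
        x: np.ndarray, members: np.ndarray, kap: float, diag_only: bool = False
    ) -> float:
        # kap pseudo-signals at the pooled mean augment the members
        n_real = members.shape[0]
        n = n_real + kap
        mean = (members.sum(axis=0) + kap * m0) / n
        scatter_full = (
            members.T @ members + kap * np.outer(m0, m0) - n * np.outer(mean, mean)
        )
        df_full = nu0 + n_real - d
        if not diag_only and n_real >= d + 2 and df_full >= 2:
            B = scatter_full + nu0 * np.diag(var0)
            shape = B * (n + 1.0) / (n * df_full)
            try:
                return float(
                    stats.multivariate_t.logpdf(x, loc=mean, shape=shape, df=df_full)
                )
            except np.linalg.LinAlgError:
                pass
        df = nu0 + n_real - 1.0
        if df <= 0 or n < 1:
            raise ValueError("too few members")
        a = np.clip(np.diag(scatter_full), 0.0, None)
        scale2 = np.clip((nu0 * var0 + a) * (n + 1.0) / (n * df), _VAR_FLOOR, None)
        return float(
            stats.t.logpdf(x, df=df, loc=mean, scale=np.sqrt(scale2)).sum()
        )

    anchored = nu0 > 0 or kappa0 > 0
    total = 0.0
    for i in range(M):
        k = labels[i]
        keep = np.ones(M, dtype=bool)
        keep[i] = False
        rows = [X[keep & (labels == k)]]
        if len(prior):
            rows.append(prior.features[prior.labels == k])
        Xk = (
            np.vstack([r for r in rows if r.size])
            if any(r.size for r in rows)
            else np.zeros((0, d))
        )
        if anchored:
            # fixed-dof t, shared pooled scale, anchored mean
            if Xk.shape[0] + kappa0 > 0:
                mean = (Xk.sum(axis=0) + kappa0 * m0) / (Xk.shape[0] + kappa0)
            else:
                mean = m0
            total += float(
                stats.t.logpdf(
                    X[i], df=_EARLY_DF, loc=mean, scale=np.sqrt(var0)
                ).sum()
            )
            continue
        n_k = Xk.shape[0] + kappa0
        if n_k >= 1 and nu0 + Xk.shape[0] - 1 > 0:
            total += anchored_logpdf(X[i], Xk, kappa0)
        else:
            pool = np.vstack([X[keep]] + ([prior.features] if len(prior) else []))
            if pool.shape[0] >= (1 if nu0 > 0 else 2) and nu0 + pool.shape[0] - 1 > 0:
                total += anchored_logpdf(X[i], pool, 0.0, diag_only=True)
            else:
                r = X[i] - pool.mean(axis=0)
                total += -0.5 * d * math.log(2.0 * math.pi) - 0.5 * float(r @ r)
    return total


def pseudo_loglikelihood(
    history: History,
    task: GridTask,
    prior: Optional[LabeledSignals] = None,
    model: Optional[TransitionModel] = None,
    config: InferenceConfig = InferenceConfig(),
) -> float:
    """Leave-one-out log pseudo-likelihood of one goal hypothesis.

    Sum over history signals of the log predictive density of each signal
    under the class model (of the label the hypothesis assigns to its
    state-action pair) fitted on all other signals plus any
    prior-labelled data.  Order-invariant by construction.
    """
    M = len(history)
    if M < 2:
        raise ValueError("pseudo-likelihood needs a history of at least 2 triplets")
    prior = prior or LabeledSignals()
    X = history.feature_matrix()
    labels = _task_labels(history, task, model)
    return float(
        _pseudo_terms(
            X,
            labels,
            prior.class_stats(X.shape[1]),
            config.anchor_pseudo_count,
            config.mean_pseudo_count,
        ).sum()
    )


def task_class_summaries(
    history: History,
    tasks: Sequence[GridTask],
    prior: Optional[LabeledSignals] = None,
    model: Optional[TransitionModel] = None,
    config: InferenceConfig = InferenceConfig(),
    kappa: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Anchored class means per task hypothesis, plus the pooled variance.

    Returns ``(means, var0)`` with ``means[j, k]`` the anchored mean of
    class ``k`` under task ``j`` (the pooled mean when the class holds no
    signals) and ``var0`` the pooled per-dimension variance.  These
    summarise each hypothesis's current signal model for the planner's
    signal-space uncertainty reward.

    ``kappa`` overrides the mean-anchor strength; the planner passes a
    small value so that the estimated class separations — which only rank
    candidate pairs and never enter a likelihood — are not flattened by
    the conservative scoring anchor.
    """
    tasks = list(tasks)
    X = history.feature_matrix()
    prior = prior or LabeledSignals()
    d = X.shape[1] if len(history) else (prior.features.shape[1] if len(prior) else 0)
    prior_stats = prior.class_stats(d)
    n_pool, s1_pool, _, var0 = _pooled_diag_stats(X.reshape(-1, d), prior_stats)
    m0 = s1_pool / n_pool if n_pool > 0 else np.zeros(d)
    kappa0 = config.mean_pseudo_count if kappa is None else kappa
    means = np.empty((len(tasks), 2, d))
    for j, task in enumerate(tasks):
        labels = _task_labels(history, task, model) if len(history) else np.zeros(0, int)
        for k in (CORRECT, ERROR):
            n0, s1_0, _ = prior_stats[k]
            Xk = X[labels == k] if len(history) else np.zeros((0, d))
            n = n0 + Xk.shape[0] + kappa0
            if n <= 0:
                means[j, k] = m0
            else:
                means[j, k] = (s1_0 + Xk.sum(axis=0) + kappa0 * m0) / n
    return means, var0


# ---------------------------------------------------------------------------
# power correction


def _batch_gaussian_logdens(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(cov)
    Z = solve_triangular(L, (X - mean).T, lower=True)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    d = X.shape[1]
    return -0.5 * (d * math.log(2.0 * math.pi) + logdet + (Z**2).sum(axis=0))


def _responsibilities(
    X: np.ndarray,
    labels: np.ndarray,
    prior: LabeledSignals,
    lam: float,
) -> np.ndarray:
    """Soft class memberships p(l=k | e_i, theta_k) of the current signals.

    Gaussian class models (shrinkage ``lam``) fitted on the task-labelled
    full data; hard policy labels are the documented fallback when a
    class is too small or its shrunk covariance degenerate.
    """
    M, d = X.shape
    hard = np.column_stack([(labels == CORRECT), (labels == ERROR)]).astype(float)
    logd = np.empty((M, 2))
    for k in (CORRECT, ERROR):
        parts = [X[labels == k]]
        if len(prior):
            parts.append(prior.features[prior.labels == k])
        Xk = np.vstack([p for p in parts if p.size]) if any(p.size for p in parts) else np.zeros((0, d))
        if Xk.shape[0] < 2:
            return hard
        m = dec.fit_class(Xk)
        cov = dec.shrink(m.cov, lam)
        try:
            logd[:, k] = _batch_gaussian_logdens(X, m.mean, cov)
        except np.linalg.LinAlgError:
            return hard
    logd -= logsumexp(logd, axis=1, keepdims=True)  # equal class priors
    return np.exp(logd)


def power_ratio(
    history: History,
    task: GridTask,
    prior: Optional[LabeledSignals] = None,
    model: Optional[TransitionModel] = None,
    lam: float = 0.5,
) -> float:
    """Ratio of weighted mean signal power, error class over correct class.

    Each class's mean power is the responsibility-weighted average of the
    raw feature inner products ``e_i^T e_i`` over the current history.
    Degenerate responsibilities (a class with zero total weight) fall
    back to a ratio of 1.
    """
    if len(history) == 0:
        raise ValueError("power ratio needs a nonempty history")
    prior = prior or LabeledSignals()
    X = history.feature_matrix()
    labels = _task_labels(history, task, model)
    resp = _responsibilities(X, labels, prior, lam)
    power = (X**2).sum(axis=1)
    weights = resp.sum(axis=0)
    if weights.min() < 1e-12:
        return 1.0
    p_c = float(resp[:, CORRECT] @ power / weights[CORRECT])
    p_w = float(resp[:, ERROR] @ power / weights[ERROR])
    if p_c <= 0.0:
        return 1.0
    return p_w / p_c


# ---------------------------------------------------------------------------
# posterior assembly


def _confidences_from_log(log_values: np.ndarray) -> np.ndarray:
    """W^t per task: minimum pairwise normalised likelihood, stably in logs."""
    T = log_values.shape[0]
    if T == 1:
        return np.ones(1)
    order = np.argsort(log_values)[::-1]
    best, second = log_values[order[0]], log_values[order[1]]
    # min over rivals is attained at the strongest rival
    rival = np.full(T, best)
    rival[order[0]] = second
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(np.clip(rival - log_values, -700, 700)))


def corrected_posterior(
    history: History,
    tasks: Sequence[GridTask],
    prior: Optional[LabeledSignals] = None,
    model: Optional[TransitionModel] = None,
    config: InferenceConfig = InferenceConfig(),
) -> TaskPosterior:
    """Power-corrected task posterior over all goal hypotheses.

    Per task: ``exp(pseudo_loglikelihood) * power_ratio``, normalised
    across tasks under a uniform task prior, computed in log space.  A
    history shorter than two triplets yields the uniform posterior by
    convention.
    """
    tasks = list(tasks)
    if len(history) < 2:
        return uniform_posterior(tasks)
    prior = prior or LabeledSignals()
    X = history.feature_matrix()
    prior_stats = prior.class_stats(X.shape[1])
    log_pl = np.empty(len(tasks))
    log_corr = np.empty(len(tasks))
    for j, task in enumerate(tasks):
        labels = _task_labels(history, task, model)
        log_pl[j] = _pseudo_terms(
            X,
            labels,
            prior_stats,
            config.anchor_pseudo_count,
            config.mean_pseudo_count,
        ).sum()
        if config.power_correction:
            resp = _responsibilities(X, labels, prior, config.shrinkage_lambda)
            power = (X**2).sum(axis=1)
            weights = resp.sum(axis=0)
            if weights.min() < 1e-12:
                ratio = 1.0
            else:
                p_c = float(resp[:, CORRECT] @ power / weights[CORRECT])
                p_w = float(resp[:, ERROR] @ power / weights[ERROR])
                ratio = p_w / p_c if p_c > 0 else 1.0
            log_corr[j] = log_pl[j] + math.log(ratio)
        else:
            log_corr[j] = log_pl[j]
    scores = np.exp(log_corr - logsumexp(log_corr))
    scores /= scores.sum()
    if config.confidence_method == "plugin":
        conf = _plugin_confidences(
            X, history, tasks, prior, log_corr, log_corr - log_pl, model, config
        )
    elif config.confidence_method in ("prequential", "combined"):
        log_preq = np.array(
            [
                _prequential_loglikelihood(X, _task_labels(history, t, model), prior_stats, config)
                for t in tasks
            ]
        )
        if config.confidence_uses_power:
            log_preq = log_preq + (log_corr - log_pl)
        conf = _confidences_from_log(log_preq)
        if config.confidence_method == "combined":
            conf = np.minimum(
                conf,
                _confidences_from_log(
                    log_corr if config.confidence_uses_power else log_pl
                ),
            )
    else:
        conf = _confidences_from_log(
            log_corr if config.confidence_uses_power else log_pl
        )
    return TaskPosterior(
        tasks=tasks,
        log_pseudolik=log_pl,
        log_corrected=log_corr,
        scores=scores,
        confidence=conf,
    )


def _plugin_confidences(
    X: np.ndarray,
    history: History,
    tasks: list[GridTask],
    prior: LabeledSignals,
    log_corr: np.ndarray,
    log_power: np.ndarray,
    model: Optional[TransitionModel],
    config: InferenceConfig,
) -> np.ndarray:
    """Confidences from the plug-in likelihood under one shared decoder.

    The decoder (shrunk Gaussian per class) is fitted with the labels of
    the leading hypothesis plus any prior-labelled signals; every
    hypothesis's history likelihood is then the product of the shared
    class densities its own labelling selects, optionally multiplied by
    its power ratio.  Falls back to an agnostic 1/2 while either class is
    too small to fit.
    """
    T = len(tasks)
    j_map = int(np.argmax(log_corr))
    map_labels = _task_labels(history, tasks[j_map], model)
    d = X.shape[1]
    logd = np.empty((X.shape[0], 2))
    for k in (CORRECT, ERROR):
        parts = [X[map_labels == k]]
        if len(prior):
            parts.append(prior.features[prior.labels == k])
        Xk = np.vstack([p for p in parts if p.size]) if any(p.size for p in parts) else np.zeros((0, d))
        if Xk.shape[0] < 2:
            return np.full(T, 0.5) if T > 1 else np.ones(1)
        m = dec.fit_class(Xk)
        cov = dec.shrink(m.cov, config.shrinkage_lambda)
        try:
            logd[:, k] = _batch_gaussian_logdens(X, m.mean, cov)
        except np.linalg.LinAlgError:
            return np.full(T, 0.5) if T > 1 else np.ones(1)
    log_plugin = np.empty(T)
    for j, task in enumerate(tasks):
        labels = _task_labels(history, task, model)
        log_plugin[j] = float(logd[np.arange(X.shape[0]), labels].sum())
    if config.confidence_uses_power:
        log_plugin = log_plugin + log_power
    return _confidences_from_log(log_plugin)


def confidence(posterior: TaskPosterior, task: GridTask) -> float:
    """``W^t`` of one task: min over rivals of P(t) / (P(t) + P(x))."""
    j = posterior.tasks.index(task)
    return float(posterior.confidence[j])


def decide(posterior: TaskPosterior, beta: float) -> Optional[GridTask]:
    """The unique task with ``W^t > beta``, or ``None``.

    Only the argmax task can exceed any ``beta >= 0.5``, so uniqueness is
    structural.
    """
    if not 0.5 <= beta <= 1.0:
        raise ValueError("beta must be in [0.5, 1]")
    j = int(np.argmax(posterior.confidence))
    if posterior.confidence[j] > beta:
        return posterior.tasks[j]
    return None


# ---------------------------------------------------------------------------
# calibrated (supervised) recursive filter


def calibrated_update(
    posterior: TaskPosterior,
    triplet: HistoryTriplet,
    models: tuple[dec.ClassModel, dec.ClassModel],
    params: dec.DecoderParams = dec.DecoderParams(),
    model: Optional[TransitionModel] = None,
    llr_scale: float = 1.0,
) -> TaskPosterior:
    """One step of the calibrated recursive task filter.

    Each task's log score is incremented by the log density of the new
    signal under the class its policy assigns to ``(state, action)``
    (hard labels collapse the class mixture to a single term); scores are
    renormalised in log space so underflow across all tasks is
    impossible.  ``llr_scale`` tempers the between-class log-likelihood
    ratio (see :func:`~errpbci.decoder.fit_llr_calibration`); task
    scores only ever depend on that ratio, so tempering it is the entire
    recalibration.
    """
    model_c, model_w = models
    logdens = np.array(
        [
            dec.gaussian_logdensity(
                triplet.features, m.mean, dec.shrink(m.cov, params.shrinkage_lambda)
            )
            + math.log(p)
            for m, p in zip((model_c, model_w), params.class_priors)
        ]
    )
    if llr_scale != 1.0:
        mid = logdens.mean()
        logdens = mid + llr_scale * (logdens - mid)
    log_scores = np.empty(len(posterior.tasks))
    for j, task in enumerate(posterior.tasks):
        p_c, _ = label_probability(triplet.state, triplet.action, task)
        k = CORRECT if p_c == 1.0 else ERROR
        log_scores[j] = posterior.log_corrected[j] + logdens[k]
    scores = np.exp(log_scores - logsumexp(log_scores))
    scores /= scores.sum()
    return TaskPosterior(
        tasks=posterior.tasks,
        log_pseudolik=log_scores.copy(),
        log_corrected=log_scores,
        scores=scores,
        confidence=_confidences_from_log(log_scores),
    )
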