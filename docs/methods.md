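# Methods

`errpbci` implements a self-calibrating brain–machine interface for
reaching tasks on a discrete grid, driven by error-related potentials
(ErrPs): the user watches a cursor act, their EEG emits a *correct* or
*error* response after every action, and the system simultaneously
(a) infers which grid cell the user wants to reach and (b) learns the
ErrP decoder — with no supervised calibration phase.

## The model

**Environment.** A `width x height` grid MDP with five deterministic
actions (up, down, left, right, goal-reached); off-grid moves leave the
state unchanged.  Each cell is one *goal hypothesis*.  A hypothesis's
optimal policy — move along the shortest Manhattan path, signal
goal-reached on the goal — assigns a hard binary label (correct/error)
to every (state, action) pair.  Labels are not softened; robustness to
user mis-assessments is carried by the heavy-tailed signal likelihood.

**Signals.** Feature vectors `e ∈ R^d` extracted from EEG epochs:
window [200, 800] ms after the action onset, decimation by 8, channels
Fz/FCz/Cz at 256 Hz, giving d = 57.  The sampling convention (half-open
index window `[ceil(t0·fs), floor(t1·fs))`, stride from the first
sample) is frozen by the dimensionality test: it is the unique
open/closed x floor/ceil variant yielding 19 samples per channel.
Each class (correct `c` / error `w`) is modelled as a multivariate
Gaussian; the error class carries higher expected signal power
`E[eᵀe]`.

**Supervised decoder.** Per-class empirical Gaussians with covariance
shrinkage toward the mean-eigenvalue identity, `(1−λ)Σ + λ(trΣ/d)I`,
λ = 0.5 by default; label posterior by Bayes' rule with equal priors.
Exposed as an sklearn-compatible classifier
(`decoder.ShrinkageGaussianDecoder`).

**Self-calibration score.** For goal hypothesis `t` and history
`D_M = {(s_i, a_i, e_i)}`, the leave-one-out pseudo-likelihood

    P(D_M | t) = Π_i p(e_i | l = k_t(s_i, a_i), D_−i),

where `k_t` is the label `t`'s policy assigns and the predictive density
of each signal is evaluated under class models fitted on all *other*
signals.  Marginalising the Gaussian parameters under a non-informative
(Jeffreys) prior turns the predictive into a multivariate Student t with
`n − d` degrees of freedom, location at the class mean and scale matrix
`S (n+1) / (n (n−d))` with `S` the class scatter matrix
(`decoder.t_predictive_logdensity`, verified against the closed
univariate form and a quadrature marginalisation oracle).

**Power correction.** Two hypotheses whose labelings are exact class
swaps of each other tie under any label-symmetric score.  Each
hypothesis's likelihood is therefore multiplied by the ratio of the
responsibility-weighted mean signal power (`eᵀe`) of its error class
over its correct class, which favours the labelling that calls the
high-power cluster erroneous.  Responsibilities come from shrunk
Gaussian class models (λ = 0.5) fitted on the task-labelled data; when
a class is too small for a fit, the hard policy labels serve as
responsibilities, and an empty class yields a neutral ratio of 1.

**Decision rule.** The confidence of hypothesis `t` is the minimum
pairwise normalised likelihood `W^t = min_x P̄(t) / (P̄(t) + P̄(x))`;
the device switches from exploration to pure exploitation of `t` while
`W^t` exceeds a threshold β ∈ [0.5, 1] (default 0.9).  The decision is
re-examined every step: a transient noise crossing revokes itself
before it can commit a goal-reached action.

**Planner.** While undecided, every (state, action) pair earns an
uncertainty reward and the resulting MDP is solved by value iteration
(discount 0.95, sup-norm tolerance 1e−6, ties broken in the documented
action order).  The default reward is the *signal-space* expected
information gain: the entropy of the mixture of task-conditioned signal
predictives minus their posterior-weighted mean entropy, approximated in
closed form with pairwise Bhattacharyya distances under the shared
pooled variance.  A label-entropy reward is also provided but is *not*
the default: at label-swap-symmetric pairs it stays at ln 2 although a
signal observed there carries no information about which hypothesis is
right, and a planner maximising it can stall on such pairs indefinitely
(we observed exactly this on 5×5 worlds).  A small exploitation blend
(0.05 × the posterior probability that a pair is assessed correct) is
added to the reward: information is label-symmetric, so the blend is
what resolves ties between equally informative actions toward the
current goal estimate and produces the characteristic declining error
rate during learning.

**Prior transfer.** When a target is reached, the segment's signals are
labelled by the identified goal's policy and banked as fixed supervised
data for all subsequent targets; the task posterior resets to uniform.
After a few correct targets the accumulated labels make the classifier
equivalent to a supervised one of the same size.

## Cold-start regularisation (the critical design area)

The Jeffreys predictive `t_{n−d}` is undefined for class counts
`n ≤ d` — with d = 57 that covers the first ~120 steps of operation —
and its scatter is near-singular for `n ≈ d`.  Naive fallbacks fail in
a specific, measurable way: any predictive whose degrees of freedom or
scale normalisation depend on the class size biases the
pseudo-likelihood across labelings by several nats in high dimension
(class sizes differ between hypotheses), and a flat prior on class
means lets tiny classes chase chance clusterings of the data, producing
spurious 5–15-nat leads for wrong hypotheses — far more than the
~0.9-nat per-signal evidence available at 75 % single-trial accuracy.

The default scoring is therefore *anchored*: every signal is scored by
a Student t with fixed degrees of freedom (10 — heavy tails for
robustness to mis-assessments), the *shared* pooled per-dimension
variance as scale, and a class mean anchored by `kappa0` pseudo-signals
at the pooled mean (a conjugate normal–inverse-Wishart structure; the
pseudo-signals tighten the location without adding scale degrees of
freedom).  Normalisation then cancels exactly between rival labelings
and the evidence flows only through class-mean residuals.
`InferenceConfig(anchor_pseudo_count=0, mean_pseudo_count=0)` recovers
the pure Jeffreys rules (exact `t_{n−d}` once a class holds d + 2
signals, per-dimension Jeffreys predictives before that, pooled data
for near-empty classes), which remain the reference semantics for
small-dimension analyses and the brute-force oracles in the tests.

`kappa0 = 192` by default.  The anchor strength trades decision latency
against premature commitment: it corresponds to a conservative prior
scale of ≈ 0.07 pooled standard deviations for per-dimension class-mean
offsets (a 75 %-accuracy decoder implies ≈ 0.18), and at the reference
conditions it delays first decisions to roughly 60–180 steps — the
range the method needs before 57-dimensional mean structure is
genuinely identifiable — while keeping chance fluctuations across the
25 candidate labelings below the β = 0.9 decision bar.

**Confidence statistic.** The leave-one-out score re-fits every class
model at every step, which makes it the best *estimator* of the
labelling (it backs the posterior, the planner, and the power
correction) but a poor statistic to threshold sequentially: re-fitting
lets the best-fitting wrong partition carry transient multi-nat leads.
The decision confidence therefore defaults to a *prequential*
likelihood — each signal scored under the class models fitted only on
the signals that came before it, plus any prior-labelled data, with
terms never revised.  Under the true hypothesis a rival's prequential
gap is (approximately) a supermartingale, so the probability that it
ever falsely exceeds `log(β/(1−β))` is bounded.  `"loo"` and
`"plugin"` (one shared decoder fitted from the leading labelling)
variants are selectable; the power correction enters the confidence by
default.

## Synthetic data

The generator draws features from two Gaussians with equal identity
covariances; `from_accuracy(acc)` places the error mean at Mahalanobis
distance `Δ = 2 Φ⁻¹(acc)` along the uniform direction, so the implied
power ratio `1 + Δ²/d` exceeds 1 by construction (at the default
acc = 0.75, d = 57: ratio ≈ 1.03).  The simulated user assesses every
device action against the intended goal's optimal policy and
mis-assesses with probability 0.05 by default (the emitted label — and
the class the signal is drawn from — flips).  A waveform mode
synthesises three-channel epochs whose error condition carries a
biphasic deflection (positive peak near 400 ms, negative near 600 ms
over white noise) so the raw-epoch feature path is exercised end to
end.

What the generator does *not* emulate: temporally correlated EEG noise
(1/f background, ocular artifacts), session non-stationarity,
structured class covariances, or latency jitter of the evoked response.
Passing closed-loop tests therefore demonstrate the *inferential*
machinery — goal identification, symmetry breaking, decoder
bootstrapping, planning — under the paper's distributional assumptions,
not robustness to real EEG artifacts.

## Evaluation machinery

* Task metrics: steps to the first target, correct/incorrect reaches
  (a reach is the goal-reached action committed in exploitation mode at
  the decided cell; the intended target advances after every reach).
* Moving-average error rate (window 10; earlier steps average the
  available prefix) over the intended-policy labels.
* Label quality: the learned labels against the intended policy's
  labels (`pct_labels_correct`, the observable ground truth) and
  against the generating signal class
  (`pct_labels_match_signal_class`, which additionally counts user
  mis-assessments), plus stratified ten-fold decoder accuracies under
  ground-truth and learned labelings (both scored against signal
  classes; fixed seed).
* Incremental calibration: decoders trained on growing prefixes of a
  300-trial pool, tested on 200 held-out trials, 10 reshuffles; the
  plateau is the first size whose accuracy stays within 1 percentage
  point of the curve's maximum for five consecutive sizes.  Anchoring on
  the global maximum matters: against a *running* maximum, a slowly
  rising curve (as a shrunk d = 57 decoder produces) would "plateau"
  long before it stops improving.  On the default synthetic conditions
  the curve genuinely keeps rising through a 300-trial pool; the
  analysis then reports no plateau and downstream consumers fall back to
  the full pool.
* Simulated supervised control: a decoder trained on the plateau-size
  calibration set drives the calibrated recursive filter; at each step
  the next unused held-out signal of the required true label is
  consumed.  Two safeguards are part of the controller.  The
  goal-reached commitment is gated on the same pairwise confidence
  exceeding β — without the gate, a freshly reset posterior lets a
  single error signal make the current cell the most likely goal and
  the replay degenerates into an instant-reach loop.  And the per-step
  log-likelihood ratio is tempered by a cross-validated logistic
  (Platt-style) slope fitted on the calibration set: plug-in Gaussian
  densities in high dimension are over-dispersed (at d = 57, n = 300 the
  measured LLR standard deviation is ~2.2x the honest evidence), and an
  untempered sequential threshold commits on that noise.  Steps to the
  first target include the calibration trials.

## Numerical choices

* All densities and posteriors are computed in log space;
  normalisations use log-sum-exp.
* The leave-one-out sweep is closed-form: removing one signal is a
  rank-one downdate of the class scatter (Sherman–Morrison for the
  Mahalanobis form, the determinant lemma for the log-determinant), so
  a step costs one Cholesky factorisation per class and hypothesis.  A
  naive refit path is kept and agrees to round-off; a full 500-step,
  25-hypothesis, d = 57 run takes ~20 s on one CPU.
* Value iteration stops when the sup-norm change is below
  `tol (1−γ)/γ`, guaranteeing the value is within `tol` of the fixed
  point; the greedy policy breaks ties by the documented action order
  (up, down, left, right, goal-reached).
* Degenerate inputs: scale floors of 1e−30 on per-dimension scatters;
  a memberless unanchored class scores against the pooled mean; scores
  of a history shorter than two triplets are the uniform posterior by
  convention.
* All randomness flows from a single integer seed per run/experiment;
  identical seeds give bit-identical run records.

## Known limitations

* The cold-start anchor strength and the exploitation blend are
  operating-point choices, reasoned for d = 57 at 60–80 % single-trial
  accuracy; substantially different dimensionalities or separabilities
  may warrant re-derivation (`kappa0 ≈ d / Δ²` up to the conservatism
  factor).
* At low separability (≈ 0.6 Bayes accuracy) first decisions may not
  occur within a 500-step budget — consistent with the weakest subjects
  the protocol was designed around, but worth knowing.
* Mid-reach goal switching by the user is not modelled; the intended
  target is fixed until a reach.
* The signal-space information reward assumes shared covariance across
  classes when ranking pairs; strongly class-specific covariances would
  make it underestimate the information at some pairs.
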