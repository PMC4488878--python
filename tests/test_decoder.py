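import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats
from sklearn.base import clone
from sklearn.model_selection import cross_val_score

from errpbci.decoder import (
    ClassModel,
    DecoderParams,
    InsufficientDataError,
    ShrinkageGaussianDecoder,
    class_posterior,
    fit_class,
    load_decoder,
    save_decoder,
    shrink,
    t_predictive_logdensity,
    t_predictive_logdensity_diag,
)


# ---------------------------------------------------------------------------
# moments


def test_fit_class_unbiased_moments():
    m = fit_class(np.array([[0.0], [2.0]]))
    assert m.mean[0] == 1.0 and m.cov[0, 0] == 2.0 and m.n == 2


def test_fit_class_identical_points_zero_covariance():
    m = fit_class(np.ones((4, 3)))
    assert not m.cov.any()


def test_fit_class_weights():
    m = fit_class(np.array([[0.0], [2.0]]), weights=[1.0, 0.0])
    assert m.mean[0] == 0.0


def test_fit_class_rejects_empty_and_bad_weights():
    with pytest.raises(ValueError):
        fit_class(np.zeros((0, 3)))
    with pytest.raises(ValueError):
        fit_class(np.zeros((2, 3)), weights=[0.0, 0.0])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 1000))
def test_fit_class_order_invariant(seed):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((8, 4))
    perm = rng.permutation(8)
    a, b = fit_class(X), fit_class(X[perm])
    np.testing.assert_allclose(a.mean, b.mean, atol=1e-12)
    np.testing.assert_allclose(a.cov, b.cov, atol=1e-12)


@pytest.mark.parametrize(
    "lam, expected",
    [(0.0, np.diag([2.0, 4.0])), (1.0, np.diag([3.0, 3.0])), (0.5, np.diag([2.5, 3.5]))],
)
def test_shrink_examples(lam, expected):
    np.testing.assert_allclose(shrink(np.diag([2.0, 4.0]), lam), expected)


# ---------------------------------------------------------------------------
# supervised posterior


def _toy_models(d=2, gap=6.0):
    mc = ClassModel(np.zeros(d), np.eye(d), 50, 0)
    mw = ClassModel(np.full(d, gap / np.sqrt(d)), np.eye(d), 50, 1)
    return mc, mw


def test_class_posterior_symmetry():
    mc, mw = _toy_models()
    mid = (mc.mean + mw.mean) / 2
    p = class_posterior(mid, (mc, mw))
    assert p[0] == pytest.approx(0.5, abs=1e-12) and sum(p) == pytest.approx(1.0)


def test_class_posterior_at_class_mean():
    mc, mw = _toy_models()
    assert class_posterior(mc.mean, (mc, mw))[0] > 0.99


def test_class_posterior_1d_logistic_closed_form():
    mc = ClassModel([0.0], [[1.0]], 10, 0)
    mw = ClassModel([2.0], [[1.0]], 10, 1)
    p_c, _ = class_posterior(np.array([0.0]), (mc, mw), DecoderParams(shrinkage_lambda=0.0))
    assert p_c == pytest.approx(1.0 / (1.0 + np.exp(-2.0)), abs=1e-12)


# ---------------------------------------------------------------------------
# Jeffreys predictive (the heavy-tailed self-calibration likelihood)


def test_t_predictive_mode_at_location(rng):
    X = rng.standard_normal((12, 3))
    m = fit_class(X)
    at_mean = t_predictive_logdensity(m.mean, m)
    for _ in range(10):
        assert t_predictive_logdensity(m.mean + 0.1 * rng.standard_normal(3), m) < at_mean


def test_t_predictive_matches_univariate_student_t(rng):
    X = rng.standard_normal((7, 1)) * 1.7 + 0.4
    m = fit_class(X)
    n = m.n
    scatter = m.cov[0, 0] * (n - 1)
    scale = np.sqrt(scatter * (n + 1) / (n * (n - 1)))
    for e in (-2.0, 0.0, 0.3, 4.0):
        expected = stats.t.logpdf(e, df=n - 1, loc=m.mean[0], scale=scale)
        assert t_predictive_logdensity(np.array([e]), m) == pytest.approx(expected, abs=1e-10)


def test_t_predictive_matches_jeffreys_quadrature():
    """Numerical marginalisation of N(e|mu, s2) under p(mu, s2) ~ 1/s2."""
    X = np.array([[0.3], [-0.9], [1.4]])
    m = fit_class(X)

    def marginal(e):
        # nested quadrature over the full (mu, sigma^2) half-plane; the
        # posterior has polynomial (t) tails, so finite truncation biases
        # the value and infinite limits are required.
        def inner(mu, with_e):
            def f(u):  # u = log sigma^2 smooths the peak for the quadrature
                s2 = np.exp(u)
                like = np.prod(stats.norm.pdf(X.ravel(), mu, np.sqrt(s2)))
                if with_e:
                    like *= stats.norm.pdf(e, mu, np.sqrt(s2))
                return like  # 1/s2 prior cancels against the du jacobian

            val, _ = integrate.quad(f, -30, 30, limit=300)
            return val

        val, _ = integrate.quad(lambda mu: inner(mu, True), -np.inf, np.inf, limit=200)
        norm, _ = integrate.quad(lambda mu: inner(mu, False), -np.inf, np.inf, limit=200)
        return np.log(val / norm)

    for e in (-1.0, 2.0):
        assert t_predictive_logdensity(np.array([e]), m) == pytest.approx(marginal(e), abs=1e-4)


def test_t_predictive_converges_to_gaussian(rng):
    d = 2
    n = 100_000 * d
    mean = np.array([0.5, -1.0])
    cov = np.array([[2.0, 0.3], [0.3, 1.0]])
    m = ClassModel(mean, cov, n, 0)
    e = np.array([1.5, 0.2])
    t_val = t_predictive_logdensity(e, m)
    g_val = stats.multivariate_normal.logpdf(e, mean, cov)
    assert abs(t_val - g_val) / abs(g_val) < 1e-3


def test_t_predictive_insufficient_data_signal():
    m = fit_class(np.random.default_rng(0).standard_normal((3, 3)))  # n = d
    with pytest.raises(InsufficientDataError):
        t_predictive_logdensity(np.zeros(3), m)
    # diagonal fallback stays defined
    assert np.isfinite(t_predictive_logdensity_diag(np.zeros(3), m))


def test_diag_fallback_matches_univariate_product(rng):
    X = rng.standard_normal((5, 2))
    m = fit_class(X)
    n = m.n
    per_dim = 0.0
    for j in range(2):
        scatter_j = m.cov[j, j] * (n - 1)
        scale = np.sqrt(scatter_j * (n + 1) / (n * (n - 1)))
        per_dim += stats.t.logpdf(0.3, df=n - 1, loc=m.mean[j], scale=scale)
    assert t_predictive_logdensity_diag(np.array([0.3, 0.3]), m) == pytest.approx(per_dim, abs=1e-12)


def test_mahalanobis_core_scale_invariance(rng):
    X = rng.standard_normal((40, 2))
    m = fit_class(X)
    e = m.mean + np.array([0.7, -0.2])
    c = 3.0
    m_scaled = ClassModel(m.mean, m.cov * c**2, m.n, 0)
    e_scaled = m.mean + c * (e - m.mean)
    base = t_predictive_logdensity(e, m)
    scaled = t_predictive_logdensity(e_scaled, m_scaled)
    # densities differ only by the deterministic log-Jacobian d*log(c)
    assert scaled == pytest.approx(base - 2 * np.log(c), abs=1e-10)


# ---------------------------------------------------------------------------
# sklearn estimator surface


def test_estimator_separates_classes(rng):
    X = np.vstack([rng.standard_normal((60, 5)), rng.standard_normal((60, 5)) + 2.0])
    y = np.repeat([0, 1], 60)
    clf = ShrinkageGaussianDecoder().fit(X, y)
    assert (clf.predict(X) == y).mean() > 0.95
    proba = clf.predict_proba(X)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
    scores = cross_val_score(clone(clf), X, y, cv=5)
    assert scores.mean() > 0.9


def test_estimator_params_roundtrip():
    clf = ShrinkageGaussianDecoder(shrinkage_lambda=0.3, priors=(0.4, 0.6))
    params = clf.get_params()
    assert params["shrinkage_lambda"] == 0.3
    clf2 = clone(clf)
    assert clf2.get_params() == params


def test_decoder_serialization_roundtrip(tmp_path, rng):
    X = rng.standard_normal((20, 4))
    models = (fit_class(X[:10], label=0), fit_class(X[10:], label=1))
    params = DecoderParams(shrinkage_lambda=0.25)
    path = tmp_path / "decoder.json"
    save_decoder(path, models, params)
    loaded, lparams = load_decoder(path)
    assert lparams == params
    for a, b in zip(models, loaded):
        np.testing.assert_allclose(a.mean, b.mean)
        np.testing.assert_allclose(a.cov, b.cov)
        assert a.n == b.n and a.label == b.label
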