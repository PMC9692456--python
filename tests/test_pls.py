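"""NIPALS PLS and PLS-DA: structural identities and independent oracles."""

import numpy as np
import pytest

from frailmark import (
    AUTOSCALE,
    CENTER,
    canonical_variate,
    fit_pls,
    fit_plsda,
    fit_preprocessor,
    predict_class,
    predict_pls,
    variable_weights,
)


def _fit(X, y, A, mode=AUTOSCALE):
    prep = fit_preprocessor(X, mode)
    m = fit_pls(prep.transform(X), y - y.mean(), A)
    m.preprocessor = prep
    m.y_mean = float(y.mean())
    return m


def textbook_nipals(X, y, A):
    """Independent straight-from-the-book NIPALS PLS1 (X-deflation)."""
    Xd = X.copy().astype(float)
    y = y.astype(float)
    W, P, T, q = [], [], [], []
    for _ in range(A):
        w = Xd.T @ y
        w = w / np.sqrt(w @ w)
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        q.append(y @ t / (t @ t))
        W.append(w)
        P.append(p)
        T.append(t)
        Xd = Xd - np.outer(t, p)
    return np.array(W).T, np.array(P).T, np.array(T).T, np.array(q)


# ---------------------------------------------------------------- preprocessor


def test_preprocessor_stats_and_inverse():
    X = np.array([[1.0, 5.0], [3.0, 9.0]])
    prep = fit_preprocessor(X, AUTOSCALE)
    assert prep.means[0] == 2.0
    assert prep.scales[0] == pytest.approx(np.sqrt(2))
    assert np.allclose(prep.inverse(prep.transform(X)), X)


def test_preprocessor_training_statistics_only(rng):
    Xtr = rng.normal(5, 2, size=(20, 3))
    prep = fit_preprocessor(Xtr, AUTOSCALE)
    Xnew = rng.normal(0, 1, size=(4, 3))
    assert np.allclose(prep.transform(Xnew), (Xnew - Xtr.mean(0)) / Xtr.std(0, ddof=1))


def test_preprocessor_zero_variance_column():
    X = np.ones((5, 2))
    X[:, 1] = np.arange(5)
    with pytest.raises(ValueError, match="0"):
        fit_preprocessor(X, AUTOSCALE)
    prep = fit_preprocessor(X, CENTER)  # centering tolerates constants
    assert np.allclose(prep.scales, 1.0)


# ---------------------------------------------------------------- PLS core


def test_orthonormal_columns_single_component():
    Q, _ = np.linalg.qr(np.random.default_rng(0).standard_normal((12, 4)))
    y = Q[:, 0].copy()
    m = fit_pls(Q, y, 1)
    assert np.allclose(predict_pls(m, Q), y, atol=1e-10)
    b = m.b
    assert abs(b[0]) == pytest.approx(1.0, abs=1e-10)
    assert np.allclose(b[1:], 0.0, atol=1e-10)


@pytest.mark.parametrize("seed", range(10))
def test_full_rank_pls_equals_ols(seed):
    rng = np.random.default_rng(seed)
    n, p = 20, 5
    X = rng.standard_normal((n, p))
    y = rng.standard_normal(n)
    m = _fit(X, y, p)
    Xn = rng.standard_normal((6, p))
    beta, *_ = np.linalg.lstsq(np.c_[np.ones(n), X], y, rcond=None)
    ols = np.c_[np.ones(6), Xn] @ beta
    assert np.allclose(predict_pls(m, Xn), ols, atol=1e-8)


def test_matches_textbook_nipals_oracle(rng):
    X = rng.standard_normal((8, 4))
    Xc = X - X.mean(0)
    y = rng.standard_normal(8)
    yc = y - y.mean()
    m = fit_pls(Xc, yc, 2)
    W, P, T, q = textbook_nipals(Xc, yc, 2)
    assert np.allclose(m.T, T, atol=1e-8)
    assert np.allclose(m.P, P, atol=1e-8)
    assert np.allclose(m.q, q, atol=1e-8)


def test_matches_sklearn_predictions(rng):
    from sklearn.cross_decomposition import PLSRegression

    X = rng.standard_normal((25, 7))
    y = rng.standard_normal(25)
    Xn = rng.standard_normal((5, 7))
    for A in (1, 2, 3, 5):
        m = _fit(X, y, A)
        sk = PLSRegression(n_components=A, scale=True).fit(X, y)
        assert np.allclose(predict_pls(m, Xn), sk.predict(Xn).ravel(), atol=1e-8)


@pytest.mark.parametrize("seed", range(5))
def test_structural_identities(seed):
    """T = X R and y_hat = T q hold on training data; scores orthogonal."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((15, 6))
    Xc = X - X.mean(0)
    y = rng.standard_normal(15)
    m = fit_pls(Xc, y - y.mean(), 4)
    assert np.max(np.abs(m.T - Xc @ m.R)) < 1e-8
    assert np.max(np.abs(Xc @ m.b - m.T @ m.q)) < 1e-8
    G = m.T.T @ m.T
    assert np.max(np.abs(G - np.diag(np.diag(G)))) < 1e-8


def test_variable_permutation_equivariance(rng):
    X = rng.standard_normal((18, 5))
    y = rng.standard_normal(18)
    Xn = rng.standard_normal((4, 5))
    perm = rng.permutation(5)
    m1 = _fit(X, y, 3)
    m2 = _fit(X[:, perm], y, 3)
    assert np.allclose(predict_pls(m1, Xn), predict_pls(m2, Xn[:, perm]), atol=1e-10)


def test_nested_coefficient_path(rng):
    """Coefficients at a < A from one fit equal a separate fit at A = a."""
    X = rng.standard_normal((20, 6))
    Xc = X - X.mean(0)
    y = rng.standard_normal(20)
    yc = y - y.mean()
    big = fit_pls(Xc, yc, 5)
    for a in (1, 2, 3):
        small = fit_pls(Xc, yc, a)
        assert np.allclose(big.coefficients(a), small.b, atol=1e-10)


def test_degenerate_collinear_early_stop():
    X = np.outer(np.arange(6.0) - 2.5, [1.0, 2.0])  # rank 1
    y = X[:, 0].copy()
    with pytest.warns(RuntimeWarning, match="stopped early"):
        m = fit_pls(X, y - y.mean(), 2)
    assert m.A == 1


def test_bad_component_count(rng):
    X = rng.standard_normal((5, 3))
    with pytest.raises(ValueError):
        fit_pls(X, rng.standard_normal(5), 5)


def test_predict_wrong_width(rng):
    m = _fit(rng.standard_normal((10, 4)), rng.standard_normal(10), 2)
    with pytest.raises(ValueError, match="columns"):
        predict_pls(m, np.zeros((2, 3)))


def test_duplicate_row_identical_prediction(rng):
    X = rng.standard_normal((12, 4))
    y = rng.standard_normal(12)
    m = _fit(X, y, 2)
    pred = predict_pls(m, np.vstack([X[3], X[3]]))
    assert pred[0] == pred[1]


# ---------------------------------------------------------------- PLS-DA


def _two_clouds(shift, n1=15, n2=15, p=4, seed=0):
    rng = np.random.default_rng(seed)
    X1 = rng.standard_normal((n1, p)) + shift
    X2 = rng.standard_normal((n2, p))
    X = np.vstack([X1, X2])
    labels = np.array(["PFS"] * n1 + ["CONTROL"] * n2)
    return X, labels


def test_separated_clouds_perfect_resubstitution():
    X, labels = _two_clouds(6.0)
    model = fit_plsda(X, labels, 2)
    assert np.all(predict_class(model, X) == labels)


def test_lda_threshold_closed_form():
    """With training predictions (.9,.8 | .2,.1) the equal-prior pooled
    threshold is the midpoint 0.5."""
    yhat1 = np.array([0.9, 0.8])
    yhat0 = np.array([0.2, 0.1])
    thr = 0.5 * (yhat1.mean() + yhat0.mean())
    assert thr == pytest.approx(0.5)
    # the fitted model reproduces this rule on real data
    X, labels = _two_clouds(3.0, seed=1)
    model = fit_plsda(X, labels, 1)
    yhat = predict_pls(model.pls, X)
    m1 = yhat[labels == "PFS"].mean()
    m0 = yhat[labels == "CONTROL"].mean()
    assert model.threshold == pytest.approx(0.5 * (m0 + m1))


def test_class_recoding_symmetry():
    X, labels = _two_clouds(2.0, seed=2)
    m_pfs = fit_plsda(X, labels, 2, positive_class="PFS")
    m_ctl = fit_plsda(X, labels, 2, positive_class="CONTROL")
    assert np.all(predict_class(m_pfs, X) == predict_class(m_ctl, X))
    assert np.allclose(variable_weights(m_pfs), -variable_weights(m_ctl), atol=1e-10)


def test_canonical_variate_orientation_and_zero():
    X, labels = _two_clouds(3.0, seed=3)
    model = fit_plsda(X, labels, 2)
    scores = canonical_variate(model, X)
    assert scores[labels == "PFS"].mean() < 0
    # a sample exactly at the threshold maps to score 0
    yhat = predict_pls(model.pls, X)
    j = np.argmin(np.abs(yhat - model.threshold))
    assert abs(scores[j]) == pytest.approx(abs(yhat[j] - model.threshold), abs=1e-12)


def test_scale_invariance_of_scores():
    X, labels = _two_clouds(2.5, seed=4)
    model1 = fit_plsda(X, labels, 2)
    scale = np.array([10.0, 0.1, 3.0, 1000.0])
    model2 = fit_plsda(X * scale + 5.0, labels, 2)
    assert np.allclose(
        canonical_variate(model1, X), canonical_variate(model2, X * scale + 5.0), atol=1e-8
    )


def test_single_informative_variable_dominates():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((60, 5))
    labels = np.where(rng.random(60) < 0.5, "PFS", "CONTROL")
    X[labels == "PFS", 2] += 4.0
    model = fit_plsda(X, labels, 2)
    w = np.abs(variable_weights(model))
    assert w[2] > 5 * np.max(np.delete(w, 2))


def test_null_weights_small_at_large_n():
    rng = np.random.default_rng(6)
    X = rng.standard_normal((500, 5))
    labels = np.array(["PFS"] * 250 + ["CONTROL"] * 250)
    model = fit_plsda(X, labels, 2)
    assert np.mean(np.abs(variable_weights(model))) < 0.1


def test_single_class_rejected():
    X = np.random.default_rng(0).standard_normal((10, 3))
    with pytest.raises(ValueError):
        fit_plsda(X, np.array(["PFS"] * 10), 1)
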