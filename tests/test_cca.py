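"""CCA engine: closed-form correctness against an independent eigen oracle,
invariances, variates, and loadings."""

import numpy as np
import pytest
from scipy import linalg

import neocca as nc


def eigen_oracle(X, Y):
    """Brute-force CCA via the generalized eigenproblem on covariance matrices.

    Solves Sxy Syy^-1 Syx a = r^2 Sxx a directly; independent of the SVD
    route used by the package.
    """
    n = X.shape[0]
    Xc = X - X.mean(0)
    Yc = Y - Y.mean(0)
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    M = Sxy @ np.linalg.solve(Syy, Sxy.T)
    evals, evecs = linalg.eigh(M, Sxx)
    order = np.argsort(evals)[::-1]
    r = np.sqrt(np.clip(evals[order], 0, 1))
    A = evecs[:, order]
    # normalize to unit-variance variates
    U = Xc @ A
    A = A / U.std(0, ddof=1)
    return r, A


@pytest.mark.parametrize("seed", range(50))
def test_oracle_equivalence(seed):
    """SVD solver equals the generalized-eigendecomposition oracle to 1e-8."""
    g = np.random.default_rng(seed)
    X = g.standard_normal((30, 4))
    Y = g.standard_normal((30, 6))
    model = nc.fit_cca(X, Y)
    r_o, A_o = eigen_oracle(X, Y)
    assert np.allclose(model.r, r_o[: model.m], atol=1e-8)
    # weights agree up to per-pair sign
    for i in range(model.m):
        a, ao = model.a[:, i], A_o[:, i]
        assert min(np.abs(a - ao).max(), np.abs(a + ao).max()) < 1e-8


def test_identical_single_columns_give_r1(rng):
    x = rng.standard_normal((40, 1))
    model = nc.fit_cca(x, x.copy())
    assert model.r[0] == pytest.approx(1.0, abs=1e-12)


def test_single_columns_r_is_abs_corr(rng):
    x = rng.standard_normal(60)
    y = 0.4 * x + rng.standard_normal(60)
    c = np.corrcoef(x, y)[0, 1]
    model = nc.fit_cca(x[:, None], y[:, None])
    assert model.r[0] == pytest.approx(abs(c), abs=1e-12)


def test_correlation_structure_invariants(rng):
    """r non-increasing; corr(U_i,V_i)=r_i; variates mutually uncorrelated."""
    X = rng.standard_normal((80, 5))
    Y = rng.standard_normal((80, 7))
    m = nc.fit_cca(X, Y)
    assert np.all(np.diff(m.r) <= 1e-12)
    for i in range(m.m):
        assert np.corrcoef(m.U[:, i], m.V[:, i])[0, 1] == pytest.approx(m.r[i], abs=1e-8)
    for Z in (m.U, m.V):
        C = np.corrcoef(Z.T)
        assert np.abs(C - np.diag(np.diag(C))).max() < 1e-6


@pytest.mark.parametrize("seed", range(5))
def test_affine_invariance_of_correlations(seed):
    """Invertible per-column rescaling and shifting of X leaves r unchanged."""
    g = np.random.default_rng(seed)
    X = g.standard_normal((50, 4))
    Y = g.standard_normal((50, 3))
    r0 = nc.fit_cca(X, Y).r
    scales = g.uniform(0.1, 10, 4) * g.choice([-1, 1], 4)
    shifts = g.uniform(-5, 5, 4)
    r1 = nc.fit_cca(X * scales + shifts, Y).r
    assert np.allclose(r0, r1, atol=1e-8)


def test_sample_size_consistency():
    """Median |r1_hat - rho| shrinks as n grows (500 -> 5000), rho = 0.6."""
    rho = 0.6

    def errs(n, reps=20):
        out = []
        for s in range(reps):
            g = np.random.default_rng(1000 + s)
            z = g.standard_normal(n)
            X = g.standard_normal((n, 4))
            Y = g.standard_normal((n, 4))
            X[:, 0] = rho * z + np.sqrt(1 - rho**2) * g.standard_normal(n)
            Y[:, 0] = z
            out.append(abs(nc.fit_cca(X, Y).r[0] - rho))
        return np.median(out)

    assert errs(5000) < errs(500)


def test_rank_deficiency_named_and_ridge_escape(rng):
    X = rng.standard_normal((30, 3))
    X[:, 2] = X[:, 0]  # collinear
    Y = rng.standard_normal((30, 4))
    with pytest.raises(np.linalg.LinAlgError, match="'X'"):
        nc.fit_cca(X, Y)
    m = nc.fit_cca(X, Y, regularization=1e-3)
    assert np.all((0 <= m.r) & (m.r <= 1))


def test_variates_reproduce_training_and_centering(rng):
    X = rng.standard_normal((40, 3))
    Y = rng.standard_normal((40, 5))
    m = nc.fit_cca(X, Y)
    U, V = nc.compute_variates(m, X, Y)
    assert np.allclose(U, m.U, atol=1e-10) and np.allclose(V, m.V, atol=1e-10)
    # a row sitting at the column means projects to zero
    U0, V0 = nc.compute_variates(m, m.x_mean[None, :], m.y_mean[None, :])
    assert np.abs(U0).max() < 1e-10 and np.abs(V0).max() < 1e-10
    # linearity: duplicated subject rows give duplicated variate rows
    U2, _ = nc.compute_variates(m, np.vstack([X[:1], X[:1]]), np.vstack([Y[:1], Y[:1]]))
    assert np.allclose(U2[0], U2[1])
    with pytest.raises(ValueError, match="columns"):
        nc.compute_variates(m, X[:, :2], Y)


def test_loadings_single_variable_and_orthogonal(rng):
    x = rng.standard_normal((50, 1))
    Y = rng.standard_normal((50, 3))
    m = nc.fit_cca(x, Y)
    lt = nc.compute_loadings(m, x, Y)
    assert lt.clinical_loadings[0, 0] == pytest.approx(1.0, abs=1e-10)
    # a variable orthogonalized against the variate loads zero
    X2 = rng.standard_normal((50, 2))
    m2 = nc.fit_cca(X2, Y)
    v = rng.standard_normal(50)
    u = m2.U[:, 0] - m2.U[:, 0].mean()
    v_orth = v - v.mean() - u * ((v - v.mean()) @ u) / (u @ u)
    X3 = np.column_stack([X2, v_orth])
    lt3 = nc.compute_loadings(m2, X2, Y)
    r_orth = np.corrcoef(v_orth, m2.U[:, 0])[0, 1]
    assert abs(r_orth) < 1e-10
    assert np.all(np.abs(lt3.clinical_loadings) <= 1)


def test_loading_weight_sign_disagreement_representable(rng):
    """A suppressor variable can have positive loading but negative weight."""
    n = 400
    z = rng.standard_normal(n)
    x1 = z + 0.2 * rng.standard_normal(n)
    # positively correlated with z marginally, but redundant given x1, so its
    # unique contribution (weight) turns negative while its loading stays positive
    x2 = x1 - 0.5 * z + 0.2 * rng.standard_normal(n)
    X = np.column_stack([x1, x2])
    Y = z[:, None] + 0.0
    m = nc.fit_cca(X, Y)
    lt = nc.compute_loadings(m, X, Y)
    signs = np.sign(lt.clinical_loadings[:, 0]) * np.sign(m.a[:, 0])
    assert (signs < 0).any()  # at least one variable disagrees in sign


def test_sign_convention_largest_loading_positive(rng):
    X = rng.standard_normal((60, 4))
    Y = rng.standard_normal((60, 4))
    m = nc.fit_cca(X, Y)
    lt = nc.compute_loadings(m, X, Y)
    for i in range(m.m):
        j = np.argmax(np.abs(lt.clinical_loadings[:, i]))
        assert lt.clinical_loadings[j, i] > 0


def test_zero_variance_variable_flagged(rng):
    X = rng.standard_normal((30, 3))
    Y = rng.standard_normal((30, 3))
    m = nc.fit_cca(X, Y)
    X_bad = X.copy()
    X_bad[:, 1] = 5.0
    with pytest.warns(UserWarning, match="zero-variance"):
        lt = nc.compute_loadings(m, X_bad, Y)
    assert np.isnan(lt.clinical_loadings[1]).all()
    assert lt.n_undefined == 1
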