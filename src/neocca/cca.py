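"""Canonical correlation analysis between a clinical block X and an imaging block Y.

CCA finds successive pairs of linear combinations ``U = X a`` and ``V = Y b``
maximizing ``corr(U_i, V_i)``, each pair uncorrelated with all preceding
pairs.  The solver works on the singular value decomposition of the whitened
cross-covariance: with orthonormal bases ``Q_x, Q_y`` of the centered column
spaces, the singular values of ``Q_x' Q_y`` are the canonical correlations
and the singular vectors map back to the canonical weights.  This closed
form is numerically stable and exactly equivalent to the classical
generalized eigenproblem on the covariance matrices.

Weights are scaled so every canonical variate has unit sample variance, and
the sign of each pair is fixed so the clinical variable with the largest
absolute loading loads positively (the CCA solution is otherwise only
defined up to a joint sign per pair).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CCAModel", "LoadingTable", "fit_cca", "compute_variates", "compute_loadings"]

# relative singular-value cutoff for declaring a block rank deficient
RANK_RTOL = 1e-10


def _as_matrix(data) -> np.ndarray:
    """Accept a bare array or anything exposing ``.values`` (ClinicalMatrix, DataFrame)."""
    if hasattr(data, "values"):
        data = data.values
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("matrix contains non-finite entries")
    return arr


@dataclass
class CCAModel:
    """Fitted canonical correlation model.

    Attributes
    ----------
    a, b
        Canonical weight matrices, ``(p, m)`` for the clinical side and
        ``(K, m)`` for the imaging side; variates have unit sample variance.
    r
        Canonical correlations, non-increasing, in ``[0, 1]``.
    U, V
        Training-data canonical variates, ``(n, m)`` each.
    x_mean, y_mean
        Column means used for centering; reapplied to new data.
    """

    a: np.ndarray
    b: np.ndarray
    r: np.ndarray
    U: np.ndarray
    V: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    m: int
    regularization: float = 0.0
    x_names: list[str] | None = None
    y_names: list[str] | None = None

    @property
    def n_subjects(self) -> int:
        return self.U.shape[0]


@dataclass
class LoadingTable:
    """Structure correlations of the original variables with the canonical variates.

    A loading is the marginal Pearson correlation of one original variable
    with the variate of its own block; it can disagree in sign with the
    corresponding canonical weight (the weight is the variable's *unique*
    contribution conditional on the others).  Inference fields (p-values,
    bootstrap intervals) are attached by :mod:`neocca.inference`.
    """

    clinical_loadings: np.ndarray  # (p, m)
    imaging_loadings: np.ndarray  # (K, m)
    x_names: list[str] | None = None
    y_names: list[str] | None = None
    clinical_p: np.ndarray | None = None
    imaging_p: np.ndarray | None = None
    clinical_ci: tuple[np.ndarray, np.ndarray] | None = None
    imaging_ci: tuple[np.ndarray, np.ndarray] | None = None
    n_undefined: int = 0


def _orthonormal_basis(mat: np.ndarray, label: str, regularization: float):
    """Return (basis Q, back-transform T) with ``mat @ T = Q`` up to whitening.

    For the exact solver, Q holds the left singular vectors spanning the
    centered data and T maps singular-vector coordinates to weight space.
    With ridge regularization the whitening uses the shrunk covariance, so
    Q is no longer exactly orthonormal — canonical correlations are then
    recomputed empirically from the variates.
    """
    n = mat.shape[0]
    if regularization > 0.0:
        cov = mat.T @ mat / (n - 1) + regularization * np.eye(mat.shape[1])
        evals, evecs = np.linalg.eigh(cov)
        white = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T  # cov^{-1/2}
        return mat @ white / np.sqrt(n - 1), white, mat.shape[1]
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    rank = int(np.sum(s > RANK_RTOL * s[0])) if s.size else 0
    if rank < mat.shape[1]:
        raise np.linalg.LinAlgError(
            f"block {label!r} is rank deficient ({rank} < {mat.shape[1]} columns); "
            "drop collinear variables or enable ridge regularization"
        )
    trans = vt.T @ np.diag(1.0 / s)  # maps SVD coordinates to column space
    return u, trans, rank


def fit_cca(X, Y, m: int | str = "max", regularization: float = 0.0,
            x_names: list[str] | None = None, y_names: list[str] | None = None) -> CCAModel:
    """Fit CCA between ``X`` (n × p) and ``Y`` (n × K).

    Parameters
    ----------
    m
        Number of canonical pairs, or ``"max"`` for ``min(p, K)``.
    regularization
        Ridge added to each block covariance before whitening.  Off by
        default: the intended regime is ``n`` well above both ``p`` and
        ``K``, where the exact solve applies.

    Raises
    ------
    numpy.linalg.LinAlgError
        If either block is rank deficient and regularization is off.
    """
    Xa = _as_matrix(X)
    Ya = _as_matrix(Y)
    if x_names is None and hasattr(X, "names"):
        x_names = list(X.names)
    if Xa.shape[0] != Ya.shape[0]:
        raise ValueError(f"subject counts differ: X has {Xa.shape[0]}, Y has {Ya.shape[0]}")
    n = Xa.shape[0]
    if n < 3:
        raise ValueError("CCA needs at least 3 subjects")

    x_mean = Xa.mean(axis=0)
    y_mean = Ya.mean(axis=0)
    Xc = Xa - x_mean
    Yc = Ya - y_mean

    Qx, Tx, rank_x = _orthonormal_basis(Xc, "X", regularization)
    Qy, Ty, rank_y = _orthonormal_basis(Yc, "Y", regularization)

    m_max = min(rank_x, rank_y, n - 1)
    m_out = m_max if m == "max" else int(m)
    if not 1 <= m_out <= m_max:
        raise ValueError(f"requested {m_out} pairs, only {m_max} identifiable")

    uc, s, vtc = np.linalg.svd(Qx.T @ Qy, full_matrices=False)
    if regularization > 0.0:
        a = Tx @ uc[:, :m_out]
        b = Ty @ vtc.T[:, :m_out]
        U = Xc @ a
        V = Yc @ b
        # rescale to unit-variance variates; correlation no longer equals s
        a /= U.std(axis=0, ddof=1)
        b /= V.std(axis=0, ddof=1)
        U = Xc @ a
        V = Yc @ b
        r = np.array([np.corrcoef(U[:, i], V[:, i])[0, 1] for i in range(m_out)])
    else:
        scale = np.sqrt(n - 1)
        a = Tx @ uc[:, :m_out] * scale
        b = Ty @ vtc.T[:, :m_out] * scale
        U = Xc @ a
        V = Yc @ b
        r = s[:m_out]
    r = np.clip(r, 0.0, 1.0)

    model = CCAModel(a=a, b=b, r=r, U=U, V=V, x_mean=x_mean, y_mean=y_mean,
                     m=m_out, regularization=regularization,
                     x_names=x_names, y_names=y_names)
    _fix_signs(model, Xc)
    return model


def _fix_signs(model: CCAModel, Xc: np.ndarray) -> None:
    """Flip each pair so the clinical variable with the largest |loading| loads positively."""
    x_sd = Xc.std(axis=0, ddof=1)
    u_sd = model.U.std(axis=0, ddof=1)
    loadings = (Xc.T @ model.U) / (model.n_subjects - 1) / np.outer(x_sd, u_sd)
    for i in range(model.m):
        j = int(np.argmax(np.abs(loadings[:, i])))
        if loadings[j, i] < 0:
            model.a[:, i] *= -1
            model.b[:, i] *= -1
            model.U[:, i] *= -1
            model.V[:, i] *= -1


def compute_variates(model: CCAModel, X, Y) -> tuple[np.ndarray, np.ndarray]:
    """Project (possibly new) data onto the fitted canonical weights.

    Data are centered with the training means; on the training data this
    reproduces the stored variates exactly.
    """
    Xa = _as_matrix(X)
    Ya = _as_matrix(Y)
    if Xa.shape[1] != model.a.shape[0]:
        raise ValueError(f"X has {Xa.shape[1]} columns, model expects {model.a.shape[0]}")
    if Ya.shape[1] != model.b.shape[0]:
        raise ValueError(f"Y has {Ya.shape[1]} columns, model expects {model.b.shape[0]}")
    return (Xa - model.x_mean) @ model.a, (Ya - model.y_mean) @ model.b


def _safe_corr(columns: np.ndarray, variates: np.ndarray) -> tuple[np.ndarray, int]:
    """Columnwise Pearson correlation of every column with every variate.

    Zero-variance columns yield NaN loadings (counted), with a warning.
    """
    n = columns.shape[0]
    cc = columns - columns.mean(axis=0)
    vc = variates - variates.mean(axis=0)
    c_sd = cc.std(axis=0, ddof=1)
    v_sd = vc.std(axis=0, ddof=1)
    bad = c_sd == 0
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(f"{n_bad} zero-variance column(s); loadings recorded as NaN")
    denom = np.outer(np.where(bad, np.nan, c_sd), v_sd)
    return (cc.T @ vc) / (n - 1) / denom, n_bad


def compute_loadings(model: CCAModel, X, Y) -> LoadingTable:
    """Correlate every original variable with the canonical variate of its own block."""
    Xa = _as_matrix(X)
    Ya = _as_matrix(Y)
    U, V = compute_variates(model, Xa, Ya)
    cl, bad_x = _safe_corr(Xa, U)
    il, bad_y = _safe_corr(Ya, V)
    return LoadingTable(clinical_loadings=cl, imaging_loadings=il,
                        x_names=model.x_names, y_names=model.y_names,
                        n_undefined=bad_x + bad_y)
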