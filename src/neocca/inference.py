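"""Resampling inference for canonical correlation models.

Three procedures:

* :func:`permutation_test_pairs` — significance of each canonical pair.
  Rows of the clinical block are shuffled against the imaging block; each
  permutation records the *maximum* canonical correlation of the refitted
  model, giving a single max-statistic null against which every observed
  pair is compared in order.  This yields monotone non-decreasing p-values
  across pairs and family-wise error control over the sequence of pairs.
  A step-down variant that residualizes out preceding pairs before each
  step is available behind ``method="stepdown"``.

* :func:`permutation_test_loadings` — significance of structure loadings,
  by default against the max-|r| null over all variables of the block
  (family-wise), switchable to per-variable nulls.

* :func:`bootstrap_cis` — percentile confidence intervals for canonical
  correlations, weights and loadings from refits on subject resamples,
  with greedy pair re-matching and sign alignment to the original model
  (bootstrap refits can reorder or flip pairs; the fraction that did is
  reported as a diagnostic).

All p-values use the add-one estimator ``(c + 1) / (P + 1)``, which is
valid (never zero) and makes the smallest attainable p-value at
``P = 10,000`` equal to ``1/10001 ≈ 0.0001``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cca import CCAModel, _as_matrix, _orthonormal_basis, compute_loadings, fit_cca

__all__ = [
    "PairPermutationResult",
    "BootstrapResult",
    "InferenceReport",
    "permutation_test_pairs",
    "permutation_test_loadings",
    "bootstrap_cis",
    "run_inference",
]


@dataclass
class PairPermutationResult:
    p_values: np.ndarray  # (m,) non-decreasing
    r_observed: np.ndarray  # (m,)
    null_max_r: np.ndarray  # (P,) max canonical correlation per permutation
    n_permutations: int
    seed: int | None
    method: str = "max"


@dataclass
class BootstrapResult:
    r_ci: tuple[np.ndarray, np.ndarray]  # (m,), (m,)
    a_ci: tuple[np.ndarray, np.ndarray]  # (p, m) each
    b_ci: tuple[np.ndarray, np.ndarray]  # (K, m) each
    clinical_loading_ci: tuple[np.ndarray, np.ndarray]
    imaging_loading_ci: tuple[np.ndarray, np.ndarray]
    r_samples: np.ndarray  # (B_kept, m)
    n_bootstrap: int
    n_dropped: int
    frac_reordered: float
    frac_sign_flipped: float
    level: float
    seed: int | None


@dataclass
class InferenceReport:
    """Assembled inference for one fitted CCA: pair p-values, CIs, loading inference."""

    model: CCAModel
    pair_test: PairPermutationResult
    bootstrap: BootstrapResult | None = None
    clinical_loading_p: np.ndarray | None = None
    imaging_loading_p: np.ndarray | None = None
    clinical_loadings: np.ndarray | None = None
    imaging_loadings: np.ndarray | None = None

    def pair_table(self, n_pairs: int | None = None) -> pd.DataFrame:
        """Per-pair summary: canonical correlation, bootstrap CI, permutation p."""
        m = self.model.m if n_pairs is None else min(n_pairs, self.model.m)
        cols = {
            "pair": np.arange(1, m + 1),
            "canonical_correlation": self.model.r[:m],
            "p": self.pair_test.p_values[:m],
        }
        if self.bootstrap is not None:
            cols["ci_lower"] = self.bootstrap.r_ci[0][:m]
            cols["ci_upper"] = self.bootstrap.r_ci[1][:m]
        return pd.DataFrame(cols)

    def loading_table(self, pair: int) -> pd.DataFrame:
        """Per-clinical-variable weights and loadings for one pair (0-based), sorted by |loading|."""
        i = pair
        names = self.model.x_names or [f"x{j}" for j in range(self.model.a.shape[0])]
        cols = {
            "variable": names,
            "weight": self.model.a[:, i],
            "loading": self.clinical_loadings[:, i],
        }
        if self.bootstrap is not None:
            cols["weight_ci_lower"] = self.bootstrap.a_ci[0][:, i]
            cols["weight_ci_upper"] = self.bootstrap.a_ci[1][:, i]
            cols["loading_ci_lower"] = self.bootstrap.clinical_loading_ci[0][:, i]
            cols["loading_ci_upper"] = self.bootstrap.clinical_loading_ci[1][:, i]
        if self.clinical_loading_p is not None:
            cols["p"] = self.clinical_loading_p[:, i]
        df = pd.DataFrame(cols)
        return df.reindex(df["loading"].abs().sort_values(ascending=False).index).reset_index(drop=True)


def _prepare_blocks(X, Y):
    Xa = _as_matrix(X)
    Ya = _as_matrix(Y)
    if Xa.shape[0] != Ya.shape[0]:
        raise ValueError(f"subject counts differ: {Xa.shape[0]} vs {Ya.shape[0]}")
    return Xa, Ya


def permutation_test_pairs(X, Y, P: int = 10_000, seed: int | None = None,
                           method: str = "max") -> PairPermutationResult:
    """Permutation significance for canonical pairs.

    Rows of the clinical block are randomly reordered against the imaging
    block ``P`` times; each refit's maximum canonical correlation forms the
    null.  ``p_k = (1 + #{max_r_perm >= r_k}) / (P + 1)``.
    """
    if P < 1:
        raise ValueError("P must be at least 1")
    Xa, Ya = _prepare_blocks(X, Y)
    n = Xa.shape[0]
    if n < 8:
        raise ValueError(f"n = {n} subjects is too few for a meaningful permutation test")

    model = fit_cca(Xa, Ya)
    rng = np.random.default_rng(seed)

    if method == "max":
        # permuting rows commutes with centering and the orthonormal basis,
        # so each permutation only needs one small SVD of Qx[perm]' Qy
        Qx, _, _ = _orthonormal_basis(Xa - Xa.mean(axis=0), "X", 0.0)
        Qy, _, _ = _orthonormal_basis(Ya - Ya.mean(axis=0), "Y", 0.0)
        null_max = np.empty(P)
        for i in range(P):
            perm = rng.permutation(n)
            null_max[i] = np.linalg.svd(Qx[perm].T @ Qy, compute_uv=False)[0]
        counts = (null_max[None, :] >= model.r[:, None]).sum(axis=1)
        p = (counts + 1.0) / (P + 1.0)
        p = np.maximum.accumulate(p)  # already monotone; guard fp ties
    elif method == "stepdown":
        p = _stepdown_pairs(Xa, Ya, model, P, rng)
        null_max = np.empty(0)
    else:
        raise ValueError(f"unknown method {method!r}")

    return PairPermutationResult(p_values=p, r_observed=model.r, null_max_r=null_max,
                                 n_permutations=P, seed=seed, method=method)


def _stepdown_pairs(Xa, Ya, model, P, rng):
    """Alternative reading: residualize out preceding observed variates per step."""
    n = Xa.shape[0]
    p_out = np.empty(model.m)
    Xr, Yr = Xa.copy(), Ya.copy()
    for k in range(model.m):
        if k > 0:
            u = model.U[:, k - 1:k]
            v = model.V[:, k - 1:k]
            for Z, w in ((Xr, u), (Yr, v)):
                Zc = Z - Z.mean(axis=0)
                beta = np.linalg.lstsq(w - w.mean(), Zc, rcond=None)[0]
                Z -= (w - w.mean()) @ beta
        try:
            Qx, _, _ = _orthonormal_basis(Xr - Xr.mean(axis=0), "X", 0.0)
            Qy, _, _ = _orthonormal_basis(Yr - Yr.mean(axis=0), "Y", 0.0)
        except np.linalg.LinAlgError:  # residualization exhausted a block
            p_out[k:] = 1.0
            break
        r_obs = np.linalg.svd(Qx.T @ Qy, compute_uv=False)[0]
        count = 0
        for _ in range(P):
            perm = rng.permutation(n)
            if np.linalg.svd(Qx[perm].T @ Qy, compute_uv=False)[0] >= r_obs:
                count += 1
        p_out[k] = (count + 1.0) / (P + 1.0)
    return np.maximum.accumulate(p_out)


def permutation_test_loadings(block, variates, P: int = 10_000, seed: int | None = None,
                              family: str = "max") -> np.ndarray:
    """Permutation p-values for the loadings of one block against its variates.

    The null shuffles subject rows of the block against the variates.  With
    ``family="max"`` (default) the null statistic is the maximum |r| across
    the block's variables — family-wise control over the block, under which
    a null variable sitting among strong ones gets a p-value near 1.
    ``family="per-variable"`` uses each variable's own null.

    Returns an array of shape ``(n_variables, n_pairs)``.
    """
    if P < 1:
        raise ValueError("P must be at least 1")
    B = _as_matrix(block)
    W = _as_matrix(variates)
    if B.shape[0] != W.shape[0]:
        raise ValueError(f"subject counts differ: {B.shape[0]} vs {W.shape[0]}")
    n = B.shape[0]
    if n < 8:
        raise ValueError(f"n = {n} subjects is too few for a meaningful permutation test")
    rng = np.random.default_rng(seed)

    def _std(Z):
        Zc = Z - Z.mean(axis=0)
        sd = Zc.std(axis=0, ddof=0)
        sd[sd == 0] = np.nan
        return Zc / sd

    Zb = _std(B)
    Zw = _std(W)
    r_obs = np.abs(Zb.T @ Zw) / n  # (p, m)

    exceed = np.zeros_like(r_obs)
    for _ in range(P):
        perm = rng.permutation(n)
        r_perm = np.abs(Zb[perm].T @ Zw) / n
        if family == "max":
            stat = np.nanmax(r_perm, axis=0, keepdims=True)  # (1, m)
        elif family == "per-variable":
            stat = r_perm
        else:
            raise ValueError(f"unknown family {family!r}")
        exceed += stat >= r_obs
    return (exceed + 1.0) / (P + 1.0)


def _align_to_reference(U_ref, V_ref, U_rep, V_rep):
    """Greedy-match replicate pairs to reference pairs by |variate correlation|.

    Returns (order, signs, reordered, flipped): for reference pair j, the
    replicate pair order[j] with sign signs[j].
    """
    m = U_ref.shape[1]

    def _corr(A, B):
        Ac = A - A.mean(axis=0)
        Bc = B - B.mean(axis=0)
        denom = np.outer(np.linalg.norm(Ac, axis=0), np.linalg.norm(Bc, axis=0))
        denom[denom == 0] = np.nan
        return (Ac.T @ Bc) / denom

    score = np.abs(_corr(U_ref, U_rep)) + np.abs(_corr(V_ref, V_rep))
    signed = _corr(U_ref, U_rep)
    order = np.full(m, -1)
    used = np.zeros(m, dtype=bool)
    flat = np.argsort(np.nan_to_num(score, nan=-np.inf), axis=None)[::-1]
    assigned = 0
    for idx in flat:
        j, k = divmod(idx, m)
        if order[j] == -1 and not used[k]:
            order[j] = k
            used[k] = True
            assigned += 1
            if assigned == m:
                break
    signs = np.where(np.nan_to_num(signed[np.arange(m), order]) < 0, -1.0, 1.0)
    reordered = bool(np.any(order != np.arange(m)))
    flipped = bool(np.any(signs < 0))
    return order, signs, reordered, flipped


def bootstrap_cis(X, Y, B: int = 10_000, level: float = 0.95, seed: int | None = None,
                  model: CCAModel | None = None, max_drop_frac: float = 0.10) -> BootstrapResult:
    """Percentile bootstrap intervals for correlations, weights and loadings.

    Subjects are resampled with replacement jointly across both blocks and
    the CCA refit per replicate.  Each replicate is aligned to the original
    model before accumulation: pairs are greedily matched on the absolute
    correlation between replicate and original variates (both computed on
    the original subjects), and signs fixed by the clinical-variate
    correlation.  Replicates whose resample loses rank are dropped and
    counted; more than ``max_drop_frac`` dropped is an error.
    """
    if B < 100:
        raise ValueError("B must be at least 100 for interval output")
    if not 0.5 < level < 1.0:
        raise ValueError("level must be in (0.5, 1)")
    Xa, Ya = _prepare_blocks(X, Y)
    n = Xa.shape[0]
    if model is None:
        model = fit_cca(Xa, Ya)
    m = model.m
    rng = np.random.default_rng(seed)

    r_s, a_s, b_s = [], [], []
    cl_s, il_s = [], []
    n_dropped = n_reordered = n_flipped = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(B):
            idx = rng.integers(0, n, size=n)
            try:
                rep = fit_cca(Xa[idx], Ya[idx], m=m)
            except (np.linalg.LinAlgError, ValueError):
                n_dropped += 1
                continue
            U_rep = (Xa - rep.x_mean) @ rep.a
            V_rep = (Ya - rep.y_mean) @ rep.b
            order, signs, reordered, flipped = _align_to_reference(model.U, model.V, U_rep, V_rep)
            n_reordered += reordered
            n_flipped += flipped
            r_s.append(rep.r[order])
            a_s.append(rep.a[:, order] * signs)
            b_s.append(rep.b[:, order] * signs)
            loads = compute_loadings(rep, Xa[idx], Ya[idx])
            cl_s.append(loads.clinical_loadings[:, order] * signs)
            il_s.append(loads.imaging_loadings[:, order] * signs)

    if n_dropped > max_drop_frac * B:
        raise RuntimeError(
            f"{n_dropped} of {B} bootstrap replicates were degenerate (rank loss); "
            "the data are too small or too collinear for a stable bootstrap"
        )

    kept = B - n_dropped
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2

    def _ci(samples):
        arr = np.asarray(samples)
        return (np.nanpercentile(arr, lo_q, axis=0), np.nanpercentile(arr, hi_q, axis=0))

    return BootstrapResult(
        r_ci=_ci(r_s), a_ci=_ci(a_s), b_ci=_ci(b_s),
        clinical_loading_ci=_ci(cl_s), imaging_loading_ci=_ci(il_s),
        r_samples=np.asarray(r_s), n_bootstrap=B, n_dropped=n_dropped,
        frac_reordered=n_reordered / kept, frac_sign_flipped=n_flipped / kept,
        level=level, seed=seed,
    )


def run_inference(X, Y, P: int = 10_000, B: int = 10_000, level: float = 0.95,
                  seed: int | None = None, loading_family: str = "max") -> InferenceReport:
    """Fit CCA and run the full inference battery (pair test, loading tests, bootstrap)."""
    Xa, Ya = _prepare_blocks(X, Y)
    model = fit_cca(X, Y)
    rng = np.random.default_rng(seed)
    child = lambda: int(rng.integers(0, 2**31 - 1))
    pair_test = permutation_test_pairs(Xa, Ya, P=P, seed=child())
    loads = compute_loadings(model, Xa, Ya)
    cl_p = permutation_test_loadings(Xa, model.U, P=P, seed=child(), family=loading_family)
    il_p = permutation_test_loadings(Ya, model.V, P=P, seed=child(), family=loading_family)
    boot = bootstrap_cis(Xa, Ya, B=B, level=level, seed=child(), model=model) if B else None
    return InferenceReport(model=model, pair_test=pair_test, bootstrap=boot,
                           clinical_loading_p=cl_p, imaging_loading_p=il_p,
                           clinical_loadings=loads.clinical_loadings,
                           imaging_loadings=loads.imaging_loadings)
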