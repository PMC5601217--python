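"""Voxel-wise loading maps for canonical variates, with permutation FWE correction.

For one canonical imaging variate V, every voxel's loading is its Pearson
correlation r(v) with V across subjects, converted to a t-statistic
``t = r·sqrt((n-2)/(1-r^2))``.  Family-wise error across voxels is
controlled with the max-statistic permutation scheme used by standard
neuroimaging permutation tools: the variate's subject rows are shuffled,
the maximum |t| over the modality's voxels recorded per permutation, and
``p_fwe(v) = (1 + #{max_t_perm >= |t_obs(v)|}) / (P + 1)``.  Correction is
per modality by default; a cross-modality max is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .decomposition import MultimodalDataset

__all__ = ["ModalityMaps", "LoadingMapSet", "voxelwise_loadings", "fwe_correct", "threshold_map"]


@dataclass
class ModalityMaps:
    """Statistical maps for one (modality, variate) combination, flat over the mask."""

    r: np.ndarray  # (V,) voxelwise loading; NaN where voxel variance is zero
    t: np.ndarray  # (V,) t-statistic; +-inf where |r| = 1
    p_fwe: np.ndarray | None = None
    sig_mask: np.ndarray | None = None
    n_undefined: int = 0


@dataclass
class LoadingMapSet:
    per_modality: dict[str, ModalityMaps]
    n_subjects: int
    variate_index: int | None = None
    n_permutations: int | None = None
    alpha: float | None = None


def _loading_stats(values: np.ndarray, variate: np.ndarray) -> ModalityMaps:
    n = values.shape[0]
    vc = variate - variate.mean()
    v_norm = np.linalg.norm(vc)
    xc = values - values.mean(axis=0)
    x_norm = np.linalg.norm(xc, axis=0)
    bad = x_norm == 0
    denom = np.where(bad, np.nan, x_norm) * v_norm
    r = (xc.T @ vc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        t[np.abs(r) == 1.0] = np.sign(r[np.abs(r) == 1.0]) * np.inf
    return ModalityMaps(r=r, t=t, n_undefined=int(bad.sum()))


def voxelwise_loadings(dataset: MultimodalDataset, variate: np.ndarray,
                       variate_index: int | None = None) -> LoadingMapSet:
    """Correlate every voxel of every modality with a canonical variate.

    Zero-variance voxels yield NaN maps and are counted; a constant variate
    is rejected outright.
    """
    variate = np.asarray(variate, dtype=float).ravel()
    if variate.std() == 0:
        raise ValueError("variate is constant; voxelwise loadings are undefined")
    if len(variate) != dataset.n_subjects:
        raise ValueError(f"variate length {len(variate)} != {dataset.n_subjects} subjects")
    per = {b.name: _loading_stats(b.values, variate) for b in dataset.blocks}
    return LoadingMapSet(per_modality=per, n_subjects=dataset.n_subjects,
                         variate_index=variate_index)


def fwe_correct(dataset: MultimodalDataset, variate: np.ndarray, P: int = 5000,
                seed: int | None = None, joint: bool = False,
                maps: LoadingMapSet | None = None) -> LoadingMapSet:
    """Max-statistic permutation FWE correction across voxels.

    ``joint=True`` pools the max statistic across all modalities (one
    family); the default corrects each modality separately.  Since t is
    monotone in |r| at fixed n, the permutation max is computed on |r|.
    """
    if P < 100:
        raise ValueError("P must be at least 100 for a usable corrected p-value")
    variate = np.asarray(variate, dtype=float).ravel()
    if maps is None:
        maps = voxelwise_loadings(dataset, variate)
    n = dataset.n_subjects
    rng = np.random.default_rng(seed)

    vc = variate - variate.mean()
    vc /= np.linalg.norm(vc)
    blocks = []
    for b in dataset.blocks:
        xc = b.values - b.values.mean(axis=0)
        norm = np.linalg.norm(xc, axis=0)
        ok = norm > 0
        blocks.append((b.name, xc[:, ok] / norm[ok], ok))

    max_r = np.empty((P, len(blocks)))
    for i in range(P):
        perm = vc[rng.permutation(n)]
        for j, (_, z, _) in enumerate(blocks):
            max_r[i, j] = np.max(np.abs(perm @ z)) if z.shape[1] else 0.0
    if joint:
        max_r = np.repeat(np.max(max_r, axis=1, keepdims=True), len(blocks), axis=1)

    for j, (name, _, ok) in enumerate(blocks):
        mm = maps.per_modality[name]
        r_obs = np.abs(np.nan_to_num(mm.r, nan=-np.inf))
        counts = (max_r[:, j][None, :] >= r_obs[:, None] - 1e-12).sum(axis=1)
        p = (counts + 1.0) / (P + 1.0)
        p[~ok] = np.nan
        mm.p_fwe = p
    maps.n_permutations = P
    return maps


def threshold_map(maps: LoadingMapSet, alpha: float = 0.01) -> LoadingMapSet:
    """Attach binary significance masks at level alpha (and the signed split via r).

    Warns when alpha is unattainable at the permutation count used.
    """
    if maps.n_permutations is None:
        raise ValueError("run fwe_correct before thresholding")
    if alpha < 1.0 / (maps.n_permutations + 1):
        warnings.warn(
            f"alpha={alpha} is below the permutation floor 1/{maps.n_permutations + 1}; "
            "no voxel can pass")
    for mm in maps.per_modality.values():
        mm.sig_mask = np.nan_to_num(mm.p_fwe, nan=np.inf) <= alpha
    maps.alpha = alpha
    return maps
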