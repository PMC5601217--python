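"""Multimodal linked decomposition: shared subject courses, per-modality spatial maps.

The model: every component k has one spatial map per imaging modality, all
tied to a single subject course c_k — the per-subject expression level of
that multimodal pattern.  Stacking the kept courses gives a parsimonious
n × K representation of the whole imaging dataset, which is the imaging
feature matrix entering CCA.

Estimation here is a deterministic pipeline: per-block variance
normalization → feature-wise concatenation → PCA whitening to at most
``max_components`` dimensions → FastICA rotation maximizing spatial
non-Gaussianity (deflation) → per-modality maps by least-squares regression
of each block onto the unit-variance courses.  Components are ordered by
explained variance, signs fixed so the largest-magnitude map entry is
positive, and components below an explained-variance share threshold can be
flagged rejected (dropped from the exported feature matrix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "MaskGeometry", "ModalityBlock", "MultimodalDataset", "ComponentDecomposition",
    "variance_normalize", "fit_linked", "reject_components",
]


@dataclass
class MaskGeometry:
    """Voxel grid underlying a flattened modality block."""

    grid_dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    mask_indices: np.ndarray  # linear indices into the grid, length V

    def __post_init__(self):
        self.mask_indices = np.asarray(self.mask_indices, dtype=np.int64)
        if self.mask_indices.max(initial=-1) >= int(np.prod(self.grid_dims)):
            raise ValueError("mask index exceeds grid volume")

    @property
    def n_voxels(self) -> int:
        return len(self.mask_indices)

    def unflatten(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Place a V-vector (or V × k matrix) back into the 3-D grid."""
        values = np.asarray(values)
        out = np.full(self.grid_dims + values.shape[1:], fill, dtype=float)
        out.reshape((-1,) + values.shape[1:])[self.mask_indices] = values
        return out


@dataclass
class ModalityBlock:
    name: str
    values: np.ndarray  # (n, V)
    geometry: MaskGeometry
    kind: str = "volume"  # or "skeleton"
    norm_scale: float | None = None  # set by variance_normalize

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"block {self.name!r}: expected 2-D (subjects × voxels)")
        if self.values.shape[1] != self.geometry.n_voxels:
            raise ValueError(
                f"block {self.name!r}: {self.values.shape[1]} columns but mask has "
                f"{self.geometry.n_voxels} voxels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"block {self.name!r} contains non-finite values")
        if self.kind not in ("volume", "skeleton"):
            raise ValueError(f"block kind must be 'volume' or 'skeleton', got {self.kind!r}")


@dataclass
class MultimodalDataset:
    """Named modality blocks over a common subject set."""

    blocks: list[ModalityBlock]
    subject_ids: list | None = None

    def __post_init__(self):
        ns = {b.values.shape[0] for b in self.blocks}
        if len(ns) > 1:
            raise ValueError(f"blocks disagree on subject count: {sorted(ns)}")
        if self.subject_ids is None:
            self.subject_ids = list(range(self.n_subjects))
        elif len(self.subject_ids) != self.n_subjects:
            raise ValueError("subject_ids length does not match blocks")

    @property
    def n_subjects(self) -> int:
        return self.blocks[0].values.shape[0]

    @property
    def modality_names(self) -> list[str]:
        return [b.name for b in self.blocks]

    def block(self, name: str) -> ModalityBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(f"no modality named {name!r}")

    def subset(self, row_idx: np.ndarray) -> "MultimodalDataset":
        ids = [self.subject_ids[i] for i in row_idx]
        return MultimodalDataset(
            blocks=[replace(b, values=b.values[row_idx]) for b in self.blocks],
            subject_ids=ids)


@dataclass
class ComponentDecomposition:
    """Result of the linked fit: courses, per-modality maps, bookkeeping."""

    subject_courses: np.ndarray  # (n, K), unit-variance columns
    spatial_maps: dict[str, np.ndarray]  # modality -> (V_m, K)
    modality_weights: dict[str, np.ndarray]  # modality -> (K,) map norms
    explained_variance_share: np.ndarray  # (K,), descending
    rejected: np.ndarray  # (K,) bool
    converged: bool
    n_iterations: int
    seed: int | None
    block_scales: dict[str, float]

    @property
    def n_components(self) -> int:
        return self.subject_courses.shape[1]

    @property
    def feature_matrix(self) -> np.ndarray:
        """Exported imaging feature matrix Y: kept subject courses only."""
        return self.subject_courses[:, ~self.rejected]

    @property
    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.rejected)

    def gram_condition_number(self) -> float:
        Y = self.feature_matrix
        s = np.linalg.svd(Y - Y.mean(axis=0), compute_uv=False)
        return float((s[0] / s[-1]) ** 2)


def variance_normalize(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Center each voxel across subjects and rescale the block to total variance 1.

    Puts modalities with different units and smoothness on a common footing
    before the linked fit.  Returns (normalized block, scale factor applied).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty block")
    centered = values - values.mean(axis=0)
    total_var = float(np.sum(centered.var(axis=0, ddof=1)))
    if total_var == 0:
        raise ValueError("block has zero variance; cannot normalize")
    scale = 1.0 / np.sqrt(total_var)
    return centered * scale, scale


def fit_linked(dataset: MultimodalDataset, max_components: int = 100,
               max_iterations: int = 5000, seed: int | None = 0,
               rotation_ev_floor: float = 1e-4) -> ComponentDecomposition:
    """Fit the linked decomposition of all modality blocks.

    The number of estimated components is ``min(max_components, n-1, rank)``.
    The independence rotation is applied only to the principal subspace whose
    eigenvalue share exceeds ``rotation_ev_floor``: dimensions at the noise
    floor are Gaussian to first order, where an ICA rotation is unidentifiable
    and only smears signal variance, so they are retained as unrotated
    principal components (and typically flagged by :func:`reject_components`).
    Non-convergence of the rotation within ``max_iterations`` is reported
    through the ``converged`` flag, not raised.
    """
    n = dataset.n_subjects
    total_v = sum(b.geometry.n_voxels for b in dataset.blocks)
    if max_components >= n:
        raise ValueError(f"max_components={max_components} must be below n={n}")
    if max_components > total_v:
        raise ValueError(f"max_components={max_components} exceeds total voxels {total_v}")

    normalized, scales = [], {}
    for b in dataset.blocks:
        norm, scale = variance_normalize(b.values)
        normalized.append(norm)
        scales[b.name] = scale
    concat = np.hstack(normalized)  # (n, sum V_m)

    u_svd, s, _ = np.linalg.svd(concat, full_matrices=False)
    rank = int(np.sum(s > 1e-10 * s[0]))
    d = min(max_components, n - 1, rank)
    ev_pca = s**2 / np.sum(s**2)
    d_rot = max(1, int(np.sum(ev_pca[:d] >= rotation_ev_floor)))

    ica = FastICA(n_components=d_rot, algorithm="deflation", fun="logcosh",
                  whiten="unit-variance", max_iter=max_iterations, tol=1e-5,
                  random_state=None if seed is None else int(seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        # voxels are samples: spatial sources independent, mixing = subject courses
        ica.fit(concat.T)
    converged = int(ica.n_iter_) < max_iterations
    courses = ica.mixing_.astype(float)  # (n, d_rot)
    if d_rot < d:  # append the unrotated noise-floor principal components
        courses = np.hstack([courses, u_svd[:, d_rot:d] * np.sqrt(n - 1)])

    courses -= courses.mean(axis=0)
    sd = courses.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    courses /= sd

    # per-modality maps by joint least squares of each block on the courses
    pinv = np.linalg.pinv(courses)
    maps = {b.name: (pinv @ norm).T for b, norm in zip(dataset.blocks, normalized)}

    total_ss = sum(float(np.sum(norm**2)) for norm in normalized)
    ev = np.zeros(d)
    course_ss = np.sum(courses**2, axis=0)
    for w in maps.values():
        ev += course_ss * np.sum(w**2, axis=0)
    ev_share = ev / total_ss

    order = np.argsort(ev_share)[::-1]
    courses = courses[:, order]
    ev_share = ev_share[order]
    maps = {k: v[:, order] for k, v in maps.items()}

    # sign: largest-|entry| across all modality maps is positive
    stacked = np.vstack(list(maps.values()))  # (sum V_m, d)
    flip = np.sign(stacked[np.argmax(np.abs(stacked), axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    courses *= flip
    maps = {k: v * flip for k, v in maps.items()}

    weights = {k: np.linalg.norm(v, axis=0) for k, v in maps.items()}
    return ComponentDecomposition(
        subject_courses=courses, spatial_maps=maps, modality_weights=weights,
        explained_variance_share=ev_share, rejected=np.zeros(d, dtype=bool),
        converged=converged, n_iterations=ica.n_iter_, seed=seed, block_scales=scales,
    )


def reject_components(decomp: ComponentDecomposition,
                      criterion_threshold: float = 1e-4) -> ComponentDecomposition:
    """Flag components with explained-variance share below the threshold as rejected.

    Rejected components stay in the decomposition for inspection but are
    excluded from the exported feature matrix.
    """
    if criterion_threshold < 0:
        raise ValueError("threshold must be nonnegative")
    rejected = decomp.explained_variance_share < criterion_threshold
    if rejected.all():
        raise ValueError(
            f"threshold {criterion_threshold} rejects every component; the largest "
            f"share is {decomp.explained_variance_share.max():.3g} — lower the threshold")
    return replace(decomp, rejected=rejected)
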