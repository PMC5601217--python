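"""Synthetic multimodal imaging + clinical + outcome data with known planted structure.

The generator reproduces the *statistical* structure the analysis pipeline
assumes, not the physics of MR acquisition: K latent components (standard
normal subject courses) drive between-subject variation in every modality
through sparse, spatially smoothed blob maps; a clinical table of mixed
continuous and binary factors is linearly linked to a chosen subset of
latents at specified population canonical correlations; developmental
outcome scores (mean 100, sd 15, the BSID-III convention) are linearly
linked to chosen variates.  Everything is reproducible from a single seed,
so planted quantities — canonical correlations, signal blobs, outcome
effects — serve as ground truth for recovery tests downstream.

:func:`study_spec` builds the default configuration emulating the cohort
the pipeline is designed around: 449 preterm infants, 4 modality blocks
(T1w Jacobian volumes, T2w intensity volumes, white-matter FA skeleton,
gray-matter MD skeleton), ~30 clinical factors with realistic prevalences,
one missing clinical entry, and 425 of 449 subjects with outcome follow-up.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .clinical import ClinicalTable
from .decomposition import MaskGeometry, ModalityBlock, MultimodalDataset

__all__ = [
    "ModalitySpec", "ClinicalVariableSpec", "OutcomeSpec", "SimulationSpec",
    "LatentMatrix", "generate_latents", "generate_spatial_maps",
    "generate_multimodal", "generate_clinical", "generate_outcomes",
    "study_spec", "simulate_study",
]

FWHM_TO_SIGMA = 1.0 / math.sqrt(8.0 * math.log(2.0))


@dataclass
class ModalitySpec:
    name: str
    grid_dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 0.1
    smooth_fwhm_mm: float = 0.0
    signal_scale: float = 1.0
    kind: str = "volume"


@dataclass
class ClinicalVariableSpec:
    name: str
    kind: str  # "continuous" | "binary"
    prevalence: float | None = None  # binary only
    linked_component: int | None = None
    link_strength: float = 0.0
    loc: float = 0.0  # continuous display shift/scale
    scale: float = 1.0
    summary_stat: str = "median"
    units: str = ""


@dataclass
class OutcomeSpec:
    name: str
    linked_pair: int | None = None
    effect_r: float = 0.0


@dataclass
class SimulationSpec:
    """Full description of one synthetic study."""

    n_subjects: int
    k_components: int
    modality_specs: list[ModalitySpec]
    clinical_spec: list[ClinicalVariableSpec]
    n_active_per_map: int = 20
    planted_rho: tuple[float, ...] = ()
    outcome_spec: list[OutcomeSpec] = field(default_factory=list)
    missing_spec: list[tuple[str, int]] = field(default_factory=list)
    n_outcome_missing: int | None = None  # None → proportional default (24 of 449)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ValueError(f"n_subjects must be positive, got {self.n_subjects}")
        if self.k_components <= 0:
            raise ValueError(f"k_components must be positive, got {self.k_components}")
        if self.n_active_per_map <= 0:
            raise ValueError(f"n_active_per_map must be positive, got {self.n_active_per_map}")
        rho = tuple(self.planted_rho)
        if any(not 0 < r <= 1 for r in rho):
            raise ValueError("planted_rho entries must lie in (0, 1]")
        if any(a <= b for a, b in zip(rho, rho[1:])):
            raise ValueError("planted_rho must be strictly descending")
        for ms in self.modality_specs:
            if ms.noise_sd < 0 or ms.smooth_fwhm_mm < 0:
                raise ValueError(f"modality {ms.name!r}: noise_sd and smooth_fwhm_mm must be nonnegative")
            if int(np.prod(ms.grid_dims)) < self.n_active_per_map:
                raise ValueError(f"modality {ms.name!r}: grid volume below n_active_per_map")
        for cv in self.clinical_spec:
            if cv.kind not in ("continuous", "binary"):
                raise ValueError(f"variable {cv.name!r}: unknown kind {cv.kind!r}")
            if cv.kind == "binary" and not (cv.prevalence and 0 < cv.prevalence < 1):
                raise ValueError(f"variable {cv.name!r}: binary prevalence must be in (0, 1)")
            if not 0 <= cv.link_strength <= 1:
                raise ValueError(f"variable {cv.name!r}: link_strength must be in [0, 1]")
            if cv.linked_component is not None and not 0 <= cv.linked_component < self.k_components:
                raise ValueError(f"variable {cv.name!r}: linked_component out of range")
        for os_ in self.outcome_spec:
            if not -1 <= os_.effect_r <= 1:
                raise ValueError(f"outcome {os_.name!r}: effect_r must be in [-1, 1]")
        if self.n_subjects <= len(self.clinical_spec) + self.k_components:
            raise ValueError(
                f"n_subjects={self.n_subjects} must exceed clinical variables "
                f"({len(self.clinical_spec)}) + components ({self.k_components}) for CCA identifiability")


@dataclass
class LatentMatrix:
    """Shared subject courses driving all modalities; exactly standardized columns."""

    values: np.ndarray  # (n, k)
    seed: int


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent child generator per stage so stages don't perturb each other."""
    tag = zlib.crc32(stream.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, tag]))


def generate_latents(spec: SimulationSpec) -> LatentMatrix:
    """Independent standard-normal latents, then exactly standardized per column."""
    rng = _rng(spec.seed, "latents")
    z = rng.standard_normal((spec.n_subjects, spec.k_components))
    z -= z.mean(axis=0)
    z /= z.std(axis=0, ddof=0)
    return LatentMatrix(values=z, seed=spec.seed)


def _grow_blob(rng, dims, n_active, taken):
    """Grow a contiguous random blob of n_active voxels avoiding `taken` voxels."""
    free = np.flatnonzero(~taken)
    if len(free) < n_active:
        return None
    grid = np.zeros(dims, dtype=bool)
    start = free[rng.integers(len(free))]
    blob = [start]
    in_blob = {int(start)}
    frontier = [int(start)]
    strides = (dims[1] * dims[2], dims[2], 1)
    shape = dims
    while len(blob) < n_active and frontier:
        idx = frontier[rng.integers(len(frontier))]
        i, j, k = np.unravel_index(idx, shape)
        nbrs = []
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + di, j + dj, k + dk
            if 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]:
                lin = ni * strides[0] + nj * strides[1] + nk
                if lin not in in_blob and not taken[lin]:
                    nbrs.append(lin)
        if not nbrs:
            frontier.remove(idx)
            continue
        pick = nbrs[rng.integers(len(nbrs))]
        blob.append(pick)
        in_blob.add(int(pick))
        frontier.append(int(pick))
    if len(blob) < n_active:
        return None
    return np.asarray(blob, dtype=np.int64)


def generate_spatial_maps(spec: SimulationSpec) -> dict[str, np.ndarray]:
    """Per modality: a V × k map matrix of disjoint contiguous blobs, smoothed, unit norm.

    Blobs of ``n_active_per_map`` voxels are placed disjointly per modality
    (spatial independence by construction), then Gaussian-smoothed on the
    grid (σ = FWHM / √(8 ln 2)) and rescaled to unit Euclidean norm.
    """
    rng = _rng(spec.seed, "maps")
    out: dict[str, np.ndarray] = {}
    for ms in spec.modality_specs:
        dims = tuple(ms.grid_dims)
        vol = int(np.prod(dims))
        if spec.k_components * spec.n_active_per_map > vol:
            raise ValueError(
                f"modality {ms.name!r}: cannot place {spec.k_components} disjoint blobs of "
                f"{spec.n_active_per_map} voxels in a {vol}-voxel grid; enlarge the grid or "
                "shrink n_active_per_map")
        taken = np.zeros(vol, dtype=bool)
        cols = np.zeros((vol, spec.k_components))
        for k in range(spec.k_components):
            blob = None
            for _ in range(50):  # retries: BFS can stall in a fragmented grid
                blob = _grow_blob(rng, dims, spec.n_active_per_map, taken)
                if blob is not None:
                    break
            if blob is None:
                raise ValueError(
                    f"modality {ms.name!r}: failed to place disjoint blob {k + 1} of "
                    f"{spec.k_components}; enlarge the grid or shrink n_active_per_map")
            taken[blob] = True
            cols[blob, k] = 1.0
        if ms.smooth_fwhm_mm > 0:
            sigma_vox = [ms.smooth_fwhm_mm * FWHM_TO_SIGMA / v for v in ms.voxel_size_mm]
            for k in range(spec.k_components):
                cols[:, k] = gaussian_filter(cols[:, k].reshape(dims), sigma_vox).ravel()
        cols /= np.linalg.norm(cols, axis=0)
        out[ms.name] = cols
    return out


def generate_multimodal(latents: LatentMatrix, maps: dict[str, np.ndarray],
                        spec: SimulationSpec) -> MultimodalDataset:
    """Assemble modality blocks: ``block_m = scale_m · Z A_mᵀ + noise``.

    Noise is i.i.d. Gaussian per voxel; when the modality is smoothed the
    noise is smoothed at the same FWHM and rescaled back to its nominal
    marginal sd, giving spatially correlated noise of the stated amplitude.
    """
    rng = _rng(spec.seed, "noise")
    z = latents.values
    blocks = []
    for ms in spec.modality_specs:
        a = maps[ms.name]
        if a.shape[1] != z.shape[1]:
            raise ValueError(
                f"modality {ms.name!r}: maps have {a.shape[1]} components, latents have {z.shape[1]}")
        signal = ms.signal_scale * (z @ a.T)
        if ms.noise_sd > 0:
            dims = tuple(ms.grid_dims)
            noise = rng.standard_normal(signal.shape)
            if ms.smooth_fwhm_mm > 0:
                sigma_vox = [ms.smooth_fwhm_mm * FWHM_TO_SIGMA / v for v in ms.voxel_size_mm]
                sm = np.empty_like(noise)
                for s_i in range(noise.shape[0]):
                    sm[s_i] = gaussian_filter(noise[s_i].reshape(dims), sigma_vox).ravel()
                sm_sd = sm.std()
                noise = sm / sm_sd if sm_sd > 0 else sm
            signal = signal + ms.noise_sd * noise
        geom = MaskGeometry(grid_dims=tuple(ms.grid_dims), voxel_size_mm=tuple(ms.voxel_size_mm),
                            mask_indices=np.arange(int(np.prod(ms.grid_dims))))
        blocks.append(ModalityBlock(name=ms.name, values=signal, geometry=geom, kind=ms.kind))
    return MultimodalDataset(blocks=blocks)


def generate_clinical(latents: LatentMatrix, spec: SimulationSpec) -> ClinicalTable:
    """Clinical table linked to the latents.

    A linked continuous variable is ``s·Z_j + √(1−s²)·ε`` shifted/scaled to
    its clinical range; a linked binary variable thresholds that same latent
    mixture at the quantile matching its prevalence.  With one linked
    continuous variable per latent, the population canonical correlation
    between the clinical block and the latent block for pair j is exactly
    the link strength s (thresholding attenuates binary links below s).
    Declared missing entries are blanked at random subject positions.
    """
    from scipy.stats import norm

    rng = _rng(spec.seed, "clinical")
    z = latents.values
    n = spec.n_subjects
    data = {}
    kinds, units, stat = {}, {}, {}
    for cv in spec.clinical_spec:
        s = cv.link_strength if cv.linked_component is not None else 0.0
        base = np.sqrt(max(0.0, 1 - s**2)) * rng.standard_normal(n)
        if cv.linked_component is not None:
            base = s * z[:, cv.linked_component] + base
        if cv.kind == "continuous":
            data[cv.name] = cv.loc + cv.scale * base
        else:
            thresh = norm.ppf(1 - cv.prevalence)
            data[cv.name] = (base > thresh).astype(float)
        kinds[cv.name] = cv.kind
        units[cv.name] = cv.units
        stat[cv.name] = cv.summary_stat
    df = pd.DataFrame(data, index=pd.RangeIndex(n, name="subject"))
    for var, n_missing in spec.missing_spec:
        if var not in df.columns:
            raise KeyError(f"missing_spec names unknown variable {var!r}")
        rows = rng.choice(n, size=n_missing, replace=False)
        df.loc[df.index[rows], var] = np.nan
    return ClinicalTable(data=df, kinds=kinds, units=units, summary_stat=stat)


def generate_outcomes(variates: np.ndarray, spec: SimulationSpec,
                      mean: float = 100.0, sd: float = 15.0) -> pd.DataFrame:
    """Outcome scores on the developmental-scale calibration (mean 100, sd 15).

    ``score = mean + sd·(effect_r·standardized variate + √(1−effect_r²)·ε)``.
    A subset of subjects has missing outcomes (default proportional to
    24 of 449, emulating incomplete follow-up).
    """
    rng = _rng(spec.seed, "outcomes")
    variates = np.atleast_2d(np.asarray(variates, dtype=float))
    if variates.shape[0] != spec.n_subjects:
        variates = variates.T
    n, q = variates.shape
    out = {}
    for os_ in spec.outcome_spec:
        eff = os_.effect_r
        noise = np.sqrt(max(0.0, 1 - eff**2)) * rng.standard_normal(n)
        if os_.linked_pair is not None:
            if not 0 <= os_.linked_pair < q:
                raise KeyError(f"outcome {os_.name!r}: linked_pair {os_.linked_pair} "
                               f"out of range for {q} variates")
            v = variates[:, os_.linked_pair]
            v = (v - v.mean()) / v.std(ddof=0)
            out[os_.name] = mean + sd * (eff * v + noise)
        else:
            out[os_.name] = mean + sd * noise
    df = pd.DataFrame(out, index=pd.RangeIndex(n, name="subject"))
    n_miss = spec.n_outcome_missing
    if n_miss is None:
        n_miss = int(round(n * 24 / 449))
    if n_miss:
        rows = rng.choice(n, size=n_miss, replace=False)
        df.iloc[rows] = np.nan
    return df


# ---------------------------------------------------------------------------
# Default study configuration

# binary cohort factors and their prevalences (positive-case fractions)
_STUDY_BINARY = [
    ("male", 0.5033), ("nonsingleton", 0.3207),
    ("pregnancy_hypertension", 0.1849), ("hypertension", 0.0489),
    ("premature_rupture_membranes", 0.1604), ("antenatal_hemorrhage", 0.1314),
    ("accidental_hemorrhage", 0.0379), ("urinary_tract_infection", 0.0245),
    ("gestational_diabetes", 0.0445), ("oligohydramnios", 0.0757),
    ("polyhydramnios", 0.0045), ("drug_abuse", 0.0133),
    ("in_vitro_fertilization", 0.1447), ("bacterial_infection", 0.0579),
    ("caesarean_section", 0.6503), ("elective_caesarean", 0.0869),
    ("twin_twin_transfusion", 0.0200), ("chorioamnionitis", 0.0668),
    ("iugr", 0.1470), ("incomplete_steroids", 0.1514),
    ("surfactant", 0.5278), ("patent_ductus_arteriosus", 0.0512),
    ("nec_surgery", 0.0200), ("formula_feeding", 0.6038),
    ("no_maternal_breast_milk", 0.1462),
]

# continuous cohort measures: (name, loc, scale, summary stat, units)
_STUDY_CONTINUOUS = [
    ("gestational_age_birth", 30.1, 2.4, "median", "weeks"),
    ("birth_weight", 1305.0, 420.0, "median", "g"),
    ("mechanical_ventilation_days", 2.89, 6.0, "mean", "days"),
    ("cpap_days", 16.74, 18.0, "mean", "days"),
    ("parenteral_nutrition_days", 8.92, 14.0, "mean", "days"),
    ("deprivation_index", 17.57, 11.0, "median", ""),
    ("mothers_age", 32.75, 5.6, "median", "years"),
]

# which continuous variable carries each planted canonical pair
_STUDY_LINKS = ["gestational_age_birth", "birth_weight", "mechanical_ventilation_days"]


def study_spec(n_subjects: int = 449, k_components: int = 8,
               planted_rho: tuple[float, ...] = (0.9, 0.7, 0.5),
               grid_dims: tuple[int, int, int] = (16, 16, 8),
               noise_sd: float = 0.02, seed: int = 0,
               include_icv: bool = False,
               outcome_effects: tuple[float, ...] = (0.15, 0.25, 0.3)) -> SimulationSpec:
    """Default simulation emulating the neonatal multimodal cohort.

    Four modality blocks (volumetric T1w-Jacobian and T2w-intensity maps
    smoothed to 8 mm FWHM; FA and MD skeletons, unsmoothed), ~30 clinical
    factors with the cohort's prevalences, one missing parenteral-nutrition
    entry, and planted canonical links carried by one continuous variable
    per latent component at strength equal to the target correlation.
    ``include_icv`` adds an intracranial-volume variable tied to its own
    dedicated latent component, for the sensitivity analysis that appends
    ICV to the clinical block.
    """
    if len(planted_rho) > min(k_components, len(_STUDY_LINKS)):
        raise ValueError("more planted correlations than available linked variables")
    modalities = [
        ModalitySpec("t1_jacobian", grid_dims, (1.0, 1.0, 1.0), noise_sd, smooth_fwhm_mm=4.0),
        ModalitySpec("t2_intensity", grid_dims, (1.0, 1.0, 1.0), noise_sd, smooth_fwhm_mm=4.0),
        ModalitySpec("fa_skeleton", grid_dims, (1.0, 1.0, 1.0), noise_sd, smooth_fwhm_mm=0.0, kind="skeleton"),
        ModalitySpec("md_skeleton", grid_dims, (1.0, 1.0, 1.0), noise_sd, smooth_fwhm_mm=0.0, kind="skeleton"),
    ]
    clin = []
    for i, (name, loc, scale, stat, unit) in enumerate(_STUDY_CONTINUOUS):
        link = _STUDY_LINKS.index(name) if name in _STUDY_LINKS[:len(planted_rho)] else None
        strength = planted_rho[link] if link is not None else 0.0
        clin.append(ClinicalVariableSpec(name, "continuous", linked_component=link,
                                         link_strength=strength, loc=loc, scale=scale,
                                         summary_stat=stat, units=unit))
    for name, prev in _STUDY_BINARY:
        clin.append(ClinicalVariableSpec(name, "binary", prevalence=prev))
    if include_icv:
        icv_component = len(planted_rho)  # a latent not carrying a planted pair
        if icv_component >= k_components:
            raise ValueError("k_components too small to dedicate a component to ICV")
        clin.append(ClinicalVariableSpec("ICV", "continuous", linked_component=icv_component,
                                         link_strength=0.85, loc=430.0, scale=55.0,
                                         summary_stat="mean", units="cm^3"))
    outcomes = [
        OutcomeSpec("cognitive", linked_pair=1 if len(planted_rho) > 1 else 0,
                    effect_r=outcome_effects[1]),
        OutcomeSpec("language", linked_pair=0, effect_r=outcome_effects[0]),
        OutcomeSpec("motor", linked_pair=min(2, len(planted_rho) - 1),
                    effect_r=outcome_effects[2]),
    ]
    return SimulationSpec(
        n_subjects=n_subjects, k_components=k_components, modality_specs=modalities,
        clinical_spec=clin, n_active_per_map=20, planted_rho=tuple(planted_rho),
        outcome_spec=outcomes, missing_spec=[("parenteral_nutrition_days", 1)], seed=seed,
    )


def simulate_study(spec: SimulationSpec):
    """Generate the full study bundle: (dataset, clinical table, outcomes, latents, maps).

    Outcomes are linked to the *latent* components carrying each planted
    pair (the population-level canonical variates); a pipeline run then
    regresses its estimated imaging variates against them.
    """
    latents = generate_latents(spec)
    maps = generate_spatial_maps(spec)
    dataset = generate_multimodal(latents, maps, spec)
    clinical = generate_clinical(latents, spec)
    n_pairs = max((o.linked_pair or 0) for o in spec.outcome_spec) + 1 if spec.outcome_spec else 1
    outcomes = generate_outcomes(latents.values[:, :max(n_pairs, 1)], spec)
    return dataset, clinical, outcomes, latents, maps
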