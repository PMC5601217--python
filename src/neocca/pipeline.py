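"""End-to-end orchestration: encode -> decompose -> CCA -> inference -> maps -> outcome.

A :class:`PipelineConfig` holds every stage parameter plus the
sensitivity-analysis switches (append ICV, drop lesion subjects, remove
pathology components, skew transforms, rare-factor filtering).  One global
seed is expanded into per-stage child seeds by hashing the stage name, so
toggling one stage never perturbs another stage's randomness.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .cca import fit_cca
from .clinical import ClinicalTable, drop_subjects, encode, filter_rare, transform_skewed
from .decomposition import MultimodalDataset, fit_linked, reject_components
from .inference import run_inference
from .maps import fwe_correct, threshold_map, voxelwise_loadings
from .outcome import outcome_table

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "child_seed"]


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed and stage name."""
    return (seed * 0x9E3779B1 + zlib.crc32(stage.encode())) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    max_components: int = 20
    component_reject_threshold: float = 1e-4
    perms: int = 1000
    boot: int = 1000
    alpha_pairs: float = 0.05
    alpha_maps: float = 0.01
    map_perms: int = 1000
    report_pairs: int = 10
    scale_binary: bool = False
    loading_family: str = "max"
    outcome_method: str = "bonferroni"
    # sensitivity-analysis variants
    include_icv: bool = False
    icv_column: str = "ICV"
    drop_lesion_ids: list = field(default_factory=list)
    remove_pathology_components: list = field(default_factory=list)
    transforms: dict = field(default_factory=dict)
    rare_factor_threshold: float | None = None
    compute_maps: bool = False
    map_pairs: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha_pairs < 1 or not 0 < self.alpha_maps < 1:
            raise ValueError("alpha levels must be in (0, 1)")
        if self.perms < 1:
            raise ValueError("perms must be positive")
        if self.max_components < 1:
            raise ValueError("max_components must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


@dataclass
class PipelineResult:
    config: PipelineConfig
    clinical_matrix: "ClinicalMatrix"
    decomposition: "ComponentDecomposition"
    report: "InferenceReport"
    n_significant_pairs: int
    outcomes: pd.DataFrame | None = None
    maps: list = field(default_factory=list)
    dropped_rare: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def result_hash(self) -> str:
        """Stable digest of the numerical outputs, for determinism checks."""
        h = hashlib.sha256()
        for arr in (self.clinical_matrix.values, self.decomposition.subject_courses,
                    self.report.model.r, self.report.pair_test.p_values):
            h.update(np.ascontiguousarray(np.round(arr, 12)).tobytes())
        if self.outcomes is not None:
            h.update(self.outcomes.round(12).to_csv().encode())
        return h.hexdigest()


def run_pipeline(dataset: MultimodalDataset, clinical: ClinicalTable,
                 outcomes: pd.DataFrame | None = None,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full analysis on in-memory inputs.

    Stages: subject exclusion -> rare-factor filter -> encode (+transforms)
    -> variance-normalized linked decomposition -> component rejection ->
    CCA -> permutation + bootstrap inference -> optional voxel maps ->
    outcome regression.  Deterministic given the config (including seed).
    """
    config = config or PipelineConfig()
    stage = "init"
    try:
        # ---- subject exclusion, applied consistently to every structure
        stage = "drop_subjects"
        if config.drop_lesion_ids:
            clinical = drop_subjects(clinical, config.drop_lesion_ids)
            keep = [i for i, sid in enumerate(dataset.subject_ids)
                    if sid not in set(config.drop_lesion_ids)]
            dataset = dataset.subset(np.asarray(keep))
            if outcomes is not None:
                outcomes = outcomes.drop(index=config.drop_lesion_ids)

        # ---- clinical encoding
        stage = "clinical_encoding"
        dropped_rare: list = []
        if not config.include_icv and config.icv_column in clinical.names:
            clinical = ClinicalTable(
                data=clinical.data.drop(columns=[config.icv_column]),
                kinds={k: v for k, v in clinical.kinds.items() if k != config.icv_column},
                units={k: v for k, v in clinical.units.items() if k != config.icv_column},
                summary_stat={k: v for k, v in clinical.summary_stat.items()
                              if k != config.icv_column})
        if config.rare_factor_threshold is not None:
            clinical, dropped_rare = filter_rare(clinical, config.rare_factor_threshold)
        # constant columns carry no information and break correlation: drop, recorded
        constant = [c for c in clinical.names
                    if clinical.data[c].dropna().nunique() < 2]
        if constant:
            clinical = ClinicalTable(
                data=clinical.data.drop(columns=constant),
                kinds={k: v for k, v in clinical.kinds.items() if k not in constant},
                units={k: v for k, v in clinical.units.items() if k not in constant},
                summary_stat={k: v for k, v in clinical.summary_stat.items()
                              if k not in constant})
        X = encode(clinical, scale_binary=config.scale_binary)
        if config.transforms:
            X = transform_skewed(X, {k: v for k, v in config.transforms.items()
                                     if k in X.names})

        # ---- linked decomposition
        stage = "linked_decomposition"
        decomp = fit_linked(dataset, max_components=config.max_components,
                            seed=child_seed(config.seed, "decomposition"))
        decomp = reject_components(decomp, config.component_reject_threshold)
        if config.remove_pathology_components:
            rej = decomp.rejected.copy()
            rej[list(config.remove_pathology_components)] = True
            decomp.rejected = rej
        Y = decomp.feature_matrix

        # ---- CCA + inference
        stage = "cca_inference"
        report = run_inference(X.values, Y, P=config.perms, B=config.boot,
                               seed=child_seed(config.seed, "inference"),
                               loading_family=config.loading_family)
        report.model.x_names = X.names
        n_sig = int(np.sum(report.pair_test.p_values <= config.alpha_pairs))

        # ---- voxel maps for the leading pairs
        stage = "voxel_maps"
        map_sets = []
        if config.compute_maps:
            for i in range(min(config.map_pairs, report.model.m)):
                ms = voxelwise_loadings(dataset, report.model.V[:, i], variate_index=i)
                ms = fwe_correct(dataset, report.model.V[:, i], P=config.map_perms,
                                 seed=child_seed(config.seed, f"maps{i}"), maps=ms)
                map_sets.append(threshold_map(ms, config.alpha_maps))

        # ---- outcome regression
        stage = "outcome_assoc"
        out_tab = None
        if outcomes is not None:
            n_var = min(config.report_pairs, report.model.m)
            out_tab = outcome_table(report.model.V[:, :n_var], outcomes,
                                    method=config.outcome_method)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest = {
        "package": "neocca",
        "version": __version__,
        "config": config.to_dict(),
        "n_subjects": dataset.n_subjects,
        "n_clinical": len(X.names),
        "n_components_kept": int((~decomp.rejected).sum()),
        "dropped_constant": constant,
        "stage_seeds": {s: child_seed(config.seed, s)
                        for s in ("decomposition", "inference")},
    }
    return PipelineResult(config=config, clinical_matrix=X, decomposition=decomp,
                          report=report, n_significant_pairs=n_sig, outcomes=out_tab,
                          maps=map_sets, dropped_rare=dropped_rare, manifest=manifest)
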