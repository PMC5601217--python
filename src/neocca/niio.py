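"""Standard-format I/O: NIfTI volumes for imaging blocks, TSV tables, JSON results.

Each modality block is stored as one 4-D NIfTI (subjects on the 4th axis)
plus a 3-D binary mask defining the voxels inside the flat matrix; clinical
and outcome tables as TSV with an explicit subject-id column; geometry
mismatches and id mismatches are rejected, and tables are auto-aligned to
the imaging subject order by id.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .clinical import ClinicalTable
from .decomposition import MaskGeometry, ModalityBlock, MultimodalDataset

__all__ = [
    "write_dataset", "read_dataset", "write_table", "read_clinical",
    "read_outcomes", "write_json", "write_decomposition_maps",
]

MISSING_TOKEN = ""  # empty cell


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def write_dataset(dataset: MultimodalDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write one 4-D NIfTI + mask per modality and a subjects TSV; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for b in dataset.blocks:
        g = b.geometry
        vol = np.zeros(g.grid_dims + (dataset.n_subjects,), dtype=np.float32)
        flat = vol.reshape(-1, dataset.n_subjects)
        flat[g.mask_indices] = b.values.T
        aff = _affine(g.voxel_size_mm)
        img_path = out_dir / f"{b.name}.nii.gz"
        nib.save(nib.Nifti1Image(vol, aff), img_path)
        mask = np.zeros(g.grid_dims, dtype=np.uint8)
        mask.reshape(-1)[g.mask_indices] = 1
        mask_path = out_dir / f"{b.name}_mask.nii.gz"
        nib.save(nib.Nifti1Image(mask, aff), mask_path)
        written[b.name] = img_path
        written[f"{b.name}_mask"] = mask_path
    subj = pd.DataFrame({"subject": dataset.subject_ids})
    subj_path = out_dir / "subjects.tsv"
    subj.to_csv(subj_path, sep="\t", index=False)
    written["subjects"] = subj_path
    return written


def read_dataset(in_dir: str | Path, modalities: list[str] | None = None,
                 kinds: dict[str, str] | None = None) -> MultimodalDataset:
    """Read modality blocks written by :func:`write_dataset`."""
    in_dir = Path(in_dir)
    if modalities is None:
        modalities = sorted(p.name[:-7] for p in in_dir.glob("*.nii.gz")
                            if not p.name.endswith("_mask.nii.gz"))
    subj_path = in_dir / "subjects.tsv"
    subject_ids = (pd.read_csv(subj_path, sep="\t")["subject"].tolist()
                   if subj_path.exists() else None)
    blocks = []
    for name in modalities:
        img = nib.load(in_dir / f"{name}.nii.gz")
        mask_img = nib.load(in_dir / f"{name}_mask.nii.gz")
        vol = np.asarray(img.dataobj, dtype=float)
        mask = np.asarray(mask_img.dataobj) > 0
        if vol.shape[:3] != mask.shape:
            raise ValueError(f"{name}: image grid {vol.shape[:3]} != mask grid {mask.shape}")
        idx = np.flatnonzero(mask.reshape(-1))
        values = vol.reshape(-1, vol.shape[3])[idx].T
        voxel_size = tuple(float(v) for v in img.header.get_zooms()[:3])
        geom = MaskGeometry(grid_dims=mask.shape, voxel_size_mm=voxel_size, mask_indices=idx)
        blocks.append(ModalityBlock(name=name, values=values, geometry=geom,
                                    kind=(kinds or {}).get(name, "volume")))
    return MultimodalDataset(blocks=blocks, subject_ids=subject_ids)


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "subject") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=True, index_label=index_label, na_rep=MISSING_TOKEN)
    return path


def _read_tsv(path: str | Path, subject_ids=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="subject")
    if subject_ids is not None:
        missing = set(subject_ids) - set(df.index)
        if missing:
            raise ValueError(f"table {path} lacks subject id(s): {sorted(missing)[:5]}")
        df = df.loc[list(subject_ids)]  # auto-align to imaging order
    return df


def read_clinical(path: str | Path, kinds: dict[str, str] | None = None,
                  subject_ids=None, sidecar: str | Path | None = None) -> ClinicalTable:
    """Read a clinical TSV; variable kinds come from a JSON sidecar or are inferred.

    Inference: a column whose non-missing values are all in {0, 1} is binary.
    """
    df = _read_tsv(path, subject_ids)
    units, stat = {}, {}
    if sidecar is not None:
        meta = json.loads(Path(sidecar).read_text())
        kinds = kinds or {k: v.get("kind") for k, v in meta.items()}
        units = {k: v.get("units", "") for k, v in meta.items()}
        stat = {k: v.get("summary_stat", "median") for k, v in meta.items()}
    if kinds is None:
        kinds = {}
        for c in df.columns:
            vals = set(df[c].dropna().unique())
            kinds[c] = "binary" if vals <= {0, 1, 0.0, 1.0} else "continuous"
    return ClinicalTable(data=df, kinds=kinds, units=units, summary_stat=stat)


def read_outcomes(path: str | Path, subject_ids=None) -> pd.DataFrame:
    return _read_tsv(path, subject_ids)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=1, default=_default, allow_nan=True))
    return path


def write_decomposition_maps(decomp, dataset: MultimodalDataset, out_dir: str | Path) -> None:
    """Export spatial maps as 4-D NIfTI per modality (components on axis 4)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for b in dataset.blocks:
        w = decomp.spatial_maps[b.name]  # (V, K)
        g = b.geometry
        vol = np.zeros(g.grid_dims + (w.shape[1],), dtype=np.float32)
        vol.reshape(-1, w.shape[1])[g.mask_indices] = w
        nib.save(nib.Nifti1Image(vol, _affine(g.voxel_size_mm)),
                 out_dir / f"{b.name}_components.nii.gz")
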