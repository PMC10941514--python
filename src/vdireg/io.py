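"""Readers and writers for the TSV/JSON interchange formats.

TSV is the canonical on-disk dialect: imaging matrices carry a
``subject_id`` first column and voxel ids in the header; dependence
indices and summary statistics are long tables keyed by ``voxel_id``;
fitted records are JSON.  A NIfTI adapter (optional, requires nibabel)
flattens per-subject volumes into in-mask voxel columns.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ImagingMatrix, Phenotype, SummaryStats, VdiVector

__all__ = [
    "read_matrix", "write_matrix",
    "read_vdi", "write_vdi",
    "read_stats", "write_stats",
    "read_phenotype", "read_covariates",
    "write_fit", "read_fit",
    "read_nifti_matrix",
]


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty table")
    return df


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def read_matrix(path, modality: str = "MRI") -> ImagingMatrix:
    """Read a subjects × voxels TSV (first column ``subject_id``)."""
    df = _read_tsv(path)
    if df.columns[0] != "subject_id":
        raise ValueError(f"{path}: first column must be 'subject_id', got {df.columns[0]!r}")
    return ImagingMatrix(
        values=df.iloc[:, 1:].to_numpy(dtype=float),
        subject_ids=df["subject_id"].astype(str).to_numpy(),
        voxel_ids=df.columns[1:].to_numpy(dtype=object),
        modality=modality,
    )


def write_matrix(X: ImagingMatrix, path) -> None:
    df = pd.DataFrame(X.values, columns=X.voxel_ids)
    df.insert(0, "subject_id", X.subject_ids)
    df.to_csv(path, sep="\t", index=False)


def write_vdi(vdi: VdiVector, path) -> None:
    pd.DataFrame(
        {"voxel_id": vdi.voxel_ids, "modality": vdi.modality,
         "vdi": vdi.v, "n_ref": vdi.n_ref}
    ).to_csv(path, sep="\t", index=False)


def read_vdi(path) -> VdiVector:
    df = _read_tsv(path)
    _require_columns(df, ["voxel_id", "modality", "vdi", "n_ref"], path)
    return VdiVector(
        v=df["vdi"].to_numpy(dtype=float),
        voxel_ids=df["voxel_id"].astype(str).to_numpy(dtype=object),
        modality=str(df["modality"].iloc[0]),
        n_ref=int(df["n_ref"].iloc[0]),
    )


def write_stats(stats: SummaryStats, path) -> None:
    pd.DataFrame(
        {"voxel_id": stats.voxel_ids, "modality": stats.modality, "t": stats.t,
         "n_eff": stats.n_eff, "df": stats.df, "trait_label": stats.trait_label}
    ).to_csv(path, sep="\t", index=False)


def read_stats(path) -> SummaryStats:
    df = _read_tsv(path)
    _require_columns(df, ["voxel_id", "modality", "t", "n_eff", "df", "trait_label"], path)
    return SummaryStats(
        t=df["t"].to_numpy(dtype=float),
        voxel_ids=df["voxel_id"].astype(str).to_numpy(dtype=object),
        modality=str(df["modality"].iloc[0]),
        trait_label=str(df["trait_label"].iloc[0]),
        n_eff=int(df["n_eff"].iloc[0]),
        df=int(df["df"].iloc[0]),
    )


def read_phenotype(path, trait: str, subject_col: str = "subject_id") -> Phenotype:
    df = _read_tsv(path)
    _require_columns(df, [subject_col, trait], path)
    sub = df[[subject_col, trait]].dropna()
    return Phenotype(
        y=sub[trait].to_numpy(dtype=float),
        subject_ids=sub[subject_col].astype(str).to_numpy(dtype=object),
        trait_label=trait,
    )


def read_covariates(path, subject_col: str = "subject_id") -> pd.DataFrame:
    df = _read_tsv(path)
    _require_columns(df, [subject_col], path)
    df[subject_col] = df[subject_col].astype(str)
    return df.set_index(subject_col)


def write_fit(fit, path) -> None:
    """Serialize a fitted record (any of the result dataclasses) as JSON."""
    if dataclasses.is_dataclass(fit):
        payload = dataclasses.asdict(fit)
    elif isinstance(fit, dict):
        payload = fit
    else:
        raise TypeError(f"cannot serialize {type(fit).__name__}")

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(type(o).__name__)

    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")


def read_fit(path) -> dict:
    return json.loads(Path(path).read_text())


def read_nifti_matrix(image_paths, mask_path, subject_ids, modality: str = "MRI") -> ImagingMatrix:
    """Flatten per-subject NIfTI volumes into an in-mask subjects × voxels matrix.

    Voxel ids encode 0-based ``i_j_k`` indices into the mask grid.  Requires
    nibabel (install the ``nifti`` extra).
    """
    try:
        import nibabel as nib
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("NIfTI support requires nibabel (pip install vdireg[nifti])") from exc
    mask = np.asarray(nib.load(str(mask_path)).get_fdata()) > 0
    idx = np.argwhere(mask)
    voxel_ids = np.array([f"{i}_{j}_{k}" for i, j, k in idx], dtype=object)
    rows = []
    for p in image_paths:
        vol = np.asarray(nib.load(str(p)).get_fdata())
        if vol.shape != mask.shape:
            raise ValueError(f"{p}: shape {vol.shape} does not match mask {mask.shape}")
        rows.append(vol[mask])
    return ImagingMatrix(
        values=np.asarray(rows, dtype=float),
        subject_ids=np.asarray(subject_ids, dtype=object),
        voxel_ids=voxel_ids,
        modality=modality,
    )
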