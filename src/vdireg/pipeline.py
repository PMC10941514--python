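"""End-to-end run: QC → VDI → association → pattern regression → inference.

A :class:`RunConfig` (built directly or loaded from TOML) names the
modality matrices, the phenotype battery and covariates; ``pipeline_run``
executes the stages in order and writes a JSON manifest recording seeds,
subject/voxel counts at every stage, and every fitted quantity, so a run is
reproducible from its config alone.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .assoc import compute_tstats
from .bav import fit_bav_combined
from .containers import ImagingMatrix
from .inference import build_quick_null, fdr_adjust, quick_p
from .qc import detect_outliers, drop_and_log
from .vdi import combine_vdi, compute_vdi

__all__ = ["RunConfig", "pipeline_run"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    modalities: list[dict]                 # [{"name":..., "matrix": path}, ...]
    pheno_path: str
    traits: list[str]
    out_dir: str = "vdireg_out"
    covariates_path: str | None = None
    categorical: list[str] = field(default_factory=list)
    quick_B: int = 0                       # 0 disables the quick null
    seed: int = 0
    outlier_majority: float = 0.5
    weight_floor: float = 1.0

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        run = raw.get("run", {})
        pheno = raw["pheno"]
        cov = raw.get("covariates", {})
        return cls(
            modalities=raw["modality"],
            pheno_path=pheno["path"],
            traits=list(pheno["traits"]),
            out_dir=run.get("out_dir", "vdireg_out"),
            covariates_path=cov.get("path"),
            categorical=list(cov.get("categorical", [])),
            quick_B=int(run.get("quick_B", 0)),
            seed=int(run.get("seed", 0)),
            outlier_majority=float(run.get("outlier_majority", 0.5)),
            weight_floor=float(run.get("weight_floor", 1.0)),
        )


def pipeline_run(config: RunConfig) -> dict:
    """Run the full estimation pipeline and return (and write) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    C = (
        io.read_covariates(config.covariates_path)
        if config.covariates_path
        else None
    )
    manifest: dict = {"seed": config.seed, "modalities": [], "traits": {}}

    mats, vdis = [], []
    for mod in config.modalities:
        X = io.read_matrix(mod["matrix"], modality=mod["name"])
        flags, report = detect_outliers(X, majority=config.outlier_majority)
        Xc = drop_and_log(X, flags)
        vdi = compute_vdi(Xc)
        io.write_vdi(vdi, out / f"vdi_{mod['name']}.tsv")
        mats.append(Xc)
        vdis.append(vdi)
        manifest["modalities"].append(
            {"name": mod["name"], "n_subjects_raw": X.n_subjects,
             "n_outliers": int(flags.sum()), "n_subjects": Xc.n_subjects,
             "m_voxels": Xc.n_voxels}
        )

    quick_nulls = None
    shared_subjects = all(
        np.array_equal(m.subject_ids, mats[0].subject_ids) for m in mats[1:]
    )
    if config.quick_B and shared_subjects:
        Xcomb = ImagingMatrix(
            values=np.hstack([m.values for m in mats]),
            subject_ids=mats[0].subject_ids.copy(),
            voxel_ids=np.concatenate([m.voxel_ids for m in mats]),
            modality="combined",
        )
        quick_nulls = build_quick_null(
            Xcomb, combine_vdi(vdis), B=config.quick_B, seed=config.seed,
            C=C, categorical=config.categorical,
        )
    elif config.quick_B:
        logger.warning("quick null skipped: modalities have different subject panels")

    pvals = []
    for trait in config.traits:
        y = io.read_phenotype(config.pheno_path, trait)
        stats_parts = [
            compute_tstats(m, y, C, categorical=config.categorical) for m in mats
        ]
        for s in stats_parts:
            io.write_stats(s, out / f"tstats_{s.modality}_{trait}.tsv")
        fit = fit_bav_combined(stats_parts, vdis, weight_floor=config.weight_floor)
        rec = {
            "b2": fit.b2, "beta": fit.beta, "c": fit.c, "a": fit.a,
            "M": fit.M, "N": fit.N,
            "n_eff": {s.modality: s.n_eff for s in stats_parts},
        }
        if quick_nulls is not None:
            rec["quick_p"] = quick_p(fit.b2, quick_nulls)
            pvals.append((trait, rec["quick_p"]))
        manifest["traits"][trait] = rec

    if pvals:
        adj = fdr_adjust([p for _, p in pvals])
        for (trait, _), padj in zip(pvals, adj):
            manifest["traits"][trait]["quick_p_fdr"] = float(padj)

    io.write_fit(manifest, out / "manifest.json")
    return manifest
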