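"""Voxel dependence index (VDI).

The VDI of voxel *i* is the sum over all other voxels *k* of the squared
sample Pearson correlation between the two voxels' signals across subjects:

    V_i = sum_{k != i} r_ik^2

It plays the role the LD score plays in summary-statistic regression of
GWAS data: a voxel with a high VDI is strongly co-activated with (or, for
structural data, similar to) the rest of the brain and therefore tags more
of the brain-wide signal.  Multi-modality panels concatenate per-modality
VDIs; correlations are never computed across modalities.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .containers import ImagingMatrix, VdiVector

__all__ = ["compute_vdi", "combine_vdi"]


def _standardize_columns(values: np.ndarray) -> np.ndarray:
    """Center each column and scale to unit Euclidean norm, so that
    Z.T @ Z is the voxel × voxel Pearson correlation matrix."""
    z = values - values.mean(axis=0)
    norms = np.linalg.norm(z, axis=0)
    return z / norms


def compute_vdi(
    X: ImagingMatrix,
    adjusted: bool = False,
    block_size: int = 1024,
) -> VdiVector:
    """Compute the per-voxel dependence index for one modality.

    Parameters
    ----------
    X : ImagingMatrix
        QC'd subject × voxel matrix; zero-variance columns are rejected.
    adjusted : bool, default False
        If True, sum the small-sample adjusted squared correlation
        ``r² − (1 − r²)/(n − 2)`` instead of the raw ``r²``.  The raw sum is
        the defining quantity; the adjustment is offered only as a
        diagnostic.
    block_size : int
        Column-block width of the chunked correlation computation; memory
        stays O(n·m + block_size²) so panels of hundreds of thousands of
        voxels remain feasible.

    Returns
    -------
    VdiVector
        V_i ≥ 0 with ``n_ref`` set to the subject count of ``X``.
    """
    n, m = X.values.shape
    bad = X.zero_variance_voxels()
    if len(bad):
        raise ValueError(
            f"zero-variance voxel column(s) {list(bad[:5])!r} — drop them in QC first"
        )
    z = _standardize_columns(X.values)
    v = np.zeros(m)
    for start in range(0, m, block_size):
        zb = z[:, start : start + block_size]
        # correlations of this block against every column, in inner blocks
        for start2 in range(0, m, block_size):
            r = zb.T @ z[:, start2 : start2 + block_size]
            r2 = r * r
            if adjusted:
                r2 = r2 - (1.0 - r2) / (n - 2)
            v[start : start + block_size] += r2.sum(axis=1)
    # remove the self term (r_ii² = 1 raw and adjusted alike)
    v -= 1.0
    if adjusted:
        v = np.maximum(v, 0.0)
    return VdiVector(v=v, voxel_ids=X.voxel_ids.copy(), modality=X.modality, n_ref=n)


def combine_vdi(parts: Sequence[VdiVector] | Iterable[VdiVector]) -> VdiVector:
    """Concatenate per-modality dependence indices into a combined panel.

    The combined VDI is a *joint* of the per-modality VDIs — the index is
    never recomputed across modalities, so each V_i keeps its within-modality
    meaning and upper bound (m_part − 1).
    """
    parts = list(parts)
    if not parts:
        raise ValueError("need at least one VdiVector")
    if len(parts) == 1:
        p = parts[0]
        return VdiVector(p.v.copy(), p.voxel_ids.copy(), p.modality, p.n_ref)
    all_ids = np.concatenate([p.voxel_ids for p in parts])
    if len(np.unique(all_ids)) != len(all_ids):
        raise ValueError("duplicate voxel id across modality parts")
    v = np.concatenate([p.v for p in parts])
    modality = "+".join(p.modality for p in parts)
    n_ref = int(min(p.n_ref for p in parts))
    return VdiVector(v=v, voxel_ids=all_ids, modality=modality, n_ref=n_ref)
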