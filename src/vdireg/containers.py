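"""In-memory containers for subject-level imaging data and voxelwise summaries.

The central objects mirror the stages of a summary-statistic pattern
regression: an :class:`ImagingMatrix` holds one modality's subjects × voxels
signal (task-fMRI activations or grey-matter volume), a :class:`VdiVector`
holds the per-voxel dependence index derived from it, and a
:class:`SummaryStats` holds the per-voxel association t-statistics of a
behavioural trait computed on that matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _check_unique(ids, what: str) -> np.ndarray:
    ids = np.asarray(ids, dtype=object)
    if len(np.unique(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")
    return ids


@dataclass
class ImagingMatrix:
    """Subjects × voxels real-valued matrix for a single imaging modality.

    Parameters
    ----------
    values : ndarray of shape (n_subjects, n_voxels)
        Signal values in arbitrary units (e.g. GLM betas, modulated GMV).
    subject_ids, voxel_ids : sequences of str
        Ordered, unique identifiers for rows and columns.
    modality : str
        Label such as ``"MID"``, ``"SST"``, ``"EFT"`` or ``"GMV"``.
    """

    values: np.ndarray
    subject_ids: np.ndarray
    voxel_ids: np.ndarray
    modality: str = "MRI"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D subjects × voxels matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("imaging matrix contains non-finite entries")
        self.subject_ids = _check_unique(self.subject_ids, "subject")
        self.voxel_ids = _check_unique(self.voxel_ids, "voxel")
        n, m = self.values.shape
        if len(self.subject_ids) != n:
            raise ValueError(f"{len(self.subject_ids)} subject ids for {n} rows")
        if len(self.voxel_ids) != m:
            raise ValueError(f"{len(self.voxel_ids)} voxel ids for {m} columns")
        if n < 3:
            raise ValueError("need at least 3 subjects (Pearson r undefined below)")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def zero_variance_voxels(self) -> np.ndarray:
        """Ids of voxels whose column is constant across subjects."""
        sd = self.values.std(axis=0)
        return self.voxel_ids[sd == 0]

    def subset_subjects(self, keep: np.ndarray) -> "ImagingMatrix":
        """Return a copy restricted to the boolean/integer subject index ``keep``."""
        return ImagingMatrix(
            values=self.values[keep],
            subject_ids=self.subject_ids[keep],
            voxel_ids=self.voxel_ids.copy(),
            modality=self.modality,
        )


@dataclass
class VdiVector:
    """Per-voxel dependence index: sum of squared Pearson correlations
    with every other voxel of the same modality."""

    v: np.ndarray
    voxel_ids: np.ndarray
    modality: str
    n_ref: int

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.voxel_ids = _check_unique(self.voxel_ids, "voxel")
        if self.v.ndim != 1 or len(self.v) != len(self.voxel_ids):
            raise ValueError("v and voxel_ids must be 1-D and aligned")
        if np.any(self.v < -1e-12):
            raise ValueError("dependence index values must be nonnegative")

    @property
    def m(self) -> int:
        return len(self.v)


@dataclass
class Phenotype:
    """Per-subject behavioural measure."""

    y: np.ndarray
    subject_ids: np.ndarray
    trait_label: str = "trait"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if not np.all(np.isfinite(self.y)):
            raise ValueError("phenotype contains non-finite values")
        self.subject_ids = _check_unique(self.subject_ids, "subject")
        if self.y.ndim != 1 or len(self.y) != len(self.subject_ids):
            raise ValueError("y and subject_ids must be 1-D and aligned")


@dataclass
class SummaryStats:
    """Per-voxel association t-statistics for one trait on one modality panel."""

    t: np.ndarray
    voxel_ids: np.ndarray
    modality: str
    trait_label: str
    n_eff: int
    df: int
    n_collinear: int = field(default=0)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.voxel_ids = _check_unique(self.voxel_ids, "voxel")
        if self.t.ndim != 1 or len(self.t) != len(self.voxel_ids):
            raise ValueError("t and voxel_ids must be 1-D and aligned")
        if not np.all(np.isfinite(self.t)):
            raise ValueError(
                "non-finite t-statistics (perfect fit?); cannot be used downstream"
            )

    @property
    def m(self) -> int:
        return len(self.t)


def check_aligned(voxel_ids_a: np.ndarray, voxel_ids_b: np.ndarray, what: str) -> None:
    """Raise unless two voxel id sequences are identical and identically ordered."""
    a = np.asarray(voxel_ids_a, dtype=object)
    b = np.asarray(voxel_ids_b, dtype=object)
    if len(a) != len(b) or not np.array_equal(a, b):
        raise ValueError(f"voxel ids of {what} are not aligned")
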