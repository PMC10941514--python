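"""Subject-level quality control.

A subject whose whole-brain pattern correlates *negatively* with the
patterns of most other subjects is almost certainly corrupted (failed
normalisation, sign-flipped contrast, severe artifact) and is removed
before any dependence index or association statistic is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import ImagingMatrix

__all__ = ["QcReport", "detect_outliers", "drop_and_log"]

logger = logging.getLogger(__name__)


@dataclass
class QcReport:
    subject_ids: np.ndarray
    negative_counts: np.ndarray  # negative correlations with other subjects
    flagged: np.ndarray          # boolean, aligned with subject_ids
    threshold: float             # fraction of other subjects required to flag


def detect_outliers(X: ImagingMatrix, majority: float = 0.5) -> tuple[np.ndarray, QcReport]:
    """Flag subjects anti-correlated with most of the rest of the sample.

    A subject is flagged when its whole-brain voxel vector has a negative
    Pearson correlation with strictly more than ``majority`` of the other
    subjects.  Constant subject vectors (undefined correlations) are
    auto-flagged with a warning.

    Returns
    -------
    flags : boolean array over subjects
    report : QcReport with per-subject negative-correlation counts
    """
    if not 0 <= majority < 1:
        raise ValueError("majority must be in [0, 1)")
    vals = X.values
    n = X.n_subjects
    sd = vals.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "constant whole-brain vector for subject(s) %s — auto-flagged",
            list(X.subject_ids[constant]),
        )
    # subject × subject correlation over voxels; constant rows handled apart
    z = vals - vals.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(z, axis=1)
    norms[constant] = 1.0
    zn = z / norms[:, None]
    corr = zn @ zn.T
    neg = (corr < 0).sum(axis=1)  # diagonal is 1 (or 0 for constant), never negative
    flags = neg > majority * (n - 1)
    flags |= constant
    report = QcReport(
        subject_ids=X.subject_ids.copy(),
        negative_counts=neg,
        flagged=flags.copy(),
        threshold=majority,
    )
    return flags, report


def drop_and_log(X: ImagingMatrix, flags: np.ndarray) -> ImagingMatrix:
    """Remove flagged subjects, logging their ids and count."""
    flags = np.asarray(flags, dtype=bool)
    if flags.shape != (X.n_subjects,):
        raise ValueError("flags must align with subjects")
    n_drop = int(flags.sum())
    if n_drop:
        logger.info(
            "QC: removing %d outlier subject(s) from %s: %s",
            n_drop, X.modality, list(X.subject_ids[flags]),
        )
    return X.subset_subjects(~flags)
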