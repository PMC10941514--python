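"""Mass-univariate association: per-voxel t-statistics with covariate adjustment.

For each voxel independently the linear model

    y ~ intercept + voxel + covariates

is fitted on the subjects shared between the imaging matrix and the
phenotype, and the t-statistic of the voxel coefficient is returned.  These
voxelwise t-values are the summary statistics the downstream pattern
regressions consume; no per-voxel significance thresholding ever happens.

The implementation projects out the covariates (and intercept) once and
computes every voxel's t from the partial correlation of the residualized
phenotype with the residualized voxel — algebraically identical
(Frisch–Waugh) to refitting the full design per voxel, with exact
degrees-of-freedom bookkeeping.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import ImagingMatrix, Phenotype, SummaryStats

__all__ = ["align_subjects", "build_design", "compute_tstats", "TstatEngine"]

logger = logging.getLogger(__name__)


def build_design(
    covariates: Optional[pd.DataFrame],
    categorical: Sequence[str] = (),
) -> Optional[pd.DataFrame]:
    """Expand declared categorical covariates to indicator columns.

    ``covariates`` must be indexed by subject id.  Each column named in
    ``categorical`` is dummy-coded dropping the first level; remaining
    columns are taken as numeric.  Returns None when no covariates.
    """
    if covariates is None or covariates.shape[1] == 0:
        return None
    C = covariates.copy()
    for col in categorical:
        if col not in C.columns:
            raise ValueError(f"declared categorical covariate {col!r} not present")
    if categorical:
        C = pd.get_dummies(C, columns=list(categorical), drop_first=True, dtype=float)
    try:
        C = C.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(
            "non-numeric covariate column; declare it categorical"
        ) from exc
    return C


def align_subjects(
    X: ImagingMatrix,
    y: Phenotype,
    C: Optional[pd.DataFrame] = None,
):
    """Inner-join imaging, phenotype and covariates on subject id.

    Order follows the imaging matrix.  Returns ``(X', y', C')`` where C' is
    None when no covariates were supplied.  Dropped-subject counts are
    logged at INFO.
    """
    y_index = pd.Index(y.subject_ids)
    keep = np.array([sid in set(y.subject_ids) for sid in X.subject_ids])
    if C is not None:
        cset = set(C.index)
        keep &= np.array([sid in cset for sid in X.subject_ids])
    if not keep.any():
        raise ValueError("no overlapping subjects between imaging and phenotype")
    Xs = X.subset_subjects(keep)
    pos = y_index.get_indexer(Xs.subject_ids)
    ys = Phenotype(y=y.y[pos], subject_ids=Xs.subject_ids.copy(), trait_label=y.trait_label)
    Cs = C.loc[Xs.subject_ids] if C is not None else None
    n_drop_x = X.n_subjects - Xs.n_subjects
    n_drop_y = len(y.y) - len(ys.y)
    if n_drop_x or n_drop_y:
        logger.info(
            "align_subjects: kept %d subjects (dropped %d imaging-only, %d phenotype-only)",
            Xs.n_subjects, n_drop_x, n_drop_y,
        )
    return Xs, ys, Cs


def _residualize(A: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Residuals of the columns of A on the orthonormal basis Q."""
    return A - Q @ (Q.T @ A)


def compute_tstats(
    X: ImagingMatrix,
    y: Phenotype,
    C: Optional[pd.DataFrame] = None,
    categorical: Sequence[str] = (),
) -> SummaryStats:
    """Per-voxel association t-statistics of a phenotype, covariate-adjusted.

    Parameters
    ----------
    X : ImagingMatrix
        QC'd imaging matrix.
    y : Phenotype
        Behavioural measure; used as given (no rank-normalisation).
    C : DataFrame or None
        Covariate table indexed by subject id (e.g. sex, handedness, site).
    categorical : sequence of str
        Covariate columns to dummy-code.

    Returns
    -------
    SummaryStats
        t-values in the voxel order of ``X``; ``n_eff`` subjects used and
        residual ``df`` recorded.  Voxels collinear with the covariates get
        t = 0 with a logged warning and are counted in ``n_collinear``.
    """
    C = build_design(C, categorical)
    Xs, ys, Cs = align_subjects(X, y, C)
    n = Xs.n_subjects
    design = np.ones((n, 1))
    if Cs is not None:
        design = np.column_stack([design, Cs.to_numpy(dtype=float)])
    k = design.shape[1]  # intercept + covariates
    if n <= k + 1:
        raise ValueError(f"only {n} subjects for {k + 1} design columns")
    Q, R = np.linalg.qr(design)
    if np.linalg.matrix_rank(R) < k:
        diag = np.abs(np.diag(R))
        bad = [i for i, d in enumerate(diag) if d < 1e-10 * diag.max()]
        raise ValueError(f"rank-deficient covariate design (columns {bad})")

    ry = _residualize(ys.y[:, None], Q)[:, 0]
    sy = np.linalg.norm(ry)
    if sy == 0:
        raise ValueError("phenotype is perfectly explained by the covariates")
    rx = _residualize(Xs.values, Q)
    sx = np.linalg.norm(rx, axis=0)
    collinear = sx <= 1e-12 * np.abs(Xs.values).max()
    sx_safe = np.where(collinear, 1.0, sx)
    rho = (rx.T @ ry) / (sx_safe * sy)
    rho[collinear] = 0.0
    df = n - k - 1  # residual df of the full per-voxel model
    denom = 1.0 - rho**2
    if np.any(denom <= 0):
        raise ValueError(
            "perfect voxel–phenotype fit encountered (t would be infinite)"
        )
    t = rho * np.sqrt(df / denom)
    n_coll = int(collinear.sum())
    if n_coll:
        logger.warning(
            "%d voxel(s) collinear with covariates; their t set to 0", n_coll
        )
    return SummaryStats(
        t=t,
        voxel_ids=Xs.voxel_ids.copy(),
        modality=Xs.modality,
        trait_label=ys.trait_label,
        n_eff=n,
        df=df,
        n_collinear=n_coll,
    )


class TstatEngine:
    """Reusable t-statistic computer for one imaging panel.

    Precomputes the covariate projection and the residualized, normalized
    voxel matrix once, so repeated phenotype evaluations (permutation and
    null-simulation loops) cost a single matrix–vector product each.
    Numerically identical to :func:`compute_tstats` on the same inputs.
    """

    def __init__(
        self,
        X: ImagingMatrix,
        C: Optional[pd.DataFrame] = None,
        categorical: Sequence[str] = (),
    ):
        C = build_design(C, categorical)
        if C is not None:
            missing = [s for s in X.subject_ids if s not in C.index]
            if missing:
                raise ValueError(f"covariates missing for subjects {missing[:5]!r}")
            C = C.loc[X.subject_ids]
        n = X.n_subjects
        design = np.ones((n, 1))
        if C is not None:
            design = np.column_stack([design, C.to_numpy(dtype=float)])
        k = design.shape[1]
        if n <= k + 1:
            raise ValueError(f"only {n} subjects for {k + 1} design columns")
        self._Q, R = np.linalg.qr(design)
        if np.linalg.matrix_rank(R) < k:
            raise ValueError("rank-deficient covariate design")
        rx = _residualize(X.values, self._Q)
        sx = np.linalg.norm(rx, axis=0)
        self._collinear = sx <= 1e-12 * np.abs(X.values).max()
        sx_safe = np.where(self._collinear, 1.0, sx)
        self._rxn = rx / sx_safe
        self._rxn[:, self._collinear] = 0.0
        self.df = n - k - 1
        self.n_eff = n
        self.modality = X.modality
        self.voxel_ids = X.voxel_ids.copy()
        self.subject_ids = X.subject_ids.copy()
        self.n_collinear = int(self._collinear.sum())

    def tstats(self, y_values: np.ndarray) -> np.ndarray:
        """t-statistics for a phenotype vector aligned with the panel's subjects."""
        y_values = np.asarray(y_values, dtype=float)
        ry = _residualize(y_values[:, None], self._Q)[:, 0]
        sy = np.linalg.norm(ry)
        if sy == 0:
            raise ValueError("phenotype is perfectly explained by the covariates")
        rho = self._rxn.T @ (ry / sy)
        rho[self._collinear] = 0.0
        denom = 1.0 - rho**2
        if np.any(denom <= 0):
            raise ValueError("perfect voxel-phenotype fit (t would be infinite)")
        return rho * np.sqrt(self.df / denom)

    def summary(self, y_values: np.ndarray, trait_label: str = "trait") -> SummaryStats:
        return SummaryStats(
            t=self.tstats(y_values),
            voxel_ids=self.voxel_ids.copy(),
            modality=self.modality,
            trait_label=trait_label,
            n_eff=self.n_eff,
            df=self.df,
            n_collinear=self.n_collinear,
        )
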