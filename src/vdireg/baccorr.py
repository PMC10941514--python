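"""Brain-associated covariance (BAC) and the neuroimaging correlation.

For two traits with per-voxel t-statistics t1, t2 measured on samples of
size N1 and N2 sharing Ns subjects with phenotypic correlation Q, the
expected product of t-statistics is linear in the dependence index:

    E[t1_i t2_i] = (√(N1 N2) Q_b / M) · V_i + Q·Ns/√(N1 N2)

where Q_b is the brain-associated covariance.  The intercept is fully
determined by the sample overlap and is therefore held FIXED in both
regression stages (unlike the variance regression, whose stage-2 intercept
is free to absorb confounding).  The neuroimaging correlation is

    r_brain = Q_b / √(b1² · b2²),

the imaging analog of a genetic correlation; traits with a non-positive
estimated BAV are excluded from correlation computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .bav import BavFit, stage1_constrained_slope
from .containers import Phenotype, SummaryStats, VdiVector, check_aligned

__all__ = [
    "BacRegression",
    "BacFit",
    "NeuroCorr",
    "fit_bac",
    "r_brain",
    "phenotypic_correlation",
]


@dataclass
class BacFit:
    """Fitted cross-trait record; ``beta_x = √(N1·N2)·qb/M`` holds exactly."""

    qb: float
    beta_x: float
    fixed_intercept: float
    N1: int
    N2: int
    Ns: int
    Q: float
    M: int


@dataclass
class NeuroCorr:
    """Neuroimaging correlation between two traits.

    ``r_capped`` clamps ``r_raw`` to [−1, 1]; when either trait's estimated
    BAV is non-positive the pair is flagged ``excluded`` and the r fields
    are NaN.  ``p_perm`` is attached by the inference machinery when a
    permutation test has been run.
    """

    r_raw: float
    r_capped: float
    excluded: bool
    p_perm: float = float("nan")


class BacRegression(BaseEstimator):
    """Two-stage slope-only weighted regression of t1·t2 on the VDI.

    Parameters
    ----------
    weight_floor : float, default 1.0
        VDI floor in the dependence weight, as in :class:`BavRegression`.

    Attributes
    ----------
    qb_ : float
        Brain-associated covariance.
    beta_x_ : float
        Cross slope on the raw VDI scale, √(N1N2)·qb/M.
    fixed_intercept_ : float
        Q·Ns/√(N1·N2), constrained in both stages.
    stage1_cross_slope_ : float
        Constrained-fit cross slope used in the variance function.
    """

    def __init__(self, weight_floor: float = 1.0):
        self.weight_floor = weight_floor

    def fit(self, V, T, *, N1, N2, Ns=0, Q=0.0):
        """Fit from dependence indices and the two traits' t-statistics.

        Parameters
        ----------
        V : array-like of shape (M,)
        T : array-like of shape (M, 2)
            Columns are the two traits' t-statistics, voxel-aligned with V.
        N1, N2 : int
            Per-trait sample sizes.
        Ns : int
            Overlapping subject count; with ``Ns = 0`` the intercept is 0
            and ``Q`` is ignored.
        Q : float
            Phenotypic correlation among the Ns overlapping subjects.
        """
        V = np.asarray(V, dtype=float).ravel()
        T = np.asarray(T, dtype=float)
        if T.shape != (V.size, 2):
            raise ValueError("T must be of shape (M, 2) aligned with V")
        if not (0 <= Ns <= min(N1, N2)):
            raise ValueError("need 0 <= Ns <= min(N1, N2)")
        if abs(Q) > 1:
            raise ValueError("|Q| must be <= 1")
        if np.ptp(V) == 0:
            raise ValueError("constant VDI: slope unidentifiable")
        if Ns == 0:
            Q = 0.0
        t1, t2 = T[:, 0], T[:, 1]
        root_n = float(np.sqrt(N1 * N2))
        intercept = Q * Ns / root_n
        prod = t1 * t2

        # stage 1: constrained cross fit plus each trait's constrained t² fit,
        # feeding the bivariate product-moment variance model
        # Var(t1 t2) ≈ E[t1²]E[t2²] + E[t1 t2]²
        s_x = stage1_constrained_slope(V, prod, intercept=intercept)
        s1_1 = max(stage1_constrained_slope(V, t1 * t1, intercept=1.0), 0.0)
        s1_2 = max(stage1_constrained_slope(V, t2 * t2, intercept=1.0), 0.0)
        f1 = s1_1 * V + 1.0
        f2 = s1_2 * V + 1.0
        h = f1 * f2 + (s_x * V + intercept) ** 2
        w = 1.0 / (h * np.maximum(V, self.weight_floor))

        # stage 2: slope-only WLS with the same fixed intercept
        beta_x = float((w * V * (prod - intercept)).sum() / (w * V * V).sum())

        self.beta_x_ = beta_x
        self.qb_ = beta_x * V.size / root_n
        self.fixed_intercept_ = intercept
        self.stage1_cross_slope_ = s_x
        self.M_ = V.size
        self.N1_, self.N2_, self.Ns_, self.Q_ = int(N1), int(N2), int(Ns), float(Q)
        return self

    def to_record(self) -> BacFit:
        return BacFit(
            qb=self.qb_,
            beta_x=self.beta_x_,
            fixed_intercept=self.fixed_intercept_,
            N1=self.N1_,
            N2=self.N2_,
            Ns=self.Ns_,
            Q=self.Q_,
            M=self.M_,
        )


def fit_bac(
    stats1: SummaryStats,
    stats2: SummaryStats,
    vdi: VdiVector,
    N1: int | None = None,
    N2: int | None = None,
    Ns: int = 0,
    Q: float = 0.0,
    weight_floor: float = 1.0,
) -> BacFit:
    """Estimate the brain-associated covariance between two traits."""
    check_aligned(stats1.voxel_ids, vdi.voxel_ids, "stats1 vs VDI")
    check_aligned(stats2.voxel_ids, vdi.voxel_ids, "stats2 vs VDI")
    N1 = stats1.n_eff if N1 is None else N1
    N2 = stats2.n_eff if N2 is None else N2
    est = BacRegression(weight_floor=weight_floor)
    est.fit(vdi.v, np.column_stack([stats1.t, stats2.t]), N1=N1, N2=N2, Ns=Ns, Q=Q)
    return est.to_record()


def r_brain(bac: BacFit, fit1: BavFit, fit2: BavFit) -> NeuroCorr:
    """Neuroimaging correlation from a covariance fit and the two BAV fits.

    Pairs where either BAV estimate is non-positive are excluded (the
    correlation is undefined); otherwise r_raw = qb/√(b1²·b2²) with a capped
    companion clamped to [−1, 1].
    """
    if fit1.b2 <= 0 or fit2.b2 <= 0:
        return NeuroCorr(r_raw=float("nan"), r_capped=float("nan"), excluded=True)
    r = bac.qb / float(np.sqrt(fit1.b2 * fit2.b2))
    return NeuroCorr(r_raw=r, r_capped=float(np.clip(r, -1.0, 1.0)), excluded=False)


def phenotypic_correlation(y1: Phenotype, y2: Phenotype) -> tuple[float, int]:
    """Pearson correlation of two phenotypes over their shared subjects.

    Returns ``(Q, Ns)``; with no overlap, ``(0.0, 0)``.
    """
    common, i1, i2 = np.intersect1d(
        y1.subject_ids, y2.subject_ids, return_indices=True
    )
    ns = len(common)
    if ns < 3:
        return 0.0, ns
    q = float(np.corrcoef(y1.y[i1], y2.y[i2])[0, 1])
    return q, ns
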