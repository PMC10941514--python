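"""Brain-associated variance (BAV) from the VDI pattern regression.

Under a polyvoxel model in which many voxels each explain a small share of a
behavioural trait, the expected squared association t-statistic of voxel *i*
is linear in its dependence index:

    E[t_i²] = (N b² / M) · V_i + c,        c = N a + 1

where N is the sample size, M the voxel count, b² the brain-associated
variance (the fraction of trait variance explained by the voxel panel
jointly) and *a* the per-subject contribution of confounding biases — so an
intercept significantly above one flags systematic confounding, exactly as
the LD-score-regression intercept flags population stratification.

Estimation is a two-stage linear regression:

1. constrained fit — OLS of (t² − 1) on the predictor through the origin
   gives a provisional slope s₁ used only to model heteroskedasticity via
   the chi-square moment Var(t²) ≈ 2·E[t²]², i.e. g(V) = 2·(s₁V + 1)²;
2. weighted fit — WLS of t² on the predictor with a free intercept and
   weight 1 / (g(V_i) · max(V_i, 1)); the second factor corrects for the
   over-representation of mutually dependent voxels.

Multi-modality panels concatenate per-modality t and V; when per-modality
sample sizes differ the regressor is (N_i/M)·V_i so the fitted slope is b²
directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .containers import SummaryStats, VdiVector, check_aligned

__all__ = ["BavRegression", "BavFit", "fit_bav", "fit_bav_combined"]


def stage1_constrained_slope(predictor: np.ndarray, t2: np.ndarray, intercept: float) -> float:
    """OLS slope of (t2 − intercept) on predictor through the origin."""
    denom = float(predictor @ predictor)
    if denom == 0:
        raise ValueError("degenerate predictor (all zero)")
    return float(predictor @ (t2 - intercept)) / denom


def wls_line(
    x: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[float, float]:
    """Weighted least squares of y on [1, x]; returns (intercept, slope)."""
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx == 0:
        raise ValueError("constant predictor: slope unidentifiable")
    slope = float((w * (x - xm) * (y - ym)).sum() / sxx)
    return float(ym - slope * xm), slope


@dataclass
class BavFit:
    """Fitted BAV record.

    ``beta = N·b2/M`` and ``a = (c − 1)/N`` hold exactly; for combined
    panels with unequal per-modality sample sizes N is the voxel-weighted
    mean sample size and ``beta`` is derived from it.
    """

    b2: float
    beta: float
    c: float
    a: float
    stage1_slope: float
    M: int
    N: float
    weights_summary: tuple[float, float, float]


class BavRegression(BaseEstimator):
    """Two-stage weighted regression of squared t-statistics on the VDI.

    Parameters
    ----------
    weight_floor : float, default 1.0
        Floor applied to the VDI inside the dependence weight,
        ``w ∝ 1/max(V, weight_floor)``; prevents exploding weights at
        near-independent voxels.
    floor_stage1 : bool, default True
        Floor the stage-1 slope at zero inside the variance function so
        weights stay positive under null noise.

    Attributes
    ----------
    b2_ : float
        Estimated brain-associated variance (may be negative; not truncated).
    c_ : float
        Free intercept of the weighted fit; ≈ 1 absent confounding.
    a_ : float
        Confounding share, (c − 1)/N.
    beta_ : float
        Slope on the raw VDI scale, N·b2/M.
    stage1_slope_ : float
        Unfloored constrained-fit slope on the (N/M)·V predictor scale.
    M_, N_ : int, float
        Voxel count and (mean) sample size.
    weights_summary_ : (min, median, max) of the final weights.
    """

    def __init__(self, weight_floor: float = 1.0, floor_stage1: bool = True):
        self.weight_floor = weight_floor
        self.floor_stage1 = floor_stage1

    def fit(self, V, t, n_subjects=None):
        """Fit from per-voxel dependence indices and t-statistics.

        Parameters
        ----------
        V : array-like of shape (M,)
            Voxel dependence indices.
        t : array-like of shape (M,)
            Association t-statistics (same voxel order).
        n_subjects : scalar or array-like of shape (M,)
            Sample size behind each t; a per-voxel array supports combined
            panels whose modalities were measured on different subjects.
        """
        V = np.asarray(V, dtype=float).ravel()
        t = np.asarray(t, dtype=float).ravel()
        if V.shape != t.shape:
            raise ValueError("V and t must have the same length")
        M = V.size
        if M < 3:
            raise ValueError("need at least 3 voxels")
        if n_subjects is None:
            raise ValueError("n_subjects is required")
        n = np.broadcast_to(np.asarray(n_subjects, dtype=float), V.shape)
        if np.ptp(V) == 0:
            raise ValueError("constant VDI: slope unidentifiable")
        t2 = t * t
        p = n * V / M  # predictor whose coefficient is b² itself

        s1 = stage1_constrained_slope(p, t2, intercept=1.0)
        s1_used = max(s1, 0.0) if self.floor_stage1 else s1
        g = 2.0 * (s1_used * p + 1.0) ** 2
        w = 1.0 / (g * np.maximum(V, self.weight_floor))

        c, b2 = wls_line(p, t2, w)
        self.b2_ = b2
        self.c_ = c
        self.M_ = M
        self.N_ = float(n.mean())
        self.a_ = (c - 1.0) / self.N_
        self.beta_ = b2 * self.N_ / M
        self.stage1_slope_ = s1
        self.weights_summary_ = (
            float(w.min()),
            float(np.median(w)),
            float(w.max()),
        )
        return self

    def to_record(self) -> BavFit:
        return BavFit(
            b2=self.b2_,
            beta=self.beta_,
            c=self.c_,
            a=self.a_,
            stage1_slope=self.stage1_slope_,
            M=self.M_,
            N=self.N_,
            weights_summary=self.weights_summary_,
        )


def fit_bav(
    stats: SummaryStats,
    vdi: VdiVector,
    N: int | None = None,
    weight_floor: float = 1.0,
) -> BavFit:
    """Estimate the brain-associated variance of one trait.

    ``N`` defaults to the effective sample size recorded in ``stats``.
    """
    check_aligned(stats.voxel_ids, vdi.voxel_ids, "summary stats vs VDI")
    if N is None:
        N = stats.n_eff
    est = BavRegression(weight_floor=weight_floor)
    est.fit(vdi.v, stats.t, n_subjects=float(N))
    return est.to_record()


def fit_bav_combined(
    stats_parts: Sequence[SummaryStats],
    vdi_parts: Sequence[VdiVector],
    weight_floor: float = 1.0,
) -> BavFit:
    """Estimate BAV on a concatenated multi-modality panel.

    Each part contributes its own effective sample size, entering the
    regression through the per-voxel predictor (N_i/M)·V_i, so modalities
    measured on different subject subsets combine coherently.
    """
    if len(stats_parts) != len(vdi_parts) or not stats_parts:
        raise ValueError("stats_parts and vdi_parts must be equal-length and nonempty")
    for s, v in zip(stats_parts, vdi_parts):
        check_aligned(s.voxel_ids, v.voxel_ids, f"part {s.modality}")
    t = np.concatenate([s.t for s in stats_parts])
    V = np.concatenate([v.v for v in vdi_parts])
    n = np.concatenate(
        [np.full(v.m, float(s.n_eff)) for s, v in zip(stats_parts, vdi_parts)]
    )
    est = BavRegression(weight_floor=weight_floor)
    est.fit(V, t, n_subjects=n)
    return est.to_record()
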