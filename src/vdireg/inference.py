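"""Significance machinery for BAV and the neuroimaging correlation.

Two complementary procedures are provided:

* the **quick p-value** — a null distribution of BAV is pre-computed once
  per imaging panel by fitting random standard-normal phenotypes (the panel
  keeps its real correlation structure); any observed BAV is then compared
  against that cached distribution.  Fast, reusable, approximate.
* the **permutation p-value** — the behavioural measure is shuffled across
  subjects (covariates stay attached to their subjects) and the statistic
  (BAV, neuroimaging correlation, or a BAV difference) is recomputed each
  time.  Exact exchangeability-based inference; requires subject-level data.

All p-values use the add-one convention p = (1 + #exceedances)/(B + 1), so
the smallest attainable value at B permutations is 1/(B + 1), never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .assoc import TstatEngine
from .baccorr import fit_bac, phenotypic_correlation, r_brain
from .bav import fit_bav
from .containers import ImagingMatrix, Phenotype, VdiVector
from .vdi import combine_vdi, compute_vdi

__all__ = [
    "NullDistribution",
    "build_quick_null",
    "quick_p",
    "permutation_p_bav",
    "permutation_p_rbrain",
    "bav_difference_test",
    "fdr_adjust",
    "split_half",
]

logger = logging.getLogger(__name__)


@dataclass
class NullDistribution:
    """Empirical null of a statistic, with its 95% envelope."""

    values: np.ndarray
    statistic_name: str
    seed: int
    ci95: tuple[float, float] = (float("nan"), float("nan"))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        lo, hi = np.percentile(self.values, [2.5, 97.5])
        self.ci95 = (float(lo), float(hi))

    @property
    def B(self) -> int:
        return len(self.values)


def build_quick_null(
    X: ImagingMatrix,
    vdi: VdiVector,
    B: int = 1000,
    seed: int = 0,
    C: Optional[pd.DataFrame] = None,
    categorical: Sequence[str] = (),
) -> NullDistribution:
    """Null BAV distribution from random standard-normal phenotypes.

    The real imaging panel (and its voxel dependence structure) is kept;
    only the phenotype is simulated, B ≥ 100 times.  The resulting 95% CI
    is the pre-computed envelope the quick p-value scans against.
    """
    if B < 100:
        raise ValueError("quick null needs B >= 100 draws")
    rng = np.random.default_rng(seed)
    engine = TstatEngine(X, C, categorical)
    vals = np.empty(B)
    for b in range(B):
        y = rng.normal(size=X.n_subjects)
        try:
            stats = engine.summary(y, trait_label=f"null{b}")
            vals[b] = fit_bav(stats, vdi).b2
        except ValueError as exc:
            raise ValueError(f"null replicate {b} failed: {exc}") from exc
    return NullDistribution(values=vals, statistic_name="b2", seed=seed)


def quick_p(observed: float, null: NullDistribution | np.ndarray) -> float:
    """One-sided empirical exceedance p-value with the add-one rule."""
    vals = null.values if isinstance(null, NullDistribution) else np.asarray(null, float)
    B = len(vals)
    return float((1 + np.sum(vals >= observed)) / (B + 1))


def permutation_p_bav(
    X: ImagingMatrix,
    y: Phenotype,
    vdi: VdiVector,
    B: int = 1000,
    seed: int = 0,
    C: Optional[pd.DataFrame] = None,
    categorical: Sequence[str] = (),
) -> tuple[float, NullDistribution]:
    """Permutation p-value for an observed BAV (one-sided, upper).

    The phenotype values are shuffled across subjects while covariates stay
    attached to their subjects; subject-level imaging data are required.
    Bit-reproducible given (seed, B).
    """
    if not np.array_equal(X.subject_ids, y.subject_ids):
        raise ValueError("phenotype must be aligned to the imaging panel")
    rng = np.random.default_rng(seed)
    engine = TstatEngine(X, C, categorical)
    observed = fit_bav(engine.summary(y.y, y.trait_label), vdi).b2
    vals = np.empty(B)
    for b in range(B):
        yp = rng.permutation(y.y)
        vals[b] = fit_bav(engine.summary(yp, f"perm{b}"), vdi).b2
    null = NullDistribution(values=vals, statistic_name="b2", seed=seed)
    return quick_p(observed, null), null


def permutation_p_rbrain(
    X: ImagingMatrix,
    y1: Phenotype,
    y2: Phenotype,
    vdi: VdiVector,
    B: int = 1000,
    seed: int = 0,
) -> tuple[float, NullDistribution]:
    """Two-sided permutation p-value for the neuroimaging correlation.

    Both phenotypes are shuffled independently across subjects each
    replicate; the statistic is |r_brain| (uncapped).  Null replicates in
    which either BAV estimate is non-positive have no defined correlation
    and are dropped (count logged); the add-one rule then uses the
    effective replicate count.
    """
    for y in (y1, y2):
        if not np.array_equal(X.subject_ids, y.subject_ids):
            raise ValueError("phenotypes must be aligned to the imaging panel")
    rng = np.random.default_rng(seed)
    engine = TstatEngine(X)

    def _r(ya: np.ndarray, yb: np.ndarray) -> float:
        s1 = engine.summary(ya, "a")
        s2 = engine.summary(yb, "b")
        q = float(np.corrcoef(ya, yb)[0, 1])
        bav1, bav2 = fit_bav(s1, vdi), fit_bav(s2, vdi)
        bac = fit_bac(s1, s2, vdi, Ns=X.n_subjects, Q=q)
        nc = r_brain(bac, bav1, bav2)
        return float("nan") if nc.excluded else nc.r_raw

    observed = _r(y1.y, y2.y)
    if np.isnan(observed):
        raise ValueError("observed pair excluded (non-positive BAV); r undefined")
    vals = []
    n_dropped = 0
    for _ in range(B):
        r = _r(rng.permutation(y1.y), rng.permutation(y2.y))
        if np.isnan(r):
            n_dropped += 1
        else:
            vals.append(r)
    if n_dropped:
        logger.info("permutation_p_rbrain: %d/%d null replicates excluded", n_dropped, B)
    vals = np.asarray(vals)
    null = NullDistribution(values=vals, statistic_name="r_brain", seed=seed)
    p = float((1 + np.sum(np.abs(vals) >= abs(observed))) / (len(vals) + 1))
    return p, null


def bav_difference_test(
    X: ImagingMatrix,
    y1: Phenotype,
    y2: Phenotype,
    vdi: VdiVector,
    B: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Paired test of a BAV difference between two traits on one subject panel.

    diff = b²(y1) − b²(y2).  The null exchanges the two trait values within
    each subject with probability ½, B times; the p-value is two-sided by
    absolute exceedance with the add-one rule.
    """
    if not (
        np.array_equal(X.subject_ids, y1.subject_ids)
        and np.array_equal(X.subject_ids, y2.subject_ids)
    ):
        raise ValueError("both phenotypes must be aligned to the imaging panel")
    rng = np.random.default_rng(seed)
    engine = TstatEngine(X)

    def _diff(a: np.ndarray, b: np.ndarray) -> float:
        f1 = fit_bav(engine.summary(a, "y1"), vdi)
        f2 = fit_bav(engine.summary(b, "y2"), vdi)
        return f1.b2 - f2.b2

    observed = _diff(y1.y, y2.y)
    vals = np.empty(B)
    for i in range(B):
        swap = rng.random(X.n_subjects) < 0.5
        a = np.where(swap, y2.y, y1.y)
        b = np.where(swap, y1.y, y2.y)
        vals[i] = _diff(a, b)
    p = float((1 + np.sum(np.abs(vals) >= abs(observed))) / (B + 1))
    return observed, p


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def split_half(
    parts: Sequence[ImagingMatrix],
    ys: Sequence[Phenotype],
    seed: int = 0,
) -> dict:
    """Split-half reproducibility of BAV estimates across a trait battery.

    The shared subject panel is split at random into two equal halves and
    each trait's BAV is estimated in each half under three dependence-index
    choices: the whole-sample VDI, each half's own VDI, and the *other*
    half's VDI.  Returns the Pearson correlation of the two half-wise BAV
    vectors per variant, plus the underlying BAV table.
    """
    parts = list(parts)
    if len(ys) < 2:
        raise ValueError("need at least 2 traits for a BAV correlation")
    subj = parts[0].subject_ids
    for p in parts[1:]:
        if not np.array_equal(p.subject_ids, subj):
            raise ValueError("all modalities must share one subject panel")
    rng = np.random.default_rng(seed)
    n = len(subj)
    perm = rng.permutation(n)
    half1 = np.zeros(n, dtype=bool)
    half1[perm[: n // 2]] = True
    half2 = ~half1
    if n % 2:  # odd subject dropped from the second half to equalize sizes
        half2[perm[-1]] = False

    vdi_whole = combine_vdi([compute_vdi(p) for p in parts])
    halves = {}
    for tag, mask in (("h1", half1), ("h2", half2)):
        sub = [p.subset_subjects(mask) for p in parts]
        X = ImagingMatrix(
            values=np.hstack([s.values for s in sub]),
            subject_ids=sub[0].subject_ids.copy(),
            voxel_ids=np.concatenate([s.voxel_ids for s in sub]),
            modality="combined",
        )
        halves[tag] = {
            "mask": mask,
            "engine": TstatEngine(X),
            "vdi": combine_vdi([compute_vdi(s) for s in sub]),
        }

    variants = {
        "whole_sample_vdi": {"h1": vdi_whole, "h2": vdi_whole},
        "own_half_vdi": {"h1": halves["h1"]["vdi"], "h2": halves["h2"]["vdi"]},
        "cross_half_vdi": {"h1": halves["h2"]["vdi"], "h2": halves["h1"]["vdi"]},
    }
    rows = []
    for trait in ys:
        if not np.array_equal(trait.subject_ids, subj):
            raise ValueError("phenotypes must be aligned to the subject panel")
        for tag in ("h1", "h2"):
            h = halves[tag]
            stats = h["engine"].summary(trait.y[h["mask"]], trait.trait_label)
            for vname, vmap in variants.items():
                fit = fit_bav(stats, vmap[tag])
                rows.append(
                    {"trait": trait.trait_label, "half": tag,
                     "variant": vname, "b2": fit.b2}
                )
    table = pd.DataFrame(rows)
    corr = {}
    for vname in variants:
        wide = table[table["variant"] == vname].pivot(
            index="trait", columns="half", values="b2"
        )
        corr[vname] = float(np.corrcoef(wide["h1"], wide["h2"])[0, 1])
    return {"correlations": corr, "bav_table": table, "seed": seed}
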