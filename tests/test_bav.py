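"""Two-stage BAV regression: exact-linear oracles, null behaviour, confounding."""

import numpy as np
import pytest
import statsmodels.api as sm

from vdireg.bav import BavRegression, fit_bav, fit_bav_combined, wls_line
from vdireg.containers import SummaryStats, VdiVector
from vdireg.synthdata import (
    ModalitySpec,
    SimulationSpec,
    TraitRecipe,
    generate_imaging,
    generate_phenotype,
)
from vdireg.assoc import compute_tstats
from vdireg.containers import ImagingMatrix, Phenotype
from vdireg.vdi import compute_vdi


def make_stats(t, n=100, modality="SIM", label="y"):
    t = np.asarray(t, dtype=float)
    ids = np.array([f"{modality}:v{i}" for i in range(len(t))], dtype=object)
    return SummaryStats(t=t, voxel_ids=ids, modality=modality,
                        trait_label=label, n_eff=n, df=n - 2)


def make_vdi(v, n_ref=100, modality="SIM"):
    v = np.asarray(v, dtype=float)
    ids = np.array([f"{modality}:v{i}" for i in range(len(v))], dtype=object)
    return VdiVector(v=v, voxel_ids=ids, modality=modality, n_ref=n_ref)


def test_unit_t_squared_gives_exact_null():
    rng = np.random.default_rng(0)
    v = rng.uniform(0, 10, size=40)
    signs = rng.choice([-1.0, 1.0], size=40)
    fit = fit_bav(make_stats(signs), make_vdi(v), N=100)
    assert fit.beta == pytest.approx(0.0, abs=1e-12)
    assert fit.b2 == pytest.approx(0.0, abs=1e-12)
    assert fit.c == pytest.approx(1.0, abs=1e-12)
    assert fit.a == pytest.approx(0.0, abs=1e-12)


def test_exact_linear_data_recovered_for_any_weights():
    rng = np.random.default_rng(1)
    v = rng.uniform(0.1, 8, size=50)
    t = np.sqrt(2 * v + 1)
    fit = fit_bav(make_stats(t, n=100), make_vdi(v), N=100)
    # slope 2 and intercept 1 are exact under WLS with any positive weights
    assert fit.beta == pytest.approx(2.0, rel=1e-10)
    assert fit.c == pytest.approx(1.0, rel=1e-10)
    assert fit.b2 == pytest.approx(2.0 * 50 / 100, rel=1e-10)  # = 1.0
    assert fit.M == 50 and fit.N == 100
    # invariants of the record
    assert fit.beta == pytest.approx(fit.N * fit.b2 / fit.M)
    assert fit.a == pytest.approx((fit.c - 1) / fit.N)


def test_stage2_matches_weighted_normal_equations_oracle():
    """On noisy data the stage-2 WLS must agree with an independently
    computed weighted least-squares solve using the same weight law."""
    rng = np.random.default_rng(2)
    M, N = 200, 500
    v = rng.uniform(0.05, 12, size=M)
    t2 = np.maximum(0.5 * v + 1 + rng.normal(0, 1, size=M), 1e-3)
    t = np.sqrt(t2)
    fit = fit_bav(make_stats(t, n=N), make_vdi(v), N=N)
    # independent weight construction from the documented law
    s1 = np.linalg.lstsq(v[:, None], (t2 - 1), rcond=None)[0][0]
    g = 2.0 * (max(s1, 0.0) * v + 1.0) ** 2
    w = 1.0 / (g * np.maximum(v, 1.0))
    res = sm.WLS(t2, sm.add_constant(v), weights=w).fit()
    assert fit.c == pytest.approx(res.params[0], rel=1e-8)
    assert fit.beta == pytest.approx(res.params[1], rel=1e-8)
    assert fit.b2 == pytest.approx(res.params[1] * M / N, rel=1e-8)


def test_weight_rescaling_invariance():
    rng = np.random.default_rng(3)
    x = rng.uniform(0, 5, 30)
    y = 2 * x + rng.normal(size=30)
    w = rng.uniform(0.1, 2, 30)
    assert np.allclose(wls_line(x, y, w), wls_line(x, y, 17.3 * w))


def test_negative_b2_reported_untruncated():
    rng = np.random.default_rng(4)
    v = np.linspace(0.5, 10, 40)
    t2 = np.maximum(2.0 - 0.15 * v + 0.01 * rng.normal(size=40), 0.01)
    fit = fit_bav(make_stats(np.sqrt(t2), n=50), make_vdi(v), N=50)
    assert fit.b2 < 0


def test_constant_vdi_rejected():
    with pytest.raises(ValueError, match="unidentifiable"):
        fit_bav(make_stats(np.ones(10)), make_vdi(np.full(10, 2.0)), N=50)


def test_too_few_voxels_rejected():
    est = BavRegression()
    with pytest.raises(ValueError, match="at least 3"):
        est.fit([1.0, 2.0], [1.0, 1.0], n_subjects=10)


def test_misaligned_voxel_ids_rejected():
    stats = make_stats(np.ones(5), modality="A")
    vdi = make_vdi(np.arange(5.0), modality="B")
    with pytest.raises(ValueError, match="aligned"):
        fit_bav(stats, vdi)


def test_sklearn_param_interface():
    est = BavRegression(weight_floor=2.0)
    assert est.get_params() == {"weight_floor": 2.0, "floor_stage1": True}
    est.set_params(weight_floor=1.0)
    est.fit(np.linspace(0, 5, 20), np.ones(20), n_subjects=100)
    assert hasattr(est, "b2_") and hasattr(est, "c_")


class TestCombined:
    def test_equal_n_reduces_to_single_fit(self):
        rng = np.random.default_rng(5)
        sa = make_stats(rng.normal(size=30), n=80, modality="A")
        sb = make_stats(rng.normal(size=25), n=80, modality="B")
        va = make_vdi(rng.uniform(0, 6, 30), modality="A")
        vb = make_vdi(rng.uniform(0, 6, 25), modality="B")
        combined = fit_bav_combined([sa, sb], [va, vb])
        concat = fit_bav(
            make_stats(np.concatenate([sa.t, sb.t]), n=80, modality="AB"),
            make_vdi(np.concatenate([va.v, vb.v]), modality="AB"),
            N=80,
        )
        assert combined.b2 == pytest.approx(concat.b2, rel=1e-12)
        assert combined.c == pytest.approx(concat.c, rel=1e-12)

    def test_null_phenotype_near_zero(self):
        spec = SimulationSpec(
            n_subjects=400,
            modalities=[ModalitySpec("A", 200, 50), ModalitySpec("B", 200, 50)],
            seed=6,
        )
        mats = generate_imaging(spec)
        rng = np.random.default_rng(7)
        b2s, cs = [], []
        for _ in range(10):
            stats, vdis = [], []
            for Xm in mats:
                y = Phenotype(rng.normal(size=400), Xm.subject_ids.copy(), "null")
                stats.append(compute_tstats(Xm, y))
                vdis.append(compute_vdi(Xm))
            fit = fit_bav_combined(stats, vdis)
            b2s.append(fit.b2)
            cs.append(fit.c)
        assert abs(np.mean(b2s)) < 0.05
        assert abs(np.mean(cs) - 1.0) < 0.15

    def test_signal_confined_to_one_part(self):
        from vdireg.assoc import TstatEngine

        spec = SimulationSpec(
            n_subjects=800,
            modalities=[ModalitySpec("A", 500, 50), ModalitySpec("B", 500, 50)],
            seed=8,
        )
        XA, XB = generate_imaging(spec)
        va, vb = compute_vdi(XA), compute_vdi(XB)
        ea, eb = TstatEngine(XA), TstatEngine(XB)
        rng = np.random.default_rng(9)
        alone, both = [], []
        for _ in range(20):
            y, _ = generate_phenotype(XA, TraitRecipe(target_bav=0.3), rng)
            sa, sb = ea.summary(y.y), eb.summary(y.y)
            alone.append(fit_bav(sa, va).b2)
            both.append(fit_bav_combined([sa, sb], [va, vb]).b2)
        # part B holds only null voxels: combined estimate tracks part A's
        assert np.corrcoef(alone, both)[0, 1] > 0.8
        assert abs(np.mean(both) - np.mean(alone)) < 0.15


def test_shared_confounder_raises_intercept_b2_stays_near_preset():
    """A site-like effect present in the phenotype and in every voxel (with
    voxel-specific sign and scale) inflates t² uniformly across the
    dependence index: the intercept absorbs it while the slope-based BAV
    stays near its preset — the confounding diagnostic the intercept exists
    for."""
    from vdireg.assoc import TstatEngine

    spec = SimulationSpec(
        n_subjects=600, modalities=[ModalitySpec("A", 500, 50)], seed=10
    )
    (X,) = generate_imaging(spec)
    rng = np.random.default_rng(11)
    confound = rng.normal(size=600)
    signs = rng.choice([-1.0, 1.0], size=500)
    sd = X.values.std(axis=0)
    Xc = ImagingMatrix(
        X.values + 0.25 * (sd * signs)[None, :] * confound[:, None],
        X.subject_ids, X.voxel_ids, X.modality,
    )
    vdi_c = compute_vdi(Xc)
    engine = TstatEngine(Xc)
    cs_clean, cs_conf, b2_conf = [], [], []
    for _ in range(15):
        y_clean, _ = generate_phenotype(Xc, TraitRecipe(target_bav=0.1), rng)
        fit_clean = fit_bav(engine.summary(y_clean.y), vdi_c)
        fit_conf = fit_bav(engine.summary(y_clean.y + 0.8 * confound), vdi_c)
        cs_clean.append(fit_clean.c)
        cs_conf.append(fit_conf.c)
        b2_conf.append(fit_conf.b2)
    assert np.mean(cs_conf) > np.mean(cs_clean) + 0.5
    assert np.mean(cs_conf) > 1.5
    # the intercept takes up most of the contamination; the slope keeps the
    # BAV in the neighbourhood of its preset (loose: a diffuse component
    # present in the voxel data is partly genuine brain signal, and the
    # replicate spread at this panel size is large)
    assert abs(np.mean(b2_conf) - 0.1) < 0.3
    assert np.mean(cs_conf) - np.mean(cs_clean) > np.mean(b2_conf) - 0.1
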