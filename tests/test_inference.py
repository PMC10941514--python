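"""Permutation and null-simulation inference: hand counts, determinism, power."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from vdireg.containers import Phenotype
from vdireg.inference import (
    NullDistribution,
    bav_difference_test,
    build_quick_null,
    fdr_adjust,
    permutation_p_bav,
    quick_p,
    split_half,
)
from vdireg.synthdata import (
    ModalitySpec,
    SimulationSpec,
    TraitRecipe,
    combined_panel,
    generate_imaging,
    generate_phenotype,
)
from vdireg.vdi import compute_vdi


def small_panel(n=300, m=400, seed=0):
    spec = SimulationSpec(
        n_subjects=n, modalities=[ModalitySpec("A", m, 50)], seed=seed
    )
    (X,) = generate_imaging(spec)
    return X, compute_vdi(X)


class TestQuickP:
    def test_hand_count(self):
        assert quick_p(0.25, np.array([0.1, 0.2, 0.3, 0.4])) == pytest.approx(3 / 5)

    def test_exceedance_floor(self):
        null = np.array([0.1, 0.2, 0.3, 0.4])
        assert quick_p(0.41, null) == pytest.approx(1 / 5)

    def test_median_observation(self):
        rng = np.random.default_rng(0)
        null = rng.normal(size=999)
        assert quick_p(np.median(null), null) == pytest.approx(0.5, abs=0.01)

    def test_never_zero_or_above_one(self):
        null = np.arange(10.0)
        assert 0 < quick_p(100.0, null)
        assert quick_p(-100.0, null) == 1.0


def test_null_distribution_ci_is_percentile_envelope():
    vals = np.arange(1000.0)
    nd = NullDistribution(values=vals, statistic_name="b2", seed=0)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    assert nd.ci95 == (lo, hi)
    assert nd.B == 1000


def test_quick_null_centered_near_zero_on_noise_panel():
    X, vdi = small_panel(n=200, m=150, seed=1)
    null = build_quick_null(X, vdi, B=100, seed=2)
    assert abs(np.median(null.values)) < 0.05
    assert null.ci95[0] < 0 < null.ci95[1]


def test_quick_null_rejects_tiny_B(small_matrix=None):
    X, vdi = small_panel(n=50, m=30, seed=3)
    with pytest.raises(ValueError, match="B >= 100"):
        build_quick_null(X, vdi, B=10)


class TestPermutationBav:
    def test_deterministic_given_seed(self):
        X, vdi = small_panel(n=120, m=100, seed=4)
        y, _ = generate_phenotype(X, TraitRecipe(0.1), 5)
        p1, null1 = permutation_p_bav(X, y, vdi, B=60, seed=9)
        p2, null2 = permutation_p_bav(X, y, vdi, B=60, seed=9)
        assert p1 == p2
        assert np.array_equal(null1.values, null2.values)
        p3, null3 = permutation_p_bav(X, y, vdi, B=60, seed=10)
        assert not np.array_equal(null1.values, null3.values)

    def test_power_on_strong_signal(self):
        # signal planted at the most brain-dependent voxel so the observed
        # BAV reliably dominates every permutation draw
        X, vdi = small_panel(n=300, m=400, seed=6)
        rng = np.random.default_rng(7)
        from scipy.stats import zscore

        j = int(np.argmax(vdi.v))
        y = Phenotype(
            zscore(X.values[:, j]) + rng.normal(0, 0.8, 300),
            X.subject_ids.copy(), "strong",
        )
        p, _ = permutation_p_bav(X, y, vdi, B=99, seed=8)
        assert p == pytest.approx(1 / 100)

    def test_null_phenotype_p_not_extreme(self):
        X, vdi = small_panel(n=150, m=100, seed=7)
        ps = []
        for s in range(10):
            y, _ = generate_phenotype(X, TraitRecipe(0.0), 100 + s)
            p, _ = permutation_p_bav(X, y, vdi, B=49, seed=s)
            ps.append(p)
        assert 0.2 < np.mean(ps) < 0.8  # uniform on average

    def test_requires_aligned_subjects(self):
        X, vdi = small_panel(n=50, m=30, seed=8)
        y = Phenotype(np.zeros(10), np.array([f"z{i}" for i in range(10)], dtype=object), "y")
        with pytest.raises(ValueError, match="aligned"):
            permutation_p_bav(X, y, vdi, B=10)


class TestBavDifference:
    def test_identical_traits_give_zero_diff_and_p_one(self):
        X, vdi = small_panel(n=150, m=100, seed=9)
        y, _ = generate_phenotype(X, TraitRecipe(0.1), 11)
        diff, p = bav_difference_test(X, y, y, vdi, B=30, seed=1)
        assert diff == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_antisymmetry(self):
        X, vdi = small_panel(n=150, m=100, seed=10)
        y1, _ = generate_phenotype(X, TraitRecipe(0.2), 12)
        y2, _ = generate_phenotype(X, TraitRecipe(0.0), 13)
        d12, p12 = bav_difference_test(X, y1, y2, vdi, B=40, seed=2)
        d21, p21 = bav_difference_test(X, y2, y1, vdi, B=40, seed=2)
        assert d12 == pytest.approx(-d21)
        assert p12 == p21  # swap scheme is symmetric under relabeling

    def test_power_against_null_trait(self):
        X, vdi = small_panel(n=300, m=400, seed=11)
        y1, _ = generate_phenotype(X, TraitRecipe(0.2), 14)
        y2, _ = generate_phenotype(X, TraitRecipe(0.0), 15)
        diff, p = bav_difference_test(X, y1, y2, vdi, B=99, seed=3)
        assert diff > 0
        assert p <= 0.05


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_all_equal_unchanged(self):
        assert np.allclose(fdr_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_hand_computed_staircase(self):
        assert np.allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_hand_computed_general(self):
        # BH: p_(i) * n / i, cumulative-min from the largest
        p = [0.005, 0.04, 0.03, 0.8]
        expected = [0.02, 0.053333333333, 0.053333333333, 0.8]
        assert np.allclose(fdr_adjust(p), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            fdr_adjust([1.5])


def test_quick_and_permutation_p_rank_agreement():
    """The two procedures order a battery of traits consistently."""
    X, vdi = small_panel(n=300, m=400, seed=12)
    null = build_quick_null(X, vdi, B=150, seed=0)
    rng = np.random.default_rng(13)
    quick_ps, perm_ps = [], []
    presets = np.linspace(0.0, 0.08, 20)
    from vdireg.assoc import TstatEngine
    from vdireg.bav import fit_bav

    engine = TstatEngine(X)
    for i, h in enumerate(presets):
        y, _ = generate_phenotype(X, TraitRecipe(float(h)), rng)
        obs = fit_bav(engine.summary(y.y), vdi).b2
        quick_ps.append(quick_p(obs, null))
        p, _ = permutation_p_bav(X, y, vdi, B=150, seed=1000 + i)
        perm_ps.append(p)
    rho, _ = spearmanr(quick_ps, perm_ps)
    assert rho >= 0.8


class TestSplitHalf:
    @staticmethod
    def _battery(X, presets, seed0):
        return [
            Phenotype(
                generate_phenotype(X, TraitRecipe(h), seed0 + i)[0].y,
                X.subject_ids.copy(),
                f"trait{i}",
            )
            for i, h in enumerate(presets)
        ]

    def test_recovers_trait_ordering_across_halves(self):
        spec = SimulationSpec(
            n_subjects=1000,
            modalities=[ModalitySpec("A", 300, 50), ModalitySpec("B", 300, 50)],
            seed=14,
        )
        mats = generate_imaging(spec)
        X, _ = combined_panel(mats)
        ys = self._battery(X, [0.0, 0.05, 0.1, 0.2, 0.3, 0.45], seed0=200)
        report = split_half(mats, ys, seed=5)
        for variant, r in report["correlations"].items():
            assert r > 0.5, f"{variant}: r={r}"

    def test_seeded_split_reproducible(self):
        spec = SimulationSpec(
            n_subjects=200, modalities=[ModalitySpec("A", 100, 25)], seed=15
        )
        mats = generate_imaging(spec)
        X, _ = combined_panel(mats)
        ys = self._battery(X, [0.0, 0.3], seed0=300)
        r1 = split_half(mats, ys, seed=7)
        r2 = split_half(mats, ys, seed=7)
        assert r1["correlations"] == r2["correlations"]

    def test_needs_two_traits(self):
        spec = SimulationSpec(
            n_subjects=100, modalities=[ModalitySpec("A", 50, 25)], seed=16
        )
        mats = generate_imaging(spec)
        ys = self._battery(mats[0], [0.1], seed0=400)
        with pytest.raises(ValueError, match="2 traits"):
            split_half(mats, ys, seed=0)
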