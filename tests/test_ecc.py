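import numpy as np
import pytest

from conftest import brute_force_chi, make_standardized
from hbpqa.ecc import (ECCurve, SmoothedECCurve, ecc_curve,
                       euler_characteristic, excursion_set, fit_fpca,
                       fpc_scores, reconstruct, smooth_ecc)


class TestEulerCharacteristic:
    def test_single_voxel(self):
        g = np.zeros((1, 1, 1), bool)
        g[0, 0, 0] = True
        assert euler_characteristic(g) == 1  # 8 - 12 + 6 - 1

    def test_two_disjoint_voxels_additive(self):
        g = np.zeros((3, 1, 1), bool)
        g[0, 0, 0] = g[2, 0, 0] = True
        assert euler_characteristic(g) == 2

    def test_hollow_cube_has_void(self):
        g = np.ones((3, 3, 3), bool)
        g[1, 1, 1] = False
        assert euler_characteristic(g) == 2  # one component + one void

    def test_voxel_ring_has_handle(self):
        g = np.zeros((4, 4, 1), bool)
        g[:, :, 0] = True
        g[1:3, 1:3, 0] = False
        assert euler_characteristic(g) == 0  # one component - one handle

    def test_empty_grid(self):
        assert euler_characteristic(np.zeros((4, 4, 4), bool)) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for density in (0.2, 0.5, 0.8):
            g = rng.random((4, 4, 4)) < density
            assert euler_characteristic(g) == brute_force_chi(g)

    def test_additive_over_disjoint_components(self):
        rng = np.random.default_rng(3)
        a = rng.random((3, 3, 3)) < 0.5
        b = rng.random((3, 3, 3)) < 0.5
        combined = np.zeros((7, 3, 3), bool)
        combined[:3] = a
        combined[4:] = b
        assert euler_characteristic(combined) == \
            euler_characteristic(a) + euler_characteristic(b)


class TestExcursionSets:
    def test_low_threshold_recovers_mask(self):
        v = make_standardized(np.ones((3, 3, 3)))
        np.testing.assert_array_equal(excursion_set(v, -10.0), v.mask)

    def test_high_threshold_empty(self):
        v = make_standardized(np.ones((3, 3, 3)))
        assert not excursion_set(v, 10.0).any()

    def test_strict_inequality_at_threshold(self):
        v = make_standardized(np.zeros((2, 2, 2)))
        assert not excursion_set(v, 0.0).any()

    def test_two_point_phantom_zero_threshold_selects_parenchyma(self):
        vals = np.full((4, 4, 4), 0.5)
        vals[0] = -1.0  # "vessel" slab
        v = make_standardized(vals)
        ex = excursion_set(v, 0.0)
        np.testing.assert_array_equal(ex, vals > 0)

    def test_nested_across_thresholds(self):
        rng = np.random.default_rng(2)
        v = make_standardized(rng.normal(size=(6, 6, 6)))
        prev = excursion_set(v, -2.0)
        for u in (-1.0, 0.0, 1.0, 2.0):
            cur = excursion_set(v, u)
            assert np.all(cur <= prev)
            prev = cur


class TestECCurve:
    def test_constant_image_step_curve(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[1:4, 1:4, 1:4] = True
        v = make_standardized(np.where(mask, 0.5, np.nan), mask)
        c = ecc_curve(v, np.linspace(-1, 2, 7))
        n = mask.sum()
        chi_mask = euler_characteristic(mask)
        expected = [chi_mask / n if u < 0.5 else 0.0
                    for u in c.thresholds]
        np.testing.assert_allclose(c.chi_norm, expected)

    def test_chi_integer_valued(self):
        rng = np.random.default_rng(0)
        v = make_standardized(rng.normal(size=(8, 8, 8)))
        c = ecc_curve(v, np.linspace(-2, 2, 21))
        assert c.chi.dtype.kind == "i"

    def test_matches_per_threshold_oracle_on_random_phantom(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(16, 16, 16))
        v = make_standardized(vals)
        thresholds = np.linspace(-2, 2, 11)
        c = ecc_curve(v, thresholds)
        for u, chi in zip(thresholds, c.chi):
            assert chi == brute_force_chi(vals > u)

    def test_constructed_handles_reduce_chi(self):
        """v tubes piercing a slab create v handles: chi = 1 - v at
        thresholds between vessel and parenchyma intensity."""
        vals = np.full((12, 12, 6), 1.0)
        for x in (2, 6, 9):
            vals[x, :, 2:4] = -1.0  # three full tubes along y
        v = make_standardized(vals)
        ex = excursion_set(v, 0.0)
        assert euler_characteristic(ex) == 1 - 3

    def test_slicewise_option_sums_slice_complexes(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(6, 6, 4))
        v = make_standardized(vals)
        c3d = ecc_curve(v, np.array([0.0]))
        c2d = ecc_curve(v, np.array([0.0]), slicewise=True)
        expected = sum(brute_force_chi((vals[:, :, k:k + 1] > 0))
                       for k in range(4))
        assert c2d.chi[0] == expected
        assert c2d.chi[0] != c3d.chi[0] or vals.shape[2] == 1


class TestSmoothing:
    def test_zero_curve_integrates_to_zero(self):
        c = ECCurve(thresholds=np.linspace(-1, 1, 11),
                    chi=np.zeros(11, int), n_liver_voxels=10)
        s = smooth_ecc(c)
        np.testing.assert_array_equal(s.values, 0.0)

    def test_unit_step_hand_integration(self):
        u = np.linspace(-1, 1, 21)     # spacing 0.1
        chi = (u < 0).astype(int) * 10
        c = ECCurve(thresholds=u, chi=chi, n_liver_voxels=10)
        s = smooth_ecc(c)
        assert s.values[0] == pytest.approx(1.0)   # 10 steps of 0.1 at height 1
        assert s.values[-1] == 0.0

    def test_right_endpoint_always_zero(self):
        rng = np.random.default_rng(0)
        c = ECCurve(thresholds=np.linspace(-3, 3, 31),
                    chi=rng.integers(-5, 5, 31), n_liver_voxels=100)
        assert smooth_ecc(c).values[-1] == 0.0

    def test_nonincreasing_where_chi_nonnegative(self):
        c = ECCurve(thresholds=np.linspace(-3, 3, 31),
                    chi=np.full(31, 2), n_liver_voxels=10)
        s = smooth_ecc(c)
        assert np.all(np.diff(s.values) <= 0)


def synthetic_curve_family(n=200, m=101, seed=0):
    """Curves mu + xi1 phi1 + xi2 phi2 with orthonormal cosine components
    and independent scores of variance (4, 1)."""
    u = np.linspace(-3, 3, m)
    L = u[-1] - u[0]
    mean = 0.5 * u ** 2 / 9
    phi1 = np.sqrt(2 / L) * np.cos(np.pi * (u - u[0]) / L)
    phi2 = np.sqrt(2 / L) * np.cos(2 * np.pi * (u - u[0]) / L)
    rng = np.random.default_rng(seed)
    xi1 = rng.normal(0, 2.0, n)
    xi2 = rng.normal(0, 1.0, n)
    curves = [SmoothedECCurve(thresholds=u,
                              values=mean + a * phi1 + b * phi2)
              for a, b in zip(xi1, xi2)]
    return u, mean, phi1, phi2, curves


class TestFPCA:
    def test_identical_curves_zero_eigenvalues_and_scores(self):
        u = np.linspace(-3, 3, 51)
        c = SmoothedECCurve(thresholds=u, values=np.sin(u))
        curves = [SmoothedECCurve(thresholds=u, values=c.values.copy())
                  for _ in range(10)]
        model = fit_fpca(curves, K=3)
        np.testing.assert_allclose(model.eigenvalues, 0.0, atol=1e-12)
        np.testing.assert_allclose(fpc_scores(model, c), 0.0, atol=1e-6)

    def test_karhunen_loeve_recovery(self):
        u, mean, phi1, phi2, curves = synthetic_curve_family(seed=0)
        model = fit_fpca(curves, K=3)
        w = model.quad_weights
        assert model.eigenvalues[0] == pytest.approx(4.0, rel=0.15)
        assert model.eigenvalues[1] == pytest.approx(1.0, rel=0.15)
        align1 = abs(np.sum(w * model.eigenfunctions[0] * phi1))
        align2 = abs(np.sum(w * model.eigenfunctions[1] * phi2))
        assert align1 > 0.99
        assert align2 > 0.99

    def test_rank_two_family_third_eigenvalue_zero(self):
        _, _, _, _, curves = synthetic_curve_family(n=50, seed=2)
        model = fit_fpca(curves, K=3)
        top2 = model.eigenvalues[:2].sum()
        assert top2 / model.total_variance == pytest.approx(1.0, abs=1e-8)
        assert model.eigenvalues[2] == pytest.approx(0.0, abs=1e-8)

    def test_eigenfunctions_orthonormal_under_quadrature(self):
        _, _, _, _, curves = synthetic_curve_family(n=40, seed=3)
        model = fit_fpca(curves, K=2)
        w = model.quad_weights
        gram = model.eigenfunctions @ (w[:, None] * model.eigenfunctions.T)
        np.testing.assert_allclose(gram, np.eye(2), atol=1e-8)

    def test_sign_convention_nonnegative_integral(self):
        _, _, _, _, curves = synthetic_curve_family(n=40, seed=4)
        model = fit_fpca(curves, K=3)
        integrals = model.eigenfunctions @ model.quad_weights
        assert np.all(integrals >= -1e-9)

    def test_too_few_curves_rejected(self):
        _, _, _, _, curves = synthetic_curve_family(n=3, seed=5)
        with pytest.raises(ValueError):
            fit_fpca(curves, K=3)


class TestScores:
    def test_mean_curve_scores_zero(self):
        _, mean, _, _, curves = synthetic_curve_family(n=30, seed=6)
        model = fit_fpca(curves, K=2)
        mean_curve = SmoothedECCurve(thresholds=model.thresholds,
                                     values=model.mean)
        np.testing.assert_allclose(fpc_scores(model, mean_curve), 0.0,
                                   atol=1e-10)

    def test_unit_component_displacement_scores_orthonormally(self):
        u, mean, phi1, phi2, curves = synthetic_curve_family(seed=7)
        model = fit_fpca(curves, K=2)
        sign = np.sign(np.sum(model.quad_weights * model.eigenfunctions[0] * phi1))
        c = SmoothedECCurve(thresholds=u, values=model.mean + 2 * phi1)
        scores = fpc_scores(model, c)
        assert scores[0] == pytest.approx(2.0 * sign, abs=0.05)
        assert scores[1] == pytest.approx(0.0, abs=0.05)

    def test_training_scores_centered(self):
        _, _, _, _, curves = synthetic_curve_family(n=60, seed=8)
        model = fit_fpca(curves, K=3)
        scores = np.stack([fpc_scores(model, c) for c in curves])
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-8)

    def test_holdout_reconstruction_error_small(self):
        """When 3 components explain >99% of training variance, held-out
        curves reconstruct with <1% relative L2 error."""
        _, _, _, _, curves = synthetic_curve_family(n=220, seed=9)
        train, test = curves[:200], curves[200:]
        model = fit_fpca(train, K=3)
        assert model.explained_variance_ratio[:3].sum() > 0.99
        w = model.quad_weights
        for c in test:
            rec = reconstruct(model, fpc_scores(model, c))
            num = np.sqrt(np.sum(w * (rec - c.values) ** 2))
            den = np.sqrt(np.sum(w * c.values ** 2))
            assert num / den < 0.01

    def test_curve_and_model_exports_roundtrip(self, tmp_path):
        import json
        import pandas as pd
        from hbpqa.ecc import curve_to_csv, fpc_model_to_json
        u = np.linspace(-1, 1, 5)
        c = ECCurve(thresholds=u, chi=np.array([2, 1, 0, -1, 0]),
                    n_liver_voxels=10)
        curve_to_csv(c, tmp_path / "curve.csv", smoothed=smooth_ecc(c))
        df = pd.read_csv(tmp_path / "curve.csv")
        np.testing.assert_allclose(df["chi_norm"], c.chi_norm)
        _, _, _, _, curves = synthetic_curve_family(n=10, seed=12)
        model = fit_fpca(curves, K=2)
        fpc_model_to_json(model, tmp_path / "model.json")
        payload = json.loads((tmp_path / "model.json").read_text())
        np.testing.assert_allclose(payload["eigenvalues"], model.eigenvalues)

    def test_grid_mismatch_rejected(self):
        _, _, _, _, curves = synthetic_curve_family(n=10, seed=10)
        model = fit_fpca(curves, K=2)
        other = SmoothedECCurve(thresholds=np.linspace(-2, 2, 101),
                                values=np.zeros(101))
        with pytest.raises(ValueError, match="grid"):
            fpc_scores(model, other)
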