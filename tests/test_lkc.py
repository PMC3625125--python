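"""Both LKC estimators, resel conversion and residual rotation."""

import numpy as np
import pytest

from spmtopo.fields_glm import ResidualSet, one_sample_t
from spmtopo.lkc import (
    LKCVector,
    lkc_regress,
    lkc_residual_set,
    lkc_smoothness,
    lkc_test_spm,
    lkc_to_resels,
    resels_to_lkc,
    rotate_residuals,
    simplex_volume,
)
from spmtopo.rft_density import FieldSpec, density_matrix, threshold_grid
from spmtopo.topology import ECCurve, build_complex, l0


def make_residual_set(data, df=None):
    n, sites = data.shape
    mask_shape = (sites,)
    df = n - 1 if df is None else df
    return ResidualSet(data=data, mask=np.ones(mask_shape, bool), df=df)


class TestSimplexVolume:
    def test_identity_gram_triangle(self):
        # columns orthonormal: area = 1/2 ("half base times height")
        delta = np.eye(4)[:, :2]
        assert simplex_volume(delta) == pytest.approx(0.5)

    def test_segment_length(self):
        delta = np.array([[3.0], [4.0]])
        assert simplex_volume(delta) == pytest.approx(5.0)

    def test_matches_gram_determinant_oracle(self, rng):
        delta = rng.standard_normal((10, 3))
        # independent computation via singular values
        sv = np.linalg.svd(delta, compute_uv=False)
        oracle = np.prod(sv[:3]) / 6.0
        assert simplex_volume(delta) == pytest.approx(oracle, abs=1e-10)

    def test_degenerate_columns_zero(self):
        col = np.array([[1.0], [2.0]])
        delta = np.hstack([col, 2 * col])
        assert simplex_volume(delta) == 0.0


class TestReselConversion:
    def test_fig_scale_factor(self):
        resels = lkc_to_resels(LKCVector([1.0, 16.65]))
        assert resels.values[1] == pytest.approx(10.0, abs=0.01)
        assert resels.values[0] == 1.0

    def test_l0_invariant(self):
        assert lkc_to_resels(LKCVector([2.0, 5.0])).values[0] == 2.0

    def test_round_trip(self, rng):
        v = LKCVector(rng.standard_normal(4))
        back = resels_to_lkc(lkc_to_resels(v))
        assert np.allclose(back.values, v.values, atol=1e-12)

    def test_double_conversion_error(self):
        r = lkc_to_resels(LKCVector([1.0, 2.0]))
        with pytest.raises(ValueError):
            lkc_to_resels(r)
        with pytest.raises(ValueError):
            resels_to_lkc(LKCVector([1.0, 2.0]))


class TestLkcSmoothness:
    def test_perfectly_correlated_residuals_zero_volume(self):
        c = build_complex(np.ones((4, 4), dtype=bool))
        base = np.random.default_rng(0).standard_normal(8)
        base = np.sqrt(7) * base / np.linalg.norm(base)
        data = np.tile(base[:, None], (1, 16))
        lkc = lkc_smoothness(make_residual_set(data), c)
        assert lkc[0] == 1
        assert lkc[1] == pytest.approx(0.0, abs=1e-12)
        assert lkc[2] == pytest.approx(0.0, abs=1e-12)

    def test_chain_sums_segment_lengths(self):
        # unit-norm residual vectors orthogonal between neighbours:
        # every edge has flattened length sqrt(2)
        sites, n = 6, 8
        df = n - 1
        data = np.zeros((n, sites))
        for j in range(sites):
            data[j, j] = np.sqrt(df)  # unit-norm after /sqrt(df)
        c = build_complex(np.ones(sites, dtype=bool))
        lkc = lkc_smoothness(make_residual_set(data, df=df), c)
        assert lkc[1] == pytest.approx((sites - 1) * np.sqrt(2.0))

    def test_analytic_smoothness_oracle_2d(self):
        """l_2 of smoothed white noise matches 4 ln2 * area / FWHM^2."""
        from spmtopo.simulation import SimConfig, gen_noise_fields

        fwhm, side = 4.0, 64
        vals = []
        for seed in range(5):
            cfg = SimConfig(shape=(side, side), n_obs=100, noise_fwhm=fwhm, seed=seed)
            fields = gen_noise_fields(cfg)
            _, rset = one_sample_t(fields)
            c = build_complex(rset.mask)
            vals.append(lkc_smoothness(rset, c)[2])
        analytic = 4 * np.log(2) * (side - 1) ** 2 / fwhm ** 2
        assert np.mean(vals) == pytest.approx(analytic, rel=0.10)

    def test_observation_sign_flip_invariance(self, rng):
        # flipping the sign of whole residual fields flips one coordinate
        # of every site vector: all Gram matrices are unchanged
        c = build_complex(np.ones((5, 5), dtype=bool))
        data = rng.standard_normal((10, 25))
        data = np.sqrt(9) * data / np.linalg.norm(data, axis=0)
        flip = np.where(rng.random(10) > 0.5, 1.0, -1.0)
        a = lkc_smoothness(make_residual_set(data), c)
        b = lkc_smoothness(make_residual_set(data * flip[:, None]), c)
        assert np.allclose(a.values, b.values, atol=1e-10)

    def test_mismatched_complex_error(self, rng):
        c = build_complex(np.ones((3, 3), dtype=bool))
        data = rng.standard_normal((5, 4))
        with pytest.raises(ValueError):
            lkc_smoothness(make_residual_set(data), c)


class TestLkcRegress:
    @pytest.mark.parametrize("D", [1, 2, 3])
    def test_noiseless_recovery(self, D):
        grid = threshold_grid()
        spec = FieldSpec("Z")
        dm = density_matrix(spec, grid, D)
        truth = np.array([1.0, 3.7, 12.2, 7.7])[: D + 1]
        ec = truth[0] * dm.rho0 + dm.matrix @ truth[1:]
        est = lkc_regress(ECCurve(grid, ec), spec, l0=truth[0], D=D)
        assert np.max(np.abs(est.values - truth)) < 1e-8

    def test_zero_curve_zero_estimate(self):
        grid = threshold_grid()
        dm = density_matrix(FieldSpec("Z"), grid, 2)
        ec = 1.0 * dm.rho0  # exactly the l0 term
        est = lkc_regress(ECCurve(grid, ec), FieldSpec("Z"), l0=1.0, D=2)
        assert np.allclose(est.values[1:], 0.0, atol=1e-10)

    def test_t_field_recovery(self):
        grid = threshold_grid()
        spec = FieldSpec("T", (19,))
        dm = density_matrix(spec, grid, 2)
        truth = np.array([1.0, 30.0, 150.0])
        ec = truth[0] * dm.rho0 + dm.matrix @ truth[1:]
        est = lkc_regress(ECCurve(grid, ec), spec, l0=1.0, D=2)
        assert np.allclose(est.values, truth, atol=1e-8)


class TestLkcResidualSet:
    def test_single_field_reduces_to_regress(self, rng):
        c = build_complex(np.ones((8, 8), dtype=bool))
        data = rng.standard_normal((1, 64))
        rset = make_residual_set(data, df=1)
        grid = threshold_grid()
        mat = lkc_residual_set(rset, c, grid)
        from spmtopo.topology import ec_curve
        curve = ec_curve(data[0], c, grid)
        single = lkc_regress(curve, FieldSpec("Z"), l0=1.0, D=2)
        assert np.allclose(mat[0], single.values[1:], atol=1e-10)

    def test_permutation_equivariance(self, rng):
        c = build_complex(np.ones((8, 8), dtype=bool))
        data = rng.standard_normal((5, 64))
        rset = make_residual_set(data)
        grid = threshold_grid()
        mat = lkc_residual_set(rset, c, grid)
        perm = np.array([3, 0, 4, 1, 2])
        mat_p = lkc_residual_set(make_residual_set(data[perm]), c, grid)
        assert np.allclose(mat_p, mat[perm], atol=1e-12)

    def test_estimators_agree_on_stationary_fields(self):
        """Regression and smoothness LKC estimators agree in expectation
        on simulated stationary 2D residual fields."""
        from spmtopo.simulation import SimConfig, gen_noise_fields

        cfg = SimConfig(shape=(64, 64), n_obs=100, noise_fwhm=4.0, seed=3)
        fields = gen_noise_fields(cfg)
        _, rset = one_sample_t(fields)
        c = build_complex(rset.mask)
        smooth_l2 = lkc_smoothness(rset, c)[2]
        reg_l2 = lkc_residual_set(rset, c, threshold_grid())[:, 1].mean()
        assert reg_l2 == pytest.approx(smooth_l2, rel=0.10)


class TestLkcTestSpm:
    def test_uses_t_densities(self, rng):
        from spmtopo.simulation import SimConfig, gen_noise_fields

        cfg = SimConfig(shape=(32, 32), n_obs=20, seed=5)
        fields = gen_noise_fields(cfg)
        spm, rset = one_sample_t(fields)
        c = build_complex(rset.mask)
        grid = threshold_grid()
        est = lkc_test_spm(spm, c, grid)
        # under the null the SPM's LKC should resemble the residual LKCs
        mat = lkc_residual_set(rset, c, grid)
        lo = mat.min(axis=0) - 3 * mat.std(axis=0)
        hi = mat.max(axis=0) + 3 * mat.std(axis=0)
        assert np.all(est.values[1:] > lo)
        assert np.all(est.values[1:] < hi)

    def test_missing_dof_error(self, rng):
        from spmtopo.fields_glm import LatticeField, SPMField

        with pytest.raises(ValueError):
            SPMField(field=LatticeField(np.zeros(4), np.ones(4, bool)),
                     stat_type="T", dof=())


class TestRotateResiduals:
    def test_orthonormal_and_isometric(self, rng):
        data = rng.standard_normal((12, 30))
        data = np.sqrt(11) * data / np.linalg.norm(data, axis=0)
        rset = make_residual_set(data)
        rot = rotate_residuals(rset, seed=42)
        # per-site sum of squares preserved (= df before and after)
        assert np.allclose((rot.data ** 2).sum(axis=0), 11.0, atol=1e-10)
        # deterministic
        rot2 = rotate_residuals(rset, seed=42)
        assert np.array_equal(rot.data, rot2.data)
        assert not np.allclose(rotate_residuals(rset, seed=43).data, rot.data)

    def test_rotation_matrix_orthonormality(self, rng):
        q, _, _ = np.linalg.svd(np.random.default_rng(42).standard_normal((12, 12)))
        assert np.max(np.abs(q.T @ q - np.eye(12))) < 1e-10

    def test_stationary_lkc_unchanged_in_expectation(self):
        from spmtopo.simulation import SimConfig, gen_noise_fields

        cfg = SimConfig(shape=(48, 48), n_obs=60, seed=9)
        fields = gen_noise_fields(cfg)
        _, rset = one_sample_t(fields)
        c = build_complex(rset.mask)
        grid = threshold_grid()
        before = lkc_residual_set(rset, c, grid).mean(axis=0)
        after = lkc_residual_set(rotate_residuals(rset, seed=1), c, grid).mean(axis=0)
        assert np.allclose(after, before, rtol=0.10)
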