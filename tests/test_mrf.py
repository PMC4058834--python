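import warnings
from dataclasses import replace

import numpy as np
import pytest

import fuzzymrf as fm
from fuzzymrf.errors import ConfigError, DegenerateRegionError, FuzzyMrfError
from conftest import random_fields


def brute_force_energy(x, fields, beta, half=(2, 2, 1), floor=1e-12):
    """Independent double-loop oracle for C(x)."""
    total = 0.0
    shape = x.shape
    for i in np.ndindex(shape):
        mix = x[i] * fields.A[i] + (1 - x[i]) * fields.B[i]
        total += np.log(max(mix, floor))
        for di in range(-half[0], half[0] + 1):
            for dj in range(-half[1], half[1] + 1):
                for dk in range(-half[2], half[2] + 1):
                    if (di, dj, dk) == (0, 0, 0):
                        continue
                    j = (i[0] + di, i[1] + dj, i[2] + dk)
                    if all(0 <= j[ax] < shape[ax] for ax in range(3)):
                        total -= beta * (x[i] - x[j]) ** 2
    return total


def single_voxel_fields(A, B):
    return fm.LikelihoodFields(
        A=np.full((1, 1, 1), A), B=np.full((1, 1, 1), B), spacing=(1, 1, 1)
    )


class TestEnergy:
    def test_single_voxel_pure_tumor_evidence(self):
        f = single_voxel_fields(1.0, 0.0)
        assert fm.energy(np.ones((1, 1, 1)), f, fm.OptimConfig(beta=0.3)) == 0.0

    def test_constant_field_kills_smoothness(self):
        f = random_fields(0, (4, 4, 3))
        cfg_b0 = fm.OptimConfig(beta=0.0)
        cfg_b = fm.OptimConfig(beta=0.7)
        for c in (0.2, 0.5, 0.9):
            x = np.full((4, 4, 3), c)
            expected = np.log(c * f.A + (1 - c) * f.B).sum()
            assert fm.energy(x, f, cfg_b) == pytest.approx(expected)
            assert fm.energy(x, f, cfg_b0) == pytest.approx(expected)

    def test_matches_double_loop_oracle_on_2x2x2(self):
        rng = np.random.default_rng(42)
        f = random_fields(42, (2, 2, 2))
        x = rng.uniform(0, 1, (2, 2, 2))
        cfg = fm.OptimConfig(beta=0.1)
        assert fm.energy(x, f, cfg) == pytest.approx(
            brute_force_energy(x, f, 0.1), rel=1e-12
        )

    @pytest.mark.parametrize("seed,shape", [(1, (3, 3, 3)), (2, (5, 2, 4)), (3, (6, 6, 2))])
    def test_matches_double_loop_oracle_with_boundary_truncation(self, seed, shape):
        rng = np.random.default_rng(seed)
        f = random_fields(seed, shape)
        x = rng.uniform(0, 1, shape)
        cfg = fm.OptimConfig(beta=0.25)
        assert fm.energy(x, f, cfg) == pytest.approx(
            brute_force_energy(x, f, 0.25), rel=1e-12
        )

    def test_out_of_range_membership_rejected(self):
        f = random_fields(0, (2, 2, 2))
        with pytest.raises(ConfigError):
            fm.energy(np.full((2, 2, 2), 1.2), f, fm.OptimConfig())


class TestGradient:
    def test_constant_field_has_no_smoothness_gradient(self):
        f = random_fields(5, (4, 4, 3))
        x = np.full((4, 4, 3), 0.4)
        cfg0 = fm.OptimConfig(beta=0.0)
        cfg = fm.OptimConfig(beta=0.9)
        np.testing.assert_allclose(
            fm.gradient(x, f, cfg), fm.gradient(x, f, cfg0), atol=1e-12
        )

    def test_equal_evidence_leaves_only_smoothness(self):
        rng = np.random.default_rng(6)
        A = rng.uniform(0.5, 1.5, (3, 3, 3))
        f = fm.LikelihoodFields(A=A, B=A.copy(), spacing=(1, 1, 1))
        x = rng.uniform(0, 1, (3, 3, 3))
        g0 = fm.gradient(x, f, fm.OptimConfig(beta=0.0))
        np.testing.assert_allclose(g0, 0.0, atol=1e-12)

    def test_finite_difference_agreement(self):
        cfg = fm.OptimConfig(beta=0.1)
        rng = np.random.default_rng(11)
        f = random_fields(11, (3, 3, 3))
        x = rng.uniform(0.05, 0.95, (3, 3, 3))
        g = fm.gradient(x, f, cfg)
        h = 1e-6
        for idx in np.ndindex(x.shape):
            xp, xm = x.copy(), x.copy()
            xp[idx] += h
            xm[idx] -= h
            fd = -(fm.energy(xp, f, cfg) - fm.energy(xm, f, cfg)) / (2 * h)
            assert g[idx] == pytest.approx(fd, rel=1e-4, abs=5e-6)


class TestOptimize:
    def test_fixed_point_returns_immediately(self):
        f = single_voxel_fields(1.0, 0.1)
        x0 = np.ones((1, 1, 1))
        x, trace = fm.optimize(x0, f, fm.OptimConfig(beta=0.0))
        assert trace.n_iter == 1 and trace.step_norm[-1] == 0.0
        np.testing.assert_array_equal(x, x0)

    @pytest.mark.parametrize("A,B,target", [(1.0, 0.2, 1.0), (0.2, 1.0, 0.0)])
    def test_single_voxel_monotone_data_term(self, A, B, target):
        """With beta=0 the 1-voxel objective ln(xA+(1-x)B) is monotone in x,
        so ascent must saturate at the favorable bound (grid-search check)."""
        f = single_voxel_fields(A, B)
        cfg = fm.OptimConfig(alpha=0.05, beta=0.0, epsilon=1e-12, max_iter=10_000)
        x, _ = fm.optimize(np.full((1, 1, 1), 0.5), f, cfg)
        assert x[0, 0, 0] == pytest.approx(target, abs=1e-6)
        grid = np.linspace(0, 1, 101)
        best = grid[np.argmax(np.log(grid * A + (1 - grid) * B))]
        assert best == pytest.approx(target)

    def test_projection_keeps_unit_interval(self):
        f = random_fields(8, (4, 4, 2))
        cfg = fm.OptimConfig(alpha=0.5, beta=0.2, epsilon=1e-8, max_iter=50,
                             enforce_ascent=False)
        x, _ = fm.optimize(np.full(f.shape, 0.5), f, cfg)
        assert x.min() >= 0.0 and x.max() <= 1.0

    def test_deterministic(self):
        f = random_fields(9, (4, 4, 2))
        cfg = fm.OptimConfig()
        x0 = fm.initialize_membership(f)
        xa, ta = fm.optimize(x0, f, cfg)
        xb, tb = fm.optimize(x0, f, cfg)
        np.testing.assert_array_equal(xa, xb)
        np.testing.assert_array_equal(ta.energy, tb.energy)

    def test_ascent_safeguard_halves_alpha_with_warning(self):
        f = random_fields(10, (3, 3, 2))
        cfg = fm.OptimConfig(alpha=5.0, beta=0.1, epsilon=1e-10, max_iter=200)
        with pytest.warns(RuntimeWarning, match="halving"):
            _, trace = fm.optimize(np.full(f.shape, 0.5), f, cfg)
        assert trace.alpha_final < 5.0
        assert (np.diff(trace.energy) >= 0).all()


class TestInitAndThreshold:
    def test_uniform_half(self):
        f = random_fields(0, (2, 3, 2))
        np.testing.assert_array_equal(fm.initialize_membership(f, "uniform_half"), 0.5)

    def test_likelihood_ratio_limits(self):
        f = fm.LikelihoodFields(
            A=np.array([[[0.0, 0.5, 0.0]]]),
            B=np.array([[[0.5, 0.5, 0.0]]]),
            spacing=(1, 1, 1),
        )
        x0 = fm.initialize_membership(f, "likelihood_ratio")
        np.testing.assert_allclose(x0.ravel(), [0.0, 0.5, 0.5])

    def test_unknown_mode(self):
        with pytest.raises(ConfigError):
            fm.initialize_membership(random_fields(0, (2, 2, 2)), "nope")

    def test_threshold_boundary_uses_geq(self):
        x = np.array([[[0.2, 0.5, 0.9]]])
        mask = fm.threshold_membership(x, 0.5)
        np.testing.assert_array_equal(mask.data, [[[0.0, 1.0, 1.0]]])

    def test_threshold_extremes(self):
        assert fm.threshold_membership(np.ones((2, 2, 2)), 0.5).data.all()
        assert not fm.threshold_membership(np.zeros((2, 2, 2)), 0.5).data.any()


class TestSegmentPipeline:
    def test_default_phantom_recovers_truth(self, default_phantom, petct_result):
        _, _, truth = default_phantom
        assert fm.dsc(petct_result.mask, truth) >= 0.85

    def test_smoothness_of_converged_field_decreases_with_beta(self, default_phantom):
        ct, suv, _ = default_phantom
        totals = []
        for beta in (0.0, 0.01, 0.1, 1.0):
            res = fm.segment(ct, suv, fm.OptimConfig(beta=beta))
            x = res.membership.data
            from fuzzymrf.mrf import _window_sum
            h = (2, 2, 1)
            n_nb = _window_sum(np.ones_like(x), h) - 1.0
            s_nb = _window_sum(x, h) - x
            q_nb = _window_sum(x * x, h) - x * x
            totals.append(float((n_nb * x * x - 2 * x * s_nb + q_nb).sum()))
        assert all(b <= a + 1e-9 for a, b in zip(totals, totals[1:]))

    def test_empty_roi_raises_stage_labeled_error(self):
        rng = np.random.default_rng(0)
        ct = fm.Volume(data=rng.normal(-700, 30, (12, 12, 4)), spacing=(1, 1, 1))
        suv = fm.Volume(
            data=rng.normal(1.0, 0.3, (12, 12, 4)), spacing=(1, 1, 1),
            modality=fm.Modality.SUV,
        )
        with pytest.raises(FuzzyMrfError, match=r"\[stage:"):
            fm.segment(ct, suv)

    def test_noise_free_phantom_degenerates(self):
        spec = replace(
            fm.default_spec(0),
            ct_sd_lung=0.0, ct_sd_tumor=0.0, ct_sd_confounder=0.0,
            suv_sd_normal=0.0, suv_psf_sigma=(0.0, 0.0, 0.0),
        )
        ct, suv, _ = fm.generate_phantom(spec)
        with pytest.raises(DegenerateRegionError):
            fm.segment(ct, suv)

    def test_pet_only_mask_is_coarser(self, default_phantom, petct_result):
        ct, suv, _ = default_phantom
        pet = fm.segment(ct, suv, mode="pet_only")
        assert pet.mask.data.sum() >= petct_result.mask.data.sum()
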