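"""Variance-exploding schedule, perturbation kernel, and reverse sampler."""

import numpy as np
import pytest

from metaldiff.errors import DomainError, SampleDivergenceError
from metaldiff.sde import (
    MixtureTarget,
    NoiseSchedule,
    analytic_mixture_score,
    diffusion_coefficient,
    dsm_loss,
    forward_perturb,
    init_prior,
    reverse_sample,
    score_target,
    sigma,
)
from metaldiff.synthetic import make_mixture_target, make_toy_complex

from conftest import random_rotation

SCH = NoiseSchedule(0.1, 20.0)


class TestSchedule:
    def test_endpoints_and_midpoint(self):
        assert sigma(0.0, SCH) == pytest.approx(0.1)
        assert sigma(1.0, SCH) == pytest.approx(20.0)
        assert sigma(0.5, SCH) == pytest.approx(np.sqrt(0.1 * 20.0))

    def test_domain(self):
        with pytest.raises(DomainError):
            sigma(-0.01, SCH)
        with pytest.raises(DomainError):
            NoiseSchedule(2.0, 1.0)

    def test_g_matches_finite_difference_of_variance(self):
        h = 1e-6
        for t in (0.2, 0.5, 0.8):
            fd = (sigma(t + h, SCH) ** 2 - sigma(t - h, SCH) ** 2) / (2 * h)
            g2 = diffusion_coefficient(t, SCH) ** 2
            assert g2 == pytest.approx(fd, rel=1e-6)

    def test_g_strictly_increasing(self):
        ts = np.linspace(0.01, 1.0, 50)
        gs = [diffusion_coefficient(t, SCH) for t in ts]
        assert all(b > a for a, b in zip(gs, gs[1:]))

    def test_degenerate_schedule_vanishing_g(self):
        sch = NoiseSchedule(1.0, 1.0 + 1e-9)
        assert diffusion_coefficient(0.5, sch) < 1e-4


class TestScoreTarget:
    def test_substitution(self):
        np.testing.assert_allclose(
            score_target(np.array([3.0, 0, 0]), np.zeros(3), 9.0),
            [-1.0 / 3.0, 0, 0],
        )

    def test_zero_at_mean(self):
        mu = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(score_target(mu, mu, 4.0), np.zeros(3))

    def test_unit_variance_displacement(self):
        var = 2.5
        np.testing.assert_allclose(
            score_target(np.array([var, 0, 0]), np.zeros(3), var), [-1.0, 0, 0]
        )

    def test_matches_numeric_gradient_of_log_density(self):
        rng = np.random.default_rng(0)
        mu = rng.standard_normal(3)
        var = 1.7
        x = rng.standard_normal(3) * 2

        def logp(y):
            return -((y - mu) ** 2).sum() / (2 * var)

        h = 1e-6
        num = np.array(
            [
                (logp(x + h * e) - logp(x - h * e)) / (2 * h)
                for e in np.eye(3)
            ]
        )
        np.testing.assert_allclose(score_target(x, mu, var), num, rtol=1e-5)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(DomainError):
            score_target(np.zeros(3), np.zeros(3), 0.0)


class TestForwardPerturb:
    def test_sample_std_matches_sigma(self):
        # sigma(t) = 2 at t = log(2/0.1)/log(20/0.1)
        t = np.log(2.0 / SCH.sigma_min) / np.log(SCH.sigma_max / SCH.sigma_min)
        assert sigma(t, SCH) == pytest.approx(2.0, abs=1e-12)
        rng = np.random.default_rng(42)
        rec = forward_perturb(np.zeros((100_000, 3)), t, SCH, rng)
        stds = rec.delta_r.std(axis=0)
        assert ((stds > 1.94) & (stds < 2.06)).all()

    def test_record_consistency(self):
        rng = np.random.default_rng(1)
        rec = forward_perturb(np.array([1.0, 2.0, 3.0]), 0.6, SCH, rng)
        assert rec.var == pytest.approx(sigma(0.6, SCH) ** 2)
        np.testing.assert_allclose(rec.target, -(rec.delta_r - rec.mu) / rec.var)


class TestInitPrior:
    def test_count_and_containment(self):
        s = make_toy_complex(20, 1, 0).structure
        pts = init_prior(s, 100, np.random.default_rng(0), pad=5.0)
        assert pts.shape == (100, 3)
        lo, hi = s.bounding_box(pad=5.0)
        assert (pts >= lo).all() and (pts <= hi).all()

    def test_deterministic(self):
        s = make_toy_complex(20, 1, 0).structure
        a = init_prior(s, 10, np.random.default_rng(7))
        b = init_prior(s, 10, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_uniform_mean_near_center(self):
        s = make_toy_complex(20, 1, 0).structure
        lo, hi = s.bounding_box(pad=5.0)
        pts = init_prior(s, 10_000, np.random.default_rng(3))
        center = (lo + hi) / 2
        se = (hi - lo) / np.sqrt(12.0) / np.sqrt(10_000)
        assert (np.abs(pts.mean(axis=0) - center) < 3 * se).all()

    def test_normal_mode_scale(self):
        s = make_toy_complex(20, 1, 0).structure
        pts = init_prior(s, 20_000, np.random.default_rng(1), mode="normal",
                         sch=SCH)
        assert abs(pts.std(axis=0).mean() - SCH.sigma_max) / SCH.sigma_max < 0.05

    def test_domain(self):
        s = make_toy_complex(20, 1, 0).structure
        with pytest.raises(DomainError):
            init_prior(s, 0, np.random.default_rng(0))
        with pytest.raises(DomainError):
            init_prior(s, 5, np.random.default_rng(0), mode="normal")


class TestReverseSample:
    def test_null_score_tiny_sigma_identity(self):
        sch = NoiseSchedule(1e-6, 2e-6)
        init = np.random.default_rng(0).uniform(-5, 5, (20, 3))
        out = reverse_sample(
            lambda x, t: np.zeros_like(x), init, 1, sch,
            np.random.default_rng(1), denoise_last=False,
        )
        np.testing.assert_allclose(out, init, atol=1e-3)

    def test_single_gaussian_analytic_target(self):
        m = np.array([3.0, -2.0, 7.0])
        target = MixtureTarget(np.array([1.0]), m[None, :], 0.25)
        rng = np.random.default_rng(5)
        init = rng.uniform(-20, 20, size=(1000, 3)) + m
        out = reverse_sample(
            lambda x, t: analytic_mixture_score(x, t, SCH, target),
            init, 200, SCH, rng,
        )
        assert np.linalg.norm(out.mean(axis=0) - m) < 0.15
        assert abs(out.std(axis=0).mean() - 0.5) < 0.125

    def test_bitwise_determinism(self):
        target = MixtureTarget(np.array([1.0]), np.zeros((1, 3)), 0.25)
        fn = lambda x, t: analytic_mixture_score(x, t, SCH, target)
        init = np.random.default_rng(2).uniform(-10, 10, (50, 3))
        a = reverse_sample(fn, init, 30, SCH, np.random.default_rng(9))
        b = reverse_sample(fn, init, 30, SCH, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_three_mode_recovery(self):
        target = make_mixture_target(3, 15.0, 0.25, 12)
        rng = np.random.default_rng(6)
        lo = target.means.min(axis=0) - 10
        hi = target.means.max(axis=0) + 10
        init = rng.uniform(lo, hi, size=(1000, 3))
        out = reverse_sample(
            lambda x, t: analytic_mixture_score(x, t, SCH, target),
            init, 200, SCH, rng,
        )
        d = np.linalg.norm(out[:, None, :] - target.means[None], axis=2)
        nearest = d.min(axis=1)
        assert (nearest < 2.0).mean() >= 0.90
        occupancy = np.bincount(d.argmin(axis=1), minlength=3) / out.shape[0]
        assert (occupancy >= 0.15).all()

    def test_integrator_equivariance_with_rotated_noise(self):
        rng = np.random.default_rng(8)
        target = make_mixture_target(2, 15.0, 0.25, 3)
        rot = random_rotation(rng)
        shift = rng.uniform(-5, 5, 3)
        n_steps = 40
        zs = [rng.standard_normal((30, 3)) for _ in range(n_steps)]
        init = rng.uniform(-20, 20, (30, 3))
        out1 = reverse_sample(
            lambda x, t: analytic_mixture_score(x, t, SCH, target),
            init, n_steps, SCH, np.random.default_rng(0),
            noise_fn=lambda i, shape: zs[i],
        )
        rotated = MixtureTarget(
            target.weights, target.means @ rot.T + shift, target.base_var
        )
        out2 = reverse_sample(
            lambda x, t: analytic_mixture_score(x, t, SCH, rotated),
            init @ rot.T + shift, n_steps, SCH, np.random.default_rng(0),
            noise_fn=lambda i, shape: zs[i] @ rot.T,
        )
        np.testing.assert_allclose(out2, out1 @ rot.T + shift, atol=1e-4)

    def test_nan_score_aborts_with_step(self):
        def bad(x, t):
            return np.full_like(x, np.nan)

        with pytest.raises(SampleDivergenceError) as e:
            reverse_sample(bad, np.zeros((2, 3)), 5, SCH, np.random.default_rng(0))
        assert e.value.step == 0


class TestMixtureScore:
    def test_zero_at_single_mode_mean(self):
        t = MixtureTarget(np.array([1.0]), np.array([[1.0, 2.0, 3.0]]), 0.5)
        np.testing.assert_allclose(
            analytic_mixture_score(np.array([1.0, 2.0, 3.0]), 0.3, SCH, t),
            np.zeros(3), atol=1e-12,
        )

    def test_zero_at_symmetric_midpoint(self):
        t = MixtureTarget(
            np.array([0.5, 0.5]), np.array([[5.0, 0, 0], [-5.0, 0, 0]]), 0.25
        )
        np.testing.assert_allclose(
            analytic_mixture_score(np.zeros(3), 0.2, SCH, t), np.zeros(3),
            atol=1e-12,
        )

    def test_matches_numeric_gradient(self):
        rng = np.random.default_rng(4)
        t = make_mixture_target(3, 8.0, 0.6, 2)
        x = rng.uniform(-10, 10, 3)
        tt = 0.35
        v = t.base_var + sigma(tt, SCH) ** 2

        def logp(y):
            from scipy.special import logsumexp

            e = np.log(t.weights) - ((y - t.means) ** 2).sum(1) / (2 * v)
            return logsumexp(e)

        h = 1e-5
        num = np.array(
            [(logp(x + h * e) - logp(x - h * e)) / (2 * h) for e in np.eye(3)]
        )
        np.testing.assert_allclose(
            analytic_mixture_score(x, tt, SCH, t), num, rtol=1e-5, atol=1e-8
        )


def test_dsm_loss_zero_for_perfect_score():
    rng = np.random.default_rng(0)
    target = rng.standard_normal((50, 3))
    assert dsm_loss(target, target) == 0.0
    sig = rng.uniform(0.1, 20.0, 50)
    assert dsm_loss(target, target, sig, weighting="sigma2") == 0.0
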