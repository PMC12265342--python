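"""Variance-exploding diffusion machinery for metal-ion translations.

The forward process has zero drift and a geometric noise schedule

    sigma(t) = sigma_min^(1-t) * sigma_max^t,        t in [0, 1],

so positions evolve as dx = g(t) dw with g(t) = sqrt(d sigma^2(t) / dt)
= sigma(t) * sqrt(2 ln(sigma_max / sigma_min)).  The perturbation kernel is
the zero-mean Gaussian N(0, sigma(t)^2 I); its score is the closed form
-(delta_r - mu) / sigma^2(t) with mu = 0, which is the regression target for
denoising score matching.  Sampling reverses the SDE

    dx = [f(x,t) - g(t)^2 S(x, y, t)] dt + g(t) dw,     f = 0,

by Euler-Maruyama on a uniform time grid from t = 1 down to t = 0; by
default the final step omits the noise injection (denoise-last).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import logsumexp

from .errors import DomainError, SampleDivergenceError
from .structure import ProteinStructure

ScoreFn = Callable[[np.ndarray, float], np.ndarray]


@dataclass(frozen=True)
class NoiseSchedule:
    """Geometric sigma schedule for the variance-exploding SDE.

    Defaults span 0.1 A (sub-coordination jitter) to 20 A (protein-scale
    translations).
    """

    sigma_min: float = 0.1
    sigma_max: float = 20.0

    def __post_init__(self) -> None:
        if not 0 < self.sigma_min < self.sigma_max:
            raise DomainError(
                f"need 0 < sigma_min < sigma_max, got ({self.sigma_min}, {self.sigma_max})"
            )


def _check_t(t: float) -> float:
    t = float(t)
    if not 0.0 <= t <= 1.0:
        raise DomainError(f"diffusion time t={t} outside [0, 1]")
    return t


def sigma(t: float, sch: NoiseSchedule) -> float:
    """Noise level sigma(t) = sigma_min^(1-t) * sigma_max^t (A)."""
    t = _check_t(t)
    return float(sch.sigma_min ** (1.0 - t) * sch.sigma_max**t)


def diffusion_coefficient(t: float, sch: NoiseSchedule) -> float:
    """g(t) = sqrt(d sigma^2/dt) = sigma(t) sqrt(2 ln(sigma_max/sigma_min))."""
    t = _check_t(t)
    return float(sigma(t, sch) * np.sqrt(2.0 * np.log(sch.sigma_max / sch.sigma_min)))


def score_target(delta_r: np.ndarray, mu: np.ndarray, var: float) -> np.ndarray:
    """Score of the Gaussian perturbation kernel: -(delta_r - mu) / var."""
    if var <= 0:
        raise DomainError(f"variance must be positive, got {var}")
    return -(np.asarray(delta_r, dtype=float) - np.asarray(mu, dtype=float)) / var


@dataclass(frozen=True)
class PerturbationRecord:
    """One forward-perturbation draw with its closed-form score target."""

    t: float
    delta_r: np.ndarray  # (..., 3) translation perturbation, A
    mu: np.ndarray  # kernel mean (identically 0 for the VE process)
    var: float  # sigma(t)^2, A^2
    target: np.ndarray  # -(delta_r - mu)/var, A^-1


def forward_perturb(
    x0: np.ndarray, t: float, sch: NoiseSchedule, rng: np.random.Generator
) -> PerturbationRecord:
    """Draw delta_r ~ N(0, sigma(t)^2 I) for each input position.

    The perturbed position is ``x0 + delta_r``; the record carries the
    denoising score-matching target for that draw.
    """
    x0 = np.asarray(x0, dtype=float)
    s = sigma(t, sch)
    delta = rng.standard_normal(x0.shape if x0.shape else (3,)) * s
    mu = np.zeros(3)
    return PerturbationRecord(
        t=float(t), delta_r=delta, mu=mu, var=s * s, target=score_target(delta, mu, s * s)
    )


def init_prior(
    s: ProteinStructure,
    n: int = 100,
    rng: np.random.Generator | None = None,
    pad: float = 5.0,
    mode: str = "box",
    sch: NoiseSchedule | None = None,
) -> np.ndarray:
    """Draw n candidate starting positions across the protein.

    ``mode='box'`` (default) samples uniformly in the bounding box padded by
    ``pad`` A — random positions across the system.  ``mode='normal'`` draws
    from N(center, sigma_max^2 I), the stationary-like prior of the
    variance-exploding process (requires ``sch``).
    """
    if n <= 0:
        raise DomainError(f"number of candidates must be positive, got {n}")
    rng = rng or np.random.default_rng()
    lo, hi = s.bounding_box(pad=pad)
    if mode == "box":
        return rng.uniform(lo, hi, size=(n, 3))
    if mode == "normal":
        if sch is None:
            raise DomainError("normal prior requires a NoiseSchedule")
        center = (lo + hi) / 2.0
        return center + rng.standard_normal((n, 3)) * sch.sigma_max
    raise DomainError(f"unknown prior mode {mode!r}")


def reverse_sample(
    score_fn: ScoreFn,
    init: np.ndarray,
    n_steps: int,
    sch: NoiseSchedule,
    rng: np.random.Generator,
    denoise_last: bool = True,
    record_trajectory: bool = False,
    noise_fn: Callable[[int, tuple], np.ndarray] | None = None,
) -> np.ndarray | tuple[np.ndarray, list[np.ndarray]]:
    """Integrate the reverse SDE from t=1 to t=0 with Euler-Maruyama.

    Parameters
    ----------
    score_fn
        Callable ``(positions (n,3), t) -> scores (n,3)``; evaluated at the
        left endpoint of each step.  Candidates move independently.
    init
        (n, 3) starting positions (typically from :func:`init_prior`).
    noise_fn
        Optional override ``(step, shape) -> z`` replacing the rng draws;
        used to probe integrator equivariance with controlled noise.

    Raises
    ------
    SampleDivergenceError
        If the score function returns non-finite values (reports the step).
    """
    if n_steps < 1:
        raise DomainError("n_steps must be >= 1")
    x = np.array(init, dtype=float).reshape(-1, 3).copy()
    ts = np.linspace(1.0, 0.0, n_steps + 1)
    traj = [x.copy()] if record_trajectory else None
    for i in range(n_steps):
        t = float(ts[i])
        dt = float(ts[i] - ts[i + 1])
        g = diffusion_coefficient(t, sch)
        score = np.asarray(score_fn(x, t), dtype=float)
        if not np.isfinite(score).all():
            raise SampleDivergenceError(i)
        x = x + g * g * score * dt
        last = i == n_steps - 1
        if not (last and denoise_last):
            z = (
                noise_fn(i, x.shape)
                if noise_fn is not None
                else rng.standard_normal(x.shape)
            )
            x = x + g * np.sqrt(dt) * z
        if record_trajectory:
            traj.append(x.copy())
    if record_trajectory:
        return x, traj
    return x


# ---------------------------------------------------------------------------
# analytic oracle


@dataclass(frozen=True)
class MixtureTarget:
    """Isotropic Gaussian mixture used as a closed-form sampling oracle."""

    weights: np.ndarray  # (k,) on the simplex
    means: np.ndarray  # (k, 3) A
    base_var: float  # A^2

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or not np.isclose(w.sum(), 1.0) or (w < 0).any():
            raise DomainError("mixture weights must lie on the simplex")


def analytic_mixture_score(
    x: np.ndarray, t: float, sch: NoiseSchedule, target: MixtureTarget
) -> np.ndarray:
    """Exact score of the mixture convolved with the perturbation kernel.

    grad_x log sum_k w_k N(x; m_k, (base_var + sigma(t)^2) I), evaluated with
    log-sum-exp stabilized responsibilities.  Accepts a single 3-vector or an
    (n, 3) batch.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x2 = x.reshape(-1, 3)
    v = target.base_var + sigma(t, sch) ** 2
    diff = x2[:, None, :] - target.means[None, :, :]  # (n, k, 3)
    logw = np.log(np.asarray(target.weights, dtype=float))
    logp_k = logw[None, :] - (diff**2).sum(-1) / (2.0 * v)  # (n, k)
    resp = np.exp(logp_k - logsumexp(logp_k, axis=1, keepdims=True))
    grad = -(resp[:, :, None] * diff).sum(axis=1) / v
    return grad[0] if single else grad


def dsm_loss(
    predicted: np.ndarray,
    target: np.ndarray,
    sigmas: np.ndarray | None = None,
    weighting: str = "none",
) -> float:
    """Denoising score-matching objective: mean squared L2 norm of the residual.

    ``weighting='sigma2'`` multiplies each sample's squared residual by
    sigma(t)^2 so all noise levels contribute comparably; ``'none'`` is the
    plain objective.
    """
    predicted = np.asarray(predicted, dtype=float).reshape(-1, 3)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    sq = ((target - predicted) ** 2).sum(axis=1)
    if weighting == "sigma2":
        if sigmas is None:
            raise DomainError("sigma2 weighting requires per-sample sigmas")
        sq = sq * np.asarray(sigmas, dtype=float).reshape(-1) ** 2
    elif weighting != "none":
        raise DomainError(f"unknown loss weighting {weighting!r}")
    return float(sq.mean())
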