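"""Wrapped-Gaussian denoising diffusion over angle matrices.

The forward process corrupts a wrapped angle matrix ``x0`` over ``T`` discrete
steps with a cosine variance schedule; because angles live on the circle
[-pi, pi), every sample is wrapped with ``w(x) = ((x + pi) mod 2pi) - pi``.
Sampling a wrapped normal is implemented exactly as "draw a normal, then
wrap".  The network regresses the *unwrapped* noise draw ``eps``; the training
residual is wrapped before entering a smooth-L1 loss with transition point
``beta_l = 0.1 * pi``.

The reverse sampler starts from wrapped white noise and applies the standard
DDPM update, wrapped at every step, then un-shifts by the training-set
angular mean ``mu``.

Timesteps are 1..T in every public signature (0-based internally).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np

from .geometry import AngleFeaturization, wrap_angles

DEFAULT_T = 1000
DEFAULT_S = 8e-3
DEFAULT_BETA_L = 0.1 * np.pi


class DenoiserFn(Protocol):
    """Noise predictor: (x [B,L,6] wrapped, t [B] in 1..T, valid-row mask
    [B,L] or None) -> eps_hat [B,L,6]."""

    def __call__(self, x: np.ndarray, t: np.ndarray,
                 mask: np.ndarray | None = None) -> np.ndarray: ...


@dataclass
class DiffusionSchedule:
    """Cosine variance schedule with clipped betas.

    alpha_bar(t) = f(t)/f(0) with f(t) = cos^2(((t/T + s)/(1 + s)) * pi/2)
    by default (``form="squared-cosine"``); ``form="literal-cosine"`` drops
    the square.  beta_t = clip(1 - abar_t/abar_{t-1}, max 0.999) and
    sigma_t = sqrt((1 - abar_{t-1})/(1 - abar_t) * beta_t), with abar_0 = 1
    (hence sigma_1 = 0).
    """

    T: int = DEFAULT_T
    s: float = DEFAULT_S
    form: str = "squared-cosine"
    beta: np.ndarray = field(init=False)
    alpha: np.ndarray = field(init=False)
    alpha_bar: np.ndarray = field(init=False)
    sigma: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.s <= 0:
            raise ValueError("s must be > 0")
        if self.form not in ("squared-cosine", "literal-cosine"):
            raise ValueError(f"unknown schedule form {self.form!r}")
        t = np.arange(self.T + 1, dtype=np.float64)  # 0..T
        f = np.cos((t / self.T + self.s) / (1.0 + self.s) * (np.pi / 2.0))
        if self.form == "squared-cosine":
            f = f ** 2
        abar_full = f / f[0]  # abar_full[0] == 1 by construction
        beta = 1.0 - abar_full[1:] / abar_full[:-1]
        self.beta = np.clip(beta, None, 0.999)
        self.alpha = 1.0 - self.beta
        # recompute cumulative products so the clip propagates consistently
        self.alpha_bar = np.cumprod(self.alpha)
        abar_prev = np.concatenate([[1.0], self.alpha_bar[:-1]])
        with np.errstate(divide="ignore", invalid="ignore"):
            self.sigma = np.sqrt((1.0 - abar_prev) / (1.0 - self.alpha_bar) * self.beta)
        if not (self.beta > 0).all():
            raise ValueError("schedule produced non-positive beta")

    # -- 1-based accessors -------------------------------------------------
    def beta_t(self, t):
        return self.beta[np.asarray(t) - 1]

    def alpha_t(self, t):
        return self.alpha[np.asarray(t) - 1]

    def alpha_bar_t(self, t):
        """abar_t for t in 0..T (abar_0 = 1)."""
        t = np.asarray(t)
        return np.where(t == 0, 1.0, self.alpha_bar[np.maximum(t, 1) - 1])

    def sigma_t(self, t):
        return self.sigma[np.asarray(t) - 1]

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"T": self.T, "s": self.s, "form": self.form,
             "beta": self.beta.tolist()}))

    @classmethod
    def from_json(cls, path: str | Path) -> "DiffusionSchedule":
        spec = json.loads(Path(path).read_text())
        schedule = cls(T=spec["T"], s=spec["s"], form=spec.get("form", "squared-cosine"))
        if not np.allclose(schedule.beta, spec["beta"], atol=1e-12):
            raise ValueError("stored betas do not match recomputed schedule")
        return schedule


def build_cosine_schedule(T: int = DEFAULT_T, s: float = DEFAULT_S,
                          form: str = "squared-cosine") -> DiffusionSchedule:
    return DiffusionSchedule(T=T, s=s, form=form)


@dataclass
class NoisedSample:
    """x_t (wrapped) together with the raw normal draw eps that produced it."""

    x_t: np.ndarray
    t: int | np.ndarray
    epsilon: np.ndarray


def _check_t(t, T: int) -> None:
    t = np.asarray(t)
    if (t < 1).any() or (t > T).any():
        raise ValueError(f"timestep {t} outside 1..{T}")


def forward_sample(x0: np.ndarray, t, schedule: DiffusionSchedule,
                   rng: np.random.Generator) -> NoisedSample:
    """Closed-form forward noising x_t = w(sqrt(abar_t) x0 + sqrt(1-abar_t) eps).

    ``t`` may be a scalar or a per-item array matching x0's leading axis.
    """
    _check_t(t, schedule.T)
    x0 = np.asarray(x0, dtype=np.float64)
    abar = schedule.alpha_bar_t(t)
    abar = np.reshape(abar, np.shape(abar) + (1,) * (x0.ndim - np.ndim(abar)))
    eps = rng.standard_normal(x0.shape)
    x_t = wrap_angles(np.sqrt(abar) * x0 + np.sqrt(1.0 - abar) * eps)
    return NoisedSample(x_t=x_t, t=t, epsilon=eps)


def forward_sample_iterative(x0: np.ndarray, t: int, schedule: DiffusionSchedule,
                             rng: np.random.Generator) -> np.ndarray:
    """Apply q(x_t | x_{t-1}) one step at a time (oracle for the closed form)."""
    _check_t(t, schedule.T)
    x = np.asarray(x0, dtype=np.float64)
    for step in range(1, int(t) + 1):
        beta = schedule.beta_t(step)
        x = wrap_angles(np.sqrt(1.0 - beta) * x
                        + np.sqrt(beta) * rng.standard_normal(x.shape))
    return x


def wrapped_smooth_l1(predicted: np.ndarray, target: np.ndarray,
                      beta_l: float = DEFAULT_BETA_L,
                      mask: np.ndarray | None = None) -> float:
    """Smooth-L1 on the wrapped residual d = w(target - predicted).

    Quadratic (0.5 d^2 / beta_l) for |d| < beta_l, linear (|d| - 0.5 beta_l)
    beyond; mean over (unmasked) elements.
    """
    predicted = np.asarray(predicted, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if predicted.shape != target.shape:
        raise ValueError("shape mismatch between predicted and target")
    d = wrap_angles(target - predicted)
    loss = np.where(np.abs(d) < beta_l,
                    0.5 * d ** 2 / beta_l,
                    np.abs(d) - 0.5 * beta_l)
    if mask is not None:
        m = np.broadcast_to(np.asarray(mask, dtype=bool)[..., None], loss.shape)
        return float(loss[m].mean())
    return float(loss.mean())


def wrapped_smooth_l1_grad(predicted: np.ndarray, target: np.ndarray,
                           beta_l: float = DEFAULT_BETA_L,
                           mask: np.ndarray | None = None
                           ) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to ``predicted``."""
    predicted = np.asarray(predicted, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    d = wrap_angles(target - predicted)
    quad = np.abs(d) < beta_l
    loss_el = np.where(quad, 0.5 * d ** 2 / beta_l, np.abs(d) - 0.5 * beta_l)
    dl_dd = np.where(quad, d / beta_l, np.sign(d))
    if mask is not None:
        m = np.broadcast_to(np.asarray(mask, dtype=bool)[..., None], loss_el.shape)
        count = m.sum()
        grad = np.where(m, -dl_dd, 0.0) / count
        return float(loss_el[m].mean()), grad
    grad = -dl_dd / d.size
    return float(loss_el.mean()), grad


def reverse_step(x_t: np.ndarray, t, predicted_noise: np.ndarray,
                 schedule: DiffusionSchedule, z: np.ndarray | float) -> np.ndarray:
    """One DDPM reverse update, wrapped into [-pi, pi).

    x_{t-1} = w( (x_t - (1-alpha_t)/sqrt(1-abar_t) * eps_hat) / sqrt(alpha_t)
                 + sigma_t * z ).
    ``z`` must be 0 at t = 1.
    """
    _check_t(t, schedule.T)
    alpha = schedule.alpha_t(t)
    abar = schedule.alpha_bar_t(t)
    sigma = schedule.sigma_t(t)
    if np.ndim(alpha):
        shape = np.shape(alpha) + (1,) * (np.ndim(x_t) - np.ndim(alpha))
        alpha, abar, sigma = (a.reshape(shape) for a in (alpha, abar, sigma))
    mean = (x_t - (1.0 - alpha) / np.sqrt(1.0 - abar) * predicted_noise) / np.sqrt(alpha)
    return wrap_angles(mean + sigma * np.asarray(z))


def sample(denoiser: DenoiserFn, length: int, schedule: DiffusionSchedule,
           mu: np.ndarray | None = None, rng: np.random.Generator | None = None,
           record_trajectory: bool = False):
    """Generate one backbone's angles by iterative denoising (Algorithm-style).

    Starts from x_T ~ w(N(0, I)) of shape (length-1, 6), applies T wrapped
    reverse steps, and returns w(x_0 + mu).  With ``record_trajectory`` the
    full list [x_T, ..., x_0] (pre-unshift) is returned alongside.
    """
    result = sample_batch(denoiser, [length], schedule, mu=mu, rng=rng,
                          record_trajectory=record_trajectory)
    if record_trajectory:
        feats, traj = result
        return feats[0], [step[0] for step in traj]
    return result[0]


def sample_batch(denoiser: DenoiserFn, lengths, schedule: DiffusionSchedule,
                 mu: np.ndarray | None = None,
                 rng: np.random.Generator | None = None,
                 record_trajectory: bool = False):
    """Batched reverse-process sampling across (possibly distinct) lengths.

    Returns a list of AngleFeaturization (one per requested residue length);
    rows beyond each item's own length are padded internally and discarded.
    """
    rng = np.random.default_rng() if rng is None else rng
    lengths = [int(l) for l in lengths]
    if any(l < 2 for l in lengths):
        raise ValueError("each length must be >= 2 residues")
    rows = [l - 1 for l in lengths]
    B, Lmax = len(lengths), max(rows)
    x = wrap_angles(rng.standard_normal((B, Lmax, 6)))
    mask = np.zeros((B, Lmax), dtype=bool)
    for i, r in enumerate(rows):
        mask[i, :r] = True
    x[~mask] = 0.0
    trajectory = [x.copy()] if record_trajectory else None
    for t in range(schedule.T, 0, -1):
        t_vec = np.full(B, t, dtype=np.int64)
        eps_hat = denoiser(x, t_vec, mask)
        if eps_hat.shape != x.shape:
            raise ValueError("denoiser output shape mismatch")
        z = rng.standard_normal(x.shape) if t > 1 else 0.0
        x = reverse_step(x, t, eps_hat, schedule, z)
        x[~mask] = 0.0
        if record_trajectory:
            trajectory.append(x.copy())
    if mu is not None:
        x = wrap_angles(x + np.asarray(mu))
    feats = [AngleFeaturization(x[i, :r].copy()) for i, r in enumerate(rows)]
    if record_trajectory:
        return feats, trajectory
    return feats
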