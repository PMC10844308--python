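"""The denoising network: a bidirectional transformer over angle sequences.

The network receives a wrapped, mean-shifted angle matrix x_t of shape
(rows, 6), linearly upscales each 6-vector to the embedding dimension, adds
a random-Fourier-feature embedding of the timestep to every position, runs a
stack of pre-LN transformer blocks with learned relative-position attention
biases, and maps each position back to a 6-vector of predicted noise through
a regression head (dense -> GELU -> layer norm -> dense).

Because the internal-angle representation is already rotation- and
translation-invariant, no equivariance machinery appears anywhere: inputs
are treated as plain sequences.  Variable lengths are batched with key
masking; masked positions carry a pad value of 0 (the post-shift mean) and
never influence unmasked outputs.

The same class doubles as the autoregressive baseline body when configured
with ``causal=True`` and absolute positional embeddings (see
:mod:`torsiondiff.baselines`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .diffusion import (DiffusionSchedule, forward_sample, wrapped_smooth_l1,
                        wrapped_smooth_l1_grad, DEFAULT_BETA_L)
from .geometry import AngleFeaturization

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DenoiserConfig:
    embed_dim: int = 384
    depth: int = 12
    heads: int = 6
    feedforward_dim: int = 768
    max_length: int = 128
    time_feature_dim: int = 384
    fourier_scale: float = 16.0
    positional_mode: str = "relative"   # "relative" | "absolute"
    causal: bool = False
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim % self.heads:
            raise ValueError("embed_dim must be divisible by heads")
        if self.time_feature_dim % 2:
            raise ValueError("time_feature_dim must be even")
        if self.positional_mode not in ("relative", "absolute"):
            raise ValueError(f"unknown positional_mode {self.positional_mode!r}")


@dataclass
class PaddedBatch:
    """angles (B, Lmax, 6), boolean mask (B, Lmax), row counts, timesteps."""

    angles: np.ndarray
    mask: np.ndarray
    lengths: np.ndarray
    t: np.ndarray

    @classmethod
    def from_arrays(cls, arrays: list[np.ndarray], t: np.ndarray,
                    pad_to: int | None = None) -> "PaddedBatch":
        rows = np.array([a.shape[0] for a in arrays])
        Lmax = int(rows.max()) if pad_to is None else pad_to
        B = len(arrays)
        x = np.zeros((B, Lmax, 6))
        mask = np.zeros((B, Lmax), dtype=bool)
        for i, a in enumerate(arrays):
            x[i, :a.shape[0]] = a
            mask[i, :a.shape[0]] = True
        return cls(angles=x, mask=mask, lengths=rows, t=np.asarray(t))


def fourier_time_features(t: np.ndarray, freqs: np.ndarray,
                          denominator: float) -> np.ndarray:
    """Random Fourier features [sin(2 pi w t'), cos(2 pi w t')], t' = t/denominator."""
    tt = np.asarray(t, dtype=np.float64)[..., None] / denominator
    arg = 2.0 * np.pi * freqs * tt
    return np.concatenate([np.sin(arg), np.cos(arg)], axis=-1)


class AngleTransformer(nn.Module):
    """Sequence-to-sequence noise predictor over (B, L, 6) angle matrices."""

    def __init__(self, config: DenoiserConfig, conditioning_scale: float = 1000.0):
        self.config = config
        #: denominator normalizing the conditioning integer (T for timestep
        #: conditioning, max generation length for the AR length signal)
        self.conditioning_scale = conditioning_scale
        rng = np.random.default_rng(config.init_seed)
        d = config.embed_dim
        # fixed (non-trainable) random Fourier frequencies
        self.fourier_freqs = rng.normal(0.0, config.fourier_scale,
                                        size=config.time_feature_dim // 2)
        self.in_proj = nn.Dense(6, d, rng)
        self.cond_proj = nn.Dense(config.time_feature_dim, d, rng)
        radius = config.max_length - 1 if config.positional_mode == "relative" else 0
        self.blocks = [
            nn.TransformerBlock(d, config.heads, config.feedforward_dim, rng,
                                relative_bias_radius=radius, causal=config.causal)
            for _ in range(config.depth)
        ]
        if config.positional_mode == "absolute":
            self.pos_emb = nn.Parameter(rng.normal(0.0, 0.02,
                                                   size=(config.max_length, d)))
        self.final_ln = nn.LayerNorm(d)
        self.head_fc1 = nn.Dense(d, d, rng)
        self.head_act = nn.GELU()
        self.head_ln = nn.LayerNorm(d)
        self.head_fc2 = nn.Dense(d, 6, rng)
        self._cache = None

    # -- inference ---------------------------------------------------------
    def time_embedding(self, t: np.ndarray) -> np.ndarray:
        """Deterministic Fourier embedding of the conditioning integer, (B, d)."""
        feats = fourier_time_features(t, self.fourier_freqs, self.conditioning_scale)
        return self.cond_proj.forward(feats[:, None, :])[:, 0, :]

    def forward(self, x: np.ndarray, t: np.ndarray,
                mask: np.ndarray | None = None) -> np.ndarray:
        B, L, _ = x.shape
        if L > self.config.max_length:
            raise ValueError(
                f"sequence length {L} exceeds max_length {self.config.max_length}")
        feats = fourier_time_features(t, self.fourier_freqs, self.conditioning_scale)
        cond = self.cond_proj.forward(feats[:, None, :])  # (B,1,d)
        h = self.in_proj.forward(x) + cond
        if self.config.positional_mode == "absolute":
            h = h + self.pos_emb.value[None, :L]
        for block in self.blocks:
            h = block.forward(h, key_mask=mask)
        h = self.final_ln.forward(h)
        h = self.head_fc1.forward(h)
        h = self.head_act.forward(h)
        h = self.head_ln.forward(h)
        out = self.head_fc2.forward(h)
        self._cache = (B, L)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        B, L = self._cache
        g = self.head_fc2.backward(g)
        g = self.head_ln.backward(g)
        g = self.head_act.backward(g)
        g = self.head_fc1.backward(g)
        g = self.final_ln.backward(g)
        for block in reversed(self.blocks):
            g = block.backward(g)
        if self.config.positional_mode == "absolute":
            self.pos_emb.grad[:L] += g.sum(axis=0)
        g_cond = self.cond_proj.backward(g.sum(axis=1, keepdims=True))
        del g_cond  # Fourier features are fixed; nothing upstream
        return self.in_proj.backward(g)

    def __call__(self, x: np.ndarray, t: np.ndarray,
                 mask: np.ndarray | None = None) -> np.ndarray:
        return self.forward(x, t, mask=mask)


def count_parameters(config: DenoiserConfig) -> int:
    """Exact count of trainable scalars for a configuration."""
    return AngleTransformer(config).n_parameters()


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainSettings:
    epochs: int = 100
    batch_size: int = 64
    peak_lr: float = 5e-5
    warmup_fraction: float = 0.1
    weight_decay: float = 0.01
    beta_l: float = DEFAULT_BETA_L
    seed: int = 0
    validate_every: int = 1
    log_every: int = 0  # epochs between log lines; 0 silences


@dataclass
class Checkpoint:
    """Self-describing training artifact: weights + everything to reuse them."""

    model: AngleTransformer
    config: DenoiserConfig
    schedule: DiffusionSchedule | None
    mu: np.ndarray | None
    history: dict[str, list[float]]
    best_epoch: int
    seed: int
    epochs_completed: int = 0

    def denoiser(self):
        """Denoiser closure matching the sampling contract (x, t, mask)."""
        def fn(x: np.ndarray, t: np.ndarray,
               mask: np.ndarray | None = None) -> np.ndarray:
            return self.model.forward(x, t, mask=mask)
        return fn

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz",
                 **{k.replace(".", "/"): v for k, v in self.model.state_dict().items()})
        manifest = {
            "config": asdict(self.config),
            "conditioning_scale": self.model.conditioning_scale,
            "schedule": None if self.schedule is None else
                {"T": self.schedule.T, "s": self.schedule.s, "form": self.schedule.form},
            "mu": None if self.mu is None else list(map(float, self.mu)),
            "history": self.history,
            "best_epoch": self.best_epoch,
            "seed": self.seed,
            "epochs_completed": self.epochs_completed,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "Checkpoint":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        config = DenoiserConfig(**manifest["config"])
        model = AngleTransformer(config, conditioning_scale=manifest["conditioning_scale"])
        with np.load(directory / "weights.npz") as data:
            model.load_state_dict({k.replace("/", "."): data[k] for k in data.files})
        sched_spec = manifest["schedule"]
        schedule = None if sched_spec is None else DiffusionSchedule(**sched_spec)
        mu = None if manifest["mu"] is None else np.array(manifest["mu"])
        return cls(model=model, config=config, schedule=schedule, mu=mu,
                   history=manifest["history"], best_epoch=manifest["best_epoch"],
                   seed=manifest["seed"],
                   epochs_completed=manifest.get("epochs_completed", 0))


def _as_arrays(dataset) -> list[np.ndarray]:
    out = []
    for item in dataset:
        a = item.angles if isinstance(item, AngleFeaturization) else np.asarray(item)
        out.append(np.asarray(a, dtype=np.float64))
    return out


def train_denoiser(
    train_set,
    schedule: DiffusionSchedule,
    config: DenoiserConfig,
    settings: TrainSettings = TrainSettings(),
    validation_set=None,
    mu: np.ndarray | None = None,
    resume_from: "Checkpoint | None" = None,
) -> Checkpoint:
    """Train the noise predictor with AdamW and a linear warmup/decay schedule.

    ``train_set``/``validation_set`` are lists of AngleFeaturization or
    (rows, 6) arrays of *wrapped, mean-shifted* angles; pass ``mu`` so the
    checkpoint can un-shift at sampling time.  Each step draws per-item
    timesteps uniformly from 1..T, noises with the closed form, and minimizes
    the wrapped smooth-L1 between the drawn noise and the prediction.
    Validation noise uses a fixed seed so the loss is comparable across
    epochs; the best-validation checkpoint is returned.

    Raises ``FloatingPointError`` on divergence (non-finite loss).
    """
    rng = np.random.default_rng(settings.seed)
    arrays = _as_arrays(train_set)
    val_arrays = _as_arrays(validation_set) if validation_set else None
    model = AngleTransformer(config, conditioning_scale=float(schedule.T))
    epochs_before = 0
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "lr": []}
    if resume_from is not None:
        if resume_from.config != config:
            raise ValueError("resume checkpoint has a different configuration")
        model.load_state_dict(resume_from.model.state_dict())
        epochs_before = resume_from.epochs_completed
        history = {k: list(v) for k, v in resume_from.history.items()}
    opt = nn.AdamW(model, lr=settings.peak_lr, weight_decay=settings.weight_decay)
    n = len(arrays)
    steps_per_epoch = max(1, int(np.ceil(n / settings.batch_size)))
    total_steps = steps_per_epoch * settings.epochs
    best = (np.inf, -1, model.state_dict())
    step = 0
    for epoch in range(settings.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        lr = settings.peak_lr
        for start in range(0, n, settings.batch_size):
            idx = order[start:start + settings.batch_size]
            t = rng.integers(1, schedule.T + 1, size=len(idx))
            batch = PaddedBatch.from_arrays([arrays[i] for i in idx], t)
            noised = forward_sample(batch.angles, t, schedule, rng)
            model.zero_grad()
            pred = model.forward(noised.x_t, t, mask=batch.mask)
            loss, grad = wrapped_smooth_l1_grad(pred, noised.epsilon,
                                                settings.beta_l, mask=batch.mask)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}, step {step}: loss={loss}")
            model.backward(grad)  # grad is already dL/dpred
            lr = nn.linear_warmup_decay(step, total_steps, settings.peak_lr,
                                        settings.warmup_fraction)
            opt.step(lr=lr)
            epoch_loss += loss * len(idx)
            step += 1
        history["train_loss"].append(epoch_loss / n)
        history["lr"].append(lr)
        if val_arrays is not None and (epoch % settings.validate_every == 0
                                       or epoch == settings.epochs - 1):
            val_loss = evaluate_loss(model, val_arrays, schedule,
                                     beta_l=settings.beta_l,
                                     seed=settings.seed + 10_000)
            history["val_loss"].append(val_loss)
            if val_loss < best[0]:
                best = (val_loss, epochs_before + epoch, model.state_dict())
        if settings.log_every and epoch % settings.log_every == 0:
            logger.info("epoch %d train %.4f val %s", epoch,
                        history["train_loss"][-1],
                        history["val_loss"][-1] if history["val_loss"] else "-")
    if val_arrays is not None and best[1] >= 0:
        model.load_state_dict(best[2])
        best_epoch = best[1]
    else:
        best_epoch = epochs_before + settings.epochs - 1
    return Checkpoint(model=model, config=config, schedule=schedule, mu=mu,
                      history=history, best_epoch=best_epoch, seed=settings.seed,
                      epochs_completed=epochs_before + settings.epochs)


def evaluate_loss(model: AngleTransformer, arrays: list[np.ndarray],
                  schedule: DiffusionSchedule, beta_l: float = DEFAULT_BETA_L,
                  seed: int = 0, batch_size: int = 64) -> float:
    """Mean wrapped smooth-L1 denoising loss under a fixed noise seed."""
    rng = np.random.default_rng(seed)
    total, count = 0.0, 0
    for start in range(0, len(arrays), batch_size):
        chunk = arrays[start:start + batch_size]
        t = rng.integers(1, schedule.T + 1, size=len(chunk))
        batch = PaddedBatch.from_arrays(chunk, t)
        noised = forward_sample(batch.angles, t, schedule, rng)
        pred = model.forward(noised.x_t, t, mask=batch.mask)
        total += wrapped_smooth_l1(pred, noised.epsilon, beta_l,
                                   mask=batch.mask) * len(chunk)
        count += len(chunk)
    return total / count
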