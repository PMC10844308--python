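"""Comparison generators: angle-row shuffling and an autoregressive transformer.

The shuffle baseline concatenates every angle row of a reference (test) set
into one pool and builds "structures" by drawing rows uniformly with
replacement.  Rows stay intact, so per-row joints (e.g. the Ramachandran
density) are preserved exactly in expectation, but all sequential ordering
is destroyed -- lag-1 angular autocorrelation collapses to ~0.

The AR baseline shares the transformer body and regression head with the
diffusion denoiser but uses causal attention masking, absolute positional
embeddings, and a Fourier embedding of the *total length* added at every
position.  It is trained with the same wrapped smooth-L1 loss to regress
row i from rows 0..i-1, and decodes deterministically (greedy regression,
no sampling noise), seeded with 4 angle rows from a natural structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .diffusion import DEFAULT_BETA_L, wrapped_smooth_l1, wrapped_smooth_l1_grad
from .geometry import AngleFeaturization, wrap_angles
from .model import (AngleTransformer, Checkpoint, DenoiserConfig, PaddedBatch,
                    TrainSettings, _as_arrays)

logger = logging.getLogger(__name__)

AR_SEED_ROWS = 4


@dataclass
class AnglePool:
    """All rows of a reference set, concatenated into one (N, 6) matrix."""

    rows: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.float64)
        if self.rows.ndim != 2 or self.rows.shape[1] != 6:
            raise ValueError("pool must have shape (n_rows, 6)")
        if self.rows.shape[0] == 0:
            raise ValueError("empty angle pool")

    @classmethod
    def from_featurizations(cls, angle_sets) -> "AnglePool":
        return cls(np.concatenate([_rows(a) for a in angle_sets], axis=0))

    def __len__(self) -> int:
        return self.rows.shape[0]


def _rows(a) -> np.ndarray:
    return a.angles if isinstance(a, AngleFeaturization) else np.asarray(a)


def shuffle_generate(pool: AnglePool, length: int,
                     rng: np.random.Generator) -> AngleFeaturization:
    """Backbone angles for ``length`` residues by uniform row resampling."""
    if length < 2:
        raise ValueError("length must be >= 2 residues")
    idx = rng.integers(0, len(pool), size=length - 1)
    return AngleFeaturization(pool.rows[idx].copy())


def lag1_circular_autocorrelation(values: np.ndarray) -> float:
    """Circular lag-1 autocorrelation (Fisher-Lee) of an angle series."""
    x = np.asarray(values, dtype=np.float64)
    a, b = x[:-1], x[1:]
    am = np.arctan2(np.sin(a).mean(), np.cos(a).mean())
    bm = np.arctan2(np.sin(b).mean(), np.cos(b).mean())
    sa, sb = np.sin(a - am), np.sin(b - bm)
    denom = np.sqrt((sa ** 2).sum() * (sb ** 2).sum())
    if denom == 0:
        return 0.0
    return float((sa * sb).sum() / denom)


# ---------------------------------------------------------------------------
# Autoregressive baseline
# ---------------------------------------------------------------------------

def ar_config(embed_dim: int = 384, depth: int = 12, heads: int = 6,
              feedforward_dim: int = 768, max_length: int = 128,
              time_feature_dim: int = 384, init_seed: int = 0) -> DenoiserConfig:
    """The AR baseline's architecture: causal, absolute positions."""
    return DenoiserConfig(embed_dim=embed_dim, depth=depth, heads=heads,
                          feedforward_dim=feedforward_dim,
                          max_length=max_length,
                          time_feature_dim=time_feature_dim,
                          positional_mode="absolute", causal=True,
                          init_seed=init_seed)


def ar_train(
    train_set,
    config: DenoiserConfig,
    settings: TrainSettings = TrainSettings(),
    validation_set=None,
    mu: np.ndarray | None = None,
) -> Checkpoint:
    """Train next-row regression with the wrapped smooth-L1 loss.

    The model conditions on the total row count of each training item via
    Fourier features (the conditioning slot that carries the timestep in the
    diffusion model); output position i predicts row i+1, so loss runs over
    positions 0..L-2 against rows 1..L-1.
    """
    if not config.causal:
        raise ValueError("AR baseline requires a causal config")
    rng = np.random.default_rng(settings.seed)
    arrays = _as_arrays(train_set)
    val_arrays = _as_arrays(validation_set) if validation_set else None
    model = AngleTransformer(config, conditioning_scale=float(config.max_length))
    opt = nn.AdamW(model, lr=settings.peak_lr, weight_decay=settings.weight_decay)
    n = len(arrays)
    steps_per_epoch = max(1, int(np.ceil(n / settings.batch_size)))
    total_steps = steps_per_epoch * settings.epochs
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "lr": []}
    best = (np.inf, -1, model.state_dict())
    step = 0
    for epoch in range(settings.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        lr = settings.peak_lr
        for start in range(0, n, settings.batch_size):
            idx = order[start:start + settings.batch_size]
            loss, lr = _ar_step(model, opt, [arrays[i] for i in idx],
                                settings, step, total_steps)
            epoch_loss += loss * len(idx)
            step += 1
        history["train_loss"].append(epoch_loss / n)
        history["lr"].append(lr)
        if val_arrays is not None:
            val_loss = ar_loss(model, val_arrays, beta_l=settings.beta_l)
            history["val_loss"].append(val_loss)
            if val_loss < best[0]:
                best = (val_loss, epoch, model.state_dict())
    if val_arrays is not None and best[1] >= 0:
        model.load_state_dict(best[2])
        best_epoch = best[1]
    else:
        best_epoch = settings.epochs - 1
    return Checkpoint(model=model, config=config, schedule=None, mu=mu,
                      history=history, best_epoch=best_epoch,
                      seed=settings.seed, epochs_completed=settings.epochs)


def _ar_targets(batch: PaddedBatch):
    """Inputs rows 0..L-2, targets rows 1..L-1, mask over valid targets."""
    x_in = batch.angles[:, :-1]
    target = batch.angles[:, 1:]
    mask_in = batch.mask[:, :-1]
    # target at output position i is row i+1: valid where row i+1 exists
    mask_target = batch.mask[:, 1:]
    lengths = batch.lengths  # total rows per item, the conditioning signal
    return x_in, target, mask_in, mask_target, lengths


def _ar_step(model, opt, chunk, settings, step, total_steps):
    batch = PaddedBatch.from_arrays(chunk, t=np.zeros(len(chunk)))
    x_in, target, mask_in, mask_target, lengths = _ar_targets(batch)
    model.zero_grad()
    pred = model.forward(x_in, lengths, mask=mask_in)
    loss, grad = wrapped_smooth_l1_grad(pred, target, settings.beta_l,
                                        mask=mask_target)
    if not np.isfinite(loss):
        raise FloatingPointError(f"AR training diverged at step {step}")
    model.backward(grad)
    lr = nn.linear_warmup_decay(step, total_steps, settings.peak_lr,
                                settings.warmup_fraction)
    opt.step(lr=lr)
    return loss, lr


def ar_loss(model: AngleTransformer, arrays, beta_l: float = DEFAULT_BETA_L,
            batch_size: int = 64) -> float:
    """Mean next-row wrapped smooth-L1 loss (deterministic)."""
    arrays = _as_arrays(arrays)
    total, count = 0.0, 0
    for start in range(0, len(arrays), batch_size):
        chunk = arrays[start:start + batch_size]
        batch = PaddedBatch.from_arrays(chunk, t=np.zeros(len(chunk)))
        x_in, target, mask_in, mask_target, lengths = _ar_targets(batch)
        pred = model.forward(x_in, lengths, mask=mask_in)
        total += wrapped_smooth_l1(pred, target, beta_l,
                                   mask=mask_target) * len(chunk)
        count += len(chunk)
    return total / count


def ar_generate(checkpoint: Checkpoint, seed_rows: np.ndarray,
                length: int) -> AngleFeaturization:
    """Greedy autoregressive roll-out to ``length`` residues.

    ``seed_rows`` are the first 4 angle rows of a natural structure and are
    reproduced verbatim at the start of the output; the model then appends
    one predicted row at a time (deterministic: the decoder has no sampling
    noise).  Output has length-1 rows.
    """
    seed_rows = np.asarray(seed_rows, dtype=np.float64)
    if seed_rows.shape != (AR_SEED_ROWS, 6):
        raise ValueError(f"seed must have shape ({AR_SEED_ROWS}, 6)")
    n_rows = length - 1
    if n_rows <= AR_SEED_ROWS:
        raise ValueError(f"length must exceed {AR_SEED_ROWS + 1} residues")
    model = checkpoint.model
    rows = list(seed_rows)
    cond = np.array([n_rows], dtype=np.float64)
    while len(rows) < n_rows:
        x = np.asarray(rows)[None]  # (1, i, 6)
        pred = model.forward(x, cond, mask=None)
        rows.append(wrap_angles(pred[0, -1]))
    return AngleFeaturization(np.asarray(rows))
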