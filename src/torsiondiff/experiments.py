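"""Desk-scale study protocols: self-contained, seeded, minutes-not-hours.

These functions bundle the synthetic-data conditions, model sizes, and
training budgets used for the package's distribution-recovery and chirality
studies, so that tests, scripts, and interactive use all run the identical
protocol.  Full-scale training on a real domain set goes through the CLI
(or ``scripts/train_cath_full.py``) instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import (DEFAULT_MIXTURE, IDEAL_THETA, WrappedMixtureSpec,
                   compute_angular_mean, empirical_mode_parameters,
                   make_wrapped_mixture_dataset, shift)
from .diffusion import build_cosine_schedule, sample_batch
from .evaluation import DEFAULT_REGIONS, ramachandran_density
from .geometry import wrap_angles
from .model import Checkpoint, DenoiserConfig, TrainSettings, train_denoiser

#: Schedule used by the desk-scale studies (full-scale default is T=1000).
TOY_TIMESTEPS = 100

#: Single-mode mixture concentrated in the right-handed-helix Ramachandran
#: region: the chirality study's training distribution.
RH_HELIX_MIXTURE = WrappedMixtureSpec(
    means=np.array([wrap_angles(
        [np.deg2rad(-47.0), np.pi, np.deg2rad(-57.0), *IDEAL_THETA])]),
    sigmas=np.array([0.15]),
    weights=np.array([1.0]),
)


def _toy_config(seed: int) -> DenoiserConfig:
    return DenoiserConfig(embed_dim=64, depth=3, heads=4, feedforward_dim=128,
                          max_length=16, time_feature_dim=64, init_seed=seed)


def train_toy_denoiser(spec: WrappedMixtureSpec = DEFAULT_MIXTURE,
                       n: int = 512, rows_per_item: int = 16,
                       epochs: int = 400, seed: int = 0) -> Checkpoint:
    """Train a small denoiser on a wrapped-mixture dataset.

    The dataset (512 items of 16 rows), schedule (T=100), architecture
    (3-layer, 64-dim) and budget (400 epochs, peak LR 2e-3) are the
    package's fixed desk-scale conditions.
    """
    data, _ = make_wrapped_mixture_dataset(spec, n=n, rows_per_item=rows_per_item,
                                           seed=seed)
    mu = compute_angular_mean(data)
    shifted = [shift(a, mu, -1) for a in data]
    n_train = int(0.875 * n)
    schedule = build_cosine_schedule(T=TOY_TIMESTEPS)
    settings = TrainSettings(epochs=epochs, batch_size=64, peak_lr=2e-3,
                             seed=seed + 1, validate_every=10)
    return train_denoiser(shifted[:n_train], schedule, _toy_config(seed),
                          settings, validation_set=shifted[n_train:], mu=mu.mu)


def generate_rows(checkpoint: Checkpoint, n_rows: int = 1008,
                  rows_per_item: int = 16, seed: int = 0) -> np.ndarray:
    """Sample ~n_rows angle rows from a trained toy checkpoint."""
    n_items = int(np.ceil(n_rows / rows_per_item))
    rng = np.random.default_rng(seed)
    feats = sample_batch(checkpoint.denoiser(), [rows_per_item + 1] * n_items,
                         checkpoint.schedule, mu=checkpoint.mu, rng=rng)
    return np.concatenate([f.angles for f in feats], axis=0)[:n_rows]


def mixture_recovery_study(seed: int = 0,
                           spec: WrappedMixtureSpec = DEFAULT_MIXTURE) -> dict:
    """Train on the 2-mode mixture; measure mode-location and weight recovery.

    Returns max circular location error (rad) over modes/columns and max
    absolute weight error, from 1008 generated rows.
    """
    checkpoint = train_toy_denoiser(spec, seed=seed)
    rows = generate_rows(checkpoint, seed=seed + 100)
    means, weights = empirical_mode_parameters(rows, spec)
    loc_err = np.abs(wrap_angles(means - spec.means))
    return {
        "mode_location_error_rad": float(np.nanmax(loc_err)),
        "mode_weight_error": float(np.abs(weights - spec.weights).max()),
        "empirical_means": means,
        "empirical_weights": weights,
        "checkpoint": checkpoint,
    }


def chirality_study(seed: int = 0, epochs: int = 200) -> dict:
    """Train on right-handed-helix-region rows; measure generated chirality.

    A model trained on (phi, psi) mass concentrated in the right-handed
    helix region should place nearly all generated mass there and nearly
    none in the mirror-image left-handed region.
    """
    checkpoint = train_toy_denoiser(RH_HELIX_MIXTURE, epochs=epochs, seed=seed)
    rows = generate_rows(checkpoint, seed=seed + 100)
    rama = ramachandran_density([rows], regions=DEFAULT_REGIONS)
    return {
        "rh_mass": rama.region_masses["rh_helix"],
        "lh_mass": rama.region_masses["lh_helix"],
        "checkpoint": checkpoint,
    }
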