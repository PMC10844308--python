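"""Dataset ingestion, filtering, splitting, normalization, and synthetic fixtures.

Real data enters as a directory of PDB-format domain files (e.g. the CATH
non-redundant domain set): chains shorter than 40 residues or with incomplete
backbones are discarded, the rest are featurized to angle matrices.  Training
angles are normalized to zero *circular* mean per column; chains longer than
128 residues are re-cropped to a random 128-residue window every epoch.

Two synthetic generators make the whole pipeline testable without any
download: idealized secondary-structure backbones (helix/strand built from
literature (phi, psi) values and idealized bond geometry), and angle
datasets drawn from wrapped-Gaussian mixtures with known parameters, which
serve as ground truth for distribution-recovery checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import (AngleFeaturization, BackboneStructure,
                       BondLengthConstants, DEFAULT_BOND_LENGTHS,
                       featurize_backbone, read_pdb, reconstruct_backbone,
                       wrap_angles)

logger = logging.getLogger(__name__)

MIN_RESIDUES = 40
CROP_WINDOW = 128

#: Idealized backbone bond angles (radians): N-CA-C, CA-C-N, C-N-CA.
IDEAL_THETA = (np.deg2rad(111.0), np.deg2rad(116.2), np.deg2rad(121.7))
#: Literature (phi, psi) idealizations, degrees (config defaults, not fitted).
HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-119.0, 113.0)


@dataclass
class DomainRecord:
    identifier: str
    structure: BackboneStructure
    angles: AngleFeaturization


@dataclass(frozen=True)
class NormalizationOffset:
    """Element-wise circular means of the six training-set angle columns."""

    mu: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=np.float64))
        if self.mu.shape != (6,):
            raise ValueError("mu must be a 6-vector")
        if (self.mu < -np.pi).any() or (self.mu >= np.pi).any():
            raise ValueError("mu components must lie in [-pi, pi)")


@dataclass(frozen=True)
class SplitAssignment:
    train: tuple[str, ...]
    validation: tuple[str, ...]
    test: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        all_ids = self.train + self.validation + self.test
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("split lists overlap")


def load_cath(path: str | Path) -> list[DomainRecord]:
    """Load and featurize every usable chain from a directory of PDB files.

    Chains with fewer than 40 residues (inclusive boundary: 40 is kept) or
    incomplete backbones are discarded with a logged warning.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise FileNotFoundError(f"no files under {path}")
    records: list[DomainRecord] = []
    for f in files:
        try:
            structures = read_pdb(f)
        except Exception as exc:  # unreadable file
            logger.warning("skipping unreadable file %s: %s", f, exc)
            continue
        for s in structures:
            if s.residue_count < MIN_RESIDUES:
                logger.warning("%s chain %s: %d residues < %d, excluded",
                               f.name, s.chain_id, s.residue_count, MIN_RESIDUES)
                continue
            ident = f.stem if len(structures) == 1 else f"{f.stem}_{s.chain_id}"
            records.append(DomainRecord(ident, s, featurize_backbone(s)))
    return records


def split_dataset(identifiers, ratios=(0.8, 0.1, 0.1), seed: int = 0
                  ) -> SplitAssignment:
    """Random train/validation/test partition with the floor convention.

    train = floor(r0 * n), validation = floor(r1 * n), test = remainder,
    so 30,395 identifiers split 80/10/10 into 24,316 / 3,039 / 3,040.
    """
    identifiers = list(identifiers)
    if not identifiers:
        raise ValueError("empty identifier list")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(identifiers))
    n = len(identifiers)
    n_train = int(np.floor(ratios[0] * n))
    n_val = int(np.floor(ratios[1] * n))
    shuffled = [identifiers[i] for i in order]
    return SplitAssignment(
        train=tuple(shuffled[:n_train]),
        validation=tuple(shuffled[n_train:n_train + n_val]),
        test=tuple(shuffled[n_train + n_val:]),
        seed=seed,
    )


def random_crop(angles: AngleFeaturization, window: int = CROP_WINDOW,
                rng: np.random.Generator | None = None,
                start: int | None = None) -> AngleFeaturization:
    """Contiguous ``window``-residue crop (window-1 angle rows).

    Inputs of at most ``window`` residues pass through unchanged.  The start
    offset is uniform over valid positions and re-drawn on every call (one
    call per epoch); pass ``start`` for a frozen deterministic crop.
    """
    n_res = angles.residue_count
    if n_res <= window:
        return angles
    max_start = n_res - window
    if start is None:
        rng = np.random.default_rng() if rng is None else rng
        start = int(rng.integers(0, max_start + 1))
    elif not (0 <= start <= max_start):
        raise ValueError(f"start must be in [0, {max_start}]")
    return AngleFeaturization(angles.angles[start:start + window - 1].copy())


def compute_angular_mean(angle_sets) -> NormalizationOffset:
    """Per-column circular mean over all rows of all training featurizations."""
    rows = np.concatenate([_rows(a) for a in angle_sets], axis=0)
    if rows.size == 0:
        raise ValueError("empty training set")
    s = np.sin(rows).sum(axis=0)
    c = np.cos(rows).sum(axis=0)
    resultant = np.hypot(s, c) / rows.shape[0]
    if (resultant < 1e-12).any():
        raise ValueError("circular mean undefined: zero resultant length")
    return NormalizationOffset(mu=wrap_angles(np.arctan2(s, c)))


def shift(angles, mu: NormalizationOffset | np.ndarray, direction: int = -1):
    """Shift by the angular mean and re-wrap.

    ``direction=-1`` subtracts mu (normalization before training);
    ``direction=+1`` adds it back (un-shift at sampling, Algorithm line
    ``w(x0 + mu)``).  shift(shift(x, mu, -1), mu, +1) is the identity.
    """
    if direction not in (-1, +1):
        raise ValueError("direction must be -1 (subtract) or +1 (add)")
    m = mu.mu if isinstance(mu, NormalizationOffset) else np.asarray(mu)
    if isinstance(angles, AngleFeaturization):
        return AngleFeaturization(wrap_angles(angles.angles + direction * m))
    return wrap_angles(np.asarray(angles) + direction * m)


def _rows(a) -> np.ndarray:
    return a.angles if isinstance(a, AngleFeaturization) else np.asarray(a)


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

def make_ideal_secondary_fixture(
    kind: str, n_res: int,
    phi: float | None = None, psi: float | None = None,
    lengths: BondLengthConstants = DEFAULT_BOND_LENGTHS,
) -> BackboneStructure:
    """Idealized single-element backbone built from constant angle rows.

    ``kind='helix'`` uses (phi, psi) = (-57, -47) degrees, ``kind='strand'``
    (-119, 113); omega is trans (pi, stored wrapped as -pi) and bond angles
    take idealized values.  Deterministic: reconstruction from constant rows.
    """
    if n_res < 4:
        raise ValueError("n_res must be >= 4")
    if kind == "helix":
        default_phi, default_psi = HELIX_PHI_PSI
    elif kind == "strand":
        default_phi, default_psi = STRAND_PHI_PSI
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    phi = np.deg2rad(default_phi) if phi is None else phi
    psi = np.deg2rad(default_psi) if psi is None else psi
    t1, t2, t3 = IDEAL_THETA
    row = wrap_angles(np.array([psi, np.pi, phi, t1, t2, t3]))
    angles = AngleFeaturization(np.tile(row, (n_res - 1, 1)))
    return reconstruct_backbone(angles, lengths)


@dataclass(frozen=True)
class WrappedMixtureSpec:
    """Ground-truth parameters of a wrapped-Gaussian mixture over angle rows."""

    means: np.ndarray    # (n_modes, 6) wrapped radians
    sigmas: np.ndarray   # (n_modes,) standard deviations, > 0
    weights: np.ndarray  # (n_modes,) summing to 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", wrap_angles(
            np.atleast_2d(np.asarray(self.means, dtype=np.float64))))
        object.__setattr__(self, "sigmas",
                           np.atleast_1d(np.asarray(self.sigmas, dtype=np.float64)))
        object.__setattr__(self, "weights",
                           np.atleast_1d(np.asarray(self.weights, dtype=np.float64)))
        if self.means.shape[1] != 6:
            raise ValueError("mode means must be 6-vectors")
        if (self.sigmas <= 0).any():
            raise ValueError("mode sigmas must be > 0")
        if abs(self.weights.sum() - 1.0) > 1e-9 or (self.weights < 0).any():
            raise ValueError("mode weights must be nonnegative and sum to 1")


#: Default 2-mode study mixture: a helix-like and a strand-like angle row,
#: idealized bond angles, trans omega; 65/35 weighting, sigma 0.2 rad.
DEFAULT_MIXTURE = WrappedMixtureSpec(
    means=np.array([
        wrap_angles([np.deg2rad(-47.0), np.pi, np.deg2rad(-57.0), *IDEAL_THETA]),
        wrap_angles([np.deg2rad(113.0), np.pi, np.deg2rad(-119.0), *IDEAL_THETA]),
    ]),
    sigmas=np.array([0.2, 0.2]),
    weights=np.array([0.65, 0.35]),
)


def make_wrapped_mixture_dataset(
    spec: WrappedMixtureSpec = DEFAULT_MIXTURE,
    n: int = 512, rows_per_item: int = 16, seed: int = 0,
) -> tuple[list[AngleFeaturization], WrappedMixtureSpec]:
    """Draw ``n`` angle matrices whose rows are i.i.d. wrapped-mixture samples.

    Each row picks a mode by weight, then draws N(mean, sigma^2 I) in R^6 and
    wraps.  Returns the dataset together with the ground-truth spec so
    recovery tests can compare against it.  Same seed, same dataset.
    """
    rng = np.random.default_rng(seed)
    out = []
    k = len(spec.weights)
    for _ in range(n):
        modes = rng.choice(k, size=rows_per_item, p=spec.weights)
        rows = (spec.means[modes]
                + rng.standard_normal((rows_per_item, 6)) * spec.sigmas[modes, None])
        out.append(AngleFeaturization(wrap_angles(rows)))
    return out, spec


def assign_to_modes(rows: np.ndarray, spec: WrappedMixtureSpec) -> np.ndarray:
    """Nearest-mode assignment under summed squared circular distance."""
    rows = np.asarray(rows)
    d = wrap_angles(rows[:, None, :] - spec.means[None, :, :])
    return np.argmin((d ** 2).sum(axis=-1), axis=1)


def empirical_mode_parameters(rows: np.ndarray, spec: WrappedMixtureSpec
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-mode circular means and weights of generated rows.

    Modes with no assigned rows get NaN means and weight 0.
    """
    rows = np.asarray(rows)
    labels = assign_to_modes(rows, spec)
    k = len(spec.weights)
    means = np.full((k, 6), np.nan)
    weights = np.zeros(k)
    for j in range(k):
        sel = rows[labels == j]
        weights[j] = len(sel) / len(rows)
        if len(sel):
            means[j] = wrap_angles(np.arctan2(np.sin(sel).sum(0), np.cos(sel).sum(0)))
    return means, weights
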