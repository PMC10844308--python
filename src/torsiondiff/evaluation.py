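"""Structure-level analyses of generated backbone ensembles.

Covers: per-angle circular histograms with a divergence score against a
reference set, Ramachandran (phi, psi) joint densities with configurable
region boxes for right-handed helix / left-handed helix / sheet, a
P-SEA-style secondary-structure annotator working purely from CA geometry,
secondary-structure co-occurrence histograms, and ensemble diversity
clustering on 1 - TMscore distances with average linkage.

The TM-score itself is never reimplemented: :func:`cluster_ensemble` takes
any injected similarity backend (an external TM-score binary wrapper, or a
cheap RMSD-based stand-in for tests).  The designability pipeline likewise
only orchestrates user-supplied external tools.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .geometry import (AngleFeaturization, BackboneStructure, wrap_angles,
                       write_pdb)

logger = logging.getLogger(__name__)

ANGLE_COLUMNS = {"psi": 0, "omega": 1, "phi": 2,
                 "theta1": 3, "theta2": 4, "theta3": 5}


# ---------------------------------------------------------------------------
# Angle distributions
# ---------------------------------------------------------------------------

def circular_histogram(values: np.ndarray, bins: int = 50) -> np.ndarray:
    """Counts over ``bins`` equal-width bins tiling [-pi, pi).

    Binning is circular by construction: the domain is already the full
    circle, so mass near -pi and near +pi sits in adjacent (wrap-around
    neighboring) bins rather than being clamped to extremes.
    """
    edges = np.linspace(-np.pi, np.pi, bins + 1)
    counts, _ = np.histogram(wrap_angles(np.asarray(values)), bins=edges)
    return counts


def jensen_shannon_divergence(p_counts: np.ndarray, q_counts: np.ndarray) -> float:
    """JS divergence (base e) between two binned distributions; 0 iff equal."""
    from scipy.spatial.distance import jensenshannon

    p = np.asarray(p_counts, dtype=np.float64)
    q = np.asarray(q_counts, dtype=np.float64)
    if p.sum() == 0 or q.sum() == 0:
        raise ValueError("empty histogram")
    return float(jensenshannon(p / p.sum(), q / q.sum(), base=np.e) ** 2)


def angle_histograms(generated, reference, bins: int = 50) -> pd.DataFrame:
    """Paired circular histograms and divergences for the six angle columns.

    Returns a DataFrame indexed by angle name with columns
    ``generated_counts``, ``reference_counts`` (arrays) and ``js_divergence``.
    """
    gen = _concat_rows(generated)
    ref = _concat_rows(reference)
    rows = {}
    for name, col in ANGLE_COLUMNS.items():
        hg = circular_histogram(gen[:, col], bins)
        hr = circular_histogram(ref[:, col], bins)
        rows[name] = {"generated_counts": hg, "reference_counts": hr,
                      "js_divergence": jensen_shannon_divergence(hg, hr)}
    return pd.DataFrame.from_dict(rows, orient="index")


def _concat_rows(angle_sets) -> np.ndarray:
    if isinstance(angle_sets, np.ndarray):
        return angle_sets
    arrays = [a.angles if isinstance(a, AngleFeaturization) else np.asarray(a)
              for a in angle_sets]
    return np.concatenate(arrays, axis=0)


# ---------------------------------------------------------------------------
# Ramachandran densities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RamachandranRegions:
    """Conventional (phi, psi) boxes, degrees; psi intervals may wrap.

    These are plotting conventions, not fitted values: right-handed helix in
    the lower-left quadrant, left-handed helix mirrored into phi > 0, sheet
    in the upper-left with its psi interval wrapping through 180.
    """

    rh_helix: tuple = ((-180.0, 0.0), (-100.0, 50.0))
    lh_helix: tuple = ((0.0, 180.0), (-50.0, 100.0))
    sheet: tuple = ((-180.0, 0.0), (50.0, -100.0))  # psi wraps through 180

    def mass(self, phi: np.ndarray, psi: np.ndarray, region: str) -> float:
        """Fraction of (phi, psi) pairs inside the named region box."""
        (phi_lo, phi_hi), (psi_lo, psi_hi) = getattr(self, region)
        phi_d = np.rad2deg(wrap_angles(phi))
        psi_d = np.rad2deg(wrap_angles(psi))
        in_phi = (phi_d >= phi_lo) & (phi_d < phi_hi)
        if psi_lo <= psi_hi:
            in_psi = (psi_d >= psi_lo) & (psi_d < psi_hi)
        else:  # wrapped interval passing through +-180
            in_psi = (psi_d >= psi_lo) | (psi_d < psi_hi)
        return float((in_phi & in_psi).mean())


DEFAULT_REGIONS = RamachandranRegions()


@dataclass
class RamachandranDensity:
    histogram: np.ndarray        # (bins, bins) counts, phi x psi
    phi_edges: np.ndarray
    psi_edges: np.ndarray
    region_masses: dict[str, float]


def ramachandran_density(angle_sets, bins: int = 72,
                         regions: RamachandranRegions = DEFAULT_REGIONS
                         ) -> RamachandranDensity:
    """Joint (phi, psi) histogram on [-pi, pi)^2 plus region mass fractions."""
    rows = _concat_rows(angle_sets)
    phi = rows[:, ANGLE_COLUMNS["phi"]]
    psi = rows[:, ANGLE_COLUMNS["psi"]]
    edges = np.linspace(-np.pi, np.pi, bins + 1)
    hist, phi_edges, psi_edges = np.histogram2d(
        wrap_angles(phi), wrap_angles(psi), bins=(edges, edges))
    masses = {name: regions.mass(phi, psi, name)
              for name in ("rh_helix", "lh_helix", "sheet")}
    return RamachandranDensity(histogram=hist, phi_edges=phi_edges,
                               psi_edges=psi_edges, region_masses=masses)


# ---------------------------------------------------------------------------
# Secondary-structure annotation (P-SEA-style, CA geometry)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SSEThresholds:
    """CA-geometry windows for helix/strand assignment.

    Defaults follow the published P-SEA criteria: CA(i)-CA(i+2|3|4)
    distances in Angstrom, plus the pseudo bond angle over three and the
    pseudo torsion over four consecutive CA atoms (radians).  An assignment
    requires a minimum run of consecutive hits (5 for helix, 4 for strand),
    then extends one relaxed-criterion residue at each edge.
    """

    helix_d3: tuple = (4.8, 5.8)
    helix_d4: tuple = (5.8, 7.0)
    helix_angle: tuple = (np.deg2rad(77.0), np.deg2rad(101.0))
    helix_torsion: tuple = (np.deg2rad(30.0), np.deg2rad(70.0))
    strand_d2: tuple = (6.1, 7.3)
    strand_d3: tuple = (9.0, 10.8)
    strand_d4: tuple = (11.3, 13.5)
    strand_angle: tuple = (np.deg2rad(110.0), np.deg2rad(138.0))
    strand_torsion_abs: tuple = (np.deg2rad(125.0), np.pi)  # |torsion| window
    min_helix_run: int = 5
    min_strand_run: int = 4


DEFAULT_SSE_THRESHOLDS = SSEThresholds()


@dataclass
class SSEAnnotation:
    labels: np.ndarray  # per-residue 'H' / 'E' / 'C'
    n_helix: int        # count of maximal H runs
    n_strand: int       # count of maximal E runs

    def __str__(self) -> str:
        return "".join(self.labels)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) spans of True runs."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def _in(x: np.ndarray, window: tuple) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return (x >= window[0]) & (x <= window[1])


def annotate_sse(structure: BackboneStructure,
                 thresholds: SSEThresholds = DEFAULT_SSE_THRESHOLDS
                 ) -> SSEAnnotation:
    """Assign per-residue H/E/C labels from CA geometry alone.

    Chains shorter than 5 residues come back all-coil.  Helix and strand
    counts are the numbers of maximal runs of each label; runs shorter than
    the configured minima never form (smoothing only removes, never creates,
    labels).
    """
    ca = structure.ca
    n = len(ca)
    labels = np.full(n, "C", dtype="U1")
    if n >= 5:
        d2 = np.full(n, np.nan)
        d3 = np.full(n, np.nan)
        d4 = np.full(n, np.nan)
        ang = np.full(n, np.nan)
        tor = np.full(n, np.nan)
        d2[1:n - 1] = np.linalg.norm(ca[2:] - ca[:-2], axis=1)
        d3[1:n - 2] = np.linalg.norm(ca[3:] - ca[:-3], axis=1)
        d4[1:n - 3] = np.linalg.norm(ca[4:] - ca[:-4], axis=1)
        for i in range(1, n - 1):
            u, v = ca[i - 1] - ca[i], ca[i + 1] - ca[i]
            ang[i] = np.arccos(np.clip(
                np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))
        from .geometry import dihedral_angle, DegenerateGeometryError
        for i in range(1, n - 2):
            try:
                tor[i] = dihedral_angle(ca[i - 1], ca[i], ca[i + 1], ca[i + 2])
            except DegenerateGeometryError:
                tor[i] = np.nan

        th = thresholds
        relaxed_helix = _in(d3, th.helix_d3) | _in(ang, th.helix_angle)
        strict_helix = (_in(d3, th.helix_d3) & _in(d4, th.helix_d4)) | (
            _in(ang, th.helix_angle) & _in(tor, th.helix_torsion))
        relaxed_strand = _in(d3, th.strand_d3)
        strict_strand = (_in(d2, th.strand_d2) & _in(d3, th.strand_d3)
                         & _in(d4, th.strand_d4)) | (
            _in(ang, th.strand_angle)
            & _in(np.abs(tor), th.strand_torsion_abs))

        helix_mask = _min_run_mask(strict_helix, th.min_helix_run)
        helix_mask = _extend(helix_mask, relaxed_helix)
        strand_mask = _min_run_mask(strict_strand, th.min_strand_run)
        strand_mask = _extend(strand_mask, relaxed_strand)
        labels[helix_mask] = "H"
        labels[strand_mask & ~helix_mask] = "E"
    return SSEAnnotation(labels=labels,
                         n_helix=len(_runs(labels == "H")),
                         n_strand=len(_runs(labels == "E")))


def _min_run_mask(candidates: np.ndarray, min_run: int) -> np.ndarray:
    mask = np.zeros_like(candidates, dtype=bool)
    cand = np.where(np.isnan(candidates.astype(float)), False, candidates)
    for start, stop in _runs(cand.astype(bool)):
        if stop - start >= min_run:
            mask[start:stop] = True
    return mask


def _extend(mask: np.ndarray, relaxed: np.ndarray) -> np.ndarray:
    out = mask.copy()
    relaxed = np.where(np.isnan(relaxed.astype(float)), False, relaxed).astype(bool)
    for start, stop in _runs(mask):
        if start > 0 and relaxed[start - 1]:
            out[start - 1] = True
        if stop < len(mask) and relaxed[stop]:
            out[stop] = True
    return out


def sse_cooccurrence(annotations: Sequence[SSEAnnotation]) -> pd.DataFrame:
    """2D count histogram over (n_helix, n_strand) plus marginals.

    Returns a DataFrame whose rows are helix counts and columns are strand
    counts; an empty input produces an empty frame.
    """
    if not annotations:
        return pd.DataFrame()
    pairs = [(a.n_helix, a.n_strand) for a in annotations]
    max_h = max(p[0] for p in pairs)
    max_e = max(p[1] for p in pairs)
    table = np.zeros((max_h + 1, max_e + 1), dtype=int)
    for h, e in pairs:
        table[h, e] += 1
    return pd.DataFrame(table,
                        index=pd.Index(range(max_h + 1), name="n_helix"),
                        columns=pd.Index(range(max_e + 1), name="n_strand"))


# ---------------------------------------------------------------------------
# Diversity clustering
# ---------------------------------------------------------------------------

@dataclass
class DiversityClustering:
    distance_matrix: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]
    linkage: np.ndarray          # scipy linkage matrix (average linkage)
    labels: np.ndarray           # flat cluster labels at the configured cut
    cut: float


def cluster_ensemble(structures: Sequence[BackboneStructure],
                     similarity_backend: Callable[[BackboneStructure,
                                                   BackboneStructure], float],
                     cut: float = 0.5) -> DiversityClustering:
    """Average-linkage clustering of backbones on d = 1 - similarity.

    ``similarity_backend(a, b)`` must return a similarity in [0, 1] (a
    TM-score wrapper in production, any injected metric in tests).  The
    result is deterministic given the distance matrix and invariant to the
    input order up to label renaming.
    """
    from scipy.cluster.hierarchy import average, fcluster
    from scipy.spatial.distance import squareform

    n = len(structures)
    if n < 2:
        raise ValueError("need at least 2 structures to cluster")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                sim = similarity_backend(structures[i], structures[j])
            except Exception as exc:
                raise RuntimeError(
                    f"distance backend failed on pair ({i}, {j})") from exc
            d[i, j] = d[j, i] = 1.0 - float(np.clip(sim, 0.0, 1.0))
    linkage = average(squareform(d, checks=False))
    labels = fcluster(linkage, t=cut, criterion="distance")
    return DiversityClustering(distance_matrix=d, linkage=linkage,
                               labels=labels, cut=cut)


def tmscore_backend(executable: str = "TMscore"
                    ) -> Callable[[BackboneStructure, BackboneStructure], float]:
    """Similarity backend wrapping an external TM-score binary.

    Raises FileNotFoundError immediately when the executable is absent.
    """
    path = shutil.which(executable)
    if path is None:
        raise FileNotFoundError(
            f"TM-score executable {executable!r} not found on PATH; "
            "install it or inject another similarity backend")

    def backend(a: BackboneStructure, b: BackboneStructure) -> float:
        with tempfile.TemporaryDirectory() as tmp:
            pa, pb = Path(tmp) / "a.pdb", Path(tmp) / "b.pdb"
            write_pdb(a, pa)
            write_pdb(b, pb)
            out = subprocess.run([path, str(pa), str(pb)], check=True,
                                 capture_output=True, text=True).stdout
        for line in out.splitlines():
            if line.startswith("TM-score"):
                return float(line.split("=")[1].split()[0])
        raise RuntimeError("could not parse TM-score output")

    return backend


# ---------------------------------------------------------------------------
# Designability (external tools only; optional)
# ---------------------------------------------------------------------------

def designability_pipeline(
    structures: Sequence[BackboneStructure],
    inverse_folder: Callable[[BackboneStructure, int], list[str]],
    structure_predictor: Callable[[str], BackboneStructure],
    similarity_backend: Callable[[BackboneStructure, BackboneStructure], float],
    n_candidates: int = 8,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Self-consistency evaluation around user-supplied external models.

    For each backbone, ``inverse_folder`` proposes ``n_candidates`` amino
    acid sequences, ``structure_predictor`` folds each, and the scTM score
    is the maximum similarity between the original backbone and any
    prediction.  Returns a per-structure table with the scTM and whether it
    clears the designability threshold (scTM >= 0.5 by convention).
    """
    records = []
    for i, s in enumerate(structures):
        sequences = inverse_folder(s, n_candidates)
        if len(sequences) != n_candidates:
            raise ValueError(f"inverse folder returned {len(sequences)} "
                             f"candidates, expected {n_candidates}")
        sctm = max(similarity_backend(s, structure_predictor(seq))
                   for seq in sequences)
        records.append({"structure": i, "residues": s.residue_count,
                        "scTM": sctm, "designable": sctm >= threshold})
    return pd.DataFrame.from_records(records, index="structure")
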