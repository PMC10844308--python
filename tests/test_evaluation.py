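"""Angle distributions, Ramachandran masses, SSE annotation, clustering."""

import numpy as np
import pandas as pd
import pytest

from torsiondiff.baselines import AnglePool, shuffle_generate
from torsiondiff.data import make_ideal_secondary_fixture, \
    make_wrapped_mixture_dataset
from torsiondiff.evaluation import (DEFAULT_REGIONS, SSEAnnotation,
                                    angle_histograms, annotate_sse,
                                    circular_histogram, cluster_ensemble,
                                    designability_pipeline,
                                    jensen_shannon_divergence,
                                    ramachandran_density, sse_cooccurrence)
from torsiondiff.geometry import (AngleFeaturization, featurize_backbone,
                                  reconstruct_backbone, superimpose_rmsd,
                                  wrap_angles)

from conftest import random_angle_matrix


def helix_rows(n, rng, sigma=0.05):
    base = wrap_angles(np.array([np.deg2rad(-47.0), np.pi, np.deg2rad(-57.0),
                                 np.deg2rad(111.0), np.deg2rad(116.2),
                                 np.deg2rad(121.7)]))
    return wrap_angles(base + rng.standard_normal((n, 6)) * sigma)


def strand_rows(n, rng, sigma=0.05):
    base = wrap_angles(np.array([np.deg2rad(113.0), np.pi, np.deg2rad(-119.0),
                                 np.deg2rad(111.0), np.deg2rad(116.2),
                                 np.deg2rad(121.7)]))
    return wrap_angles(base + rng.standard_normal((n, 6)) * sigma)


class TestAngleHistograms:
    def test_reference_vs_itself_zero_divergence(self, rng):
        rows = [wrap_angles(random_angle_matrix(rng, 30))]
        table = angle_histograms(rows, rows)
        assert (table["js_divergence"] == 0).all()
        assert set(table.index) == {"psi", "omega", "phi",
                                    "theta1", "theta2", "theta3"}

    def test_histogram_mass_conservation(self, rng):
        rows = wrap_angles(random_angle_matrix(rng, 500))
        counts = circular_histogram(rows[:, 1], bins=40)
        assert counts.sum() == 500

    def test_omega_boundary_mass_in_adjacent_circular_bins(self, rng):
        # trans omega sits at +-pi: all mass in the two bins flanking the
        # wrap-around seam, none in the middle of the domain
        omegas = wrap_angles(np.pi + rng.normal(0, 0.05, size=2000))
        counts = circular_histogram(omegas, bins=50)
        assert counts[0] + counts[-1] > 0.95 * 2000
        assert counts[10:40].sum() == 0

    def test_shuffle_output_close_to_pool(self, rng):
        data, _ = make_wrapped_mixture_dataset(n=50, rows_per_item=20, seed=0)
        pool = AnglePool.from_featurizations(data)
        gen = [shuffle_generate(pool, 200, rng) for _ in range(20)]
        table = angle_histograms(gen, data)
        assert (table["js_divergence"] < 0.01).all()


class TestRamachandran:
    def test_helix_mass_in_rh_region(self, rng):
        rama = ramachandran_density([helix_rows(500, rng)])
        assert rama.region_masses["rh_helix"] == 1.0
        assert rama.region_masses["lh_helix"] == 0.0
        assert rama.histogram.sum() == 500

    def test_negation_moves_mass_to_lh_region(self, rng):
        rows = helix_rows(500, rng)
        mirrored = rows.copy()
        mirrored[:, [0, 2]] = wrap_angles(-mirrored[:, [0, 2]])
        rama = ramachandran_density([mirrored])
        assert rama.region_masses["lh_helix"] == 1.0
        assert rama.region_masses["rh_helix"] == 0.0

    def test_mixture_region_masses_track_composition(self, rng):
        n = 2000
        k = int(0.7 * n)
        rows = np.concatenate([helix_rows(k, rng), strand_rows(n - k, rng)])
        rama = ramachandran_density([rows])
        se = 3 * np.sqrt(0.7 * 0.3 / n)
        assert abs(rama.region_masses["rh_helix"] - 0.7) < se
        assert abs(rama.region_masses["sheet"] - 0.3) < se


class TestSSEAnnotation:
    def test_ideal_helix_single_run(self, helix_structure):
        ann = annotate_sse(helix_structure)
        assert ann.n_helix == 1
        assert ann.n_strand == 0
        assert (ann.labels == "H").sum() >= 10

    def test_ideal_strand_annotated_extended(self, strand_structure):
        ann = annotate_sse(strand_structure)
        assert ann.n_helix == 0
        assert ann.n_strand >= 1

    def test_agrees_with_reference_annotator_on_fixtures(self, tmp_path,
                                                         helix_structure,
                                                         strand_structure):
        """biotite's P-SEA implementation is the independent oracle."""
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile
        from torsiondiff.geometry import place_oxygens, write_pdb

        for structure, ours_label in [(helix_structure, "H"),
                                      (strand_structure, "E")]:
            path = tmp_path / "s.pdb"
            write_pdb(place_oxygens(structure), path)
            arr = PDBFile.read(str(path)).get_structure(model=1)
            ref = struc.annotate_sse(arr)
            ours = annotate_sse(structure).labels
            mapping = {"a": "H", "b": "E", "c": "C"}
            ref_mapped = np.array([mapping[x] for x in ref])
            agree = (ours == ref_mapped).mean()
            assert agree > 0.8
            assert (ours == ours_label).sum() > 0

    def test_shuffled_structures_have_fewer_sse_residues(self, rng):
        data, _ = make_wrapped_mixture_dataset(n=20, rows_per_item=30, seed=0)
        pool = AnglePool.from_featurizations(data)
        fixture_sse = (annotate_sse(make_ideal_secondary_fixture("helix", 31))
                       .labels != "C").mean()
        shuffled_sse = np.mean([
            (annotate_sse(reconstruct_backbone(
                shuffle_generate(pool, 31, rng))).labels != "C").mean()
            for _ in range(10)])
        assert shuffled_sse < fixture_sse

    def test_short_chain_all_coil(self):
        ann = annotate_sse(make_ideal_secondary_fixture("helix", 4))
        assert (ann.labels == "C").all()
        assert ann.n_helix == 0


class TestCooccurrence:
    def test_all_helix_ensemble_single_column(self, helix_structure):
        table = sse_cooccurrence([annotate_sse(helix_structure)] * 5)
        assert table.loc[1, 0] == 5
        assert table.to_numpy().sum() == 5
        assert table.shape[1] == 1  # no strand counts beyond zero

    def test_empty_ensemble_no_crash(self):
        assert sse_cooccurrence([]).empty

    def test_mixed_ensemble_counts(self, helix_structure, strand_structure):
        k, m = 3, 2
        anns = [annotate_sse(helix_structure)] * k + \
               [annotate_sse(strand_structure)] * m
        table = sse_cooccurrence(anns)
        assert table.loc[1, 0] == k
        strand_ann = annotate_sse(strand_structure)
        assert table.loc[0, strand_ann.n_strand] == m


def rmsd_similarity(a, b):
    """Injected test metric: maps superposition RMSD into (0, 1]."""
    if a.residue_count != b.residue_count:
        return 0.0
    return 1.0 / (1.0 + superimpose_rmsd(a, b))


def _jitter(structure, rng, scale=0.05):
    """Small Cartesian perturbation: same fold, near-zero pairwise RMSD."""
    from torsiondiff.geometry import BackboneStructure
    return BackboneStructure(
        n=structure.n + rng.normal(0, scale, structure.n.shape),
        ca=structure.ca + rng.normal(0, scale, structure.ca.shape),
        c=structure.c + rng.normal(0, scale, structure.c.shape))


class TestClustering:
    def test_identical_structures_single_cluster(self, helix_structure):
        result = cluster_ensemble([helix_structure] * 4, rmsd_similarity)
        assert np.allclose(result.distance_matrix, 0.0)
        assert len(set(result.labels)) == 1

    def test_two_tight_groups_two_clusters(self, rng):
        helices = [_jitter(make_ideal_secondary_fixture("helix", 24), rng)
                   for _ in range(4)]
        strands = [_jitter(make_ideal_secondary_fixture("strand", 24), rng)
                   for _ in range(4)]
        result = cluster_ensemble(helices + strands, rmsd_similarity, cut=0.5)
        labels = result.labels
        assert len(set(labels)) == 2
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[-1]

    def test_permutation_invariant_flat_clusters(self, rng):
        helices = [_jitter(make_ideal_secondary_fixture("helix", 24), rng)
                   for _ in range(3)]
        strands = [_jitter(make_ideal_secondary_fixture("strand", 24), rng)
                   for _ in range(3)]
        structures = helices + strands
        a = cluster_ensemble(structures, rmsd_similarity, cut=0.5)
        perm = [3, 0, 4, 1, 5, 2]
        b = cluster_ensemble([structures[i] for i in perm], rmsd_similarity,
                             cut=0.5)
        for i in range(6):
            for j in range(6):
                same_a = a.labels[i] == a.labels[j]
                same_b = b.labels[perm.index(i)] == b.labels[perm.index(j)]
                assert same_a == same_b

    def test_backend_failure_names_pair(self, helix_structure):
        def broken(a, b):
            raise RuntimeError("boom")
        with pytest.raises(RuntimeError, match=r"\(0, 1\)"):
            cluster_ensemble([helix_structure] * 3, broken)

    def test_fewer_than_two_rejected(self, helix_structure):
        with pytest.raises(ValueError):
            cluster_ensemble([helix_structure], rmsd_similarity)


class TestDesignability:
    def test_identity_predictor_gives_perfect_sctm(self, helix_structure,
                                                   strand_structure):
        structures = [helix_structure, strand_structure]
        store = {}

        def inverse_folder(s, n):
            keys = [f"{id(s)}:{i}" for i in range(n)]
            for k in keys:
                store[k] = s
            return keys

        table = designability_pipeline(
            structures, inverse_folder, lambda seq: store[seq],
            rmsd_similarity)
        assert np.allclose(table["scTM"], 1.0, atol=1e-9)
        assert table["designable"].all()
        assert len(store) == 2 * 8  # 8 candidates requested by default

    def test_threshold_counts(self, helix_structure):
        table = designability_pipeline(
            [helix_structure], lambda s, n: ["x"] * n,
            lambda seq: helix_structure, lambda a, b: 0.4)
        assert not table["designable"].any()
        assert (table["scTM"] < 0.5).all()

    def test_wrong_candidate_count_rejected(self, helix_structure):
        with pytest.raises(ValueError):
            designability_pipeline([helix_structure], lambda s, n: ["x"],
                                   lambda seq: helix_structure,
                                   lambda a, b: 1.0)
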