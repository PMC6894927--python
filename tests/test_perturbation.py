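"""Force sampling, shoulder clustering, elbow selection, domain motions."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from crankshaft.anm import ForcePerturbation, build_anm, rotation_about_z
from crankshaft.perturbation import (
    ForceEnsemble,
    domain_motion,
    elbow_select_k,
    kmeans_cluster,
    representative_force,
    run_perturbation_experiment,
    sample_force_directions,
    shoulder_features,
)
from crankshaft.structures import ResidueSelection, resolve_selection
from crankshaft.synth import make_c4_structure, make_cluster_blobs, make_coupled_assembly
from crankshaft.anm import ResponseField


class TestSampleForceDirections:
    def test_unit_norm_and_count(self):
        d = sample_force_directions(1000, seed=1)
        assert d.shape == (1000, 3)
        np.testing.assert_allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-12)

    def test_deterministic_per_seed(self):
        np.testing.assert_array_equal(sample_force_directions(50, seed=9),
                                      sample_force_directions(50, seed=9))

    def test_uniform_on_sphere(self):
        """Mean vector vanishes and the z-component is uniform on [-1, 1]."""
        d = sample_force_directions(100_000, seed=2)
        assert np.linalg.norm(d.mean(axis=0)) < 0.02
        ks = stats.kstest(d[:, 2], stats.uniform(loc=-1, scale=2).cdf)
        assert ks.pvalue > 0.01

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            sample_force_directions(0, seed=0)


class TestShoulderFeatures:
    @pytest.fixture(scope="class")
    def model_and_response(self):
        s = make_c4_structure(30, seed=0)
        model = build_anm(s)
        ens = ForceEnsemble(model, residue_number=15, n_samples=3, seed=0)
        return s, model, ens.responses[0]

    def test_feature_length_is_three_per_bead(self, model_and_response):
        s, model, resp = model_and_response
        idx = resolve_selection(s, ResidueSelection.from_range(10, 14))
        assert len(idx) == 20  # 5 residues x 4 chains
        assert shoulder_features(resp, idx).shape == (60,)

    def test_zero_response_gives_zero_feature(self, model_and_response):
        s, model, resp = model_and_response
        idx = resolve_selection(s, ResidueSelection.from_range(10, 14))
        zero = ResponseField(np.zeros_like(resp.displacements),
                             resp.perturbation)
        assert np.all(shoulder_features(zero, idx) == 0)

    def test_extraction_is_linear(self, model_and_response):
        s, model, resp = model_and_response
        idx = resolve_selection(s, ResidueSelection.from_range(10, 14))
        double = ResponseField(2 * resp.displacements, resp.perturbation)
        np.testing.assert_allclose(shoulder_features(double, idx),
                                   2 * shoulder_features(resp, idx))

    def test_empty_selection_raises(self, model_and_response):
        _, _, resp = model_and_response
        with pytest.raises(ValueError, match="empty"):
            shoulder_features(resp, np.array([], dtype=int))


class TestKMeans:
    def test_k1_withinss_is_total_sum_of_squares(self):
        x, _ = make_cluster_blobs(k=3, n_per=30, seed=0)
        res = kmeans_cluster(x, k=1, seed=0)
        tss = ((x - x.mean(axis=0)) ** 2).sum()
        assert res.k == 1
        np.testing.assert_allclose(res.withinss[0], tss, rtol=1e-10)

    def test_separated_blobs_recovered_exactly(self):
        x, truth = make_cluster_blobs(k=4, separation=10.0, spread=1.0,
                                      n_per=50, seed=1)
        res = kmeans_cluster(x, k=4, seed=1)
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_duplicated_points_share_labels(self):
        x, _ = make_cluster_blobs(k=2, n_per=20, seed=2)
        doubled = np.vstack([x, x])
        res = kmeans_cluster(doubled, k=2, seed=2)
        np.testing.assert_array_equal(res.labels[:len(x)], res.labels[len(x):])

    def test_representative_matches_exhaustive_scan(self):
        x, _ = make_cluster_blobs(k=3, n_per=40, seed=3)
        res = kmeans_cluster(x, k=3, seed=3)
        for ci in range(3):
            members = np.flatnonzero(res.labels == ci)
            d2 = ((x[members] - res.centroids[ci]) ** 2).sum(axis=1)
            assert res.representative_index[ci] == members[np.argmin(d2)]

    def test_k_larger_than_samples_rejected(self):
        with pytest.raises(ValueError):
            kmeans_cluster(np.zeros((3, 2)), k=5)


class TestElbow:
    def test_four_separated_blobs_select_k4(self):
        x, _ = make_cluster_blobs(k=4, separation=10.0, spread=1.0,
                                  n_per=50, seed=4)
        chosen, table = elbow_select_k(x, range(1, 9), seed=4)
        assert chosen == 4
        assert set(table) == set(range(1, 9))

    def test_identical_points_choose_k1_with_guarded_log(self):
        x = np.ones((40, 5))
        chosen, table = elbow_select_k(x, range(1, 5), seed=0)
        assert chosen == 1
        assert all(np.isfinite(v) for v in table.values())

    def test_single_blob_has_no_elbow(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(300, 6))
        chosen, _ = elbow_select_k(x, range(1, 9), seed=5)
        assert chosen == 1


class TestRepresentativeForce:
    def test_singleton_cluster_returns_its_member(self):
        s = make_c4_structure(20, seed=0)
        model = build_anm(s)
        ens = ForceEnsemble(model, residue_number=10, n_samples=5, seed=1)
        # features separating sample 0 from the rest
        feats = np.zeros((5, 2))
        feats[0] = [100.0, 100.0]
        res = kmeans_cluster(feats, k=2, seed=0)
        singleton = int(np.flatnonzero(np.bincount(res.labels) == 1)[0])
        pert = representative_force(res, ens, singleton)
        np.testing.assert_allclose(pert.targets[0][1], ens.directions[0])

    def test_cluster_index_out_of_range(self):
        s = make_c4_structure(20, seed=0)
        model = build_anm(s)
        ens = ForceEnsemble(model, residue_number=10, n_samples=4, seed=1)
        res = kmeans_cluster(np.arange(8, dtype=float).reshape(4, 2), k=2)
        with pytest.raises(IndexError):
            representative_force(res, ens, 5)


class TestDomainMotion:
    def test_rigid_rotation_about_z_recovered(self):
        s = make_c4_structure(30, seed=1)
        idx = resolve_selection(s, ResidueSelection.from_range(5, 25))
        com = s.coords.mean(axis=0)
        rot = rotation_about_z(5.0)
        disp = np.zeros_like(s.coords)
        disp[idx] = (s.coords[idx] - com) @ rot.T + com - s.coords[idx]
        resp = ResponseField(disp, ForcePerturbation(targets=()))
        m = domain_motion(resp, s, idx)
        assert m.in_plane_rotation == pytest.approx(5.0, abs=0.1)

    @pytest.mark.parametrize("direction,expected_angle", [
        ((0.0, 0.0, 1.0), 0.0),
        ((1.0, 0.0, 0.0), 90.0),
        ((0.0, 0.0, -1.0), 180.0),
    ])
    def test_uniform_displacement_angle_to_z(self, direction, expected_angle):
        s = make_c4_structure(20, seed=1)
        idx = np.arange(s.n_beads)
        disp = np.tile(direction, (s.n_beads, 1)).astype(float)
        resp = ResponseField(disp, ForcePerturbation(targets=()))
        m = domain_motion(resp, s, idx)
        assert m.angle_to_z == pytest.approx(expected_angle, abs=1e-9)

    def test_zero_displacement_flagged_undefined(self):
        s = make_c4_structure(20, seed=1)
        resp = ResponseField(np.zeros_like(s.coords), ForcePerturbation(targets=()))
        m = domain_motion(resp, s, np.arange(10))
        assert m.undefined
        assert np.isnan(m.angle_to_z)


class TestExperiment:
    def test_c4_symmetric_domains_move_equivalently(self):
        """Per-chain copies of a domain rotate into each other under C4."""
        asm = make_coupled_assembly(seed=2)
        model = build_anm(asm.structure)
        domains_per_chain = {
            c: ResidueSelection.from_range(11, 20, chains=[c])
            for c in "ABCD"
        }
        report = run_perturbation_experiment(
            model, asm.sites["linker"], asm.domains["linker"],
            domains_per_chain, n_samples=60, seed=3)
        rot = rotation_about_z(90.0)
        for motions in report.motions:
            means = [motions[c].mean_displacement for c in "ABCD"]
            for k in range(4):
                np.testing.assert_allclose(
                    means[(k + 1) % 4], rot @ means[k],
                    atol=1e-6 * max(np.abs(means[k]).max(), 1e-12))

    def test_protocol_reports_one_representative_per_cluster(self):
        asm = make_coupled_assembly(seed=2)
        model = build_anm(asm.structure)
        report = run_perturbation_experiment(
            model, asm.sites["linker"], asm.domains["linker"], asm.domains,
            n_samples=200, k=4, seed=3)
        assert report.chosen_k == 4
        assert len(report.representatives) == 4
        assert len(report.motions) == 4

    def test_pipeline_reproducible_from_seed(self):
        asm = make_coupled_assembly(seed=2)
        model = build_anm(asm.structure)
        kwargs = dict(n_samples=80, k=2, seed=11)
        r1 = run_perturbation_experiment(
            model, asm.sites["hcnd"], asm.domains["linker"], asm.domains,
            **kwargs)
        r2 = run_perturbation_experiment(
            model, asm.sites["hcnd"], asm.domains["linker"], asm.domains,
            **kwargs)
        np.testing.assert_array_equal(r1.cluster.labels, r2.cluster.labels)
        np.testing.assert_array_equal(r1.cluster.representative_index,
                                      r2.cluster.representative_index)
        for m1, m2 in zip(r1.motions, r2.motions):
            for d in m1:
                np.testing.assert_array_equal(m1[d].mean_displacement,
                                              m2[d].mean_displacement)

    def test_identical_force_directions_collapse_to_one_cluster(self):
        s = make_c4_structure(25, seed=4)
        model = build_anm(s)
        ens = ForceEnsemble(model, residue_number=12, n_samples=30, seed=0)
        ens.directions = np.tile([0.0, 0.0, 1.0], (30, 1))
        ens._responses = None
        idx = resolve_selection(s, ResidueSelection.from_range(5, 10))
        feats = np.stack([shoulder_features(r, idx) for r in ens.responses])
        chosen, _ = elbow_select_k(feats, range(1, 5), seed=0)
        assert chosen == 1
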