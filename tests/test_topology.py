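"""Neighbor search, transform clustering, symmetry, classification."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from sklearn.metrics import adjusted_rand_score

from ribotopo import load_condition_config, simulate_field
from ribotopo.field import ParticleField
from ribotopo.geometry import (
    compose_transform,
    euler_to_quat,
    geodesic_angle_deg,
    invert_transforms,
    rotation_to_quat,
)
from ribotopo.templates import FIVE_CLASSES
from ribotopo.topology import (
    PairSet,
    analyze_topology,
    classify_particles,
    cluster_transforms,
    detect_c2,
    detect_collided,
    extendability,
    find_neighbors,
    neighbor_transforms,
)


from tests_support import field_from_positions as _field_from_positions


class TestFindNeighbors:
    def test_far_pair_empty(self):
        field = _field_from_positions(np.array([[0.0, 0, 0], [500.0, 0, 0]]))
        assert len(find_neighbors(field, cutoff=400)) == 0

    def test_dimer_both_orders(self):
        field = _field_from_positions(np.array([[0.0, 0, 0], [260.0, 0, 0]]))
        pairs = find_neighbors(field, cutoff=400)
        assert {tuple(p) for p in pairs} == {(0, 1), (1, 0)}

    def test_matches_brute_force(self, rng):
        pos = rng.uniform(0, 3000, size=(200, 3))
        field = _field_from_positions(pos)
        pairs = {tuple(p) for p in find_neighbors(field, cutoff=400)}
        brute = set()
        for i in range(200):
            for j in range(200):
                if i != j and np.linalg.norm(pos[i] - pos[j]) <= 400:
                    brute.add((i, j))
        assert pairs == brute

    def test_no_cross_tomogram_pairs(self):
        pos = np.array([[0.0, 0, 0], [260.0, 0, 0]])
        field = _field_from_positions(pos, tomo=np.array([0, 1]))
        assert len(find_neighbors(field, cutoff=400)) == 0

    def test_invalid_cutoff(self):
        field = _field_from_positions(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            find_neighbors(field, cutoff=0)


def _make_pairs(t, q):
    m = len(t)
    return PairSet(np.arange(m), np.arange(m) + 10_000, np.asarray(t), np.asarray(q))


class TestClustering:
    def test_empty_input(self):
        labels, clusters = cluster_transforms(_make_pairs(np.empty((0, 3)), np.empty((0, 4))))
        assert len(labels) == 0
        assert clusters == []

    def test_planted_partition_recovered(self, rng):
        """Three well-separated transform families cluster perfectly."""
        families = [
            (np.array([250.0, 0, 0]), Rotation.identity()),
            (np.array([0.0, 250.0, 0]), Rotation.from_euler("x", 120, degrees=True)),
            (np.array([100.0, 100.0, 100.0]), Rotation.from_euler("z", 60, degrees=True)),
        ]
        t, q, truth = [], [], []
        for fam_idx, (t0, r0) in enumerate(families):
            for _ in range(50):
                noise_r = Rotation.from_rotvec(np.deg2rad(rng.normal(0, 1.0, 3)))
                t.append(t0 + rng.normal(0, 5.0, 3))
                q.append(rotation_to_quat(r0 * noise_r))
                truth.append(fam_idx)
        labels, clusters = cluster_transforms(_make_pairs(np.array(t), np.array(q)))
        assert len(clusters) == 3
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_medoid_is_member(self, rng):
        t = np.tile([250.0, 0, 0], (30, 1)) + rng.normal(0, 5, (30, 3))
        q = np.tile([1.0, 0, 0, 0], (30, 1))
        pairs = _make_pairs(t, q)
        _, clusters = cluster_transforms(pairs)
        med = clusters[0].medoid_t
        assert any(np.allclose(med, row) for row in t)


class TestC2Detection:
    def test_exact_c2_transform(self):
        t = np.array([200.0, 0, 0])
        q = euler_to_quat([180.0, 0.0, 0.0])  # 180 deg about z
        assert detect_c2(t, q)
        # equivalent algebra: composing with itself returns to the origin
        t2, q2 = compose_transform(t, q, t, q)
        assert np.linalg.norm(t2) < 1e-9
        assert geodesic_angle_deg(q2, np.array([1.0, 0, 0, 0])) < 1e-9

    def test_pure_translation_not_c2(self):
        t = np.array([300.0, 0, 0])
        q = np.array([1.0, 0, 0, 0])
        assert not detect_c2(t, q)

    def test_template_symmetry_attributes(self, templates):
        assert detect_c2(templates["disome2"].t0, templates["disome2"].q0)
        assert not detect_c2(templates["disome3"].t0, templates["disome3"].q0)
        assert not detect_c2(templates["disome1"].t0, templates["disome1"].q0)


class TestExtendability:
    def test_helix_template_is_helical(self, templates):
        tpl = templates["cyto_helical"]
        assert extendability(tpl.t0, tpl.q0) == "helical"

    def test_c2_template_is_terminal(self, templates):
        tpl = templates["disome2"]
        assert extendability(tpl.t0, tpl.q0) == "terminal"
        # T^2 returns onto the origin particle
        t2, _ = compose_transform(tpl.t0, tpl.q0, tpl.t0, tpl.q0)
        assert np.linalg.norm(t2) < 200.0

    def test_disome3_sterically_capped(self, templates):
        tpl = templates["disome3"]
        assert extendability(tpl.t0, tpl.q0) == "terminal"

    def test_planar_flag(self, templates):
        tpl = templates["membrane_planar"]
        verdict = extendability(tpl.t0, tpl.q0, planar_generator=tpl.generators[0])
        assert verdict == "planar"

    def test_k_steps_validation(self, templates):
        tpl = templates["cyto_helical"]
        with pytest.raises(ValueError):
            extendability(tpl.t0, tpl.q0, k_steps=1)


class TestClassification:
    def test_pure_monomer_field_unclassified(self, templates, monomer_config):
        field = simulate_field(monomer_config(n=60, seed=9, box=(20000.0, 20000.0, 2500.0)))
        res = analyze_topology(field, templates)
        assert res.classification.classified_fraction == 0.0
        ab = res.classification.abundance
        classified = ab[ab["topology_class"] != "unclassified"]
        assert (classified["fraction"] == 0.0).all()

    def test_zero_noise_field_fully_recovered(self, templates):
        cfg = load_condition_config(
            "treated", n_particles=800, seed=31, sigma_t=0.0, sigma_theta=0.0
        )
        field = simulate_field(cfg)
        res = analyze_topology(field, templates)
        truth = field.df["truth_motif"].to_numpy()
        pred = res.classification.particle_class.to_numpy()
        planted = np.isin(truth, FIVE_CLASSES)
        assert (pred[planted] == truth[planted]).all()

    def test_noisy_recovery_at_default_noise(self, templates, small_treated_field):
        res = analyze_topology(small_treated_field, templates)
        truth = small_treated_field.df["truth_motif"].to_numpy()
        pred = res.classification.particle_class.to_numpy()
        planted = np.isin(truth, FIVE_CLASSES)
        assert (pred[planted] == truth[planted]).mean() >= 0.95

    def test_five_template_classes_found(self, templates, small_treated_field):
        res = analyze_topology(small_treated_field, templates)
        found = {c.assigned_class for c in res.classification.clusters}
        assert set(FIVE_CLASSES) <= found

    def test_pair_symmetry_no_double_count(self, templates, small_treated_field):
        """Both orderings of a physical pair land in the same cluster, and
        abundances count particles (not ordered pairs)."""
        res = analyze_topology(small_treated_field, templates)
        pairs = res.pairs
        labels = res.classification.labels
        key_to_label = {}
        for idx in range(len(pairs.src)):
            key = (min(pairs.src[idx], pairs.dst[idx]), max(pairs.src[idx], pairs.dst[idx]))
            key_to_label.setdefault(key, set()).add(labels[idx])
        clustered = [v for v in key_to_label.values() if any(l >= 0 for l in v)]
        same = sum(1 for v in clustered if len(v) == 1)
        assert same / len(clustered) >= 0.99
        ab = res.classification.abundance
        n_classified = (res.classification.particle_class != "unclassified").sum()
        assert ab[ab["topology_class"] != "unclassified"]["n"].sum() == n_classified

    def test_rigid_motion_equivariance(self, templates, small_treated_field, rng):
        """One global rotation+translation changes nothing downstream."""
        moved = small_treated_field.transformed(
            Rotation.from_quat(rng.normal(size=4) / 1.0), rng.uniform(-5000, 5000, 3)
        )
        res_a = analyze_topology(small_treated_field, templates)
        res_b = analyze_topology(moved, templates)
        assert np.allclose(np.sort(res_a.pairs.t, axis=0), np.sort(res_b.pairs.t, axis=0), atol=1e-6)
        assert (res_a.classification.particle_class == res_b.classification.particle_class).all()
        assert res_a.collided_pairs == res_b.collided_pairs
        assert res_a.collided_fraction == res_b.collided_fraction


class TestCollidedDetection:
    def test_absent_motif_yields_empty(self, templates, monomer_config):
        field = simulate_field(monomer_config(n=80, seed=13, box=(20000.0, 20000.0, 2500.0)))
        res = analyze_topology(field, templates)
        assert res.collided_pairs == set()
        assert res.collided_fraction == 0.0

    def test_threshold_behavior(self, templates):
        """Exact template pairs are detected; pairs displaced by twice the
        strict radius are not."""
        tpl = templates["collided"]
        strict_eps = 2.25
        exact_t = np.tile(tpl.t0, (10, 1))
        exact_q = np.tile(tpl.q0, (10, 1))
        offset = np.array([2 * strict_eps * 25.0, 0.0, 0.0])
        far_t = exact_t + offset
        pairs_exact = _make_pairs(exact_t, exact_q)
        pairs_far = _make_pairs(far_t, exact_q)
        hit, frac = detect_collided(pairs_exact, tpl, strict_eps=strict_eps, n_particles=20)
        assert len(hit) == 10
        assert frac == 1.0
        miss, _ = detect_collided(pairs_far, tpl, strict_eps=strict_eps, n_particles=20)
        assert miss == set()

    def test_strict_eps_must_be_tight(self, templates):
        pairs = _make_pairs(np.zeros((1, 3)), np.array([[1.0, 0, 0, 0]]))
        with pytest.raises(ValueError):
            detect_collided(pairs, templates["collided"], strict_eps=3.5, eps=3.0)
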