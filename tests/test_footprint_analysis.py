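"""Tests for spherical-detector footprints, L2 comparison and classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.transform import Rotation

from spisim.cei_dynamics import ChargedSystem, ExplosionResult, IonizationEventLog
from spisim.footprint_analysis import (
    EmbeddingResult,
    Footprint,
    SphericalDetectorSpec,
    classify,
    direction_footprint,
    embed,
    l2_distance,
    project,
)

SPEC = SphericalDetectorSpec()


def synthetic_result(velocities, charges=None):
    n = len(velocities)
    charges = np.ones(n, int) if charges is None else np.asarray(charges)
    system = ChargedSystem(
        np.array(["C"] * n),
        np.zeros((n, 3)) + np.arange(n)[:, None] * 0.1,
        np.asarray(velocities, float),
        charges,
        np.full(n, 12.011),
    )
    events = IonizationEventLog(np.empty(0), np.empty(0, int), np.empty(0, int))
    return ExplosionResult(system, events, 300.0)


def isotropic_velocities(n, seed):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestProject:
    def test_pole_convention(self):
        fp = project(synthetic_result([[0.0, 0.0, 1.0]]), SPEC)
        assert fp.counts[SPEC.n_elevation - 1].sum() == 1
        assert fp.total_ions == 1

    def test_count_conservation(self):
        v = isotropic_velocities(500, 1)
        fp = project(synthetic_result(v), SPEC)
        assert fp.total_ions == 500

    def test_neutrals_invisible(self):
        v = isotropic_velocities(10, 2)
        charges = np.array([1, 1, 0, 0, 0, 1, 2, 0, 3, 0])
        fp = project(synthetic_result(v, charges), SPEC)
        assert fp.total_ions == int(np.sum(charges >= 1))

    def test_zero_velocity_ion_excluded_and_logged(self):
        v = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        fp = project(synthetic_result(v), SPEC)
        assert fp.total_ions == 1
        assert fp.n_excluded == 1

    def test_isotropic_input_follows_solid_angle_profile(self):
        # row totals of an isotropic source follow the equal-angle bins'
        # solid angle ~ cos(elevation), within 3 sigma Poisson per row
        n = 100_000
        fp = direction_footprint(isotropic_velocities(n, 3), SPEC)
        edges = np.radians(np.linspace(-90, 90, SPEC.n_elevation + 1))
        expected = n * (np.sin(edges[1:]) - np.sin(edges[:-1])) / 2.0
        rows = fp.counts.sum(axis=1)
        z = (rows - expected) / np.sqrt(expected)
        assert np.all(np.abs(z) < 3.0)


class TestL2Distance:
    def test_identity_and_symmetry(self):
        fp = direction_footprint(isotropic_velocities(200, 4), SPEC)
        fq = direction_footprint(isotropic_velocities(200, 5), SPEC)
        assert l2_distance(fp, fp) == 0.0
        assert l2_distance(fp, fq) == l2_distance(fq, fp)

    def test_mismatched_specs_rejected(self):
        a = direction_footprint(isotropic_velocities(10, 1), SPEC)
        b = direction_footprint(
            isotropic_velocities(10, 1), SphericalDetectorSpec(20, 40)
        )
        with pytest.raises(ValueError):
            l2_distance(a, b)

    def test_small_rotations_closer_than_large(self):
        # footprints of one explosion rotated by 5 deg stay closer than
        # rotated by 90 deg, averaged over random axes
        v = isotropic_velocities(2000, 6)
        base = direction_footprint(v, SPEC)
        rng = np.random.default_rng(7)
        d_small, d_large = [], []
        for _ in range(10):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            for angle, out in ((5.0, d_small), (90.0, d_large)):
                rot = Rotation.from_rotvec(np.radians(angle) * axis)
                d = l2_distance(base, direction_footprint(rot.apply(v), SPEC))
                out.append(d)
        assert np.mean(d_small) < np.mean(d_large)

    def test_rotation_monotone_small_angles(self):
        # mean L2 to a rotated copy is nondecreasing in the angle; beyond the
        # ~4.5 deg bin width the distance saturates, so allow a small
        # statistical slack there
        v = isotropic_velocities(5000, 8)
        base = direction_footprint(v, SPEC)
        rng = np.random.default_rng(9)
        axes = rng.normal(size=(16, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        means = []
        for angle in (0.0, 2.0, 5.0, 10.0, 20.0, 30.0):
            dists = [
                l2_distance(
                    base,
                    direction_footprint(
                        Rotation.from_rotvec(np.radians(angle) * axis).apply(v), SPEC
                    ),
                )
                for axis in axes
            ]
            means.append(np.mean(dists))
        slack = 0.02 * max(means)
        assert all(b >= a - slack for a, b in zip(means, means[1:]))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        arrays(np.int64, (5, 8), elements=st.integers(0, 9)),
        arrays(np.int64, (5, 8), elements=st.integers(0, 9)),
        arrays(np.int64, (5, 8), elements=st.integers(0, 9)),
    )
    def test_metric_axioms(self, a, b, c):
        spec = SphericalDetectorSpec(5, 8)
        fa, fb, fc = (Footprint(x, spec) for x in (a, b, c))
        dab = l2_distance(fa, fb)
        assert dab >= 0
        assert dab == l2_distance(fb, fa)
        assert l2_distance(fa, fc) <= dab + l2_distance(fb, fc) + 1e-9


class TestEmbedClassify:
    def make_families(self, per_family=10, n_ions=400):
        # two synthetic footprint families with distinct mean emission maps
        rng = np.random.default_rng(10)
        footprints, labels = [], []
        for fam, mu in enumerate(((0.0, 0.0, 1.0), (1.0, 0.0, 0.0))):
            for _ in range(per_family):
                v = rng.normal(size=(n_ions, 3)) + 1.5 * np.array(mu)
                v /= np.linalg.norm(v, axis=1, keepdims=True)
                footprints.append(direction_footprint(v, SPEC))
                labels.append(fam)
        return footprints, labels

    def test_identical_footprints_collapse_under_pca(self):
        fp = direction_footprint(isotropic_velocities(100, 11), SPEC)
        emb = embed([fp] * 5, method="pca", seed=0)
        assert np.allclose(emb.coordinates, emb.coordinates[0])

    def test_separated_families_separate_in_embedding(self):
        footprints, labels = self.make_families()
        for method in ("pca", "tsne"):
            emb = embed(footprints, method=method, seed=1)
            coords = emb.coordinates
            a = coords[np.array(labels) == 0]
            b = coords[np.array(labels) == 1]
            centroid_gap = np.linalg.norm(a.mean(0) - b.mean(0))
            spread = 0.5 * (
                np.linalg.norm(a - a.mean(0), axis=1).mean()
                + np.linalg.norm(b - b.mean(0), axis=1).mean()
            )
            assert centroid_gap > spread

    def test_tsne_seeded_determinism(self):
        footprints, _ = self.make_families(per_family=6)
        a = embed(footprints, method="tsne", seed=7)
        b = embed(footprints, method="tsne", seed=7)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_too_few_footprints_rejected(self):
        fp = direction_footprint(isotropic_velocities(10, 12), SPEC)
        with pytest.raises(ValueError):
            embed([fp, fp], method="tsne")

    def test_explicit_perplexity_validated(self):
        footprints, _ = self.make_families(per_family=3)
        with pytest.raises(ValueError, match="perplexity"):
            embed(footprints, method="tsne", perplexity=10.0)

    def test_classify_two_families(self):
        footprints, labels = self.make_families()
        emb = embed(footprints, method="pca", seed=2)
        assert classify(emb, labels, k=2, seed=2) >= 0.9

    def test_single_label_trivial(self):
        emb = EmbeddingResult(np.zeros((4, 2)), "pca")
        assert classify(emb, [0, 0, 0, 0], k=1) == 1.0

    def test_random_labels_near_chance(self):
        # permutation null: k-means on random points vs arbitrary labels
        rng = np.random.default_rng(13)
        accs = []
        for rep in range(20):
            emb = EmbeddingResult(rng.normal(size=(40, 2)), "pca")
            labels = rng.integers(0, 2, size=40)
            if len(set(labels.tolist())) < 2:
                continue
            accs.append(classify(emb, labels.tolist(), k=2, seed=rep))
        assert 0.45 < np.mean(accs) < 0.70

    def test_k_mismatch_rejected(self):
        emb = EmbeddingResult(np.random.default_rng(0).normal(size=(6, 2)), "pca")
        with pytest.raises(ValueError):
            classify(emb, [0, 0, 0, 1, 1, 1], k=3)
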