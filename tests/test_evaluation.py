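"""Scoring and interpretability: pair-counting oracles, LOO, axis artifacts."""

import itertools

import numpy as np
import pytest

from leafcat import evaluation as ev
from leafcat import morphospace as ms


def pairwise_f_oracle(true_labels, cluster_labels):
    """Exhaustive enumeration of all unordered sample pairs."""
    n = len(true_labels)
    tp = fp = fn = 0
    for i, j in itertools.combinations(range(n), 2):
        same_class = true_labels[i] == true_labels[j]
        same_cluster = cluster_labels[i] == cluster_labels[j]
        tp += same_class and same_cluster
        fp += (not same_class) and same_cluster
        fn += same_class and (not same_cluster)
    if tp + fp == 0 and tp + fn == 0:
        return 1.0
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return 2 * p * r / (p + r) if p + r else 0.0


class TestConfusion:
    def test_perfect_clustering_is_diagonal(self):
        conf = ev.confusion(["a", "a", "b", "b", "c", "c"],
                            [0, 0, 1, 1, 2, 2])
        np.testing.assert_array_equal(conf.counts, np.diag([2, 2, 2]))

    def test_single_cluster_column(self):
        conf = ev.confusion(["a", "a", "b", "c"], [0, 0, 0, 0])
        assert conf.counts.shape == (3, 1)
        assert conf.counts.ravel().tolist() == [2, 1, 1]

    def test_total_preserved(self):
        rng = np.random.default_rng(0)
        t = rng.integers(0, 4, 37)
        g = rng.integers(0, 6, 37)
        assert ev.confusion(t, g).total == 37

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            ev.confusion([1, 2], [1])


class TestFMeasure:
    def test_diagonal_is_one_both_variants(self):
        conf = ev.confusion(["a", "a", "b", "b"], [0, 0, 1, 1])
        assert ev.f_measure(conf, "pairwise") == 1.0
        assert ev.f_measure(conf, "weighted_best_match") == 1.0

    def test_two_classes_merged(self):
        # 2 same-class pairs out of 6 same-cluster pairs; recall 1 -> F 0.5
        conf = ev.confusion(["a", "a", "b", "b"], [0, 0, 0, 0])
        assert ev.f_measure(conf, "pairwise") == pytest.approx(0.5)

    def test_one_class_split(self):
        # precision 1, recall 2/6 -> F = 0.5
        conf = ev.confusion(["a", "a", "a", "a"], [0, 0, 1, 1])
        assert ev.f_measure(conf, "pairwise") == pytest.approx(0.5)

    def test_matches_exhaustive_pair_oracle(self):
        rng = np.random.default_rng(1)
        for trial in range(5):
            n = 50
            t = rng.integers(0, 5, n)
            g = rng.integers(0, 7, n)
            conf = ev.confusion(t, g)
            assert ev.f_measure(conf, "pairwise") == pytest.approx(
                pairwise_f_oracle(t, g), abs=0)

    def test_invariant_to_relabeling_and_order(self):
        rng = np.random.default_rng(2)
        t = rng.integers(0, 3, 30)
        g = rng.integers(0, 4, 30)
        f0 = ev.f_measure(ev.confusion(t, g))
        # relabel clusters
        f1 = ev.f_measure(ev.confusion(t, (g + 2) % 4))
        # permute sample order
        perm = rng.permutation(30)
        f2 = ev.f_measure(ev.confusion(t[perm], g[perm]))
        assert f0 == pytest.approx(f1) == pytest.approx(f2)

    def test_one_iff_partitions_equal(self):
        t = np.array([0, 0, 1, 1, 2])
        assert ev.f_measure(ev.confusion(t, t * 7 + 1)) == 1.0
        assert ev.f_measure(ev.confusion(t, [0, 0, 1, 2, 2])) < 1.0

    def test_weighted_best_match_hand_value(self):
        # class a (2 samples) pure in cluster 0; class b (2) split
        conf = ev.confusion(["a", "a", "b", "b"], [0, 0, 0, 1])
        # F1(a,0)=2*2/(2+3)=0.8 ; F1(b,1)=2*1/(2+1)=2/3 ; weights 1/2 each
        assert ev.f_measure(conf, "weighted_best_match") == pytest.approx(
            0.5 * 0.8 + 0.5 * 2 / 3)


def tiny_matrix(points):
    """Wrap d-dim real points as a fake 1-harmonic matrix for LOO tests."""
    phi = np.asarray(points, float).T.astype(complex)
    band = np.arange(1, phi.shape[0] + 1)
    return ms.HarmonicMatrix(phi, list(range(phi.shape[1])), band, 64, 0.1)


class TestLooVariability:
    def test_separated_fixture_perfect_and_stable(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 0.05, (6, 2)),
                         rng.normal(10, 0.05, (6, 2)),
                         rng.normal([0, 10], 0.05, (6, 2))])
        labels = [0] * 6 + [1] * 6 + [2] * 6
        phi = tiny_matrix(pts)
        mean, sd, scores = ev.loo_variability(phi, labels, d=2, k=3)
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.0)
        assert len(scores) == 18

    def test_n_subruns_equals_n(self):
        pts = np.array([[0.0, 0], [0.1, 0], [10.0, 0]])
        phi = tiny_matrix(pts)
        mean, sd, scores = ev.loo_variability(phi, [0, 0, 1], d=1, k=1)
        assert len(scores) == 3

    def test_reproducible_bit_exact(self, default_phi, default_dataset):
        sub = ms.HarmonicMatrix(default_phi.phi[:, :36],
                                default_phi.sample_ids[:36],
                                default_phi.band, default_phi.n_points,
                                default_phi.step_length)
        labels = default_dataset.labels[:36]
        a = ev.loo_variability(sub, labels)
        b = ev.loo_variability(sub, labels)
        assert a == b

    def test_too_few_samples_rejected(self):
        phi = tiny_matrix(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="at least 3"):
            ev.loo_variability(phi, [0, 1])


class TestAxisExemplars:
    def test_three_samples_in_order(self):
        scores = np.array([[-2.0, 0], [0.0, 0], [2.0, 0]])
        out = ev.axis_exemplars(scores, ["lo", "mid", "hi"], axis=0,
                                m_points=3)
        assert out == ["lo", "mid", "hi"]

    def test_two_points_give_extremes(self):
        scores = np.array([[-1.0, 0], [0.3, 0], [0.9, 0]])
        out = ev.axis_exemplars(scores, list("abc"), axis=0, m_points=2)
        assert out == ["a", "c"]

    def test_nearest_in_full_space(self):
        # sample b is nearest to the axis point (0, 0) despite its pc1 offset
        scores = np.array([[0.0, 5.0], [0.4, 0.0], [2.0, 0.0]])
        out = ev.axis_exemplars(scores, list("abc"), axis=0, m_points=2)
        assert out[0] == "b"

    def test_m_below_two_rejected(self):
        with pytest.raises(ValueError, match="m_points"):
            ev.axis_exemplars(np.zeros((3, 2)), list("abc"), 0, 1)


class TestAxisShape:
    def test_coordinate_zero_is_mean_shape(self, default_phi):
        from leafcat import fourier_descriptor as fd

        space = ms.pca_embed(default_phi, d=3)
        space.apply_whitening()
        c0 = ev.axis_shape(space, axis=0, coordinate=0.0)
        # direct reconstruction of the de-whitened center harmonic vector
        harm = space.inverse_transform(np.zeros(3))
        desc = fd.HarmonicDescriptor(harm, space.band, space.n_points,
                                     space.step_length)
        ref = fd.reconstruct(desc)
        np.testing.assert_allclose(c0.vertices, ref.vertices, atol=1e-9)

    def test_deterministic(self, default_phi):
        space = ms.pca_embed(default_phi, d=3)
        a = ev.axis_shape(space, 1, 1.5)
        b = ev.axis_shape(space, 1, 1.5)
        np.testing.assert_array_equal(a.vertices, b.vertices)

    def test_band_energy_monotone_away_from_center(self, default_phi):
        """Moving out along PC1 monotonically changes the margin-band
        energy of the reconstructed harmonic vector (the energy is
        quadratic about the mean shape, so the check runs on a half-axis)."""
        space = ms.pca_embed(default_phi, d=3)
        space.apply_whitening()
        sel = np.abs(space.band) >= 4
        energies = []
        for coord in (0.0, 1.0, 2.0):
            harm = space.inverse_transform(np.array([coord, 0.0, 0.0]))
            energies.append(float(np.sum(np.abs(harm[sel]) ** 2)))
        assert energies[0] < energies[1] < energies[2]

    def test_complex_mode_not_invertible(self, default_phi):
        space = ms.pca_embed(default_phi, d=3, mode="complex")
        with pytest.raises(ValueError, match="real_stack"):
            ev.axis_shape(space, 0, 1.0)
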