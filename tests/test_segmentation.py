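"""Segmentation transforms, clustering and the semantic loss."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from semfuse.autograd import Tensor
from semfuse.segmentation import (ClusterState, PhotometricJitter,
                                  SegmentationNet, cluster_views, clust_loss,
                                  geometric_transform, inverse_geometric,
                                  kmeans, photometric_transform, seg_forward,
                                  semantic_loss)


# ------------------------------------------------------------- photometric
def test_zero_jitter_is_identity(rng):
    img = rng.random((16, 16))
    out = photometric_transform(img, seed=0,
                                jitter=PhotometricJitter(0.0, 0.0, 0.0))
    np.testing.assert_allclose(out, img, atol=1e-12)


def test_photometric_seeded_determinism(rng):
    img = rng.random((16, 16))
    o1 = photometric_transform(img, seed=5)
    o2 = photometric_transform(img, seed=5)
    assert np.array_equal(o1, o2)
    assert not np.array_equal(o1, photometric_transform(img, seed=6))


def test_photometric_preserves_rank_order(rng):
    img = rng.random((12, 12))
    out = photometric_transform(img, seed=3,
                                jitter=PhotometricJitter(0.0, 0.05, 0.3))
    rho = spearmanr(img.ravel(), out.ravel()).statistic
    assert rho == pytest.approx(1.0)


def test_photometric_clips_to_unit_interval(rng):
    img = rng.random((8, 8))
    out = photometric_transform(img, seed=1,
                                jitter=PhotometricJitter(0.9, 0.5, 0.5))
    assert out.min() >= 0.0 and out.max() <= 1.0


def test_invalid_jitter_bounds_rejected():
    with pytest.raises(ValueError):
        PhotometricJitter(brightness=-0.1)
    with pytest.raises(ValueError):
        PhotometricJitter(contrast=1.5)


# --------------------------------------------------------------- geometric
def test_flip_twice_is_identity(rng):
    f = rng.random((3, 8, 8))
    p = {"hflip": True}
    np.testing.assert_array_equal(
        geometric_transform(geometric_transform(f, p), p), f)


def test_inverse_undoes_forward_for_flip_and_rescale(rng):
    f = rng.random((2, 8, 8))
    for params in ({"hflip": True}, {"scale": 2}, {"hflip": True, "scale": 3}):
        round_trip = inverse_geometric(geometric_transform(f, params), params)
        assert np.abs(round_trip - f).max() < 1e-6


def test_flip_preserves_label_counts(rng):
    labels = rng.integers(0, 4, size=(8, 8))
    flipped = geometric_transform(labels, {"hflip": True})
    assert flipped.dtype == labels.dtype
    assert np.array_equal(np.bincount(flipped.ravel()),
                          np.bincount(labels.ravel()))


def test_invalid_scale_rejected(rng):
    with pytest.raises(ValueError):
        geometric_transform(rng.random((4, 4)), {"scale": 0})


# ------------------------------------------------------------- seg network
def test_seg_forward_shape_unit_norm_deterministic(rng):
    net = SegmentationNet(feature_dim=8, hidden=4, seed=2)
    img = rng.random((16, 16))
    z1 = seg_forward(img, net)
    assert z1.shape == (1, 8, 16, 16)
    norms = np.sqrt((z1.numpy() ** 2).sum(axis=1))
    np.testing.assert_allclose(norms, 1.0, atol=1e-5)
    assert np.array_equal(z1.numpy(), seg_forward(img, net).numpy())


def test_seg_forward_rejects_indivisible_size(rng):
    net = SegmentationNet(feature_dim=4, hidden=2, seed=0)
    with pytest.raises(ValueError):
        seg_forward(rng.random((10, 10)), net)


# ---------------------------------------------------------------- k-means
def test_kmeans_recovers_two_antipodal_blobs():
    rng = np.random.default_rng(0)
    base = np.array([1.0, 0.0, 0.0])
    pts = np.concatenate([
        base + 0.01 * rng.standard_normal((4, 3)),
        -base + 0.01 * rng.standard_normal((4, 3))])
    labels, centers, obj = kmeans(pts, 2, np.random.default_rng(1))
    assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
    assert labels[0] != labels[4]


def test_kmeans_objective_non_increasing(rng):
    pts = rng.random((100, 5))
    _, _, obj = kmeans(pts, 6, np.random.default_rng(3))
    assert all(b <= a + 1e-9 for a, b in zip(obj, obj[1:]))


def test_kmeans_k_equals_one_gives_mean_center(rng):
    pts = rng.random((20, 4))
    labels, centers, _ = kmeans(pts, 1, np.random.default_rng(0))
    assert set(labels) == {0}
    np.testing.assert_allclose(centers[0], pts.mean(axis=0))


def test_kmeans_partition_matches_sklearn_on_separated_blobs():
    """Independent cross-check: on well-separated blobs our Lloyd iteration
    and sklearn's KMeans recover the same partition and the same objective."""
    from sklearn.cluster import KMeans

    rng = np.random.default_rng(7)
    centers = np.array([[5.0, 0.0], [-5.0, 0.0], [0.0, 5.0]])
    pts = np.concatenate([c + 0.1 * rng.standard_normal((10, 2))
                          for c in centers])
    labels, ours_centers, obj = kmeans(pts, 3, np.random.default_rng(0))
    sk = KMeans(n_clusters=3, n_init=5, random_state=0).fit(pts)
    # same partition up to label permutation
    mapping = {}
    for u, v in zip(labels, sk.labels_):
        assert mapping.setdefault(u, v) == v
    assert len(set(mapping.values())) == 3
    assert obj[-1] == pytest.approx(float(sk.inertia_), rel=1e-9)


def test_kmeans_rejects_more_clusters_than_points(rng):
    with pytest.raises(ValueError):
        kmeans(rng.random((3, 2)), 5, np.random.default_rng(0))


def test_cluster_views_seeded_determinism(rng):
    z1 = rng.random((40, 6))
    z2 = rng.random((40, 6))
    s1 = cluster_views(z1, z2, 3, seed=9)
    s2 = cluster_views(z1, z2, 3, seed=9)
    assert np.array_equal(s1.labels1, s2.labels1)
    assert np.array_equal(s1.labels2, s2.labels2)
    norms = np.linalg.norm(s1.centers1, axis=1)
    np.testing.assert_allclose(norms, 1.0, atol=1e-9)


# --------------------------------------------------------------- clust loss
def test_clust_loss_single_cluster_is_zero(rng):
    z = rng.standard_normal((5, 4))
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    loss = clust_loss(Tensor(z), np.zeros(5, dtype=int),
                      z.mean(axis=0, keepdims=True))
    assert float(loss.data) == pytest.approx(0.0, abs=1e-12)


def test_clust_loss_hand_value_antipodal_centers():
    z = np.array([[1.0, 0.0]])
    centers = np.array([[1.0, 0.0], [-1.0, 0.0]])
    loss = clust_loss(Tensor(z), np.array([0]), centers)
    expected = -np.log(1.0 / (1.0 + np.exp(-2.0)))  # d(z, -z) = 2
    assert float(loss.data) == pytest.approx(expected)


def test_clust_loss_decreases_as_feature_rotates_toward_center():
    centers = np.array([[1.0, 0.0], [0.0, 1.0]])
    values = []
    for theta in np.linspace(np.pi / 3, 0.0, 6):
        z = np.array([[np.cos(theta), np.sin(theta)]])
        values.append(float(clust_loss(Tensor(z), np.array([0]),
                                       centers).data))
    assert all(b < a for a, b in zip(values, values[1:]))


def test_clust_loss_label_out_of_range():
    with pytest.raises(IndexError):
        clust_loss(Tensor(np.ones((1, 2))), np.array([2]), np.eye(2))


def test_within_and_cross_match_scalar_evaluation():
    """Two-pixel, two-cluster hand fixture versus direct scalar evaluation."""
    z1 = np.array([[1.0, 0.0], [0.0, 1.0]])
    z2 = np.array([[0.8, 0.6], [0.6, 0.8]])
    c1 = np.array([[1.0, 0.0], [0.0, 1.0]])
    c2 = np.array([[0.6, 0.8], [0.8, 0.6]])
    y1 = np.array([0, 1])
    y2 = np.array([1, 0])

    def scalar_clust(z, y, mu):
        total = 0.0
        for p in range(z.shape[0]):
            d = 1.0 - z[p] @ mu.T
            total += -np.log(np.exp(-d[y[p]]) / np.exp(-d).sum())
        return total / z.shape[0]

    l_within = float((clust_loss(Tensor(z1), y1, c1)
                      + clust_loss(Tensor(z2), y2, c2)).data)
    l_cross = float((clust_loss(Tensor(z1), y2, c2)
                     + clust_loss(Tensor(z2), y1, c1)).data)
    assert l_within == pytest.approx(scalar_clust(z1, y1, c1)
                                     + scalar_clust(z2, y2, c2))
    assert l_cross == pytest.approx(scalar_clust(z1, y2, c2)
                                    + scalar_clust(z2, y1, c1))


# ------------------------------------------------------------ semantic loss
def test_semantic_loss_zero_with_single_cluster(rng):
    net = SegmentationNet(feature_dim=4, hidden=2, seed=1)
    fused = rng.random((2, 1, 16, 16))
    total, within, cross = semantic_loss(Tensor(fused), net, k=1,
                                         rng=np.random.default_rng(0))
    assert float(total.data) == pytest.approx(0.0, abs=1e-12)
    assert within == pytest.approx(0.0, abs=1e-12)


def test_identical_views_make_within_equal_cross(rng):
    """With degenerate jitter and no geometric transform the two views are
    identical, so intra-view and inter-view losses coincide exactly."""
    net = SegmentationNet(feature_dim=4, hidden=2, seed=1)
    fused = rng.random((1, 1, 16, 16))
    total, within, cross = semantic_loss(
        Tensor(fused), net, k=3, rng=np.random.default_rng(4),
        jitter=PhotometricJitter(0.0, 0.0, 0.0), use_geometric=False)
    assert within == pytest.approx(cross, abs=1e-10)
    assert float(total.data) == pytest.approx(within + cross)
    assert float(total.data) >= 0.0


def test_semantic_loss_nonnegative_and_gradients_reach_input(rng):
    net = SegmentationNet(feature_dim=4, hidden=2, seed=2)
    fused = Tensor(rng.random((1, 1, 16, 16)), requires_grad=True)
    total, _, _ = semantic_loss(fused, net, k=2, rng=np.random.default_rng(1))
    assert float(total.data) >= 0.0
    total.backward()
    assert fused.grad is not None and np.any(fused.grad)


def test_clustering_is_stop_gradient():
    """Labels and centers are plain numpy constants: no gradient path exists
    through the clustering, only through the feature field z."""
    state = cluster_views(np.random.default_rng(0).random((30, 4)),
                          np.random.default_rng(1).random((30, 4)), 2, seed=0)
    assert isinstance(state.labels1, np.ndarray)
    assert isinstance(state.centers1, np.ndarray)
    assert not isinstance(state.centers1, Tensor)


def test_flip_equivariant_features_give_transported_labels():
    """With a hand-built flip-equivariant feature field, the flipped view's
    pseudo-label map is the flip of the unflipped view's map (up to cluster
    id permutation)."""
    rng = np.random.default_rng(5)
    # three well-separated feature blobs assigned to spatial thirds, so every
    # k-means run recovers the same partition regardless of seeding
    z = np.zeros((1, 4, 6, 6))
    for third, axis in enumerate([0, 1, 2]):
        z[0, axis, :, third * 2:(third + 1) * 2] = 1.0
    z += 0.01 * rng.standard_normal(z.shape)
    z /= np.sqrt((z ** 2).sum(axis=1, keepdims=True))
    z_flipped = z[..., ::-1].copy()

    def flatten(a):
        return np.ascontiguousarray(a.transpose(0, 2, 3, 1)).reshape(-1, 4)

    state = cluster_views(flatten(z), flatten(z_flipped), 3, seed=2)
    lab1 = state.labels1.reshape(6, 6)
    lab2 = state.labels2.reshape(6, 6)
    transported = lab1[:, ::-1]
    # partitions must agree via a bijective relabeling
    mapping = {}
    for u, v in zip(transported.ravel(), lab2.ravel()):
        assert mapping.setdefault(u, v) == v
    assert len(set(mapping.values())) == len(mapping) == 3
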