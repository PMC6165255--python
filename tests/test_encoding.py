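"""Codebook construction and bag-of-features encoding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histosift.encoding import (
    Codebook,
    assign_codewords,
    build_codebook,
    encode,
    encode_pyramid,
    load_codebook,
    save_codebook,
)
from histosift.sift import Keypoint


def _cloud_descriptors(centers, n_per, spread, seed):
    rng = np.random.default_rng(seed)
    out = []
    for c in centers:
        out.append(c + rng.normal(0, spread, size=(n_per, 128)))
    return np.vstack(out)


def _toy_codebook(k=4, seed=0):
    rng = np.random.default_rng(seed)
    return Codebook(centroids=rng.random((k, 128)), seed=seed)


def test_two_separated_clouds_recover_means():
    rng = np.random.default_rng(1)
    c1, c2 = rng.random(128), rng.random(128) + 5.0
    X = _cloud_descriptors([c1, c2], 50, 1e-3, seed=2)
    cb = build_codebook(X, k=2, seed=0)
    means = np.sort([X[:50].mean(0).sum(), X[50:].mean(0).sum()])
    got = np.sort(cb.centroids.sum(axis=1))
    # centroids equal the exact cloud means to clustering precision
    expected = [X[:50].mean(0), X[50:].mean(0)]
    order = np.argsort([c.sum() for c in cb.centroids])
    eorder = np.argsort([e.sum() for e in expected])
    for i, j in zip(order, eorder):
        np.testing.assert_allclose(cb.centroids[i], expected[j], atol=1e-6)


def test_codebook_determinism_and_default_size():
    X = np.random.default_rng(3).random((1200, 128))
    cb1 = build_codebook(X, k=500, seed=7)
    cb2 = build_codebook(X, k=500, seed=7)
    assert cb1.k == 500
    np.testing.assert_array_equal(cb1.centroids, cb2.centroids)


def test_too_few_descriptors_error_names_both_counts():
    X = np.random.default_rng(0).random((5, 128))
    with pytest.raises(ValueError, match="k=10.*got 5"):
        build_codebook(X, k=10)


def test_subsampling_is_seeded_and_bounding():
    X = np.random.default_rng(4).random((500, 128))
    cb1 = build_codebook(X, k=8, seed=1, max_train_descriptors=200)
    cb2 = build_codebook(X, k=8, seed=1, max_train_descriptors=200)
    np.testing.assert_array_equal(cb1.centroids, cb2.centroids)


def test_single_descriptor_one_hot():
    cb = _toy_codebook()
    d = cb.centroids[2] + 1e-6
    h = encode(d[None, :], cb)
    np.testing.assert_allclose(h, np.eye(4)[2])


def test_concentrated_descriptors():
    cb = _toy_codebook()
    X = np.tile(cb.centroids[3], (10, 1)) + 1e-9
    h = encode(X, cb)
    np.testing.assert_allclose(h, [0, 0, 0, 1])


def test_tie_breaks_to_lowest_index():
    c = np.random.default_rng(5).random(128)
    cb = Codebook(centroids=np.vstack([c, c + 1e-18, c + 2.0]), seed=0)
    assert assign_codewords(c[None, :], cb)[0] == 0


def test_empty_descriptor_set_is_an_error():
    with pytest.raises(ValueError, match="no features"):
        encode(np.empty((0, 128)), _toy_codebook())
    with pytest.raises(ValueError, match="no features"):
        encode_pyramid([], _toy_codebook(), levels=2, image_size=(64, 64))


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(min_value=1, max_value=40), st.integers(min_value=0, max_value=999))
def test_histogram_mass_and_permutation_invariance(n, seed):
    """Histograms sum to 1 and do not depend on descriptor order; the raw
    codeword counts conserve the descriptor count."""
    cb = _toy_codebook()
    X = np.random.default_rng(seed).random((n, 128))
    h = encode(X, cb)
    assert h.sum() == pytest.approx(1.0, abs=1e-9)
    perm = np.random.default_rng(seed + 1).permutation(n)
    np.testing.assert_array_equal(h, encode(X[perm], cb))
    counts = np.bincount(assign_codewords(X, cb), minlength=cb.k)
    assert counts.sum() == n


def test_kmeans_distortion_monotone_in_k():
    """More codewords never increase the quantization distortion.

    Distortion is measured by a brute-force nearest-centroid assignment
    independent of the clustering implementation.
    """
    X = _cloud_descriptors(
        [np.zeros(128), np.ones(128), 2 * np.ones(128), 3 * np.ones(128)],
        20, 0.3, seed=6,
    )

    def distortion(cb):
        d2 = ((X[:, None, :] - cb.centroids[None, :, :]) ** 2).sum(-1)
        return d2.min(axis=1).sum()

    values = [distortion(build_codebook(X, k=k, seed=0)) for k in (2, 3, 4, 6)]
    assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))


def _features_at(points, descs):
    return [
        (Keypoint(x=x, y=y, octave=0, interval=0, sigma=1.7), d)
        for (x, y), d in zip(points, descs)
    ]


def test_pyramid_level1_equals_flat():
    cb = _toy_codebook()
    rng = np.random.default_rng(8)
    descs = rng.random((12, 128))
    pts = rng.uniform(0, 64, size=(12, 2))
    flat = encode(descs, cb)
    pyr = encode_pyramid(_features_at(pts, descs), cb, levels=1, image_size=(64, 64))
    np.testing.assert_allclose(pyr, flat)


def test_pyramid_length_and_empty_cells():
    cb = _toy_codebook()
    rng = np.random.default_rng(9)
    descs = rng.random((10, 128))
    # all keypoints in the upper-left quadrant
    pts = rng.uniform(0, 30, size=(10, 2))
    pyr = encode_pyramid(_features_at(pts, descs), cb, levels=2, image_size=(64, 64))
    assert pyr.shape == (5 * cb.k,)  # k * (1 + 4) cells
    assert pyr.sum() == pytest.approx(1.0, abs=1e-9)
    cells = pyr[cb.k :].reshape(4, cb.k)  # level-1 cells: UL, UR, LL, LR
    assert cells[0].sum() > 0
    np.testing.assert_allclose(cells[1:], 0.0)


def test_codebook_roundtrip(tmp_path):
    cb = _toy_codebook(k=6, seed=11)
    path = tmp_path / "cb.txt"
    save_codebook(cb, path)
    back = load_codebook(path)
    assert back.seed == cb.seed
    np.testing.assert_array_equal(back.centroids, cb.centroids)
    with pytest.raises(ValueError, match="not a histosift codebook"):
        (tmp_path / "junk.txt").write_text("hello\n")
        load_codebook(tmp_path / "junk.txt")
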