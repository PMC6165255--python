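"""Extremum detection, sub-pixel localization, and keypoint rejection."""

import numpy as np
import pytest

from histosift.sift import (
    DogPyramid,
    Keypoint,
    SiftParams,
    build_scale_space,
    compute_dog,
    detect_extrema,
    extract_features,
    localize_keypoint,
    reject_edge_response,
)


def _pyramid_from_array(D: np.ndarray, params: SiftParams | None = None) -> DogPyramid:
    params = params or SiftParams()
    s = D.shape[0] - 2
    sigmas = params.sigma0 * params.k ** np.arange(D.shape[0])
    return DogPyramid([D.astype(float)], [sigmas], [1.0], params)


def _brute_force_extrema(D: np.ndarray) -> set[tuple[int, int, int]]:
    """Exhaustive 26-neighbor comparison oracle."""
    out = set()
    n, h, w = D.shape
    for i in range(1, n - 1):
        for r in range(1, h - 1):
            for c in range(1, w - 1):
                patch = D[i - 1 : i + 2, r - 1 : r + 2, c - 1 : c + 2]
                neighbors = np.delete(patch.ravel(), 13)
                assert neighbors.size == 26
                v = D[i, r, c]
                if v > neighbors.max() or v < neighbors.min():
                    out.add((i, r, c))
    return out


def test_single_impulse_yields_one_candidate():
    D = np.zeros((3, 9, 9))
    D[1, 4, 5] = 1.0
    cands = detect_extrema(_pyramid_from_array(D))
    assert len(cands) == 1
    kp = cands[0]
    assert (kp.interval, int(kp.r_oct), int(kp.c_oct)) == (1, 4, 5)


def test_extrema_match_brute_force_oracle():
    """The vectorized 26-neighbor test agrees exactly with exhaustive search."""
    rng = np.random.default_rng(42)
    for _ in range(5):
        D = rng.normal(size=(5, 12, 12))
        got = {
            (kp.interval, int(kp.r_oct), int(kp.c_oct))
            for kp in detect_extrema(_pyramid_from_array(D))
        }
        assert got == _brute_force_extrema(D)


def test_plateau_is_not_a_strict_extremum():
    D = np.zeros((3, 7, 7))
    D[1, 3, 3] = D[1, 3, 4] = 1.0  # tie with a neighbor
    assert detect_extrema(_pyramid_from_array(D)) == []


def _quadratic_dog(vertex, amplitude=1.0, shape=(5, 11, 11)):
    """Separable concave quadratic with a known sub-grid vertex."""
    i, r, c = np.mgrid[: shape[0], : shape[1], : shape[2]].astype(float)
    vi, vr, vc = vertex
    D = amplitude - 0.05 * ((i - vi) ** 2 + (r - vr) ** 2 + (c - vc) ** 2)
    return D


def test_subpixel_localization_recovers_quadratic_vertex():
    """The 3-D quadratic fit recovers a vertex at +0.3 within 1e-6."""
    vertex = (2.0 - 0.1, 5.3, 6.2)  # offsets -0.1, +0.3, +0.2 from (2, 5, 6)
    D = _quadratic_dog(vertex)
    dog = _pyramid_from_array(D)
    cand = Keypoint(
        x=6, y=5, octave=0, interval=2, sigma=1.7, c_oct=6.0, r_oct=5.0, sigma_oct=1.7
    )
    kp = localize_keypoint(cand, dog, SiftParams())
    assert kp is not None
    assert kp.c_oct == pytest.approx(6.2, abs=1e-6)
    assert kp.r_oct == pytest.approx(5.3, abs=1e-6)
    assert kp.x == pytest.approx(6.2, abs=1e-6)


def test_symmetric_neighborhood_gives_zero_offset():
    D = _quadratic_dog((2.0, 5.0, 6.0))
    cand = Keypoint(
        x=6, y=5, octave=0, interval=2, sigma=1.7, c_oct=6.0, r_oct=5.0, sigma_oct=1.7
    )
    kp = localize_keypoint(cand, dog := _pyramid_from_array(D), SiftParams())
    assert kp is not None
    assert kp.c_oct == pytest.approx(6.0, abs=1e-12)
    assert kp.r_oct == pytest.approx(5.0, abs=1e-12)


def test_low_contrast_rejected_at_operating_threshold():
    """|D(z)| below CC = 0.04 is rejected; above survives."""
    cand = Keypoint(
        x=6, y=5, octave=0, interval=2, sigma=1.7, c_oct=6.0, r_oct=5.0, sigma_oct=1.7
    )
    weak = _pyramid_from_array(_quadratic_dog((2, 5, 6), amplitude=0.03))
    assert localize_keypoint(cand, weak, SiftParams()) is None
    strong = _pyramid_from_array(_quadratic_dog((2, 5, 6), amplitude=0.05))
    assert localize_keypoint(cand, strong, SiftParams()) is not None


def test_singular_hessian_rejected():
    D = np.zeros((5, 11, 11))  # all derivatives vanish
    cand = Keypoint(
        x=6, y=5, octave=0, interval=2, sigma=1.7, c_oct=6.0, r_oct=5.0, sigma_oct=1.7
    )
    assert localize_keypoint(cand, _pyramid_from_array(D), SiftParams()) is None


def _dog_with_curvatures(lam1, lam2):
    """DoG whose spatial Hessian at (2, 5, 6) has given eigenvalues."""
    i, r, c = np.mgrid[:5, :11, :11].astype(float)
    D = 0.5 * lam1 * (c - 6) ** 2 + 0.5 * lam2 * (r - 5) ** 2
    return _pyramid_from_array(D + 0.2)


@pytest.mark.parametrize(
    "lam1,lam2,ce,kept",
    [
        (1.0, 1.0, 11, True),    # isotropic: ratio 1, kept for any CE >= 1
        (1.0, 0.0, 11, False),   # ideal step edge: Det = 0 -> discarded
        (11.0, 1.0, 11, False),  # boundary: Tr^2/Det = 144/11 = bound -> discarded
        (5.0, 1.0, 11, True),    # moderate anisotropy below the bound
        (1.0, -1.0, 11, False),  # saddle: Det < 0 -> discarded
    ],
)
def test_edge_response_ratio_test(lam1, lam2, ce, kept):
    dog = _dog_with_curvatures(lam1, lam2)
    kp = Keypoint(
        x=6, y=5, octave=0, interval=2, sigma=1.7, c_oct=6.0, r_oct=5.0, sigma_oct=1.7
    )
    assert reject_edge_response(kp, dog, ce) is kept


def test_threshold_monotonicity(texture):
    """Raising CC never increases keypoints; raising CE never decreases."""
    counts_cc = [
        len(extract_features(texture, SiftParams(contrast_threshold=cc)))
        for cc in (0.02, 0.04, 0.06)
    ]
    assert counts_cc[0] >= counts_cc[1] >= counts_cc[2]
    counts_ce = [
        len(extract_features(texture, SiftParams(edge_threshold=ce)))
        for ce in (5, 11, 29)
    ]
    assert counts_ce[0] <= counts_ce[1] <= counts_ce[2]


def test_keypoints_corroborated_by_independent_detector(texture):
    """Keypoint locations coincide with scikit-image's SIFT detector.

    The two implementations differ in octave seeding and threshold
    conventions, so exact agreement is not expected; but nearly every
    keypoint found here should have a counterpart within 3 px in the
    independent implementation run with matched parameters.
    """
    from skimage.feature import SIFT

    det = SIFT(upsampling=1, sigma_min=1.7, n_scales=3, c_dog=0.04 / 3, c_edge=11)
    det.detect_and_extract(texture)
    theirs = det.keypoints[:, ::-1].astype(float)  # (row, col) -> (x, y)
    mine = np.array([[kp.x, kp.y] for kp, _ in extract_features(texture)])
    assert len(mine) > 20
    d2 = ((mine[:, None, :] - theirs[None, :, :]) ** 2).sum(-1).min(axis=1)
    assert np.mean(d2 <= 9.0) >= 0.9
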