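"""Scale-invariant feature transform (SIFT) for grayscale image tiles.

The four classic stages are implemented as separate, individually testable
operations:

1. scale-space construction (:func:`build_scale_space`) and its
   difference-of-Gaussians pyramid (:func:`compute_dog`);
2. 26-neighbor extremum detection (:func:`detect_extrema`) followed by
   sub-pixel localization with contrast rejection
   (:func:`localize_keypoint`) and principal-curvature edge rejection
   (:func:`reject_edge_response`);
3. orientation assignment from a 36-bin gradient-orientation histogram
   (:func:`assign_orientations`);
4. the 4x4x8 = 128-element gradient descriptor
   (:func:`compute_descriptor`).

:func:`extract_features` composes all of them.  Everything is deterministic:
no randomness enters feature extraction.

Conventions: images are 2-D float arrays in [0, 1], indexed ``[row, col]``;
keypoint coordinates are ``(x, y) = (col, row)``, 0-based, pixel centers at
integers, reported in the full-resolution frame.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

MIN_IMAGE_SIZE = 32

__all__ = [
    "SiftParams",
    "ScaleSpace",
    "DogPyramid",
    "Keypoint",
    "as_gray_image",
    "build_scale_space",
    "compute_dog",
    "detect_extrema",
    "localize_keypoint",
    "reject_edge_response",
    "orientation_histogram",
    "assign_orientations",
    "compute_descriptor",
    "extract_features",
]


# ---------------------------------------------------------------------------
# parameters and containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiftParams:
    """Free parameters of the detector/descriptor.

    Attributes
    ----------
    sigma0:
        Base Gaussian width of the scale-space schedule (pixels of the
        first octave).
    contrast_threshold:
        Keypoints whose interpolated |DoG| response falls below this value
        (images scaled to [0, 1]) are rejected.  No per-interval
        renormalization is applied.
    edge_threshold:
        Maximum allowed ratio between the principal curvatures of the DoG
        surface; larger ratios indicate edge-like, poorly localized points.
    n_octaves:
        Number of octaves, or ``None`` for ``floor(log2(min(h, w))) - 2``.
    intervals_per_octave:
        ``s``; each octave holds ``s + 3`` Gaussian images and adjacent
        scales differ by ``k = 2**(1/s)``.
    upsample_first_octave:
        If true the image is 2x bilinearly upsampled before octave 0,
        doubling keypoint yield at extra cost.  Off by default.
    assumed_blur:
        Blur assumed already present in the input (camera/scanner
        anti-aliasing), folded into the first pre-smoothing.
    max_interp_iter:
        Cap on re-centering iterations during sub-pixel localization.
    """

    sigma0: float = 1.7
    contrast_threshold: float = 0.04
    edge_threshold: float = 11.0
    n_octaves: int | None = None
    intervals_per_octave: int = 3
    upsample_first_octave: bool = False
    assumed_blur: float = 0.5
    max_interp_iter: int = 5

    def __post_init__(self) -> None:
        if not self.sigma0 > 0:
            raise ValueError(f"sigma0 must be > 0, got {self.sigma0}")
        if not self.contrast_threshold > 0:
            raise ValueError(
                f"contrast_threshold must be > 0, got {self.contrast_threshold}"
            )
        if not self.edge_threshold >= 1:
            raise ValueError(
                f"edge_threshold must be >= 1, got {self.edge_threshold}"
            )
        if self.intervals_per_octave < 1:
            raise ValueError(
                "intervals_per_octave must be >= 1, got "
                f"{self.intervals_per_octave}"
            )
        if self.n_octaves is not None and self.n_octaves < 1:
            raise ValueError(f"n_octaves must be >= 1, got {self.n_octaves}")

    @property
    def k(self) -> float:
        """Multiplicative scale factor between adjacent intervals."""
        return 2.0 ** (1.0 / self.intervals_per_octave)


@dataclass
class ScaleSpace:
    """Gaussian scale-space pyramid.

    ``octaves[o]`` is an array of shape ``(s + 3, h_o, w_o)``;
    ``sigmas[o][i]`` is the blur of level ``i`` in the pixel units of
    octave ``o``; ``factors[o]`` converts octave-o pixels to
    full-resolution pixels (0.5 for an upsampled first octave).
    """

    octaves: list[np.ndarray]
    sigmas: list[np.ndarray]
    factors: list[float]
    params: SiftParams
    # gradient cache: (octave, level) -> (dx, dy)
    _grad: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False
    )

    @property
    def n_octaves(self) -> int:
        return len(self.octaves)

    def gradients(self, octave: int, level: int) -> tuple[np.ndarray, np.ndarray]:
        """Central-difference gradient components (dx, dy) of one level.

        dx = L(x+1, y) - L(x-1, y), dy = L(x, y+1) - L(x, y-1); magnitude
        and orientation follow as m = sqrt(dx^2 + dy^2),
        theta = atan2(dy, dx).  Cached per level: orientation assignment
        and descriptors reuse it.
        """
        key = (octave, level)
        if key not in self._grad:
            L = self.octaves[octave][level]
            dx = np.zeros_like(L)
            dy = np.zeros_like(L)
            dx[:, 1:-1] = L[:, 2:] - L[:, :-2]
            dy[1:-1, :] = L[2:, :] - L[:-2, :]
            self._grad[key] = (dx, dy)
        return self._grad[key]


@dataclass
class DogPyramid:
    """Difference-of-Gaussians pyramid; ``octaves[o]`` has shape (s+2, h, w)."""

    octaves: list[np.ndarray]
    sigmas: list[np.ndarray]  # sigma of the lower image of each pair
    factors: list[float]
    params: SiftParams


@dataclass
class Keypoint:
    """A localized, scale-assigned, oriented interest point.

    ``x``/``y`` are sub-pixel column/row in the full-resolution frame;
    ``sigma`` the absolute scale there.  ``c_oct``/``r_oct``/``sigma_oct``
    are the same quantities in the keypoint's octave frame, kept for
    orientation and descriptor sampling.
    """

    x: float
    y: float
    octave: int
    interval: int
    sigma: float
    orientation: float = 0.0  # degrees in [0, 360)
    response: float = 0.0
    c_oct: float = 0.0
    r_oct: float = 0.0
    sigma_oct: float = 0.0


def as_gray_image(image: np.ndarray) -> np.ndarray:
    """Validate and return a float64 grayscale image in [0, 1]."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale array, got shape {arr.shape}")
    if arr.shape[0] < MIN_IMAGE_SIZE or arr.shape[1] < MIN_IMAGE_SIZE:
        raise ValueError(
            f"image {arr.shape} smaller than minimum "
            f"{MIN_IMAGE_SIZE}x{MIN_IMAGE_SIZE} for feature extraction"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("image intensities must lie in [0, 1]")
    return arr


# ---------------------------------------------------------------------------
# stage 1: scale space and DoG
# ---------------------------------------------------------------------------


def build_scale_space(image: np.ndarray, params: SiftParams) -> ScaleSpace:
    """Build the Gaussian pyramid L(x, y, sigma).

    Each octave holds ``s + 3`` images with blurs ``sigma0 * k**i`` in
    octave pixel units; blurring is incremental so each level is a single
    small-kernel convolution of the previous one.  The next octave starts
    from the level with blur ``2 * sigma0``, downsampled by 2.
    """
    img = as_gray_image(image)
    s = params.intervals_per_octave
    k = params.k

    assumed = params.assumed_blur
    factor = 1.0
    if params.upsample_first_octave:
        img = ndimage.zoom(img, 2.0, order=1, mode="nearest", grid_mode=False)
        assumed *= 2.0
        factor = 0.5

    max_octaves = int(math.floor(math.log2(min(img.shape)))) - 2
    max_octaves = max(max_octaves, 1)
    n_octaves = params.n_octaves if params.n_octaves is not None else max_octaves
    if n_octaves > max_octaves:
        logger.warning(
            "requested %d octaves but image %s supports only %d; reducing",
            n_octaves, img.shape, max_octaves,
        )
        n_octaves = max_octaves

    # pre-smooth the input up to sigma0
    delta = math.sqrt(max(params.sigma0**2 - assumed**2, 0.01))
    base = ndimage.gaussian_filter(img, delta, mode="nearest")

    rel_sigmas = params.sigma0 * k ** np.arange(s + 3)
    incr = np.sqrt(rel_sigmas[1:] ** 2 - rel_sigmas[:-1] ** 2)

    octaves: list[np.ndarray] = []
    sigmas: list[np.ndarray] = []
    factors: list[float] = []
    current = base
    for o in range(n_octaves):
        levels = np.empty((s + 3, *current.shape))
        levels[0] = current
        for i in range(1, s + 3):
            levels[i] = ndimage.gaussian_filter(
                levels[i - 1], incr[i - 1], mode="nearest"
            )
        octaves.append(levels)
        sigmas.append(rel_sigmas.copy())
        factors.append(factor)
        # level s has blur sigma0 * 2; halving restores relative blur sigma0
        current = levels[s][::2, ::2]
        factor *= 2.0
    return ScaleSpace(octaves, sigmas, factors, params)


def compute_dog(ss: ScaleSpace) -> DogPyramid:
    """Difference-of-Gaussians pyramid: D_i = L_{i+1} - L_i per octave."""
    dogs = [levels[1:] - levels[:-1] for levels in ss.octaves]
    sigmas = [sig[:-1].copy() for sig in ss.sigmas]
    return DogPyramid(dogs, sigmas, list(ss.factors), ss.params)


# ---------------------------------------------------------------------------
# stage 2: extrema detection, localization, rejection
# ---------------------------------------------------------------------------

_FOOTPRINT = np.ones((3, 3, 3), dtype=bool)
_FOOTPRINT[1, 1, 1] = False  # the 26 neighbors, center excluded


def detect_extrema(dog: DogPyramid) -> list[Keypoint]:
    """Candidate keypoints: strict extrema over the 26-pixel neighborhood.

    A sample qualifies iff it is strictly greater (or strictly smaller)
    than all 8 in-plane neighbors plus the 9 above and 9 below in scale.
    Only interior intervals and interior pixels are scanned.
    """
    candidates: list[Keypoint] = []
    for o, D in enumerate(dog.octaves):
        if D.shape[0] < 3:
            continue
        neigh_max = ndimage.maximum_filter(
            D, footprint=_FOOTPRINT, mode="constant", cval=-np.inf
        )
        neigh_min = ndimage.minimum_filter(
            D, footprint=_FOOTPRINT, mode="constant", cval=np.inf
        )
        mask = (D > neigh_max) | (D < neigh_min)
        mask[0] = mask[-1] = False
        mask[:, :1, :] = mask[:, -1:, :] = False
        mask[:, :, :1] = mask[:, :, -1:] = False
        for i, r, c in zip(*np.nonzero(mask)):
            f = dog.factors[o]
            candidates.append(
                Keypoint(
                    x=float(c) * f,
                    y=float(r) * f,
                    octave=o,
                    interval=int(i),
                    sigma=float(dog.sigmas[o][i]) * f,
                    response=float(D[i, r, c]),
                    c_oct=float(c),
                    r_oct=float(r),
                    sigma_oct=float(dog.sigmas[o][i]),
                )
            )
    return candidates


def _dog_derivatives(D: np.ndarray, i: int, r: int, c: int):
    """Central-difference gradient and Hessian of D at (interval, row, col)."""
    g = 0.5 * np.array(
        [
            D[i, r, c + 1] - D[i, r, c - 1],
            D[i, r + 1, c] - D[i, r - 1, c],
            D[i + 1, r, c] - D[i - 1, r, c],
        ]
    )
    center = D[i, r, c]
    dxx = D[i, r, c + 1] - 2 * center + D[i, r, c - 1]
    dyy = D[i, r + 1, c] - 2 * center + D[i, r - 1, c]
    dss = D[i + 1, r, c] - 2 * center + D[i - 1, r, c]
    dxy = 0.25 * (
        D[i, r + 1, c + 1] - D[i, r + 1, c - 1]
        - D[i, r - 1, c + 1] + D[i, r - 1, c - 1]
    )
    dxs = 0.25 * (
        D[i + 1, r, c + 1] - D[i + 1, r, c - 1]
        - D[i - 1, r, c + 1] + D[i - 1, r, c - 1]
    )
    dys = 0.25 * (
        D[i + 1, r + 1, c] - D[i + 1, r - 1, c]
        - D[i - 1, r + 1, c] + D[i - 1, r - 1, c]
    )
    H = np.array([[dxx, dxy, dxs], [dxy, dyy, dys], [dxs, dys, dss]])
    return g, H


def localize_keypoint(
    candidate: Keypoint, dog: DogPyramid, params: SiftParams
) -> Keypoint | None:
    """Refine a candidate to sub-pixel accuracy; reject unstable points.

    Fits a quadratic to the DoG neighborhood, z = -H^{-1} g over
    (x, y, scale), re-centering while any offset component exceeds 0.5
    (up to ``max_interp_iter`` iterations).  Returns ``None`` when the
    point leaves the valid volume, the Hessian is singular, refinement
    does not converge, or the interpolated contrast |D(z)| falls below
    ``contrast_threshold``.
    """
    D = dog.octaves[candidate.octave]
    n_int, h, w = D.shape
    i, r, c = candidate.interval, int(round(candidate.r_oct)), int(round(candidate.c_oct))
    offset = np.zeros(3)
    for _ in range(params.max_interp_iter):
        if not (1 <= i < n_int - 1 and 1 <= r < h - 1 and 1 <= c < w - 1):
            return None
        g, H = _dog_derivatives(D, i, r, c)
        det = np.linalg.det(H)
        if abs(det) < 1e-30:
            return None  # unstable: singular quadratic fit
        offset = -np.linalg.solve(H, g)
        if np.all(np.abs(offset) <= 0.5):
            break
        c += int(round(np.clip(offset[0], -1, 1)))
        r += int(round(np.clip(offset[1], -1, 1)))
        i += int(round(np.clip(offset[2], -1, 1)))
    else:
        return None  # did not converge within the iteration cap
    if not (1 <= i < n_int - 1 and 1 <= r < h - 1 and 1 <= c < w - 1):
        return None
    value = D[i, r, c] + 0.5 * float(g @ offset)
    if abs(value) < params.contrast_threshold:
        return None
    f = dog.factors[candidate.octave]
    k = params.k
    sigma_oct = float(dog.sigmas[candidate.octave][i]) * k ** float(offset[2])
    return replace(
        candidate,
        x=(c + float(offset[0])) * f,
        y=(r + float(offset[1])) * f,
        interval=i,
        sigma=sigma_oct * f,
        response=float(value),
        c_oct=c + float(offset[0]),
        r_oct=r + float(offset[1]),
        sigma_oct=sigma_oct,
    )


def reject_edge_response(
    kp: Keypoint, dog: DogPyramid, edge_threshold: float | None = None
) -> bool:
    """Return True iff the keypoint survives the edge-response test.

    The 2x2 spatial Hessian of D at the keypoint gives principal
    curvatures; edge-like points have one large and one small curvature.
    Implemented via the ratio test Tr(H)^2 / Det(H) < (CE+1)^2 / CE,
    discarding at equality and whenever Det(H) <= 0.
    """
    ce = dog.params.edge_threshold if edge_threshold is None else edge_threshold
    D = dog.octaves[kp.octave]
    _, h, w = D.shape
    i = kp.interval
    r = int(round(kp.r_oct))
    c = int(round(kp.c_oct))
    if not (1 <= r < h - 1 and 1 <= c < w - 1):
        return False
    center = D[i, r, c]
    dxx = D[i, r, c + 1] - 2 * center + D[i, r, c - 1]
    dyy = D[i, r + 1, c] - 2 * center + D[i, r - 1, c]
    dxy = 0.25 * (
        D[i, r + 1, c + 1] - D[i, r + 1, c - 1]
        - D[i, r - 1, c + 1] + D[i, r - 1, c - 1]
    )
    tr = dxx + dyy
    det = dxx * dyy - dxy * dxy
    if det <= 0:
        return False
    return bool(tr * tr / det < (ce + 1.0) ** 2 / ce)


# ---------------------------------------------------------------------------
# stage 3: orientation assignment
# ---------------------------------------------------------------------------

N_ORI_BINS = 36
PEAK_RATIO = 0.8


def orientation_histogram(kp: Keypoint, ss: ScaleSpace) -> np.ndarray:
    """36-bin gradient-orientation histogram around a keypoint.

    Samples are taken from the Gaussian level nearest the keypoint's
    scale, weighted by gradient magnitude and by a circular Gaussian of
    width 1.5x the keypoint's (octave-frame) scale.
    """
    s = ss.params.intervals_per_octave
    level = int(np.clip(kp.interval, 0, s + 2))
    dx, dy = ss.gradients(kp.octave, level)
    h, w = dx.shape
    sigma_w = 1.5 * kp.sigma_oct
    radius = max(int(round(3.0 * sigma_w)), 1)
    r0, c0 = int(round(kp.r_oct)), int(round(kp.c_oct))
    rlo, rhi = max(r0 - radius, 0), min(r0 + radius + 1, h)
    clo, chi = max(c0 - radius, 0), min(c0 + radius + 1, w)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dist2 = (rr - kp.r_oct) ** 2 + (cc - kp.c_oct) ** 2
    gx = dx[rlo:rhi, clo:chi]
    gy = dy[rlo:rhi, clo:chi]
    weight = np.exp(-dist2 / (2.0 * sigma_w**2)) * np.hypot(gx, gy)
    theta = np.degrees(np.arctan2(gy, gx)) % 360.0
    bins = (theta // (360.0 / N_ORI_BINS)).astype(int) % N_ORI_BINS
    hist = np.zeros(N_ORI_BINS)
    np.add.at(hist, bins.ravel(), weight.ravel())
    # circular [1, 4, 6, 4, 1]/16 smoothing stabilizes peak detection
    kernel = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0
    padded = np.concatenate([hist[-2:], hist, hist[:2]])
    return np.convolve(padded, kernel, mode="valid")


def assign_orientations(kp: Keypoint, ss: ScaleSpace) -> list[Keypoint]:
    """Emit one oriented keypoint per dominant orientation-histogram peak.

    Peaks at or above 80% of the maximum that are local maxima of the
    circular histogram each yield a keypoint; peak positions are refined
    by parabolic interpolation over the peak and its two neighbors.
    """
    hist = orientation_histogram(kp, ss)
    peak = hist.max()
    if peak <= 0:
        logger.warning(
            "all-zero gradient region at keypoint (%.1f, %.1f); orientation 0",
            kp.x, kp.y,
        )
        return [replace(kp, orientation=0.0)]
    out: list[Keypoint] = []
    left = np.roll(hist, 1)
    right = np.roll(hist, -1)
    for b in np.nonzero((hist >= PEAK_RATIO * peak) & (hist > left) & (hist > right))[0]:
        l, c, r = left[b], hist[b], right[b]
        denom = l - 2.0 * c + r
        shift = 0.0 if denom == 0 else 0.5 * (l - r) / denom
        angle = ((b + shift) * (360.0 / N_ORI_BINS)) % 360.0
        out.append(replace(kp, orientation=float(angle)))
    if not out:  # flat plateau at the maximum: no strict local peak
        b = int(np.argmax(hist))
        out.append(replace(kp, orientation=float(b * 360.0 / N_ORI_BINS)))
    return out


# ---------------------------------------------------------------------------
# stage 4: descriptor
# ---------------------------------------------------------------------------

DESC_WIDTH = 4        # 4x4 spatial sub-regions
DESC_ORI_BINS = 8
DESC_SAMPLES = 16     # 16x16 sample grid
DESC_CLAMP = 0.2
DESC_SUBREGION_SCALE = 3.0  # sub-region width in units of keypoint scale

# relative sample offsets, in sub-region units, centered on the keypoint
_GRID = (np.arange(DESC_SAMPLES) - (DESC_SAMPLES - 1) / 2.0) * (
    DESC_WIDTH / DESC_SAMPLES
)
_GV, _GU = np.meshgrid(_GRID, _GRID, indexing="ij")  # rows (v), cols (u)
_SPATIAL_W = np.exp(-(_GU**2 + _GV**2) / (2.0 * (0.5 * DESC_WIDTH) ** 2))


def compute_descriptor(kp: Keypoint, ss: ScaleSpace) -> np.ndarray | None:
    """128-element gradient descriptor of one oriented keypoint.

    Gradients are sampled bilinearly on a 16x16 grid scaled by the
    keypoint scale and rotated by -orientation, accumulated into a
    4x4 grid of 8-bin orientation histograms with trilinear
    interpolation and a Gaussian spatial weight, then normalized,
    clamped at 0.2 and renormalized.  Out-of-bounds samples contribute
    zero.  Returns ``None`` for a zero-gradient window (the zero vector
    cannot be normalized).
    """
    s = ss.params.intervals_per_octave
    level = int(np.clip(kp.interval, 0, s + 2))
    dx_map, dy_map = ss.gradients(kp.octave, level)
    h, w = dx_map.shape

    theta = math.radians(kp.orientation)
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    spacing = DESC_SUBREGION_SCALE * kp.sigma_oct  # pixels per sub-region unit

    # rotate grid into image frame: u along the keypoint orientation
    du = (cos_t * _GU - sin_t * _GV) * spacing
    dv = (sin_t * _GU + cos_t * _GV) * spacing
    cols = kp.c_oct + du
    rows = kp.r_oct + dv

    c0 = np.floor(cols).astype(int)
    r0 = np.floor(rows).astype(int)
    fc = cols - c0
    fr = rows - r0
    valid = (r0 >= 0) & (r0 < h - 1) & (c0 >= 0) & (c0 < w - 1)
    c0c = np.clip(c0, 0, w - 2)
    r0c = np.clip(r0, 0, h - 2)

    def _bilinear(a: np.ndarray) -> np.ndarray:
        return (
            a[r0c, c0c] * (1 - fr) * (1 - fc)
            + a[r0c, c0c + 1] * (1 - fr) * fc
            + a[r0c + 1, c0c] * fr * (1 - fc)
            + a[r0c + 1, c0c + 1] * fr * fc
        )

    # interpolate the gradient *components*, then take magnitude/angle;
    # interpolating angles directly is ill-defined across the wrap
    gx = np.where(valid, _bilinear(dx_map), 0.0)
    gy = np.where(valid, _bilinear(dy_map), 0.0)
    m = np.hypot(gx, gy) * _SPATIAL_W
    ang = np.degrees(np.arctan2(gy, gx))
    rel = (ang - kp.orientation) % 360.0
    obin = rel / (360.0 / DESC_ORI_BINS)

    # trilinear accumulation into (row-bin, col-bin, orientation-bin)
    rbin = _GV + (DESC_WIDTH - 1) / 2.0  # in [-0.375, 3.375]
    cbin = _GU + (DESC_WIDTH - 1) / 2.0
    hist = np.zeros((DESC_WIDTH + 2, DESC_WIDTH + 2, DESC_ORI_BINS))
    rb0 = np.floor(rbin).astype(int)
    cb0 = np.floor(cbin).astype(int)
    ob0 = np.floor(obin).astype(int)
    frb = rbin - rb0
    fcb = cbin - cb0
    fob = obin - ob0
    for dr, wr in ((0, 1 - frb), (1, frb)):
        for dc, wc in ((0, 1 - fcb), (1, fcb)):
            for do, wo in ((0, 1 - fob), (1, fob)):
                np.add.at(
                    hist,
                    (rb0 + dr + 1, cb0 + dc + 1, (ob0 + do) % DESC_ORI_BINS),
                    m * wr * wc * wo,
                )
    vec = hist[1 : DESC_WIDTH + 1, 1 : DESC_WIDTH + 1, :].ravel()
    norm = np.linalg.norm(vec)
    if norm < 1e-12:
        return None
    vec = np.minimum(vec / norm, DESC_CLAMP)
    norm = np.linalg.norm(vec)
    if norm < 1e-12:
        return None
    return vec / norm


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def extract_features(
    image: np.ndarray, params: SiftParams | None = None
) -> list[tuple[Keypoint, np.ndarray]]:
    """Run the full SIFT pipeline on one grayscale image.

    Returns ``(keypoint, descriptor)`` pairs with keypoints in
    full-resolution coordinates.  Deterministic for fixed input and
    parameters; an empty list is a legal result.
    """
    params = params or SiftParams()
    ss = build_scale_space(image, params)
    dog = compute_dog(ss)
    out: list[tuple[Keypoint, np.ndarray]] = []
    for cand in detect_extrema(dog):
        kp = localize_keypoint(cand, dog, params)
        if kp is None or not reject_edge_response(kp, dog):
            continue
        for oriented in assign_orientations(kp, ss):
            desc = compute_descriptor(oriented, ss)
            if desc is not None:
                out.append((oriented, desc))
    return out
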