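"""Bag-of-features encoding over a k-means codebook.

A codebook of ``k`` codewords is learned by k-means over training
descriptors; an image is then represented by the L1-normalized histogram
of its descriptors' nearest codewords, either flat or concatenated over
a spatial pyramid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .sift import Keypoint

DESCRIPTOR_DIM = 128
DEFAULT_CODEBOOK_SIZE = 500
MAX_TRAIN_DESCRIPTORS = 100_000

__all__ = [
    "Codebook",
    "build_codebook",
    "assign_codewords",
    "encode",
    "encode_pyramid",
    "save_codebook",
    "load_codebook",
]


@dataclass(frozen=True)
class Codebook:
    """k cluster centroids in 128-dimensional descriptor space."""

    centroids: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        c = np.asarray(self.centroids, dtype=np.float64)
        if c.ndim != 2 or c.shape[1] != DESCRIPTOR_DIM:
            raise ValueError(
                f"centroids must be (k, {DESCRIPTOR_DIM}), got {c.shape}"
            )
        if c.shape[0] < 2:
            raise ValueError(f"codebook needs k >= 2, got k={c.shape[0]}")
        if not np.all(np.isfinite(c)):
            raise ValueError("centroids contain non-finite values")
        object.__setattr__(self, "centroids", c)

    @property
    def k(self) -> int:
        return int(self.centroids.shape[0])


def _stack_descriptors(descriptors) -> np.ndarray:
    arr = np.asarray(descriptors, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != DESCRIPTOR_DIM:
        raise ValueError(
            f"expected an (n, {DESCRIPTOR_DIM}) descriptor array, got {arr.shape}"
        )
    return arr


def build_codebook(
    descriptors,
    k: int = DEFAULT_CODEBOOK_SIZE,
    seed: int = 0,
    max_train_descriptors: int = MAX_TRAIN_DESCRIPTORS,
) -> Codebook:
    """Cluster descriptors into ``k`` codewords with k-means.

    k-means++ initialization, up to 300 iterations, best of 3 restarts by
    within-cluster sum of squares; deterministic for a fixed seed.  When
    more than ``max_train_descriptors`` descriptors are supplied a seeded
    uniform subsample bounds the clustering cost.
    """
    X = _stack_descriptors(descriptors)
    if X.shape[0] < k:
        raise ValueError(
            f"need at least k={k} descriptors to build the codebook, "
            f"got {X.shape[0]}"
        )
    if X.shape[0] > max_train_descriptors:
        rng = np.random.default_rng(seed)
        idx = rng.choice(X.shape[0], size=max_train_descriptors, replace=False)
        X = X[np.sort(idx)]
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=3,
        max_iter=300,
        random_state=seed,
    ).fit(X)
    return Codebook(centroids=km.cluster_centers_, seed=seed)


def assign_codewords(descriptors: np.ndarray, cb: Codebook) -> np.ndarray:
    """Nearest-centroid index (Euclidean) per descriptor; ties -> lowest index."""
    X = _stack_descriptors(descriptors)
    C = cb.centroids
    c2 = np.einsum("ij,ij->i", C, C)
    out = np.empty(X.shape[0], dtype=np.intp)
    for lo in range(0, X.shape[0], 4096):
        chunk = X[lo : lo + 4096]
        d2 = c2[None, :] - 2.0 * chunk @ C.T  # + ||x||^2, constant per row
        out[lo : lo + 4096] = np.argmin(d2, axis=1)
    return out


def encode(descriptors, cb: Codebook) -> np.ndarray:
    """Flat bag-of-features histogram: codeword counts, L1-normalized."""
    X = _stack_descriptors(descriptors)
    if X.shape[0] == 0:
        raise ValueError("no features extracted: cannot encode an empty image")
    counts = np.bincount(assign_codewords(X, cb), minlength=cb.k).astype(float)
    return counts / counts.sum()


def encode_pyramid(
    features: list[tuple[Keypoint, np.ndarray]],
    cb: Codebook,
    levels: int = 2,
    image_size: tuple[int, int] | None = None,
) -> np.ndarray:
    """Spatial-pyramid bag of features.

    Level ``l`` (0-based) partitions the image into ``2^l x 2^l`` cells;
    each cell histogram is L1-normalized, weighted by the pyramid-match
    weight ``1 / 2^(L - l)`` (level 0 halved to ``1 / 2^L``), and the
    concatenation over all cells of all levels is L1-normalized.
    ``levels=1`` reduces exactly to the flat encoding.
    """
    if levels < 1:
        raise ValueError(f"levels must be >= 1, got {levels}")
    if not features:
        raise ValueError("no features extracted: cannot encode an empty image")
    keypoints, descs = zip(*features)
    X = _stack_descriptors(list(descs))
    if image_size is None:
        h = max(kp.y for kp in keypoints) + 1.0
        w = max(kp.x for kp in keypoints) + 1.0
    else:
        h, w = float(image_size[0]), float(image_size[1])
    words = assign_codewords(X, cb)
    xs = np.array([kp.x for kp in keypoints])
    ys = np.array([kp.y for kp in keypoints])

    blocks: list[np.ndarray] = []
    L = levels - 1
    for level in range(levels):
        n = 2**level
        ci = np.minimum((xs / w * n).astype(int), n - 1)
        ri = np.minimum((ys / h * n).astype(int), n - 1)
        weight = 1.0 / 2.0**L if level == 0 else 1.0 / 2.0 ** (L - level + 1)
        for r in range(n):
            for c in range(n):
                sel = (ri == r) & (ci == c)
                counts = np.bincount(words[sel], minlength=cb.k).astype(float)
                total = counts.sum()
                if total > 0:
                    counts /= total
                blocks.append(weight * counts)
    vec = np.concatenate(blocks)
    return vec / vec.sum()


# ---------------------------------------------------------------------------
# text serialization
# ---------------------------------------------------------------------------

_CB_HEADER = "#histosift-cb v1"


def save_codebook(cb: Codebook, path: str | Path) -> None:
    """Write a codebook as text: header, k, seed, then k centroid lines."""
    lines = [_CB_HEADER, str(cb.k), str(cb.seed)]
    lines += [" ".join(f"{v:.17g}" for v in row) for row in cb.centroids]
    Path(path).write_text("\n".join(lines) + "\n")


def load_codebook(path: str | Path) -> Codebook:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _CB_HEADER:
        raise ValueError(f"{path}: not a histosift codebook file")
    k = int(lines[1])
    seed = int(lines[2])
    rows = [np.array(ln.split(), dtype=float) for ln in lines[3 : 3 + k]]
    return Codebook(centroids=np.vstack(rows), seed=seed)
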