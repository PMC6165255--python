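"""Kernel-SVM classification of bag-of-features histograms.

Two kernels are supported: the Gaussian RBF,
``K(a, b) = exp(-gamma * ||a - b||^2)`` with the operating width
gamma = 0.004, and the histogram intersection kernel,
``K(a, b) = sum_i min(a_i, b_i)``, a positive semi-definite kernel
well suited to L1-normalized histograms.  Multiclass problems use the
one-vs-one scheme.  The estimator itself lives in
:class:`histosift.estimators.HistogramKernelSVC`; the functions here are
the thin procedural face over it plus model serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "KernelSpec",
    "kernel_value",
    "gram_matrix",
    "train",
    "predict",
    "save_model",
    "load_model",
]

KERNEL_KINDS = ("rbf", "histogram_intersection")


@dataclass(frozen=True)
class KernelSpec:
    """SVM kernel choice and its parameters."""

    kind: str = "rbf"
    gamma: float = 0.004
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"kernel kind must be one of {KERNEL_KINDS}, got {self.kind!r}")
        if self.kind == "rbf" and not self.gamma > 0:
            raise ValueError(f"gamma must be > 0 for rbf, got {self.gamma}")
        if not self.C > 0:
            raise ValueError(f"C must be > 0, got {self.C}")


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[-1] != b.shape[-1]:
        raise ValueError(f"histogram length mismatch: {a.shape[-1]} vs {b.shape[-1]}")
    return a, b


def kernel_value(a, b, spec: KernelSpec) -> float:
    """Scalar kernel between two histograms."""
    a, b = _check_pair(np.ravel(a), np.ravel(b))
    if spec.kind == "rbf":
        d = a - b
        return float(np.exp(-spec.gamma * float(d @ d)))
    return float(np.minimum(a, b).sum())


def gram_matrix(A, B, spec: KernelSpec) -> np.ndarray:
    """Kernel matrix K[i, j] = K(A[i], B[j]) for row-wise histogram sets."""
    A, B = _check_pair(np.atleast_2d(A), np.atleast_2d(B))
    if spec.kind == "rbf":
        a2 = np.einsum("ij,ij->i", A, A)
        b2 = np.einsum("ij,ij->i", B, B)
        d2 = np.maximum(a2[:, None] + b2[None, :] - 2.0 * A @ B.T, 0.0)
        return np.exp(-spec.gamma * d2)
    # intersection: sum of elementwise minima, chunked to bound memory
    out = np.empty((A.shape[0], B.shape[0]))
    for i in range(A.shape[0]):
        out[i] = np.minimum(A[i][None, :], B).sum(axis=1)
    return out


def train(histograms, labels, spec: KernelSpec = KernelSpec(), seed: int = 0):
    """Fit a one-vs-one kernel SVM; returns a fitted HistogramKernelSVC."""
    from .estimators import HistogramKernelSVC

    clf = HistogramKernelSVC(
        kernel=spec.kind, gamma=spec.gamma, C=spec.C, random_state=seed
    )
    return clf.fit(np.atleast_2d(np.asarray(histograms, dtype=float)), labels)


def predict(model, hist) -> tuple[object, np.ndarray]:
    """Predict one histogram; returns (label, per-class decision scores)."""
    h = np.atleast_2d(np.asarray(hist, dtype=float))
    labels = model.predict(h)
    scores = model.decision_scores(h)
    return labels[0], scores[0]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

MODEL_HEADER = "histosift-model v1"


def save_model(model, path: str | Path, codebook_hash: str | None = None) -> None:
    """Archive a fitted model: kernel spec, labels, training arrays.

    The archive stores the exact training histograms and labels together
    with the kernel specification and seed; loading refits the SVM, which
    is deterministic, so the round-tripped model predicts identically.
    """
    meta = {
        "header": MODEL_HEADER,
        "kernel": model.kernel,
        "gamma": model.gamma,
        "C": model.C,
        "random_state": model.random_state,
        "codebook_hash": codebook_hash,
    }
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        X=model.X_fit_,
        y=np.asarray(model.y_fit_),
    )


def load_model(path: str | Path):
    from .estimators import HistogramKernelSVC

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        if meta.get("header") != MODEL_HEADER:
            raise ValueError(f"{path}: not a histosift model archive")
        X = z["X"]
        y = z["y"]
    clf = HistogramKernelSVC(
        kernel=meta["kernel"],
        gamma=meta["gamma"],
        C=meta["C"],
        random_state=meta["random_state"],
    )
    clf.fit(X, y)
    clf.codebook_hash_ = meta.get("codebook_hash")
    return clf
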