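"""Scikit-learn-style estimators composing the classification pipeline.

* :class:`SiftTransformer` — stateless image -> SIFT feature transformer.
* :class:`BagOfFeaturesEncoder` — ``fit`` learns the k-means codebook,
  ``transform`` produces L1-normalized (optionally spatial-pyramid)
  bag-of-features histograms.
* :class:`HistogramKernelSVC` — one-vs-one SVM over histograms with an
  RBF or histogram-intersection kernel.
* :class:`HistoSiftPipeline` — the full image-tile classifier
  (SIFT -> bag of features -> kernel SVM) behind a single fit/predict.

All estimators follow sklearn conventions (``get_params``/``set_params``,
fitted attributes with trailing underscores) and compose with sklearn
model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from . import encoding
from .classify import KernelSpec, gram_matrix
from .sift import SiftParams, extract_features
from .utils import derive_seed

__all__ = [
    "SiftTransformer",
    "BagOfFeaturesEncoder",
    "HistogramKernelSVC",
    "HistoSiftPipeline",
]


class SiftTransformer(TransformerMixin, BaseEstimator):
    """Map grayscale images to lists of (keypoint, descriptor) pairs.

    Stateless: ``fit`` is a no-op; all behavior is set by the detector
    parameters (see :class:`histosift.sift.SiftParams`).
    """

    def __init__(
        self,
        sigma0: float = 1.7,
        contrast_threshold: float = 0.04,
        edge_threshold: float = 11.0,
        n_octaves: int | None = None,
        intervals_per_octave: int = 3,
        upsample_first_octave: bool = False,
    ):
        self.sigma0 = sigma0
        self.contrast_threshold = contrast_threshold
        self.edge_threshold = edge_threshold
        self.n_octaves = n_octaves
        self.intervals_per_octave = intervals_per_octave
        self.upsample_first_octave = upsample_first_octave

    def _params(self) -> SiftParams:
        return SiftParams(
            sigma0=self.sigma0,
            contrast_threshold=self.contrast_threshold,
            edge_threshold=self.edge_threshold,
            n_octaves=self.n_octaves,
            intervals_per_octave=self.intervals_per_octave,
            upsample_first_octave=self.upsample_first_octave,
        )

    def fit(self, X=None, y=None):
        self.is_fitted_ = True
        return self

    def transform(self, X):
        p = self._params()
        return [extract_features(img, p) for img in X]


def _descriptor_matrix(item) -> np.ndarray:
    """Accept either a raw (n, 128) array or a list of (kp, desc) pairs."""
    if isinstance(item, np.ndarray):
        return item
    if len(item) == 0:
        return np.empty((0, encoding.DESCRIPTOR_DIM))
    return np.vstack([d for _, d in item])


class BagOfFeaturesEncoder(TransformerMixin, BaseEstimator):
    """Learn a codebook (fit) and encode images as BoF histograms (transform).

    Parameters
    ----------
    k : codebook size (number of k-means centroids).
    levels : spatial-pyramid levels; 1 gives the flat encoding.
    image_shape : (h, w) used to place keypoints into pyramid cells;
        required only for ``levels > 1`` with raw descriptor input absent.
    random_state : seed for k-means (k-means++, best of 3 restarts).
    max_train_descriptors : cap on descriptors used for clustering
        (seeded uniform subsample beyond it).
    """

    def __init__(
        self,
        k: int = encoding.DEFAULT_CODEBOOK_SIZE,
        levels: int = 1,
        image_shape: tuple[int, int] | None = None,
        random_state: int = 0,
        max_train_descriptors: int = encoding.MAX_TRAIN_DESCRIPTORS,
    ):
        self.k = k
        self.levels = levels
        self.image_shape = image_shape
        self.random_state = random_state
        self.max_train_descriptors = max_train_descriptors

    def fit(self, X, y=None):
        """X: sequence of per-image feature lists or descriptor arrays."""
        descs = [_descriptor_matrix(item) for item in X]
        stacked = (
            np.vstack([d for d in descs if d.size])
            if any(d.size for d in descs)
            else np.empty((0, encoding.DESCRIPTOR_DIM))
        )
        self.codebook_ = encoding.build_codebook(
            stacked,
            k=self.k,
            seed=self.random_state,
            max_train_descriptors=self.max_train_descriptors,
        )
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "codebook_")
        rows = []
        for item in X:
            if self.levels == 1:
                rows.append(encoding.encode(_descriptor_matrix(item), self.codebook_))
            else:
                if isinstance(item, np.ndarray):
                    raise ValueError(
                        "pyramid encoding needs keypoint coordinates; pass "
                        "(keypoint, descriptor) feature lists, not raw arrays"
                    )
                rows.append(
                    encoding.encode_pyramid(
                        item,
                        self.codebook_,
                        levels=self.levels,
                        image_size=self.image_shape,
                    )
                )
        return np.vstack(rows)


class HistogramKernelSVC(ClassifierMixin, BaseEstimator):
    """One-vs-one SVM over histograms with an RBF or intersection kernel.

    The histogram-intersection kernel is supplied to the SVM as a
    precomputed Gram matrix; the fitted model keeps its training
    histograms so prediction can compute the kernel row against them.
    """

    def __init__(
        self,
        kernel: str = "rbf",
        gamma: float = 0.004,
        C: float = 1.0,
        random_state: int = 0,
    ):
        self.kernel = kernel
        self.gamma = gamma
        self.C = C
        self.random_state = random_state

    def _spec(self) -> KernelSpec:
        return KernelSpec(kind=self.kernel, gamma=self.gamma, C=self.C)

    def fit(self, X, y):
        spec = self._spec()  # validates kernel/gamma/C
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if y.dtype == object:  # e.g. pandas string columns; keep archivable
            y = y.astype(str)
        if X.ndim != 2:
            raise ValueError(f"X must be 2-D (n_samples, n_bins), got {X.shape}")
        if X.shape[0] != y.shape[0]:
            raise ValueError(f"{X.shape[0]} histograms but {y.shape[0]} labels")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("need at least 2 classes to train")
        for cls, n in zip(classes, counts):
            if n < 2:
                raise ValueError(f"class {cls} has only {n} example(s); need >= 2")
        self.X_fit_ = X.copy()
        self.y_fit_ = y.copy()
        if spec.kind == "rbf":
            self._svc = SVC(
                kernel="rbf", gamma=spec.gamma, C=spec.C,
                random_state=self.random_state,
            )
            self._svc.fit(X, y)
        else:
            self._svc = SVC(
                kernel="precomputed", C=spec.C, random_state=self.random_state
            )
            self._svc.fit(gram_matrix(X, X, spec), y)
        self.classes_ = self._svc.classes_
        return self

    def _test_kernel(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.X_fit_.shape[1]:
            raise ValueError(
                f"histogram length {X.shape[1]} does not match training "
                f"dimensionality {self.X_fit_.shape[1]}"
            )
        if self.kernel == "rbf":
            return X
        return gram_matrix(X, self.X_fit_, self._spec())

    def predict(self, X):
        check_is_fitted(self, "classes_")
        return self._svc.predict(self._test_kernel(X))

    def decision_scores(self, X) -> np.ndarray:
        """Per-class aggregated one-vs-rest decision values, (n, n_classes)."""
        check_is_fitted(self, "classes_")
        d = self._svc.decision_function(self._test_kernel(X))
        if d.ndim == 1:  # binary: positive favors classes_[1]
            d = np.column_stack([-d, d])
        return d

    def decision_function(self, X):
        return self.decision_scores(X)


class HistoSiftPipeline(ClassifierMixin, BaseEstimator):
    """End-to-end tile classifier: SIFT -> bag of features -> kernel SVM.

    ``fit`` takes a sequence of grayscale images in [0, 1] plus labels;
    the codebook is learned on the training descriptors only.  Seeds for
    clustering and the SVM are derived from ``random_state`` via named
    substreams.
    """

    def __init__(
        self,
        sigma0: float = 1.7,
        contrast_threshold: float = 0.04,
        edge_threshold: float = 11.0,
        n_octaves: int | None = None,
        intervals_per_octave: int = 3,
        upsample_first_octave: bool = False,
        k: int = encoding.DEFAULT_CODEBOOK_SIZE,
        levels: int = 1,
        kernel: str = "rbf",
        gamma: float = 0.004,
        C: float = 1.0,
        random_state: int = 0,
        max_train_descriptors: int = encoding.MAX_TRAIN_DESCRIPTORS,
    ):
        self.sigma0 = sigma0
        self.contrast_threshold = contrast_threshold
        self.edge_threshold = edge_threshold
        self.n_octaves = n_octaves
        self.intervals_per_octave = intervals_per_octave
        self.upsample_first_octave = upsample_first_octave
        self.k = k
        self.levels = levels
        self.kernel = kernel
        self.gamma = gamma
        self.C = C
        self.random_state = random_state
        self.max_train_descriptors = max_train_descriptors

    # -- stages, reusable with precomputed features ---------------------

    def extract(self, images):
        """Run SIFT on each image; returns per-image feature lists."""
        return SiftTransformer(
            sigma0=self.sigma0,
            contrast_threshold=self.contrast_threshold,
            edge_threshold=self.edge_threshold,
            n_octaves=self.n_octaves,
            intervals_per_octave=self.intervals_per_octave,
            upsample_first_octave=self.upsample_first_octave,
        ).transform(images)

    def fit_from_features(self, features, y, image_shape=None):
        empty = [i for i, f in enumerate(features) if len(f) == 0]
        if empty:
            raise ValueError(f"no features extracted from image(s) {empty}")
        self.encoder_ = BagOfFeaturesEncoder(
            k=self.k,
            levels=self.levels,
            image_shape=image_shape,
            random_state=derive_seed(self.random_state, "codebook"),
            max_train_descriptors=self.max_train_descriptors,
        ).fit(features)
        H = self.encoder_.transform(features)
        self.classifier_ = HistogramKernelSVC(
            kernel=self.kernel,
            gamma=self.gamma,
            C=self.C,
            random_state=derive_seed(self.random_state, "svm"),
        ).fit(H, y)
        self.classes_ = self.classifier_.classes_
        return self

    def predict_from_features(self, features):
        check_is_fitted(self, "classifier_")
        return self.classifier_.predict(self.encoder_.transform(features))

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y):
        shape = X[0].shape if len(X) else None
        return self.fit_from_features(self.extract(X), y, image_shape=shape)

    def predict(self, X):
        return self.predict_from_features(self.extract(X))

    def decision_scores(self, X) -> np.ndarray:
        check_is_fitted(self, "classifier_")
        return self.classifier_.decision_scores(
            self.encoder_.transform(self.extract(X))
        )

    @property
    def codebook_(self):
        check_is_fitted(self, "encoder_")
        return self.encoder_.codebook_
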