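"""Reusable evaluation protocols over the synthetic study conditions.

These functions bundle the full study design — seeded synthetic data,
train/held-out separation, pipeline fitting, and tile-, patient- and
section-level scoring — so that scripts and tests exercise one code
path.  Problem sizes default to 50 tiles per class (40 used for
training, 10 held out), a scale at which the five default texture
classes are reliably separable while a full run stays in the minutes
range on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .estimators import HistoSiftPipeline
from .evaluate import (
    EvaluationReport,
    PatientRecord,
    confusion_and_weighted_metrics,
    majority_vote,
    recognition_rate,
)
from .sift import SiftParams, extract_features
from .synthetic import default_class_specs, generate_dataset
from .utils import derive_seed

__all__ = [
    "EndToEndResult",
    "run_end_to_end",
    "repeated_trials",
    "rotation_match_rate",
    "downscale_recovery_rate",
]


@dataclass
class EndToEndResult:
    """Held-out performance of one end-to-end pipeline run."""

    accuracy: float
    report: EvaluationReport
    recognition_rate: float
    n_patients: int
    sections_correct: int
    n_sections: int
    n_train: int
    n_test: int
    predicted: list
    actual: list


def _train_test_indices(labels, train_per_class: int, seed: int):
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(labels):
        idx = np.where(labels == cls)[0]
        perm = rng.permutation(len(idx))
        train.extend(idx[perm[:train_per_class]])
        test.extend(idx[perm[train_per_class:]])
    return np.sort(train), np.sort(test)


def run_end_to_end(
    master_seed: int = 0,
    images_per_class: int = 50,
    train_per_class: int = 40,
    jitter: bool = True,
    kernel: str = "histogram_intersection",
    k: int = 500,
    features=None,
    dataset=None,
) -> EndToEndResult:
    """Generate data, fit the pipeline, and score the held-out tiles.

    ``jitter=False`` disables the within-class global scale jitter,
    isolating its effect on accuracy.  Precomputed ``features`` and
    ``dataset`` (from a previous call with the same seed and jitter
    setting) may be passed to avoid re-extracting.
    """
    if dataset is None:
        specs = default_class_specs()
        if not jitter:
            specs = [replace(s, scale_jitter=(1.0, 1.0)) for s in specs]
        dataset = generate_dataset(
            specs, images_per_class, derive_seed(master_seed, "dataset")
        )
    labels = np.asarray(dataset.labels)
    if features is None:
        features = [extract_features(img, SiftParams()) for img in dataset.images]
    tr, te = _train_test_indices(labels, train_per_class, derive_seed(master_seed, "split"))

    pipe = HistoSiftPipeline(
        k=k, kernel=kernel, random_state=derive_seed(master_seed, "fit")
    )
    pipe.fit_from_features(
        [features[i] for i in tr], labels[tr],
        image_shape=dataset.images[0].shape,
    )
    pred = pipe.predict_from_features([features[i] for i in te])
    actual = labels[te]
    report = confusion_and_weighted_metrics(list(actual), list(pred))

    correct = pred == actual
    patients: dict[str, list[bool]] = {}
    sections: dict[str, tuple[list, str]] = {}
    for j, i in enumerate(te):
        patients.setdefault(dataset.patient_ids[i], []).append(bool(correct[j]))
        sections.setdefault(dataset.section_ids[i], ([], labels[i]))[0].append(pred[j])
    records = [
        PatientRecord(pid, len(hits), int(sum(hits))) for pid, hits in patients.items()
    ]
    sec_correct = sum(
        majority_vote(votes)[0] == truth for votes, truth in sections.values()
    )
    return EndToEndResult(
        accuracy=float(np.mean(correct)),
        report=report,
        recognition_rate=recognition_rate(records),
        n_patients=len(records),
        sections_correct=int(sec_correct),
        n_sections=len(sections),
        n_train=len(tr),
        n_test=len(te),
        predicted=list(pred),
        actual=list(actual),
    )


def repeated_trials(
    n_trials: int = 10,
    master_seed: int = 0,
    images_per_class: int = 50,
    train_per_class: int = 40,
    kernels: tuple[str, ...] = ("histogram_intersection", "rbf"),
    k: int = 500,
    features=None,
    dataset=None,
) -> dict[str, list[EvaluationReport]]:
    """Repeated random-split trials, re-splitting each trial.

    Features are extracted once; each trial draws a fresh train/held-out
    split, refits the codebook on that trial's training tiles only, and
    fits one model per kernel on identical histograms — a paired design
    for comparing the kernels across trials.
    """
    from .estimators import BagOfFeaturesEncoder, HistogramKernelSVC

    if dataset is None:
        dataset = generate_dataset(
            default_class_specs(), images_per_class, derive_seed(master_seed, "dataset")
        )
    labels = np.asarray(dataset.labels)
    if features is None:
        features = [extract_features(img, SiftParams()) for img in dataset.images]
    out: dict[str, list[EvaluationReport]] = {kern: [] for kern in kernels}
    for t in range(n_trials):
        seed_t = derive_seed(master_seed, "trial", t)
        tr, te = _train_test_indices(
            labels, train_per_class, derive_seed(seed_t, "split")
        )
        enc = BagOfFeaturesEncoder(
            k=k, random_state=derive_seed(seed_t, "codebook")
        ).fit([features[i] for i in tr])
        H_tr = enc.transform([features[i] for i in tr])
        H_te = enc.transform([features[i] for i in te])
        for kern in kernels:
            clf = HistogramKernelSVC(
                kernel=kern, random_state=derive_seed(seed_t, "svm")
            ).fit(H_tr, labels[tr])
            pred = clf.predict(H_te)
            out[kern].append(
                confusion_and_weighted_metrics(list(labels[te]), list(pred))
            )
    return out


# ---------------------------------------------------------------------------
# invariance measurements
# ---------------------------------------------------------------------------


def rotation_match_rate(
    images, params: SiftParams | None = None, cosine_threshold: float = 0.9
) -> tuple[float, float]:
    """Descriptor agreement between each image and its 90-degree rotation.

    Keypoints of the rotated image are mapped back onto the original
    frame; a keypoint matches when a counterpart lies within 1.5 px at a
    compatible scale (within one interval factor).  Returns
    ``(fraction of keypoints matched, fraction of matches with
    descriptor cosine >= threshold)`` pooled over the images.
    """
    params = params or SiftParams()
    k_tol = params.k * 1.001
    matched = good = total = 0
    for img in images:
        feats = extract_features(img, params)
        rot = np.ascontiguousarray(np.rot90(img))
        feats_r = extract_features(rot, params)
        if not feats or not feats_r:
            continue
        w = img.shape[1]
        back = np.array([[w - 1 - kp.y, kp.x, kp.sigma] for kp, _ in feats_r])
        descs_r = [d for _, d in feats_r]
        total += len(feats)
        for kp, d in feats:
            d2 = (back[:, 0] - kp.x) ** 2 + (back[:, 1] - kp.y) ** 2
            scale_ok = np.maximum(back[:, 2] / kp.sigma, kp.sigma / back[:, 2]) <= k_tol
            ok = np.where((d2 <= 1.5**2) & scale_ok)[0]
            if ok.size == 0:
                continue
            matched += 1
            best = max(float(d @ descs_r[j]) for j in ok)
            good += best >= cosine_threshold
    if matched == 0:
        return 0.0, 0.0
    return matched / total, good / matched


def downscale_recovery_rate(images, params: SiftParams | None = None) -> float:
    """Fraction of keypoints recovered after 2x downscaling.

    A keypoint (x, y, sigma) is recovered when the half-size image
    contains a keypoint within 2 px of (x/2, y/2) at scale within one
    interval factor of sigma/2.  Only keypoints whose halved scale stays
    inside the pyramid's detectable band (sigma/2 >= sigma0 * sqrt(k))
    are counted: finer keypoints fall below the base of the scale space
    after halving and are unrecoverable by construction, for any
    detector built on the same pyramid.  Pooled over the images.
    """
    from skimage.transform import rescale

    params = params or SiftParams()
    k_tol = params.k * 1.001
    floor = params.sigma0 * params.k**0.5
    recovered = total = 0
    for img in images:
        feats = extract_features(img, params)
        small = np.clip(rescale(img, 0.5, anti_aliasing=True), 0.0, 1.0)
        feats_s = extract_features(small, params)
        if not feats or not feats_s:
            continue
        pts = np.array([[kp.x, kp.y, kp.sigma] for kp, _ in feats_s])
        for kp, _ in feats:
            x, y, s = kp.x / 2, kp.y / 2, kp.sigma / 2
            if s < floor:
                continue
            total += 1
            d2 = (pts[:, 0] - x) ** 2 + (pts[:, 1] - y) ** 2
            scale_ok = np.maximum(pts[:, 2] / s, s / pts[:, 2]) <= k_tol
            recovered += bool(np.any((d2 <= 4.0) & scale_ok))
    return recovered / total if total else 0.0
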