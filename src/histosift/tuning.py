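"""One-axis-at-a-time hyper-parameter tuning on a validation set.

The protocol sweeps one parameter axis at a time in a fixed order —
Gaussian base width sigma0, then contrast threshold, then edge
threshold, then codebook size — scoring each grid value by the mean
accuracy over repeated random sub-splits of the validation images
(a 150/61-style ~71/29 train/score split).  After each axis the best
value is frozen before the next axis is swept.  A full-factorial sweep
is available behind ``factorial=True``.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .estimators import HistoSiftPipeline
from .io import RunConfig
from .utils import derive_seed

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_GRIDS", "tune_grid"]

# grid values swept for each axis, in sweep order
DEFAULT_GRIDS: dict[str, list] = {
    "sigma0": [0.1, 0.5, 0.9, 1.3, 1.7, 2.1],
    "contrast_threshold": [0.02, 0.03, 0.04, 0.05, 0.06],
    "edge_threshold": [5, 11, 17, 23, 29],
    "codebook_k": [300, 400, 500, 600, 700],
}

# fraction of the validation images used for fitting in each sub-split
# (150 of 211 in the reference protocol)
SUBSPLIT_TRAIN_FRACTION = 150 / 211


def _pipeline_from_config(config: RunConfig, **overrides) -> HistoSiftPipeline:
    s = config.sift
    kwargs = dict(
        sigma0=s.sigma0,
        contrast_threshold=s.contrast_threshold,
        edge_threshold=s.edge_threshold,
        n_octaves=s.n_octaves,
        intervals_per_octave=s.intervals_per_octave,
        upsample_first_octave=s.upsample_first_octave,
        k=config.codebook_k,
        levels=config.levels,
        kernel=config.kernel,
        gamma=config.gamma,
        C=config.C,
    )
    kwargs.update(overrides)
    return HistoSiftPipeline(**kwargs)


def _subsplit_accuracy(
    images, labels, pipeline: HistoSiftPipeline, seed: int
) -> float:
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    idx = rng.permutation(len(images))
    n_train = max(int(round(SUBSPLIT_TRAIN_FRACTION * len(images))), 1)
    # keep at least one scoring image
    n_train = min(n_train, len(images) - 1)
    tr, te = idx[:n_train], idx[n_train:]
    if len(set(labels[tr])) < 2:
        raise ValueError("sub-split left fewer than 2 classes in training")
    # harsh grid values can strip an image of every feature; such images
    # are dropped from training and scored as errors at test time, so a
    # bad cell scores low instead of aborting the sweep
    f_tr = pipeline.extract([images[i] for i in tr])
    keep = [i for i, f in enumerate(f_tr) if len(f) > 0]
    if len(keep) < len(f_tr):
        logger.warning(
            "%d training image(s) yielded no features; dropped", len(f_tr) - len(keep)
        )
    pipeline.fit_from_features(
        [f_tr[i] for i in keep], labels[tr][keep], image_shape=images[0].shape
    )
    f_te = pipeline.extract([images[i] for i in te])
    correct = 0
    for f, truth in zip(f_te, labels[te]):
        if len(f) == 0:
            continue  # unscorable image counts as an error
        correct += pipeline.predict_from_features([f])[0] == truth
    return float(correct / len(te))


def tune_grid(
    config: RunConfig,
    images,
    labels,
    grids: dict[str, list] | None = None,
    repeats: int | None = None,
    factorial: bool = False,
) -> tuple[pd.DataFrame, RunConfig]:
    """Sweep the tuning grids; returns (result table, tuned RunConfig).

    The table has one row per evaluated cell with columns ``axis``,
    ``value``, ``mean_accuracy``, ``n_repeats`` and ``selected``.
    Grid values are validated against parameter invariants before any
    computation starts.
    """
    grids = dict(DEFAULT_GRIDS) if grids is None else dict(grids)
    repeats = config.trials if repeats is None else repeats
    if len(images) == 0:
        raise ValueError("validation manifest is empty")

    # validate every grid value up front
    for axis, values in grids.items():
        for v in values:
            if axis == "codebook_k":
                if int(v) < 2:
                    raise ValueError(f"codebook_k grid value {v} invalid (k >= 2)")
            else:
                replace(config.sift, **{axis: v})

    current = config
    rows = []
    if factorial:
        axes = list(grids)

        def _walk(i, overrides):
            if i == len(axes):
                yield dict(overrides)
                return
            for v in grids[axes[i]]:
                overrides[axes[i]] = v
                yield from _walk(i + 1, overrides)

        for cell in _walk(0, {}):
            accs = _cell_accuracies(config, images, labels, cell, repeats)
            rows.append(
                {"axis": "factorial", "value": str(cell),
                 "mean_accuracy": float(np.mean(accs)), "n_repeats": repeats,
                 "selected": False}
            )
        table = pd.DataFrame(rows)
        best = table.loc[table["mean_accuracy"].idxmax()]
        table.loc[best.name, "selected"] = True
        return table, current

    for axis in ("sigma0", "contrast_threshold", "edge_threshold", "codebook_k"):
        if axis not in grids:
            continue
        cell_means = []
        for v in grids[axis]:
            accs = _cell_accuracies(current, images, labels, {axis: v}, repeats)
            cell_means.append(float(np.mean(accs)))
            rows.append(
                {"axis": axis, "value": v, "mean_accuracy": cell_means[-1],
                 "n_repeats": repeats, "accuracies": tuple(accs),
                 "selected": False}
            )
        best_value = grids[axis][int(np.argmax(cell_means))]
        rows[-len(grids[axis]) + int(np.argmax(cell_means))]["selected"] = True
        logger.info("axis %s: best value %s", axis, best_value)
        if axis == "codebook_k":
            current = replace(current, codebook_k=int(best_value))
        else:
            current = replace(current, sift=replace(current.sift, **{axis: best_value}))
    return pd.DataFrame(rows), current


def _cell_accuracies(config, images, labels, overrides: dict, repeats: int):
    sift_over = {k: v for k, v in overrides.items() if k != "codebook_k"}
    pipe_over: dict = {}
    if sift_over:
        pipe_over.update(sift_over)
    if "codebook_k" in overrides:
        pipe_over["k"] = int(overrides["codebook_k"])
    accs = []
    for rep in range(repeats):
        seed = derive_seed(config.master_seed, "tune-subsplit", rep)
        pipeline = _pipeline_from_config(
            config, random_state=derive_seed(config.master_seed, "tune-fit", rep),
            **pipe_over,
        )
        accs.append(_subsplit_accuracy(images, labels, pipeline, seed))
    return accs
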