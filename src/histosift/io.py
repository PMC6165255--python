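"""Image/manifest I/O, run configuration, and dataset splitting."""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageOps, UnidentifiedImageError

from .sift import Keypoint, SiftParams
from .utils import derive_seed

logger = logging.getLogger(__name__)

__all__ = [
    "load_image_as_gray",
    "load_manifest",
    "save_manifest",
    "stratified_split",
    "RunConfig",
    "write_keypoints",
    "read_keypoints",
]

# ITU-R BT.601 luminance weights for RGB -> gray
_BT601 = np.array([0.299, 0.587, 0.114])

MANIFEST_COLUMNS = ["path", "label", "patient_id", "section_id"]


def load_image_as_gray(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF/JPEG as a float grayscale array in [0, 1].

    8- and 16-bit integer inputs are rescaled by their full range; RGB is
    converted with BT.601 luminance; EXIF orientation is honored.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = ImageOps.exif_transpose(im)
            if im.mode in ("RGBA", "P", "LA"):
                im = im.convert("RGB")
            arr = np.asarray(im)
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise ValueError(f"cannot read image file {path}: {exc}") from exc
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype in (np.uint16, np.int32):  # PIL mode I;16 loads as int32
        scale = 65535.0
    else:
        raise ValueError(
            f"{path}: unsupported bit depth / dtype {arr.dtype}; "
            "expected 8- or 16-bit integer samples"
        )
    gray = arr.astype(np.float64) / scale
    if gray.ndim == 3:
        gray = gray @ _BT601
    return np.clip(gray, 0.0, 1.0)


# ---------------------------------------------------------------------------
# manifests and splits
# ---------------------------------------------------------------------------


def load_manifest(
    path: str | Path,
    class_set: list[str] | None = None,
    check_paths: bool = True,
) -> pd.DataFrame:
    """Read a delimited manifest (path, label[, patient_id[, section_id]])."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ("path", "label") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest lacks required column(s) {missing}")
    for col in ("patient_id", "section_id"):
        if col not in df.columns:
            df[col] = ""
    df = df[MANIFEST_COLUMNS].fillna("")
    if check_paths:
        root = path.parent
        resolved = [
            p if Path(p).is_absolute() else str(root / p) for p in df["path"]
        ]
        absent = [p for p in resolved if not Path(p).exists()]
        if absent:
            raise ValueError(f"manifest references missing file(s), e.g. {absent[0]}")
        df["path"] = resolved
    if class_set is not None:
        bad = sorted(set(df["label"]) - set(class_set))
        if bad:
            raise ValueError(f"manifest labels {bad} outside declared class set")
    return df


def save_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def stratified_split(
    manifest: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    patient_disjoint: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Random per-class split into (train, validation, test) manifests.

    Validation and test receive ``floor(frac * n)`` images per class
    (per patient group in patient-disjoint mode); the remainder goes to
    training.  Reproducible for a fixed seed; the three parts are
    disjoint and their union is the input.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    parts: list[list[pd.DataFrame]] = [[], [], []]
    for label, grp in manifest.groupby("label", sort=True):
        if len(grp) < 3:
            raise ValueError(
                f"class {label!r} has only {len(grp)} image(s); need >= 3 to split"
            )
        if patient_disjoint:
            units = [g for _, g in grp.groupby("patient_id", sort=True)]
        else:
            units = [grp.iloc[[i]] for i in range(len(grp))]
        order = rng.permutation(len(units))
        total = len(grp)
        # round the validation/test shares; leftovers go to training
        n_val = int(np.floor(fractions[1] * total + 0.5))
        n_test = int(np.floor(fractions[2] * total + 0.5))
        sizes = np.array([len(units[i]) for i in order])
        csum = np.cumsum(sizes)
        test_take = int(np.searchsorted(csum, n_test, side="left") + 1) if n_test else 0
        val_take = (
            int(np.searchsorted(csum[test_take:] - (csum[test_take - 1] if test_take else 0), n_val, side="left") + 1)
            if n_val
            else 0
        )
        chunks = [units[i] for i in order]
        test = chunks[:test_take]
        val = chunks[test_take : test_take + val_take]
        train = chunks[test_take + val_take :]
        for bucket, sel in zip(parts, (train, val, test)):
            if sel:
                bucket.append(pd.concat(sel))
    out = tuple(
        pd.concat(b).reset_index(drop=True) if b else manifest.iloc[0:0].copy()
        for b in parts
    )
    return out  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Split fractions default to the 623/211/209 proportions of a
    1043-image set; ``trials`` repeated random splits with seeds derived
    from ``master_seed`` via named substreams.
    """

    sift: SiftParams = field(default_factory=SiftParams)
    codebook_k: int = 500
    kernel: str = "rbf"
    gamma: float = 0.004
    C: float = 1.0
    levels: int = 1
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    trials: int = 10
    master_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.fractions}")
        if self.trials < 1:
            raise ValueError(f"trials must be >= 1, got {self.trials}")

    def seed_for(self, purpose: str, index: int = 0) -> int:
        return derive_seed(self.master_seed, purpose, index)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a key-value config file ([run] section, key = value)."""
        cp = configparser.ConfigParser()
        with open(path) as fh:
            cp.read_file(fh)
        sec = cp["run"] if cp.has_section("run") else cp[cp.default_section]
        sift_kwargs = {}
        for key, cast in (
            ("sigma0", float),
            ("contrast_threshold", float),
            ("edge_threshold", float),
            ("intervals_per_octave", int),
            ("n_octaves", int),
            ("upsample_first_octave", lambda v: v.lower() in ("1", "true", "yes")),
        ):
            if key in sec:
                sift_kwargs[key] = cast(sec[key])
        kwargs: dict = {"sift": SiftParams(**sift_kwargs)}
        for key, cast in (
            ("codebook_k", int),
            ("kernel", str),
            ("gamma", float),
            ("c", float),
            ("levels", int),
            ("trials", int),
            ("master_seed", int),
        ):
            if key in sec:
                kwargs["C" if key == "c" else key] = cast(sec[key])
        if "fractions" in sec:
            kwargs["fractions"] = tuple(
                float(v) for v in sec["fractions"].replace(",", " ").split()
            )
        return cls(**kwargs)

    def to_text(self) -> str:
        """Full resolved configuration, all defaults explicit."""
        s = self.sift
        lines = ["[run]"]
        for key, val in (
            ("sigma0", s.sigma0),
            ("contrast_threshold", s.contrast_threshold),
            ("edge_threshold", s.edge_threshold),
            ("intervals_per_octave", s.intervals_per_octave),
            ("n_octaves", "" if s.n_octaves is None else s.n_octaves),
            ("upsample_first_octave", s.upsample_first_octave),
            ("codebook_k", self.codebook_k),
            ("kernel", self.kernel),
            ("gamma", self.gamma),
            ("C", self.C),
            ("levels", self.levels),
            ("fractions", " ".join(str(f) for f in self.fractions)),
            ("trials", self.trials),
            ("master_seed", self.master_seed),
        ):
            if val != "":
                lines.append(f"{key} = {val}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# keypoint sidecar files
# ---------------------------------------------------------------------------

_KP_HEADER = "#histosift-kp v1"


def write_keypoints(
    features: list[tuple[Keypoint, np.ndarray]], path: str | Path
) -> None:
    """Tab-separated keypoints: x, y, sigma, orientation, response, 128 values."""
    lines = [_KP_HEADER]
    for kp, desc in features:
        head = [f"{kp.x:.4f}", f"{kp.y:.4f}", f"{kp.sigma:.4f}",
                f"{kp.orientation:.2f}", f"{kp.response:.6g}"]
        lines.append("\t".join(head + [f"{v:.6f}" for v in desc]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_keypoints(path: str | Path) -> list[tuple[Keypoint, np.ndarray]]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _KP_HEADER:
        raise ValueError(f"{path}: not a histosift keypoint file")
    out = []
    for ln in lines[1:]:
        vals = ln.split("\t")
        kp = Keypoint(
            x=float(vals[0]), y=float(vals[1]), octave=0, interval=0,
            sigma=float(vals[2]), orientation=float(vals[3]),
            response=float(vals[4]),
        )
        out.append((kp, np.array(vals[5:], dtype=float)))
    return out
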