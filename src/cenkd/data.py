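"""Dataset handling: image-folder ingestion, stratified splitting, and a
procedural six-class image generator.

The generator stands in for photographic datasets (the motivating task is a
six-class mosquito-species collection of ~3,600 images): each class is a
distinct parametric texture family — an oriented sinusoidal grating at a
class-specific angle and frequency with a random phase per image, overlaid
with a class-specific layout of Gaussian blobs and a subtle color tint —
plus additive Gaussian pixel noise.  At zero noise the classes are linearly
separable from raw pixels; raising the noise level degrades separability
smoothly, which is how test difficulty is controlled.

Splitting follows the Pareto 80/20 protocol, stratified per class with
round-half-up on the training side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp", ".gif", ".tif", ".tiff"}

#: published per-class train/validation counts of the six-class mosquito
#: photograph dataset (Park et al.) under the 80/20 protocol; kept as the
#: worked example for manifest summaries.
MOSQUITO_SPLIT_COUNTS = {
    "Non-Vector": (480, 120),
    "Aedes albopictus": (480, 120),
    "Aedes vexans": (473, 118),
    "Anopheles sinensis": (485, 108),
    "Culex pipiens": (420, 180),
    "Culex tritaeniorhynchus": (475, 119),
}


@dataclass(frozen=True)
class SynthSpec:
    """Conditions for the procedural generator.

    Defaults are the study conditions used throughout the test suite: six
    classes of 60 images at 32×32 with noise σ=0.075 (pixel units on [0, 1]),
    calibrated so a plainly trained compressed student sits noticeably below
    ceiling while the task stays learnable.
    """

    classes: int = 6
    per_class: int = 60
    image_size: int = 32
    noise: float = 0.075
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classes < 2 or self.per_class < 1 or self.image_size < 8:
            raise ValueError("invalid synthetic spec")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


@dataclass
class Sample:
    path: str
    label: int
    split: str = ""  # "train" | "validation" | ""


@dataclass
class DatasetManifest:
    """Class names, sample references and split assignment for one dataset."""

    classes: list[str]
    samples: list[Sample] = field(default_factory=list)
    image_size: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")

    def subset(self, split: str) -> list[Sample]:
        return [s for s in self.samples if s.split == split]

    def class_counts(self, split: str | None = None) -> list[int]:
        counts = [0] * len(self.classes)
        for s in self.samples:
            if split is None or s.split == split:
                counts[s.label] += 1
        return counts

    # -- persistence -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "path": [s.path for s in self.samples],
                "class": [self.classes[s.label] for s in self.samples],
                "split": [s.split for s in self.samples],
            }
        )

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path, image_size: int = 0, seed: int = 0) -> "DatasetManifest":
        df = pd.read_csv(path, keep_default_na=False)
        classes = sorted(df["class"].unique())
        index = {c: i for i, c in enumerate(classes)}
        samples = [
            Sample(p, index[c], sp)
            for p, c, sp in zip(df["path"], df["class"], df["split"])
        ]
        return cls(classes, samples, image_size=image_size, seed=seed)


# -- synthesis -------------------------------------------------------------


def _class_pattern(spec: SynthSpec, label: int,
                   rng: np.random.Generator) -> np.ndarray:
    """One noiseless image of a class; per-image randomness from ``rng``."""
    s = spec.image_size
    yy, xx = np.mgrid[0:s, 0:s] / s
    angle = np.pi * label / spec.classes
    freq = 3.0 + (label % 3)
    phase = rng.uniform(0, 2 * np.pi)
    grating = np.sin(2 * np.pi * freq * (np.cos(angle) * xx + np.sin(angle) * yy) + phase)

    # class-specific blob layout (fixed per class given the dataset seed)
    blob_rng = np.random.default_rng([spec.seed, 104729, label])
    blobs = np.zeros((s, s))
    for _ in range(3):
        cx, cy = blob_rng.uniform(0.2, 0.8, size=2)
        sigma = blob_rng.uniform(0.08, 0.15)
        blobs += np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2)))

    tint = np.array([
        0.9 + 0.1 * np.cos(2 * np.pi * label / spec.classes + k)
        for k in (0.0, 2.1, 4.2)
    ])
    img = 0.5 + 0.18 * grating[..., None] + 0.35 * blobs[..., None]
    img = img * tint
    img += rng.normal(0.0, spec.noise, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def synthesize_dataset(spec: SynthSpec, out_dir) -> DatasetManifest:
    """Generate the image folder and manifest; byte-identical per seed."""
    out = Path(out_dir)
    classes = [f"class_{c}" for c in range(spec.classes)]
    samples: list[Sample] = []
    for label, cname in enumerate(classes):
        cdir = out / cname
        cdir.mkdir(parents=True, exist_ok=True)
        for i in range(spec.per_class):
            rng = np.random.default_rng([spec.seed, label, i])
            img = _class_pattern(spec, label, rng)
            arr = (img * 255.0).round().astype(np.uint8)
            path = cdir / f"img_{i:04d}.png"
            Image.fromarray(arr).save(path)
            samples.append(Sample(str(path), label))
    return DatasetManifest(classes, samples, image_size=spec.image_size,
                           seed=spec.seed)


def split_dataset(manifest: DatasetManifest, train_fraction: float = 0.8,
                  seed: int = 0) -> DatasetManifest:
    """Per-class stratified train/validation split.

    The training count is ``round_half_up(fraction · class_total)``; the
    remainder goes to validation.  Assignment is shuffled by ``seed`` and is
    stable for a given manifest and seed.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng([seed, 15485863])
    by_class: dict[int, list[int]] = {i: [] for i in range(len(manifest.classes))}
    for idx, s in enumerate(manifest.samples):
        by_class[s.label].append(idx)
    new_samples = [replace(s) for s in manifest.samples]
    for label, indices in by_class.items():
        if len(indices) < 2:
            raise ValueError(
                f"class {manifest.classes[label]!r} has < 2 samples; cannot split"
            )
        n_train = int(np.floor(train_fraction * len(indices) + 0.5))
        order = rng.permutation(len(indices))
        for rank, pos in enumerate(order):
            new_samples[indices[pos]].split = (
                "train" if rank < n_train else "validation"
            )
    return DatasetManifest(manifest.classes, new_samples,
                           image_size=manifest.image_size, seed=seed)


def load_image_folder(path) -> DatasetManifest:
    """Build a manifest from one-subdirectory-per-class raster images.

    Classes are ordered lexicographically; files that are not readable
    images are skipped with a logged count.
    """
    root = Path(path)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories under {root}")
    classes = [d.name for d in class_dirs]
    samples: list[Sample] = []
    skipped = 0
    size = 0
    for label, cdir in enumerate(class_dirs):
        for f in sorted(cdir.iterdir()):
            if f.suffix.lower() not in IMAGE_EXTENSIONS:
                skipped += 1
                continue
            try:
                with Image.open(f) as im:
                    size = max(size, im.size[0])
            except Exception:
                skipped += 1
                continue
            samples.append(Sample(str(f), label))
    if skipped:
        logger.warning("skipped %d unreadable/non-image files under %s", skipped, root)
    if not samples:
        raise ValueError(f"no readable images under {root}")
    return DatasetManifest(classes, samples, image_size=size)


def load_arrays(manifest: DatasetManifest, split: str | None = None,
                image_size: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Load (X, y): NHWC float64 pixels in [0, 1] and integer labels."""
    samples = manifest.samples if split is None else manifest.subset(split)
    if not samples:
        raise ValueError(f"no samples in split {split!r}")
    size = image_size or manifest.image_size
    xs, ys = [], []
    for s in samples:
        with Image.open(s.path) as im:
            im = im.convert("RGB")
            if size and im.size != (size, size):
                im = im.resize((size, size), Image.BILINEAR)
            xs.append(np.asarray(im, dtype=np.float64) / 255.0)
        ys.append(s.label)
    return np.stack(xs), np.asarray(ys)


def manifest_summary(manifest: DatasetManifest | None = None,
                     counts: dict[str, tuple[int, int]] | None = None) -> pd.DataFrame:
    """Per-class train/validation/total table with a grand-total row.

    Either summarizes a manifest or tabulates explicit printed per-class
    ``(train, validation)`` counts (printed manifests are authoritative for
    published datasets whose splits deviate from the 80/20 rule).
    """
    if counts is None:
        if manifest is None:
            raise ValueError("need a manifest or explicit counts")
        train = manifest.class_counts("train")
        val = manifest.class_counts("validation")
        total = manifest.class_counts(None)
        names = manifest.classes
        rows = [
            {"class": n, "train": t, "validation": v, "total": tot}
            for n, t, v, tot in zip(names, train, val, total)
        ]
    else:
        rows = [
            {"class": n, "train": t, "validation": v, "total": t + v}
            for n, (t, v) in counts.items()
        ]
    df = pd.DataFrame(rows)
    totals = {
        "class": "Total",
        "train": int(df["train"].sum()),
        "validation": int(df["validation"].sum()),
        "total": int(df["total"].sum()),
    }
    return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)
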