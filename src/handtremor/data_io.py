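"""Dataset manifests for handwriting-drawing collections.

Drawings follow the HandPD naming convention ``ID_EXAM-ID_IMAGE.jpg``: the
first integer identifies the exam (subject), the second the repetition of the
drawing within that exam.  A manifest is an ordered list of
:class:`SampleRecord` rows that can be built from a directory tree, expanded
by class-wise geometric augmentation (rotation / translation / shearing) and
partitioned into stratified train/test splits.  Manifests round-trip
losslessly through CSV.
"""

from __future__ import annotations

import logging
import os
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import AffineTransform, warp

logger = logging.getLogger(__name__)

PATTERNS = ("spiral", "meander")
LABELS = ("healthy", "patient")
AUGMENTATION_OPS = ("rotation", "translation", "shearing")

_FILENAME_RE = re.compile(r"^(\d+)-(\d+)\.([A-Za-z0-9]+)$")

#: columns of the persisted manifest CSV, in order
MANIFEST_COLUMNS = (
    "exam_id",
    "image_id",
    "pattern",
    "label",
    "path",
    "provenance",
    "augmentation_op",
)

_IMAGE_EXTENSIONS = {".jpg", ".jpeg", ".png"}


class FilenameParseError(ValueError):
    """Raised when a file name does not match ``<exam>-<image>.<ext>``."""


def parse_filename(name: str) -> tuple[int, int]:
    """Parse ``ID_EXAM-ID_IMAGE.ext`` into ``(exam_id, image_id)``.

    >>> parse_filename("103-4.jpg")
    (103, 4)
    """
    base = os.path.basename(str(name))
    m = _FILENAME_RE.match(base)
    if m is None:
        raise FilenameParseError(
            f"file name {base!r} does not match '<exam_id>-<image_id>.<ext>'"
        )
    return int(m.group(1)), int(m.group(2))


def format_filename(exam_id: int, image_id: int, ext: str = "jpg") -> str:
    """Inverse of :func:`parse_filename`."""
    if exam_id < 0 or image_id < 0:
        raise ValueError("identifiers must be non-negative")
    return f"{exam_id}-{image_id}.{ext.lstrip('.')}"


@dataclass(frozen=True)
class SampleRecord:
    """One drawing image and its metadata."""

    exam_id: int
    image_id: int
    pattern: str
    label: str
    path: str
    provenance: str = "original"
    augmentation_op: str | None = None

    def __post_init__(self) -> None:
        if self.exam_id < 0:
            raise ValueError("exam_id must be >= 0")
        if self.image_id < 1:
            raise ValueError("image_id must be >= 1")
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if self.provenance not in ("original", "augmented"):
            raise ValueError("provenance must be 'original' or 'augmented'")
        if self.provenance == "augmented" and self.augmentation_op not in AUGMENTATION_OPS:
            raise ValueError("augmented records need an augmentation_op")


@dataclass
class DatasetManifest:
    """Ordered collection of :class:`SampleRecord`."""

    records: list[SampleRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def class_counts(self) -> dict[str, int]:
        return dict(Counter(r.label for r in self.records))

    @property
    def pattern_counts(self) -> dict[str, int]:
        return dict(Counter(r.pattern for r in self.records))

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "exam_id": r.exam_id,
                "image_id": r.image_id,
                "pattern": r.pattern,
                "label": r.label,
                "path": r.path,
                "provenance": r.provenance,
                "augmentation_op": r.augmentation_op or "",
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DatasetManifest":
        records = []
        for row in df.itertuples(index=False):
            op = getattr(row, "augmentation_op", "")
            op = None if (op is None or (isinstance(op, float) and np.isnan(op)) or op == "") else str(op)
            records.append(
                SampleRecord(
                    exam_id=int(row.exam_id),
                    image_id=int(row.image_id),
                    pattern=str(row.pattern),
                    label=str(row.label),
                    path=str(row.path),
                    provenance=str(row.provenance),
                    augmentation_op=op,
                )
            )
        return cls(records)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "DatasetManifest":
        df = pd.read_csv(path, keep_default_na=False)
        return cls.from_frame(df)


@dataclass(frozen=True)
class AugmentationSpec:
    """Per-class expansion factors and geometric jitter ranges.

    ``multiplier_per_class`` counts total copies including the original, so a
    multiplier of 9 for the healthy class turns 72 originals into 648 records.
    Defaults reproduce the post-augmentation class sizes of the HandPD
    collections (healthy x9 -> 648, patient x2 -> 592).
    """

    multiplier_per_class: dict[str, int] = field(
        default_factory=lambda: {"healthy": 9, "patient": 2}
    )
    rotation_range: float = 15.0  # degrees, +/-
    translation_range: float = 0.10  # fraction of image side, +/-
    shear_range: float = 10.0  # degrees, +/-
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m < 1 for m in self.multiplier_per_class.values()):
            raise ValueError("multipliers must be >= 1")
        if min(self.rotation_range, self.translation_range, self.shear_range) < 0:
            raise ValueError("ranges must be non-negative")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    stratify: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def build_manifest(
    root: str | Path,
    label_map: dict[str, str],
    pattern: str | None = None,
) -> DatasetManifest:
    """Scan ``root``'s per-class subdirectories into a manifest.

    ``label_map`` maps subdirectory names (relative to ``root``) to labels.
    The drawing pattern is taken from ``pattern`` if given, otherwise guessed
    from the file's path ('meander' substring -> meander, else spiral).
    Unreadable images are skipped with a warning; an empty tree yields an
    empty manifest (also warned about).
    """
    root = Path(root)
    records: list[SampleRecord] = []
    for subdir, label in label_map.items():
        directory = root / subdir
        if not directory.is_dir():
            logger.warning("label directory %s does not exist; skipping", directory)
            continue
        for path in sorted(directory.rglob("*")):
            if path.suffix.lower() not in _IMAGE_EXTENSIONS:
                continue
            try:
                exam_id, image_id = parse_filename(path.name)
            except FilenameParseError as exc:
                logger.warning("skipping %s: %s", path, exc)
                continue
            try:
                iio.immeta(path)
            except Exception as exc:  # unreadable/corrupt image
                logger.warning("skipping unreadable image %s: %s", path, exc)
                continue
            pat = pattern or ("meander" if "meander" in str(path).lower() else "spiral")
            records.append(
                SampleRecord(
                    exam_id=exam_id,
                    image_id=image_id,
                    pattern=pat,
                    label=label,
                    path=str(path),
                )
            )
    if not records:
        warnings.warn("build_manifest produced an empty manifest", stacklevel=2)
    return DatasetManifest(records)


def _random_affine(
    rng: np.random.Generator, op: str, spec: AugmentationSpec, side: float
) -> AffineTransform:
    if op == "rotation":
        angle = np.deg2rad(rng.uniform(-spec.rotation_range, spec.rotation_range))
        return AffineTransform(rotation=angle)
    if op == "translation":
        t = rng.uniform(-spec.translation_range, spec.translation_range, size=2) * side
        return AffineTransform(translation=tuple(t))
    if op == "shearing":
        shear = np.deg2rad(rng.uniform(-spec.shear_range, spec.shear_range))
        return AffineTransform(shear=shear)
    raise ValueError(f"unknown augmentation op {op!r}")


def _centered(tf: AffineTransform, shape: tuple[int, int]) -> AffineTransform:
    # warp around the image centre rather than the corner
    centre = np.array([shape[1], shape[0]]) / 2.0 - 0.5
    shift = AffineTransform(translation=-centre)
    unshift = AffineTransform(translation=centre)
    return AffineTransform(matrix=unshift.params @ tf.params @ shift.params)


def augment_dataset(
    manifest: DatasetManifest,
    spec: AugmentationSpec,
    out_dir: str | Path,
) -> DatasetManifest:
    """Expand each class by its multiplier with randomly-transformed copies.

    Every original record of label ``l`` contributes
    ``multiplier_per_class[l]`` records in the output (itself plus
    ``multiplier - 1`` warped PNG copies written under ``out_dir``).  The
    transform sequence is reproducible from ``spec.seed``.
    """
    missing = {r.label for r in manifest} - set(spec.multiplier_per_class)
    if missing:
        raise ValueError(f"no multiplier defined for labels: {sorted(missing)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    records: list[SampleRecord] = []
    for rec in manifest:
        records.append(rec)
        n_extra = spec.multiplier_per_class[rec.label] - 1
        if n_extra == 0:
            continue
        image = np.asarray(iio.imread(rec.path), dtype=np.float64)
        side = float(max(image.shape[:2]))
        for k in range(n_extra):
            op = AUGMENTATION_OPS[int(rng.integers(len(AUGMENTATION_OPS)))]
            tf = _centered(_random_affine(rng, op, spec, side), image.shape[:2])
            warped = warp(
                image, tf.inverse, mode="constant", cval=255.0, preserve_range=True
            )
            stem = f"{rec.exam_id}-{rec.image_id}_{rec.pattern}_{rec.label}_aug{k + 1}"
            path = out_dir / f"{stem}.png"
            iio.imwrite(path, np.clip(warped, 0, 255).astype(np.uint8))
            records.append(
                replace(
                    rec,
                    path=str(path),
                    provenance="augmented",
                    augmentation_op=op,
                )
            )
    return DatasetManifest(records)


def split(
    manifest: DatasetManifest, spec: SplitSpec
) -> tuple[DatasetManifest, DatasetManifest]:
    """Disjoint, exhaustive train/test partition, stratified by label.

    Per-class training counts are ``round(train_fraction * n_class)`` with
    half-counts resolved toward the training set, so proportions are within
    one record of ``train_fraction``.  Reproducible from ``spec.seed``.
    """
    if len(manifest) == 0:
        raise ValueError("cannot split an empty manifest")
    rng = np.random.default_rng(spec.seed)
    train: list[SampleRecord] = []
    test: list[SampleRecord] = []
    if spec.stratify:
        groups: dict[str, list[int]] = {}
        for i, rec in enumerate(manifest):
            groups.setdefault(rec.label, []).append(i)
        for label in sorted(groups):
            idx = np.array(groups[label])
            if len(idx) < 2:
                raise ValueError(
                    f"class {label!r} has fewer than 2 records; cannot stratify"
                )
            rng.shuffle(idx)
            # round half toward train
            n_train = int(np.floor(spec.train_fraction * len(idx) + 0.5))
            n_train = min(max(n_train, 1), len(idx) - 1)
            train.extend(manifest.records[i] for i in idx[:n_train])
            test.extend(manifest.records[i] for i in idx[n_train:])
    else:
        idx = np.arange(len(manifest))
        rng.shuffle(idx)
        n_train = int(np.floor(spec.train_fraction * len(idx) + 0.5))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train.extend(manifest.records[i] for i in idx[:n_train])
        test.extend(manifest.records[i] for i in idx[n_train:])
    return DatasetManifest(train), DatasetManifest(test)
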