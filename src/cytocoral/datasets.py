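"""Dataset container, manifest I/O, augmentation, balancing and splitting.

The on-disk layout is a directory of PNG images plus a ``manifest.csv`` with
columns ``path,label,domain,split``.  Balancing augments every class up to
the size of the largest class using randomized rotation/flip copies while
guaranteeing that no two copies of the same source image share a transform.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import transform as sktransform

from .errors import CapacityError, DomainError, FormatError
from .types import CLASSES, BethesdaClass, LabeledImage

MANIFEST_COLUMNS = ["path", "label", "domain", "split"]


class Dataset:
    """An ordered collection of :class:`LabeledImage`."""

    def __init__(self, images: Iterable[LabeledImage] = ()):
        self.images: list[LabeledImage] = list(images)

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self) -> Iterator[LabeledImage]:
        return iter(self.images)

    def __getitem__(self, i):
        return self.images[i]

    def class_counts(self) -> dict[BethesdaClass, int]:
        counts = {c: 0 for c in CLASSES}
        for im in self.images:
            counts[im.label] += 1
        return counts

    def subset(self, split: str) -> "Dataset":
        return Dataset(im for im in self.images if im.split == split)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack into (X, y) with X of shape (n, H, W, 3), y int labels."""
        X = np.stack([im.pixels for im in self.images]).astype(np.float32)
        y = np.array([int(im.label) for im in self.images], dtype=np.int64)
        return X, y


# ---------------------------------------------------------------------------
# manifest I/O

def save_dataset(dataset: Dataset, out_dir: str | Path) -> Path:
    """Write PNGs plus ``manifest.csv``; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, im in enumerate(dataset):
        rel = f"img_{i:05d}_{im.label.name}.png"
        iio.imwrite(out_dir / rel, (np.round(im.pixels * 255)).astype(np.uint8))
        rows.append({"path": rel, "label": im.label.name,
                     "domain": im.domain, "split": im.split})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def load_dataset(manifest_path: str | Path) -> Dataset:
    """Load a dataset from a manifest CSV; image paths resolve relative to it."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise IOError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest missing columns {missing}")
    images = []
    for rec in df.itertuples(index=False):
        try:
            label = BethesdaClass.from_string(rec.label)
        except DomainError as e:
            raise FormatError(str(e)) from None
        img_path = manifest_path.parent / rec.path
        if not img_path.exists():
            raise IOError(f"image file missing: {img_path}")
        px = iio.imread(img_path)
        px = np.asarray(px, dtype=np.float32) / 255.0
        images.append(LabeledImage(pixels=px, label=label, domain=rec.domain,
                                   split=rec.split, path=str(rec.path)))
    return Dataset(images)


# ---------------------------------------------------------------------------
# augmentation

@dataclass(frozen=True)
class AugmentTransform:
    """One rotation+flip modification applied to a duplicated image."""

    rotation_degrees: float = 0.0
    flip_horizontal: bool = False
    flip_vertical: bool = False

    @property
    def is_identity(self) -> bool:
        return (self.rotation_degrees == 0.0 and not self.flip_horizontal
                and not self.flip_vertical)


@dataclass(frozen=True)
class AugmentationPolicy:
    """Bounds on the randomized transforms used to create copies.

    ``max_rotation`` is capped at 45 degrees: larger rotations visibly
    degrade multi-cell images.  ``right_angle`` restricts rotation to
    {90, 180, 270} instead of a continuous range.
    """

    max_rotation: float = 25.0
    allow_flips: bool = True
    right_angle: bool = False
    fill_mode: str = "reflect"

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_rotation <= 45.0):
            raise DomainError("max_rotation must be in [0, 45]")
        if self.fill_mode not in ("reflect", "edge", "constant"):
            raise DomainError(f"unknown fill_mode {self.fill_mode!r}")

    def transform_budget(self) -> float:
        """Number of distinct non-identity transforms per source image."""
        n_flips = 4 if self.allow_flips else 1
        if self.right_angle:
            return 4 * n_flips - 1
        if self.max_rotation == 0.0:
            return n_flips - 1
        return math.inf

    def sample_transform(self, rng: np.random.Generator) -> AugmentTransform:
        if self.right_angle:
            rot = float(rng.integers(0, 4) * 90)
        elif self.max_rotation > 0:
            rot = float(rng.uniform(-self.max_rotation, self.max_rotation))
        else:
            rot = 0.0
        fh = bool(rng.integers(2)) if self.allow_flips else False
        fv = bool(rng.integers(2)) if self.allow_flips else False
        return AugmentTransform(rot, fh, fv)


def augment_image(image: LabeledImage, transform: AugmentTransform,
                  policy: Optional[AugmentationPolicy] = None) -> LabeledImage:
    """Apply one rotation/flip transform, preserving label and domain.

    The identity transform is rejected: an augmented copy must differ from
    its source.  Rotation interpolates bilinearly with the policy's border
    fill rule (reflect by default, avoiding learnable black corners).
    """
    policy = policy or AugmentationPolicy()
    if transform.is_identity:
        raise DomainError("identity transform is excluded for augmented copies")
    if not policy.right_angle and abs(transform.rotation_degrees) > policy.max_rotation \
            and transform.rotation_degrees % 90 != 0:
        raise DomainError(
            f"rotation {transform.rotation_degrees} exceeds policy max "
            f"{policy.max_rotation}")
    px = image.pixels
    if transform.flip_horizontal:
        px = px[:, ::-1]
    if transform.flip_vertical:
        px = px[::-1, :]
    rot = transform.rotation_degrees % 360
    if rot:
        if rot in (90.0, 180.0, 270.0):
            px = np.rot90(px, k=int(rot // 90))
        else:
            px = sktransform.rotate(px.astype(np.float64), rot,
                                    mode=policy.fill_mode, order=1)
    px = np.clip(np.ascontiguousarray(px), 0.0, 1.0).astype(np.float32)
    return image.copy_with(pixels=px, transform=transform,
                           cell_mask=None, nucleus_mask=None)


def balance_classes(dataset: Dataset, policy: Optional[AugmentationPolicy] = None,
                    seed: int = 0, target_count: Optional[int] = None) -> Dataset:
    """Augment every class up to the largest class's size (or ``target_count``).

    Originals are kept untouched; copies carry ``source_id`` and their
    transform, and no (source, transform) pair repeats.  Raises
    :class:`CapacityError` when a class cannot reach the target within the
    policy's distinct-transform budget.
    """
    policy = policy or AugmentationPolicy()
    counts = {c: n for c, n in dataset.class_counts().items() if n > 0}
    if not counts:
        raise DomainError("dataset is empty")
    target = target_count if target_count is not None else max(counts.values())
    budget = policy.transform_budget()

    rng = np.random.Generator(np.random.PCG64(seed))
    out = list(dataset.images)
    by_class: dict[BethesdaClass, list[tuple[int, LabeledImage]]] = {}
    for idx, im in enumerate(dataset.images):
        by_class.setdefault(im.label, []).append((idx, im))

    for cls, members in sorted(by_class.items(), key=lambda kv: int(kv[0])):
        need = target - len(members)
        if need < 0:
            raise CapacityError(
                f"class {cls.name} already exceeds target {target}")
        if need == 0:
            continue
        capacity = len(members) * budget
        if need > capacity:
            raise CapacityError(
                f"class {cls.name}: need {need} copies but the policy allows "
                f"at most {capacity:g} distinct augmented copies "
                f"({len(members)} sources x budget {budget:g})")
        used: dict[int, set[AugmentTransform]] = {i: set() for i, _ in members}
        order = [members[i % len(members)] for i in range(need)]
        for src_idx, src in order:
            for _ in range(10_000):
                tr = policy.sample_transform(rng)
                if not tr.is_identity and tr not in used[src_idx]:
                    break
            else:  # pragma: no cover - rejection sampling exhausted
                raise CapacityError(f"could not sample a fresh transform for "
                                    f"source {src_idx}")
            used[src_idx].add(tr)
            copy = augment_image(src, tr, policy)
            out.append(copy.copy_with(source_id=src_idx))
    return Dataset(out)


# ---------------------------------------------------------------------------
# splitting

@dataclass
class SplitAssignment:
    """Per-image train/val/test tags produced by :func:`stratified_split`."""

    fractions: tuple[float, float, float]
    seed: int
    tags: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        out = {"train": 0, "val": 0, "test": 0}
        for t in self.tags:
            out[t] += 1
        return out


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(dataset: Dataset,
                     fractions: tuple[float, float, float] = (0.65, 0.15, 0.20),
                     seed: int = 0) -> SplitAssignment:
    """Shuffled per-class split into train/val/test.

    Per class of size m the test share is ``round(f_test*m)`` (half-up),
    the validation share ``round(f_val*m)``, and training takes the
    remainder — the rounding rule that maps 4x613 balanced images onto a
    492-image test partition under (0.65, 0.15, 0.20).
    """
    f_train, f_val, f_test = fractions
    if min(fractions) < 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise DomainError("fractions must be non-negative and sum to 1")
    rng = np.random.Generator(np.random.PCG64(seed))
    tags = [""] * len(dataset)
    by_class: dict[BethesdaClass, list[int]] = {}
    for idx, im in enumerate(dataset):
        by_class.setdefault(im.label, []).append(idx)
    for cls in sorted(by_class, key=int):
        idxs = np.array(by_class[cls])
        m = len(idxs)
        if m < 3 and f_train > 0 and f_val > 0 and f_test > 0:
            warnings.warn(f"class {cls.name} has only {m} images; split is "
                          f"degenerate", stacklevel=2)
        n_test = min(m, _round_half_up(f_test * m))
        n_val = min(m - n_test, _round_half_up(f_val * m))
        perm = idxs[rng.permutation(m)]
        for i in perm[:n_test]:
            tags[i] = "test"
        for i in perm[n_test:n_test + n_val]:
            tags[i] = "val"
        for i in perm[n_test + n_val:]:
            tags[i] = "train"
    return SplitAssignment(fractions=tuple(fractions), seed=seed, tags=tags)


def apply_split(dataset: Dataset, assignment: SplitAssignment) -> Dataset:
    """Return a copy of the dataset with split tags applied."""
    if len(assignment.tags) != len(dataset):
        raise DomainError("assignment length does not match dataset")
    return Dataset(im.copy_with(split=t)
                   for im, t in zip(dataset, assignment.tags))


__all__ = [
    "Dataset", "AugmentTransform", "AugmentationPolicy", "SplitAssignment",
    "load_dataset", "save_dataset", "augment_image", "balance_classes",
    "stratified_split", "apply_split", "MANIFEST_COLUMNS",
]
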