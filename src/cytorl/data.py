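"""Image-tree loading, preprocessing, augmentation and data splits.

Loading maps class subdirectories to contiguous integer labels in sorted
name order.  Preprocessing resizes to a fixed target (default 244 x 244,
configurable) and rescales to [0, 1].  Augmentation applies label-preserving
random rotations, flips, zooms and shifts, and is wired so that only
training manifests can be augmented.  The stratified split apportions each
class 70/15/15 by largest remainder (ties resolved train > val > test) and
k-fold cross-validation folds are stratified the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage

from .manifest import DatasetManifest, ManifestRecord

__all__ = [
    "PreprocConfig", "AugmentConfig", "SplitSpec", "load_image_tree",
    "load_pixels", "preprocess", "augment", "stratified_split",
    "largest_remainder_apportion", "kfold",
]

_IMAGE_SUFFIXES = (".png", ".bmp", ".jpg", ".jpeg")


@dataclass(frozen=True)
class PreprocConfig:
    target_size: tuple[int, int] = (244, 244)
    normalize: bool = True
    grayscale: bool = False

    def __post_init__(self):
        h, w = self.target_size
        if h <= 0 or w <= 0:
            raise ValueError("target_size must be positive")


@dataclass(frozen=True)
class AugmentConfig:
    rotation_max_deg: float = 20.0
    hflip: bool = True
    vflip: bool = True
    zoom_range: tuple[float, float] = (0.9, 1.1)
    shift_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.zoom_range
        if lo > hi:
            raise ValueError("zoom_range low must be <= high")
        if not (0.0 <= self.shift_fraction < 0.5):
            raise ValueError("shift_fraction must be in [0, 0.5)")

    @property
    def identity(self) -> bool:
        return (self.rotation_max_deg == 0 and not self.hflip and not self.vflip
                and self.zoom_range == (1.0, 1.0) and self.shift_fraction == 0.0)


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    rounding: str = "largest_remainder"

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if any(not (0.0 < f < 1.0) for f in self.fractions):
            raise ValueError("each split fraction must be in (0, 1)")
        if self.rounding != "largest_remainder":
            raise ValueError("only largest_remainder rounding is supported")


def load_image_tree(root: Path | str) -> DatasetManifest:
    """Scan ``<root>/<class>/<image>`` into a manifest.

    Class ids are assigned to subdirectory names in sorted order; records are
    sorted by (class, filename) so repeated loads are identical.  Group flags
    are read from an adjacent ``manifest.csv`` when present, else "normal".
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories under {root}")

    groups: dict[str, str] = {}
    csv = root / "manifest.csv"
    if csv.exists():
        prior = DatasetManifest.from_csv(csv)
        groups = {Path(r.path).name + "|" + Path(r.path).parent.name: r.group
                  for r in prior.records}

    records: list[ManifestRecord] = []
    names: dict[int, str] = {}
    for label, d in enumerate(class_dirs):
        names[label] = d.name
        files = sorted(p for p in d.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise ValueError(f"class directory {d} contains no images")
        for p in files:
            try:
                with Image.open(p) as im:
                    im.verify()
            except (UnidentifiedImageError, OSError) as exc:
                raise ValueError(f"unreadable image file: {p}") from exc
            grp = groups.get(p.name + "|" + d.name, "normal")
            records.append(ManifestRecord(p, label, grp))
    return DatasetManifest(records, names, root)


def load_pixels(path: Path | str) -> np.ndarray:
    """Read one image file to an (H, W, 3) uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def preprocess(image: np.ndarray, config: PreprocConfig = PreprocConfig()) -> np.ndarray:
    """Resize to ``target_size`` and rescale intensities to [0, 1].

    Returns (H, W, C) float64 with C = 1 when grayscale else 3.
    """
    if image.size == 0:
        raise ValueError("empty image")
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = arr[:, :, None].repeat(3, axis=2)
    im = Image.fromarray(arr.astype(np.uint8))
    if config.grayscale:
        im = im.convert("L")
    h, w = config.target_size
    im = im.resize((w, h), resample=Image.BILINEAR)
    out = np.asarray(im, dtype=np.float64)
    if out.ndim == 2:
        out = out[:, :, None]
    if config.normalize:
        out = out / 255.0
    return out


def augment(image: np.ndarray, config: AugmentConfig, sample_seed: int) -> np.ndarray:
    """Label-preserving random transform, deterministic in (config.seed, sample_seed)."""
    if config.identity:
        return image.copy()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, int(sample_seed)]))
    out = image
    if config.hflip and rng.random() < 0.5:
        out = out[:, ::-1]
    if config.vflip and rng.random() < 0.5:
        out = out[::-1, :]
    angle = rng.uniform(-config.rotation_max_deg, config.rotation_max_deg)
    if angle != 0.0:
        out = ndimage.rotate(out, angle, axes=(1, 0), reshape=False,
                             order=1, mode="nearest")
    zlo, zhi = config.zoom_range
    zoom = rng.uniform(zlo, zhi)
    if zoom != 1.0:
        h, w = out.shape[:2]
        zoomed = ndimage.zoom(out, (zoom, zoom, 1), order=1, mode="nearest")
        zh, zw = zoomed.shape[:2]
        if zoom > 1.0:  # centre crop back
            y0, x0 = (zh - h) // 2, (zw - w) // 2
            out = zoomed[y0 : y0 + h, x0 : x0 + w]
        else:  # pad back to size
            py, px = h - zh, w - zw
            out = np.pad(zoomed, ((py // 2, py - py // 2), (px // 2, px - px // 2),
                                  (0, 0)), mode="edge")
    if config.shift_fraction > 0:
        h, w = out.shape[:2]
        dy = rng.uniform(-config.shift_fraction, config.shift_fraction) * h
        dx = rng.uniform(-config.shift_fraction, config.shift_fraction) * w
        out = ndimage.shift(out, (dy, dx, 0), order=1, mode="nearest")
    return np.ascontiguousarray(out)


def largest_remainder_apportion(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Apportion ``n`` items by largest remainder; ties go to earlier entries."""
    quotas = [n * f for f in fractions]
    base = [int(np.floor(q)) for q in quotas]
    left = n - sum(base)
    remainders = [q - b for q, b in zip(quotas, base)]
    # sort by (-remainder, position): larger remainder first, earlier wins ties
    order = sorted(range(len(fractions)), key=lambda i: (-remainders[i], i))
    for i in order[:left]:
        base[i] += 1
    return base


def stratified_split(manifest: DatasetManifest, spec: SplitSpec = SplitSpec()
                     ) -> tuple[DatasetManifest, DatasetManifest, DatasetManifest]:
    """Per-class 70/15/15 split (largest remainder, train > val > test ties)."""
    counts = manifest.class_counts
    for label, n in counts.items():
        if n < 3:
            raise ValueError(f"class {label} has only {n} samples; need >= 3 to split")
    rng = np.random.default_rng(spec.seed)
    buckets: tuple[list[int], list[int], list[int]] = ([], [], [])
    for label in sorted(counts):
        idx = [i for i, r in enumerate(manifest.records) if r.label == label]
        idx = list(rng.permutation(idx))
        n_tr, n_va, n_te = largest_remainder_apportion(len(idx), spec.fractions)
        buckets[0].extend(idx[:n_tr])
        buckets[1].extend(idx[n_tr : n_tr + n_va])
        buckets[2].extend(idx[n_tr + n_va :])
    return tuple(manifest.subset(sorted(b)) for b in buckets)  # type: ignore[return-value]


def kfold(manifest: DatasetManifest, k: int = 5, seed: int = 0
          ) -> list[tuple[DatasetManifest, DatasetManifest]]:
    """Stratified k-fold partition into (fit, holdout) manifest pairs."""
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = manifest.class_counts
    for label, n in counts.items():
        if n < k:
            raise ValueError(f"class {label} has {n} samples, fewer than k={k}")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(manifest), dtype=int)
    for label in sorted(counts):
        idx = [i for i, r in enumerate(manifest.records) if r.label == label]
        idx = list(rng.permutation(idx))
        for pos, i in enumerate(idx):
            fold_of[i] = pos % k
    pairs = []
    for f in range(k):
        hold = [i for i in range(len(manifest)) if fold_of[i] == f]
        fit = [i for i in range(len(manifest)) if fold_of[i] != f]
        pairs.append((manifest.subset(fit), manifest.subset(hold)))
    return pairs
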