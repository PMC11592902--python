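"""Seeded generator of synthetic single-cell cytology images.

Each image contains one elliptical cytoplasm region with an interior
elliptical nucleus, on a light background, in a Pap-stain-like palette.
Class identity is encoded primarily in the nucleus-to-cytoplasm area
fraction — enlarged nuclei being the classic cytological marker of dysplasia
— with class-dependent texture noise and stain intensity.  Everything is
fully determined by (spec, seed, size), and datasets are written as
``<root>/<class_name>/<index>.png`` plus a ``manifest.csv``.

Presets mirror the class structure of the two public Pap-smear collections
this generator emulates: a seven-class set of 917 single-cell images (three
normal epithelial classes, four dysplastic/carcinoma classes) and a
five-class set whose printed per-class counts are {813, 787, 825, 813, 793}
against a printed grand total of 4049 (the rows sum to 4031; both numbers
are kept, see :data:`SIPAKMED_PRINTED_TOTAL`).
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .manifest import DatasetManifest, ManifestRecord

__all__ = [
    "SyntheticClassSpec", "ImageSample", "generate_cell_image", "generate_dataset",
    "herlev_like_preset", "sipakmed_like_preset", "imbalanced_pair_specs",
    "group_percentages", "nucleus_fraction_estimate",
    "HERLEV_CLASS_COUNTS", "HERLEV_GROUPS", "SIPAKMED_CLASS_COUNTS",
    "SIPAKMED_GROUPS", "SIPAKMED_PRINTED_TOTAL",
]

# Per-class image counts and clinical group flags of the emulated collections,
# in table row order.
HERLEV_CLASS_NAMES = (
    "moderate_dysplasia", "carcinoma_in_situ", "severe_dysplasia",
    "mild_dysplasia", "columnar_epithelial", "superficial_squamous",
    "intermediate_squamous",
)
HERLEV_CLASS_COUNTS = (146, 150, 197, 182, 98, 74, 70)
HERLEV_GROUPS = ("abnormal",) * 4 + ("normal",) * 3

SIPAKMED_CLASS_NAMES = (
    "superficial_intermediate", "parabasal", "koilocytotic", "dyskeratotic",
    "metaplastic",
)
SIPAKMED_CLASS_COUNTS = (813, 787, 825, 813, 793)
SIPAKMED_GROUPS = ("normal", "normal", "abnormal", "abnormal", "benign")
# The collection's published size; its per-class rows sum to 4031.  Published
# group percentages (39.5% normal / 40.5% abnormal) use this denominator.
SIPAKMED_PRINTED_TOTAL = 4049

_VALID_GROUPS = ("normal", "abnormal", "benign")


@dataclass(frozen=True)
class SyntheticClassSpec:
    """Recipe for one synthetic cell class."""

    class_id: int
    count: int
    nucleus_area_fraction_range: tuple[float, float]
    texture_noise_sd: float = 0.0
    stain_level: float = 0.5
    group: str = "normal"
    name: str | None = None

    def __post_init__(self):
        lo, hi = self.nucleus_area_fraction_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(
                "nucleus_area_fraction_range must satisfy 0 < low < high < 1, "
                f"got {self.nucleus_area_fraction_range}"
            )
        if self.class_id < 0:
            raise ValueError("class_id must be >= 0")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.texture_noise_sd < 0:
            raise ValueError("texture_noise_sd must be >= 0")
        if not (0.0 <= self.stain_level <= 1.0):
            raise ValueError("stain_level must be in [0, 1]")
        if self.group not in _VALID_GROUPS:
            raise ValueError(f"group must be one of {_VALID_GROUPS}")

    @property
    def label(self) -> str:
        return self.name if self.name is not None else f"class{self.class_id}"


@dataclass
class ImageSample:
    """One labelled synthetic cell image with its generation masks."""

    pixels: np.ndarray          # (H, W, 3) uint8
    label: int
    group: str
    nucleus_mask: np.ndarray    # (H, W) bool
    cytoplasm_mask: np.ndarray  # (H, W) bool, includes the nucleus interior
    nucleus_fraction: float     # area fraction drawn for this sample


def _ellipse_mask(h, w, cy, cx, ry, rx, theta):
    yy, xx = np.mgrid[0:h, 0:w]
    y = yy - cy
    x = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def generate_cell_image(spec: SyntheticClassSpec, seed: int,
                        size: tuple[int, int] = (64, 64)) -> ImageSample:
    """Render one cell image, fully determined by (spec, seed, size)."""
    h, w = size
    if h < 32 or w < 32:
        raise ValueError(f"size must be at least 32x32, got {size}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**32]))

    # cytoplasm: large ellipse near the image centre
    cy = h / 2 + rng.uniform(-0.05, 0.05) * h
    cx = w / 2 + rng.uniform(-0.05, 0.05) * w
    ry = rng.uniform(0.30, 0.40) * h
    rx = rng.uniform(0.30, 0.40) * w
    theta_c = rng.uniform(0, np.pi)
    cyto = _ellipse_mask(h, w, cy, cx, ry, rx, theta_c)

    # nucleus: interior ellipse with the drawn area fraction
    lo, hi = spec.nucleus_area_fraction_range
    frac = rng.uniform(lo, hi)
    ecc = rng.uniform(0.75, 1.0)  # nucleus axis ratio
    # area(nucleus) = frac * area(cyto)  =>  rn_y*rn_x = frac*ry*rx
    rn_y = np.sqrt(frac * ry * rx * ecc)
    rn_x = np.sqrt(frac * ry * rx / ecc)
    # keep the nucleus strictly inside the cytoplasm
    max_off = max(0.0, 1.0 - max(rn_y / ry, rn_x / rx)) * 0.5
    off_y = rng.uniform(-max_off, max_off) * ry
    off_x = rng.uniform(-max_off, max_off) * rx
    theta_n = rng.uniform(0, np.pi)
    nuc = _ellipse_mask(h, w, cy + off_y, cx + off_x, rn_y, rn_x, theta_n)
    nuc &= cyto

    # Pap-like palette: light background, eosinophilic cytoplasm,
    # hematoxylin-dark nucleus; stain_level deepens the stain.
    s = spec.stain_level
    bg = np.array([235.0, 233.0, 238.0])
    cyto_rgb = np.array([205.0 - 35.0 * s, 170.0 - 45.0 * s, 200.0 - 25.0 * s])
    nuc_rgb = np.array([120.0 - 50.0 * s, 90.0 - 45.0 * s, 150.0 - 40.0 * s])

    img = np.empty((h, w, 3))
    img[:] = bg
    img[cyto] = cyto_rgb
    img[nuc] = nuc_rgb
    if spec.texture_noise_sd > 0:
        img = img + rng.normal(0.0, spec.texture_noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return ImageSample(img, spec.class_id, spec.group, nuc, cyto, float(frac))


def _per_image_seed(dataset_seed: int, class_id: int, index: int) -> int:
    """Stable per-image seed from (dataset seed, class, index)."""
    ss = np.random.SeedSequence([int(dataset_seed), int(class_id), int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def generate_dataset(specs: list[SyntheticClassSpec], seed: int,
                     size: tuple[int, int], out_dir: Path | str,
                     overwrite: bool = False) -> DatasetManifest:
    """Write one PNG subdirectory per class and return the manifest."""
    ids = [s.class_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("class_ids must be distinct across the dataset spec")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not overwrite:
            raise FileExistsError(
                f"{out} exists and is not empty; pass overwrite=True to replace it"
            )
        shutil.rmtree(out)
    out.mkdir(parents=True, exist_ok=True)

    records: list[ManifestRecord] = []
    names: dict[int, str] = {}
    for spec in specs:
        names[spec.class_id] = spec.label
        cls_dir = out / spec.label
        cls_dir.mkdir()
        for i in range(spec.count):
            sample = generate_cell_image(
                spec, _per_image_seed(seed, spec.class_id, i), size
            )
            path = cls_dir / f"{i:05d}.png"
            Image.fromarray(sample.pixels).save(path, format="PNG")
            records.append(ManifestRecord(path, spec.class_id, spec.group))
    manifest = DatasetManifest(records, names, out)
    manifest.save_csv(out / "manifest.csv")
    return manifest


# ---------------------------------------------------------------- presets

def _preset_specs(names, counts, groups, scale: float) -> list[SyntheticClassSpec]:
    if not (0.0 < scale <= 1.0):
        raise ValueError("scale must be in (0, 1]")
    scaled = [int(round(c * scale)) for c in counts]
    if min(scaled) < 2:
        raise ValueError(
            f"scale {scale} leaves a class with fewer than 2 images: {scaled}"
        )
    specs = []
    for cid, (name, cnt, grp) in enumerate(zip(names, scaled, groups)):
        # abnormal classes get larger, more variable nuclei and heavier stain
        if grp == "abnormal":
            frac_range = (0.30 + 0.02 * cid, 0.55 + 0.02 * cid)
            stain = 0.8
        elif grp == "benign":
            frac_range = (0.20, 0.35)
            stain = 0.6
        else:
            frac_range = (0.05 + 0.02 * cid, 0.18 + 0.02 * cid)
            stain = 0.4
        specs.append(
            SyntheticClassSpec(
                class_id=cid, count=cnt, nucleus_area_fraction_range=frac_range,
                texture_noise_sd=6.0, stain_level=stain, group=grp, name=name,
            )
        )
    return specs


def herlev_like_preset(out_dir: Path | str, seed: int, scale: float = 1.0,
                       size: tuple[int, int] = (64, 64),
                       overwrite: bool = False) -> DatasetManifest:
    """Seven-class preset with the 917-image collection's per-class counts."""
    specs = _preset_specs(HERLEV_CLASS_NAMES, HERLEV_CLASS_COUNTS, HERLEV_GROUPS, scale)
    return generate_dataset(specs, seed, size, out_dir, overwrite=overwrite)


def sipakmed_like_preset(out_dir: Path | str, seed: int, scale: float = 1.0,
                         size: tuple[int, int] = (64, 64),
                         overwrite: bool = False) -> DatasetManifest:
    """Five-class preset with the printed per-class row counts."""
    specs = _preset_specs(
        SIPAKMED_CLASS_NAMES, SIPAKMED_CLASS_COUNTS, SIPAKMED_GROUPS, scale
    )
    return generate_dataset(specs, seed, size, out_dir, overwrite=overwrite)


def imbalanced_pair_specs(n_majority: int = 200, n_minority: int = 20,
                          noise_sd: float = 8.0) -> list[SyntheticClassSpec]:
    """Two-class imbalanced recipe for the reweighting experiments.

    The minority (abnormal) class has an enlarged-nucleus morphology whose
    area-fraction range overlaps the majority's, so short training does not
    trivially saturate minority recall — mimicking the early-dysplasia cells
    that imbalance-aware training is meant to recover.
    """
    return [
        SyntheticClassSpec(0, n_majority, (0.10, 0.30), noise_sd, 0.45,
                           "normal", "normal"),
        SyntheticClassSpec(1, n_minority, (0.26, 0.46), noise_sd, 0.55,
                           "abnormal", "abnormal"),
    ]


# ------------------------------------------------- composition arithmetic

def group_percentages(counts, groups, printed_total: int | None = None
                      ) -> dict[str, float]:
    """Percent of samples per clinical group, on the published denominator.

    ``printed_total`` overrides the row sum when a collection's published
    total disagrees with its per-class rows (as it does for the five-class
    set: rows sum to 4031, printed total 4049).
    """
    if len(counts) != len(groups):
        raise ValueError("counts and groups must align")
    total = printed_total if printed_total is not None else sum(counts)
    out: dict[str, float] = {}
    for c, g in zip(counts, groups):
        out[g] = out.get(g, 0.0) + c
    return {g: 100.0 * n / total for g, n in out.items()}


def nucleus_fraction_estimate(pixels: np.ndarray) -> float:
    """Estimate nucleus/cytoplasm area fraction from pixel intensities alone.

    Uses the palette's intensity ordering (nucleus darkest, background
    lightest); serves as the trivial threshold classifier that certifies
    generated classes are separable.
    """
    gray = pixels.astype(float).mean(axis=-1)
    cell = gray < 215.0      # cytoplasm + nucleus
    nucleus = gray < 130.0
    n_cell = int(cell.sum())
    if n_cell == 0:
        return 0.0
    return float(nucleus.sum()) / n_cell
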