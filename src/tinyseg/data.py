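"""Image/mask I/O, label codecs, class balancing and synthetic scenes.

Ground-truth masks are RGB images in which each colour denotes a class;
:class:`LabelCodec` maps colours to contiguous integer labels (0 is
always background) and back.  Per-pixel training targets are one-hot
tensors, and loss weighting uses median frequency balancing: classes
that occupy many pixels get weight < 1, rare classes weight > 1, and the
median-frequency class exactly 1.

The synthetic scene generator stands in for field datasets of flowers
and rosette plants: a textured soil-like background (class 0) with a few
elliptical, distinctly coloured foreground objects.  Backgrounds
dominate by construction, so the generated class frequencies are
strongly imbalanced — the regime median frequency balancing exists for.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "LabelCodec",
    "ClassWeightTable",
    "SyntheticScene",
    "SceneProfile",
    "default_palette",
    "encode_mask",
    "decode_labels",
    "one_hot",
    "median_frequency_weights",
    "split_dataset",
    "synthesize_dataset",
    "normalize_image",
    "load_image",
    "load_mask",
    "resize_image",
    "resize_mask",
    "write_dataset",
    "read_manifest",
]

#: Colours printed in the source data convention: class 1 is
#: [255, 255, 0], class 2 is [255, 64, 64]; background is black.
_BASE_PALETTE = ((0, 0, 0), (255, 255, 0), (255, 64, 64))


def default_palette(n_classes: int) -> tuple[tuple[int, int, int], ...]:
    """A deterministic palette of well-separated colours.

    The first three entries follow the published convention; further
    classes take fully saturated colours at golden-angle hue spacing,
    which keeps any two classes far apart in RGB space.
    """
    colors = list(_BASE_PALETTE[: min(n_classes, 3)])
    hue = 0.61
    while len(colors) < n_classes:
        hue = (hue + 0.381966) % 1.0
        rgb = tuple(int(round(255 * v)) for v in colorsys.hsv_to_rgb(hue, 1.0, 1.0))
        if rgb not in colors:
            colors.append(rgb)
    return tuple(colors)


@dataclass(frozen=True)
class LabelCodec:
    """Bidirectional RGB-triplet <-> class-index mapping."""

    palette: tuple[tuple[int, int, int], ...]

    def __post_init__(self):
        if len(set(self.palette)) != len(self.palette):
            raise ValueError("palette colours must be unique")

    @classmethod
    def for_classes(cls, n_classes: int) -> "LabelCodec":
        return cls(default_palette(n_classes))

    @property
    def n_classes(self) -> int:
        return len(self.palette)


def _pack(rgb: np.ndarray) -> np.ndarray:
    rgb = rgb.astype(np.uint32)
    return (rgb[..., 0] << 16) | (rgb[..., 1] << 8) | rgb[..., 2]


def encode_mask(rgb_mask: np.ndarray, codec: LabelCodec) -> np.ndarray:
    """RGB mask -> integer label map; unknown colours are an error."""
    rgb_mask = np.asarray(rgb_mask)
    if rgb_mask.ndim != 3 or rgb_mask.shape[-1] != 3:
        raise ValueError("mask must be (H, W, 3)")
    packed = _pack(rgb_mask)
    keys = _pack(np.array(codec.palette, np.uint32))
    labels = np.full(packed.shape, -1, np.int64)
    for idx, key in enumerate(keys):
        labels[packed == key] = idx
    if (labels < 0).any():
        i, j = np.argwhere(labels < 0)[0]
        raise ValueError(
            f"mask colour {tuple(int(v) for v in rgb_mask[i, j])} at pixel "
            f"({i}, {j}) is not in the palette"
        )
    return labels


def decode_labels(labels: np.ndarray, codec: LabelCodec) -> np.ndarray:
    """Integer label map -> RGB mask."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= codec.n_classes:
        raise ValueError("label out of palette range")
    lut = np.array(codec.palette, np.uint8)
    return lut[labels]


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Per-pixel binary class-membership tensor (H, W, C)."""
    labels = np.asarray(labels)
    if labels.max() >= n_classes or labels.min() < 0:
        raise ValueError(f"label outside [0, {n_classes})")
    return np.eye(n_classes, dtype=np.float32)[labels]


@dataclass(frozen=True)
class ClassWeightTable:
    """Pixel frequencies and median-frequency loss weights per class."""

    freq: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        if not np.isclose(self.freq.sum(), 1.0):
            raise ValueError("frequencies must sum to 1")


def median_frequency_weights(label_maps) -> ClassWeightTable:
    """weight_c = median(freq) / freq_c over a collection of label maps.

    Every class must occur at least once, otherwise its weight is
    undefined.  The median is the interpolated (numpy) median.
    """
    label_maps = [np.asarray(m) for m in label_maps]
    n_classes = int(max(m.max() for m in label_maps)) + 1
    counts = np.zeros(n_classes, np.int64)
    for m in label_maps:
        counts += np.bincount(m.ravel(), minlength=n_classes)
    if (counts == 0).any():
        missing = np.flatnonzero(counts == 0).tolist()
        raise ValueError(f"classes {missing} never occur; weights undefined")
    freq = counts / counts.sum()
    weights = np.median(freq) / freq
    return ClassWeightTable(freq=freq, weights=weights)


def split_dataset(items, seed: int):
    """Deterministic 64/16/20 train/val/test index split.

    The data are first split 80/20 into train+val vs test, then the
    80% further 80/20 into train vs val.
    """
    n = items if isinstance(items, int) else len(items)
    if n < 5:
        raise ValueError("need at least 5 items to split")
    order = np.random.default_rng(seed).permutation(n)
    n_trainval = round(0.8 * n)
    n_train = round(0.8 * n_trainval)
    return (
        np.sort(order[:n_train]),
        np.sort(order[n_train:n_trainval]),
        np.sort(order[n_trainval:]),
    )


def normalize_image(raw: np.ndarray) -> np.ndarray:
    """8-bit image -> float32 in [0, 1]."""
    return np.asarray(raw, np.float32) / 255.0


# ---------------------------------------------------------------------------
# synthetic scenes


@dataclass(frozen=True)
class SceneProfile:
    """Tunable knobs of the scene generator.

    ``max_axis_frac`` bounds each ellipse semi-axis as a fraction of the
    image side; with at most ``max_objects`` ellipses the foreground can
    never exceed half the pixels, preserving the background-dominated
    imbalance of field imagery.  ``color_jitter``/``pixel_noise`` control
    how far object pixels stray from their class colour.
    """

    min_objects: int = 1
    max_objects: int = 5
    min_axis_frac: float = 0.06
    max_axis_frac: float = 0.16
    color_jitter: float = 0.08
    pixel_noise: float = 0.03
    background_noise: float = 0.05

    @classmethod
    def easy(cls) -> "SceneProfile":
        """Well-separated colours, mild noise: trivially learnable."""
        return cls(color_jitter=0.04, pixel_noise=0.02, background_noise=0.03)


@dataclass(frozen=True)
class SyntheticScene:
    image: np.ndarray  # (H, W, 3) float32 in [0, 1]
    mask: np.ndarray  # (H, W) int64 class labels
    class_counts: np.ndarray  # (C,) pixel counts, sums to H*W
    seed: int


def _smooth_noise(rng, h, w, scale=8):
    coarse = rng.standard_normal((max(h // scale, 1), max(w // scale, 1)))
    img = Image.fromarray(coarse.astype(np.float32), mode="F")
    return np.asarray(img.resize((w, h), Image.BILINEAR))


def _render_scene(seed: int, n_classes: int, h: int, w: int, profile: SceneProfile,
                  forced_class: int | None) -> SyntheticScene:
    rng = np.random.default_rng(seed)
    # textured soil-like background around a dark brown-green base
    base = np.array([0.22, 0.19, 0.12], np.float32)
    image = np.empty((h, w, 3), np.float32)
    texture = _smooth_noise(rng, h, w)
    for c in range(3):
        image[..., c] = base[c] + 0.08 * texture
    image += profile.background_noise * rng.standard_normal((h, w, 3))
    mask = np.zeros((h, w), np.int64)

    palette = np.array(default_palette(n_classes), np.float32) / 255.0
    yy, xx = np.mgrid[0:h, 0:w]
    n_objects = int(rng.integers(profile.min_objects, profile.max_objects + 1))
    for obj in range(n_objects):
        if obj == 0 and forced_class is not None:
            cls = forced_class
        else:
            cls = int(rng.integers(1, n_classes))
        cy, cx = rng.uniform(0.15, 0.85) * h, rng.uniform(0.15, 0.85) * w
        a = rng.uniform(profile.min_axis_frac, profile.max_axis_frac) * h
        b = rng.uniform(profile.min_axis_frac, profile.max_axis_frac) * w
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        inside = (u / b) ** 2 + (v / a) ** 2 <= 1.0
        color = palette[cls] * (1.0 + profile.color_jitter * rng.uniform(-1, 1))
        image[inside] = color + profile.pixel_noise * rng.standard_normal(
            (int(inside.sum()), 3)
        )
        mask[inside] = cls

    np.clip(image, 0.0, 1.0, out=image)
    counts = np.bincount(mask.ravel(), minlength=n_classes)
    return SyntheticScene(
        image=image, mask=mask, class_counts=counts, seed=seed
    )


def synthesize_dataset(
    n_images: int,
    n_classes: int,
    *,
    height: int = 224,
    width: int = 224,
    seed: int = 0,
    profile: SceneProfile | None = None,
) -> list[SyntheticScene]:
    """Generate ``n_images`` reproducible scenes.

    Each scene has a textured background plus 1-5 elliptical objects;
    the first object of scene ``i`` is forced to class
    ``1 + i mod (C-1)`` so every foreground class occurs in any dataset
    of at least C-1 scenes.  Identical arguments give byte-identical
    output.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    profile = profile or SceneProfile()
    scene_seeds = np.random.SeedSequence(seed).generate_state(n_images)
    return [
        _render_scene(
            int(s), n_classes, height, width, profile, 1 + i % (n_classes - 1)
        )
        for i, s in enumerate(scene_seeds)
    ]


# ---------------------------------------------------------------------------
# files


def load_image(path) -> np.ndarray:
    """PNG/JPEG -> float32 RGB in [0, 1]."""
    with Image.open(path) as img:
        return normalize_image(np.asarray(img.convert("RGB")))


def load_mask(path, codec: LabelCodec) -> np.ndarray:
    """RGB mask PNG -> integer label map."""
    with Image.open(path) as img:
        return encode_mask(np.asarray(img.convert("RGB")), codec)


def resize_image(image: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of a float image to (H, W)."""
    arr = (np.clip(image, 0, 1) * 255).astype(np.uint8)
    with Image.fromarray(arr) as img:
        out = img.resize((size[1], size[0]), Image.BILINEAR)
        return normalize_image(np.asarray(out))


def resize_mask(labels: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize of a label map (labels must not blend)."""
    with Image.fromarray(labels.astype(np.int32), mode="I") as img:
        out = img.resize((size[1], size[0]), Image.NEAREST)
        return np.asarray(out).astype(np.int64)


def write_dataset(directory, scenes, codec: LabelCodec) -> Path:
    """Write scenes as paired PNGs plus a tab-separated manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = []
    for i, scene in enumerate(scenes):
        img_path = directory / f"image_{i:04d}.png"
        mask_path = directory / f"mask_{i:04d}.png"
        Image.fromarray((scene.image * 255).round().astype(np.uint8)).save(img_path)
        Image.fromarray(decode_labels(scene.mask, codec)).save(mask_path)
        lines.append(f"{img_path.name}\t{mask_path.name}")
    manifest = directory / "manifest.tsv"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def read_manifest(manifest_path):
    """Manifest -> list of (image_path, mask_path) pairs."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    pairs = []
    for line in manifest_path.read_text().splitlines():
        if not line.strip():
            continue
        img, mask = line.split("\t")
        pairs.append((root / img, root / mask))
    return pairs
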