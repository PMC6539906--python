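"""Synthetic labeled scenes and image/mask file handling.

The generator emulates the structure of orchard and greenhouse imagery at
desk scale: elliptical "fruits" of one jittered color on a differently
colored textured background, under a spatial illumination field, with
optional additive sensor noise.  Illumination is multiplicative (gain),
matching how sunlight and shading scale a surface's reflected color; the
Normalized Difference Index is exactly invariant to such gain, which is
the property the adaptive detector exploits.

Ground truth is pixel-exact by construction: the mask is precisely the
set of rasterized ellipse pixels.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.draw import ellipse as _ellipse

from .colorspace import ColorImage
from .training import LabeledImage


@dataclass
class IlluminationSpec:
    """Multiplicative illumination gain across the image.

    ``zones=None`` gives a smooth linear ramp from ``min_gain`` to
    ``max_gain`` along the orientation axis.  An integer ``zones=k`` gives
    k constant-gain bands with gains evenly spaced over the same range;
    band edges follow successive halving (1/2, 3/4, ...) so the bands are
    aligned with the detector's quadrant splitting and emulate a large
    shaded area plus progressively sunnier strips.
    """

    orientation: str = "horizontal"  # gain varies along columns
    min_gain: float = 1.0
    max_gain: float = 1.0
    zones: int | None = 3

    def __post_init__(self) -> None:
        if not (0 < self.min_gain <= self.max_gain <= 2):
            raise ValueError("need 0 < min_gain <= max_gain <= 2")
        if self.orientation not in ("horizontal", "vertical"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.zones is not None and self.zones < 1:
            raise ValueError("zones must be >= 1 or None")

    def profile(self, n: int) -> np.ndarray:
        """Gain as a function of position along the orientation axis."""
        if self.zones is None:
            return np.linspace(self.min_gain, self.max_gain, n)
        k = self.zones
        gains = np.linspace(self.min_gain, self.max_gain, k) if k > 1 else [
            (self.min_gain + self.max_gain) / 2.0
        ]
        edges = [0.0] + [1.0 - 0.5**i for i in range(1, k)] + [1.0]
        out = np.empty(n)
        for g, (a, b) in zip(gains, zip(edges, edges[1:])):
            out[int(round(a * n)) : int(round(b * n))] = g
        return out


@dataclass
class SceneSpec:
    """Parameters of one synthetic labeled scene.

    Fruit axes default to 20-32 px on a 256 x 256 canvas so that fruits
    are much larger than the 11 x 11 morphological structuring element, as
    real fruit are at camera resolution.  Colors default to red fruit on
    green foliage; per-fruit color jitter is uniform within +/- the jitter
    amplitude, the background gets a per-image color jitter plus a
    per-pixel multiplicative brightness texture.
    """

    size: tuple[int, int] = (256, 256)
    n_fruits: int = 4
    fruit_color: tuple[float, float, float] = (200.0, 30.0, 30.0)
    fruit_jitter: float = 10.0
    bg_color: tuple[float, float, float] = (40.0, 160.0, 40.0)
    bg_jitter: float = 10.0
    axis_range: tuple[float, float] = (20.0, 32.0)
    illumination: IlluminationSpec = field(default_factory=IlluminationSpec)
    texture_std: float = 0.05
    noise_percent: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fruits < 0:
            raise ValueError("n_fruits must be >= 0")
        if not 0 < self.axis_range[0] <= self.axis_range[1]:
            raise ValueError("invalid axis_range")
        if tuple(self.fruit_color) == tuple(self.bg_color):
            raise ValueError("fruit and background colors must differ")


def generate_scene(spec: SceneSpec, id: str = "scene") -> LabeledImage:
    """Render one scene; deterministic for a fixed ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    bg = np.asarray(spec.bg_color) + rng.uniform(-spec.bg_jitter, spec.bg_jitter, 3)
    img = np.broadcast_to(bg, (h, w, 3)).astype(np.float64).copy()
    if spec.texture_std > 0:
        img *= 1.0 + rng.normal(0.0, spec.texture_std, (h, w))[..., None]
    truth = np.zeros((h, w), dtype=bool)

    margin_needed = 2 * math.ceil(spec.axis_range[1]) + 2
    if spec.n_fruits > 0 and (h < margin_needed or w < margin_needed):
        raise ValueError(f"canvas {spec.size} too small for fruits of this size")
    for _ in range(spec.n_fruits):
        placed = False
        for _attempt in range(500):
            a = rng.uniform(*spec.axis_range)
            b = rng.uniform(*spec.axis_range)
            theta = rng.uniform(0.0, np.pi)
            m = math.ceil(max(a, b)) + 1
            cy = int(rng.integers(m, h - m))
            cx = int(rng.integers(m, w - m))
            rr, cc = _ellipse(cy, cx, a, b, rotation=theta, shape=(h, w))
            if truth[rr, cc].any():
                continue
            color = np.asarray(spec.fruit_color) + rng.uniform(
                -spec.fruit_jitter, spec.fruit_jitter, 3
            )
            img[rr, cc] = color
            truth[rr, cc] = True
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place {spec.n_fruits} non-overlapping fruits "
                f"on a {spec.size} canvas"
            )

    gains = spec.illumination.profile(w if spec.illumination.orientation == "horizontal" else h)
    if spec.illumination.orientation == "horizontal":
        img *= gains[None, :, None]
    else:
        img *= gains[:, None, None]
    rgb = ColorImage(np.clip(img, 0.0, 255.0), "rgb")
    if spec.noise_percent > 0:
        from .experiments import add_noise

        rgb = add_noise(
            rgb, spec.noise_percent, seed=int(rng.integers(2**31))
        )
    return LabeledImage(rgb=rgb, truth=truth, id=id)


def generate_dataset(spec: SceneSpec, n_images: int) -> list[LabeledImage]:
    """Generate ``n_images`` scenes with per-image seeds derived from
    ``spec.seed``; each scene varies fruit placement, jitter, and noise."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    seeds = np.random.SeedSequence(spec.seed).generate_state(n_images) % (2**31)
    return [
        generate_scene(
            dataclasses.replace(spec, seed=int(s)), id=f"scene_{i:03d}"
        )
        for i, s in enumerate(seeds)
    ]


def read_labeled(image_path, mask_path) -> LabeledImage:
    """Load an image/mask pair; any nonzero mask pixel counts as fruit."""
    from .colorspace import load_rgb

    rgb = load_rgb(image_path)
    with Image.open(mask_path) as im:
        mask = np.asarray(im.convert("L")) > 0
    if mask.shape != rgb.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image {rgb.shape}"
        )
    return LabeledImage(rgb=rgb, truth=mask, id=Path(image_path).stem)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit single-channel PNG with values 0/255."""
    arr = (np.asarray(mask).astype(bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(path)


def write_image(rgb: ColorImage, path) -> None:
    """Write an RGB image as 8-bit PNG (values rounded and clipped)."""
    arr = np.clip(np.rint(rgb.pixels), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


def write_dataset(images: list[LabeledImage], out_dir) -> "pd.DataFrame":
    """Write scenes and masks as PNG plus a manifest CSV; returns the manifest."""
    import pandas as pd

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for im in images:
        ipath = out / "images" / f"{im.id}.png"
        mpath = out / "masks" / f"{im.id}.png"
        write_image(im.rgb, ipath)
        if im.truth is not None:
            write_mask(im.truth, mpath)
        rows.append({"id": im.id, "image": str(ipath), "mask": str(mpath)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_directory(images_dir, masks_dir) -> list[LabeledImage]:
    """Pair images and masks by file stem across two directories."""
    images_dir, masks_dir = Path(images_dir), Path(masks_dir)
    masks = {p.stem: p for p in sorted(masks_dir.iterdir()) if p.is_file()}
    out = []
    for p in sorted(images_dir.iterdir()):
        if not p.is_file() or p.stem not in masks:
            continue
        out.append(read_labeled(p, masks[p.stem]))
    if not out:
        raise FileNotFoundError(
            f"no image/mask pairs found under {images_dir} and {masks_dir}"
        )
    return out
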