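"""Color-space transforms used by the adaptive thresholding detector.

Four working color spaces share a uniform three-channel interface:

* ``rgb`` — the camera channels, each in [0, 255];
* ``ndi`` — three Normalized Difference Indices, ``(X - Y) / (X + Y)`` for
  the channel pairs (R, G), (R, B), (B, G), each bounded in [-1, 1] and
  invariant to multiplicative illumination gain;
* ``hsi`` — hue, saturation, intensity, each scaled to [0, 1];
* ``lab`` — CIELAB under the D65 white point: L in [0, 100], a and b in
  roughly [-128, 127].

A grayscale view in [0, 255] supplies the light-level measurements that
drive the illumination-aware splitting of images into homogeneous regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from skimage import color as _skcolor

RGB = "rgb"
NDI = "ndi"
HSI = "hsi"
LAB = "lab"
SPACES = (RGB, NDI, HSI, LAB)

#: Declared (min, max) per channel for every working space.
CHANNEL_RANGES: dict[str, tuple[tuple[float, float], ...]] = {
    RGB: ((0.0, 255.0),) * 3,
    NDI: ((-1.0, 1.0),) * 3,
    HSI: ((0.0, 1.0),) * 3,
    LAB: ((0.0, 100.0), (-128.0, 127.0), (-128.0, 127.0)),
}

#: ITU-R BT.601 luminance weights for the grayscale view.
GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])


class ColorSpaceError(ValueError):
    """Raised when an image carries the wrong space tag for an operation."""


@dataclass
class ColorImage:
    """A height x width x 3 image tagged with its color space.

    Pixels are stored as float64 regardless of the input dtype so that all
    downstream arithmetic (NDI ratios, threshold interpolation) runs in
    floating point.
    """

    pixels: np.ndarray
    space: str = RGB

    def __post_init__(self) -> None:
        if self.space not in SPACES:
            raise ColorSpaceError(f"unknown color space {self.space!r}")
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"expected a (H, W, 3) array, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] == 0 or self.pixels.shape[1] == 0:
            raise ValueError("image has no pixels")

    @property
    def channel_ranges(self) -> tuple[tuple[float, float], ...]:
        return CHANNEL_RANGES[self.space]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def _require(img: ColorImage, space: str) -> None:
    if img.space != space:
        raise ColorSpaceError(f"expected a {space!r} image, got {img.space!r}")


def to_ndi(rgb: ColorImage) -> ColorImage:
    """Normalized Difference Index transform.

    Channel 1 is ``(R - G) / (R + G)``, channel 2 ``(R - B) / (R + B)``,
    channel 3 ``(B - G) / (B + G)``.  Pixels whose pair sums to zero (both
    channels black) are mapped to 0, the symmetric "no difference" value,
    which also keeps the output inside [-1, 1].
    """
    _require(rgb, RGB)
    p = rgb.pixels
    r, g, b = p[..., 0], p[..., 1], p[..., 2]
    out = np.empty_like(p)
    for k, (x, y) in enumerate(((r, g), (r, b), (b, g))):
        num = x - y
        den = x + y
        with np.errstate(divide="ignore", invalid="ignore"):
            out[..., k] = np.where(den == 0, 0.0, num / np.where(den == 0, 1, den))
    return ColorImage(out, NDI)


def to_hsi(rgb: ColorImage, variant: str = "hsi") -> ColorImage:
    """Hue / saturation / intensity transform, all channels in [0, 1].

    ``variant="hsi"`` (default) uses the classical polar decomposition:
    ``I = (R + G + B) / 3`` (scaled by 255), ``S = 1 - min(R, G, B) / mean``,
    and hue from the arccos of the chroma geometry, expressed as a fraction
    of the full circle.  ``variant="hsv"`` delegates to the hexcone
    hue/saturation/value model instead; the two families are often
    conflated and both are exposed.  Achromatic pixels get H = 0 and S = 0.
    """
    _require(rgb, RGB)
    p = rgb.pixels / 255.0
    if variant == "hsv":
        return ColorImage(_skcolor.rgb2hsv(p), HSI)
    if variant != "hsi":
        raise ValueError(f"unknown HSI variant {variant!r}")
    r, g, b = p[..., 0], p[..., 1], p[..., 2]
    total = r + g + b
    intensity = total / 3.0
    mn = p.min(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(total > 0, 1.0 - 3.0 * mn / np.where(total == 0, 1, total), 0.0)
    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.arccos(np.clip(num / np.where(den == 0, 1, den), -1.0, 1.0))
    hue = np.where(b > g, 2.0 * np.pi - theta, theta) / (2.0 * np.pi)
    achromatic = (den == 0) | (sat == 0)
    hue = np.where(achromatic, 0.0, hue)
    sat = np.where(achromatic, 0.0, sat)
    return ColorImage(np.stack([hue, sat, intensity], axis=-1), HSI)


def to_lab(rgb: ColorImage) -> ColorImage:
    """sRGB -> CIELAB (D65): L lightness, a green-red, b blue-yellow."""
    _require(rgb, RGB)
    return ColorImage(_skcolor.rgb2lab(rgb.pixels / 255.0), LAB)


def to_gray(rgb: ColorImage) -> np.ndarray:
    """Luminance grayscale in [0, 255] (BT.601 weights), as a 2-D array."""
    _require(rgb, RGB)
    return rgb.pixels @ GRAY_WEIGHTS


def convert(rgb: ColorImage, target: str, hsi_variant: str = "hsi") -> ColorImage:
    """Dispatch to the requested space; ``target="rgb"`` is the identity."""
    _require(rgb, RGB)
    if target == RGB:
        return rgb
    if target == NDI:
        return to_ndi(rgb)
    if target == HSI:
        return to_hsi(rgb, variant=hsi_variant)
    if target == LAB:
        return to_lab(rgb)
    raise ColorSpaceError(f"unknown color space {target!r}")


def load_rgb(path) -> ColorImage:
    """Load a PNG/JPEG/TIFF file as an RGB image, dropping any alpha channel."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float64)
    return ColorImage(arr, RGB)
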