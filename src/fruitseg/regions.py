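"""Recursive splitting of images into illumination-homogeneous regions.

An image is split top-down into quadrants (a quadtree) until the grayscale
standard deviation of a region falls below a stop value, or the region is
too small to split again.  Each final region carries its light level (mean
grayscale value) and an illumination group: LOW, MEDIUM, HIGH, or
OVEREXPOSED.  Group membership is decided by two tuned cutoffs T1 < T2 plus
an overexposure cutoff above which regions are treated as washed out.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

Box = tuple[int, int, int, int]  # (row_start, col_start, row_end, col_end), half-open


class LightGroup(enum.Enum):
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"
    OVEREXPOSED = "overexposed"


#: The trainable groups, in increasing order of illumination.
TRAINABLE_GROUPS = (LightGroup.LOW, LightGroup.MEDIUM, LightGroup.HIGH)


@dataclass(frozen=True)
class Region:
    box: Box
    light_level: float
    group: LightGroup | None = None

    @property
    def shape(self) -> tuple[int, int]:
        r0, c0, r1, c1 = self.box
        return (r1 - r0, c1 - c0)

    def slice(self) -> tuple[slice, slice]:
        r0, c0, r1, c1 = self.box
        return (slice(r0, r1), slice(c0, c1))


@dataclass
class SplitConfig:
    """Parameters of the recursive split and the light-group assignment.

    ``std_stop`` is the grayscale standard deviation below which a region is
    considered homogeneous.  ``t1``/``t2`` are the light-level cutoffs
    between LOW/MEDIUM and MEDIUM/HIGH; ``t_over`` marks overexposure.
    ``min_side`` prevents degenerate regions that would contain a single
    class only.
    """

    std_stop: float
    t1: float
    t2: float
    t_over: float = 250.0
    min_side: int = 16

    def __post_init__(self) -> None:
        if self.std_stop < 0:
            raise ValueError("std_stop must be >= 0")
        if not (0 < self.t1 < self.t2 <= self.t_over <= 255):
            raise ValueError(
                f"need 0 < t1 < t2 <= t_over <= 255, got "
                f"t1={self.t1}, t2={self.t2}, t_over={self.t_over}"
            )
        if self.min_side < 1:
            raise ValueError("min_side must be >= 1")

    def to_dict(self) -> dict:
        return {
            "std_stop": self.std_stop,
            "t1": self.t1,
            "t2": self.t2,
            "t_over": self.t_over,
            "min_side": self.min_side,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplitConfig":
        return cls(**d)


def light_level(gray: np.ndarray, box: Box) -> float:
    """Mean grayscale value inside ``box``."""
    r0, c0, r1, c1 = box
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"empty box {box}")
    return float(gray[r0:r1, c0:c1].mean())


def categorize(level: float, cfg: SplitConfig) -> LightGroup:
    """Assign a light level to its illumination group.

    Cutoff boundaries go to the upper group; levels above ``t_over`` are
    OVEREXPOSED and are excluded from training.
    """
    if level > cfg.t_over:
        return LightGroup.OVEREXPOSED
    if level >= cfg.t2:
        return LightGroup.HIGH
    if level >= cfg.t1:
        return LightGroup.MEDIUM
    return LightGroup.LOW


def split_recursive(gray: np.ndarray, cfg: SplitConfig) -> list[Region]:
    """Quadtree-split ``gray`` into illumination-homogeneous regions.

    Returns a partition of the image: regions are pairwise disjoint and
    cover every pixel.  A region is final when its grayscale standard
    deviation is <= ``cfg.std_stop`` or either side is shorter than
    ``2 * cfg.min_side`` (no further 4-way split possible).
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2 or gray.size == 0:
        raise ValueError("expected a nonempty 2-D grayscale image")
    out: list[Region] = []
    stack: list[Box] = [(0, 0, gray.shape[0], gray.shape[1])]
    while stack:
        r0, c0, r1, c1 = stack.pop()
        sub = gray[r0:r1, c0:c1]
        h, w = r1 - r0, c1 - c0
        if sub.std() <= cfg.std_stop or min(h, w) < 2 * cfg.min_side:
            level = float(sub.mean())
            out.append(Region((r0, c0, r1, c1), level, categorize(level, cfg)))
            continue
        rm = r0 + h // 2
        cm = c0 + w // 2
        # pushed in reverse so regions pop in row-major order
        stack.extend(
            [(rm, cm, r1, c1), (rm, c0, r1, cm), (r0, cm, rm, c1), (r0, c0, rm, cm)]
        )
    return out


def grid_tiles(gray: np.ndarray, fraction: float = 0.01) -> list[Region]:
    """Tile the image with squares of area ~``fraction`` of the image.

    Used by the tuning stage to sample the light-level distribution: tiles
    partition the image exactly, with edge tiles truncated.  Group
    assignment is deferred (``group=None``) because the cutoffs are what
    the sampling is meant to determine.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    h, w = gray.shape
    side = int(round(math.sqrt(fraction * h * w)))
    if side < 1:
        raise ValueError(f"fraction {fraction} yields a tile smaller than 1 px")
    tiles: list[Region] = []
    for r0 in range(0, h, side):
        for c0 in range(0, w, side):
            box = (r0, c0, min(r0 + side, h), min(c0 + side, w))
            tiles.append(Region(box, light_level(gray, box)))
    return tiles
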