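"""Grayscale-to-binary conversion and the grayscale/percent threshold convention.

A threshold is expressed both as a grayscale level g in [0, 255] and as a
percentage of the full intensity range.  The percent convention divides by
256 (the number of representable levels), i.e. percent = 100*g/256; this is
the convention that makes every printed level/percent pair in the source
analyses consistent (110 <-> 42.96875, 95 <-> 37.109375, 80 <-> 31.25).

Pixels exactly at the threshold count as foreground (>= rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_io import GrayImage

#: Number of grayscale levels; denominator of the percent convention.
FULL_SCALE = 256


def percent_of(gray_level: int) -> float:
    """Percent of full scale for a grayscale threshold level.

    percent = 100 * g / 256, exact in binary floating point.
    """
    g = int(gray_level)
    if g != gray_level or not (0 <= g <= 255):
        raise ValueError(f"gray_level must be an integer in [0, 255], got {gray_level}")
    return 100.0 * g / FULL_SCALE


def gray_of(percent: float) -> int:
    """Invert percent_of on the grid of representable levels."""
    g = percent * FULL_SCALE / 100.0
    gi = int(round(g))
    if abs(g - gi) > 1e-9 or not (0 <= gi <= 255):
        raise ValueError(f"{percent}% does not correspond to an integer gray level")
    return gi


@dataclass(frozen=True)
class ThresholdSpec:
    """A binarization cut level with its percent-of-full-scale representation."""

    gray_level: int

    def __post_init__(self) -> None:
        percent_of(self.gray_level)  # validates range

    @property
    def percent(self) -> float:
        return percent_of(self.gray_level)

    def __str__(self) -> str:  # e.g. "110 (42.9688%)"
        return f"{self.gray_level} ({self.percent:.4f}%)"


@dataclass(frozen=True)
class BinaryImage:
    """A {0,1} mask with the threshold that produced it (when applicable)."""

    pixels: np.ndarray
    provenance: ThresholdSpec | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("mask must be a non-empty 2D array")
        if not np.isin(px, (0, 1)).all():
            raise ValueError("mask pixels must be 0 or 1")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def foreground_count(self) -> int:
        return int(self.pixels.sum())


def binarize(image: GrayImage, t: ThresholdSpec | int) -> BinaryImage:
    """Binarize: pixel -> 1 iff intensity >= gray_level, else 0."""
    if not isinstance(t, ThresholdSpec):
        t = ThresholdSpec(int(t))
    mask = (image.pixels >= t.gray_level).astype(np.uint8)
    return BinaryImage(pixels=mask, provenance=t)


def threshold_grid(start_level: int = 25, stop_level: int = 155,
                   step: int = 5) -> list[ThresholdSpec]:
    """Inclusive arithmetic grid of thresholds; default 25..155 step 5."""
    if step < 1:
        raise ValueError("step must be >= 1")
    if not (0 <= start_level <= stop_level <= 255):
        raise ValueError("need 0 <= start <= stop <= 255")
    levels = range(int(start_level), int(stop_level) + 1, int(step))
    grid = [ThresholdSpec(g) for g in levels]
    if not grid:
        raise ValueError("empty threshold grid")
    return grid
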