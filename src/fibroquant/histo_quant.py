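"""Picrosirius-red collagen histomorphometry.

Collagen appears as picrosirius-red stained area under bright-field
illumination. The stained colour is extracted by explicit per-channel
threshold bounds, the stained area is expressed as a percentage of the
total lung surface analyzed, several slides per animal are averaged, and
each animal's mean percentage is divided by the saline-group mean to give
the unitless picrosirius factor (saline mean factor = 1 by construction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv

__all__ = [
    "StainThreshold",
    "SlideMeasurement",
    "default_picrosirius_threshold",
    "measure_slide",
    "animal_mean",
    "picrosirius_factors",
]


@dataclass(frozen=True)
class StainThreshold:
    """Per-channel colour bounds defining "picrosirius-coloured".

    ``colorspace`` is ``"rgb"`` (bounds on 0-255 channels) or ``"hsv"``
    (bounds on scikit-image's 0-1 hue/saturation/value). Bounds are
    inclusive; ``lower <= upper`` per channel.
    """

    colorspace: str
    lower: tuple[float, float, float]
    upper: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.colorspace not in {"rgb", "hsv"}:
            raise ValueError("colorspace must be 'rgb' or 'hsv'")
        if any(l > u for l, u in zip(self.lower, self.upper)):
            raise ValueError("lower bound exceeds upper bound")

    def contains(self, image: np.ndarray) -> np.ndarray:
        """Boolean mask of pixels inside all channel bounds."""
        if image.ndim != 3 or image.shape[2] < 3:
            raise ValueError("expected an RGB image")
        rgb = image[..., :3]
        chans = rgb2hsv(rgb) if self.colorspace == "hsv" else rgb.astype(float)
        lo = np.asarray(self.lower)
        hi = np.asarray(self.upper)
        return np.all((chans >= lo) & (chans <= hi), axis=-1)


def default_picrosirius_threshold() -> StainThreshold:
    """Default HSV window for picrosirius red under bright field: a red hue
    near the top of the hue circle with appreciable saturation. The exact
    bounds are a configuration choice and are recorded with every
    measurement."""
    return StainThreshold(colorspace="hsv",
                          lower=(0.88, 0.25, 0.15),
                          upper=(1.00, 1.00, 1.00))


@dataclass
class SlideMeasurement:
    """Stained area and percent of lung surface for one slide."""

    stained_area_px: int
    total_lung_area_px: int
    percent_stained: float
    stained_area_mm2: float | None = None
    total_lung_area_mm2: float | None = None

    def __post_init__(self) -> None:
        if self.stained_area_px > self.total_lung_area_px:
            raise ValueError("stained area exceeds lung area")
        if not 0.0 <= self.percent_stained <= 100.0:
            raise ValueError("percent_stained must lie in [0, 100]")


def measure_slide(slide: np.ndarray,
                  stain: StainThreshold | None = None,
                  lung_mask: np.ndarray | None = None,
                  background_level: int = 240,
                  mm_per_px: float | None = None) -> SlideMeasurement:
    """Measure stained area on an 8-bit RGB slide.

    If ``lung_mask`` is absent, the total lung surface is taken as the
    non-background pixels, where background means every channel at or above
    ``background_level`` (near-white airspace/glass).
    """
    slide = np.asarray(slide)
    if slide.ndim != 3 or slide.shape[2] < 3 or slide.dtype != np.uint8:
        raise ValueError("slide must be an 8-bit RGB image")
    stain = stain or default_picrosirius_threshold()
    if lung_mask is not None:
        lung = np.asarray(lung_mask).astype(bool)
        if lung.shape != slide.shape[:2]:
            raise ValueError("lung_mask shape does not match slide")
    else:
        lung = ~np.all(slide[..., :3] >= background_level, axis=-1)
    total = int(lung.sum())
    if total == 0:
        raise ValueError("zero total lung area")
    stained = int((stain.contains(slide) & lung).sum())
    area_scale = mm_per_px ** 2 if mm_per_px else None
    return SlideMeasurement(
        stained_area_px=stained,
        total_lung_area_px=total,
        percent_stained=100.0 * stained / total,
        stained_area_mm2=stained * area_scale if area_scale else None,
        total_lung_area_mm2=total * area_scale if area_scale else None,
    )


def animal_mean(measurements: Sequence[SlideMeasurement]) -> float:
    """Mean percent stained over an animal's slides (typically several
    slices per lung)."""
    if not measurements:
        raise ValueError("no measurements")
    return float(np.mean([m.percent_stained for m in measurements]))


def picrosirius_factors(animal_means: pd.DataFrame,
                        saline_group: str = "Saline",
                        percent_col: str = "mean_percent",
                        group_col: str = "group") -> pd.DataFrame:
    """Express each animal's collagen content relative to the saline-group
    mean percent (the picrosirius factor).

    ``animal_means`` needs columns ``animal_id``, ``group`` and
    ``mean_percent``. The mean factor over the saline group is exactly 1.
    """
    if group_col not in animal_means or percent_col not in animal_means:
        raise ValueError(f"need columns {group_col!r} and {percent_col!r}")
    saline = animal_means.loc[animal_means[group_col] == saline_group,
                              percent_col]
    if saline.empty:
        raise ValueError(f"saline group {saline_group!r} is empty")
    ref = float(saline.mean())
    if ref <= 0:
        raise ValueError("undefined factor: saline-group mean percent is 0")
    out = animal_means.copy()
    out["picrosirius_factor"] = out[percent_col] / ref
    return out
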