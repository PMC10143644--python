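"""RGB plant-view segmentation and the optical indices PSA, HUE and SI.

Conveyor phenotyping platforms image each plant three times — one top view
(TV) and two side views 90° apart (SV0, SV90).  From the plant masks of
those views three optical indices are derived:

* **PSA** (projected shoot area): the summed plant-pixel area of the three
  views, scaled to cm² by a per-pixel calibration factor — a proxy for
  shoot biomass.
* **HUE**: the arithmetic mean hue angle of plant pixels on the standard
  0–360° wheel (green = 120°, yellow = 60°); leaf colour drifts from green
  toward yellow as chlorophyll breaks down.
* **SI** (senescence index): the fraction of green-region pixels
  (hue 60–180°) that fall outside the stricter "greener" region
  (80–180°), i.e. the yellowed share of the canopy, computed on side views.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv

__all__ = [
    "RGBView",
    "OIRecord",
    "segment_rgb",
    "pixel_hues",
    "psa",
    "hue_index",
    "senescence_index",
    "compute_oi_record",
]

VIEWS = ("TV", "SV0", "SV90")

# hue bands of the senescence index, degrees, [left, right)
GREEN_BAND = (60.0, 180.0)
GREENER_BAND = (80.0, 180.0)


class UndefinedSenescenceError(ValueError):
    """No pixels in the green hue band: SI is undefined (distinct from 0)."""


@dataclass
class RGBView:
    """One 8-bit RGB frame with its view label and area calibration."""

    image: np.ndarray
    view: str
    px_area_cm2: float = 1.0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be H×W×3")
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")
        if not self.px_area_cm2 > 0:
            raise ValueError("px_area_cm2 must be positive")


@dataclass(frozen=True)
class OIRecord:
    psa: float  # cm²
    hue: float  # degrees
    si: float   # fraction in [0, 1]


def pixel_hues(image: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Hue of (masked) pixels in degrees on the 0–360° wheel."""
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = img / 255.0
    hsv = rgb2hsv(img)
    hues = hsv[..., 0] * 360.0
    return hues[np.asarray(mask, dtype=bool)] if mask is not None else hues


def segment_rgb(
    view: RGBView, hue_range: tuple[float, float] = (60.0, 180.0), value_cutoff: float = 0.15
) -> np.ndarray:
    """Plant mask by a hue-range + brightness rule.

    A pixel is plant if its hue lies in ``hue_range`` (degrees, closed-left/
    open-right) and its HSV value exceeds ``value_cutoff`` — enough to
    separate green foliage from a near-black background.  An empty mask is
    a legitimate outcome (bare pot).
    """
    img = view.image / 255.0 if view.image.dtype == np.uint8 else view.image
    hsv = rgb2hsv(img)
    hue_deg = hsv[..., 0] * 360.0
    lo, hi = hue_range
    return (hue_deg >= lo) & (hue_deg < hi) & (hsv[..., 2] > value_cutoff)


def psa(masks: dict[str, np.ndarray], px_area_cm2: float) -> float:
    """Projected shoot area: total plant pixels of TV + SV0 + SV90, in cm²."""
    missing = [v for v in VIEWS if v not in masks]
    if missing:
        raise ValueError(f"missing views: {missing}")
    if not px_area_cm2 > 0:
        raise ValueError("px_area_cm2 must be positive")
    total_px = sum(int(np.asarray(masks[v], dtype=bool).sum()) for v in VIEWS)
    return total_px * px_area_cm2


def hue_index(view: RGBView, mask: np.ndarray) -> float:
    """Mean hue (degrees) of plant pixels.

    Arithmetic, not circular: leaf hues live in 60–180°, far from the 0/360
    wrap, so the plain mean is well defined.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return float(pixel_hues(view.image, mask).mean())


def _si_one_view(hues: np.ndarray) -> float:
    gas = int(((hues >= GREEN_BAND[0]) & (hues < GREEN_BAND[1])).sum())
    if gas == 0:
        raise UndefinedSenescenceError("no pixels in the 60–180° green band; SI undefined")
    geras = int(((hues >= GREENER_BAND[0]) & (hues < GREENER_BAND[1])).sum())
    return (gas - geras) / gas


def senescence_index(
    side_views: RGBView | list[RGBView], masks: np.ndarray | list[np.ndarray]
) -> float:
    """SI = (GAS − GerAS)/GAS per side view, averaged over the views given.

    GAS counts masked pixels with hue in [60°, 180°) and GerAS those in
    [80°, 180°); the index is the yellowed fraction of the green canopy.
    Raises :class:`UndefinedSenescenceError` when GAS is zero.
    """
    if isinstance(side_views, RGBView):
        side_views, masks = [side_views], [masks]
    if len(side_views) != len(masks) or not side_views:
        raise ValueError("need matching, non-empty view and mask lists")
    vals = []
    for view, mask in zip(side_views, masks):
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError(f"empty mask for view {view.view}")
        vals.append(_si_one_view(pixel_hues(view.image, mask)))
    return float(np.mean(vals))


def compute_oi_record(
    views: dict[str, RGBView],
    px_area_cm2: float,
    masks: dict[str, np.ndarray] | None = None,
) -> OIRecord:
    """All three optical indices for one plant acquisition.

    Masks are computed with :func:`segment_rgb` unless supplied.  HUE is
    the pixel-weighted mean over all three views; SI averages SV0 and SV90.
    """
    missing = [v for v in VIEWS if v not in views]
    if missing:
        raise ValueError(f"missing views: {missing}")
    if masks is None:
        masks = {v: segment_rgb(views[v]) for v in VIEWS}
    area = psa(masks, px_area_cm2)
    all_hues = np.concatenate(
        [pixel_hues(views[v].image, masks[v]) for v in VIEWS if masks[v].any()]
    )
    if all_hues.size == 0:
        raise ValueError("no plant pixels in any view")
    hue = float(all_hues.mean())
    si = senescence_index(
        [views["SV0"], views["SV90"]], [masks["SV0"], masks["SV90"]]
    )
    return OIRecord(psa=area, hue=hue, si=si)
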