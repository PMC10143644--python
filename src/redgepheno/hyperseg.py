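"""One-band percentile segmentation of hypercubes and storage accounting.

The segmentation strategy assumes a dark, matt background and a plant whose
NIR reflectance is high: on a single well-separating band (default 750 nm,
the top of the red edge) the brightest pixels are leaf regions facing the
camera under direct illumination.  Selecting pixels above a high percentile
(default the 96th) of the panel-cropped frame therefore isolates
illuminated, near-orthogonal leaf area; the one-band binary mask is then
propagated to every band, and only the selected spectra are stored.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .hypercube_io import Hypercube, PanelRegion, band_at

__all__ = [
    "PlantMask",
    "MaskedCube",
    "ReductionReport",
    "crop_panel",
    "percentile_mask",
    "nearest_rank_threshold",
    "segment_cube",
    "reduction_report",
    "reduction_from_bytes",
]


class EmptyMaskWarning(UserWarning):
    pass


@dataclass
class PlantMask:
    """Binary plant-pixel selection with its provenance.

    ``crop`` records the rectangle (half-open, frame coordinates of the
    original cube) removed before thresholding; the mask itself lives in
    cropped-frame coordinates.
    """

    mask: np.ndarray
    source_band_nm: float
    percentile: float
    n_selected: int
    crop: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.n_selected != int(self.mask.sum()):
            raise ValueError("n_selected inconsistent with mask")


@dataclass
class MaskedCube:
    """Sparse store of a segmented cube: selected pixel coordinates plus
    per-band values at those pixels only."""

    values: np.ndarray  # (bands, n_selected)
    rows: np.ndarray
    cols: np.ndarray
    frame_shape: tuple[int, int]
    wavelengths: np.ndarray
    units: str
    plant_mask: PlantMask

    @property
    def n_pixels(self) -> int:
        return self.values.shape[1]

    def dense(self, fill: float = 0.0) -> Hypercube:
        """Reconstruct a dense cube (unselected pixels set to ``fill``)."""
        data = np.full(
            (self.values.shape[0], *self.frame_shape), fill, dtype=self.values.dtype
        )
        data[:, self.rows, self.cols] = self.values
        return Hypercube(data, self.wavelengths, self.units, "densified masked cube")

    def serialized_bytes(self) -> bytes:
        buf = io.BytesIO()
        np.savez_compressed(
            buf,
            values=self.values,
            rows=self.rows.astype(np.int32),
            cols=self.cols.astype(np.int32),
            frame_shape=np.array(self.frame_shape, dtype=np.int32),
            wavelengths=self.wavelengths,
            units=np.bytes_(self.units.encode()),
        )
        return buf.getvalue()

    def save(self, path) -> Path:
        path = Path(path)
        path.write_bytes(self.serialized_bytes())
        return path


@dataclass(frozen=True)
class ReductionReport:
    bytes_before: int
    bytes_after: int

    @property
    def reduction_pct(self) -> float:
        return 100.0 * (1.0 - self.bytes_after / self.bytes_before)

    def to_dict(self) -> dict:
        return {
            "bytes_before": self.bytes_before,
            "bytes_after": self.bytes_after,
            "reduction_pct": self.reduction_pct,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


# ---------------------------------------------------------------------------

def crop_panel(cube: Hypercube, panel: PanelRegion) -> tuple[Hypercube, tuple[int, int, int, int]]:
    """Remove the reference-panel strip from the frame.

    Keeps the largest rectangle that excludes the panel ROI: candidates are
    the full-height strips left/right of the panel and the full-width strips
    above/below it.  An empty panel ROI is the identity (no crop).

    Returns the cropped cube and the (row0, col0, row1, col1) rectangle of
    the original frame that was KEPT.
    """
    n_rows, n_cols = cube.frame_shape
    if panel.is_empty:
        return cube, (0, 0, n_rows, n_cols)
    panel.validate_within(cube.frame_shape)
    r0, c0, r1, c1 = panel.roi
    candidates = [
        (0, 0, n_rows, c0),        # left of panel
        (0, c1, n_rows, n_cols),   # right of panel
        (0, 0, r0, n_cols),        # above panel
        (r1, 0, n_rows, n_cols),   # below panel
    ]
    keep = max(candidates, key=lambda r: (r[2] - r[0]) * (r[3] - r[1]))
    if (keep[2] - keep[0]) * (keep[3] - keep[1]) <= 0:
        raise ValueError("panel covers the frame; crop would be empty")
    kr0, kc0, kr1, kc1 = keep
    cropped = Hypercube(
        cube.data[:, kr0:kr1, kc0:kc1].copy(),
        cube.wavelengths,
        cube.units,
        cube.provenance + f" | crop_panel(keep={keep})",
    )
    return cropped, keep


def nearest_rank_threshold(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the value at rank ceil(p·n/100) of the
    sorted sample (1-based)."""
    flat = np.sort(np.asarray(values).ravel())
    n = flat.size
    if n == 0:
        raise ValueError("empty frame")
    rank = int(np.ceil(percentile * n / 100.0))
    rank = min(max(rank, 1), n)
    return float(flat[rank - 1])


def percentile_mask(
    band_image: np.ndarray,
    percentile: float = 96.0,
    source_band_nm: float = float("nan"),
    crop: tuple[int, int, int, int] | None = None,
) -> PlantMask:
    """Select pixels strictly above the nearest-rank percentile threshold.

    On a frame of all-distinct values this retains the top (100−p)% of
    pixels to within one pixel.  A constant frame yields an empty mask and
    an :class:`EmptyMaskWarning`.
    """
    band_image = np.asarray(band_image)
    if band_image.size == 0:
        raise ValueError("empty frame")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    thr = nearest_rank_threshold(band_image, percentile)
    mask = band_image > thr
    n_sel = int(mask.sum())
    if n_sel == 0:
        warnings.warn(
            "percentile mask is empty (constant or near-constant frame)",
            EmptyMaskWarning,
            stacklevel=2,
        )
    return PlantMask(mask, source_band_nm, percentile, n_sel, crop)


def segment_cube(
    cube: Hypercube,
    panel: PanelRegion,
    band_nm: float = 750.0,
    percentile: float = 96.0,
    red_band_nm: float = 650.0,
    red_reflectance_bound: float = 0.5,
) -> tuple[MaskedCube, PlantMask]:
    """Crop the panel, threshold the band nearest ``band_nm``, and apply the
    resulting one-band mask to every band.

    A plausibility guard warns when the masked mean reflectance at
    ``red_band_nm`` exceeds ``red_reflectance_bound``: vegetation is dark in
    the red, so a bright masked red band suggests the mask leaked onto
    non-plant pixels (plant smaller than the retained top fraction).
    """
    if cube.units != "reflectance":
        raise ValueError(f"segment_cube requires a reflectance cube, got {cube.units}")
    cropped, keep = crop_panel(cube, panel)
    idx, actual_nm = band_at(cropped, band_nm)
    pmask = percentile_mask(cropped.data[idx], percentile, actual_nm, crop=keep)
    if pmask.n_selected == 0:
        raise ValueError("segmentation produced an empty mask")
    rows, cols = np.nonzero(pmask.mask)
    values = cropped.data[:, rows, cols]
    masked = MaskedCube(
        values=values,
        rows=rows,
        cols=cols,
        frame_shape=cropped.frame_shape,
        wavelengths=cropped.wavelengths,
        units=cropped.units,
        plant_mask=pmask,
    )
    try:
        ridx, _ = band_at(cropped, red_band_nm)
        red_mean = float(values[ridx].mean())
        if red_mean > red_reflectance_bound:
            warnings.warn(
                f"masked mean reflectance {red_mean:.3f} at {red_band_nm:g} nm exceeds "
                f"{red_reflectance_bound}; mask may include bright background",
                UserWarning,
                stacklevel=2,
            )
    except ValueError:
        pass  # red guard band outside the cube's range
    return masked, pmask


def _dense_serialized_bytes(cube: Hypercube) -> bytes:
    buf = io.BytesIO()
    np.savez_compressed(buf, data=cube.data, wavelengths=cube.wavelengths)
    return buf.getvalue()


def reduction_report(cube_before: Hypercube, masked_after: MaskedCube) -> ReductionReport:
    """Storage saved by the sparse masked store relative to the dense cube,
    both serialized with the same compressed container."""
    before = len(_dense_serialized_bytes(cube_before))
    after = len(masked_after.serialized_bytes())
    return ReductionReport(before, after)


def reduction_from_bytes(bytes_before: int, bytes_after: int) -> ReductionReport:
    if bytes_before <= 0 or bytes_after < 0:
        raise ValueError("sizes must be positive")
    return ReductionReport(int(bytes_before), int(bytes_after))
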