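"""Hypercube container, ENVI/TIFF I/O and radiometric calibration.

A hypercube is a 3-D array ``[band, row, col]`` with a uniform ascending
wavelength grid (nm) and an explicit unit state.  Units follow the
acquisition chain of a snapshot VIS/NIR camera:

    DN  --(gain/offset)-->  radiance  --(white panel ratio)-->  reflectance

Reflectance calibration divides each band by the mean radiance over a
white Lambertian reference panel of known nominal reflectance (default
0.75), optionally rescaling so the panel maps to its true value.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "Hypercube",
    "PanelRegion",
    "UNITS",
    "read_cube",
    "write_cube",
    "dn_to_radiance",
    "to_reflectance",
    "band_at",
]

UNITS = ("dn", "radiance", "reflectance")

_ENVI_DTYPES = {4: np.float32, 5: np.float64, 12: np.uint16, 2: np.int16, 3: np.int32}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


class UnitStateError(ValueError):
    """Operation applied to a cube in the wrong unit state."""


@dataclass
class Hypercube:
    """Spectral image cube.

    Parameters
    ----------
    data : ndarray, shape (bands, rows, cols)
    wavelengths : ndarray of nm, strictly increasing, uniform spacing
    units : {"dn", "radiance", "reflectance"}
        Radiance is in mW/(nm·sr·m²).
    provenance : free-text processing history.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    units: str
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D [band,row,col], got ndim={self.data.ndim}")
        if len(self.wavelengths) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.wavelengths)} wavelengths for {self.data.shape[0]} bands"
            )
        if self.units not in UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {UNITS}")
        dw = np.diff(self.wavelengths)
        if len(dw) and (np.any(dw <= 0) or np.ptp(dw) > 1e-9):
            raise ValueError("wavelengths must be strictly increasing with uniform spacing")
        if self.units == "reflectance" and np.any(self.data < 0):
            raise ValueError("reflectance cube contains negative values")

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def band_spacing(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])


@dataclass(frozen=True)
class PanelRegion:
    """White-reference panel location: half-open 0-based rectangle
    (row0, col0, row1, col1) and the panel's nominal reflectance."""

    roi: tuple[int, int, int, int]
    nominal_reflectance: float = 0.75

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.roi
        if r1 < r0 or c1 < c0:
            raise ValueError(f"malformed roi {self.roi}")
        if not 0 < self.nominal_reflectance <= 1:
            raise ValueError("nominal_reflectance must be in (0, 1]")

    @property
    def is_empty(self) -> bool:
        r0, c0, r1, c1 = self.roi
        return r1 == r0 or c1 == c0

    def slices(self) -> tuple[slice, slice]:
        r0, c0, r1, c1 = self.roi
        return slice(r0, r1), slice(c0, c1)

    def validate_within(self, frame_shape: tuple[int, int]) -> None:
        r0, c0, r1, c1 = self.roi
        if r0 < 0 or c0 < 0 or r1 > frame_shape[0] or c1 > frame_shape[1]:
            raise ValueError(f"panel roi {self.roi} outside frame {frame_shape}")


# ---------------------------------------------------------------------------
# calibration

def dn_to_radiance(cube: Hypercube, gain, offset=0.0) -> Hypercube:
    """Convert a digital-number cube to radiance, band-wise linear model.

    radiance = gain·DN + offset, with gain/offset scalar or per-band.
    """
    if cube.units != "dn":
        raise UnitStateError(f"dn_to_radiance requires DN units, cube is {cube.units}")
    gain = np.asarray(gain, dtype=float)
    offset = np.asarray(offset, dtype=float)
    for name, arr in (("gain", gain), ("offset", offset)):
        if arr.ndim not in (0, 1) or (arr.ndim == 1 and len(arr) != cube.n_bands):
            raise ValueError(f"{name} must be scalar or per-band (length {cube.n_bands})")
    g = gain.reshape(-1, 1, 1) if gain.ndim == 1 else gain
    o = offset.reshape(-1, 1, 1) if offset.ndim == 1 else offset
    return Hypercube(
        data=g * cube.data.astype(float) + o,
        wavelengths=cube.wavelengths,
        units="radiance",
        provenance=cube.provenance + " | dn_to_radiance",
    )


def to_reflectance(
    cube: Hypercube, panel: PanelRegion, apply_panel_scale: bool = True
) -> Hypercube:
    """Reflectance by ratio against the white reference panel.

    Per band, Ref = Rad / RT with RT the mean radiance over the panel ROI.
    With ``apply_panel_scale`` (default) the ratio is multiplied by the
    panel's nominal reflectance so the panel itself maps to its true value;
    switching it off gives the bare ratio.
    """
    if cube.units != "radiance":
        raise UnitStateError(f"to_reflectance requires radiance units, cube is {cube.units}")
    if panel.is_empty:
        raise ValueError("panel roi is empty")
    panel.validate_within(cube.frame_shape)
    rs, cs = panel.slices()
    rt = cube.data[:, rs, cs].mean(axis=(1, 2))
    if np.any(rt <= 0):
        bad = np.where(rt <= 0)[0]
        raise ValueError(f"non-positive panel radiance in bands {bad.tolist()}")
    ref = cube.data / rt.reshape(-1, 1, 1)
    if apply_panel_scale:
        ref = ref * panel.nominal_reflectance
    return Hypercube(
        data=ref,
        wavelengths=cube.wavelengths,
        units="reflectance",
        provenance=cube.provenance
        + f" | to_reflectance(panel={panel.roi}, scale={apply_panel_scale})",
    )


def band_at(cube: Hypercube, target_nm: float) -> tuple[int, float]:
    """Index and actual wavelength of the band nearest ``target_nm``.

    Ties between two equidistant bands go to the longer wavelength.
    """
    wl = cube.wavelengths
    if not wl[0] <= target_nm <= wl[-1]:
        raise ValueError(f"{target_nm} nm outside [{wl[0]}, {wl[-1]}] nm")
    dist = np.abs(wl - target_nm)
    # reversed argmin prefers the longer wavelength on exact ties
    idx = len(wl) - 1 - int(np.argmin(dist[::-1]))
    return idx, float(wl[idx])


# ---------------------------------------------------------------------------
# I/O: ENVI header + raw, multi-page TIFF

def write_cube(cube: Hypercube, path, format: str | None = None, interleave: str = "bsq") -> Path:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "envi":
        _write_envi(cube, path, interleave)
    else:
        _write_tiff(cube, path)
    return path


def read_cube(path, format: str | None = None) -> Hypercube:
    path = Path(path)
    fmt = _infer_format(path, format)
    return _read_envi(path) if fmt == "envi" else _read_tiff(path)


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        f = format.lower()
        if f not in ("envi", "tiff", "tif"):
            raise ValueError(f"unknown format {format!r}")
        return "tiff" if f.startswith("tif") else "envi"
    suf = path.suffix.lower()
    if suf in (".tif", ".tiff"):
        return "tiff"
    if suf in (".hdr", ".bsq", ".bil", ".bip", ".img", ".raw"):
        return "envi"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def _write_envi(cube: Hypercube, path: Path, interleave: str) -> None:
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unknown interleave {interleave!r}")
    data_path = path.with_suffix("." + interleave)
    hdr_path = path.with_suffix(".hdr")
    code = _ENVI_CODES.get(cube.data.dtype)
    if code is None:
        raise ValueError(f"unsupported dtype {cube.data.dtype} for ENVI")
    # ENVI axis orders: BSQ (band,row,col), BIL (row,band,col), BIP (row,col,band)
    order = {"bsq": (0, 1, 2), "bil": (1, 0, 2), "bip": (1, 2, 0)}[interleave]
    np.ascontiguousarray(cube.data.transpose(order)).tofile(data_path)
    bands, lines, samples = cube.data.shape
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    hdr_path.write_text(
        "ENVI\n"
        f"description = {{{cube.provenance or 'redgepheno cube'}}}\n"
        f"samples = {samples}\nlines = {lines}\nbands = {bands}\n"
        "header offset = 0\nfile type = ENVI Standard\n"
        f"data type = {code}\ninterleave = {interleave}\nbyte order = 0\n"
        "wavelength units = Nanometers\n"
        f"units = {cube.units}\n"
        f"wavelength = {{{wl}}}\n"
    )


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    # collapse {...} blocks onto one line before splitting
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" in line:
            key, val = line.split("=", 1)
            fields[key.strip().lower()] = val.strip()
    return fields


def _read_envi(path: Path) -> Hypercube:
    hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FileNotFoundError(hdr_path)
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        interleave = fields["interleave"].lower()
        code = int(fields["data type"])
    except KeyError as exc:
        raise ValueError(f"ENVI header missing field {exc}") from exc
    if "wavelength" not in fields:
        raise ValueError("ENVI header lacks wavelength metadata")
    wl = np.array(
        [float(t) for t in fields["wavelength"].strip("{} ").split(",") if t.strip()]
    )
    if len(wl) != bands:
        raise ValueError(f"header declares {bands} bands but lists {len(wl)} wavelengths")
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unknown interleave {interleave!r}")
    dtype = _ENVI_DTYPES.get(code)
    if dtype is None:
        raise ValueError(f"unsupported ENVI data type {code}")
    data_path = path.with_suffix("." + interleave)
    if not data_path.exists():
        data_path = path if path.suffix != ".hdr" else None
        if data_path is None or not data_path.exists():
            raise FileNotFoundError(f"no data file next to {hdr_path}")
    raw = np.fromfile(data_path, dtype=dtype)
    expected = bands * lines * samples
    if raw.size != expected:
        raise ValueError(f"data file holds {raw.size} values, header implies {expected}")
    shape = {
        "bsq": (bands, lines, samples),
        "bil": (lines, bands, samples),
        "bip": (lines, samples, bands),
    }[interleave]
    back = {"bsq": (0, 1, 2), "bil": (1, 0, 2), "bip": (2, 0, 1)}[interleave]
    data = raw.reshape(shape).transpose(back)
    units = fields.get("units", "dn")
    prov = fields.get("description", "").strip("{} ")
    return Hypercube(np.ascontiguousarray(data), wl, units, prov)


def _write_tiff(cube: Hypercube, path: Path) -> None:
    meta = {
        "wavelengths_nm": [float(w) for w in cube.wavelengths],
        "units": cube.units,
        "provenance": cube.provenance,
    }
    tifffile.imwrite(path, cube.data, description=json.dumps(meta))


def _read_tiff(path: Path) -> Hypercube:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    try:
        meta = json.loads(desc)
        wl = np.array(meta["wavelengths_nm"], dtype=float)
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"{path.name}: missing wavelength metadata") from exc
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != len(wl):
        raise ValueError(
            f"{path.name}: {data.shape[0]} planes but {len(wl)} wavelengths declared"
        )
    return Hypercube(data, wl, meta.get("units", "dn"), meta.get("provenance", ""))
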