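"""Reading, writing and describing hyperspectral reflectance cubes.

A cube is a ``lines x samples x bands`` array of unitless reflectance
together with its band calibration (center wavelength per band, nm) and
acquisition metadata.  On disk the format is an ENVI-style pair: a plain
text ``.hdr`` file with ``key = value`` entries and a raw binary file in
BSQ, BIL or BIP interleave.  In memory the layout is always band-
interleaved-by-pixel (``(line, sample, band)``, row major) regardless of
the on-disk interleave.

Conventions used throughout the package:

* 0-based indices, half-open ``[start, stop)`` ranges;
* bands are referenced by 0-based index into the calibration list;
* cubes are stored as 32-bit floats on disk and promoted to float64 in
  memory.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "BandCalibration",
    "AcquisitionMeta",
    "SpectralCube",
    "load_profile",
    "read_cube",
    "write_cube",
    "crop_cube",
    "along_track_pixel_size",
    "cross_track_pixel_size",
    "wavelength_of_band",
]

#: Named camera profiles shipped with the package (synthetic stand-in
#: calibration tables, see files under ``profiles/``).
PROFILE_FILES = {
    "vnir": "vnir1800_synthetic.txt",
    "swir": "swir384_synthetic.txt",
}

INTERLEAVES = ("bsq", "bil", "bip")


class CubeFormatError(ValueError):
    """Malformed header/binary pair or inconsistent cube metadata."""


@dataclass(frozen=True)
class BandCalibration:
    """Ordered center wavelengths (nm) of the spectral bands."""

    centers: np.ndarray
    profile: Optional[str] = None

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        if centers.ndim != 1 or centers.size == 0:
            raise CubeFormatError("calibration must be a non-empty 1-D wavelength list")
        if not np.all(np.diff(centers) > 0):
            raise CubeFormatError("band wavelengths must be strictly increasing")
        object.__setattr__(self, "centers", centers)

    def __len__(self) -> int:
        return int(self.centers.size)

    def wavelength_of_band(self, index: int) -> float:
        if not 0 <= index < len(self):
            raise IndexError(f"band index {index} out of range [0, {len(self)})")
        return float(self.centers[index])

    @classmethod
    def from_file(cls, path: str | Path, profile: Optional[str] = None) -> "BandCalibration":
        values = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            values.append(float(line))
        return cls(np.asarray(values), profile=profile)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(f"{w:.2f}" for w in self.centers) + "\n")


def load_profile(name: str) -> BandCalibration:
    """Load a named camera calibration profile ("vnir" or "swir")."""
    key = name.lower()
    if key not in PROFILE_FILES:
        raise KeyError(f"unknown profile {name!r}; available: {sorted(PROFILE_FILES)}")
    ref = resources.files("cuscuta_hsi") / "profiles" / PROFILE_FILES[key]
    with resources.as_file(ref) as path:
        return BandCalibration.from_file(path, profile=key)


@dataclass(frozen=True)
class AcquisitionMeta:
    """Line-scan acquisition geometry; any field may be absent (None)."""

    camera_id: Optional[str] = None
    exposure_ms: Optional[float] = None
    belt_speed_mm_s: Optional[float] = None
    fov_mm: Optional[float] = None
    spatial_pixels: Optional[int] = None
    working_distance_mm: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("exposure_ms", "belt_speed_mm_s", "fov_mm", "spatial_pixels",
                     "working_distance_mm"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")


@dataclass
class SpectralCube:
    """Reflectance cube with band calibration and acquisition metadata."""

    reflectance: np.ndarray
    calibration: BandCalibration
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self) -> None:
        arr = np.asarray(self.reflectance, dtype=np.float64)
        if arr.ndim != 3:
            raise CubeFormatError("reflectance must be a (lines, samples, bands) array")
        if arr.shape[2] != len(self.calibration):
            raise CubeFormatError(
                f"cube has {arr.shape[2]} bands but calibration lists {len(self.calibration)}"
            )
        if not np.all(np.isfinite(arr)):
            raise CubeFormatError("reflectance contains non-finite values")
        self.reflectance = arr

    @property
    def lines(self) -> int:
        return self.reflectance.shape[0]

    @property
    def samples(self) -> int:
        return self.reflectance.shape[1]

    @property
    def bands(self) -> int:
        return self.reflectance.shape[2]

    def describe(self) -> dict:
        wl = self.calibration.centers
        return {
            "lines": self.lines,
            "samples": self.samples,
            "bands": self.bands,
            "wavelength_min_nm": float(wl[0]),
            "wavelength_max_nm": float(wl[-1]),
            "profile": self.calibration.profile,
            "reflectance_min": float(self.reflectance.min()),
            "reflectance_max": float(self.reflectance.max()),
        }


# ---------------------------------------------------------------------------
# ENVI-style I/O

_REQUIRED_KEYS = ("lines", "samples", "bands", "interleave", "data type")

# numeric codes from the ENVI header convention
_DTYPES = {4: np.float32, 5: np.float64}
_DTYPE_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def _parse_header(text: str) -> dict:
    """Parse ``key = value`` pairs; ``{...}`` lists may span lines."""
    entries: dict[str, str] = {}
    # normalise: join brace blocks onto one line
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        line = line.strip()
        if not line or line.upper() == "ENVI" or line.startswith(";"):
            continue
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        entries[key.strip().lower()] = value.strip()
    return entries


def _header_path(path: Path) -> Path:
    if path.suffix == ".hdr":
        return path
    return path.with_name(path.name + ".hdr")


def _data_path(path: Path) -> Path:
    if path.suffix == ".hdr":
        return path.with_name(path.name[: -len(".hdr")])
    return path


def read_cube(path: str | Path, meta: Optional[AcquisitionMeta] = None) -> SpectralCube:
    """Read an ENVI-style header+binary pair into a :class:`SpectralCube`.

    ``path`` may point at either the binary file or its ``.hdr``.  All
    three interleaves (BSQ/BIL/BIP) are accepted and normalised to the
    in-memory ``(line, sample, band)`` layout.
    """
    path = Path(path)
    hdr_path, data_path = _header_path(path), _data_path(path)
    if not hdr_path.exists():
        raise FileNotFoundError(f"missing header file {hdr_path}")
    if not data_path.exists():
        raise FileNotFoundError(f"missing binary cube {data_path}")

    header = _parse_header(hdr_path.read_text())
    missing = [k for k in _REQUIRED_KEYS if k not in header]
    if missing:
        raise CubeFormatError(f"header missing required keys: {missing}")

    lines, samples, bands = (int(header[k]) for k in ("lines", "samples", "bands"))
    interleave = header["interleave"].lower()
    if interleave not in INTERLEAVES:
        raise CubeFormatError(f"unknown interleave {interleave!r}")
    dtype_code = int(header["data type"])
    if dtype_code not in _DTYPES:
        raise CubeFormatError(f"unsupported data type code {dtype_code}")
    dtype = _DTYPES[dtype_code]

    raw = np.fromfile(data_path, dtype=dtype)
    expected = lines * samples * bands
    if raw.size != expected:
        raise CubeFormatError(
            f"binary holds {raw.size} values but header implies {expected} "
            f"({lines}x{samples}x{bands})"
        )

    if interleave == "bsq":      # (band, line, sample)
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":    # (line, band, sample)
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:                        # bip: (line, sample, band)
        cube = raw.reshape(lines, samples, bands)

    if "wavelength" in header:
        wl_text = header["wavelength"].strip().lstrip("{").rstrip("}")
        centers = np.array([float(v) for v in wl_text.replace(",", " ").split()])
        if centers.size != bands:
            raise CubeFormatError("wavelength list length does not match band count")
        calibration = BandCalibration(centers, profile=header.get("profile"))
    else:
        raise CubeFormatError("header has no wavelength list")

    return SpectralCube(cube.astype(np.float64), calibration, meta or AcquisitionMeta())


def write_cube(cube: SpectralCube, path: str | Path, interleave: str = "bsq") -> Path:
    """Write ``cube`` as float32 binary plus ENVI-style ``.hdr``.

    Returns the binary path.  ``read_cube(write_cube(c))`` reproduces the
    float32-rounded values bit-exactly.
    """
    interleave = interleave.lower()
    if interleave not in INTERLEAVES:
        raise ValueError(f"interleave must be one of {INTERLEAVES}, got {interleave!r}")
    if cube.lines == 0 or cube.samples == 0 or cube.bands == 0:
        raise ValueError("refusing to write an empty cube")
    path = Path(path)
    data_path = _data_path(path)
    data_path.parent.mkdir(parents=True, exist_ok=True)

    arr = cube.reflectance.astype(np.float32)
    if interleave == "bsq":
        flat = arr.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = arr.transpose(0, 2, 1)
    else:
        flat = arr
    flat.tofile(data_path)

    wl = ", ".join(f"{w:.4f}" for w in cube.calibration.centers)
    header_lines = [
        "ENVI",
        f"lines = {cube.lines}",
        f"samples = {cube.samples}",
        f"bands = {cube.bands}",
        "header offset = 0",
        f"data type = {_DTYPE_CODES[np.dtype(np.float32)]}",
        f"interleave = {interleave}",
        "byte order = 0",
        "wavelength = { " + wl + " }",
    ]
    if cube.calibration.profile:
        header_lines.append(f"profile = {cube.calibration.profile}")
    _header_path(data_path).write_text("\n".join(header_lines) + "\n")
    return data_path


# ---------------------------------------------------------------------------
# Geometry helpers

def crop_cube(cube: SpectralCube, row_range: Sequence[int], col_range: Sequence[int]) -> SpectralCube:
    """Spatial crop by 0-based half-open ``[start, stop)`` ranges.

    The full spectral axis and the calibration are retained.
    """
    r0, r1 = (int(v) for v in row_range)
    c0, c1 = (int(v) for v in col_range)
    if not (0 <= r0 < r1 <= cube.lines):
        raise IndexError(f"row range [{r0}, {r1}) invalid for {cube.lines} lines")
    if not (0 <= c0 < c1 <= cube.samples):
        raise IndexError(f"col range [{c0}, {c1}) invalid for {cube.samples} samples")
    return SpectralCube(cube.reflectance[r0:r1, c0:c1].copy(), cube.calibration, cube.meta)


def along_track_pixel_size(belt_speed_mm_s: float, exposure_ms: float) -> float:
    """Along-track pixel footprint (mm) of a line-scan camera.

    Equals belt speed times exposure time: the distance the conveyor
    travels while one line integrates.  E.g. 102 mm/s at 4.8 ms exposure
    gives 0.4896 mm (prints as 0.49 mm).
    """
    if belt_speed_mm_s <= 0 or exposure_ms <= 0:
        raise ValueError("belt speed and exposure must be positive")
    return belt_speed_mm_s * exposure_ms / 1000.0


def cross_track_pixel_size(fov_mm: float, spatial_pixels: int) -> float:
    """Cross-track pixel footprint (mm): field of view / spatial pixels."""
    if fov_mm <= 0 or spatial_pixels <= 0:
        raise ValueError("field of view and spatial pixel count must be positive")
    return fov_mm / spatial_pixels


def wavelength_of_band(calibration: BandCalibration, index: int) -> float:
    """Calibrated center wavelength (nm) of a 0-based band index."""
    return calibration.wavelength_of_band(index)
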