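"""Pre-processing: flat-field calibration, Savitzky-Golay spectral
smoothing, and train-set-anchored min-max normalization with a persisted
scaler.

Pipeline order is fixed: calibrate -> smooth -> scale.  Segmentation runs
on smoothed (un-normalized) reflectance; only classifier inputs are
scaled, because the normalized-difference indices are invariant to
per-pixel gain but not to a per-band affine map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.signal import savgol_filter

from .cube_io import SpectralCube
from .pixels import PixelTable

__all__ = [
    "flat_field_calibrate",
    "savitzky_golay_smooth",
    "MinMaxScaler",
    "fit_minmax",
    "apply_minmax",
    "save_scaler",
    "load_scaler",
]

logger = logging.getLogger(__name__)

SG_WINDOW = 13  # default smoothing window (bands)
SG_DEGREE = 3   # default polynomial degree


def flat_field_calibrate(raw: SpectralCube, white: SpectralCube,
                         dark: Optional[SpectralCube] = None) -> SpectralCube:
    """Convert raw counts to reflectance against a white reference.

    ``reflectance = (raw - dark) / (white - dark)`` per spatial sample
    and band.  The white (and dark) cube may have any number of lines;
    it is averaged along-track first.  Entries where ``white <= dark``
    are undefined and set to 0; their count is logged.
    """
    if white.samples != raw.samples or white.bands != raw.bands:
        raise ValueError(
            f"white reference shape (samples={white.samples}, bands={white.bands}) "
            f"does not match raw (samples={raw.samples}, bands={raw.bands})"
        )
    white_ref = white.reflectance.mean(axis=0)  # (samples, bands)
    if dark is not None:
        if dark.samples != raw.samples or dark.bands != raw.bands:
            raise ValueError("dark reference shape does not match raw cube")
        dark_ref = dark.reflectance.mean(axis=0)
    else:
        dark_ref = np.zeros_like(white_ref)

    denom = white_ref - dark_ref
    bad = denom <= 0  # (samples, bands)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (raw.reflectance - dark_ref[None]) / denom[None]
    if bad.any():
        n_bad = int(bad.sum()) * raw.lines
        out[:, bad] = 0.0
        logger.warning(
            "flat-field: white <= dark at %d cube entries; set to 0", n_bad
        )
    out = np.where(np.isfinite(out), out, 0.0)
    return SpectralCube(out, raw.calibration, raw.meta)


def savitzky_golay_smooth(data: Union[SpectralCube, np.ndarray],
                          window: int = SG_WINDOW,
                          degree: int = SG_DEGREE) -> Union[SpectralCube, np.ndarray]:
    """Savitzky-Golay smoothing of each pixel spectrum along the band axis.

    The filter is a sliding least-squares polynomial fit (default window
    13, degree 3).  Spectrum ends use the standard one-sided polynomial
    fit on the terminal window rather than padded data.  Accepts a cube
    or any array whose last axis is spectral; spatial arrangement is
    untouched.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if degree >= window:
        raise ValueError(f"degree ({degree}) must be smaller than window ({window})")
    arr = data.reflectance if isinstance(data, SpectralCube) else np.asarray(data, dtype=float)
    if arr.shape[-1] < window:
        raise ValueError(
            f"spectrum has {arr.shape[-1]} bands, fewer than window {window}"
        )
    smoothed = savgol_filter(arr, window_length=window, polyorder=degree,
                             axis=-1, mode="interp")
    if isinstance(data, SpectralCube):
        return SpectralCube(smoothed, data.calibration, data.meta)
    return smoothed


@dataclass
class MinMaxScaler:
    """Per-band min-max scaler fitted on the training split only.

    Bands where max equals min map to 0 by convention (logged).  Unseen
    data outside the training range is NOT clipped, so out-of-range
    inputs remain visible downstream.  The scaler is bound to the
    calibration profile it was fitted under and refuses application to a
    different profile.
    """

    mins: Optional[np.ndarray] = None
    maxs: Optional[np.ndarray] = None
    profile: Optional[str] = None

    @property
    def fitted(self) -> bool:
        return self.mins is not None

    def fit(self, train: Union[PixelTable, np.ndarray]) -> "MinMaxScaler":
        if isinstance(train, PixelTable):
            data, self.profile = train.spectra, train.profile
        else:
            data = np.asarray(train, dtype=float)
        if data.size == 0:
            raise ValueError("cannot fit scaler on an empty table")
        self.mins = data.min(axis=0)
        self.maxs = data.max(axis=0)
        n_const = int(np.sum(self.maxs == self.mins))
        if n_const:
            logger.warning("scaler: %d constant band(s) will map to 0", n_const)
        return self

    def _check(self, n_bands: int, profile: Optional[str]) -> None:
        if not self.fitted:
            raise RuntimeError("scaler has not been fitted")
        if n_bands != self.mins.size:
            raise ValueError(
                f"data has {n_bands} bands but scaler was fitted on {self.mins.size}"
            )
        if profile is not None and self.profile is not None and profile != self.profile:
            raise ValueError(
                f"scaler is bound to profile {self.profile!r}; refusing to scale "
                f"data from profile {profile!r}"
            )

    def transform_array(self, data: np.ndarray) -> np.ndarray:
        data = np.asarray(data, dtype=float)
        self._check(data.shape[-1], None)
        span = self.maxs - self.mins
        safe = np.where(span == 0, 1.0, span)
        return (data - self.mins) / safe

    def transform(self, data: Union[PixelTable, SpectralCube, np.ndarray]):
        if isinstance(data, PixelTable):
            self._check(data.n_bands, data.profile)
            return data.with_spectra(self.transform_array(data.spectra))
        if isinstance(data, SpectralCube):
            self._check(data.bands, data.calibration.profile)
            return self.transform_array(data.reflectance)
        return self.transform_array(data)

    def inverse_transform_array(self, data: np.ndarray) -> np.ndarray:
        data = np.asarray(data, dtype=float)
        self._check(data.shape[-1], None)
        span = self.maxs - self.mins
        safe = np.where(span == 0, 1.0, span)
        return data * safe + self.mins

    def save(self, path: str | Path) -> None:
        if not self.fitted:
            raise RuntimeError("cannot save an unfitted scaler")
        lines = [
            f"# min-max scaler, profile = {self.profile or '-'}",
            " ".join(repr(float(v)) for v in self.mins),
            " ".join(repr(float(v)) for v in self.maxs),
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "MinMaxScaler":
        lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
        if len(lines) != 3 or not lines[0].startswith("#"):
            raise ValueError(f"malformed scaler file {path}")
        profile = lines[0].split("=", 1)[1].strip()
        profile = None if profile == "-" else profile
        mins = np.array([float(v) for v in lines[1].split()])
        maxs = np.array([float(v) for v in lines[2].split()])
        if mins.size != maxs.size or mins.size == 0:
            raise ValueError(f"malformed scaler file {path}")
        if np.any(maxs < mins):
            raise ValueError("scaler file has max < min")
        return cls(mins=mins, maxs=maxs, profile=profile)


def fit_minmax(train: Union[PixelTable, np.ndarray]) -> MinMaxScaler:
    """Fit a per-band min-max scaler on the training rows only."""
    return MinMaxScaler().fit(train)


def apply_minmax(scaler: MinMaxScaler, data):
    """Scale a table, cube or array with a fitted scaler (no clipping)."""
    return scaler.transform(data)


def save_scaler(scaler: MinMaxScaler, path: str | Path) -> None:
    scaler.save(path)


def load_scaler(path: str | Path) -> MinMaxScaler:
    return MinMaxScaler.load(path)
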