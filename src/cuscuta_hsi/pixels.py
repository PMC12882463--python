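"""Flattened labelled pixel spectra — the tabular container shared by the
preprocessing, splitting, classification and band-selection stages.

A :class:`PixelTable` pairs an ``(n_pixels, n_bands)`` spectra matrix with
a pandas metadata frame (one row per pixel: class label, source image,
tile, coordinates, infection flag, split tag).  It plays the role an
AnnData-style X/obs pair plays elsewhere: array maths on the spectra,
pandas bookkeeping on the provenance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["PixelTable", "concat_tables"]

META_DEFAULTS = {
    "label": "",
    "image_id": "",
    "tile_id": "",
    "row": -1,
    "col": -1,
    "infection": False,
    "split": "",
}


@dataclass
class PixelTable:
    spectra: np.ndarray
    meta: pd.DataFrame
    profile: Optional[str] = None

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=np.float64)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be a 2-D (pixels, bands) array")
        if len(self.meta) != self.spectra.shape[0]:
            raise ValueError(
                f"metadata has {len(self.meta)} rows but spectra has "
                f"{self.spectra.shape[0]}"
            )
        meta = self.meta.reset_index(drop=True).copy()
        for col, default in META_DEFAULTS.items():
            if col not in meta.columns:
                meta[col] = default
        self.meta = meta

    def __len__(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    @property
    def labels(self) -> np.ndarray:
        return self.meta["label"].to_numpy()

    def classes(self) -> list[str]:
        """Distinct labels in fixed (alphabetical) order."""
        return sorted(self.meta["label"].unique())

    def select(self, mask: np.ndarray) -> "PixelTable":
        mask = np.asarray(mask)
        return PixelTable(self.spectra[mask], self.meta.loc[mask].copy(), self.profile)

    def subset_split(self, split: str) -> "PixelTable":
        return self.select((self.meta["split"] == split).to_numpy())

    def subset_bands(self, band_indices: Sequence[int]) -> "PixelTable":
        idx = np.asarray(band_indices, dtype=int)
        if idx.size == 0:
            raise ValueError("band subset must be non-empty")
        if idx.min() < 0 or idx.max() >= self.n_bands:
            raise IndexError("band subset index out of range")
        return PixelTable(self.spectra[:, idx], self.meta.copy(), self.profile)

    def with_spectra(self, spectra: np.ndarray) -> "PixelTable":
        return PixelTable(spectra, self.meta.copy(), self.profile)

    def copy(self) -> "PixelTable":
        return PixelTable(self.spectra.copy(), self.meta.copy(), self.profile)


def concat_tables(tables: Iterable[PixelTable]) -> PixelTable:
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to concatenate")
    bands = {t.n_bands for t in tables}
    if len(bands) != 1:
        raise ValueError(f"band counts differ across tables: {sorted(bands)}")
    profiles = {t.profile for t in tables if t.profile is not None}
    if len(profiles) > 1:
        raise ValueError(f"calibration profiles differ across tables: {sorted(profiles)}")
    spectra = np.vstack([t.spectra for t in tables])
    meta = pd.concat([t.meta for t in tables], ignore_index=True)
    return PixelTable(spectra, meta, profiles.pop() if profiles else None)
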