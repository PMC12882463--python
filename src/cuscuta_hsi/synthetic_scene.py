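"""Synthetic hyperspectral scene generator.

Emulates conveyor-belt line-scan imagery of winding parasitic stems
(*Cuscuta* spp.) and leafy host shoots on a dark cloth background, so the
whole pipeline can be exercised and validated without camera data.

Spectral model
--------------
Each class is a parametric endmember built from vegetation spectroscopy
features: a reflectance baseline, a broad chlorophyll-a absorption well
centered at 662 nm, a carotenoid absorption band around 470 nm (covering
the 400-515 nm region), water absorption wells near 1450 and 1950 nm for
the SWIR range, and a logistic red-edge rise between ~680 and 750 nm.
Species differ chiefly in red-edge position/steepness and pigment depths
— parasitic dodder shoots carry less chlorophyll and relatively more
carotenoids than a green host, which is what makes the 640-800 nm region
discriminative.

Spatial model
-------------
Stems are sinusoidal winding paths of configurable width rasterized onto
the scene; one species per scene mirrors the per-species cropping of real
trays, except that infection scenes overlay parasite stems on host stems
and mark the contact pixels, whose spectra are a convex host/parasite
mixture.  A multiplicative illumination ramp and per-band additive
Gaussian sensor noise complete the forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cube_io import AcquisitionMeta, BandCalibration, SpectralCube, load_profile
from .pixels import PixelTable

__all__ = [
    "SpeciesSpectrumModel",
    "SceneSpec",
    "GroundTruth",
    "endmember_spectrum",
    "render_scene",
    "make_pixel_dataset",
    "default_species_models",
    "cloth_background",
    "default_scene_spec",
]

CHL_CENTER_NM = 662.0
CAROTENOID_CENTER_NM = 470.0
WATER_CENTERS_NM = (1450.0, 1950.0)


@dataclass(frozen=True)
class SpeciesSpectrumModel:
    """Parametric endmember for one pixel class.

    All depths are unitless reflectance decrements and must not exceed
    ``baseline``; ``red_edge_height`` is the amplitude of the logistic
    NIR rise and defaults to ``chl_depth`` (the red edge recovers what
    chlorophyll absorbs).
    """

    name: str
    baseline: float = 0.45
    chl_depth: float = 0.0
    chl_width: float = 80.0
    red_edge_center: float = 710.0
    red_edge_width: float = 12.0
    red_edge_height: Optional[float] = None
    carotenoid_depth: float = 0.0
    carotenoid_width: float = 60.0
    water_depths: tuple[float, float] = (0.0, 0.0)
    water_widths: tuple[float, float] = (140.0, 180.0)
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.baseline <= 1:
            raise ValueError(f"baseline must lie in (0, 1], got {self.baseline}")
        for label, depth in [("chl_depth", self.chl_depth),
                             ("carotenoid_depth", self.carotenoid_depth),
                             ("water_depth_1450", self.water_depths[0]),
                             ("water_depth_1950", self.water_depths[1])]:
            if not 0 <= depth <= self.baseline:
                raise ValueError(f"{label} must lie in [0, baseline], got {depth}")
        for label, width in [("chl_width", self.chl_width),
                             ("red_edge_width", self.red_edge_width),
                             ("carotenoid_width", self.carotenoid_width),
                             ("water_width_1450", self.water_widths[0]),
                             ("water_width_1950", self.water_widths[1])]:
            if width <= 0:
                raise ValueError(f"{label} must be positive, got {width}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def rise_height(self) -> float:
        return self.chl_depth if self.red_edge_height is None else self.red_edge_height


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-((wl - center) ** 2) / (2.0 * width ** 2))


def endmember_spectrum(model: SpeciesSpectrumModel, calibration: BandCalibration) -> np.ndarray:
    """Noise-free reflectance spectrum of ``model`` on a band grid.

    baseline − Gaussian absorptions (chlorophyll 662 nm, carotenoid
    470 nm, water 1450/1950 nm) + logistic red-edge rise, clipped to
    [0, 1].
    """
    wl = calibration.centers
    spectrum = np.full(wl.shape, model.baseline, dtype=np.float64)
    spectrum -= model.chl_depth * _gauss(wl, CHL_CENTER_NM, model.chl_width)
    spectrum -= model.carotenoid_depth * _gauss(wl, CAROTENOID_CENTER_NM, model.carotenoid_width)
    for depth, center, width in zip(model.water_depths, WATER_CENTERS_NM, model.water_widths):
        spectrum -= depth * _gauss(wl, center, width)
    if model.rise_height > 0:
        z = (wl - model.red_edge_center) / model.red_edge_width
        spectrum += model.rise_height / (1.0 + np.exp(-z))
    return np.clip(spectrum, 0.0, 1.0)


def default_species_models(noise_sd: float = 0.01) -> list[SpeciesSpectrumModel]:
    """The five study classes: one leafy host and four dodder species.

    Red-edge centers place *campestris*/*platyloba* (subgenus Grammica)
    and *monogyna*/*reflexa* (subgenus Monogynella) as spectrally
    adjacent pairs, reproducing the within-subgenus similarity structure
    of the real species.
    """
    return [
        SpeciesSpectrumModel("host", baseline=0.48, chl_depth=0.46, carotenoid_depth=0.06,
                             red_edge_center=702.0, red_edge_width=11.0,
                             red_edge_height=0.46, water_depths=(0.28, 0.38),
                             noise_sd=noise_sd),
        SpeciesSpectrumModel("campestris", baseline=0.46, chl_depth=0.43, carotenoid_depth=0.14,
                             red_edge_center=712.0, red_edge_width=12.0,
                             red_edge_height=0.43, water_depths=(0.26, 0.36),
                             noise_sd=noise_sd),
        SpeciesSpectrumModel("platyloba", baseline=0.46, chl_depth=0.42, carotenoid_depth=0.16,
                             red_edge_center=717.0, red_edge_width=12.0,
                             red_edge_height=0.42, water_depths=(0.25, 0.35),
                             noise_sd=noise_sd),
        SpeciesSpectrumModel("monogyna", baseline=0.45, chl_depth=0.42, carotenoid_depth=0.20,
                             red_edge_center=727.0, red_edge_width=13.0,
                             red_edge_height=0.41, water_depths=(0.24, 0.34),
                             noise_sd=noise_sd),
        SpeciesSpectrumModel("reflexa", baseline=0.45, chl_depth=0.41, carotenoid_depth=0.22,
                             red_edge_center=733.0, red_edge_width=13.0,
                             red_edge_height=0.41, water_depths=(0.23, 0.33),
                             noise_sd=noise_sd),
    ]


def cloth_background(noise_sd: float = 0.01) -> SpeciesSpectrumModel:
    """Dark black-cloth background: low flat reflectance, no red edge."""
    return SpeciesSpectrumModel("background", baseline=0.05, noise_sd=noise_sd,
                                red_edge_height=0.0)


@dataclass(frozen=True)
class SceneSpec:
    """Complete description of one synthetic scene."""

    lines: int
    samples: int
    calibration: BandCalibration
    classes: tuple[SpeciesSpectrumModel, ...]
    background_model: SpeciesSpectrumModel = field(default_factory=cloth_background)
    stem_width: int = 2
    n_stems_per_class: int = 3
    include_infection_sites: bool = False
    infection_mixture: float = 0.5
    illumination_gradient: tuple[float, float] = (0.95, 1.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("at least one plant class is required")
        if self.stem_width < 1:
            raise ValueError("stem_width must be >= 1")
        if self.n_stems_per_class < 0:
            raise ValueError("n_stems_per_class must be >= 0")
        if not 0 <= self.infection_mixture <= 1:
            raise ValueError("infection_mixture must lie in [0, 1]")
        lo, hi = self.illumination_gradient
        if lo <= 0 or hi < lo:
            raise ValueError("illumination_gradient must be (lo, hi) with 0 < lo <= hi")


@dataclass
class GroundTruth:
    """Per-pixel class codes (0 = background) plus infection flags."""

    label_map: np.ndarray
    infection_mask: np.ndarray
    class_names: list[str]

    def name_of_code(self, code: int) -> str:
        if code == 0:
            return "background"
        return self.class_names[code - 1]


def default_scene_spec(profile: str = "vnir", seed: int = 0, lines: int = 96,
                       samples: int = 96, noise_sd: float = 0.01,
                       classes: Optional[Sequence[SpeciesSpectrumModel]] = None,
                       **kwargs) -> SceneSpec:
    """Study-condition scene: five classes, 96x96, 1% sensor noise."""
    models = tuple(classes) if classes is not None else tuple(default_species_models(noise_sd))
    return SceneSpec(lines=lines, samples=samples, calibration=load_profile(profile),
                     classes=models, background_model=cloth_background(noise_sd),
                     seed=seed, **kwargs)


def _stem_path(rng: np.random.Generator, lines: int, samples: int) -> np.ndarray:
    """Row index of a sinusoidal winding stem centreline per column."""
    margin = max(2, lines // 10)
    center = rng.uniform(margin, lines - margin)
    amplitude = rng.uniform(0.05, 0.22) * lines
    cycles = rng.uniform(1.0, 3.0)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    x = np.arange(samples)
    rows = center + amplitude * np.sin(2.0 * np.pi * cycles * x / samples + phase)
    return np.clip(np.round(rows).astype(int), 0, lines - 1)


def render_scene(spec: SceneSpec) -> tuple[SpectralCube, GroundTruth]:
    """Rasterize winding stems and synthesize the reflectance cube.

    Deterministic for a fixed ``spec.seed``.  When infection sites are
    enabled, parasite stems drawn over host-labelled pixels keep the
    parasite code, are flagged in the infection mask, and receive the
    convex endmember mixture ``(1-a)*host + a*parasite`` with
    ``a = spec.infection_mixture``.
    """
    min_extent = spec.stem_width + 6
    if spec.n_stems_per_class > 0 and (spec.lines < min_extent or spec.samples < min_extent):
        raise ValueError(
            f"scene {spec.lines}x{spec.samples} too small to place stems of "
            f"width {spec.stem_width}"
        )
    rng = np.random.default_rng(spec.seed)
    n_bands = len(spec.calibration)
    label_map = np.zeros((spec.lines, spec.samples), dtype=np.int32)
    infection_mask = np.zeros((spec.lines, spec.samples), dtype=bool)

    class_names = [m.name for m in spec.classes]
    host_code = 1
    if spec.include_infection_sites and "host" in class_names:
        host_code = class_names.index("host") + 1

    # draw order: host first so parasite stems can cross it
    order = sorted(range(1, len(spec.classes) + 1), key=lambda c: c != host_code)
    for code in order:
        for _ in range(spec.n_stems_per_class):
            rows = _stem_path(rng, spec.lines, spec.samples)
            for offset in range(spec.stem_width):
                rr = np.clip(rows + offset, 0, spec.lines - 1)
                cc = np.arange(spec.samples)
                if spec.include_infection_sites and code != host_code:
                    hit = label_map[rr, cc] == host_code
                    infection_mask[rr[hit], cc[hit]] = True
                label_map[rr, cc] = code

    # spectra: per-class endmember, illumination ramp, per-band noise
    endmembers = np.stack(
        [endmember_spectrum(spec.background_model, spec.calibration)]
        + [endmember_spectrum(m, spec.calibration) for m in spec.classes]
    )
    cube = endmembers[label_map]  # (lines, samples, bands)

    if spec.include_infection_sites and infection_mask.any():
        host_spec = endmembers[host_code]
        a = spec.infection_mixture
        for code in range(1, len(spec.classes) + 1):
            if code == host_code:
                continue
            sel = infection_mask & (label_map == code)
            cube[sel] = (1.0 - a) * host_spec + a * endmembers[code]

    lo, hi = spec.illumination_gradient
    gain = np.linspace(lo, hi, spec.samples)[None, :, None]
    cube = cube * gain

    noise_sd = np.concatenate(
        [[spec.background_model.noise_sd], [m.noise_sd for m in spec.classes]]
    )[label_map]
    if np.any(noise_sd > 0):
        cube = cube + rng.standard_normal(cube.shape) * noise_sd[:, :, None]

    meta = AcquisitionMeta(camera_id=f"synthetic-{spec.calibration.profile or 'custom'}")
    return (SpectralCube(cube, spec.calibration, meta),
            GroundTruth(label_map, infection_mask, class_names))


# sign patterns of the planted-band class offsets; rows = classes.  Every
# band discriminates several class pairs, so each one carries real signal.
_PLANTED_PATTERNS = np.array([
    [1, 1, 1, 1, 1],
    [1, -1, 1, -1, -1],
    [-1, 1, -1, 1, -1],
    [-1, -1, -1, -1, 1],
], dtype=float)


def planted_band_dataset(n_pixels: int = 1200, n_bands: int = 60,
                         planted: Sequence[int] = (7, 19, 23, 41, 52),
                         shift: float = 0.15, noise_sd: float = 0.15,
                         n_classes: int = 4, n_images: int = 12,
                         seed: int = 0) -> PixelTable:
    """Spectra where only the planted bands carry class information.

    Every band is i.i.d. Gaussian around 0.5; on the planted bands each
    class adds ``shift`` times its fixed sign pattern.  The shift is
    chosen so that no single band separates the classes and dropping any
    planted band measurably hurts a classifier — a band-selection
    procedure must recover (most of) the planted set to match the
    full-feature score.  Rows carry rotating image ids so leakage-aware
    splitting applies.
    """
    planted = np.asarray(planted, dtype=int)
    if planted.size and (planted.min() < 0 or planted.max() >= n_bands):
        raise ValueError("planted band index out of range")
    if not 2 <= n_classes <= _PLANTED_PATTERNS.shape[0]:
        raise ValueError(f"n_classes must lie in [2, {_PLANTED_PATTERNS.shape[0]}]")
    rng = np.random.default_rng(seed)
    labels_idx = rng.integers(n_classes, size=n_pixels)
    spectra = rng.normal(0.5, noise_sd, size=(n_pixels, n_bands))
    patterns = _PLANTED_PATTERNS[:n_classes][:, np.arange(planted.size) % 5]
    spectra[:, planted] += shift * patterns[labels_idx]
    meta = pd.DataFrame({
        "label": [f"class{c}" for c in labels_idx],
        "image_id": [f"img{i % n_images:02d}" for i in range(n_pixels)],
        "row": np.zeros(n_pixels, dtype=int),
        "col": np.arange(n_pixels),
    })
    return PixelTable(spectra, meta)


def make_pixel_dataset(scenes: Sequence[tuple[SpectralCube, GroundTruth]],
                       image_ids: Optional[Sequence[str]] = None) -> PixelTable:
    """Flatten scenes into one labelled table, background excluded."""
    if not scenes:
        raise ValueError("no scenes given")
    ref = scenes[0][0].calibration
    if image_ids is None:
        image_ids = [f"scene{i:03d}" for i in range(len(scenes))]
    if len(image_ids) != len(scenes):
        raise ValueError("image_ids length must match scene count")

    spectra_parts, meta_parts = [], []
    for image_id, (cube, truth) in zip(image_ids, scenes):
        if len(cube.calibration) != len(ref) or not np.allclose(
                cube.calibration.centers, ref.centers):
            raise ValueError("scenes do not share one band calibration")
        rows, cols = np.nonzero(truth.label_map)
        if rows.size == 0:
            continue
        spectra_parts.append(cube.reflectance[rows, cols])
        meta_parts.append(pd.DataFrame({
            "label": [truth.name_of_code(c) for c in truth.label_map[rows, cols]],
            "image_id": image_id,
            "row": rows,
            "col": cols,
            "infection": truth.infection_mask[rows, cols],
        }))
    if not spectra_parts:
        spectra = np.empty((0, len(ref)))
        meta = pd.DataFrame(columns=["label", "image_id", "row", "col", "infection"])
    else:
        spectra = np.vstack(spectra_parts)
        meta = pd.concat(meta_parts, ignore_index=True)
    return PixelTable(spectra, meta, profile=ref.profile)
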