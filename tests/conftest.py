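import numpy as np
import pandas as pd
import pytest

from cuscuta_hsi import (BandCalibration, PixelTable, SpectralCube,
                         cloth_background, default_scene_spec,
                         default_species_models, grouped_split, load_profile,
                         make_pixel_dataset, planted_band_dataset,
                         render_scene)


@pytest.fixture(scope="session")
def vnir_cal():
    return load_profile("vnir")


@pytest.fixture(scope="session")
def swir_cal():
    return load_profile("swir")


@pytest.fixture
def tiny_cal():
    return BandCalibration(np.array([450.0, 550.0, 650.0]))


@pytest.fixture
def tiny_cube(tiny_cal):
    rng = np.random.default_rng(42)
    return SpectralCube(rng.random((4, 5, 3)), tiny_cal)


@pytest.fixture(scope="session")
def vnir_scene():
    """One noisy five-class VNIR scene with ground truth."""
    return render_scene(default_scene_spec(seed=11))


@pytest.fixture(scope="session")
def multiclass_dataset():
    """Five-class labelled pixel table from 20 scenes (4 per species),
    split leakage-free and min-max scaled; ~7k pixels."""
    from cuscuta_hsi import fit_minmax

    scenes, ids = [], []
    for ci, model in enumerate(default_species_models()):
        for i in range(4):
            spec = default_scene_spec(seed=1000 + 100 * ci + i, classes=[model],
                                      lines=64, samples=64)
            scenes.append(render_scene(spec))
            ids.append(f"{model.name}_{i}")
    table = make_pixel_dataset(scenes, ids)
    assignment = grouped_split(table, seed=5)
    tagged = assignment.tag(table, "image_id")
    train = tagged.subset_split("train")
    scaler = fit_minmax(train)
    return {
        "train": scaler.transform(train),
        "val": scaler.transform(tagged.subset_split("val")),
        "test": scaler.transform(tagged.subset_split("test")),
        "scaler": scaler,
        "raw": tagged,
    }


@pytest.fixture(scope="session")
def planted_tables():
    """Train/val/test tables where 5 of 60 bands carry the class signal."""
    return {name: planted_band_dataset(n_pixels=n, seed=seed)
            for name, n, seed in [("train", 1500, 0), ("val", 700, 1),
                                  ("test", 700, 2)]}


@pytest.fixture
def random_group_table():
    """200 single-class groups of uneven size for split stress tests."""
    def build(seed=0, n_groups=200, n_classes=5):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(40, 400, size=n_groups)
        labels, images = [], []
        for g, size in enumerate(sizes):
            labels += [f"class{g % n_classes}"] * size
            images += [f"img{g:03d}"] * size
        n = len(labels)
        return PixelTable(np.zeros((n, 3)),
                          pd.DataFrame({"label": labels, "image_id": images}))
    return build
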