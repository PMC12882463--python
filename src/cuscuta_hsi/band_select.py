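"""Spectral band (feature) selection.

Two complementary reducers over the band axis:

* **LIME + elbow** — rank bands by local-surrogate importance (ridge
  fits to the classifier's probabilities on Gaussian-perturbed spectra,
  absolute weights averaged over explained pixels), then retrain on
  top-k prefixes and keep the smallest k whose validation macro F1 is
  within tolerance of the full-feature model.
* **Genetic algorithm** — individuals are band-inclusion bit patterns;
  fitness is the validation macro F1 of a model trained on the subset;
  elitism, fitness-proportional parent selection, uniform crossover and
  per-bit mutation refine the population until the fitness target (the
  full-feature score, computed before the search) or the generation cap
  (default 50) is reached.

Selection decisions read the validation split only; wrap the test split
in :class:`GuardedPixelTable` to make any accidental read raise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .classify import EvaluationReport, evaluate
from .pixels import PixelTable

__all__ = [
    "ImportanceRanking",
    "BandSubset",
    "GAConfig",
    "GuardedPixelTable",
    "lime_importances",
    "elbow_reduce",
    "genetic_band_search",
    "retrain_on_subset",
]

logger = logging.getLogger(__name__)

Trainer = Callable[[PixelTable], object]  # fits a classifier on the given table


class GuardedPixelTable:
    """Raises on any attribute access; guards the test split during selection."""

    def __init__(self, table: PixelTable):
        object.__setattr__(self, "_guarded_table", table)

    def release(self) -> PixelTable:
        """Hand the table back once selection is over."""
        return object.__getattribute__(self, "_guarded_table")

    def __getattr__(self, name):
        raise RuntimeError(
            "test split accessed during feature selection; selection may "
            "only read the validation split"
        )

    def __len__(self):
        raise RuntimeError("test split accessed during feature selection")


@dataclass
class ImportanceRanking:
    """Bands ordered most- to least-important with their scores."""

    order: np.ndarray       # permutation of all band indices
    scores: np.ndarray      # aligned with ``order``, non-increasing
    model_family: str = ""

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if sorted(self.order.tolist()) != list(range(self.order.size)):
            raise ValueError("ranking must be a permutation of all band indices")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing in rank order")

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]

    def to_frame(self, wavelengths: Optional[np.ndarray] = None) -> pd.DataFrame:
        df = pd.DataFrame({"rank": np.arange(self.order.size),
                           "band": self.order, "importance": self.scores})
        if wavelengths is not None:
            df["wavelength_nm"] = wavelengths[self.order]
        return df


@dataclass
class BandSubset:
    """Outcome of a selection run: which bands, at what validation score."""

    bands: np.ndarray
    macro_f1: float
    method: str
    steps: int = 0

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=int)
        if self.bands.size == 0:
            raise ValueError("band subset must be non-empty")
        if np.unique(self.bands).size != self.bands.size:
            raise ValueError("band subset contains duplicates")


# ---------------------------------------------------------------------------
# LIME-style local surrogate importances

def lime_importances(classifier, background: PixelTable, n_explained: int = 200,
                     n_perturbations: int = 1000, seed: int = 0,
                     model_family: str = "") -> ImportanceRanking:
    """Per-band importances from local ridge surrogates.

    For each explained pixel, the classifier's probability for that
    pixel's predicted class is regressed (ridge, RBF-kernel sample
    weights) on standardized Gaussian perturbations of the spectrum;
    absolute surrogate weights are averaged over pixels.
    """
    if n_explained > len(background):
        raise ValueError(
            f"n_explained={n_explained} exceeds table size {len(background)}")
    rng = np.random.default_rng(seed)
    n_bands = background.n_bands
    sigma = background.spectra.std(axis=0)
    sigma = np.where(sigma <= 0, 1e-6, sigma)
    kernel_width = 0.75 * np.sqrt(n_bands)

    picks = rng.choice(len(background), size=n_explained, replace=False)
    class_list = [str(c) for c in classifier.classes_]
    totals = np.zeros(n_bands)
    surrogate = Ridge(alpha=1.0)
    for i in picks:
        x = background.spectra[i]
        noise = rng.standard_normal((n_perturbations, n_bands))
        perturbed = x + noise * sigma
        probs = classifier.predict_proba(perturbed)
        target = class_list.index(
            str(np.asarray(classifier.predict(x[None]))[0]))
        d = np.linalg.norm(noise, axis=1)
        weights = np.exp(-(d ** 2) / kernel_width ** 2)
        surrogate.fit(noise, probs[:, target], sample_weight=weights)
        totals += np.abs(surrogate.coef_)

    scores = totals / n_explained
    order = np.argsort(-scores, kind="stable")
    return ImportanceRanking(order, scores[order], model_family=model_family)


# ---------------------------------------------------------------------------
# Elbow reduction over ranked prefixes

def elbow_reduce(ranking: ImportanceRanking, trainer: Trainer,
                 train: PixelTable, validation: PixelTable,
                 k_grid: Sequence[int], tolerance: float = 0.01
                 ) -> tuple[BandSubset, pd.DataFrame]:
    """Smallest ranked prefix whose score is within tolerance of full.

    Trains on the top-k bands for each k in the (ascending) grid and
    returns the smallest k with validation macro F1 at least
    ``full_score - tolerance``; falls back to the best-scoring k when
    none qualifies.
    """
    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("k_grid is empty")
    if sorted(k_grid) != k_grid:
        raise ValueError("k_grid must be sorted ascending")
    if k_grid[-1] > ranking.order.size:
        raise ValueError("k_grid exceeds the number of bands")

    full_model = trainer(train)
    full_score = evaluate(full_model, validation).macro_f1

    records = []
    for k in k_grid:
        bands = ranking.top(k)
        model = trainer(train.subset_bands(bands))
        score = evaluate(model, validation.subset_bands(bands)).macro_f1
        records.append({"k": k, "val_macro_f1": score})
    curve = pd.DataFrame(records)

    ok = curve[curve["val_macro_f1"] >= full_score - tolerance]
    if len(ok):
        chosen = ok.iloc[0]
    else:
        logger.warning("elbow: no prefix within tolerance %.3f of full score %.4f",
                       tolerance, full_score)
        chosen = curve.loc[curve["val_macro_f1"].idxmax()]
    k = int(chosen["k"])
    subset = BandSubset(ranking.top(k), float(chosen["val_macro_f1"]),
                        method="elbow", steps=len(k_grid))
    curve.attrs["full_score"] = full_score
    return subset, curve


# ---------------------------------------------------------------------------
# Genetic algorithm over band-inclusion bit patterns

@dataclass(frozen=True)
class GAConfig:
    population_size: int = 30
    mutation_rate: float = 0.05
    elite_count: int = 2
    max_generations: int = 50
    f1_target: Optional[float] = None  # computed from the full-feature fit if None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 < self.mutation_rate < 1:
            raise ValueError("mutation_rate must lie in (0, 1)")
        if not 0 <= self.elite_count < self.population_size:
            raise ValueError("elite_count must be smaller than the population")
        if self.max_generations < 0:
            raise ValueError("max_generations must be >= 0")


def _repair(individual: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not individual.any():
        individual = individual.copy()
        individual[rng.integers(individual.size)] = True
    return individual


def genetic_band_search(trainer: Trainer, train: PixelTable,
                        validation: PixelTable, config: GAConfig = GAConfig()
                        ) -> tuple[BandSubset, pd.DataFrame]:
    """GA over band subsets with macro-F1 fitness.

    Returns the best-ever subset and a per-generation trace (best and
    mean fitness).  Fitness evaluations are cached by bit pattern, so
    duplicated individuals cost nothing.
    """
    n_bands = train.n_bands
    rng = np.random.default_rng(config.seed)

    cache: dict[bytes, float] = {}

    def fitness(individual: np.ndarray) -> float:
        key = np.packbits(individual).tobytes()
        if key not in cache:
            bands = np.nonzero(individual)[0]
            model = trainer(train.subset_bands(bands))
            cache[key] = evaluate(model, validation.subset_bands(bands)).macro_f1
        return cache[key]

    if config.f1_target is None:
        full_model = trainer(train)
        f1_target = evaluate(full_model, validation).macro_f1
    else:
        f1_target = float(config.f1_target)

    population = [
        _repair(rng.random(n_bands) < 0.5, rng)
        for _ in range(config.population_size)
    ]
    scores = np.array([fitness(ind) for ind in population])

    best_idx = int(np.argmax(scores))
    best_ever = (population[best_idx].copy(), float(scores[best_idx]))
    trace = [{"generation": 0, "best_fitness": float(scores.max()),
              "mean_fitness": float(scores.mean()),
              "best_n_bands": int(population[best_idx].sum())}]

    generation = 0
    while generation < config.max_generations and best_ever[1] < f1_target:
        generation += 1
        order = np.argsort(-scores, kind="stable")
        elites = [population[i].copy() for i in order[:config.elite_count]]
        shifted = scores - scores.min() + 1e-9
        probs = shifted / shifted.sum()
        children = []
        while len(children) < config.population_size - config.elite_count:
            pa, pb = rng.choice(len(population), size=2, p=probs)
            mask = rng.random(n_bands) < 0.5
            child = np.where(mask, population[pa], population[pb])
            flip = rng.random(n_bands) < config.mutation_rate
            child = np.logical_xor(child, flip)
            children.append(_repair(child, rng))
        population = elites + children
        scores = np.array([fitness(ind) for ind in population])
        gen_best = int(np.argmax(scores))
        if scores[gen_best] > best_ever[1]:
            best_ever = (population[gen_best].copy(), float(scores[gen_best]))
        trace.append({"generation": generation, "best_fitness": float(scores.max()),
                      "mean_fitness": float(scores.mean()),
                      "best_n_bands": int(population[gen_best].sum())})

    subset = BandSubset(np.nonzero(best_ever[0])[0], best_ever[1],
                        method="ga", steps=generation)
    trace_df = pd.DataFrame(trace)
    trace_df.attrs["f1_target"] = f1_target
    return subset, trace_df


def retrain_on_subset(subset: BandSubset, trainer: Trainer, train: PixelTable,
                      test: PixelTable) -> tuple[object, EvaluationReport]:
    """Train on the selected bands only and evaluate on the test split.

    This is the single point where the test split is read after
    selection.
    """
    if isinstance(test, GuardedPixelTable):
        test = test.release()
    if subset.bands.max() >= train.n_bands:
        raise ValueError("subset refers to bands outside the training table")
    model = trainer(train.subset_bands(subset.bands))
    report = evaluate(model, test.subset_bands(subset.bands),
                      tag=f"{subset.method}:{subset.bands.size}bands")
    return model, report
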