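"""Leakage-aware partitioning of labelled pixels into train/val/test.

Pixels from one image (or spatially linked tiles of one image) always
land in a single subset, so evaluation is never contaminated by spectra
correlated with the training data.  Allocation is greedy: groups are
shuffled under the seed, ordered largest first, and each is assigned to
the subset currently furthest below its target pixel fraction, class by
class, after every subset has received at least one group of each class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pixels import PixelTable

__all__ = ["TileAssignment", "tile_pixels", "grouped_split", "class_counts"]

SUBSETS = ("train", "val", "test")
DEFAULT_FRACTIONS = (0.60, 0.20, 0.20)


@dataclass
class TileAssignment:
    """Mapping group id -> subset, plus per-group bookkeeping."""

    table: pd.DataFrame  # columns: group_id, subset, image_id, n_pixels

    def subset_of(self, group_id: str) -> str:
        row = self.table.loc[self.table["group_id"] == group_id, "subset"]
        if row.empty:
            raise KeyError(f"unknown group {group_id!r}")
        return str(row.iloc[0])

    def tag(self, pixels: PixelTable, group_col: str) -> PixelTable:
        """Return a copy of ``pixels`` with the split column filled in."""
        mapping = dict(zip(self.table["group_id"], self.table["subset"]))
        tagged = pixels.copy()
        tagged.meta["split"] = tagged.meta[group_col].map(mapping)
        if tagged.meta["split"].isna().any():
            missing = sorted(tagged.meta.loc[tagged.meta["split"].isna(), group_col].unique())
            raise KeyError(f"groups without assignment: {missing[:5]}")
        return tagged

    def achieved_fractions(self) -> dict[str, float]:
        totals = self.table.groupby("subset")["n_pixels"].sum()
        grand = float(totals.sum())
        return {s: float(totals.get(s, 0)) / grand for s in SUBSETS}

    def save(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "TileAssignment":
        return cls(pd.read_csv(path))


def tile_pixels(table: PixelTable, tile_size: int) -> PixelTable:
    """Assign each pixel to a grid tile of its source image.

    Tile ids are ``image_id:ty_tx`` with ``ty = row // tile_size`` etc.;
    every pixel gets exactly one tile and counts are conserved.
    """
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    if (table.meta["row"] < 0).any() or (table.meta["col"] < 0).any():
        raise ValueError("pixel coordinates are required for tiling")
    out = table.copy()
    ty = out.meta["row"] // tile_size
    tx = out.meta["col"] // tile_size
    out.meta["tile_id"] = (
        out.meta["image_id"].astype(str) + ":" + ty.astype(str) + "_" + tx.astype(str)
    )
    return out


def _link_adjacent_tiles(meta: pd.DataFrame) -> dict[str, str]:
    """Union tiles of one image that touch in the 8-neighborhood."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    tiles = meta[["image_id", "tile_id"]].drop_duplicates()
    coords = {}
    for _, row in tiles.iterrows():
        ty, tx = row["tile_id"].rsplit(":", 1)[1].split("_")
        coords[row["tile_id"]] = (row["image_id"], int(ty), int(tx))
        parent[row["tile_id"]] = row["tile_id"]
    by_pos = {(img, ty, tx): tid for tid, (img, ty, tx) in coords.items()}
    for tid, (img, ty, tx) in coords.items():
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == dx == 0:
                    continue
                other = by_pos.get((img, ty + dy, tx + dx))
                if other is not None:
                    union(tid, other)
    return {tid: find(tid) for tid in parent}


def grouped_split(table: PixelTable,
                  fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
                  group_by: str = "image", proximity_linking: bool = True,
                  seed: int = 0) -> TileAssignment:
    """Greedy leakage-free split into train/val/test pixel fractions.

    ``group_by`` is ``"image"`` or ``"tile"``; with ``proximity_linking``
    spatially adjacent tiles of one image are merged into one group.
    Stratified per class at the group level: every class must be able to
    appear in every subset, so a class needs at least three groups.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    if len(table) == 0:
        raise ValueError("cannot split an empty table")

    meta = table.meta.copy()
    if group_by == "image":
        meta["unit_id"] = meta["image_id"].astype(str)
        meta["group_id"] = meta["unit_id"]
    elif group_by == "tile":
        if (meta["tile_id"] == "").any():
            raise ValueError("tile ids missing; run tile_pixels first")
        meta["unit_id"] = meta["tile_id"]
        if proximity_linking:
            link = _link_adjacent_tiles(meta)
            meta["group_id"] = meta["tile_id"].map(link)
        else:
            meta["group_id"] = meta["tile_id"]
    else:
        raise ValueError(f"group_by must be 'image' or 'tile', got {group_by!r}")

    groups = (meta.groupby("group_id")
                  .agg(n_pixels=("label", "size"),
                       label=("label", lambda s: s.mode().iloc[0]),
                       image_id=("image_id", "first"))
                  .reset_index())

    rng = np.random.default_rng(seed)
    records = []
    for cls, cls_groups in groups.groupby("label"):
        if len(cls_groups) < len(SUBSETS):
            raise ValueError(
                f"class {cls!r} has only {len(cls_groups)} group(s); "
                f"cannot stratify across {len(SUBSETS)} subsets"
            )
        cls_groups = cls_groups.iloc[rng.permutation(len(cls_groups))]
        cls_groups = cls_groups.sort_values("n_pixels", ascending=False,
                                            kind="stable")
        total = float(cls_groups["n_pixels"].sum())
        assigned = {s: 0.0 for s in SUBSETS}
        seen = {s: 0 for s in SUBSETS}
        for _, grp in cls_groups.iterrows():
            empty = [s for s in SUBSETS if seen[s] == 0]
            candidates = empty if empty else list(SUBSETS)
            # most-deficient subset; ties broken by target size then order
            deficits = {
                s: fractions[SUBSETS.index(s)] - assigned[s] / total
                for s in candidates
            }
            target = max(candidates,
                         key=lambda s: (deficits[s], fractions[SUBSETS.index(s)],
                                        -SUBSETS.index(s)))
            assigned[target] += grp["n_pixels"]
            seen[target] += 1
            records.append({"linked_group": grp["group_id"], "subset": target})

    by_group = pd.DataFrame(records)
    # expand linked groups back to their member units (tiles or images)
    units = (meta.groupby("unit_id")
                 .agg(linked_group=("group_id", "first"),
                      image_id=("image_id", "first"),
                      n_pixels=("label", "size"))
                 .reset_index()
                 .rename(columns={"unit_id": "group_id"}))
    out = units.merge(by_group, on="linked_group")[
        ["group_id", "subset", "image_id", "n_pixels", "linked_group"]]
    assert out["group_id"].is_unique, "leakage: a group appeared twice"
    assert (out.groupby("linked_group")["subset"].nunique() == 1).all(), \
        "leakage: a linked group spans subsets"
    return TileAssignment(out)


def class_counts(table: PixelTable) -> pd.DataFrame:
    """Per-class pixel counts with the imbalance ratio to the rarest class."""
    if len(table) == 0:
        return pd.DataFrame(columns=["label", "n_pixels", "imbalance_ratio"])
    counts = (table.meta.groupby("label").size()
              .rename("n_pixels").reset_index()
              .sort_values("label").reset_index(drop=True))
    counts["imbalance_ratio"] = counts["n_pixels"] / counts["n_pixels"].min()
    return counts
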