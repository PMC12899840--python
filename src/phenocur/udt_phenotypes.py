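"""Unidimensional temporality (UDT) phenotypes from mask sequences.

Given a time-ordered sequence of segmented plant masks S_1 … S_n (one plant,
one fixed view), each consecutive pair (S_t, S_{t+1}) yields two binary change
masks:

    Change+(t) = max(S_{t+1} - S_t, 0)      newly appearing plant pixels
    Change-(t) = max(S_t - S_{t+1}, 0)      disappearing plant pixels

applied element-wise.  From the 8-connected components of each change mask we
derive:

* ``NChange±``  — number of components (count of distinct growth / decay
  events; not normalised by plant size),
* ``MaxChange±`` — pixel area of the largest component (the dominant
  contiguous event),
* ``Dispersion+`` — mean Euclidean distance from each Change+ component
  centroid to the centroid of its nearest other component.  Low values mean
  spatially clustered growth; high values mean canopy-wide, dispersed change.
  With fewer than two components the nearest neighbour is undefined and the
  value is *missing* (NaN), never zero.

Decay and occlusion are deliberately conflated: a pixel leaving the mask may
mean tissue loss or a leaf moving in front of it, and both are biological
signal here.  Dispersion is defined for positive change only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .dataset_model import BinaryMask, DimensionError, MaskSequence

#: 3x3 all-ones structuring element: edge or corner contact joins pixels
_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class ChangePair:
    """Change masks for one consecutive time pair; ``t`` is the earlier frame."""

    t: int
    change_pos: BinaryMask
    change_neg: BinaryMask


@dataclass(frozen=True)
class Component:
    id: int
    area_px: int
    centroid: tuple[float, float]  # (row, col), unweighted pixel mean


@dataclass(frozen=True)
class ComponentSet:
    """8-connected labeling of a binary mask.

    Labels are assigned in raster-scan order of each component's first pixel,
    so the labeling is deterministic.  Background pixels carry label 0.
    """

    labels: np.ndarray
    components: tuple[Component, ...]

    def __len__(self) -> int:
        return len(self.components)

    def areas(self) -> np.ndarray:
        return np.array([c.area_px for c in self.components], dtype=int)

    def centroids(self) -> np.ndarray:
        if not self.components:
            return np.empty((0, 2))
        return np.array([c.centroid for c in self.components], dtype=float)


@dataclass(frozen=True)
class UDTRecord:
    """All temporal phenotypes for one consecutive time pair."""

    t: int
    change_pos_area: int
    change_neg_area: int
    nchange_pos: int
    nchange_neg: int
    maxchange_pos: int
    maxchange_neg: int
    dispersion_pos: float  # NaN when < 2 positive components


def change_masks(prev: BinaryMask, next: BinaryMask, t: int = 0) -> ChangePair:
    """Element-wise change decomposition between two masks of equal shape."""
    if prev.shape != next.shape:
        raise DimensionError(f"mask shapes differ: {prev.shape} vs {next.shape}")
    a = prev.pixels.astype(np.int16)
    b = next.pixels.astype(np.int16)
    pos = np.maximum(b - a, 0).astype(np.uint8)
    neg = np.maximum(a - b, 0).astype(np.uint8)
    return ChangePair(t=t, change_pos=BinaryMask(pos), change_neg=BinaryMask(neg))


def label_components(mask: BinaryMask) -> ComponentSet:
    """Label 8-connected components with areas and centroids.

    ``scipy.ndimage.label`` assigns ids in raster-scan order of each
    component's first-encountered pixel, which is the determinism this
    package guarantees.
    """
    labels, n = ndimage.label(mask.pixels, structure=_EIGHT_CONN)
    if n == 0:
        return ComponentSet(labels=labels, components=())
    ids = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=ids).astype(int)
    centroids = ndimage.center_of_mass(mask.pixels, labels, index=ids)
    comps = tuple(
        Component(id=int(i), area_px=int(a), centroid=(float(r), float(c)))
        for i, a, (r, c) in zip(ids, areas, centroids)
    )
    return ComponentSet(labels=labels, components=comps)


def _mean_nearest_neighbour_distance(centroids: np.ndarray) -> float:
    """Mean distance from each centroid to its nearest other centroid.

    NaN with fewer than two points (nearest neighbour undefined).  Ties in
    the nearest neighbour do not affect the mean (the distances are equal).
    """
    k = len(centroids)
    if k < 2:
        return math.nan
    if k <= 64:  # tiny cases: exact pairwise scan
        d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        return float(d.min(axis=1).mean())
    tree = cKDTree(centroids)
    dist, _ = tree.query(centroids, k=2)
    return float(dist[:, 1].mean())


def udt_record(pair: ChangePair) -> UDTRecord:
    """Component-level temporal phenotypes for one change pair."""
    pos = label_components(pair.change_pos)
    neg = label_components(pair.change_neg)
    pos_areas = pos.areas()
    neg_areas = neg.areas()
    return UDTRecord(
        t=pair.t,
        change_pos_area=pair.change_pos.area(),
        change_neg_area=pair.change_neg.area(),
        nchange_pos=len(pos),
        nchange_neg=len(neg),
        maxchange_pos=int(pos_areas.max()) if len(pos) else 0,
        maxchange_neg=int(neg_areas.max()) if len(neg) else 0,
        dispersion_pos=_mean_nearest_neighbour_distance(pos.centroids()),
    )


def projected_area(mask: BinaryMask) -> int:
    """Baseline phenotype: foreground pixel count."""
    return mask.area()


def udt_series(seq: MaskSequence) -> list[UDTRecord]:
    """UDT records for every consecutive pair of a sequence (n-1 records)."""
    out = []
    for i in range(len(seq) - 1):
        pair = change_masks(seq.masks[i], seq.masks[i + 1], t=seq.times[i])
        out.append(udt_record(pair))
    return out


def udt_table(seq: MaskSequence) -> pd.DataFrame:
    """Tidy per-pair table with baseline areas alongside the UDT phenotypes."""
    records = udt_series(seq)
    rows = []
    for i, rec in enumerate(records):
        rows.append({
            "species": seq.key.species,
            "treatment": seq.key.treatment,
            "plant_id": seq.key.plant_id,
            "view_deg": seq.key.view_deg,
            "t": rec.t,
            "area_t": projected_area(seq.masks[i]),
            "area_t1": projected_area(seq.masks[i + 1]),
            "change_pos_area": rec.change_pos_area,
            "change_neg_area": rec.change_neg_area,
            "nchange_pos": rec.nchange_pos,
            "nchange_neg": rec.nchange_neg,
            "maxchange_pos": rec.maxchange_pos,
            "maxchange_neg": rec.maxchange_neg,
            "dispersion_pos": rec.dispersion_pos,
        })
    cols = ["species", "treatment", "plant_id", "view_deg", "t", "area_t", "area_t1",
            "change_pos_area", "change_neg_area", "nchange_pos", "nchange_neg",
            "maxchange_pos", "maxchange_neg", "dispersion_pos"]
    return pd.DataFrame(rows, columns=cols)


def change_overlay(prev: BinaryMask, next: BinaryMask) -> np.ndarray:
    """Diagnostic RGB image: green = Change+, red = Change-, gray = silhouette."""
    pair = change_masks(prev, next)
    h, w = prev.shape
    img = np.zeros((h, w, 3), dtype=np.uint8)
    both = (prev.pixels & next.pixels).astype(bool)
    img[both] = (128, 128, 128)
    img[pair.change_pos.pixels.astype(bool)] = (0, 200, 0)
    img[pair.change_neg.pixels.astype(bool)] = (200, 0, 0)
    return img
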