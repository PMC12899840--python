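"""Unidimensional perspective (UDP) phenotypes from same-time multi-view masks.

A plant imaged from several side-view angles at one time point presents a
different silhouette width in each view while (ideally) sharing one height.
Writing h for the shared height and w_i for the silhouette width in view i:

    TARmax = Wmax / h        Wmax = max_i w_i
    TARmin = Wmin / h        Wmin = min_i w_i
    TWR    = Wmin / Wmax

The two "true aspect ratios" bound the plant's width-to-height proportions
over all observed perspectives, and the true width ratio TWR quantifies
rotational asymmetry: TWR = 1 means the silhouette width is view-invariant.

Real silhouettes violate the equal-height idealisation slightly, so ``h`` is
taken as the maximum height over views — the least-occluded estimate, which
collapses to the shared height whenever the idealisation holds — and the
per-view height spread is kept as a diagnostic.

The single-view baseline ``aspect_ratio`` is height/width of the tight
bounding box, so values above 1 indicate vertical dominance (an upright
sunflower mid-growth typically exceeds 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .dataset_model import BinaryMask, PhenocurError


class EmptySilhouetteError(PhenocurError):
    """A view mask has no foreground pixels; extents are undefined."""


class InsufficientViewsError(PhenocurError):
    """Perspective ratios need at least two views."""


@dataclass(frozen=True)
class ViewExtents:
    """Tight bounding-box height and width of the silhouette in one view."""

    view_deg: Optional[int]
    h_i: int
    w_i: int

    def __post_init__(self) -> None:
        if self.h_i < 1 or self.w_i < 1:
            raise ValueError("extents must be >= 1 (empty silhouettes are rejected upstream)")


@dataclass(frozen=True)
class PerspectiveRatios:
    h: int
    w_min: int
    w_max: int
    tar_max: float
    tar_min: float
    twr: float
    height_spread: int  # max_i h_i - min_i h_i, equal-height diagnostic


def bounding_extent(mask: BinaryMask, view_deg: Optional[int] = None) -> ViewExtents:
    """Tight bounding-box extents of the foreground; error on empty masks."""
    rows, cols = np.nonzero(mask.pixels)
    if rows.size == 0:
        raise EmptySilhouetteError("mask has no foreground pixels")
    return ViewExtents(
        view_deg=view_deg,
        h_i=int(rows.max() - rows.min() + 1),
        w_i=int(cols.max() - cols.min() + 1),
    )


def true_aspect_ratios(views: Sequence[ViewExtents]) -> PerspectiveRatios:
    """TARmax, TARmin and TWR from two or more same-time views."""
    if len(views) < 2:
        raise InsufficientViewsError(f"need >= 2 views, got {len(views)}")
    heights = np.array([v.h_i for v in views], dtype=int)
    widths = np.array([v.w_i for v in views], dtype=int)
    h = int(heights.max())
    w_min = int(widths.min())
    w_max = int(widths.max())
    return PerspectiveRatios(
        h=h,
        w_min=w_min,
        w_max=w_max,
        tar_max=w_max / h,
        tar_min=w_min / h,
        twr=w_min / w_max,
        height_spread=int(heights.max() - heights.min()),
    )


def aspect_ratio(mask: BinaryMask) -> float:
    """Baseline single-view aspect ratio: bounding-box height over width."""
    ext = bounding_extent(mask)
    return ext.h_i / ext.w_i
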