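"""Unidimensional modality (UDM) phenotypes: intermodal correlation and
mutual information.

Concurrent images of the same plant in two modalities (visible, infrared,
fluorescence) are compared over the overlapping plant pixels.  Both
bounding-box crops are resampled bilinearly to the lower resolution of the
two, their foreground masks intersected, and the paired intensity lists
X = {x_1..x_n}, Y = {y_1..y_n} read at the n overlap pixels.

Intermodal Correlation (IC) is Pearson's r over (X, Y):

    IC = S_xy / (S_x * S_y)

with S_x, S_y the sample standard deviations and S_xy the sample covariance.
IC in [-1, 1] measures linear coupling between modalities; near zero means
the channels are linearly unrelated.

Intermodal Mutual Information (IMI) discretises each channel into 64
equal-width bins over [0, 255] and computes

    IMI = H(X) + H(Y) - H(X, Y)       (bits, base-2 entropies)

from the marginal and 64x64 joint histograms.  IMI >= 0 captures any
(including nonlinear) dependency; 0 means independence at histogram
resolution, and IMI <= min(H(X), H(Y)).

The fixed binning keeps entropies comparable across time points regardless
of the observed intensity range.  Alignment is purely scale-based: the
acquisition geometry keeps the plant registered across modalities, so no
spatial registration is attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize

from .dataset_model import (
    BinaryMask,
    DatasetIndex,
    IntensityImage,
    PhenocurError,
    load_intensity,
)

logger = logging.getLogger("phenocur")

N_BINS = 64
INTENSITY_RANGE = (0.0, 255.0)

#: modality-pairing shorthand used in reports: visible-fluorescence, etc.
PAIRINGS = {
    "vf": ("visible", "fluorescence"),
    "vi": ("visible", "infrared"),
    "if": ("infrared", "fluorescence"),
}


class InsufficientOverlapError(PhenocurError):
    """Fewer than two overlapping plant pixels after alignment."""


class DegenerateVarianceError(PhenocurError):
    """A channel is constant over the overlap; Pearson r is undefined."""


class EmptySeriesError(PhenocurError):
    """No time point has both modalities available."""


@dataclass(frozen=True)
class ModalityCrop:
    """One modality image cropped to the plant's tight bounding box."""

    image: IntensityImage
    fg_mask: BinaryMask

    def __post_init__(self) -> None:
        if self.image.shape != self.fg_mask.shape:
            raise ValueError("crop image and mask shapes differ")
        if self.fg_mask.area() < 1:
            raise ValueError("crop must contain at least one foreground pixel")


@dataclass(frozen=True)
class AlignedModalityPair:
    """Two crops resampled to a common shape with their overlap pixel values."""

    x_img: np.ndarray
    y_img: np.ndarray
    overlap: BinaryMask
    x_vals: np.ndarray
    y_vals: np.ndarray

    @property
    def n(self) -> int:
        return int(self.x_vals.size)


@dataclass(frozen=True)
class ICResult:
    ic: float
    s_x: float
    s_y: float
    s_xy: float


@dataclass(frozen=True)
class IMIResult:
    imi: float
    h_x: float
    h_y: float
    h_xy: float
    p_x: np.ndarray
    p_y: np.ndarray
    p_xy: np.ndarray


def modality_crop(
    img: IntensityImage,
    fg_mask: Optional[BinaryMask] = None,
    fg_threshold: float = 0.0,
) -> ModalityCrop:
    """Crop an image to the tight bounding box of its plant pixels.

    Without an explicit mask, foreground is intensity > ``fg_threshold``
    (the acquisition background is black).
    """
    fg = fg_mask.pixels if fg_mask is not None else (img.pixels > fg_threshold).astype(np.uint8)
    rows, cols = np.nonzero(fg)
    if rows.size == 0:
        raise ValueError("no foreground pixels to crop")
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    return ModalityCrop(
        image=IntensityImage(img.pixels[r0:r1, c0:c1], img.modality),
        fg_mask=BinaryMask(fg[r0:r1, c0:c1]),
    )


def _resample(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if img.shape == shape:
        return img.astype(float)
    return resize(img.astype(float), shape, order=1, preserve_range=True,
                  anti_aliasing=False)


def prepare_pair(
    a: ModalityCrop, b: ModalityCrop, full_box: bool = False
) -> AlignedModalityPair:
    """Resample two crops to the lower resolution and read overlap intensities.

    Both image and foreground mask are interpolated bilinearly to the smaller
    crop's (rows, cols); the mask is re-binarised at 0.5.  Paired values are
    extracted in raster order over the overlap B12 (or over the whole common
    box when ``full_box`` is set).
    """
    target = a.image.shape if np.prod(a.image.shape) <= np.prod(b.image.shape) else b.image.shape
    x_img = _resample(a.image.pixels, target)
    y_img = _resample(b.image.pixels, target)
    fg_a = _resample(a.fg_mask.pixels, target) >= 0.5
    fg_b = _resample(b.fg_mask.pixels, target) >= 0.5
    overlap = (fg_a & fg_b) if not full_box else np.ones(target, dtype=bool)
    if overlap.sum() < 2:
        raise InsufficientOverlapError(
            f"only {int(overlap.sum())} overlapping plant pixels after alignment"
        )
    sel = overlap  # boolean indexing follows raster (row-major) order
    return AlignedModalityPair(
        x_img=x_img,
        y_img=y_img,
        overlap=BinaryMask(overlap.astype(np.uint8)),
        x_vals=x_img[sel],
        y_vals=y_img[sel],
    )


def intermodal_correlation(pair: AlignedModalityPair) -> ICResult:
    """Pearson correlation of the paired overlap intensities."""
    x = pair.x_vals.astype(float)
    y = pair.y_vals.astype(float)
    cov = np.cov(x, y, ddof=1)
    if cov[0, 0] == 0.0 or cov[1, 1] == 0.0:
        raise DegenerateVarianceError("a channel is constant over the overlap")
    s_x = float(math.sqrt(cov[0, 0]))
    s_y = float(math.sqrt(cov[1, 1]))
    s_xy = float(cov[0, 1])
    # r = s_xy / sqrt(var_x * var_y): algebraically s_xy/(s_x*s_y), evaluated
    # under a shared summation so IC(X, X) is exactly 1
    ic = s_xy / math.sqrt(cov[0, 0] * cov[1, 1])
    if abs(ic) > 1.0:
        if abs(ic) - 1.0 > 1e-12:
            raise AssertionError(f"correlation {ic} outside [-1, 1] beyond float residue")
        ic = math.copysign(1.0, ic)
    return ICResult(ic=ic, s_x=s_x, s_y=s_y, s_xy=s_xy)


def _bin_counts(values: np.ndarray) -> np.ndarray:
    counts, _ = np.histogram(values, bins=N_BINS, range=INTENSITY_RANGE)
    return counts


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def histogram_entropy(values: Sequence[float] | np.ndarray,
                      bins: int = N_BINS) -> float:
    """Shannon entropy (bits) of intensities under fixed equal-width binning.

    Values are binned into ``bins`` equal-width bins over [0, 255] (the last
    bin includes its right edge); 0 * log 0 := 0.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("entropy needs at least one value")
    counts, _ = np.histogram(values, bins=bins, range=INTENSITY_RANGE)
    return _entropy_bits(counts / counts.sum())


def intermodal_mutual_information(pair: AlignedModalityPair) -> IMIResult:
    """Histogram mutual information (bits) of the paired overlap intensities."""
    cx = _bin_counts(pair.x_vals)
    cy = _bin_counts(pair.y_vals)
    cxy, _, _ = np.histogram2d(pair.x_vals, pair.y_vals, bins=N_BINS,
                               range=[INTENSITY_RANGE, INTENSITY_RANGE])
    p_x = cx / cx.sum()
    p_y = cy / cy.sum()
    p_xy = cxy / cxy.sum()
    h_x = _entropy_bits(p_x)
    h_y = _entropy_bits(p_y)
    h_xy = _entropy_bits(p_xy.ravel())
    return IMIResult(imi=h_x + h_y - h_xy, h_x=h_x, h_y=h_y, h_xy=h_xy,
                     p_x=p_x, p_y=p_y, p_xy=p_xy)


def udm_series(
    index: DatasetIndex,
    plant_id: str,
    pairing: str,
    fg_threshold: float = 0.0,
    full_box: bool = False,
) -> pd.DataFrame:
    """IC and IMI at every time point where both modalities of a pairing exist.

    ``pairing`` is one of ``vf`` (visible-fluorescence), ``vi``
    (visible-infrared), ``if`` (infrared-fluorescence).  Time points with a
    missing modality are skipped with a warning; degenerate-variance time
    points report IC as missing.
    """
    if pairing not in PAIRINGS:
        raise ValueError(f"pairing must be one of {sorted(PAIRINGS)}")
    mod_a, mod_b = PAIRINGS[pairing]
    sub_a = index.filter(plant_id=plant_id, modality=mod_a)
    sub_b = index.filter(plant_id=plant_id, modality=mod_b)
    by_time_a = {k.time_index: (k, p) for k, p in sub_a.records}
    by_time_b = {k.time_index: (k, p) for k, p in sub_b.records}
    all_times = sorted(set(by_time_a) | set(by_time_b))
    common = sorted(set(by_time_a) & set(by_time_b))
    for t in set(all_times) - set(common):
        missing = mod_a if t not in by_time_a else mod_b
        logger.warning("plant %s t=%d: %s image missing, time point skipped",
                       plant_id, t, missing)
    if not common:
        raise EmptySeriesError(f"no common time points for plant {plant_id!r} "
                               f"pairing {pairing!r}")
    rows = []
    for t in common:
        key_a, path_a = by_time_a[t]
        _, path_b = by_time_b[t]
        img_a = load_intensity(path_a, mod_a)
        img_b = load_intensity(path_b, mod_b)
        pair = prepare_pair(modality_crop(img_a, fg_threshold=fg_threshold),
                            modality_crop(img_b, fg_threshold=fg_threshold),
                            full_box=full_box)
        try:
            ic = intermodal_correlation(pair)
            ic_vals = {"ic": ic.ic, "s_x": ic.s_x, "s_y": ic.s_y, "s_xy": ic.s_xy}
        except DegenerateVarianceError:
            logger.warning("plant %s t=%d pairing %s: constant channel, IC missing",
                           plant_id, t, pairing)
            ic_vals = {"ic": math.nan, "s_x": math.nan, "s_y": math.nan,
                       "s_xy": math.nan}
        imi = intermodal_mutual_information(pair)
        rows.append({
            "species": key_a.species, "treatment": key_a.treatment,
            "plant_id": plant_id, "t": t, "pairing": pairing, **ic_vals,
            "imi": imi.imi, "h_x": imi.h_x, "h_y": imi.h_y, "h_xy": imi.h_xy,
            "n_overlap": pair.n,
        })
    return pd.DataFrame(rows)
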