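"""Dataset index and typed in-memory representations for concurrent plant imaging.

Concurrent-imaging phenotyping datasets index every image by plant, treatment,
time point, and either a side-view angle (multi-view layouts) or an imaging
modality (multi-modality layouts).  A *unidimensional* analysis holds all axes
fixed except one: time for temporal change phenotypes, view for perspective
ratios, modality for intermodal dependency.  This module defines the key/index
types, reads binary plant masks and modality images from PNG, and validates
manifests for SIPID/SIMID-style directory trees.

Conventions
-----------
* Pixel coordinates are 0-based, row-major, origin at the top-left; ``(row,
  col)`` order everywhere.
* Masks use the nonzero-is-plant convention.
* Masks within one plant/view sequence must share dimensions (fixed camera
  geometry); a mismatch is an error, never a silent resize.
* Dates are metadata only; analysis time is the integer ``time_index``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger("phenocur")

SPECIES = ("buckwheat", "sunflower")
TREATMENTS = ("control", "drought")
VIEW_ANGLES = (0, 72, 144, 216)
MODALITIES = ("visible", "infrared", "fluorescence")

#: directory names used by the manifest-free layout convention
AXIS_LABELS = {
    "deg000": ("view", 0),
    "deg072": ("view", 72),
    "deg144": ("view", 144),
    "deg216": ("view", 216),
    "vis": ("modality", "visible"),
    "ir": ("modality", "infrared"),
    "fluo": ("modality", "fluorescence"),
}

MANIFEST_COLUMNS = [
    "species", "treatment", "plant_id", "time_index",
    "date", "view_deg", "modality", "relpath",
]

# ITU-R BT.601 luminance weights for RGB -> single channel
_BT601 = np.array([0.299, 0.587, 0.114])


class PhenocurError(Exception):
    """Base class for all package errors."""


class DecodeError(PhenocurError):
    """An image file could not be read or decoded."""


class DimensionError(PhenocurError):
    """Image dimensions are zero-sized or inconsistent across a sequence."""


class IndexError_(PhenocurError):
    """Dataset index is invalid (duplicate keys, missing files)."""


@dataclass(frozen=True)
class BinaryMask:
    """A segmented plant mask: 2-D grid of {0, 1}, nonzero = plant."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise DimensionError(f"mask must be 2-D and non-empty, got shape {px.shape}")
        if not np.isin(px, (0, 1)).all():
            raise ValueError("mask pixels must be exactly 0 or 1")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def area(self) -> int:
        """Foreground pixel count (projected area)."""
        return int(self.pixels.sum())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BinaryMask) and np.array_equal(self.pixels, other.pixels)

    def __hash__(self) -> int:  # frozen dataclass requires explicit pairing with __eq__
        return hash((self.pixels.shape, self.pixels.tobytes()))


@dataclass(frozen=True)
class IntensityImage:
    """Single-channel image with intensities in [0, 255] plus its modality tag."""

    pixels: np.ndarray
    modality: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise DimensionError(f"intensity image must be 2-D, got shape {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True, order=True)
class ObservationKey:
    """Identity of one image: which plant, when, and along which axis."""

    species: str
    treatment: str
    plant_id: str
    time_index: int
    view_deg: Optional[int] = None
    modality: Optional[str] = None
    date: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.time_index < 0:
            raise ValueError("time_index must be >= 0")
        if self.view_deg is not None and self.view_deg not in VIEW_ANGLES:
            raise ValueError(f"view_deg must be one of {VIEW_ANGLES}")
        if self.modality is not None and self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.view_deg is not None and self.modality is not None:
            raise ValueError("an observation varies along view OR modality, not both")


@dataclass
class DatasetIndex:
    """Validated list of (ObservationKey, file path) records."""

    records: list[tuple[ObservationKey, Path]]

    def __post_init__(self) -> None:
        seen: dict[ObservationKey, Path] = {}
        dups = []
        for key, path in self.records:
            if key in seen:
                dups.append(key)
            seen[key] = path
        if dups:
            raise IndexError_(f"duplicate observation keys: {dups}")

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, DatasetIndex) and sorted(
            (k, str(p)) for k, p in self.records
        ) == sorted((k, str(p)) for k, p in other.records)

    def filter(self, **attrs) -> "DatasetIndex":
        """Sub-index of records whose key matches every given attribute."""
        kept = [
            (k, p) for k, p in self.records
            if all(getattr(k, a) == v for a, v in attrs.items())
        ]
        return DatasetIndex(kept)

    def plant_ids(self) -> list[str]:
        return sorted({k.plant_id for k, _ in self.records})

    def axis_summary(self) -> pd.DataFrame:
        """Record counts per (species, treatment, plant, view/modality)."""
        rows = [
            {
                "species": k.species, "treatment": k.treatment, "plant_id": k.plant_id,
                "time_index": k.time_index, "view_deg": k.view_deg, "modality": k.modality,
            }
            for k, _ in self.records
        ]
        df = pd.DataFrame(rows, columns=["species", "treatment", "plant_id",
                                         "time_index", "view_deg", "modality"])
        if df.empty:
            return df
        return (
            df.groupby(["species", "treatment", "plant_id"], dropna=False)
            .agg(n_records=("time_index", "size"),
                 n_times=("time_index", "nunique"),
                 n_views=("view_deg", "nunique"),
                 n_modalities=("modality", "nunique"))
            .reset_index()
        )


@dataclass
class MaskSequence:
    """Time-ordered masks S_1 … S_n for one plant at one fixed view."""

    masks: list[BinaryMask]
    times: list[int]
    key: ObservationKey  # time_index field is not meaningful here

    def __post_init__(self) -> None:
        if not self.masks:
            raise ValueError("a mask sequence needs at least one mask")
        if len(self.masks) != len(self.times):
            raise ValueError("masks and times must be the same length")
        shape = self.masks[0].shape
        for m in self.masks[1:]:
            if m.shape != shape:
                raise DimensionError(
                    f"masks in a sequence must share dimensions: {shape} vs {m.shape} "
                    f"(plant {self.key.plant_id!r})"
                )
        if sorted(self.times) != list(self.times) or len(set(self.times)) != len(self.times):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.masks)


# ---------------------------------------------------------------------------
# image loading
# ---------------------------------------------------------------------------

def load_mask(path: Path | str, foreground_threshold: int = 0) -> BinaryMask:
    """Read a PNG (8-bit gray or RGB) as a binary plant mask.

    A pixel is foreground iff its decoded intensity exceeds
    ``foreground_threshold`` (default 0, i.e. nonzero = plant).  RGB inputs
    are reduced with an any-channel rule.
    """
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise DecodeError(f"cannot decode {path}: {exc}") from exc
    if arr.ndim == 3:
        fg = (arr[..., :3] > foreground_threshold).any(axis=-1)
    elif arr.ndim == 2:
        fg = arr > foreground_threshold
    else:
        raise DecodeError(f"unsupported image layout {arr.shape} in {path}")
    if fg.shape[0] < 1 or fg.shape[1] < 1:
        raise DimensionError(f"zero-size image {path}")
    return BinaryMask(fg.astype(np.uint8))


def save_mask(mask: BinaryMask, path: Path | str) -> None:
    """Write a mask as 8-bit gray PNG, foreground = 255."""
    iio.imwrite(path, (mask.pixels * 255).astype(np.uint8))


def load_intensity(path: Path | str, modality: str) -> IntensityImage:
    """Read a modality image; RGB is converted to BT.601 luminance."""
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise DecodeError(f"cannot decode {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., :3].astype(float) @ _BT601
    return IntensityImage(np.clip(arr.astype(float), 0, 255), modality)


# ---------------------------------------------------------------------------
# dataset scanning
# ---------------------------------------------------------------------------

def _key_from_manifest_row(row: pd.Series) -> ObservationKey:
    view = row.get("view_deg")
    modality = row.get("modality")
    view = None if pd.isna(view) or view == "" else int(view)
    modality = None if pd.isna(modality) or modality == "" else str(modality)
    date = row.get("date")
    date = None if pd.isna(date) or date == "" else str(date)
    return ObservationKey(
        species=str(row["species"]), treatment=str(row["treatment"]),
        plant_id=str(row["plant_id"]), time_index=int(row["time_index"]),
        view_deg=view, modality=modality, date=date,
    )


def scan_dataset(root: Path | str, manifest: Optional[Path | str] = None) -> DatasetIndex:
    """Build a DatasetIndex from a manifest CSV or a conventional tree.

    With a manifest, rows are ``species,treatment,plant_id,time_index,date,
    view_deg,modality,relpath`` and every referenced file must exist.  Without
    one, paths matching ``root/<species>/<treatment>/<plant_id>/<axis_label>/
    <time_index>.png`` are collected, with ``axis_label`` one of
    ``deg000/deg072/deg144/deg216`` (views) or ``vis/ir/fluo`` (modalities).
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")

    records: list[tuple[ObservationKey, Path]] = []
    if manifest is not None:
        df = pd.read_csv(manifest, dtype=str, keep_default_na=False)
        missing_cols = set(MANIFEST_COLUMNS) - set(df.columns)
        if missing_cols:
            raise IndexError_(f"manifest missing columns: {sorted(missing_cols)}")
        missing_files = []
        for _, row in df.iterrows():
            path = root / row["relpath"]
            if not path.is_file():
                missing_files.append(str(path))
                continue
            records.append((_key_from_manifest_row(row), path))
        if missing_files:
            raise IndexError_(f"manifest references missing files: {missing_files}")
    else:
        for species_dir in sorted(p for p in root.iterdir() if p.is_dir()):
            if species_dir.name not in SPECIES:
                continue
            for treat_dir in sorted(p for p in species_dir.iterdir() if p.is_dir()):
                if treat_dir.name not in TREATMENTS:
                    continue
                for plant_dir in sorted(p for p in treat_dir.iterdir() if p.is_dir()):
                    for axis_dir in sorted(p for p in plant_dir.iterdir() if p.is_dir()):
                        if axis_dir.name not in AXIS_LABELS:
                            continue
                        kind, value = AXIS_LABELS[axis_dir.name]
                        for png in sorted(axis_dir.glob("*.png")):
                            key = ObservationKey(
                                species=species_dir.name,
                                treatment=treat_dir.name,
                                plant_id=plant_dir.name,
                                time_index=int(png.stem),
                                view_deg=value if kind == "view" else None,
                                modality=value if kind == "modality" else None,
                            )
                            records.append((key, png))
    return DatasetIndex(records)


def mask_sequence(
    index: DatasetIndex,
    plant_id: str,
    view_deg: Optional[int] = None,
    foreground_threshold: int = 0,
) -> MaskSequence:
    """Load the time-ordered mask sequence for one plant at one view."""
    sub = index.filter(plant_id=plant_id, view_deg=view_deg)
    if len(sub) == 0:
        raise IndexError_(f"no records for plant {plant_id!r} at view {view_deg!r}")
    pairs = sorted(sub.records, key=lambda kp: kp[0].time_index)
    masks = [load_mask(p, foreground_threshold) for _, p in pairs]
    times = [k.time_index for k, _ in pairs]
    key = replace(pairs[0][0], time_index=0)
    return MaskSequence(masks=masks, times=times, key=key)
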