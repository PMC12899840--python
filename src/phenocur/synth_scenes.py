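"""Synthetic concurrent-imaging scenes with planted, fully known ground truth.

Every phenotype in this package is verifiable against construction-time
truth: temporal scenes plant appearing/disappearing 8-connected components
of exact area and known centroid, view scenes render silhouettes with exact
bounding-box extents, and modality pairs draw foreground intensities from a
bivariate normal with a prescribed Pearson correlation before quantisation.

Exactness guarantees
--------------------
* Planted components keep a Chebyshev gap of at least 2 pixels from every
  other foreground pixel, so 8-connectivity can never merge them: component
  counts and largest-component areas are recovered with integer equality.
* Blobs rendered as rectangles have their requested area exactly; disks are
  rendered then measured, and the measured area is what the truth log
  records.
* Correlated intensities use a Gaussian copula mapped linearly to [0, 255];
  quantisation to integer intensities slightly attenuates |rho|, hence
  recovery tests allow a +-0.05 band.

Determinism: identical parameters (including the seed) produce bit-identical
outputs.  Cohorts derive one seed per plant by stable hashing of the plant
id mixed with the global seed, so adding or removing plants does not
reshuffle the others.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .dataset_model import (
    BinaryMask,
    IntensityImage,
    MaskSequence,
    ObservationKey,
    PhenocurError,
    save_mask,
)

import imageio.v3 as iio

#: minimum Chebyshev gap (px) between a planted blob and any other foreground
GAP = 2

_PAIR_INDEX = {"vf": (0, 2), "vi": (0, 1), "if": (1, 2)}  # (visible, infrared, fluorescence)


class PlacementError(PhenocurError):
    """A planted blob could not be placed with the required gaps."""


@dataclass(frozen=True)
class BlobSpec:
    """One planted component: exact target area and a shape family."""

    area_px: int
    shape: str = "rect"  # "rect" (area-exact) or "disk" (area measured after render)
    centroid: Optional[tuple[float, float]] = None  # requested placement, optional

    def __post_init__(self) -> None:
        if self.area_px < 1:
            raise ValueError("blob area must be >= 1 px")
        if self.shape not in ("rect", "disk"):
            raise ValueError(f"unknown blob shape {self.shape!r}")


@dataclass
class SceneParams:
    """Parameters of one synthetic scene (temporal, view, and modality axes)."""

    image_shape: tuple[int, int] = (96, 96)
    n_timepoints: int = 6
    base_plant: BlobSpec = field(default_factory=lambda: BlobSpec(area_px=120))
    growth_events: Optional[list[list[BlobSpec]]] = None  # per step, len n_timepoints-1
    decay_events: Optional[list[int]] = None  # planted components removed per step
    view_widths: Optional[list[list[int]]] = None  # per time point, one width per view
    shared_height: Optional[list[int]] = None  # per time point
    modality_coupling: dict = field(
        default_factory=lambda: {"rho": {"vf": 0.5, "vi": 0.3, "if": 0.2},
                                 "noise_sd": 0.0})
    rng_seed: int = 0


@dataclass
class GroundTruthLog:
    """Construction-time truth for every generated frame."""

    #: per consecutive pair: t, nchange_pos/neg, maxchange_pos/neg, dispersion_pos
    pairs: list[dict] = field(default_factory=list)
    #: per time point: {"h": int, "widths": [int, ...]}
    views: list[dict] = field(default_factory=list)
    #: planted Pearson correlation per modality pairing
    rho: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# blob rendering and placement
# ---------------------------------------------------------------------------

def _render_blob(spec: BlobSpec) -> np.ndarray:
    """Render a blob as a small boolean patch with exact (rect) area."""
    a = spec.area_px
    if spec.shape == "rect":
        w = math.ceil(math.sqrt(a))
        full_rows, rem = divmod(a, w)
        h = full_rows + (1 if rem else 0)
        patch = np.zeros((h, w), dtype=bool)
        patch[:full_rows, :] = True
        if rem:
            patch[full_rows, :rem] = True
        return patch
    # disk: radius from the continuous-area relation, actual pixel count varies
    r = max(math.sqrt(a / math.pi), 0.5)
    n = int(math.ceil(2 * r)) + 1
    yy, xx = np.mgrid[:n, :n]
    c = (n - 1) / 2
    patch = (yy - c) ** 2 + (xx - c) ** 2 <= r**2
    return patch


def _place_patch(
    canvas: np.ndarray, patch: np.ndarray, rng: np.random.Generator,
    at: Optional[tuple[int, int]] = None, max_tries: int = 500,
) -> tuple[int, int]:
    """Stamp ``patch`` onto ``canvas`` keeping a >= GAP Chebyshev clearance.

    The clearance test inspects the patch bounding box expanded by GAP pixels
    against all current foreground, which is conservative but guarantees that
    no 8-connected merge is possible.  Returns the (row, col) of the placed
    patch's top-left corner.
    """
    ph, pw = patch.shape
    H, W = canvas.shape
    if ph + 2 * GAP > H or pw + 2 * GAP > W:
        raise PlacementError(f"blob {patch.shape} cannot fit in frame {canvas.shape}")

    def fits(r0: int, c0: int) -> bool:
        rl, rh = max(r0 - GAP, 0), min(r0 + ph + GAP, H)
        cl, ch = max(c0 - GAP, 0), min(c0 + pw + GAP, W)
        return not canvas[rl:rh, cl:ch].any()

    if at is not None:
        r0, c0 = at
        if not (0 <= r0 <= H - ph and 0 <= c0 <= W - pw) or not fits(r0, c0):
            raise PlacementError(f"requested position {at} violates gap constraints")
        canvas[r0:r0 + ph, c0:c0 + pw] |= patch
        return r0, c0

    for _ in range(max_tries):
        r0 = int(rng.integers(GAP, H - ph - GAP + 1))
        c0 = int(rng.integers(GAP, W - pw - GAP + 1))
        if fits(r0, c0):
            canvas[r0:r0 + ph, c0:c0 + pw] |= patch
            return r0, c0
    raise PlacementError(
        f"no valid position for blob {patch.shape} after {max_tries} tries")


def _patch_centroid(patch: np.ndarray, r0: int, c0: int) -> tuple[float, float]:
    rows, cols = np.nonzero(patch)
    return float(rows.mean() + r0), float(cols.mean() + c0)


def _mean_nn_distance(centroids: list[tuple[float, float]]) -> float:
    """Truth-side mean nearest-neighbour distance (independent closed form)."""
    k = len(centroids)
    if k < 2:
        return math.nan
    pts = np.asarray(centroids)
    total = 0.0
    for i in range(k):
        d = np.sqrt(((pts - pts[i]) ** 2).sum(axis=1))
        d[i] = np.inf
        total += d.min()
    return total / k


# ---------------------------------------------------------------------------
# temporal scenes
# ---------------------------------------------------------------------------

@dataclass
class _Planted:
    patch: np.ndarray
    r0: int
    c0: int
    area: int
    centroid: tuple[float, float]


def generate_temporal_scene(
    params: SceneParams,
    key: Optional[ObservationKey] = None,
) -> tuple[MaskSequence, GroundTruthLog]:
    """Mask sequence with planted appearing/disappearing components.

    The base plant is placed first and persists.  At each step, the requested
    number of previously planted components is removed (each removal is one
    exact negative-change component), then the step's growth blobs are added
    (each an exact positive-change component).  The truth log records the
    per-pair component counts, largest areas, and the mean nearest-neighbour
    distance of the added components' centroids.
    """
    rng = np.random.default_rng(params.rng_seed)
    n = params.n_timepoints
    if n < 1:
        raise ValueError("need at least one time point")
    growth = params.growth_events or [[] for _ in range(n - 1)]
    decay = params.decay_events or [0] * (n - 1)
    if len(growth) != n - 1 or len(decay) != n - 1:
        raise ValueError("event schedules must have n_timepoints - 1 entries")

    canvas = np.zeros(params.image_shape, dtype=bool)
    base_patch = _render_blob(params.base_plant)
    at = None
    if params.base_plant.centroid is None:
        # centre the base plant so random events spread around it
        at = ((params.image_shape[0] - base_patch.shape[0]) // 2,
              (params.image_shape[1] - base_patch.shape[1]) // 2)
    _place_patch(canvas, base_patch, rng, at=at)

    alive: list[_Planted] = []
    masks = [BinaryMask(canvas.astype(np.uint8))]
    truth = GroundTruthLog()

    for step in range(n - 1):
        n_decay = min(decay[step], len(alive))
        removed: list[_Planted] = []
        for _ in range(n_decay):
            idx = int(rng.integers(len(alive)))
            removed.append(alive.pop(idx))
        for pl in removed:
            canvas[pl.r0:pl.r0 + pl.patch.shape[0],
                   pl.c0:pl.c0 + pl.patch.shape[1]] &= ~pl.patch

        # growth blobs must also clear pixels vacated THIS step: those were
        # foreground at time t, and overlap would clip the observed Change+
        forbidden = canvas.copy()
        for pl in removed:
            forbidden[pl.r0:pl.r0 + pl.patch.shape[0],
                      pl.c0:pl.c0 + pl.patch.shape[1]] |= pl.patch

        added: list[_Planted] = []
        for spec in growth[step]:
            patch = _render_blob(spec)
            at = None
            if spec.centroid is not None:
                rows, cols = np.nonzero(patch)
                at = (int(round(spec.centroid[0] - rows.mean())),
                      int(round(spec.centroid[1] - cols.mean())))
            r0, c0 = _place_patch(forbidden, patch, rng, at=at)
            canvas[r0:r0 + patch.shape[0], c0:c0 + patch.shape[1]] |= patch
            pl = _Planted(patch=patch, r0=r0, c0=c0, area=int(patch.sum()),
                          centroid=_patch_centroid(patch, r0, c0))
            added.append(pl)
            alive.append(pl)

        masks.append(BinaryMask(canvas.astype(np.uint8)))
        truth.pairs.append({
            "t": step,
            "nchange_pos": len(added),
            "nchange_neg": len(removed),
            "maxchange_pos": max((p.area for p in added), default=0),
            "maxchange_neg": max((p.area for p in removed), default=0),
            "change_pos_area": sum(p.area for p in added),
            "change_neg_area": sum(p.area for p in removed),
            "dispersion_pos": _mean_nn_distance([p.centroid for p in added]),
            "centroids_pos": [p.centroid for p in added],
        })

    if key is None:
        key = ObservationKey(species="buckwheat", treatment="control",
                             plant_id="synthetic", time_index=0, view_deg=0)
    seq = MaskSequence(masks=masks, times=list(range(n)), key=key)
    return seq, truth


# ---------------------------------------------------------------------------
# view scenes
# ---------------------------------------------------------------------------

def generate_view_scene(params: SceneParams) -> tuple[list[list[BinaryMask]], GroundTruthLog]:
    """Per-view solid silhouettes with exact bounding-box extents.

    ``params.view_widths[t]`` gives one width per view at time point t and
    ``params.shared_height[t]`` the common height.  Returns masks indexed as
    ``masks[t][view]`` plus the truth log of (h, widths) per time point.
    """
    if params.view_widths is None or params.shared_height is None:
        raise ValueError("view_widths and shared_height schedules are required")
    if len(params.view_widths) != len(params.shared_height):
        raise ValueError("schedules must cover the same time points")
    H, W = params.image_shape
    truth = GroundTruthLog()
    masks: list[list[BinaryMask]] = []
    for widths, h in zip(params.view_widths, params.shared_height):
        if h > H or max(widths) > W:
            raise PlacementError(f"silhouette {h}x{max(widths)} exceeds frame {params.image_shape}")
        row = []
        for w in widths:
            canvas = np.zeros((H, W), dtype=np.uint8)
            canvas[:h, :w] = 1
            row.append(BinaryMask(canvas))
        masks.append(row)
        truth.views.append({"h": int(h), "widths": [int(w) for w in widths]})
    return masks, truth


# ---------------------------------------------------------------------------
# modality pairs
# ---------------------------------------------------------------------------

def _disk_mask(shape: tuple[int, int], fill: float = 0.85) -> np.ndarray:
    H, W = shape
    yy, xx = np.mgrid[:H, :W]
    r = fill * min(H, W) / 2
    return ((yy - (H - 1) / 2) ** 2 + (xx - (W - 1) / 2) ** 2 <= r**2)


def _quantize(z: np.ndarray) -> np.ndarray:
    """Map standard-normal values linearly onto [1, 255] integer intensities.

    Intensity 0 is reserved for background so foreground pixels stay above
    the default foreground threshold.
    """
    return np.clip(np.rint(128.0 + 40.0 * z), 1, 255)


def generate_modality_pair(
    rho_target: float,
    shape: tuple[int, int] = (64, 64),
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    modalities: tuple[str, str] = ("visible", "fluorescence"),
) -> tuple[IntensityImage, IntensityImage, BinaryMask, float]:
    """Two modality images with a planted Pearson correlation on a shared disk.

    Foreground intensities are a bivariate standard normal with correlation
    ``rho_target`` mapped linearly to [1, 255]; ``noise_sd`` adds independent
    Gaussian noise to each channel before quantisation (attenuating the
    realised correlation).  Background is 0.  Returns the two images, the
    shared foreground mask, and the planted rho.
    """
    if not -1.0 <= rho_target <= 1.0:
        raise ValueError("rho_target must lie in [-1, 1]")
    rng = np.random.default_rng(rng_seed)
    fg = _disk_mask(shape)
    n = int(fg.sum())
    z1 = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    z2 = rho_target * z1 + math.sqrt(max(0.0, 1.0 - rho_target**2)) * eps
    if noise_sd > 0:
        z1 = z1 + noise_sd * rng.standard_normal(n)
        z2 = z2 + noise_sd * rng.standard_normal(n)
    img_a = np.zeros(shape)
    img_b = np.zeros(shape)
    img_a[fg] = _quantize(z1)
    img_b[fg] = _quantize(z2)
    return (
        IntensityImage(img_a, modalities[0]),
        IntensityImage(img_b, modalities[1]),
        BinaryMask(fg.astype(np.uint8)),
        float(rho_target),
    )


def _modality_triple(
    fg: np.ndarray, rho: dict[str, float], noise_sd: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Visible/infrared/fluorescence intensities with pairwise target rhos."""
    n = int(fg.sum())
    corr = np.eye(3)
    corr[0, 1] = corr[1, 0] = rho.get("vi", 0.0)
    corr[0, 2] = corr[2, 0] = rho.get("vf", 0.0)
    corr[1, 2] = corr[2, 1] = rho.get("if", 0.0)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"pairwise rhos {rho} do not form a valid correlation "
                         "matrix") from exc
    z = rng.standard_normal((3, n))
    z = chol @ z
    if noise_sd > 0:
        z = z + noise_sd * rng.standard_normal(z.shape)
    out = {}
    for name, zi in zip(("visible", "infrared", "fluorescence"), z):
        img = np.zeros(fg.shape)
        img[fg] = _quantize(zi)
        out[name] = img
    return out


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def plant_seed(global_seed: int, plant_id: str) -> int:
    """Stable per-plant seed derived from the cohort seed and the plant id."""
    return zlib.crc32(f"{global_seed}:{plant_id}".encode()) & 0x7FFFFFFF


def generate_cohort(
    root: Path | str,
    n_control: int = 8,
    n_drought: int = 8,
    suppression: float = 1.0,
    species: str = "sunflower",
    n_timepoints: int = 6,
    image_shape: tuple[int, int] = (96, 96),
    base_area: int = 150,
    events_per_step: tuple[int, int] = (2, 4),
    event_area: tuple[int, int] = (20, 60),
    decay_prob: float = 0.3,
    with_modalities: bool = False,
    modality_rho: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> tuple[Path, dict[str, GroundTruthLog]]:
    """Write a full synthetic dataset tree plus manifest; return the truth.

    Each plant is an independent temporal scene; drought plants receive a
    planted suppression of growth-event areas (``suppression`` multiplies
    every event area, floored at 1 px), emulating stress-reduced expansion.
    With ``with_modalities`` the tree also carries per-time visible/infrared/
    fluorescence intensity images over the plant's current silhouette with
    the given pairwise correlations.  The layout matches what
    :func:`phenocur.dataset_model.scan_dataset` consumes.
    """
    if n_control < 2 or n_drought < 2:
        raise ValueError("need at least 2 plants per treatment")
    root = Path(root)
    rows = []
    truths: dict[str, GroundTruthLog] = {}
    groups = [("control", n_control), ("drought", n_drought)]
    for treatment, n_plants in groups:
        factor = suppression if treatment == "drought" else 1.0
        for i in range(n_plants):
            plant_id = f"{treatment[:1]}{i:02d}"
            prng = np.random.default_rng(plant_seed(seed, plant_id))
            growth: list[list[BlobSpec]] = []
            decay: list[int] = []
            for _ in range(n_timepoints - 1):
                k = int(prng.integers(events_per_step[0], events_per_step[1] + 1))
                areas = prng.integers(event_area[0], event_area[1] + 1, size=k)
                growth.append([BlobSpec(area_px=max(1, int(round(a * factor))))
                               for a in areas])
                decay.append(int(prng.random() < decay_prob))
            params = SceneParams(
                image_shape=image_shape, n_timepoints=n_timepoints,
                base_plant=BlobSpec(area_px=base_area),
                growth_events=growth, decay_events=decay,
                rng_seed=plant_seed(seed, plant_id + "/scene"),
            )
            key = ObservationKey(species=species, treatment=treatment,
                                 plant_id=plant_id, time_index=0, view_deg=0)
            seq, truth = generate_temporal_scene(params, key=key)
            if with_modalities and modality_rho is not None:
                truth.rho = dict(modality_rho)
            truths[plant_id] = truth

            mask_dir = root / species / treatment / plant_id / "deg000"
            mask_dir.mkdir(parents=True, exist_ok=True)
            for t, mask in zip(seq.times, seq.masks):
                rel = Path(species) / treatment / plant_id / "deg000" / f"{t}.png"
                save_mask(mask, root / rel)
                rows.append({"species": species, "treatment": treatment,
                             "plant_id": plant_id, "time_index": t, "date": "",
                             "view_deg": 0, "modality": "", "relpath": str(rel)})

            if with_modalities:
                rho = modality_rho or {"vf": 0.5, "vi": 0.3, "if": 0.2}
                mrng = np.random.default_rng(plant_seed(seed, plant_id + "/mod"))
                for t, mask in zip(seq.times, seq.masks):
                    triple = _modality_triple(mask.pixels.astype(bool), rho,
                                              0.0, mrng)
                    for mod, label in (("visible", "vis"), ("infrared", "ir"),
                                       ("fluorescence", "fluo")):
                        mdir = root / species / treatment / plant_id / label
                        mdir.mkdir(parents=True, exist_ok=True)
                        rel = (Path(species) / treatment / plant_id / label
                               / f"{t}.png")
                        iio.imwrite(root / rel,
                                    triple[mod].astype(np.uint8))
                        rows.append({"species": species, "treatment": treatment,
                                     "plant_id": plant_id, "time_index": t,
                                     "date": "", "view_deg": "",
                                     "modality": mod, "relpath": str(rel)})

    manifest = root / "manifest.csv"
    pd.DataFrame(rows, columns=["species", "treatment", "plant_id", "time_index",
                                "date", "view_deg", "modality", "relpath"]
                 ).to_csv(manifest, index=False)
    return manifest, truths


def cohort_params_from_yaml(path: Path | str) -> dict:
    """Read a cohort scene-spec YAML into ``generate_cohort`` keyword form."""
    with open(path) as fh:
        spec = yaml.safe_load(fh) or {}
    allowed = {"n_control", "n_drought", "suppression", "species", "n_timepoints",
               "image_shape", "base_area", "events_per_step", "event_area",
               "decay_prob", "with_modalities", "modality_rho", "seed"}
    unknown = set(spec) - allowed
    if unknown:
        raise ValueError(f"unknown cohort spec keys: {sorted(unknown)}")
    for tup_key in ("image_shape", "events_per_step", "event_area"):
        if tup_key in spec:
            spec[tup_key] = tuple(spec[tup_key])
    return spec
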