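"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from phenocur import BinaryMask


def mask_from_coords(coords, shape) -> BinaryMask:
    """Build a mask from a list of (row, col) foreground coordinates."""
    px = np.zeros(shape, dtype=np.uint8)
    for r, c in coords:
        px[r, c] = 1
    return BinaryMask(px)


def bfs_partition(mask: BinaryMask) -> set[frozenset[tuple[int, int]]]:
    """Independent breadth-first flood-fill oracle for 8-connected components.

    Returns the partition of foreground pixels as a set of frozen pixel sets,
    so equality checks are label-free.
    """
    px = mask.pixels
    h, w = px.shape
    seen = np.zeros_like(px, dtype=bool)
    parts: set[frozenset[tuple[int, int]]] = set()
    for r0 in range(h):
        for c0 in range(w):
            if px[r0, c0] and not seen[r0, c0]:
                comp = []
                queue = deque([(r0, c0)])
                seen[r0, c0] = True
                while queue:
                    r, c = queue.popleft()
                    comp.append((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < h and 0 <= cc < w
                                    and px[rr, cc] and not seen[rr, cc]):
                                seen[rr, cc] = True
                                queue.append((rr, cc))
                parts.add(frozenset(comp))
    return parts


def label_partition(labels: np.ndarray) -> set[frozenset[tuple[int, int]]]:
    """Partition induced by a label image (label 0 = background)."""
    parts = {}
    for r, c in zip(*np.nonzero(labels)):
        parts.setdefault(labels[r, c], []).append((int(r), int(c)))
    return {frozenset(v) for v in parts.values()}


def random_mask(rng: np.random.Generator, shape=(32, 32), density=0.3) -> BinaryMask:
    return BinaryMask((rng.random(shape) < density).astype(np.uint8))


def welch_closed_form(a, b):
    """Hand-rolled Welch t / df / two-sided p, independent of the package."""
    from scipy.stats import t as t_dist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * t_dist.sf(abs(t), df)
    return t, df, p


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
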