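"""Idealized pit-geometry model: cells invaginate corona by corona.

On an idealized placode (hexagonal lattice clipped to a disk) the cells at
the pit internalize first, then their first shell of neighbours, and so on.
The number of cells per corona depends strongly on pit placement: a central
single-cell pit collects an ever-increasing 6k cells in shell k; an
eccentric pit at the placode boundary collects a steady, low number per
corona; an enlarged pit collects a large first corona followed by steady
numbers.  Only the eccentric geometry yields a narrow symmetrical tube.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tissue_io import GeometryError, TrackedTissue

__all__ = [
    "CoronaLayout",
    "build_ideal_placode",
    "predict_corona_series",
    "classify_series",
    "observed_corona_counts",
]

STEADY_SLOPE = 0.5  # cells/corona below which a fitted series counts as steady


@dataclass
class CoronaLayout:
    centers: np.ndarray  # (n, 2) cell centres, µm
    adjacency: list[tuple[int, int]]
    pit_cells: list[int]
    corona_index: np.ndarray  # per cell; -1 for unreachable cells
    counts: np.ndarray  # cells per corona, index 0 = pit


def _hex_lattice(R: float, d: float) -> np.ndarray:
    """Triangular lattice with spacing d covering the disk of radius R."""
    pts = []
    m = int(np.ceil(R / d)) + 2
    for j in range(-m, m + 1):
        y = j * d * np.sqrt(3) / 2
        for i in range(-m, m + 1):
            x = (i + 0.5 * (j % 2)) * d
            if x * x + y * y <= R * R + 1e-9:
                pts.append((x, y))
    return np.array(pts)


def build_ideal_placode(
    R: float, d: float, pit_center: np.ndarray, pit_radius: float = 0.0
) -> CoronaLayout:
    """Hexagonal-lattice placode clipped to a disk, with corona indices.

    ``pit_center`` may sit anywhere inside or on the disk; cells within
    ``pit_radius`` of it (or the single nearest cell) form corona 0.  The
    corona index of every other cell is its adjacency-graph distance from
    the pit set.
    """
    if not (R > d > 0):
        raise GeometryError("need R > d > 0")
    pit_center = np.asarray(pit_center, dtype=float)
    if np.linalg.norm(pit_center) > R + 1e-9:
        raise GeometryError("pit center lies outside the placode")
    centers = _hex_lattice(R, d)
    n = len(centers)
    dist2 = np.sum((centers[:, None] - centers[None]) ** 2, axis=-1)
    thr = (1.05 * d) ** 2
    adjacency = [
        (i, j) for i in range(n) for j in range(i + 1, n) if dist2[i, j] <= thr
    ]
    pit_d = np.linalg.norm(centers - pit_center, axis=1)
    pit_cells = list(np.nonzero(pit_d <= pit_radius + 1e-9)[0])
    if not pit_cells:
        pit_cells = [int(np.argmin(pit_d))]

    neigh: dict[int, set[int]] = {i: set() for i in range(n)}
    for i, j in adjacency:
        neigh[i].add(j)
        neigh[j].add(i)
    index = np.full(n, -1, dtype=int)
    frontier = set(pit_cells)
    for i in frontier:
        index[i] = 0
    k = 0
    while frontier:
        nxt = set()
        for i in frontier:
            for j in neigh[i]:
                if index[j] < 0:
                    index[j] = k + 1
                    nxt.add(j)
        frontier = nxt
        k += 1
    n_coronae = int(index.max()) + 1
    counts = np.bincount(index[index >= 0], minlength=n_coronae)
    return CoronaLayout(
        centers=centers,
        adjacency=adjacency,
        pit_cells=[int(i) for i in pit_cells],
        corona_index=index,
        counts=counts,
    )


def predict_corona_series(layout: CoronaLayout) -> tuple[np.ndarray, str]:
    """Ordered per-corona counts plus the scenario classification."""
    return layout.counts, classify_series(layout.counts)


def classify_series(counts: np.ndarray) -> str:
    """steady | increasing | large-then-steady, by fitted slope/intercept.

    The slope is fitted over coronae >= 1; ``steady`` needs
    |slope| < 0.5 cells/corona, ``large-then-steady`` additionally needs a
    corona-0 count well above the steady level.
    """
    counts = np.asarray(counts, dtype=float)
    if len(counts) < 3:
        return "steady"
    tail = counts[1:]
    k = np.arange(1, len(counts))
    slope = float(np.polyfit(k, tail, 1)[0])
    if abs(slope) >= STEADY_SLOPE:
        return "increasing" if slope > 0 else "steady"
    if counts[0] > 1.5 * tail.mean():
        return "large-then-steady"
    return "steady"


def observed_corona_counts(tissue: TrackedTissue) -> np.ndarray:
    """Counts of internalizing cells per corona in a tracked tissue.

    A cell internalizes when its track ends before the last frame.  The seed
    corona is the earliest-disappearing group; every other internalized cell
    is assigned the adjacency-shell distance from that seed on the first
    frame's mesh (the initial tissue, before any cell has left).
    """
    last = tissue.n_frames - 1
    end_frame = {
        tid: tissue.presence(tid)[-1]
        for tid in tissue.track_ids()
    }
    internalized = sorted(t for t, e in end_frame.items() if e < last)
    if not internalized:
        return np.array([], dtype=int)
    f0 = tissue.frames[0]
    neigh = {t: f0.neighbors(t) for t in f0.cells}
    first = min(end_frame[t] for t in internalized)
    seed = {t for t in internalized if end_frame[t] == first and t in f0.cells}
    index: dict[int, int] = {t: 0 for t in seed}
    frontier = set(seed)
    k = 0
    while frontier:
        nxt = set()
        for i in frontier:
            for j in neigh.get(i, ()):
                if j not in index:
                    index[j] = k + 1
                    nxt.add(j)
        frontier = nxt
        k += 1
    shells = [index[t] for t in internalized if t in index]
    if not shells:
        return np.array([], dtype=int)
    return np.bincount(shells)
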