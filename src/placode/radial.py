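"""Mobile radial coordinate system centred on the invagination pit.

The origin is specified once, at t = 0 min, and tracked forwards and
backwards in time by following the mean displacement of the nearest placodal
cells.  Every cell then carries a radial distance ``r`` (µm), a
circumferential angle ``theta`` (zero toward posterior, anti-clockwise for a
left-side placode and clockwise for a right-side one so data from the two
sides overlay), the distance ``D`` from the origin to the far placode edge
along the cell's own ray, a near/far region label (near iff
``r <= 0.33 * D``), and a radial stripe index fixed from the t = 0 frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, MultiPoint, Point
from shapely.geometry import Polygon as ShapelyPolygon
from shapely.ops import unary_union

from .tissue_io import GeometryError, TissueValidationError, TrackedTissue

__all__ = [
    "RadialFrame",
    "propagate_origin",
    "assign_radial_coordinates",
    "assign_regions",
    "regions_at_t0",
    "assign_stripes",
    "stripe_kymograph",
]

NEAR_FRACTION = 0.33  # near region: up to 33% of the pit-to-edge distance
POSTERIOR = np.array([1.0, 0.0])  # default posterior unit vector


@dataclass
class RadialFrame:
    """Per-frame radial coordinates keyed by track id."""

    origin: np.ndarray
    r: dict[int, float]
    theta: dict[int, float]  # NaN where undefined (cell at the origin)
    D: dict[int, float]
    region: dict[int, str] = field(default_factory=dict)
    stripe: dict[int, int] = field(default_factory=dict)


def propagate_origin(
    tissue: TrackedTissue, origin_t0: np.ndarray, k: int = 10
) -> list[np.ndarray]:
    """Track the pit origin through all frames.

    A linear displacement field is fitted to the ``k`` placodal cells
    nearest the current origin and the origin is displaced by that field
    evaluated *at* the origin, both forwards and backwards from the t = 0
    frame.  This is exact for bulk translation and, unlike the plain mean
    displacement of nearby cells, is neutral under a radially symmetric
    in-flow: the converging components cancel in the fit instead of
    advecting the origin into the pit.

    The pit is additionally the sink where tracks end, so whenever cells
    internalize close to the current estimate (track ends within two frames
    of the target frame, last centroid within two cell diameters) the origin
    is blended halfway toward their mean final position.  This anchors the
    estimate on the observable definition of the pit and keeps it unbiased
    late in invagination, when all supply arrives from one side of the pit
    and a purely kinematic tracker extrapolates off-centre.
    """
    origin_t0 = np.asarray(origin_t0, dtype=float)
    f0 = tissue.frames[tissue.t0_index]
    pts = [f0.cells[t].centroid for t in sorted(f0.placode_ids)]
    if len(pts) >= 3:
        hull = MultiPoint([tuple(p) for p in pts]).convex_hull
        if not hull.buffer(1e-9).contains(Point(origin_t0)):
            raise GeometryError("origin_t0 lies outside the placode hull at t=0")

    origins: list[np.ndarray | None] = [None] * tissue.n_frames
    origins[tissue.t0_index] = origin_t0

    last_frame: dict[int, int] = {}
    final_pos: dict[int, np.ndarray] = {}
    n_frames = tissue.n_frames
    for tid in tissue.track_ids():
        idx = tissue.presence(tid)
        if idx and idx[-1] < n_frames - 1:
            last_frame[tid] = idx[-1]
            final_pos[tid] = tissue.frames[idx[-1]].cells[tid].centroid
    mean_area = float(
        np.mean([c.area for c in tissue.frames[tissue.t0_index].cells.values()])
    )
    anchor_radius = 4.0 * np.sqrt(mean_area / np.pi)  # two cell diameters

    def _anchor(o: np.ndarray, j: int) -> np.ndarray:
        ending = [
            final_pos[t]
            for t, lf in last_frame.items()
            if abs(lf - j) <= 3 and np.linalg.norm(final_pos[t] - o) <= anchor_radius
        ]
        if not ending:
            return o
        return 0.3 * o + 0.7 * np.mean(ending, axis=0)

    def step(i_from: int, i_to: int) -> np.ndarray:
        fa, fb = tissue.frames[i_from], tissue.frames[i_to]
        common = sorted(
            (fa.placode_ids & set(fa.cells) & set(fb.cells))
        )
        if len(common) < k:
            raise GeometryError(
                f"fewer than {k} tracked placodal cells between frames {i_from} and {i_to}"
            )
        o = origins[i_from]
        dist = np.array([np.linalg.norm(fa.cells[t].centroid - o) for t in common])
        nearest = [common[j] for j in np.argsort(dist, kind="stable")[:k]]
        x0 = np.array([fa.cells[t].centroid for t in nearest])
        u = np.array([fb.cells[t].centroid - fa.cells[t].centroid for t in nearest])
        design = np.column_stack([x0 - o, np.ones(len(x0))])
        try:
            coef, *_ = np.linalg.lstsq(design, u, rcond=None)
            disp = coef[2]  # fitted displacement at the origin itself
        except np.linalg.LinAlgError:
            disp = u.mean(axis=0)
        return _anchor(o + disp, i_to)

    for i in range(tissue.t0_index, tissue.n_frames - 1):
        origins[i + 1] = step(i, i + 1)
    for i in range(tissue.t0_index, 0, -1):
        origins[i - 1] = step(i, i - 1)
    return [np.asarray(o) for o in origins]


def _placode_boundary(tissue: TrackedTissue, frame_idx: int) -> ShapelyPolygon | None:
    frame = tissue.frames[frame_idx]
    polys = [ShapelyPolygon(frame.cells[t].polygon) for t in frame.placode_ids]
    polys = [p.buffer(0) if not p.is_valid else p for p in polys]
    if not polys:
        return None
    merged = unary_union(polys)
    if merged.geom_type == "MultiPolygon":
        merged = max(merged.geoms, key=lambda g: g.area)
    return merged


def assign_radial_coordinates(
    tissue: TrackedTissue,
    origins: list[np.ndarray],
    side: str | None = None,
    posterior: np.ndarray = POSTERIOR,
) -> list[RadialFrame]:
    """Compute (r, theta, D) for every cell in every frame.

    ``theta`` is measured from the posterior direction, anti-clockwise on the
    left side and clockwise on the right, so mirrored placodes give identical
    coordinates.  ``D`` is the distance from the origin to the placode
    boundary along the cell's own ray.
    """
    side = side or tissue.side
    if side not in ("left", "right"):
        raise TissueValidationError(f"side must be left/right, got {side!r}")
    p = np.asarray(posterior, dtype=float)
    p = p / np.linalg.norm(p)
    sense = 1.0 if side == "left" else -1.0

    out: list[RadialFrame] = []
    for i, frame in enumerate(tissue.frames):
        origin = np.asarray(origins[i], dtype=float)
        boundary = _placode_boundary(tissue, i)
        ring = boundary.exterior if boundary is not None else None
        max_span = 0.0
        if ring is not None:
            coords = np.asarray(ring.coords)
            max_span = float(np.max(np.linalg.norm(coords - origin, axis=1)))
        r_map: dict[int, float] = {}
        th_map: dict[int, float] = {}
        d_map: dict[int, float] = {}
        for tid, cell in frame.cells.items():
            d = cell.centroid - origin
            r = float(np.linalg.norm(d))
            r_map[tid] = r
            if r < 1e-12:
                th_map[tid] = float("nan")
                d_map[tid] = 0.0
                continue
            u = d / r
            ang = np.arctan2(sense * (p[0] * u[1] - p[1] * u[0]), p @ u)
            th_map[tid] = float(ang % (2 * np.pi))
            dd = r
            if ring is not None:
                ray = LineString(
                    [tuple(origin), tuple(origin + u * (max_span + 1.0))]
                )
                hit = ray.intersection(ring)
                if not hit.is_empty:
                    pts = (
                        [hit]
                        if hit.geom_type == "Point"
                        else list(getattr(hit, "geoms", []))
                    )
                    dists = [
                        np.linalg.norm(np.array(pt.coords[0]) - origin)
                        for pt in pts
                        if pt.geom_type == "Point"
                    ]
                    if dists:
                        dd = float(max(dists))
            d_map[tid] = max(dd, r)
        out.append(RadialFrame(origin=origin, r=r_map, theta=th_map, D=d_map))
    return out


def assign_regions(
    rframe: RadialFrame, threshold: float = NEAR_FRACTION
) -> dict[int, str]:
    """Label cells near/far; the 33% boundary is inclusive to 'near'."""
    region = {}
    for tid, r in rframe.r.items():
        d = rframe.D[tid]
        region[tid] = "near" if (d > 0 and r <= threshold * d) or r == 0 else "far"
    rframe.region = region
    return region


def regions_at_t0(
    tissue: TrackedTissue,
    rframes: list[RadialFrame],
    threshold: float = NEAR_FRACTION,
) -> dict[int, str]:
    """Cohort labels fixed at the t = 0 frame, keyed by track id."""
    return assign_regions(rframes[tissue.t0_index], threshold)


def assign_stripes(
    tissue: TrackedTissue,
    rframes: list[RadialFrame],
    n_stripes: int = 10,
    stripe_width: float | None = None,
) -> tuple[dict[int, int], float]:
    """Radial stripe index from the t = 0 frame, retained by track id.

    Default stripes span [0, max D at t0] in ``n_stripes`` equal bins.
    Returns ``(stripes, stripe_width)``.
    """
    rf0 = rframes[tissue.t0_index]
    if not rf0.r:
        return {}, float("nan")
    if stripe_width is None:
        dmax = max(rf0.D.values())
        if dmax <= 0:
            raise GeometryError("cannot derive stripe width: all D are zero")
        stripe_width = dmax / n_stripes
    if stripe_width <= 0:
        raise GeometryError("stripe_width must be positive")
    stripes = {
        tid: min(int(np.floor(r / stripe_width)), n_stripes - 1)
        for tid, r in rf0.r.items()
    }
    rf0.stripe = stripes
    return stripes, float(stripe_width)


def stripe_kymograph(
    tissue: TrackedTissue,
    stripes: dict[int, int],
    quantity: dict[int, np.ndarray],
    n_stripes: int | None = None,
) -> np.ndarray:
    """Mean of a per-cell quantity per (t0-stripe, frame); NaN where empty.

    ``quantity`` maps track id to a series aligned with the tissue frames
    (NaN marks absence).
    """
    nf = tissue.n_frames
    for tid, series in quantity.items():
        if len(series) != nf:
            raise TissueValidationError(
                f"quantity series for track {tid} has length {len(series)} != {nf} frames"
            )
    ns = n_stripes if n_stripes is not None else (max(stripes.values()) + 1 if stripes else 0)
    mat = np.full((ns, nf), np.nan)
    for s in range(ns):
        members = [t for t, st in stripes.items() if st == s and t in quantity]
        if not members:
            continue
        for f in range(nf):
            present = [
                quantity[t][f]
                for t in members
                if t in tissue.frames[f].cells and np.isfinite(quantity[t][f])
            ]
            if present:
                mat[s, f] = float(np.mean(present))
    return mat
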