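"""Synthetic tracked placodes with full ground truth.

The generator emulates the geometry and kinematics of a ~100-cell circular
placode (radius ~47 µm) around an invagination pit, without any mechanics:
cells are Voronoi regions of seed points advected by a prescribed flow, and
their areas follow a prescribed per-cell program (each Voronoi polygon is
rescaled about its centroid to match the programmed area exactly).

Scenarios
---------
``eccentric`` / ``central`` / ``enlarged``
    Sink flow into a pit.  Inside the constriction-onset radius the radial
    inflow ``v(r) = drift + (k_area/2) r`` has divergence ``-(k_area +
    drift/r)``, so cells constrict, fastest at the pit; outside, the flow is
    incompressible (``v ~ 1/r``) so far cells drift inward at constant area
    until they cross the onset radius — the programmed behaviour switch.
    Cells whose seed enters the pit radius internalize: their area collapses
    over two frames and the track ends.
``uniform``
    Linear isotropic contraction ``v = -k x`` of points, boundary and
    tessellation alike: every strain measure equals ``-k`` exactly and there
    is no rearrangement.
``shear_rigid``
    Pure-shear point motion with rigid per-cell polygon templates:
    cell-shape strain is identically zero and all tissue strain is
    intercalation.
``static``
    Nothing moves.

Scripted T1 exchanges with controlled orientation are generated separately
on a hexagonal lattice (:func:`scripted_t1_tissue`) where adjacency is
edited explicitly, giving an exact event list as truth.

Medial-pool oscillations (short periods near the pit, long far from it,
within the 3–6 min range), junctional Fourier polarity, image background
and noise are all parameterised and recorded in the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import LineString, Point
from shapely.geometry import Polygon as ShapelyPolygon
from shapely import affinity

from .tissue_io import (
    CellState,
    FrameState,
    GeometryError,
    TrackedTissue,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_placode",
    "scripted_t1_tissue",
    "render_images",
    "ground_truth_report",
    "mirror_tissue",
]


@dataclass
class SyntheticConfig:
    seed: int = 0
    scenario: str = "eccentric"  # eccentric|central|enlarged|uniform|shear_rigid|static
    n_cells: int = 100
    R_um: float = 47.0
    # pit (sink scenarios); None -> scenario default
    pit_center: tuple[float, float] | None = None
    pit_radius: float | None = None
    # flow
    k: float = 0.01  # /min, uniform & shear scenarios
    k_area: float = 0.02  # pp/min, sink constriction rate away from the drift term
    drift: float = 0.6  # µm/min extra inward drift inside the onset radius
    onset_radius_um: float = 13.7  # near-pit constriction onset (near-region extent)
    # medial signal
    period_near_min: float = 3.5
    period_far_min: float = 5.5
    medial_amp: float = 30.0
    medial_base: float = 100.0
    trend_slope: float = 1.0  # a.u./min slow drift, removed by detrending
    signal_noise_sd: float = 1.0
    # junctional polarity (circumferentially enriched, as in the wild type)
    junctional_base: float = 150.0
    uni_amp: float = 0.1
    bi_amp: float = 0.3
    # imaging
    background: float = 20.0
    image_noise_sd: float = 2.0
    px_um: float = 0.22
    edge_halfwidth_px: int = 2
    # sampling
    dt_min: float = 1.0
    t_start_min: float = -40.0
    t_end_min: float = 70.0
    side: str = "left"

    def validate(self) -> None:
        if self.dt_min <= 0 or self.t_end_min <= self.t_start_min:
            raise GeometryError("invalid sampling parameters")
        if self.n_cells < 4 or self.R_um <= 0:
            raise GeometryError("need n_cells >= 4 and R_um > 0")
        for name in ("period_near_min", "period_far_min", "px_um"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")

    def resolved_pit(self) -> tuple[np.ndarray, float]:
        u = np.array([1.0, 1.0]) / np.sqrt(2.0)  # dorsal-posterior direction
        defaults = {
            "eccentric": (0.68 * self.R_um * u, 5.0),
            "central": (np.zeros(2), 5.0),
            "enlarged": (0.34 * self.R_um * u, 18.0),
        }
        center, radius = defaults.get(self.scenario, (np.zeros(2), 0.0))
        if self.pit_center is not None:
            center = np.asarray(self.pit_center, dtype=float)
        if self.pit_radius is not None:
            radius = float(self.pit_radius)
        return center, radius


@dataclass
class GroundTruth:
    config: SyntheticConfig
    pit_center: np.ndarray
    pit_radius: float
    onset_frame: dict[int, int] = field(default_factory=dict)  # far->near crossing
    internalization_frame: dict[int, int] = field(default_factory=dict)
    area_rate: dict[int, np.ndarray] = field(default_factory=dict)  # programmed, /min
    medial_signal: dict[int, np.ndarray] = field(default_factory=dict)
    period_min: dict[int, float] = field(default_factory=dict)
    amp: dict[int, float] = field(default_factory=dict)
    region_t0: dict[int, str] = field(default_factory=dict)
    uni_phase: dict[int, float] = field(default_factory=dict)
    bi_phase: dict[int, float] = field(default_factory=dict)
    t1_events: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# tessellation helpers
# ---------------------------------------------------------------------------


def _disk(R: float) -> ShapelyPolygon:
    return Point(0.0, 0.0).buffer(R, quad_segs=64)


def _clipped_voronoi(
    points: np.ndarray, R: float
) -> tuple[dict[int, ShapelyPolygon], list[tuple[int, int, float]]]:
    """Voronoi cells of ``points`` clipped to the disk of radius R.

    A ring of ghost points keeps all real regions bounded.  Returns the
    per-point polygons and the ridge adjacency ``(i, j, shared length)``.
    """
    n = len(points)
    spacing = R / max(np.sqrt(n), 1.0)
    n_ghost = 72
    ang = np.linspace(0, 2 * np.pi, n_ghost, endpoint=False)
    ghosts = (R + 2.5 * spacing) * np.column_stack([np.cos(ang), np.sin(ang)])
    vor = Voronoi(np.vstack([points, ghosts]))
    disk = _disk(R)

    polys: dict[int, ShapelyPolygon] = {}
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:
            continue
        poly = ShapelyPolygon(vor.vertices[region]).intersection(disk)
        if poly.geom_type == "Polygon" and poly.area > 0:
            polys[i] = poly

    adjacency: list[tuple[int, int, float]] = []
    for (p, q), rv in zip(vor.ridge_points, vor.ridge_vertices):
        if p >= n or q >= n or -1 in rv:
            continue
        seg = LineString(vor.vertices[rv]).intersection(disk)
        if seg.length > 0.05:
            adjacency.append((min(p, q), max(p, q), float(seg.length)))
    return polys, adjacency


def _lloyd_points(rng: np.random.Generator, n: int, R: float, iters: int = 3) -> np.ndarray:
    r = R * np.sqrt(rng.uniform(0, 1, n)) * 0.98
    a = rng.uniform(0, 2 * np.pi, n)
    pts = np.column_stack([r * np.cos(a), r * np.sin(a)])
    for _ in range(iters):
        polys, _ = _clipped_voronoi(pts, R)
        for i, poly in polys.items():
            c = poly.centroid
            pts[i] = (c.x, c.y)
    return pts


def _scale_to_area(poly: ShapelyPolygon, target: float) -> ShapelyPolygon:
    f = np.sqrt(target / poly.area)
    c = poly.centroid
    return affinity.scale(poly, xfact=f, yfact=f, origin=(c.x, c.y))


def _cellstate(poly: ShapelyPolygon) -> CellState:
    coords = np.asarray(poly.exterior.coords)[:-1]
    return CellState.from_polygon(coords)


# ---------------------------------------------------------------------------
# flows
# ---------------------------------------------------------------------------


def _sink_velocity(
    pos: np.ndarray, pit: np.ndarray, cfg: SyntheticConfig
) -> np.ndarray:
    """Inward radial flow: constricting inside the onset radius,
    incompressible (1/r) outside."""
    rel = pos - pit
    r = np.linalg.norm(rel, axis=1)
    r_safe = np.maximum(r, 1e-9)
    u = rel / r_safe[:, None]
    r_on = cfg.onset_radius_um
    v_on = cfg.drift + 0.5 * cfg.k_area * r_on
    speed = np.where(
        r <= r_on,
        cfg.drift + 0.5 * cfg.k_area * r_safe,
        v_on * r_on / r_safe,
    )
    return -u * speed[:, None]


def _programmed_rate(r: float, cfg: SyntheticConfig) -> float:
    if r <= cfg.onset_radius_um:
        return -(cfg.k_area + cfg.drift / max(r, 1.0))
    return 0.0


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


def generate_placode(cfg: SyntheticConfig) -> tuple[TrackedTissue, GroundTruth]:
    """Generate a synthetic tracked placode and its ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    nf = int(round((cfg.t_end_min - cfg.t_start_min) / cfg.dt_min)) + 1
    times = cfg.t_start_min + cfg.dt_min * np.arange(nf)
    t0_index = int(np.argmin(np.abs(times)))
    pit, pit_radius = cfg.resolved_pit()

    sink = cfg.scenario in ("eccentric", "central", "enlarged")
    # R_um is the placode extent at t = 0; for sink scenarios the tissue is
    # seeded larger at t_start so that the incompressible far-field inflow
    # (flux 2*pi*v_on*r_on, which internalizes roughly one cell per
    # mean-area/flux minutes) has contracted it to R_um by t = 0.
    R_seed = cfg.R_um
    if sink and cfg.t_start_min < 0:
        v_on = cfg.drift + 0.5 * cfg.k_area * cfg.onset_radius_um
        q = v_on * cfg.onset_radius_um
        R_seed = float(np.sqrt(cfg.R_um**2 + 2.0 * q * abs(cfg.t_start_min)))
    pts = _lloyd_points(rng, cfg.n_cells, R_seed)
    gt = GroundTruth(config=cfg, pit_center=pit, pit_radius=pit_radius)
    alive = np.ones(cfg.n_cells, dtype=bool)
    stage = np.zeros(cfg.n_cells, dtype=int)  # internalization countdown
    area_target = np.full(cfg.n_cells, np.nan)
    templates: dict[int, ShapelyPolygon] = {}
    for tid in range(cfg.n_cells):
        gt.area_rate[tid] = np.full(nf, np.nan)

    frames: list[FrameState] = []
    R_t = R_seed
    positions = pts.copy()
    for fi in range(nf):
        ids = np.nonzero(alive)[0]
        if len(ids) < 4:
            raise GeometryError("too few cells left to tessellate")
        polys, adj = _clipped_voronoi(positions[ids], R_t)
        id_of = {local: int(ids[local]) for local in range(len(ids))}

        cells: dict[int, CellState] = {}
        boundary_ids: set[int] = set()
        disk_ring = _disk(R_t).exterior
        for local, poly in polys.items():
            tid = id_of[local]
            if np.isnan(area_target[tid]):
                area_target[tid] = poly.area
            if cfg.scenario == "shear_rigid":
                if tid not in templates:
                    templates[tid] = poly
                c0 = templates[tid].centroid
                shaped = affinity.translate(
                    templates[tid],
                    xoff=positions[tid, 0] - c0.x,
                    yoff=positions[tid, 1] - c0.y,
                )
            elif sink:
                shaped = _scale_to_area(poly, area_target[tid])
            else:
                shaped = poly
            cells[tid] = _cellstate(shaped)
            if poly.exterior.distance(disk_ring) < 1e-6 or poly.intersects(disk_ring):
                boundary_ids.add(tid)

        adjacency = {
            (id_of[i], id_of[j]) if id_of[i] < id_of[j] else (id_of[j], id_of[i]): l
            for i, j, l in adj
            if id_of[i] in cells and id_of[j] in cells
        }
        frames.append(
            FrameState(
                t_min=float(times[fi]),
                cells=cells,
                adjacency=adjacency,
                placode_ids=set(cells),
                boundary_ids=boundary_ids,
            )
        )

        if fi == nf - 1:
            break

        # advance state to the next frame
        if cfg.scenario == "uniform":
            f = np.exp(-cfg.k * cfg.dt_min)
            positions = positions * f
            R_t *= f
        elif cfg.scenario == "shear_rigid":
            # v = (k*y, k*x): symmetric pure shear, principal rates +/- k
            dx = cfg.k * positions[:, 1] * cfg.dt_min
            dy = cfg.k * positions[:, 0] * cfg.dt_min
            positions = positions + np.column_stack([dx, dy])
        elif sink:
            vel = _sink_velocity(positions[ids], pit, cfg)
            positions[ids] += vel * cfg.dt_min
            for tid in ids:
                r = float(np.linalg.norm(positions[tid] - pit))
                rate = _programmed_rate(r, cfg)
                if stage[tid] == 0 and r < pit_radius:
                    stage[tid] = 1
                    gt.internalization_frame[tid] = fi + 1
                if stage[tid] > 0:
                    area_target[tid] *= 0.3
                    stage[tid] += 1
                    gt.area_rate[tid][fi] = np.nan
                    if stage[tid] > 2:
                        alive[tid] = False
                else:
                    if rate < 0 and tid not in gt.onset_frame:
                        gt.onset_frame[tid] = fi + 1
                    area_target[tid] *= np.exp(rate * cfg.dt_min)
                    gt.area_rate[tid][fi] = rate
        # static: nothing to do

    tissue = TrackedTissue(
        frames=frames,
        dt_min=cfg.dt_min,
        px_um=cfg.px_um,
        side=cfg.side,
        t0_index=t0_index,
    )
    tissue.validate()
    _attach_signals(tissue, gt, rng)
    return tissue, gt


def _attach_signals(
    tissue: TrackedTissue, gt: GroundTruth, rng: np.random.Generator
) -> None:
    cfg = gt.config
    nf = tissue.n_frames
    times = tissue.times
    f0 = tissue.frames[tissue.t0_index]
    for tid in sorted(tissue.track_ids()):
        if tid in f0.cells:
            r0 = float(np.linalg.norm(f0.cells[tid].centroid - gt.pit_center))
        else:
            r0 = np.inf
        near = r0 <= cfg.onset_radius_um
        gt.region_t0[tid] = "near" if near else "far"
        period = cfg.period_near_min if near else cfg.period_far_min
        phase = rng.uniform(0, 2 * np.pi)
        series = (
            cfg.medial_base
            + cfg.trend_slope * times
            + cfg.medial_amp * np.sin(2 * np.pi * times / period + phase)
        )
        if cfg.signal_noise_sd > 0:
            series = series + rng.normal(0, cfg.signal_noise_sd, nf)
        present = np.array([tid in f.cells for f in tissue.frames])
        series = np.where(present, series, np.nan)
        gt.medial_signal[tid] = series
        gt.period_min[tid] = period
        gt.amp[tid] = cfg.medial_amp
        # circumferential junctional enrichment: bipolar axis along the
        # circumferential direction, unipolar vector pointing at the pit
        if tid in f0.cells and r0 > 1e-9:
            u = (f0.cells[tid].centroid - gt.pit_center) / r0
            radial_ang = float(np.arctan2(u[1], u[0]))
            gt.uni_phase[tid] = (radial_ang + np.pi) % (2 * np.pi)
            gt.bi_phase[tid] = (radial_ang + np.pi / 2) % np.pi
        else:
            gt.uni_phase[tid] = 0.0
            gt.bi_phase[tid] = 0.0


# ---------------------------------------------------------------------------
# scripted T1 exchanges on a hexagonal lattice
# ---------------------------------------------------------------------------


def scripted_t1_tissue(
    n_events: int = 50,
    n_reversals: int = 5,
    seed: int = 0,
    dt_min: float = 1.0,
    d_um: float = 3.0,
    circumferential_bias: float = 1.0,
) -> tuple[TrackedTissue, GroundTruth]:
    """Static hexagonal lattice with explicitly scripted neighbor exchanges.

    Each exchange flips the diagonal of a distinct quartet at a scheduled
    frame; ``n_reversals`` of them are reverted two frames later (two truth
    events each, with roles swapped).  ``circumferential_bias`` is the
    probability that a scripted quartet is chosen with its gain axis clearly
    circumferential about the lattice centre (the rest are radial).  Gained
    adjacency persists for at least two frames so detection hysteresis never
    hides a scripted event.
    """
    rng = np.random.default_rng(seed)
    # lattice big enough for disjoint quartets
    R = d_um * (int(np.ceil(np.sqrt(n_events) * 3.0)) + 6)
    pts = []
    m = int(np.ceil(R / d_um)) + 2
    for j in range(-m, m + 1):
        y = j * d_um * np.sqrt(3) / 2
        for i in range(-m, m + 1):
            x = (i + 0.5 * (j % 2)) * d_um
            if x * x + y * y <= R * R:
                pts.append((x, y))
    pts = np.array(pts)
    n = len(pts)
    polys, adj = _clipped_voronoi(pts, R + d_um)
    cells = {i: _cellstate(polys[i]) for i in sorted(polys)}
    base_adj = {
        (min(i, j), max(i, j)): l for i, j, l in adj if i in cells and j in cells
    }

    neigh: dict[int, set[int]] = {i: set() for i in cells}
    for a, b in base_adj:
        neigh[a].add(b)
        neigh[b].add(a)

    # choose disjoint quartets with the requested orientation mix
    used: set[int] = set()
    quartets: list[tuple[tuple[int, int], tuple[int, int]]] = []
    order = rng.permutation(sorted(cells))
    for a in order:
        if len(quartets) >= n_events:
            break
        if a in used:
            continue
        for b in sorted(neigh[a]):
            if b in used or (a, b) in [q[0] for q in quartets]:
                continue
            common = sorted((neigh[a] & neigh[b]) - used - {a, b})
            if len(common) < 2:
                continue
            c, d = common[0], common[1]
            quartet = {int(a), int(b), int(c), int(d)}
            if quartet & used:
                continue
            # orientation of the would-be gain axis about the lattice centre
            mid = 0.25 * sum((cells[i].centroid for i in quartet), np.zeros(2))
            rmid = np.linalg.norm(mid)
            if rmid < 2 * d_um:
                continue  # too close to the centre: orientation ill-defined
            axis = cells[d].centroid - cells[c].centroid
            axis = axis / np.linalg.norm(axis)
            u_c = np.array([-mid[1], mid[0]]) / rmid
            align = abs(float(axis @ u_c))
            want_circ = rng.uniform() < circumferential_bias
            is_clear_circ = align > np.cos(np.deg2rad(30))
            is_clear_rad = align < np.cos(np.deg2rad(60))
            if (want_circ and is_clear_circ) or (not want_circ and is_clear_rad):
                quartets.append(((int(a), int(b)), (int(c), int(d))))
                used |= quartet
                break
    if len(quartets) < n_events:
        raise GeometryError(
            f"could only place {len(quartets)} of {n_events} scripted exchanges"
        )

    nf = max(12, n_events // 4 + 10)
    t0_index = 2
    # schedule gains on frames 2..nf-4
    gain_frames = rng.integers(2, nf - 4, size=n_events)
    reversed_idx = set(rng.choice(n_events, size=n_reversals, replace=False).tolist())

    overrides: list[dict] = []
    gt_events: list[dict] = []
    for k, ((a, b), (c, d)) in enumerate(quartets):
        tg = int(gain_frames[k])
        overrides.append({"t": tg, "lost": (a, b), "gained": (c, d)})
        gt_events.append(
            {"t_gain": tg, "lost_a": a, "lost_b": b, "gained_a": c, "gained_b": d}
        )
        if k in reversed_idx:
            overrides.append({"t": tg + 2, "lost": (c, d), "gained": (a, b)})
            gt_events.append(
                {
                    "t_gain": tg + 2,
                    "lost_a": c,
                    "lost_b": d,
                    "gained_a": a,
                    "gained_b": b,
                }
            )

    frames: list[FrameState] = []
    current = dict(base_adj)
    per_frame_adj: list[dict] = []
    for fi in range(nf):
        for ov in overrides:
            if ov["t"] == fi:
                lp = (min(ov["lost"]), max(ov["lost"]))
                gp = (min(ov["gained"]), max(ov["gained"]))
                current.pop(lp, None)
                current[gp] = 0.5
        per_frame_adj.append(dict(current))

    for fi in range(nf):
        frames.append(
            FrameState(
                t_min=(fi - t0_index) * dt_min,
                cells=dict(cells),
                adjacency=per_frame_adj[fi],
                placode_ids=set(cells),
                boundary_ids=set(),
            )
        )
    tissue = TrackedTissue(
        frames=frames, dt_min=dt_min, px_um=None, side="left", t0_index=t0_index
    )
    tissue.validate()
    cfg = SyntheticConfig(seed=seed, scenario="static", n_cells=n)
    gt = GroundTruth(config=cfg, pit_center=np.zeros(2), pit_radius=0.0)
    gt.t1_events = gt_events
    return tissue, gt


# ---------------------------------------------------------------------------
# rendering & reports
# ---------------------------------------------------------------------------


def render_images(
    tissue: TrackedTissue, cfg: SyntheticConfig, gt: GroundTruth
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rasterize the tissue into label and intensity stacks.

    Returns ``(labels, intensity, offset_um)``: labels are uint16 pages, one
    per frame, with pixel value ``track_id + 1`` (0 is background); intensity
    is float32 with medial oscillation values inside cells, junctional
    Fourier-mode values on the edge band, plus constant background and
    Gaussian noise.  ``offset_um`` maps tissue to image coordinates:
    ``(row, col) = ((y - offset[1])/px, (x - offset[0])/px)``.
    """
    from skimage.draw import polygon as draw_polygon
    from scipy import ndimage

    px = cfg.px_um
    rng = np.random.default_rng(cfg.seed + 1)
    all_xy = np.vstack(
        [c.polygon for f in tissue.frames for c in f.cells.values()]
    )
    lo = all_xy.min(axis=0) - 4 * px
    hi = all_xy.max(axis=0) + 4 * px
    offset = lo
    w = int(np.ceil((hi[0] - lo[0]) / px)) + 1
    h = int(np.ceil((hi[1] - lo[1]) / px)) + 1

    labels = np.zeros((tissue.n_frames, h, w), dtype=np.uint16)
    intensity = np.full((tissue.n_frames, h, w), cfg.background, dtype=np.float64)

    for fi, frame in enumerate(tissue.frames):
        page = labels[fi]
        img = intensity[fi]
        for tid in sorted(frame.cells):
            cell = frame.cells[tid]
            if np.sqrt(cell.area) / px < 3:
                raise GeometryError(
                    f"cell {tid} smaller than 3 px across at px_um={px}"
                )
            poly = (cell.polygon - offset) / px
            rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=page.shape)
            if len(rr) == 0:
                continue
            page[rr, cc] = tid + 1
        for tid in sorted(frame.cells):
            mask = page == tid + 1
            if not mask.any():
                continue
            dist = ndimage.distance_transform_edt(mask)
            junctional = mask & (dist <= 1 + cfg.edge_halfwidth_px)
            medial = mask & ~junctional
            med_val = gt.medial_signal.get(tid, np.full(tissue.n_frames, np.nan))[fi]
            if np.isfinite(med_val):
                img[medial] += max(med_val, 0.0)
            cent = (frame.cells[tid].centroid - offset) / px
            rows, cols = np.nonzero(junctional)
            theta = np.arctan2(rows - cent[1], cols - cent[0])
            uni = cfg.uni_amp * np.cos(theta - gt.uni_phase.get(tid, 0.0))
            bi = cfg.bi_amp * np.cos(2 * (theta - gt.bi_phase.get(tid, 0.0)))
            img[rows, cols] += cfg.junctional_base * (1.0 + uni + bi)
        if cfg.image_noise_sd > 0:
            img += rng.normal(0, cfg.image_noise_sd, img.shape)
    return labels, intensity.astype(np.float32), np.asarray(offset)


def ground_truth_report(gt: GroundTruth, out_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Machine-readable truth tables, keyed like the pipeline outputs."""
    ids = sorted(gt.medial_signal) if gt.medial_signal else sorted(gt.area_rate)
    cells = pd.DataFrame(
        {
            "track_id": ids,
            "region_t0": [gt.region_t0.get(t, "") for t in ids],
            "onset_frame": [gt.onset_frame.get(t, -1) for t in ids],
            "internalization_frame": [gt.internalization_frame.get(t, -1) for t in ids],
            "period_min": [gt.period_min.get(t, np.nan) for t in ids],
            "amp": [gt.amp.get(t, np.nan) for t in ids],
            "uni_phase": [gt.uni_phase.get(t, np.nan) for t in ids],
            "bi_phase": [gt.bi_phase.get(t, np.nan) for t in ids],
        }
    )
    t1 = pd.DataFrame(
        gt.t1_events,
        columns=["t_gain", "lost_a", "lost_b", "gained_a", "gained_b"],
    )
    rates_rows = []
    for tid in sorted(gt.area_rate):
        for fi, r in enumerate(gt.area_rate[tid]):
            if np.isfinite(r):
                rates_rows.append({"track_id": tid, "frame": fi, "area_rate": r})
    rates = pd.DataFrame(rates_rows, columns=["track_id", "frame", "area_rate"])
    tables = {"cells": cells, "t1_events": t1, "area_rates": rates}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"truth_{name}.csv", index=False)
    return tables


def mirror_tissue(tissue: TrackedTissue) -> TrackedTissue:
    """Mirror a tissue about the AP axis (y -> -y) and flip its side label."""
    frames = []
    for f in tissue.frames:
        cells = {}
        for tid, c in f.cells.items():
            poly = c.polygon.copy()
            poly[:, 1] *= -1
            cells[tid] = CellState.from_polygon(poly)
        frames.append(
            FrameState(
                t_min=f.t_min,
                cells=cells,
                adjacency=dict(f.adjacency),
                placode_ids=set(f.placode_ids),
                boundary_ids=set(f.boundary_ids),
            )
        )
    return TrackedTissue(
        frames=frames,
        dt_min=tissue.dt_min,
        px_um=tissue.px_um,
        side="right" if tissue.side == "left" else "left",
        t0_index=tissue.t0_index,
    )
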