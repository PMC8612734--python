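"""Tracked-tissue data model, interchange format and label-stack ingestion.

A *tracked tissue* is an ordered list of frames; each frame holds the apical
polygon of every cell present, keyed by a persistent track id, together with
the cell-cell adjacency graph (with shared-interface lengths), the subset of
cells belonging to the placode, and the subset sitting on the supracellular
actomyosin cable at the placode boundary.  Time ``t = 0 min`` is the frame
just before the first sign of tissue bending.

The interchange format is deliberately plain: a JSON header plus per-frame
CSV tables of cell polygons, one adjacency table and one membership table.
It round-trips bit-exactly (floats are written with ``repr``).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Polygon as ShapelyPolygon
from shapely.geometry.polygon import orient

from .geometry import ensure_ccw, moments_ellipse, polygon_area, polygon_centroid

__all__ = [
    "CellState",
    "FrameState",
    "TrackedTissue",
    "QualityFilterConfig",
    "FormatError",
    "TissueValidationError",
    "ConfigError",
    "GeometryError",
    "read_tracked_tissue",
    "write_tracked_tissue",
    "ingest_label_stack",
    "apply_quality_filters",
]


class FormatError(ValueError):
    """Raised when an interchange bundle is missing files or malformed."""


class TissueValidationError(ValueError):
    """Raised when a tissue violates a structural invariant."""


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


class GeometryError(ValueError):
    """Raised when a geometric construction is impossible."""


@dataclass
class CellState:
    """One cell in one frame: apical polygon plus derived shape summaries.

    ``polygon`` is an (N, 2) float array of µm vertices, counter-clockwise,
    closing vertex not repeated.  ``ellipse`` is the equivalent-moment
    ellipse ``(major, minor, phi)`` with *semi*-axes in µm.
    """

    polygon: np.ndarray
    centroid: np.ndarray
    area: float
    ellipse: tuple[float, float, float]

    @classmethod
    def from_polygon(cls, polygon: np.ndarray) -> "CellState":
        poly = ensure_ccw(np.asarray(polygon, dtype=float))
        return cls(
            polygon=poly,
            centroid=polygon_centroid(poly),
            area=polygon_area(poly),
            ellipse=moments_ellipse(poly),
        )

    def validate(self) -> None:
        if self.area <= 0:
            raise TissueValidationError(f"cell area must be positive, got {self.area}")
        if abs(self.area - polygon_area(self.polygon)) > 1e-6:
            raise TissueValidationError("stored area disagrees with polygon area")
        major, minor, _ = self.ellipse
        if not (major >= minor > 0):
            raise TissueValidationError(f"degenerate ellipse axes ({major}, {minor})")
        if not ShapelyPolygon(self.polygon).is_simple:
            raise TissueValidationError("polygon is self-intersecting")


@dataclass
class FrameState:
    t_min: float
    cells: dict[int, CellState]
    adjacency: dict[tuple[int, int], float] = field(default_factory=dict)
    placode_ids: set[int] = field(default_factory=set)
    boundary_ids: set[int] = field(default_factory=set)

    def validate(self) -> None:
        for (a, b), length in self.adjacency.items():
            if a not in self.cells or b not in self.cells:
                raise TissueValidationError(f"adjacency pair ({a}, {b}) references missing cell")
            if length <= 0:
                raise TissueValidationError(f"shared-interface length must be > 0 for ({a}, {b})")
        if not self.placode_ids <= set(self.cells):
            raise TissueValidationError("placode_ids not a subset of cell ids")
        for cell in self.cells.values():
            cell.validate()

    def neighbors(self, track_id: int) -> set[int]:
        out = set()
        for a, b in self.adjacency:
            if a == track_id:
                out.add(b)
            elif b == track_id:
                out.add(a)
        return out


def _norm_pair(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


@dataclass
class TrackedTissue:
    frames: list[FrameState]
    dt_min: float
    px_um: float | None
    side: str
    t0_index: int

    def validate(self) -> None:
        if self.side not in ("left", "right"):
            raise TissueValidationError(f"side must be left/right, got {self.side!r}")
        if not (0 <= self.t0_index < len(self.frames)):
            raise TissueValidationError("t0_index out of range")
        times = [f.t_min for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise TissueValidationError("timestamps must be strictly increasing")
        for f in self.frames:
            f.validate()

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.t_min for f in self.frames])

    def track_ids(self) -> set[int]:
        ids: set[int] = set()
        for f in self.frames:
            ids |= set(f.cells)
        return ids

    def presence(self, track_id: int) -> list[int]:
        """Frame indices at which a track is present."""
        return [i for i, f in enumerate(self.frames) if track_id in f.cells]

    def area_series(self, track_id: int) -> tuple[np.ndarray, np.ndarray]:
        idx = self.presence(track_id)
        t = np.array([self.frames[i].t_min for i in idx])
        a = np.array([self.frames[i].cells[track_id].area for i in idx])
        return t, a


@dataclass
class QualityFilterConfig:
    """Track quality criteria: lineage length, area, aspect ratio, velocity.

    Velocity is measured relative to the mean per-frame displacement of all
    cells, so a rigid drift of the whole field of view is not penalised.
    """

    min_lineage_len: int = 3
    area_range: tuple[float, float] = (1.0, 200.0)
    max_aspect: float = 8.0
    max_rel_velocity: float = 10.0

    def validate(self) -> None:
        if self.min_lineage_len <= 0 or self.max_aspect <= 0 or self.max_rel_velocity <= 0:
            raise ConfigError("quality-filter bounds must be positive")
        lo, hi = self.area_range
        if not (0 < lo < hi):
            raise ConfigError(f"area_range must satisfy 0 < low < high, got {self.area_range}")


# ---------------------------------------------------------------------------
# interchange format
# ---------------------------------------------------------------------------

_CELL_COLUMNS = [
    "track_id",
    "centroid_x",
    "centroid_y",
    "area",
    "ellipse_major",
    "ellipse_minor",
    "ellipse_phi",
    "vertices",
]


def _fmt(x: float) -> str:
    return repr(float(x))


def _encode_vertices(poly: np.ndarray) -> str:
    return ";".join(f"{_fmt(x)} {_fmt(y)}" for x, y in poly)


def _decode_vertices(s: str) -> np.ndarray:
    pts = [tuple(float(v) for v in p.split()) for p in s.split(";")]
    return np.array(pts, dtype=float)


def write_tracked_tissue(tissue: TrackedTissue, path: str | Path) -> Path:
    """Write a tissue as an interchange bundle (JSON header + CSV tables)."""
    tissue.validate()
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    header = {
        "dt_min": tissue.dt_min,
        "px_um": tissue.px_um,
        "side": tissue.side,
        "t0_index": tissue.t0_index,
        "n_frames": tissue.n_frames,
        "t_min": [f.t_min for f in tissue.frames],
    }
    (root / "header.json").write_text(json.dumps(header, indent=2, sort_keys=True) + "\n")

    for i, frame in enumerate(tissue.frames):
        with open(root / f"cells_{i:04d}.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(_CELL_COLUMNS)
            for tid in sorted(frame.cells):
                c = frame.cells[tid]
                w.writerow(
                    [
                        tid,
                        _fmt(c.centroid[0]),
                        _fmt(c.centroid[1]),
                        _fmt(c.area),
                        _fmt(c.ellipse[0]),
                        _fmt(c.ellipse[1]),
                        _fmt(c.ellipse[2]),
                        _encode_vertices(c.polygon),
                    ]
                )

    with open(root / "adjacency.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "track_a", "track_b", "shared_length_um"])
        for i, frame in enumerate(tissue.frames):
            for (a, b) in sorted(frame.adjacency):
                w.writerow([i, a, b, _fmt(frame.adjacency[(a, b)])])

    with open(root / "membership.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "track_id", "in_placode", "on_boundary"])
        for i, frame in enumerate(tissue.frames):
            for tid in sorted(frame.cells):
                w.writerow(
                    [i, tid, int(tid in frame.placode_ids), int(tid in frame.boundary_ids)]
                )
    return root


def read_tracked_tissue(path: str | Path) -> TrackedTissue:
    """Read an interchange bundle written by :func:`write_tracked_tissue`."""
    root = Path(path)
    header_path = root / "header.json"
    if not header_path.exists():
        raise FormatError(f"missing header.json in {root}")
    header = json.loads(header_path.read_text())
    n_frames = int(header["n_frames"])
    times = header["t_min"]

    frames: list[FrameState] = []
    for i in range(n_frames):
        fpath = root / f"cells_{i:04d}.csv"
        if not fpath.exists():
            raise FormatError(f"missing frame file cells_{i:04d}.csv in {root}")
        cells: dict[int, CellState] = {}
        with open(fpath, newline="") as fh:
            for row in csv.DictReader(fh):
                tid = int(row["track_id"])
                if tid in cells:
                    raise TissueValidationError(
                        f"duplicated track id {tid} in frame {i}"
                    )
                cells[tid] = CellState(
                    polygon=_decode_vertices(row["vertices"]),
                    centroid=np.array(
                        [float(row["centroid_x"]), float(row["centroid_y"])]
                    ),
                    area=float(row["area"]),
                    ellipse=(
                        float(row["ellipse_major"]),
                        float(row["ellipse_minor"]),
                        float(row["ellipse_phi"]),
                    ),
                )
        frames.append(FrameState(t_min=float(times[i]), cells=cells))

    adj_path = root / "adjacency.csv"
    if adj_path.exists():
        with open(adj_path, newline="") as fh:
            for row in csv.DictReader(fh):
                i = int(row["frame"])
                pair = _norm_pair(int(row["track_a"]), int(row["track_b"]))
                frames[i].adjacency[pair] = float(row["shared_length_um"])

    mem_path = root / "membership.csv"
    if mem_path.exists():
        with open(mem_path, newline="") as fh:
            for row in csv.DictReader(fh):
                i = int(row["frame"])
                tid = int(row["track_id"])
                if int(row["in_placode"]):
                    frames[i].placode_ids.add(tid)
                if int(row["on_boundary"]):
                    frames[i].boundary_ids.add(tid)

    tissue = TrackedTissue(
        frames=frames,
        dt_min=float(header["dt_min"]),
        px_um=None if header["px_um"] is None else float(header["px_um"]),
        side=str(header["side"]),
        t0_index=int(header["t0_index"]),
    )
    tissue.validate()
    return tissue


# ---------------------------------------------------------------------------
# label-stack ingestion
# ---------------------------------------------------------------------------


def _pixel_polygon(mask: np.ndarray, px_um: float) -> np.ndarray:
    """Trace the outer boundary of a pixel region as a µm polygon.

    The polygon is the boundary of the union of pixel squares (pixel-centre
    convention: pixel (row, col) is the square centred at
    ``(col*px_um, row*px_um)``), so its area equals the pixel count times
    ``px_um**2`` exactly.
    """
    rows, cols = np.nonzero(mask)
    # exact half-integer bounds in pixel units, scaled to µm afterwards
    boxes = shapely.box(cols - 0.5, rows - 0.5, cols + 0.5, rows + 0.5)
    merged = shapely.union_all(boxes)
    if merged.geom_type != "Polygon":
        raise TissueValidationError("pixel region does not merge into a single polygon")
    merged = orient(merged.simplify(0), sign=1.0)
    coords = np.asarray(merged.exterior.coords)[:-1] * px_um
    return coords


def ingest_label_stack(
    labels: str | Path | np.ndarray,
    px_um: float,
    dt_min: float,
    side: str = "left",
    min_shared_px: int = 2,
    t0_index: int = 0,
) -> TrackedTissue:
    """Build a TrackedTissue from a multi-page label image stack.

    The same nonzero label id must denote the same cell across pages;
    background is 0.  Adjacency requires at least ``min_shared_px`` shared
    boundary pixels (suppresses four-fold-vertex false contacts).
    """
    if isinstance(labels, (str, Path)):
        import tifffile

        stack = tifffile.imread(str(labels))
    else:
        stack = np.asarray(labels)
    if stack.ndim == 2:
        stack = stack[None]

    from skimage.measure import label as cc_label

    frames: list[FrameState] = []
    for page_idx, page in enumerate(stack):
        cells: dict[int, CellState] = {}
        boundary_ids: set[int] = set()
        for lab in np.unique(page):
            if lab == 0:
                continue
            mask = page == lab
            if cc_label(mask, connectivity=1).max() != 1:
                raise TissueValidationError(
                    f"label {int(lab)} in page {page_idx} is not contiguous"
                )
            poly = _pixel_polygon(mask, px_um)
            cells[int(lab)] = CellState.from_polygon(poly)
            padded = np.pad(page, 1)
            touches_bg = mask & (
                (padded[:-2, 1:-1] == 0)
                | (padded[2:, 1:-1] == 0)
                | (padded[1:-1, :-2] == 0)
                | (padded[1:-1, 2:] == 0)
            )
            if touches_bg.any():
                boundary_ids.add(int(lab))

        adjacency: dict[tuple[int, int], int] = {}
        for a, b in [(page[:, :-1], page[:, 1:]), (page[:-1, :], page[1:, :])]:
            diff = (a != b) & (a > 0) & (b > 0)
            for la, lb in zip(a[diff].ravel(), b[diff].ravel()):
                pair = _norm_pair(int(la), int(lb))
                adjacency[pair] = adjacency.get(pair, 0) + 1
        adjacency_um = {
            pair: n * px_um for pair, n in adjacency.items() if n >= min_shared_px
        }
        frames.append(
            FrameState(
                t_min=(page_idx - t0_index) * dt_min,
                cells=cells,
                adjacency=adjacency_um,
                placode_ids=set(cells),
                boundary_ids=boundary_ids,
            )
        )

    tissue = TrackedTissue(
        frames=frames, dt_min=dt_min, px_um=px_um, side=side, t0_index=t0_index
    )
    tissue.validate()
    return tissue


# ---------------------------------------------------------------------------
# quality filters
# ---------------------------------------------------------------------------


def apply_quality_filters(
    tissue: TrackedTissue, cfg: QualityFilterConfig | None = None
) -> tuple[TrackedTissue, list[tuple[int, str]]]:
    """Remove badly tracked cells (whole tracks) from every frame.

    Criteria, in order of checking: lineage length, area range, aspect
    ratio, relative velocity.  Returns the filtered tissue and a report of
    ``(track_id, reason)`` for every removed track.
    """
    cfg = cfg or QualityFilterConfig()
    cfg.validate()

    report: list[tuple[int, str]] = []
    lo, hi = cfg.area_range

    # mean displacement per consecutive-frame pair over co-present cells
    mean_disp: list[np.ndarray] = []
    for f0, f1 in zip(tissue.frames, tissue.frames[1:]):
        common = set(f0.cells) & set(f1.cells)
        if common:
            d = np.mean(
                [f1.cells[t].centroid - f0.cells[t].centroid for t in sorted(common)],
                axis=0,
            )
        else:
            d = np.zeros(2)
        mean_disp.append(d)

    for tid in sorted(tissue.track_ids()):
        idx = tissue.presence(tid)
        if len(idx) < cfg.min_lineage_len:
            report.append((tid, "lineage"))
            continue
        states = [tissue.frames[i].cells[tid] for i in idx]
        if any(not (lo <= s.area <= hi) for s in states):
            report.append((tid, "area"))
            continue
        if any(s.ellipse[0] / max(s.ellipse[1], 1e-12) > cfg.max_aspect for s in states):
            report.append((tid, "aspect"))
            continue
        bad_velocity = False
        for i0, i1 in zip(idx, idx[1:]):
            if i1 != i0 + 1:
                continue
            dt = tissue.frames[i1].t_min - tissue.frames[i0].t_min
            rel = (
                tissue.frames[i1].cells[tid].centroid
                - tissue.frames[i0].cells[tid].centroid
                - mean_disp[i0]
            )
            if np.linalg.norm(rel) / dt > cfg.max_rel_velocity:
                bad_velocity = True
                break
        if bad_velocity:
            report.append((tid, "velocity"))

    removed = {tid for tid, _ in report}
    new_frames = []
    for frame in tissue.frames:
        cells = {t: c for t, c in frame.cells.items() if t not in removed}
        adjacency = {
            p: l for p, l in frame.adjacency.items() if p[0] in cells and p[1] in cells
        }
        new_frames.append(
            FrameState(
                t_min=frame.t_min,
                cells=cells,
                adjacency=adjacency,
                placode_ids=frame.placode_ids & set(cells),
                boundary_ids=frame.boundary_ids & set(cells),
            )
        )
    out = replace(tissue, frames=new_frames)
    return out, report
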