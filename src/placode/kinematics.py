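"""Strain-rate decomposition on focal-cell domains.

Deformation is measured on small spatio-temporal domains: a focal cell plus
its first corona of adjacent cells, over a window of about 3 minutes.  Three
symmetric 2x2 rate tensors (units: proportional size change per minute) are
computed per domain:

* total tissue strain rate ``T`` — symmetric part of the least-squares
  velocity-gradient tensor fitted to the relative motion of member centroids;
* cell-shape strain rate ``C`` — area-weighted mean over members of the
  log-stretch taking each cell's best-fit ellipse at the window start to its
  ellipse at the window end, with minimal rotation;
* intercalation strain rate ``I = T - C`` — the residual sliding of cells
  past one another.

Tensors are projected onto the local radial/circumferential axes of the
mobile pit-centred coordinate system as quadratic forms, and scalar rates
are accumulated multiplicatively over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .radial import RadialFrame
from .tissue_io import GeometryError, TissueValidationError, TrackedTissue

__all__ = [
    "DomainSpec",
    "StrainRecord",
    "strain_window",
    "build_domains",
    "fit_total_strain",
    "fit_cellshape_strain",
    "decompose_strain",
    "project_strain",
    "accumulate_strain",
    "area_change_rate",
    "aspect_ratio_radial",
]

DEFAULT_WINDOW_MIN = 3.0


@dataclass
class DomainSpec:
    """Focal cell plus first corona, tracked across [f_start, f_end]."""

    focal_id: int
    member_ids: list[int]
    f_start: int
    f_end: int


@dataclass
class StrainRecord:
    focal_id: int
    t: float
    T: np.ndarray
    C: np.ndarray
    I: np.ndarray
    rotation_rate: float = 0.0  # antisymmetric part, diagnostics only
    ellip: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    proj: dict[str, float] = field(default_factory=dict)


def strain_window(
    tissue: TrackedTissue, frame: int, window_min: float = DEFAULT_WINDOW_MIN
) -> tuple[int, int]:
    """Frame span of the ~3-min window centred on ``frame``.

    Uses the nearest integer number of frames; centred when possible,
    shifted forward/backward at the series ends.
    """
    w = max(1, int(round(window_min / tissue.dt_min)))
    f_start = frame - w // 2
    f_start = max(0, min(f_start, tissue.n_frames - 1 - w))
    f_end = f_start + w
    if f_end >= tissue.n_frames:
        raise GeometryError("tissue too short for the strain window")
    return f_start, f_end


def build_domains(
    tissue: TrackedTissue, frame: int, window_min: float = DEFAULT_WINDOW_MIN
) -> tuple[list[DomainSpec], list[int]]:
    """One domain per placodal focal cell with >= 3 corona members that
    survive the window.  Returns (domains, skipped focal ids)."""
    f_start, f_end = strain_window(tissue, frame, window_min)
    fs = tissue.frames[frame]
    span = range(f_start, f_end + 1)
    domains: list[DomainSpec] = []
    skipped: list[int] = []
    for focal in sorted(fs.placode_ids):
        members = [focal] + sorted(fs.neighbors(focal))
        members = [
            m for m in members if all(m in tissue.frames[i].cells for i in span)
        ]
        if focal not in members or len(members) < 4:
            skipped.append(focal)
            continue
        domains.append(
            DomainSpec(focal_id=focal, member_ids=members, f_start=f_start, f_end=f_end)
        )
    return domains, skipped


def fit_total_strain(domain: DomainSpec, tissue: TrackedTissue) -> tuple[np.ndarray, float]:
    """Least-squares velocity-gradient fit to member centroid motion.

    Returns ``(T, rotation_rate)`` where T is the symmetric part of the
    velocity gradient and rotation_rate the antisymmetric component (rad/min,
    positive anti-clockwise), discarded from strain but kept as diagnostics.
    """
    fa = tissue.frames[domain.f_start]
    fb = tissue.frames[domain.f_end]
    dt = fb.t_min - fa.t_min
    x0 = np.array([fa.cells[m].centroid for m in domain.member_ids])
    x1 = np.array([fb.cells[m].centroid for m in domain.member_ids])
    xc = x0 - x0.mean(axis=0)
    # rank check: members must not be collinear
    if np.linalg.matrix_rank(xc, tol=1e-9 * max(1.0, np.abs(xc).max())) < 2:
        raise GeometryError(
            f"collinear member centroids in domain of cell {domain.focal_id}"
        )
    u = x1 - x0
    design = np.column_stack([xc, np.ones(len(xc))])
    coef, *_ = np.linalg.lstsq(design, u, rcond=None)
    grad = coef[:2].T / dt  # velocity gradient du_i/dx_j per minute
    T = 0.5 * (grad + grad.T)
    rotation = 0.5 * (grad[1, 0] - grad[0, 1])
    return T, float(rotation)


def _wrap_half_pi(a: float) -> float:
    """Wrap an axial angle difference into (-pi/2, pi/2]."""
    a = (a + np.pi / 2) % np.pi - np.pi / 2
    if a == -np.pi / 2:
        a = np.pi / 2
    return a


def _cell_log_stretch(
    e0: tuple[float, float, float], e1: tuple[float, float, float]
) -> np.ndarray:
    """Log of the minimal-rotation symmetric stretch mapping ellipse e0 to e1.

    Axes are paired major-with-major; the stretch is expressed in the
    mid-orientation frame so a rigid rotation carries no strain.
    """
    a0, b0, p0 = e0
    a1, b1, p1 = e1
    if min(a0, b0, a1, b1) <= 0:
        raise GeometryError("degenerate ellipse in cell-shape strain")
    iso0 = (a0 - b0) < 1e-9 * a0
    iso1 = (a1 - b1) < 1e-9 * a1
    if iso0 and iso1:
        phi_m = 0.0
    elif iso0:
        phi_m = p1
        p0 = p1
    elif iso1:
        phi_m = p0
        p1 = p0
    else:
        dphi = _wrap_half_pi(p1 - p0)
        phi_m = p0 + dphi / 2.0
    la = np.log(a1 / a0)
    lb = np.log(b1 / b0)
    c, s = np.cos(phi_m), np.sin(phi_m)
    r = np.array([[c, -s], [s, c]])
    return r @ np.diag([la, lb]) @ r.T


def fit_cellshape_strain(domain: DomainSpec, tissue: TrackedTissue) -> np.ndarray:
    """Area-weighted mean of per-cell ellipse log-stretch rates."""
    fa = tissue.frames[domain.f_start]
    fb = tissue.frames[domain.f_end]
    dt = fb.t_min - fa.t_min
    tensors, weights = [], []
    for m in domain.member_ids:
        c0, c1 = fa.cells[m], fb.cells[m]
        if min(c0.ellipse[1], c1.ellipse[1]) <= 0:
            continue  # degenerate ellipse: excluded
        tensors.append(_cell_log_stretch(c0.ellipse, c1.ellipse) / dt)
        weights.append(0.5 * (c0.area + c1.area))
    if not tensors:
        raise GeometryError("no valid ellipses in domain")
    w = np.asarray(weights)
    return np.tensordot(w / w.sum(), np.asarray(tensors), axes=1)


def _ellip(M: np.ndarray) -> tuple[float, float, float]:
    """(e1, e2, phi): principal rates (e1 >= e2) and e1-axis orientation."""
    evals, evecs = np.linalg.eigh(M)
    e1, e2 = float(evals[1]), float(evals[0])
    if abs(e1 - e2) < 1e-15:
        phi = 0.0  # tie-break: orientation undefined
    else:
        v = evecs[:, 1]
        phi = float(np.arctan2(v[1], v[0])) % np.pi
    return e1, e2, phi


def decompose_strain(
    T: np.ndarray,
    C: np.ndarray,
    focal_id: int = -1,
    t: float = 0.0,
    rotation_rate: float = 0.0,
) -> StrainRecord:
    """Intercalation as the residual I = T - C, with elliptical summaries."""
    I = T - C
    rec = StrainRecord(
        focal_id=focal_id, t=t, T=T, C=C, I=I, rotation_rate=rotation_rate
    )
    rec.ellip = {"T": _ellip(T), "C": _ellip(C), "I": _ellip(I)}
    return rec


def _local_axes(centroid: np.ndarray, origin: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(centroid) - np.asarray(origin)
    r = np.linalg.norm(d)
    if r < 1e-12:
        raise GeometryError("cell at the origin: radial projection undefined")
    u_r = d / r
    u_c = np.array([-u_r[1], u_r[0]])
    return u_r, u_c


def project_strain(
    record: StrainRecord, rframe: RadialFrame, tissue: TrackedTissue, frame: int
) -> StrainRecord:
    """Quadratic-form projections onto local radial/circumferential axes."""
    cell = tissue.frames[frame].cells[record.focal_id]
    u_r, u_c = _local_axes(cell.centroid, rframe.origin)
    for name, M in (("T", record.T), ("C", record.C), ("I", record.I)):
        record.proj[f"{name}_radial"] = float(u_r @ M @ u_r)
        record.proj[f"{name}_circ"] = float(u_c @ M @ u_c)
    return record


def accumulate_strain(
    rates: np.ndarray, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative strain exp(sum(rate*dt)) - 1 as a proportion.

    ``rates[i]`` applies over the step from ``times[i]`` to ``times[i+1]``.
    Returns ``(cumulative, flags)`` aligned with ``times``; NaN rates split
    the accumulation and flag subsequent points.
    """
    rates = np.asarray(rates, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(times) != len(rates) + 1:
        raise TissueValidationError("need len(times) == len(rates) + 1")
    cum = np.zeros(len(times))
    flags = np.zeros(len(times), dtype=bool)
    log_acc = 0.0
    broken = False
    for i, rate in enumerate(rates):
        dt = times[i + 1] - times[i]
        if not np.isfinite(rate):
            broken = True
        else:
            log_acc += rate * dt
        cum[i + 1] = np.exp(log_acc) - 1.0
        flags[i + 1] = broken
    return cum, flags


def area_change_rate(times: np.ndarray, areas: np.ndarray) -> np.ndarray:
    """Per-step proportional area change rate d(ln A)/dt (pp/min)."""
    areas = np.asarray(areas, dtype=float)
    times = np.asarray(times, dtype=float)
    if np.any(areas <= 0):
        raise TissueValidationError("areas must be positive")
    return np.diff(np.log(areas)) / np.diff(times)


def aspect_ratio_radial(
    cell_ellipse: tuple[float, float, float],
    centroid: np.ndarray,
    origin: np.ndarray,
) -> float:
    """Ratio of the ellipse half-width along the radial axis to the
    circumferential axis; > 1 means radially elongated."""
    major, minor, phi = cell_ellipse
    u_r, u_c = _local_axes(centroid, origin)
    c, s = np.cos(phi), np.sin(phi)
    r = np.array([[c, -s], [s, c]])
    S = r @ np.diag([major**2, minor**2]) @ r.T
    w_r = np.sqrt(u_r @ S @ u_r)
    w_c = np.sqrt(u_c @ S @ u_c)
    return float(w_r / w_c)
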