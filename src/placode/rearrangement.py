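"""T1 neighbor-exchange detection, orientation classes and gain rates.

A neighbor exchange is identified from the adjacency graph of tracked
cells: the pair that loses connectivity between frames t and t+1 and the
pair that gains it, the four cells forming a quartet around the exchanged
interface.  Gains are classed circumferential or radial by whichever local
axis the gaining pair's centroid-centroid line is more closely aligned to
(ties at 45 degrees go to circumferential).  The net circumferential gain
per step is expressed as a proportion of half the number of tracked
cell-cell interfaces, corrected for incomplete interface tracking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .radial import RadialFrame
from .tissue_io import TrackedTissue

__all__ = ["T1Event", "detect_t1_events", "classify_gain_orientation", "gain_rates"]


@dataclass
class T1Event:
    t_gain: int  # frame index of the gain (pair adjacent from this frame)
    lost_pair: tuple[int, int]
    gained_pair: tuple[int, int]
    gain_axis: float = float("nan")  # rad, orientation of the gained pair axis
    klass: str = "unclassified"  # circumferential | radial | unclassified


def _pair(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


def _clean_presence(present: np.ndarray, hysteresis: int = 1) -> np.ndarray:
    """Fill single-frame gaps and drop single-frame appearances.

    Suppresses pixel-noise flickers of an interface around the adjacency
    threshold; an exchange must persist for more than ``hysteresis`` frames
    to count.
    """
    out = present.copy()
    n = len(out)
    # fill single-frame absences
    for i in range(1, n - 1):
        if not out[i] and out[i - 1] and out[i + 1]:
            out[i] = True
    # drop single-frame presences (after gap filling)
    for i in range(n):
        prev_ = out[i - 1] if i > 0 else False
        next_ = out[i + 1] if i < n - 1 else False
        if out[i] and not prev_ and not next_:
            out[i] = False
    return out


def _cleaned_adjacency(tissue: TrackedTissue) -> list[set[tuple[int, int]]]:
    nf = tissue.n_frames
    pairs: set[tuple[int, int]] = set()
    for f in tissue.frames:
        pairs |= set(f.adjacency)
    series = {}
    for p in pairs:
        present = np.array([p in tissue.frames[i].adjacency for i in range(nf)])
        series[p] = _clean_presence(present)
    out: list[set[tuple[int, int]]] = []
    for i in range(nf):
        out.append({p for p, s in series.items() if s[i]})
    return out


def detect_t1_events(tissue: TrackedTissue) -> list[T1Event]:
    """One event per (lost pair at t, gained pair at t+1) quartet.

    Reversals are separate events; rosette-like exchanges are decomposed
    pairwise.  Only pairs whose cells exist in both frames participate, so
    track ends never masquerade as exchanges.
    """
    adj = _cleaned_adjacency(tissue)
    events: list[T1Event] = []
    for t in range(tissue.n_frames - 1):
        f0, f1 = tissue.frames[t], tissue.frames[t + 1]
        both = set(f0.cells) & set(f1.cells)
        a0 = {p for p in adj[t] if p[0] in both and p[1] in both}
        a1 = {p for p in adj[t + 1] if p[0] in both and p[1] in both}
        lost = a0 - a1
        gained = a1 - a0
        if not gained or not lost:
            continue
        neigh0: dict[int, set[int]] = {}
        for a, b in a0:
            neigh0.setdefault(a, set()).add(b)
            neigh0.setdefault(b, set()).add(a)
        for c, d in sorted(gained):
            common = neigh0.get(c, set()) & neigh0.get(d, set())
            candidates = [lp for lp in lost if lp[0] in common and lp[1] in common]
            if not candidates:
                continue
            if len(candidates) > 1:
                mid_g = 0.5 * (f1.cells[c].centroid + f1.cells[d].centroid)

                def _dist(lp: tuple[int, int]) -> float:
                    mid_l = 0.5 * (f0.cells[lp[0]].centroid + f0.cells[lp[1]].centroid)
                    return float(np.linalg.norm(mid_l - mid_g))

                candidates.sort(key=_dist)
            lp = candidates[0]
            axis_vec = f1.cells[d].centroid - f1.cells[c].centroid
            axis = float(np.arctan2(axis_vec[1], axis_vec[0])) % np.pi
            events.append(
                T1Event(t_gain=t + 1, lost_pair=lp, gained_pair=_pair(c, d), gain_axis=axis)
            )
    return events


def classify_gain_orientation(
    event: T1Event, rframe: RadialFrame, tissue: TrackedTissue
) -> str:
    """Circumferential if the gain axis is within 45 deg (inclusive) of the
    local circumferential direction, else radial."""
    f1 = tissue.frames[event.t_gain]
    c, d = event.gained_pair
    mid = 0.5 * (f1.cells[c].centroid + f1.cells[d].centroid)
    rel = mid - rframe.origin
    r = np.linalg.norm(rel)
    if r < 1e-12 or not np.isfinite(event.gain_axis):
        event.klass = "unclassified"
        return event.klass
    u_c = np.array([-rel[1], rel[0]]) / r
    axis = np.array([np.cos(event.gain_axis), np.sin(event.gain_axis)])
    cos_acute = abs(float(axis @ u_c))
    # acute angle <= 45 deg  <=>  |cos| >= cos(45 deg); tie -> circumferential
    event.klass = (
        "circumferential" if cos_acute >= np.cos(np.pi / 4) - 1e-12 else "radial"
    )
    return event.klass


def gain_rates(
    events: list[T1Event],
    tissue: TrackedTissue,
    rframes: list[RadialFrame] | None = None,
    cohort: dict[int, str] | None = None,
    coverage: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Per-step neighbor-gain counts, net circumferential gain and rate.

    ``rate = net / (0.5 * n_tracked_interfaces) / coverage_fraction`` where
    coverage is the fraction of interfaces successfully tracked in that
    step (default 1).  ``cumulative`` is the running sum of the rate —
    the cumulative proportion of productive neighbor gains.  If ``cohort``
    maps track ids to labels (fixed at t=0), rows are per step per cohort
    (an event belongs to a cohort if either gaining cell does).
    """
    if rframes is not None:
        for ev in events:
            if ev.klass == "unclassified":
                classify_gain_orientation(ev, rframes[ev.t_gain], tissue)

    labels = sorted(set(cohort.values())) if cohort else ["all"]
    rows = []
    cum = {lab: 0.0 for lab in labels}
    for t in range(tissue.n_frames - 1):
        f0, f1 = tissue.frames[t], tissue.frames[t + 1]
        both = set(f0.cells) & set(f1.cells)
        n_tracked = sum(1 for (a, b) in f0.adjacency if a in both and b in both)
        cov = 1.0 if coverage is None else coverage.get(t, 1.0)
        step_events = [e for e in events if e.t_gain == t + 1]
        for lab in labels:
            if cohort:
                sel = [
                    e
                    for e in step_events
                    if cohort.get(e.gained_pair[0]) == lab
                    or cohort.get(e.gained_pair[1]) == lab
                ]
            else:
                sel = step_events
            n_circ = sum(1 for e in sel if e.klass == "circumferential")
            n_rad = sum(1 for e in sel if e.klass == "radial")
            net = n_circ - n_rad
            if n_tracked == 0 or cov == 0:
                rate = float("nan")
            else:
                rate = net / (0.5 * n_tracked) / cov
                cum[lab] += rate
            rows.append(
                {
                    "step": t,
                    "t_min": f0.t_min,
                    "cohort": lab,
                    "n_circ": n_circ,
                    "n_rad": n_rad,
                    "net": net,
                    "n_tracked_interfaces": n_tracked,
                    "coverage": cov,
                    "rate": rate,
                    "cumulative": cum[lab],
                }
            )
    return pd.DataFrame(rows)
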