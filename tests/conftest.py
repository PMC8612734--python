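"""Shared fixtures: tiny hand-built tissues and cached synthetic placodes."""

from __future__ import annotations

import numpy as np
import pytest

from placode.synthetic import SyntheticConfig, generate_placode, scripted_t1_tissue
from placode.tissue_io import CellState, FrameState, TrackedTissue


def square_cell(cx: float, cy: float, side: float = 2.0) -> CellState:
    h = side / 2.0
    poly = np.array(
        [[cx - h, cy - h], [cx + h, cy - h], [cx + h, cy + h], [cx - h, cy + h]]
    )
    return CellState.from_polygon(poly)


def grid_tissue(
    n: int = 3,
    n_frames: int = 5,
    side: float = 2.0,
    dt_min: float = 1.0,
    displace=None,
) -> TrackedTissue:
    """n x n lattice of square cells; ``displace(tid, frame)`` moves centres."""
    frames = []
    for f in range(n_frames):
        cells = {}
        adjacency = {}
        for i in range(n):
            for j in range(n):
                tid = i * n + j
                cx, cy = j * side, i * side
                if displace is not None:
                    dx, dy = displace(tid, f)
                    cx, cy = cx + dx, cy + dy
                cells[tid] = square_cell(cx, cy, side)
        for i in range(n):
            for j in range(n):
                tid = i * n + j
                if j + 1 < n:
                    adjacency[(tid, tid + 1)] = side
                if i + 1 < n:
                    adjacency[(tid, tid + n)] = side
        frames.append(
            FrameState(
                t_min=float(f) * dt_min,
                cells=cells,
                adjacency=adjacency,
                placode_ids=set(cells),
            )
        )
    return TrackedTissue(frames=frames, dt_min=dt_min, px_um=None, side="left", t0_index=0)


@pytest.fixture(scope="session")
def eccentric_run():
    """Wild-type-like eccentric-pit placode, full default duration."""
    cfg = SyntheticConfig(scenario="eccentric", seed=11)
    return generate_placode(cfg)


@pytest.fixture(scope="session")
def short_eccentric_run():
    cfg = SyntheticConfig(
        scenario="eccentric", seed=7, n_cells=80, t_start_min=-5.0, t_end_min=15.0
    )
    return generate_placode(cfg)


@pytest.fixture(scope="session")
def scripted_run():
    return scripted_t1_tissue(n_events=50, n_reversals=5, seed=2)
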