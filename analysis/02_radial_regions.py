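#!/usr/bin/env python
"""Radial coordinates and region occupancy of the wild-type run.

Tracks the pit origin through all frames, assigns (r, theta, D) to every
cell, labels near/far cohorts at t=0, and reports how the near region is
re-populated as far cells flow inward — the geometric substrate of the
behaviour switch.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from placode import radial
from placode.synthetic import SyntheticConfig, generate_placode

SEED = 11
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = SyntheticConfig(scenario="eccentric", seed=SEED)
    tissue, gt = generate_placode(cfg)

    origins = radial.propagate_origin(tissue, gt.pit_center)
    drift = max(float(np.linalg.norm(o - gt.pit_center)) for o in origins)
    rframes = radial.assign_radial_coordinates(tissue, origins)
    cohort = radial.regions_at_t0(tissue, rframes)

    rows = []
    for fi, rf in enumerate(rframes):
        radial.assign_regions(rf)
        n_near_now = sum(1 for v in rf.region.values() if v == "near")
        far_inside = sum(
            1
            for tid, reg in rf.region.items()
            if reg == "near" and cohort.get(tid) == "far"
        )
        rows.append(
            {
                "frame": fi,
                "t_min": tissue.frames[fi].t_min,
                "n_in_near_region": n_near_now,
                "far_cohort_cells_now_near": far_inside,
            }
        )
    df = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    df.to_csv(ROOT / "results" / "02_region_occupancy.csv", index=False)

    mean_area = np.mean(
        [c.area for c in tissue.frames[tissue.t0_index].cells.values()]
    )
    diam = 2 * np.sqrt(mean_area / np.pi)
    print(f"origin max drift from the sink: {drift:.1f} µm (cell diameter {diam:.1f} µm)")
    late = df[df.t_min >= 30]
    print(
        "far-cohort cells occupying the near region at t>=+30 min: "
        f"{late.far_cohort_cells_now_near.mean():.1f} on average -- the near "
        "zone is continuously re-populated by inflowing far cells"
    )
    print("occupancy table -> results/02_region_occupancy.csv")


if __name__ == "__main__":
    main()
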