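"""End-to-end orchestration: coordinates -> kinematics -> exchanges -> summaries.

``run_pipeline`` drives every analysis stage from a single declarative
config, writes one CSV per stage plus a manifest (config echo, row counts,
checksums), and is deterministic: rerunning with the same inputs reproduces
the outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinematics as kin
from . import radial, rearrangement
from .corona import observed_corona_counts
from .tissue_io import ConfigError, TrackedTissue, read_tracked_tissue

__all__ = ["PipelineConfig", "run_pipeline", "cohort_summary"]


@dataclass
class PipelineConfig:
    tissue_path: str | None = None
    origin_t0: tuple[float, float] = (0.0, 0.0)
    side: str | None = None  # None -> from tissue header
    posterior: tuple[float, float] = (1.0, 0.0)
    region_threshold: float = 0.33
    n_stripes: int = 10
    stripe_width: float | None = None
    strain_window_min: float = 3.0
    origin_k: int = 6
    out_dir: str = "placode_out"
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.region_threshold < 1.0):
            raise ConfigError(
                f"region_threshold must be in (0,1), got {self.region_threshold}"
            )
        if self.strain_window_min <= 0:
            raise ConfigError("strain_window_min must be positive")
        if self.n_stripes <= 0:
            raise ConfigError("n_stripes must be positive")


def _write_csv(df: pd.DataFrame, path: Path) -> dict:
    df.to_csv(path, index=False, float_format="%.12g")
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    return {"file": path.name, "rows": int(len(df)), "sha256": digest}


def cohort_summary(table: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Per-minute per-cohort mean, SD, SEM and n of a per-cell quantity.

    ``table`` needs columns ``t_min``, ``cohort`` and the value column; cells
    absent from a frame are simply absent from the table and drop out of n.
    """
    def agg(g: pd.Series) -> pd.Series:
        v = g.dropna().to_numpy()
        n = len(v)
        mean = float(np.mean(v)) if n else float("nan")
        sd = float(np.std(v, ddof=1)) if n > 1 else 0.0 if n == 1 else float("nan")
        sem = sd / np.sqrt(n) if n >= 1 else float("nan")
        return pd.Series({"mean": mean, "sd": sd, "sem": sem, "n": n})

    out = (
        table.groupby(["cohort", "t_min"], sort=True)[value]
        .apply(agg)
        .unstack()
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out


def run_pipeline(
    cfg: PipelineConfig, tissue: TrackedTissue | None = None
) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    cfg.validate()
    if tissue is None:
        if cfg.tissue_path is None:
            raise ConfigError("either a tissue or a tissue_path is required")
        tissue = read_tracked_tissue(cfg.tissue_path)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(cfg),
        "n_frames": tissue.n_frames,
        "n_tracks": len(tissue.track_ids()),
        "stages": {},
    }

    # stage 1: radial coordinates
    origins = radial.propagate_origin(
        tissue, np.asarray(cfg.origin_t0, dtype=float), k=cfg.origin_k
    )
    rframes = radial.assign_radial_coordinates(
        tissue, origins, side=cfg.side, posterior=np.asarray(cfg.posterior)
    )
    for rf in rframes:
        radial.assign_regions(rf, cfg.region_threshold)
    cohort = radial.regions_at_t0(tissue, rframes, cfg.region_threshold)
    stripes, stripe_width = radial.assign_stripes(
        tissue, rframes, n_stripes=cfg.n_stripes, stripe_width=cfg.stripe_width
    )
    rows = []
    for fi, rf in enumerate(rframes):
        for tid in sorted(rf.r):
            rows.append(
                {
                    "frame": fi,
                    "t_min": tissue.frames[fi].t_min,
                    "track_id": tid,
                    "r_um": rf.r[tid],
                    "theta_rad": rf.theta[tid],
                    "D_um": rf.D[tid],
                    "region": rf.region.get(tid, ""),
                    "region_t0": cohort.get(tid, ""),
                    "stripe_t0": stripes.get(tid, -1),
                }
            )
    radial_df = pd.DataFrame(rows)
    manifest["stages"]["radial"] = _write_csv(radial_df, out / "radial.csv")

    # stage 2: strain rates on focal domains
    srows = []
    w_frames = max(1, int(round(cfg.strain_window_min / tissue.dt_min)))
    for fi in range(tissue.n_frames - w_frames):
        try:
            domains, _ = kin.build_domains(tissue, fi, cfg.strain_window_min)
        except Exception:
            continue
        rf = rframes[fi]
        for dom in domains:
            try:
                T, rot = kin.fit_total_strain(dom, tissue)
                C = kin.fit_cellshape_strain(dom, tissue)
            except Exception:
                continue
            rec = kin.decompose_strain(
                T, C, focal_id=dom.focal_id, t=tissue.frames[fi].t_min, rotation_rate=rot
            )
            if rf.r.get(dom.focal_id, 0.0) > 0:
                kin.project_strain(rec, rf, tissue, fi)
            row = {
                "frame": fi,
                "t_min": rec.t,
                "focal_id": rec.focal_id,
                "region_t0": cohort.get(rec.focal_id, ""),
                "rotation_rate": rec.rotation_rate,
            }
            for name, M in (("T", rec.T), ("C", rec.C), ("I", rec.I)):
                row[f"{name}xx"], row[f"{name}xy"], row[f"{name}yy"] = (
                    M[0, 0],
                    M[0, 1],
                    M[1, 1],
                )
                e1, e2, phi = rec.ellip[name]
                row[f"e1_{name}"], row[f"e2_{name}"], row[f"phi_{name}"] = e1, e2, phi
                row[f"proj_{name}_rad"] = rec.proj.get(f"{name}_radial", np.nan)
                row[f"proj_{name}_circ"] = rec.proj.get(f"{name}_circ", np.nan)
            srows.append(row)
    strain_df = pd.DataFrame(srows)
    manifest["stages"]["strain"] = _write_csv(strain_df, out / "strain.csv")

    # stage 3: cohort strain summary
    if len(strain_df):
        pieces = []
        for col in ("proj_T_rad", "proj_T_circ", "proj_C_rad", "proj_C_circ",
                    "proj_I_rad", "proj_I_circ"):
            t = strain_df.rename(columns={col: "value", "region_t0": "cohort"})[
                ["t_min", "cohort", "value"]
            ]
            s = cohort_summary(t)
            s.insert(0, "quantity", col)
            pieces.append(s)
        strain_cohort = pd.concat(pieces, ignore_index=True)
    else:
        strain_cohort = pd.DataFrame(
            columns=["quantity", "cohort", "t_min", "mean", "sd", "sem", "n"]
        )
    manifest["stages"]["strain_cohort"] = _write_csv(
        strain_cohort, out / "strain_cohort.csv"
    )

    # stage 4: per-cell area-change rates and cohort means
    arows = []
    for tid in sorted(tissue.track_ids()):
        t, a = tissue.area_series(tid)
        if len(t) < 2:
            continue
        rates = kin.area_change_rate(t, a)
        for i, r in enumerate(rates):
            arows.append(
                {
                    "t_min": t[i],
                    "track_id": tid,
                    "cohort": cohort.get(tid, ""),
                    "value": r,
                }
            )
    area_df = pd.DataFrame(arows)
    area_cohort = (
        cohort_summary(area_df)
        if len(area_df)
        else pd.DataFrame(columns=["cohort", "t_min", "mean", "sd", "sem", "n"])
    )
    manifest["stages"]["area_rate_cohort"] = _write_csv(
        area_cohort, out / "area_rate_cohort.csv"
    )

    # stage 5: neighbor exchanges
    events = rearrangement.detect_t1_events(tissue)
    for ev in events:
        rearrangement.classify_gain_orientation(ev, rframes[ev.t_gain], tissue)
    edf = pd.DataFrame(
        [
            {
                "t_gain": ev.t_gain,
                "t_min": tissue.frames[ev.t_gain].t_min,
                "lost_a": ev.lost_pair[0],
                "lost_b": ev.lost_pair[1],
                "gained_a": ev.gained_pair[0],
                "gained_b": ev.gained_pair[1],
                "gain_axis_deg": np.degrees(ev.gain_axis),
                "class": ev.klass,
            }
            for ev in events
        ],
        columns=[
            "t_gain", "t_min", "lost_a", "lost_b", "gained_a", "gained_b",
            "gain_axis_deg", "class",
        ],
    )
    manifest["stages"]["t1_events"] = _write_csv(edf, out / "t1_events.csv")
    rates_df = rearrangement.gain_rates(events, tissue, rframes, cohort=cohort)
    manifest["stages"]["t1_rates"] = _write_csv(rates_df, out / "t1_rates.csv")

    # stage 6: area kymograph over t0 stripes
    quantity = {}
    for tid in sorted(tissue.track_ids()):
        series = np.full(tissue.n_frames, np.nan)
        for fi, f in enumerate(tissue.frames):
            if tid in f.cells:
                series[fi] = f.cells[tid].area
        quantity[tid] = series
    kymo = radial.stripe_kymograph(tissue, stripes, quantity, n_stripes=cfg.n_stripes)
    kymo_df = pd.DataFrame(
        kymo,
        index=[f"stripe_{i}" for i in range(kymo.shape[0])],
        columns=[f"{t:g}" for t in tissue.times],
    ).reset_index(names="stripe")
    manifest["stages"]["kymograph_area"] = _write_csv(
        kymo_df, out / "kymograph_area.csv"
    )

    # stage 7: observed invagination coronae
    counts = observed_corona_counts(tissue)
    corona_df = pd.DataFrame(
        {"corona": np.arange(len(counts)), "n_cells": counts}
    )
    manifest["stages"]["corona_observed"] = _write_csv(
        corona_df, out / "corona_observed.csv"
    )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
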