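"""Selection of analyzable wells and assembly of pixel trajectories.

A well is analyzable when it holds exactly one cell and exactly one bead at
every imaged time point (cells dividing or objects dropping out of
segmentation at any frame exclude the well).  Wells are immobile, so
identity across time is by well id alone — no object matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segment import DetectedObject, WellOccupancy
from .simulate import ArrayFrame

log = logging.getLogger(__name__)


@dataclass
class WellTrajectory:
    """Detection-channel pixel samples of one single-cell/single-bead well.

    ``cell_pixels`` are the cell's non-overlapped pixels (cell mask minus
    bead mask).  ``background_estimates`` holds the per-frame per-well
    background level used for correction downstream.
    """

    well_id: tuple[int, int]
    time_points_h: tuple[float, ...]
    bead_pixels: list[np.ndarray]
    cell_pixels: list[np.ndarray]
    background_estimates: list[float]
    complete: bool = True


def select_single_single(occupancy: list[WellOccupancy]) -> set[tuple[int, int]]:
    """Wells with cell_count == 1 and bead_count == 1 at every time point."""
    ok: dict[tuple[int, int], bool] = {}
    for occ in occupancy:
        good = occ.cell_count == 1 and occ.bead_count == 1
        ok[occ.well_id] = ok.get(occ.well_id, True) and good
    return {wid for wid, good in ok.items() if good}


def build_trajectories(selected: set[tuple[int, int]],
                       objects_per_frame: dict[float, list[DetectedObject]],
                       frames: list[ArrayFrame]) -> list[WellTrajectory]:
    """Extract detection-channel samples using each frame's own masks.

    Wells whose cell is fully covered by the bead at some frame are dropped
    with a logged reason (no non-overlapped cell pixels to compare against).
    """
    from .secretion import estimate_background

    frames_by_t = {f.time_h: f for f in frames}
    tps = tuple(sorted(frames_by_t))
    out: list[WellTrajectory] = []
    for wid in sorted(selected):
        bead_px, cell_px, bgs = [], [], []
        degenerate = False
        for t in tps:
            frame = frames_by_t[t]
            objs = [o for o in objects_per_frame[t] if o.well_id == wid]
            bead = next(o for o in objs if o.kind == "bead")
            cell = next(o for o in objs if o.kind == "cell")
            det = frame.channel("detection")
            bead_set = {tuple(p) for p in bead.pixel_set}
            cell_coords = np.array(
                [p for p in cell.pixel_set if tuple(p) not in bead_set], dtype=int)
            if cell_coords.size == 0:
                log.warning("well %s dropped: cell fully covered by bead at t=%s h",
                            wid, t)
                degenerate = True
                break
            bead_px.append(det[bead.pixel_set[:, 0], bead.pixel_set[:, 1]].astype(float))
            cell_px.append(det[cell_coords[:, 0], cell_coords[:, 1]].astype(float))
            bgs.append(estimate_background(frame, wid, objects_per_frame[t]))
        if degenerate:
            continue
        out.append(WellTrajectory(well_id=wid, time_points_h=tps,
                                  bead_pixels=bead_px, cell_pixels=cell_px,
                                  background_estimates=bgs, complete=True))
    return out


def trajectories_frame(trajectories: list[WellTrajectory]) -> pd.DataFrame:
    """Tidy table: well_id, time_h, compartment, pixel_value."""
    rows = []
    for tr in trajectories:
        wid = f"{tr.well_id[0]},{tr.well_id[1]}"
        for t, bead, cell, bg in zip(tr.time_points_h, tr.bead_pixels,
                                     tr.cell_pixels, tr.background_estimates):
            rows.extend({"well_id": wid, "time_h": t, "compartment": "bead",
                         "pixel_value": v} for v in bead)
            rows.extend({"well_id": wid, "time_h": t, "compartment": "cell",
                         "pixel_value": v} for v in cell)
            rows.append({"well_id": wid, "time_h": t, "compartment": "background",
                         "pixel_value": bg})
    return pd.DataFrame(rows)
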