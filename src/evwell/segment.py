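"""Cell/bead detection and well assignment.

Classical pipeline: Otsu threshold on the object's dedicated label channel,
4-connected components clipped to well interiors, then area and (for beads)
circularity gates.  Deterministic by construction — no learned components.

Coordinate convention: (row, col), 0-based, pixel centers at integer
coordinates; well bounding boxes are half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .simulate import ArrayConfig, ArrayFrame


@dataclass
class DetectedObject:
    kind: str                                # "cell" | "bead"
    centroid: tuple[float, float]            # (row, col)
    pixel_set: np.ndarray                    # (n, 2) int (row, col)
    area_px: int
    circularity: float                       # 4*pi*area / perimeter^2
    well_id: tuple[int, int] | None = None   # None = unassigned


@dataclass
class WellOccupancy:
    well_id: tuple[int, int]
    time_point_h: float
    cell_count: int
    bead_count: int

    @property
    def cell_to_bead_ratio(self) -> float | None:
        """Cells per bead; None when the well holds no bead."""
        if self.bead_count == 0:
            return None
        return self.cell_count / self.bead_count


@dataclass
class SegmentationParams:
    """Gates for connected components.

    Bead defaults: area within +/-30% of the configured disc area and
    circularity >= 0.8 (beads are monodisperse spheres).  Cells: area gate
    only (pleomorphic).  ``area_range=None`` derives the gate from the array
    config geometry.
    """

    area_range: tuple[float, float] | None = None
    min_circularity: float | None = None

    @staticmethod
    def defaults_for(kind: str, config: ArrayConfig) -> "SegmentationParams":
        if kind == "bead":
            disc = np.pi * (config.bead_diameter_px / 2.0) ** 2
            return SegmentationParams(area_range=(0.7 * disc, 1.3 * disc),
                                      min_circularity=0.8)
        d_lo, d_hi = config.cell_diameter_px_range
        return SegmentationParams(
            area_range=(0.5 * np.pi * (d_lo / 2.0) ** 2,
                        1.6 * np.pi * (d_hi / 2.0) ** 2),
            min_circularity=None)


def _interior_mask(config: ArrayConfig) -> np.ndarray:
    """Boolean mask of well interiors (septum pixels False)."""
    mask = np.zeros(config.image_shape, dtype=bool)
    m = config.well_margin_px
    s = config.well_size_px
    p = config.well_pitch_px
    for i in range(config.n_rows):
        r0 = i * p + m
        for j in range(config.n_cols):
            c0 = j * p + m
            mask[r0:r0 + s, c0:c0 + s] = True
    return mask


def segment_objects(frame: ArrayFrame, kind: str,
                    params: SegmentationParams | None = None
                    ) -> list[DetectedObject]:
    """Detect objects of one kind in a frame.

    Raises ``ValueError`` on an all-saturated (constant non-zero at the dtype
    ceiling is indistinguishable from constant) channel; a channel with no
    foreground yields an empty list.
    """
    if kind not in ("cell", "bead"):
        raise ValueError(f"kind must be 'cell' or 'bead', got {kind!r}")
    if params is None:
        params = SegmentationParams.defaults_for(kind, frame.config)

    img = frame.channel(kind)
    lo, hi = float(img.min()), float(img.max())
    if lo == hi:
        if lo > 0:
            raise ValueError("channel is saturated/constant: unusable frame")
        return []

    thr = threshold_otsu(img)
    fg = img > thr
    # threshold of a noise-only channel lands inside the noise: reject when
    # the "foreground" is not well separated from the rest of the histogram
    if fg.any() and img[fg].mean() - img[~fg].mean() < 6 * max(img[~fg].std(), 1e-12):
        return []
    fg &= _interior_mask(frame.config)  # never merge across well septa

    labels = cc_label(fg, connectivity=1)  # 4-connected
    out: list[DetectedObject] = []
    for prop in regionprops(labels):
        area = int(prop.area)
        if params.area_range is not None:
            a_lo, a_hi = params.area_range
            if not (a_lo <= area <= a_hi):
                continue
        perim = prop.perimeter_crofton if prop.perimeter_crofton > 0 else prop.perimeter
        circ = float(4 * np.pi * area / perim ** 2) if perim > 0 else 0.0
        if params.min_circularity is not None and circ < params.min_circularity:
            continue
        out.append(DetectedObject(
            kind=kind,
            centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
            pixel_set=prop.coords.copy(),
            area_px=area,
            circularity=circ,
        ))
    return out


def assign_to_wells(objects: list[DetectedObject], config: ArrayConfig
                    ) -> list[DetectedObject]:
    """Fill ``well_id`` from the centroid; septum centroids stay unassigned."""
    for obj in objects:
        r, c = obj.centroid
        i, j = int(r // config.well_pitch_px), int(c // config.well_pitch_px)
        if not (0 <= i < config.n_rows and 0 <= j < config.n_cols):
            obj.well_id = None
            continue
        r0, c0, r1, c1 = config.well_interior((i, j))
        obj.well_id = (i, j) if (r0 <= r < r1 and c0 <= c < c1) else None
    return objects


def census(objects_per_frame: dict[float, list[DetectedObject]],
           config: ArrayConfig) -> list[WellOccupancy]:
    """Exact per-well, per-time-point tallies over all wells (zeros included)."""
    out: list[WellOccupancy] = []
    for t, objects in objects_per_frame.items():
        counts: dict[tuple[int, int], list[int]] = {
            (i, j): [0, 0] for i in range(config.n_rows) for j in range(config.n_cols)}
        for obj in objects:
            if obj.well_id is None:
                continue
            counts[obj.well_id][0 if obj.kind == "cell" else 1] += 1
        for wid, (nc, nb) in counts.items():
            out.append(WellOccupancy(well_id=wid, time_point_h=t,
                                     cell_count=nc, bead_count=nb))
    return out


def segment_frame(frame: ArrayFrame) -> list[DetectedObject]:
    """Both kinds, assigned to wells — the per-frame driver."""
    objs = segment_objects(frame, "cell") + segment_objects(frame, "bead")
    return assign_to_wells(objs, frame.config)


def occupancy_frame(occupancy: list[WellOccupancy]) -> pd.DataFrame:
    rows = [{"well_row": o.well_id[0], "well_col": o.well_id[1],
             "time_h": o.time_point_h, "cell_count": o.cell_count,
             "bead_count": o.bead_count,
             "cell_to_bead_ratio": o.cell_to_bead_ratio}
            for o in occupancy]
    return pd.DataFrame(rows)
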