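"""Per-cell secretor calling from bead-vs-cell pixel comparisons.

The per-cell readout is the detection-channel fluorescence accumulated on
the capture bead.  A cell is called a *secretor* at a time point when the
background-corrected bead pixels are significantly brighter than the cell's
own non-overlapped surface pixels: two-tailed Welch t-test p below ``alpha``
(default 0.01) together with a positive bead-minus-cell mean difference.
Background is the per-well median detection intensity outside all object
masks, subtracted from both samples and clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .census_filter import WellTrajectory
from .segment import DetectedObject
from .simulate import ArrayFrame


@dataclass(frozen=True)
class ClassifierParams:
    alpha: float = 0.01
    min_effect: float = 0.0
    background_method: str = "well_median_outside_objects"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_effect < 0:
            raise ValueError("min_effect must be >= 0")


@dataclass
class SecretionCall:
    well_id: tuple[int, int]
    time_point_h: float
    t_statistic: float
    p_value: float
    bead_mean_corrected: float
    cell_mean_corrected: float
    label: str  # "secretor" | "non_secretor"

    @property
    def effect_direction(self) -> int:
        return int(np.sign(self.bead_mean_corrected - self.cell_mean_corrected))


def estimate_background(frame: ArrayFrame, well_id: tuple[int, int],
                        objects: list[DetectedObject]) -> float:
    """Median detection intensity over well-interior pixels outside all masks."""
    r0, c0, r1, c1 = frame.config.well_interior(well_id)
    det = frame.channel("detection")
    covered = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    for obj in objects:
        if obj.well_id != well_id:
            continue
        px = obj.pixel_set
        inside = (px[:, 0] >= r0) & (px[:, 0] < r1) & (px[:, 1] >= c0) & (px[:, 1] < c1)
        covered[px[inside, 0] - r0, px[inside, 1] - c0] = True
    free = det[r0:r1, c0:c1][~covered]
    if free.size == 0:
        raise ValueError(f"well {well_id} fully covered by objects: unusable")
    return float(np.median(free))


def bead_cell_test(bead_pixels: np.ndarray, cell_pixels: np.ndarray
                   ) -> tuple[float, float]:
    """Welch two-sample t-statistic and two-tailed p-value.

    Degenerate conventions: both samples constant and equal -> (0, 1);
    both constant and unequal -> (+/-inf, 0).
    """
    bead = np.asarray(bead_pixels, dtype=float)
    cell = np.asarray(cell_pixels, dtype=float)
    if bead.size < 2 or cell.size < 2:
        raise ValueError("need >= 2 pixels per compartment")
    if bead.std() == 0 and cell.std() == 0:
        if bead.mean() == cell.mean():
            return 0.0, 1.0
        return float(np.sign(bead.mean() - cell.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(bead, cell, equal_var=False)
    return float(t), float(p)


def classify_secretor(trajectory: WellTrajectory,
                      params: ClassifierParams | None = None
                      ) -> list[SecretionCall]:
    """One call per time point after t = 0.

    secretor  <=>  p < alpha  AND  bead_mean - cell_mean > min_effect,
    on background-corrected (subtract per-well median, clip at 0) pixels.
    """
    if params is None:
        params = ClassifierParams()
    calls = []
    for k, t in enumerate(trajectory.time_points_h):
        if t == trajectory.time_points_h[0]:
            continue
        bg = trajectory.background_estimates[k]
        bead = np.clip(np.asarray(trajectory.bead_pixels[k], float) - bg, 0, None)
        cell = np.clip(np.asarray(trajectory.cell_pixels[k], float) - bg, 0, None)
        t_stat, p = bead_cell_test(bead, cell)
        diff = bead.mean() - cell.mean()
        label = ("secretor" if (p < params.alpha and diff > params.min_effect)
                 else "non_secretor")
        calls.append(SecretionCall(
            well_id=trajectory.well_id, time_point_h=t, t_statistic=t_stat,
            p_value=p, bead_mean_corrected=float(bead.mean()),
            cell_mean_corrected=float(cell.mean()), label=label))
    return calls


def secretor_frequency(calls: list[SecretionCall], time_point_h: float
                       ) -> tuple[float, float]:
    """Secretor proportion at a time point with its binomial standard error."""
    at_t = [c for c in calls if c.time_point_h == time_point_h]
    if not at_t:
        raise ValueError(f"no calls at t = {time_point_h} h")
    n = len(at_t)
    f = sum(c.label == "secretor" for c in at_t) / n
    return f, float(np.sqrt(f * (1 - f) / n))


def compare_intensity_distributions(calls_a: list[SecretionCall],
                                    calls_b: list[SecretionCall],
                                    secretors_only: bool = True) -> float:
    """Two-sided Mann-Whitney p on corrected bead means between populations."""
    def values(calls):
        return [c.bead_mean_corrected for c in calls
                if not secretors_only or c.label == "secretor"]

    a, b = values(calls_a), values(calls_b)
    if not a or not b:
        raise ValueError("both populations need at least one value")
    method = "exact" if max(len(a), len(b)) <= 20 else "auto"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def calls_frame(calls: list[SecretionCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "well_id": f"{c.well_id[0]},{c.well_id[1]}", "time_h": c.time_point_h,
        "t": c.t_statistic, "p": c.p_value, "bead_mean": c.bead_mean_corrected,
        "cell_mean": c.cell_mean_corrected, "label": c.label} for c in calls])
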