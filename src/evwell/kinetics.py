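"""Kinetic classification of secretion from consecutive-time-point events.

For each pair of consecutive time points a two-tailed Welch t-test is run on
the background-corrected bead pixel values; an *event* (active secretion in
that interval) is called when the mean increased AND p < ``event_alpha``
(default 0.01).  The boolean event vector over the three intervals
(0-2, 2-4, 4-6 h) maps onto the kinetic subpopulations:

* first interval active, any later activity      -> ``continuous``
* first interval active, then silent             -> ``early_stop``
* first interval silent, any later activity      -> ``delayed``
* never active                                   -> ``non_secretor``

Finer patterns (e.g. delayed-then-stopped, [0,1,0]) keep their raw vector in
``sub_pattern`` but fold into the three primary classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .census_filter import WellTrajectory
from .secretion import bead_cell_test


@dataclass(frozen=True)
class KineticParams:
    event_alpha: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.event_alpha < 1:
            raise ValueError("event_alpha must be in (0, 1)")


@dataclass
class KineticProfile:
    well_id: tuple[int, int]
    event_vector: tuple[bool, ...]
    interval_p_values: tuple[float, ...]
    kinetic_class: str
    sub_pattern: tuple[bool, ...]


def call_events(trajectory: WellTrajectory,
                params: KineticParams | None = None
                ) -> tuple[tuple[bool, ...], tuple[float, ...]]:
    """Per-interval events from consecutive bead-pixel comparisons."""
    if params is None:
        params = KineticParams()
    if not trajectory.complete:
        raise ValueError("kinetic analysis requires a complete trajectory")
    events, pvals = [], []
    for k in range(len(trajectory.time_points_h) - 1):
        b0 = np.clip(np.asarray(trajectory.bead_pixels[k], float)
                     - trajectory.background_estimates[k], 0, None)
        b1 = np.clip(np.asarray(trajectory.bead_pixels[k + 1], float)
                     - trajectory.background_estimates[k + 1], 0, None)
        t, p = bead_cell_test(b1, b0)
        events.append(bool(b1.mean() > b0.mean() and p < params.event_alpha))
        pvals.append(p)
    return tuple(events), tuple(pvals)


def classify_kinetics(event_vector: tuple[bool, ...] | list[bool]) -> str:
    """Deterministic, total mapping from event vectors to kinetic classes."""
    ev = tuple(bool(e) for e in event_vector)
    if len(ev) < 2:
        raise ValueError("event vector must cover at least two intervals")
    first, later = ev[0], any(ev[1:])
    if first and later:
        return "continuous"
    if first:
        return "early_stop"
    if later:
        return "delayed"
    return "non_secretor"


def profile_trajectory(trajectory: WellTrajectory,
                       params: KineticParams | None = None) -> KineticProfile:
    events, pvals = call_events(trajectory, params)
    return KineticProfile(well_id=trajectory.well_id, event_vector=events,
                          interval_p_values=pvals,
                          kinetic_class=classify_kinetics(events),
                          sub_pattern=events)


def class_trends(profiles: list[KineticProfile],
                 trajectories: list[WellTrajectory]) -> pd.DataFrame:
    """Per-class mean +/- SEM of corrected bead means at each time point."""
    by_well = {tr.well_id: tr for tr in trajectories}
    rows = []
    for prof in profiles:
        tr = by_well[prof.well_id]
        for k, t in enumerate(tr.time_points_h):
            corrected = np.clip(np.asarray(tr.bead_pixels[k], float)
                                - tr.background_estimates[k], 0, None)
            rows.append({"kinetic_class": prof.kinetic_class, "time_h": t,
                         "bead_mean": corrected.mean()})
    df = pd.DataFrame(rows)
    out = (df.groupby(["kinetic_class", "time_h"])["bead_mean"]
             .agg(mean="mean", sem=lambda v: (v.std(ddof=1) / np.sqrt(len(v))
                                              if len(v) > 1 else 0.0),
                  n="size")
             .reset_index())
    return out


def profiles_frame(profiles: list[KineticProfile]) -> pd.DataFrame:
    return pd.DataFrame([{
        "well_id": f"{p.well_id[0]},{p.well_id[1]}",
        "events": "".join(str(int(e)) for e in p.event_vector),
        "p_values": ";".join(f"{v:.3g}" for v in p.interval_p_values),
        "kinetic_class": p.kinetic_class} for p in profiles])
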