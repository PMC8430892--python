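"""Synthetic data generators for the nanowell EV-secretion assay and for
expression/survival cohorts.

The image generator emulates a nanowell array in which cells and
antibody-coated capture beads are co-loaded by Poisson statistics, the array
is imaged at t = 0 and then every two hours, and secreted extracellular
vesicles (EVs) accumulate detection-antibody fluorescence on the bead surface.
Each cell belongs to one of four kinetic classes:

* ``continuous``  — secretes in every inter-time-point interval,
* ``early_stop``  — secretes only in the first (0–2 h) interval,
* ``delayed``     — silent in the first interval, secretes afterwards,
* ``nonsecretor`` — never secretes.

Noise-free bead intensity in the detection channel at time ``t`` is
``background_level + capture_efficiency * secretion_rate * (active hours up
to t)``; cells carry a constant surface-stain level in the same channel.
Additive Gaussian pixel noise (clipped at zero) is drawn independently per
frame.

The cohort generator emulates a two-group patient cohort: signature genes are
up-regulated by a configurable linear fold change in the high group, and
survival is exponential with a configurable hazard ratio (high vs low) and
independent exponential censoring.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

KINETIC_CLASSES = ("continuous", "early_stop", "delayed", "nonsecretor")

#: Default gene names for the EV-secretion signature (synthetic placeholders
#: drawn from ESCRT / ALIX-syndecan-syntenin / tetraspanin vocabulary).
DEFAULT_SIGNATURE_GENES = (
    "CD81", "CD63", "CD9", "PDCD6IP", "SDCBP", "SDC1", "RAB27A",
    "RAB27B", "RAB7A", "TSG101", "VPS4A", "STAM", "HGS",
)


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArrayConfig:
    """Geometry, loading and noise parameters of a simulated nanowell array.

    Defaults give the full 96 x 96 = 9216-well chip imaged at 0/2/4/6 h with
    mean occupancy 0.3 cells and 0.3 beads per well.  Pixel geometry is an
    artifact choice (the assay's magnification is not modelled): wells are
    ``well_size_px`` x ``well_size_px`` interiors on a ``well_pitch_px`` grid,
    separated by septum pixels.
    """

    n_rows: int = 96
    n_cols: int = 96
    well_pitch_px: int = 30
    well_size_px: int = 24
    channels: tuple[str, ...] = ("cell", "bead", "detection")
    time_points_h: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0)
    cell_load_rate: float = 0.3
    bead_load_rate: float = 0.3
    bead_diameter_px: int = 6
    cell_diameter_px_range: tuple[int, int] = (7, 11)
    noise_sd: float = 2.0
    background_level: float = 100.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows * self.n_cols < 1:
            raise ValueError("array must contain at least one well")
        tp = np.asarray(self.time_points_h, dtype=float)
        if tp[0] != 0 or np.any(np.diff(tp) <= 0):
            raise ValueError("time_points_h must start at 0 and be strictly increasing")
        if self.cell_load_rate < 0 or self.bead_load_rate < 0:
            raise ValueError("load rates must be >= 0")
        if self.well_size_px > self.well_pitch_px:
            raise ValueError("well_size_px cannot exceed well_pitch_px")
        if self.bead_diameter_px >= self.well_size_px:
            raise ValueError("bead diameter must be smaller than the well")
        if max(self.cell_diameter_px_range) >= self.well_size_px:
            raise ValueError("cell diameters must be smaller than the well")

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def image_shape(self) -> tuple[int, int]:
        return (self.n_rows * self.well_pitch_px, self.n_cols * self.well_pitch_px)

    @property
    def well_margin_px(self) -> int:
        """Offset of the well interior from the pitch-cell origin."""
        return (self.well_pitch_px - self.well_size_px) // 2

    def well_interior(self, well_id: tuple[int, int]) -> tuple[int, int, int, int]:
        """Half-open bounding box ``(r0, c0, r1, c1)`` of a well interior."""
        i, j = well_id
        m = self.well_margin_px
        r0 = i * self.well_pitch_px + m
        c0 = j * self.well_pitch_px + m
        return (r0, c0, r0 + self.well_size_px, c0 + self.well_size_px)


@dataclass(frozen=True)
class SecretionModel:
    """Kinetic behaviour of one cell.

    ``activity_windows`` holds the indices of the inter-time-point intervals
    (0 = first interval) during which the cell actively secretes; it is
    derived from ``kinetic_class`` unless given explicitly.
    """

    kinetic_class: str = "nonsecretor"
    secretion_rate: float = 30.0      # bead intensity units per active hour
    cell_stain_level: float = 25.0    # detection-channel stain on the cell body
    capture_efficiency: float = 1.0   # scales secretion_rate (pan vs subset assays)
    activity_windows: frozenset[int] | None = None

    def windows(self, n_intervals: int) -> frozenset[int]:
        if self.activity_windows is not None:
            return self.activity_windows
        if self.kinetic_class == "continuous":
            return frozenset(range(n_intervals))
        if self.kinetic_class == "early_stop":
            return frozenset({0})
        if self.kinetic_class == "delayed":
            return frozenset(range(1, n_intervals))
        if self.kinetic_class == "nonsecretor":
            return frozenset()
        raise ValueError(f"unknown kinetic class {self.kinetic_class!r}")

    def active_hours(self, time_points_h: tuple[float, ...]) -> np.ndarray:
        """Cumulative active hours at each acquisition time."""
        tp = np.asarray(time_points_h, dtype=float)
        windows = self.windows(len(tp) - 1)
        hours = np.zeros_like(tp)
        for k in range(len(tp) - 1):
            dt = tp[k + 1] - tp[k] if k in windows else 0.0
            hours[k + 1] = hours[k] + dt
        return hours

    def true_bead_signal(self, time_points_h: tuple[float, ...]) -> np.ndarray:
        """Noise-free bead accumulation (above background) at each time point."""
        if self.kinetic_class == "nonsecretor":
            return np.zeros(len(time_points_h))
        rate = self.capture_efficiency * self.secretion_rate
        return rate * self.active_hours(time_points_h)


@dataclass
class ObjectTruth:
    """Ground truth for one rendered object (static across time points)."""

    kind: str                      # "cell" or "bead"
    well_id: tuple[int, int]
    centroid: tuple[float, float]  # mask centroid, (row, col)
    pixels: np.ndarray             # (n, 2) int array of (row, col)
    model: SecretionModel | None = None  # cells only


@dataclass
class WellTruth:
    cell_count: int
    bead_count: int
    cells: list[ObjectTruth] = field(default_factory=list)
    beads: list[ObjectTruth] = field(default_factory=list)
    true_bead_intensity: np.ndarray | None = None  # noise-free, incl. background


@dataclass
class GroundTruth:
    config: ArrayConfig
    wells: dict[tuple[int, int], WellTruth]

    def occupancy_table(self) -> pd.DataFrame:
        rows = [
            {"well_row": w[0], "well_col": w[1],
             "cell_count": t.cell_count, "bead_count": t.bead_count}
            for w, t in self.wells.items()
        ]
        return pd.DataFrame(rows)

    def single_single_wells(self) -> set[tuple[int, int]]:
        return {w for w, t in self.wells.items()
                if t.cell_count == 1 and t.bead_count == 1}


@dataclass
class ArrayFrame:
    """One time point's multi-channel image of the whole array."""

    time_h: float
    channels: dict[str, np.ndarray]
    config: ArrayConfig

    def channel(self, role: str) -> np.ndarray:
        return self.channels[role]


# ---------------------------------------------------------------------------
# array simulation
# ---------------------------------------------------------------------------

#: Rendered intensity of object bodies in their dedicated label channels.
LABEL_LEVEL = 500.0

def draw_well_occupancy(config: ArrayConfig, rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray]:
    """i.i.d. Poisson cell and bead counts per well, shape (n_rows, n_cols)."""
    shape = (config.n_rows, config.n_cols)
    cells = rng.poisson(config.cell_load_rate, size=shape)
    beads = rng.poisson(config.bead_load_rate, size=shape)
    return cells, beads


def _try_place(config: ArrayConfig, well_id: tuple[int, int], radii: list[float],
               rng: np.random.Generator) -> list[tuple[float, float]] | None:
    """One greedy attempt at non-touching centers inside a well interior.

    Same-kind objects must stay disjoint (with a >1.5 px boundary gap) so
    4-connected components resolve them; across kinds overlap is allowed
    (bead pixels win the detection mask).
    """
    r0, c0, r1, c1 = config.well_interior(well_id)
    centers: list[tuple[float, float]] = []
    for k, r in enumerate(radii):
        lo_r, hi_r = r0 + r + 1, r1 - r - 2
        lo_c, hi_c = c0 + r + 1, c1 - r - 2
        if hi_r < lo_r or hi_c < lo_c:
            raise ValueError("object does not fit in the well interior")
        for _ in range(100):
            cr = rng.uniform(lo_r, hi_r)
            cc = rng.uniform(lo_c, hi_c)
            if all(np.hypot(cr - pr, cc - pc) > r + radii[m] + 1.5
                   for m, (pr, pc) in enumerate(centers)):
                centers.append((cr, cc))
                break
        else:
            return None
    return centers


def _place_objects(config: ArrayConfig, well_id: tuple[int, int], radii: list[float],
                   rng: np.random.Generator) -> list[tuple[float, float]]:
    """Non-touching centers via repeated greedy attempts, largest first."""
    order = np.argsort(radii)[::-1]
    sorted_radii = [radii[k] for k in order]
    for _ in range(60):
        placed = _try_place(config, well_id, sorted_radii, rng)
        if placed is not None:
            centers = [None] * len(radii)
            for pos, k in enumerate(order):
                centers[k] = placed[pos]
            return centers
    raise ValueError(
        f"could not place {len(radii)} disjoint objects in well {well_id}; "
        "enlarge well_size_px or lower load rates")


def simulate_array(config: ArrayConfig,
                   class_mix: dict[str, float] | None = None,
                   rate_params: SecretionModel | None = None,
                   ) -> tuple[list[ArrayFrame], GroundTruth]:
    """Render one multi-channel frame per time point plus full ground truth.

    ``class_mix`` gives the kinetic-class proportions assigned to cells
    (default: 20% continuous, 10% early-stop, 10% delayed, 60% nonsecretor —
    a 40% overall secretor fraction with continuous as the major secretor
    class).  ``rate_params`` supplies the shared rate / stain / capture
    efficiency; its ``kinetic_class`` field is ignored.
    """
    if class_mix is None:
        class_mix = {"continuous": 0.2, "early_stop": 0.1,
                     "delayed": 0.1, "nonsecretor": 0.6}
    if rate_params is None:
        rate_params = SecretionModel()
    probs = np.array([class_mix.get(k, 0.0) for k in KINETIC_CLASSES], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    unknown = set(class_mix) - set(KINETIC_CLASSES)
    if unknown:
        raise ValueError(f"unknown kinetic classes in class_mix: {sorted(unknown)}")

    rng = np.random.default_rng(config.rng_seed)
    cell_counts, bead_counts = draw_well_occupancy(config, rng)
    tp = tuple(config.time_points_h)
    shape = config.image_shape

    cell_base = np.zeros(shape, dtype=np.float32)
    bead_base = np.zeros(shape, dtype=np.float32)
    cell_stain = np.zeros(shape, dtype=np.float32)   # detection-channel stain
    bead_rows: list[np.ndarray] = []                 # per-bead-well pixel indices
    wells: dict[tuple[int, int], WellTruth] = {}

    # per-well bead accumulation over time (noise-free, above background)
    bead_signal: dict[tuple[int, int], np.ndarray] = {}

    d_lo, d_hi = config.cell_diameter_px_range
    bead_r = config.bead_diameter_px / 2.0

    for i in range(config.n_rows):
        for j in range(config.n_cols):
            wid = (i, j)
            nc, nb = int(cell_counts[i, j]), int(bead_counts[i, j])
            truth = WellTruth(cell_count=nc, bead_count=nb)

            # crowded wells re-draw progressively smaller diameters so the
            # objects stay disjoint; such wells are excluded from analysis
            # (not single-cell/single-bead), so this does not bias results
            cell_axes: list[tuple[float, float]] = []
            cell_centers: list[tuple[float, float]] = []
            for shrink in range(5):
                hi = d_hi - shrink * (d_hi - d_lo) / 4.0
                cell_axes = [(rng.uniform(d_lo, hi) / 2.0,
                              rng.uniform(d_lo, hi) / 2.0) for _ in range(nc)]
                try:
                    cell_centers = _place_objects(
                        config, wid, [max(a) for a in cell_axes], rng)
                    break
                except ValueError:
                    if shrink == 4:
                        raise
            bead_centers = _place_objects(config, wid, [bead_r] * nb, rng)

            signal = np.zeros(len(tp))
            for (cr, cc), (a, b) in zip(cell_centers, cell_axes):
                rr, ccx = draw_ellipse(cr, cc, a, b, shape=shape,
                                       rotation=rng.uniform(0, np.pi))
                pix = np.column_stack([rr, ccx])
                cell_base[rr, ccx] = LABEL_LEVEL
                klass = KINETIC_CLASSES[rng.choice(len(KINETIC_CLASSES), p=probs)]
                model = dataclasses.replace(rate_params, kinetic_class=klass,
                                            activity_windows=None)
                cell_stain[rr, ccx] = model.cell_stain_level
                truth.cells.append(ObjectTruth(
                    kind="cell", well_id=wid,
                    centroid=(float(rr.mean()), float(ccx.mean())),
                    pixels=pix, model=model))
                signal += model.true_bead_signal(tp)
            for (cr, cc) in bead_centers:
                rr, ccx = draw_disk((cr, cc), bead_r, shape=shape)
                bead_base[rr, ccx] = LABEL_LEVEL
                truth.beads.append(ObjectTruth(
                    kind="bead", well_id=wid,
                    centroid=(float(rr.mean()), float(ccx.mean())),
                    pixels=np.column_stack([rr, ccx]), model=None))
                bead_rows.append(np.column_stack([rr, ccx]))

            truth.true_bead_intensity = config.background_level + signal
            bead_signal[wid] = signal
            wells[wid] = truth

    # bead pixel index arrays grouped by well for fast accumulation painting
    frames: list[ArrayFrame] = []
    for k, t in enumerate(tp):
        det = np.full(shape, config.background_level, dtype=np.float32)
        det += cell_stain
        for wid, truth in wells.items():
            sig = bead_signal[wid][k]
            for bead in truth.beads:
                det[bead.pixels[:, 0], bead.pixels[:, 1]] = (
                    config.background_level + sig)
        channels = {}
        for role, base in (("cell", cell_base), ("bead", bead_base),
                           ("detection", det)):
            img = base.copy()
            if config.noise_sd > 0:
                img = img + rng.normal(0.0, config.noise_sd,
                                       size=shape).astype(np.float32)
                np.clip(img, 0.0, None, out=img)
            channels[role] = img
        frames.append(ArrayFrame(time_h=float(t), channels=channels, config=config))

    return frames, GroundTruth(config=config, wells=wells)


# ---------------------------------------------------------------------------
# trajectory-level fast path
# ---------------------------------------------------------------------------

def simulate_well_trajectories(n_wells: int,
                               model: SecretionModel | None = None,
                               class_mix: dict[str, float] | None = None,
                               time_points_h: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0),
                               n_bead_px: int = 28,
                               n_cell_px: int = 60,
                               n_background_px: int = 488,
                               background_level: float = 100.0,
                               noise_sd: float = 2.0,
                               rng: np.random.Generator | int | None = 0,
                               ):
    """Draw per-well pixel samples directly, skipping image rendering.

    Statistically identical to extracting trajectories from rendered
    single-cell/single-bead wells (same additive-Gaussian pixel model,
    clipped at zero), but O(pixels-per-well) instead of O(image).  Used for
    large-scale calibration: type-I error, power, and contrast recovery.
    Default pixel counts mirror the renderer's default geometry: a 6 px bead
    disc (~28 px), a 7-11 px cell ellipse (~60 px) and the free interior of
    a 24 px well (~488 px) for the background median.

    Returns ``(trajectories, classes)`` where ``trajectories`` is a list of
    :class:`evwell.census_filter.WellTrajectory` and ``classes`` the
    ground-truth kinetic class per well.
    """
    from .census_filter import WellTrajectory

    if model is None:
        model = SecretionModel()
    if class_mix is None:
        class_mix = {model.kinetic_class: 1.0}
    probs = np.array([class_mix.get(k, 0.0) for k in KINETIC_CLASSES])
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    tp = tuple(float(t) for t in time_points_h)
    trajectories, classes = [], []
    for w in range(n_wells):
        klass = KINETIC_CLASSES[rng.choice(len(KINETIC_CLASSES), p=probs)]
        m = dataclasses.replace(model, kinetic_class=klass, activity_windows=None)
        signal = m.true_bead_signal(tp)
        bead_px, cell_px, bg = [], [], []
        for k in range(len(tp)):
            b = background_level + signal[k] + rng.normal(0, noise_sd, n_bead_px)
            c = (background_level + m.cell_stain_level
                 + rng.normal(0, noise_sd, n_cell_px))
            g = background_level + rng.normal(0, noise_sd, n_background_px)
            bead_px.append(np.clip(b, 0, None))
            cell_px.append(np.clip(c, 0, None))
            bg.append(float(np.median(np.clip(g, 0, None))))
        trajectories.append(WellTrajectory(
            well_id=(w, 0), time_points_h=tp, bead_pixels=bead_px,
            cell_pixels=cell_px, background_estimates=bg, complete=True))
        classes.append(klass)
    return trajectories, classes


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Two-latent-group expression + survival cohort.

    Defaults mirror the non-metastatic breast-cancer analysis scale: 450
    patients, a 13-gene EV-secretion signature up-regulated 1.2-fold in the
    high group, exponential survival with a 10.8-year median in the low group
    (baseline hazard ln2/10.8 per year) and hazard ratio 0.4 (high vs low).
    """

    n_samples: int = 450
    n_genes: int = 100
    signature_genes: tuple[str, ...] = DEFAULT_SIGNATURE_GENES
    signature_fold_change: float = 1.2
    group_fraction: float = 0.5
    baseline_hazard: float = float(np.log(2) / 10.8)  # per year, low group
    hazard_ratio: float = 0.4                          # high vs low
    censor_rate: float = 0.03                          # per year, exponential
    dispersion: float = 0.2                            # log-normal sigma
    baseline_expression: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if not 0 < self.group_fraction < 1:
            raise ValueError("group_fraction must be in (0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if self.n_genes < len(self.signature_genes) + 2:
            raise ValueError("n_genes too small for the signature plus GZMA/PRF1")


def simulate_cohort(config: CohortConfig):
    """Generate expression and survival tables with planted structure.

    Returns a :class:`evwell.signature.CohortTables`.  Gene universe: the
    signature genes, GZMA and PRF1 (cytolytic score), then filler genes
    ``G0001``...  Expression value = gene baseline x group fold change x
    LogNormal(-sigma^2/2, sigma) (multiplicative noise with unit mean).
    Survival: exponential with hazard ``baseline_hazard`` (low group) or
    ``baseline_hazard * hazard_ratio`` (high group); censoring time is an
    independent exponential with rate ``censor_rate``.
    """
    from .signature import CohortTables

    rng = np.random.default_rng(config.rng_seed)
    named = list(config.signature_genes) + ["GZMA", "PRF1"]
    n_fill = config.n_genes - len(named)
    genes = named + [f"G{k:04d}" for k in range(1, n_fill + 1)]
    samples = [f"S{k:04d}" for k in range(1, config.n_samples + 1)]

    n_high = int(round(config.group_fraction * config.n_samples))
    group = np.zeros(config.n_samples, dtype=int)
    group[rng.permutation(config.n_samples)[:n_high]] = 1  # 1 = high

    base = config.baseline_expression * np.exp(
        rng.normal(0.0, 0.5, size=config.n_genes))  # gene-specific baselines
    fc = np.ones((config.n_samples, config.n_genes))
    sig_idx = [genes.index(g) for g in config.signature_genes]
    fc[np.ix_(group == 1, sig_idx)] = config.signature_fold_change

    sigma = config.dispersion
    noise = np.exp(rng.normal(-sigma ** 2 / 2.0, sigma,
                              size=(config.n_samples, config.n_genes)))
    expr = pd.DataFrame(base[None, :] * fc * noise, index=samples, columns=genes)

    hazard = np.where(group == 1,
                      config.baseline_hazard * config.hazard_ratio,
                      config.baseline_hazard)
    t_event = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        t_cens = rng.exponential(1.0 / config.censor_rate, size=config.n_samples)
    else:
        t_cens = np.full(config.n_samples, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    survival = pd.DataFrame({
        "sample_id": samples,
        "time": time,
        "event": event,
        "group": np.where(group == 1, "high", "low"),
    })

    labels = pd.Series(np.where(group == 1, "high", "low"), index=samples)
    return CohortTables(expression=expr, survival=survival,
                        cluster_labels=labels,
                        candidate_genes=tuple(genes))


# ---------------------------------------------------------------------------
# on-disk interfaces
# ---------------------------------------------------------------------------

def write_array(frames: list[ArrayFrame], truth: GroundTruth, out_dir: str | Path
                ) -> None:
    """Write per-time-point multi-page TIFFs, ground-truth JSON and config JSON."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = truth.config
    for frame in frames:
        stack = np.stack([frame.channels[c] for c in cfg.channels])
        tifffile.imwrite(out / f"t{frame.time_h:04.1f}h.tiff", stack,
                         photometric="minisblack")
    gt = {
        f"{i},{j}": {
            "cell_count": t.cell_count,
            "bead_count": t.bead_count,
            "true_bead_intensity": list(map(float, t.true_bead_intensity)),
            "cells": [{"centroid": o.centroid, "n_px": len(o.pixels),
                       "kinetic_class": o.model.kinetic_class} for o in t.cells],
            "beads": [{"centroid": o.centroid, "n_px": len(o.pixels)}
                      for o in t.beads],
        }
        for (i, j), t in truth.wells.items()
    }
    (out / "ground_truth.json").write_text(json.dumps(gt))
    (out / "config.json").write_text(json.dumps(dataclasses.asdict(cfg)))


def read_array(in_dir: str | Path) -> list[ArrayFrame]:
    """Re-read frames written by :func:`write_array` (TIFF + config JSON)."""
    import tifffile

    src = Path(in_dir)
    cfg_dict = json.loads((src / "config.json").read_text())
    for key in ("channels", "time_points_h", "cell_diameter_px_range"):
        cfg_dict[key] = tuple(cfg_dict[key])
    cfg = ArrayConfig(**cfg_dict)
    frames = []
    for t in cfg.time_points_h:
        stack = tifffile.imread(src / f"t{t:04.1f}h.tiff")
        channels = {role: stack[k] for k, role in enumerate(cfg.channels)}
        frames.append(ArrayFrame(time_h=float(t), channels=channels, config=cfg))
    return frames


def write_cohort(tables, out_dir: str | Path) -> None:
    """Expression as samples x genes TSV; survival as TSV (sample_id, time, event, group)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables.expression.to_csv(out / "expression.tsv", sep="\t")
    tables.survival.to_csv(out / "survival.tsv", sep="\t", index=False)
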