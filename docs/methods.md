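# Methods

## The assay model

A nanowell array is a grid of `n_rows x n_cols` open wells (default
96 x 96 = 9216). Cells and antibody-coated capture beads are loaded by
gravity, so per-well counts are independent Poisson draws with means
`cell_load_rate` and `bead_load_rate` (default 0.3 each — sparse loading
that maximizes informative single-cell/single-bead wells without
multi-occupancy). The array is imaged at t = 0 (pre-secretion baseline) and
then every two hours (default 0/2/4/6 h); each acquisition yields three
channels: a cell label, a bead label, and the EV-detection channel.

Each cell carries one of four kinetic behaviours over the inter-time-point
intervals:

| class        | active intervals (0–2, 2–4, 4–6 h) |
|--------------|-------------------------------------|
| continuous   | all                                 |
| early_stop   | first only                          |
| delayed      | all but the first                   |
| nonsecretor  | none                                |

Noise-free bead intensity in the detection channel is

    I_bead(t) = background_level + capture_efficiency * secretion_rate * A(t)

where `A(t)` is the cumulative active hours up to t. Cells carry a constant
`cell_stain_level` on their body in the same channel (their own surface
staining — the *reference* the secretor test compares against).
`capture_efficiency` is a scalar on the accumulation rate so that a
pan-tetraspanin vs single-pair (subset) assay contrast, e.g. 4:1, is a
one-parameter configuration.

Rendering: beads are filled discs of fixed diameter (default 6 px) in the
bead channel; cells are rotated ellipses with axes drawn uniformly from
`cell_diameter_px_range` (default 7–11 px) in the cell channel. Same-kind
objects in one well are placed disjoint (rejection sampling with full-well
restarts, largest first; crowded wells re-draw progressively smaller
diameters from the configured range — such wells are excluded from analysis
anyway, so this affects only occupancy realism, not results). Where a cell
and a bead overlap, overlap pixels belong to the bead mask; the cell's
"non-overlapped" pixels are cell minus bead. Pixel noise is additive
Gaussian (default σ = 2 intensity units on a background of 100), redrawn
per frame, clipped at 0. Object masks are static across time: wells are
immobile and within-well cell motion is out of scope, so time-lapse
identity is by well id alone.

The default kinetic mix is 20% continuous, 10% early-stop, 10% delayed,
60% non-secretor: a 40% overall secretor fraction with continuous as the
major secretor class.

### Geometry defaults

The pixel geometry (30 px pitch, 24 px well interior) is an artifact
choice — the physical assay's magnification is not part of the model. It
was set once so that (a) up to ~4 objects fit disjointly in a well and
(b) a full 9216-well array renders in seconds; all of it is exposed in
`ArrayConfig`.

### The trajectory fast path

`simulate_well_trajectories` draws per-well pixel samples directly from the
same statistical model the renderer uses (bead/cell/background Gaussians,
clip at 0, median background estimate), with pixel counts matched to the
rendered geometry (28 bead px, 60 cell px, 488 free interior px). It exists
because calibration checks need thousands of single-cell wells, and at
Poisson(0.3) loading only ~5% of rendered wells qualify. The image route is
exercised end-to-end by the segmentation and occupancy tests; a green
calibration test therefore establishes the statistics of the *calling*
stages, not the segmenter — the segmenter has its own exact-recovery tests.

## Segmentation

Otsu threshold on the object's label channel, 4-connected components
clipped to well interiors (so touching-but-distinct wells can never merge
objects), then gates: beads keep components with area within ±30% of the
configured disc area and circularity (4π·area/perimeter², Crofton
perimeter) ≥ 0.8; cells have only a generous area gate (pleomorphic).
Because the threshold is histogram-derived and the gates are
intensity-free, segmentation is invariant under a constant intensity offset.
A constant channel is either empty (value 0 → no objects) or unusable
(saturated → error). On noise-only blank channels, a separation heuristic
(foreground mean must exceed the rest by 6 background SDs) rejects Otsu's
spurious split of the noise histogram.

Well assignment: an object belongs to the unique well whose half-open
interior box contains its centroid; centroids on the septum stay
unassigned. Coordinates are (row, col), 0-based.

## Secretor calling

Per analyzable well (one cell + one bead at *every* time point, including
t = 0) and per time point t > 0:

1. background = median detection intensity over well-interior pixels
   outside all object masks (robust, local, deterministic);
2. subtract it from bead and cell pixels, clip at 0;
3. Welch two-sample t-test, two-tailed, bead vs non-overlapped cell pixels;
4. label `secretor` iff p < α (default 0.01) *and*
   mean(bead) − mean(cell) > min_effect (default 0).

Welch rather than pooled because bead and cell pixel variances have no
reason to match. Degenerate conventions: both samples constant and equal
→ p = 1; constant and unequal → p = 0. Labels are per time point — a cell
can be non-secretor at 2 h and secretor at 6 h; population frequencies are
reported per time point with binomial SE. Cross-population intensity
comparisons use the two-sided Mann–Whitney test (exact for n ≤ 20) on
corrected bead means.

## Kinetic classes

For each consecutive time-point pair, an *event* is a mean increase in
corrected bead pixels with two-tailed Welch p < 0.01 (the test is
two-tailed, the direction rule one-sided, so the null event rate is ≈ α/2).
The event vector maps to classes: first-interval event with any later event
→ continuous; first only → early_stop; no first but any later → delayed;
none → non_secretor. Finer patterns (e.g. [0,1,0], delayed-then-stop) fold
into the three primary classes but keep their raw vector in `sub_pattern`.
The baseline for the first comparison is the t = 0 frame.

## Cohort stage

The cohort generator plants two latent groups (default 50/50 over 450
samples): signature genes (13 by default) are multiplied by
`signature_fold_change` in the high group; every expression value is
gene-baseline x fold x LogNormal(−σ²/2, σ) (unit-mean multiplicative noise,
σ = 0.2). Survival is exponential — low-group hazard ln 2 / 10.8 per year
(a 10.8-year median) and high-group hazard scaled by `hazard_ratio`
(default 0.4) — with independent exponential censoring (0.03/yr).

Analysis: fold change on linear-scale means (a log-scale switch exists),
strict inequality at the threshold; EV score = per-sample median of
signature-gene expression; median split with ties assigned to Lo; cytolytic
score = √((GZMA+0.01)(PRF1+0.01)); survival comparison = Kaplan–Meier
curves (lifelines) + native log-rank O/E/V accounting over shared event
times + Pike O/E hazard ratio with log-scale CI. The O/E estimator is
mildly attenuated for HRs far from 1 but stays well inside a ±10% log-bias
at HR 0.4, n = 450 (verified by simulation in the acceptance suite); a
regression HR could be slotted in behind the same contract. Cluster labels
are an input — how the two patient clusters were obtained (unsupervised
clustering of an external tumor cohort) is out of scope.

The 13 default signature gene names are placeholders drawn from the
ESCRT/ALIX–syndecan–syntenin and tetraspanin vocabulary; the signature gene
list is always an explicit input to the analysis functions.

## Numerical choices and known limitations

* **Clipping bias.** Corrected pixels are clipped at 0, so a zero-signal
  compartment's mean is biased up by ≈ σ/√(2π). This affects only displays
  of near-zero trends (the t = 0 point of trend lines), not the paired
  tests, which compare compartments corrected by the same background.
* **Background-estimate noise.** The per-frame background median is a
  common offset on all corrected pixels of that frame; the t-test treats
  pixels as independent, so consecutive-frame event tests run slightly
  anti-conservative. With the rendered geometry (≈488 free background
  pixels per well) the null event rate stays below the α/2 + 3 SE band;
  with much smaller wells it would not.
* **Welch vs exact permutation.** For group sizes ≤ 8 the full-enumeration
  permutation p (mid-p convention) and the Welch p agree in the rejection
  tail but diverge at moderate p — at n = 4 the permutation support
  granularity alone is 2/70 ≈ 0.029. The suite asserts tail agreement;
  instance-wise agreement within ±0.02 at these sizes is not a property
  these tests have.
* **What green tests establish.** The generators emulate the statistical
  structure the pipeline assumes (Poisson loading, linear accumulation,
  Gaussian noise, log-normal expression, exponential survival). They do not
  emulate optics (PSF, photobleaching, drift), bead-binding chemistry,
  segmentation pathologies of real micrographs, or real transcriptome
  covariance — recovery rates measured here are upper bounds on real-data
  performance.
* **Exclusions are strict.** Any frame where a well's census deviates from
  one cell + one bead (division, dropout) excludes the well; no
  interpolation.
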