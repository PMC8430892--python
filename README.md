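# evwell

Single-cell analysis of extracellular-vesicle (EV) secretion from nanowell
time-lapse assays, plus the downstream cohort-level EV-signature survival
analysis.

## The problem

Bulk EV assays average over millions of cells and cannot say *which* cells
secrete, *how much*, or *when*. In the nanowell assay, single cells are
co-loaded with antibody-functionalized capture beads into thousands of
sub-nanoliter wells; secreted EVs bind the bead, and a fluorescent detection
antibody read out every two hours turns each bead into a per-cell secretion
reporter. `evwell` implements the computational side of that assay for
people who run or study it:

* **simulate** — synthetic multi-channel image stacks of a nanowell array
  with full ground truth (Poisson co-loading, three secretion kinetic
  classes, additive imaging noise), and synthetic expression/survival
  cohorts with planted group structure;
* **segment** — Otsu + 4-connected components + area/circularity gates to
  detect cells and beads and assign them to wells;
* **census_filter** — selection of wells with exactly one cell and one bead
  at every time point, and assembly of their pixel trajectories;
* **secretion** — per-cell secretor calls: background-corrected bead pixels
  vs the cell's own non-overlapped pixels, two-tailed Welch *t*-test at
  α = 0.01 with a positive bead−cell effect required;
* **kinetics** — per-interval secretion events (consecutive-time-point
  Welch test, increase + *p* < 0.01) mapped to kinetic classes:
  *continuous*, *early-stop*, *delayed*, *non-secretor*;
* **signature** — cohort stage: EV gene signature by linear fold change
  > 1.2 between two clusters, per-sample EV score (median signature
  expression), median-split stratification, GZMA/PRF1 cytolytic score, and
  Kaplan–Meier / log-rank survival comparison with the O/E (Pike) hazard
  ratio: HR = (O_Hi/E_Hi)/(O_Lo/E_Lo), se(log HR) = √(1/E_Hi + 1/E_Lo).

## Worked example

The `analysis/` scripts run the whole chain on synthetic data (seconds
each). `01` renders a 1024-well array and writes it to `scratch/array/`;
`02`–`04` segment it, select analyzable wells, and call secretors and
kinetic classes; `05` checks the pan-vs-subset capture contrast; `06` runs
the cohort stage.

```text
$ python analysis/01_simulate_array.py
simulated 1024 wells at 0/2/4/6 h -> scratch/array
single-cell/single-bead fraction: 0.0498 (Poisson product predicts 0.0494)

$ python analysis/02_segment_census.py
objects per frame: {0.0: 622, 2.0: 622, 4.0: 622, 6.0: 622}
single-cell/single-bead wells complete at all time points: 51 of 1024

$ python analysis/03_secretion_calls.py
t = 2 h: secretor frequency 0.275 +/- 0.062
t = 4 h: secretor frequency 0.373 +/- 0.068
t = 6 h: secretor frequency 0.373 +/- 0.068

$ python analysis/04_kinetics.py
called classes: {'non_secretor': 31, 'continuous': 8, 'delayed': 6, 'early_stop': 6}
true classes:   {'non_secretor': 32, 'continuous': 8, 'delayed': 5, 'early_stop': 6}
agreement: 50/51 (98.0%)

$ python analysis/06_cohort_signature.py
signature (FC > 1.2): 13 genes (planted: 13)
median-split strata recover planted groups: accuracy 0.987
log-rank chi2 87.4 (p = 8.8e-21); HR 0.32 [0.25, 0.42] (true 0.4)
```

Reading the numbers: the 1024-well occupancy reproduces the Poisson
co-loading product; 51 wells carry exactly one cell and one bead through
all four frames and are analyzable; of those, 37% are called secretors by
6 h (the simulated mix plants 40% secretor classes, with the delayed class
only reaching significance from 4 h — hence the rise from 27%); kinetic
classes agree with ground truth for 50/51 wells. In the cohort arm the
13 planted signature genes are recovered exactly, the median split of the
EV score reconstructs the latent groups at 98.7% accuracy, and the EV-high
stratum shows the planted survival advantage (true hazard ratio 0.4; a
single cohort's estimate scatters around it).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs both arms of the pipeline from scratch with the given seed —
array simulation through kinetic profiling, and cohort simulation through
survival comparison — printing a run log and writing the results JSON.
Property-level guarantees (occupancy statistics, exact segmentation on
noiseless frames, test calibration, class recovery, contrast and
hazard-ratio recovery) live in `tests/test_acceptance.py`.

## Layout

```
src/evwell/   library: simulate, segment, census_filter, secretion,
              kinetics, signature
analysis/     numbered narrative drivers writing tables to results/
tests/        pytest suite (unit + property + acceptance)
docs/         methods note
```
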