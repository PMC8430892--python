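"""Pan-EV vs subset-EV assay contrast at 4:1 capture efficiency.

Simulates two assays that differ only in capture efficiency (1.0 for the
pan-tetraspanin cocktail, 0.25 for the single capture/detection pair) and
checks that the ratio of mean background-corrected bead intensities among
secretors at 6 h recovers the configured 4-fold difference.  Uses the
trajectory-level generator (300 wells per arm).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from evwell import secretion, simulate

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 1) -> None:
    arms = {"pan": 1.0, "subset": 0.25}
    means = {}
    for k, (arm, eff) in enumerate(arms.items()):
        model = simulate.SecretionModel(capture_efficiency=eff)
        trajs, _ = simulate.simulate_well_trajectories(
            300, model=model, class_mix={"continuous": 1.0}, rng=seed + k)
        vals = [c.bead_mean_corrected for tr in trajs
                for c in secretion.classify_secretor(tr)
                if c.time_point_h == 6.0]
        means[arm] = float(np.mean(vals))

    ratio = means["pan"] / means["subset"]
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    pd.DataFrame([{"arm": a, "capture_efficiency": arms[a],
                   "mean_bead_intensity_6h": means[a]} for a in arms]).to_csv(
        results / "contrast_pan_subset.tsv", sep="\t", index=False)

    print(f"pan arm mean corrected bead intensity at 6 h:    {means['pan']:.1f}")
    print(f"subset arm mean corrected bead intensity at 6 h: {means['subset']:.1f}")
    print(f"pan:subset ratio {ratio:.2f} (configured 4.0)")
    print(f"wrote {results / 'contrast_pan_subset.tsv'}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    main(**vars(ap.parse_args()))
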