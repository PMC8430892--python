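"""Secretor calling: background correction, Welch test, labels, frequencies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from evwell import secretion, segment, simulate
from evwell.census_filter import WellTrajectory
from evwell.secretion import ClassifierParams, bead_cell_test, classify_secretor
from oracles import perm_welch_p


def _traj(bead_by_t, cell_by_t, bg, tps=(0.0, 2.0, 4.0, 6.0)):
    return WellTrajectory(well_id=(0, 0), time_points_h=tps,
                          bead_pixels=[np.asarray(b, float) for b in bead_by_t],
                          cell_pixels=[np.asarray(c, float) for c in cell_by_t],
                          background_estimates=list(bg))


class TestEstimateBackground:
    def test_exact_on_noiseless_well(self, noiseless_array):
        cfg, frames, truth = noiseless_array
        objs = segment.segment_frame(frames[0])
        wid = next(iter(truth.single_single_wells()))
        bg = secretion.estimate_background(frames[0], wid, objs)
        assert bg == pytest.approx(cfg.background_level)

    def test_median_of_free_pixels(self):
        """{10, 10, 20} -> 10: the estimate is a median, not a mean."""
        cfg = simulate.ArrayConfig(n_rows=1, n_cols=1, well_pitch_px=4,
                                   well_size_px=3, bead_diameter_px=1,
                                   cell_diameter_px_range=(1, 2))
        det = np.zeros((4, 4))
        r0, c0, r1, c1 = cfg.well_interior((0, 0))
        det[r0:r1, c0:c1] = 10.0
        det[r0, c0] = 20.0
        # cover all but three interior pixels with a fake object
        interior = [(r, c) for r in range(r0, r1) for c in range(c0, c1)]
        covered = np.array(interior[3:], int)
        obj = segment.DetectedObject(kind="cell", centroid=(r0, c0),
                                     pixel_set=covered, area_px=len(covered),
                                     circularity=1.0, well_id=(0, 0))
        frame = simulate.ArrayFrame(time_h=0.0, channels={"detection": det},
                                    config=cfg)
        assert secretion.estimate_background(frame, (0, 0), [obj]) == 10.0

    def test_fully_covered_well_is_error(self):
        cfg = simulate.ArrayConfig(n_rows=1, n_cols=1, well_pitch_px=4,
                                   well_size_px=3, bead_diameter_px=1,
                                   cell_diameter_px_range=(1, 2))
        r0, c0, r1, c1 = cfg.well_interior((0, 0))
        allpx = np.array([(r, c) for r in range(r0, r1) for c in range(c0, c1)], int)
        obj = segment.DetectedObject(kind="cell", centroid=(r0, c0),
                                     pixel_set=allpx, area_px=len(allpx),
                                     circularity=1.0, well_id=(0, 0))
        frame = simulate.ArrayFrame(time_h=0.0,
                                    channels={"detection": np.zeros((4, 4))},
                                    config=cfg)
        with pytest.raises(ValueError, match="fully covered"):
            secretion.estimate_background(frame, (0, 0), [obj])

    def test_noisy_estimate_concentrates_on_background(self, rng):
        """Median of n noisy pixels lands within ~3*sigma*sqrt(pi/2n) of truth."""
        B, sd, n = 100.0, 4.0, 400
        cfg = simulate.ArrayConfig(n_rows=1, n_cols=1, well_pitch_px=22,
                                   well_size_px=20)
        det = np.full((22, 22), B) + rng.normal(0, sd, (22, 22))
        frame = simulate.ArrayFrame(time_h=0.0, channels={"detection": det},
                                    config=cfg)
        est = secretion.estimate_background(frame, (0, 0), [])
        assert abs(est - B) < 3 * sd * np.sqrt(np.pi / (2 * n))


class TestBeadCellTest:
    def test_identical_constant_samples_p_one(self):
        t, p = bead_cell_test([5, 5, 5, 6, 6, 6], [5, 5, 5, 6, 6, 6])
        assert p == pytest.approx(1.0)

    def test_constant_unequal_p_zero(self):
        t, p = bead_cell_test([5, 5, 5], [7, 7, 7])
        assert p == 0.0 and t == -np.inf

    def test_affine_invariance(self):
        a = np.array([12.0, 13.0, 14.0, 15.0])
        b = np.array([2.0, 3.0, 4.0, 5.5])
        _, p0 = bead_cell_test(a, b)
        _, p1 = bead_cell_test(2 * a + 7, 2 * b + 7)
        assert p1 == pytest.approx(p0, rel=1e-12)

    @given(scale=st.floats(0.1, 50), shift=st.floats(-100, 100))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_affine_invariance_property(self, scale, shift):
        rng = np.random.default_rng(3)
        a, b = rng.normal(5, 1, 12), rng.normal(4, 1, 9)
        assert bead_cell_test(scale * a + shift, scale * b + shift)[1] == \
            pytest.approx(bead_cell_test(a, b)[1], rel=1e-9)

    def test_too_few_pixels_rejected(self):
        with pytest.raises(ValueError):
            bead_cell_test([1.0], [1.0, 2.0])

    def test_agrees_with_permutation_oracle_in_decision_tail(self, rng):
        """Both tests reject strong effects at alpha = 0.01 and track each
        other closely in the median over random instances."""
        diffs = []
        for _ in range(30):
            n1, n2 = rng.integers(6, 9, 2)
            a = rng.normal(5.0, 1, n1)  # d = 5: decisively non-null
            b = rng.normal(0.0, 1, n2)
            p_w = bead_cell_test(a, b)[1]
            p_perm = perm_welch_p(a, b)
            assert p_w < 0.01 and p_perm < 0.01
            diffs.append(abs(p_w - p_perm))
        assert np.median(diffs) < 0.02


class TestClassifySecretor:
    def test_strong_effect_is_secretor_at_all_later_times(self, rng):
        """Cohen's d = 5 with 50 px per compartment: power ~ 1."""
        bead = [rng.normal(100, 2, 50)] + [rng.normal(120, 2, 50) for _ in range(3)]
        cell = [rng.normal(110, 2, 60) for _ in range(4)]
        tr = _traj(bead, cell, [100.0] * 4)
        calls = classify_secretor(tr)
        assert [c.time_point_h for c in calls] == [2.0, 4.0, 6.0]
        assert all(c.label == "secretor" for c in calls)

    def test_direction_rule_blocks_bright_cells(self, rng):
        """Bead significantly BELOW cell stays non-secretor despite tiny p."""
        bead = [rng.normal(100, 2, 50) for _ in range(4)]
        cell = [rng.normal(120, 2, 60) for _ in range(4)]
        calls = classify_secretor(_traj(bead, cell, [100.0] * 4))
        assert all(c.label == "non_secretor" for c in calls)
        assert all(c.p_value < 0.01 and c.effect_direction < 0 for c in calls)

    def test_type_one_error_calibrated(self):
        """Null wells (rate 0, stain 0): secretor rate <= alpha + 3 SE."""
        model = simulate.SecretionModel(secretion_rate=0.0, cell_stain_level=0.0)
        trajs, _ = simulate.simulate_well_trajectories(600, model=model, rng=8)
        calls = [c for tr in trajs for c in classify_secretor(tr)]
        rate = np.mean([c.label == "secretor" for c in calls])
        alpha = 0.01
        se = np.sqrt(alpha * (1 - alpha) / len(calls))
        assert rate <= alpha + 3 * se

    def test_scale_equivariance_of_labels(self, trajectories):
        """Doubling exposure before correction changes no label."""
        _, trajs = trajectories
        for tr in trajs[:10]:
            doubled = WellTrajectory(
                well_id=tr.well_id, time_points_h=tr.time_points_h,
                bead_pixels=[2 * np.asarray(b) for b in tr.bead_pixels],
                cell_pixels=[2 * np.asarray(c) for c in tr.cell_pixels],
                background_estimates=[2 * g for g in tr.background_estimates])
            l0 = [c.label for c in classify_secretor(tr)]
            l1 = [c.label for c in classify_secretor(doubled)]
            assert l0 == l1

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            ClassifierParams(alpha=1.5)
        with pytest.raises(ValueError):
            ClassifierParams(min_effect=-1)


class TestSecretorFrequency:
    def test_closed_form_proportion_and_se(self):
        calls = [secretion.SecretionCall((i, 0), 2.0, 0.0, 1.0, 0.0, 0.0,
                                         "secretor" if i < 25 else "non_secretor")
                 for i in range(100)]
        f, se = secretion.secretor_frequency(calls, 2.0)
        assert f == 0.25
        assert se == pytest.approx(0.0433, abs=1e-4)

    def test_zero_secretors(self):
        calls = [secretion.SecretionCall((i, 0), 2.0, 0.0, 1.0, 0.0, 0.0,
                                         "non_secretor") for i in range(100)]
        assert secretion.secretor_frequency(calls, 2.0) == (0.0, 0.0)

    def test_recovers_configured_mix(self):
        """40% secretor classes at saturating rate -> frequency ~ 0.40 at 6 h."""
        mix = {"continuous": 0.2, "early_stop": 0.1, "delayed": 0.1,
               "nonsecretor": 0.6}
        model = simulate.SecretionModel(secretion_rate=30.0, cell_stain_level=25.0)
        trajs, _ = simulate.simulate_well_trajectories(
            800, model=model, class_mix=mix, rng=15)
        calls = [c for tr in trajs for c in classify_secretor(tr)]
        f, _ = secretion.secretor_frequency(calls, 6.0)
        se = np.sqrt(0.4 * 0.6 / 800)
        assert abs(f - 0.40) <= 3 * se


class TestCompareIntensityDistributions:
    def test_exact_small_sample_p(self):
        """{1,2,3} vs {4,5,6}: exact two-sided rank-sum p = 0.1."""
        a = [secretion.SecretionCall((i, 0), 6.0, 0, 1, float(v), 0.0, "secretor")
             for i, v in enumerate([1, 2, 3])]
        b = [secretion.SecretionCall((i, 1), 6.0, 0, 1, float(v), 0.0, "secretor")
             for i, v in enumerate([4, 5, 6])]
        assert secretion.compare_intensity_distributions(a, b) == pytest.approx(0.1)

    def test_null_p_uniform(self, rng):
        pvals = []
        for _ in range(60):
            mk = lambda vals: [secretion.SecretionCall((i, 0), 6.0, 0, 1, v, 0.0,
                                                       "secretor")
                               for i, v in enumerate(vals)]
            pvals.append(secretion.compare_intensity_distributions(
                mk(rng.normal(10, 1, 30)), mk(rng.normal(10, 1, 30))))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_fourfold_rate_contrast_detected(self):
        """Rate 4x higher in arm A: p < 0.001 at n = 100 per arm."""
        pan = simulate.SecretionModel(secretion_rate=30.0)
        sub = simulate.SecretionModel(secretion_rate=30.0, capture_efficiency=0.25)
        ta, _ = simulate.simulate_well_trajectories(
            100, model=pan, class_mix={"continuous": 1.0}, rng=21)
        tb, _ = simulate.simulate_well_trajectories(
            100, model=sub, class_mix={"continuous": 1.0}, rng=22)
        ca = [c for tr in ta for c in classify_secretor(tr) if c.time_point_h == 6.0]
        cb = [c for tr in tb for c in classify_secretor(tr) if c.time_point_h == 6.0]
        assert secretion.compare_intensity_distributions(ca, cb) < 0.001
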