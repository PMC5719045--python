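"""Phase transformation, irregularity thresholds, variability statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quadgait.coordination import (IrregularityRule, classify_irregular,
                                   control_threshold, cov, interlimb_phase,
                                   match_stride_changes, per_step_change,
                                   phase_series_from_footfalls,
                                   phase_series_from_swim, poincare,
                                   remove_outliers, swim_phase,
                                   transform_phase)


def _series(phases, animal="a", pass_id="p", condition="control",
            timepoint="baseline", pair="hindlimbs", task="step"):
    n = len(phases)
    return pd.DataFrame({
        "animal_id": animal, "pass_id": pass_id,
        "cycle_index": np.arange(n), "phase": phases,
        "phase_transformed": transform_phase(np.asarray(phases, float)),
        "condition": condition, "timepoint": timepoint,
        "pair": pair, "task": task,
    })


class TestInterlimbPhase:
    def test_midpoint_contact_is_half(self):
        df = interlimb_phase(left_contacts=[0.4], right_contacts=[0.0, 0.8])
        assert df.phase.iloc[0] == pytest.approx(0.5)

    def test_direct_arithmetic(self):
        df = interlimb_phase(left_contacts=[0.2], right_contacts=[0.0, 0.8])
        assert df.phase.iloc[0] == pytest.approx(0.25)

    def test_missed_and_double_contacts_flagged(self):
        df = interlimb_phase(left_contacts=[0.1, 0.2],
                             right_contacts=[0.0, 0.5, 1.0])
        assert df.n_events.tolist() == [2, 0]
        assert df.phase.isna().all()

    def test_zero_length_stride_errors(self):
        with pytest.raises(ValueError):
            interlimb_phase([0.1], [0.5, 0.5])

    def test_tight_trot_circular_mean_near_half(self, control_phases):
        from quadgait.circstats import circular_summary, phase_to_angle
        mu, _ = circular_summary(
            phase_to_angle(control_phases.phase.dropna()))
        assert abs(mu / (2 * np.pi) - 0.5) < 0.02


class TestSwimPhase:
    def test_stroke_arithmetic(self):
        df = swim_phase(left_peaks=[0.5], right_peaks=[0.0, 1.25])
        assert df.phase.iloc[0] == pytest.approx(0.4)

    def test_control_swim_rarely_irregular(self, control_dataset):
        ser = phase_series_from_swim(control_dataset.swim)
        t = ser.phase_transformed.dropna()
        assert len(t) >= 80
        assert (t > 0.64).mean() < 2 / 80


class TestTransformPhase:
    @pytest.mark.parametrize("raw,expected", [
        (0.3, 0.7), (0.5, 0.5), (0.85, 0.85), (0.0, 1.0),
    ])
    def test_examples(self, raw, expected):
        assert transform_phase(raw) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            transform_phase(1.5)
        with pytest.raises(ValueError):
            transform_phase(-0.1)

    @given(st.floats(0.0, 0.999999))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_idempotent_and_mirror_symmetric(self, x):
        t = transform_phase(x)
        assert 0.5 <= t <= 1.0
        assert transform_phase(t) == t
        mirror = 1.0 - x if x > 0 else 0.0   # 1-x folds back into [0,1)
        assert transform_phase(mirror) == pytest.approx(t)


class TestControlThreshold:
    def test_paper_scale_mean_sd_cutoff(self):
        # mean 0.55, sd 0.04 -> cutoff 0.63
        rule = IrregularityRule(control_mean=0.55, control_sd=0.04,
                                scope="step_hind")
        assert rule.cutoff == pytest.approx(0.63)

    def test_two_value_hand_computation(self):
        rule = control_threshold([0.5, 0.6])
        assert rule.control_mean == pytest.approx(0.55)
        assert rule.control_sd == pytest.approx(0.070710678, abs=1e-8)
        assert rule.cutoff == pytest.approx(0.6914213562, abs=1e-8)

    def test_constant_sample_cutoff_equals_mean(self):
        rule = control_threshold([0.5, 0.5, 0.5])
        assert rule.cutoff == rule.control_mean == 0.5

    def test_single_value_errors(self):
        with pytest.raises(ValueError):
            control_threshold([0.5])


class TestRemoveOutliers:
    def test_no_outliers_unchanged(self, rng):
        x = rng.normal(0.55, 0.02, 30)
        x = np.clip(x, 0.51, 0.59)
        keep, dropped = remove_outliers(x)
        assert keep.all() and len(dropped) == 0

    def test_single_extreme_removed_first_pass(self):
        x = np.array([0.5] * 19 + [0.99])
        x[:19] += np.linspace(-0.005, 0.005, 19)     # nonzero sd
        keep, dropped = remove_outliers(x)
        assert dropped.tolist() == [19]

    def test_identical_values_untouched(self):
        keep, dropped = remove_outliers(np.full(10, 0.5))
        assert keep.all()

    def test_iterative_until_stable(self):
        # masking: second outlier hidden until the first is removed
        x = np.concatenate([np.linspace(0.54, 0.56, 40), [0.75, 3.0]])
        keep, dropped = remove_outliers(x)
        assert set(dropped) == {40, 41}

    def test_grouped_by_timepoint(self):
        df = pd.DataFrame({
            "timepoint": ["t1"] * 20 + ["t2"] * 20,
            "value": np.concatenate([
                np.linspace(0.5, 0.6, 19), [5.0],
                np.linspace(0.5, 0.6, 20)]),
        })
        keep, dropped = remove_outliers(df, value_col="value")
        assert dropped.tolist() == [19]


class TestClassifyIrregular:
    def test_all_alternating_none_irregular(self):
        ser = _series([0.5] * 8)
        rule = IrregularityRule(0.55, 0.04, scope="step_hind")
        out = classify_irregular(ser, rule)
        assert out.n_irregular.iloc[0] == 0
        assert out.n_total.iloc[0] == 8

    def test_strictly_above_cutoff_counted(self):
        ser = _series([0.55, 0.64, 0.70, 0.60])
        rule = IrregularityRule(0.55, 0.04, scope="step_hind")   # cutoff 0.63
        out = classify_irregular(ser, rule)
        assert out.n_irregular.iloc[0] == 2

    def test_value_exactly_at_cutoff_is_regular(self):
        ser = _series([0.63, 0.6300000001])
        rule = IrregularityRule(0.55, 0.04, scope="step_hind")
        out = classify_irregular(ser, rule)
        assert out.n_irregular.iloc[0] == 1

    def test_scope_mismatch_errors(self):
        ser = _series([0.5] * 4, pair="forelimbs")
        rule = IrregularityRule(0.55, 0.04, scope="step_hind")
        with pytest.raises(ValueError):
            classify_irregular(ser, rule)

    def test_counts_invariant_to_pass_order_and_sum_to_pool(self):
        s1 = _series([0.5, 0.7, 0.6], pass_id="p1", timepoint="t1")
        s2 = _series([0.66, 0.5], pass_id="p2", timepoint="t2")
        rule = IrregularityRule(0.55, 0.04, scope="step_hind")
        fwd = classify_irregular(pd.concat([s1, s2]), rule)
        rev = classify_irregular(pd.concat([s2, s1]), rule)
        pd.testing.assert_frame_equal(
            fwd.sort_values("timepoint").reset_index(drop=True),
            rev.sort_values("timepoint").reset_index(drop=True))
        pooled = classify_irregular(pd.concat([s1, s2]), rule, by=())
        assert pooled.n_irregular.iloc[0] == fwd.n_irregular.sum()
        assert pooled.n_total.iloc[0] == fwd.n_total.sum()

    def test_calibrated_control_tail_near_gaussian(self):
        from quadgait.synthetic import SimulationConfig, simulate_footfalls
        cfg = SimulationConfig(seed=51, n_animals=50, passes_per_animal=18,
                               steps_per_pass=14)
        ser = phase_series_from_footfalls(simulate_footfalls(cfg).footfalls)
        t = ser.phase_transformed.dropna().to_numpy()
        assert len(t) >= 5000
        cutoff = t.mean() + 2 * t.std(ddof=1)
        assert abs((t > cutoff).mean() - 0.0228) < 0.01


class TestPerStepChange:
    def test_constant_phases_zero_change(self):
        out = per_step_change(_series([0.5, 0.5, 0.5]))
        np.testing.assert_array_equal(out.change, [0.0, 0.0])

    def test_arithmetic_and_change_rule(self):
        out = per_step_change(_series([0.5, 0.75, 0.6]))
        np.testing.assert_allclose(out.change, [0.25, 0.15])
        rule = IrregularityRule(0.043, 0.035, scope="per_step_change_hind")
        assert (out.change > rule.cutoff).sum() == 2    # cutoff 0.113
        assert not (0.10 > rule.cutoff)                 # change 0.10 regular

    def test_circular_variant_wraps(self):
        out = per_step_change(_series([0.05, 0.95]), circular=True)
        assert out.change.iloc[0] == pytest.approx(0.10)

    def test_changes_never_span_passes(self):
        s1 = _series([0.5, 0.6], pass_id="p1")
        s2 = _series([0.9, 0.8], pass_id="p2")
        out = per_step_change(pd.concat([s1, s2]))
        assert len(out) == 2
        np.testing.assert_allclose(sorted(out.change), [0.1, 0.1])


class TestMatchStrideChanges:
    def test_constant_stride_times_give_zero_dt(self, control_dataset):
        from quadgait.gait_events import extract_strides
        ser = _series([0.5, 0.6, 0.7])
        strides = pd.DataFrame({
            "animal_id": "a", "pass_id": "p", "limb": "RH",
            "stride_index": [0, 1, 2], "stride_time_s": 0.4,
        })
        out = match_stride_changes(ser, strides)
        np.testing.assert_array_equal(out.dstride_time_s, 0.0)
        np.testing.assert_allclose(out.dphase, [0.1, 0.1])

    def test_single_stride_empty(self):
        ser = _series([0.5])
        strides = pd.DataFrame({
            "animal_id": ["a"], "pass_id": ["p"], "limb": ["RH"],
            "stride_index": [0], "stride_time_s": [0.4]})
        assert match_stride_changes(ser, strides).empty

    def test_silenced_phase_changes_outpace_stride_time_changes(
            self, control_dataset, silenced_dataset):
        from quadgait.gait_events import extract_strides
        ctrl_strides = extract_strides(control_dataset.footfalls)
        ctrl = match_stride_changes(
            phase_series_from_footfalls(control_dataset.footfalls),
            ctrl_strides)
        band = ctrl.dstride_time_s.mean() + 2 * ctrl.dstride_time_s.std(ddof=1)
        sil = match_stride_changes(
            phase_series_from_footfalls(silenced_dataset.footfalls),
            extract_strides(silenced_dataset.footfalls))
        irregular = sil[sil.dphase > 0.113]
        assert len(irregular) > 10
        assert (irregular.dstride_time_s <= band).mean() >= 0.9


class TestCov:
    def test_constant_values_zero_percent(self):
        ser = _series([0.5] * 6)
        res = cov(ser, pools={"control": ["baseline"]})
        assert res.per_animal.cov_pct.iloc[0] == 0.0

    def test_two_value_hand_computation(self):
        ser = _series([0.5, 0.6])
        res = cov(ser, pools={"control": ["baseline"]})
        assert res.per_animal.cov_pct.iloc[0] == pytest.approx(
            100 * 0.070710678 / 0.55, abs=1e-6)

    def test_arithmetic_magnitude_anchor(self):
        # mean 0.55, sd 0.0586 -> 10.65%
        assert 100 * 0.0586 / 0.55 == pytest.approx(10.65, abs=0.01)

    def test_silenced_cov_exceeds_control_on_every_seed(self):
        from quadgait.synthetic import SimulationConfig, simulate_footfalls
        for seed in range(10):
            frames = []
            for cond in ("control", "silenced"):
                cfg = SimulationConfig(seed=seed, condition=cond,
                                       n_animals=4, passes_per_animal=3)
                frames.append(phase_series_from_footfalls(
                    simulate_footfalls(cfg).footfalls))
            res = cov(pd.concat(frames, ignore_index=True))
            g = res.group.set_index("pool").mean_cov_pct
            assert g["silenced"] > g["control"], f"seed {seed}"


class TestPoincare:
    def test_constant_series_pairs(self):
        out = poincare(_series([0.5, 0.5, 0.5]))
        assert out[["phase_n", "phase_n1"]].values.tolist() == [[0.5, 0.5],
                                                                [0.5, 0.5]]

    def test_ordered_pairs(self):
        out = poincare(_series([0.4, 0.6, 0.5]))
        assert out[["phase_n", "phase_n1"]].values.tolist() == [[0.4, 0.6],
                                                                [0.6, 0.5]]

    def test_pair_count_law_per_pass(self, control_phases):
        out = poincare(control_phases)
        sizes = control_phases.groupby("pass_id").size()
        pair_counts = out.groupby("pass_id").size()
        for pass_id, n in sizes.items():
            assert pair_counts.get(pass_id, 0) == n - 1
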