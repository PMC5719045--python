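"""Stride derivation, spatiotemporal identities, SSP classification."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from quadgait.gait_events import (SSP_ORDERS, classify_ssp, extract_strides,
                                  overall_speed, pass_summaries, ssp_tally,
                                  step_ratio, swing_stance_percent)


def _events(records):
    return pd.DataFrame(records, columns=["animal_id", "pass_id", "limb",
                                          "contact_time_s", "liftoff_time_s",
                                          "contact_x_cm"])


class TestExtractStrides:
    def test_basic_stride_arithmetic(self):
        ev = _events([("a", "p", "RH", 0.0, 0.3, 0.0),
                      ("a", "p", "RH", 0.5, 0.8, 10.0)])
        s = extract_strides(ev)
        assert len(s) == 1
        row = s.iloc[0]
        assert row.stride_time_s == pytest.approx(0.5)
        assert row.stance_s == pytest.approx(0.3)
        assert row.swing_s == pytest.approx(0.2)
        assert row.step_frequency_hz == pytest.approx(2.0)
        assert row.stride_length_cm == pytest.approx(10.0)
        assert row.instantaneous_speed_cm_s == pytest.approx(20.0)

    def test_last_contact_yields_no_stride(self):
        ev = _events([("a", "p", "RH", 0.0, 0.3, 0.0),
                      ("a", "p", "RH", 0.5, 0.8, 10.0),
                      ("a", "p", "RH", 1.0, 1.3, 20.0)])
        assert len(extract_strides(ev)) == 2

    def test_negative_swing_rejected_with_diagnostic(self):
        ev = _events([("a", "p", "RH", 0.0, 0.6, 0.0),      # liftoff after next
                      ("a", "p", "RH", 0.5, 0.8, 10.0),
                      ("a", "p", "RH", 1.0, 1.3, 20.0)])
        s = extract_strides(ev)
        assert len(s) == 1
        rejected = s.attrs["rejected"]
        assert len(rejected) == 1
        assert "liftoff" in rejected.reason.iloc[0]

    def test_identities_exact_on_synthetic(self, control_dataset):
        s = extract_strides(control_dataset.footfalls)
        np.testing.assert_array_equal(s.stance_s + s.swing_s, s.stride_time_s)
        np.testing.assert_allclose(s.stance_pct + s.swing_pct, 100.0,
                                   rtol=1e-12)
        np.testing.assert_allclose(
            s.instantaneous_speed_cm_s * s.stride_time_s, s.stride_length_cm,
            rtol=1e-12)

    def test_stride_times_match_generator_truth(self, control_dataset):
        s = extract_strides(control_dataset.footfalls)
        for p in control_dataset.truth["passes"]:
            rh = s[(s.pass_id == p["pass_id"]) & (s.limb == "RH")] \
                .sort_values("stride_index")
            np.testing.assert_allclose(rh.stride_time_s,
                                       p["stride_times_s"], atol=1e-9)


class TestSwingStancePercent:
    def test_single_stride_percentages(self):
        ev = _events([("a", "p", "RH", 0.0, 0.3, 0.0),
                      ("a", "p", "RH", 0.5, 0.8, 10.0)])
        out = swing_stance_percent(extract_strides(ev))
        assert out.mean_stance_pct.iloc[0] == pytest.approx(60.0)
        assert out.mean_swing_pct.iloc[0] == pytest.approx(40.0)

    def test_complementarity_exact(self, control_dataset):
        out = swing_stance_percent(extract_strides(control_dataset.footfalls))
        np.testing.assert_allclose(out.mean_swing_pct + out.mean_stance_pct,
                                   100.0, rtol=1e-12)

    def test_generator_stance_fraction_recovered(self):
        from quadgait.synthetic import SimulationConfig, simulate_footfalls
        cfg = SimulationConfig(seed=31, speed_range=(40.0, 40.0),
                               stance_speed_slope=0.0)
        out = swing_stance_percent(
            extract_strides(simulate_footfalls(cfg).footfalls))
        assert abs(out.mean_stance_pct.iloc[0] - 55.0) < 1.0

    def test_empty_speed_class_absent(self):
        ev = _events([("a", "p", "RH", 0.0, 0.3, 0.0),
                      ("a", "p", "RH", 0.5, 0.8, 10.0)])   # 20 cm/s only
        out = swing_stance_percent(extract_strides(ev), speed_cutoff=90.0)
        assert out.speed_class.tolist() == ["low"]


class TestOverallSpeed:
    def test_distance_over_time(self):
        ev = _events([("a", "p", "RH", 0.0, 0.1, 0.0),
                      ("a", "p", "RH", 2.0, 2.1, 100.0)])
        assert overall_speed(ev) == pytest.approx(50.0)

    def test_single_contact_errors(self):
        ev = _events([("a", "p", "RH", 0.0, 0.1, 0.0)])
        with pytest.raises(ValueError):
            overall_speed(ev)

    def test_synthetic_pass_speed_recovered(self, control_dataset):
        for p in control_dataset.truth["passes"][:4]:
            ev = control_dataset.footfalls[
                control_dataset.footfalls.pass_id == p["pass_id"]]
            assert abs(overall_speed(ev) - p["speed_cm_s"]) < 2.0


class TestSSPClassifier:
    @pytest.mark.parametrize("order,pattern,subtype", [
        (("RF", "LH", "LF", "RH"), "alternate", "a"),
        (("LF", "RH", "RF", "LH"), "alternate", "b"),
        (("RF", "LF", "RH", "LH"), "cruciate", "a"),
        (("LF", "RF", "LH", "RH"), "cruciate", "b"),
        (("RF", "LF", "LH", "RH"), "rotate", "a"),
        (("LF", "RF", "RH", "LH"), "rotate", "b"),
    ])
    def test_canonical_orders(self, order, pattern, subtype):
        lab = classify_ssp(order)
        assert (lab.pattern, lab.subtype) == (pattern, subtype)
        assert lab.initiating_limb == order[0]

    def test_full_permutation_table(self):
        # all 24 orderings of the four limbs: 6 canonical, 18 unclassified
        tallied = {}
        for perm in permutations(("LF", "RF", "LH", "RH")):
            lab = classify_ssp(perm)
            tallied[perm] = (lab.pattern, lab.subtype)
        canonical = {p: v for p, v in tallied.items() if v[0] != "unclassified"}
        assert len(tallied) == 24
        assert len(canonical) == 6
        assert canonical == {k: v for k, v in
                             ((o, SSP_ORDERS[o]) for o in SSP_ORDERS)}
        assert all(v == ("unclassified", "none") for p, v in tallied.items()
                   if p not in SSP_ORDERS)

    @pytest.mark.parametrize("seq", [
        ("RF", "RF", "LH", "RH"),              # repeated limb
        ("RF", "LH", "LF"),                    # too short
        (),                                    # empty
    ])
    def test_degenerate_windows_unclassified(self, seq):
        lab = classify_ssp(seq)
        assert lab.pattern == "unclassified"
        assert lab.subtype == "none"

    def test_control_tally_dominated_by_alternate(self, control_dataset):
        tally = ssp_tally(control_dataset.footfalls,
                          group_cols=("condition",))
        pooled = tally[tally.subtype == "pooled"].set_index("pattern").percent
        assert pooled.get("alternate", 0.0) > 80.0

    def test_silenced_increases_cruciate_share(self, control_dataset,
                                               silenced_dataset):
        def share(ds):
            t = ssp_tally(ds.footfalls, group_cols=("condition",))
            pooled = t[t.subtype == "pooled"].set_index("pattern").percent
            return pooled.get("cruciate", 0.0)
        assert share(silenced_dataset) > share(control_dataset)


class TestStepRatio:
    def test_matched_counts_give_unity(self):
        rows = []
        for k in range(9):
            t = 0.5 * k
            for limb, off in (("RH", 0.0), ("LH", 0.25), ("RF", 0.1),
                              ("LF", 0.35)):
                rows.append(("a", "p", limb, t + off, t + off + 0.2,
                             10.0 * k + off))
        assert step_ratio(_events(rows)) == pytest.approx(1.0)

    def test_ratio_above_one_with_extra_hind_steps(self):
        rows = []
        for k in range(13):                    # 12 hind strides
            rows.append(("a", "p", "RH", 0.5 * k, 0.5 * k + 0.2, 10.0 * k))
        for k in range(11):                    # 10 fore strides
            rows.append(("a", "p", "RF", 0.6 * k + 0.1, 0.6 * k + 0.3,
                         10.0 * k))
        assert step_ratio(_events(rows)) == pytest.approx(1.2)

    def test_no_forelimb_strides_errors(self):
        rows = [("a", "p", "RH", 0.0, 0.2, 0.0),
                ("a", "p", "RH", 0.5, 0.7, 10.0)]
        with pytest.raises(ValueError):
            step_ratio(_events(rows))

    def test_default_synthetic_ratio_exactly_one(self, control_dataset):
        ps = pass_summaries(control_dataset.footfalls)
        np.testing.assert_array_equal(ps.step_ratio, 1.0)


class TestSpeedIndexRelations:
    def test_spearman_signs_speed_vs_frequency_and_stride_time(self):
        from quadgait.synthetic import SimulationConfig, simulate_footfalls
        cfg = SimulationConfig(seed=41, n_animals=8, passes_per_animal=6)
        s = extract_strides(simulate_footfalls(cfg).footfalls)
        s = s[s.limb == "RH"]
        r_freq, _ = spearmanr(s.instantaneous_speed_cm_s, s.step_frequency_hz)
        r_time, _ = spearmanr(s.instantaneous_speed_cm_s, s.stride_time_s)
        assert r_freq > 0.5
        assert r_time < -0.5
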