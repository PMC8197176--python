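"""Tests for the reduction of records and trajectories to calibration points."""

import numpy as np
import pytest

from ctldyn.model import ModelParameters, simulate
from ctldyn.observation import (
    CTL_APOPTOSIS, CTL_MITOSIS, ET_RATIO, GROWTH, KILLING, TC_MITOSIS,
    CalibrationPoint, IntravitalPosition, MouseRecord,
    assemble_points, growth_rate_series, intravital_rates, model_predictions,
    read_cohort, write_cohort,
)


def by_kind(points):
    out = {}
    for pt in points:
        out.setdefault(pt.kind, []).append(pt)
    return out


class TestGrowthRateSeries:
    def test_constant_volume_gives_zero_rate_at_midpoint(self):
        pts = growth_rate_series([(1.0, 0.1), (3.0, 0.1)])
        assert len(pts) == 1
        assert pts[0].value == 0.0
        assert pts[0].day == 2.0
        assert pts[0].interval == (1.0, 3.0)

    def test_e_fold_over_two_days_is_half_per_day(self):
        pts = growth_rate_series([(1.0, 0.1), (3.0, 0.1 * np.e)])
        assert pts[0].value == pytest.approx(0.5)

    def test_one_point_per_interval(self):
        days = [1.0, 3.0, 6.0, 9.0, 13.0, 15.0]
        pts = growth_rate_series([(d, 0.1 * 2**i) for i, d in enumerate(days)])
        assert len(pts) == 5
        assert [p.day for p in pts] == [2.0, 4.5, 7.5, 11.0, 14.0]

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            growth_rate_series([(1.0, 0.1), (3.0, 0.0)])

    def test_requires_two_measurements(self):
        with pytest.raises(ValueError):
            growth_rate_series([(1.0, 0.1)])


class TestIntravitalRates:
    def test_rates_per_capita_per_day(self):
        pos = IntravitalPosition("m1", 6.0, duration=2.0, n_ctl=4, n_tc=50,
                                 tc_apoptosis=2, tc_mitosis=1)
        k = {p.kind: p.value for p in intravital_rates(pos)}
        assert k[KILLING] == pytest.approx(6.0)       # 2/(2h*4) * 24
        assert k[TC_MITOSIS] == pytest.approx(0.24)   # 1/(2h*50) * 24
        assert k[ET_RATIO] == pytest.approx(0.08)
        assert k[CTL_MITOSIS] == 0.0 and k[CTL_APOPTOSIS] == 0.0

    def test_zero_events_give_zero_rates(self):
        pos = IntravitalPosition("m1", 6.0, duration=1.5, n_ctl=3, n_tc=40)
        k = {p.kind: p.value for p in intravital_rates(pos)}
        assert k[KILLING] == 0.0 and k[TC_MITOSIS] == 0.0
        assert k[ET_RATIO] == pytest.approx(3 / 40)

    def test_no_ctls_suppresses_per_ctl_rates_but_keeps_et(self):
        pos = IntravitalPosition("m1", 6.0, duration=2.0, n_ctl=0, n_tc=50,
                                 tc_mitosis=3)
        kinds = {p.kind for p in intravital_rates(pos)}
        assert KILLING not in kinds and CTL_MITOSIS not in kinds
        et = [p for p in intravital_rates(pos) if p.kind == ET_RATIO]
        assert et[0].value == 0.0

    def test_rates_inversely_proportional_to_duration(self):
        a = IntravitalPosition("m", 6.0, duration=1.0, n_ctl=5, n_tc=100,
                               tc_apoptosis=3, ctl_mitosis=2)
        b = IntravitalPosition("m", 6.0, duration=2.0, n_ctl=5, n_tc=100,
                               tc_apoptosis=3, ctl_mitosis=2)
        ka = {p.kind: p.value for p in intravital_rates(a)}
        kb = {p.kind: p.value for p in intravital_rates(b)}
        for kind in (KILLING, CTL_MITOSIS):
            assert ka[kind] == pytest.approx(2.0 * kb[kind])

    def test_event_rate_recovered_in_expectation(self, rng):
        # Poisson counts at rate 0.44 CTL^-1 day^-1 over many positions
        rate, n = 0.44, 500
        vals = []
        for _ in range(n):
            n_ctl = rng.integers(2, 20)
            tau = rng.uniform(1.0, 3.0)
            kills = rng.poisson(rate * n_ctl * tau / 24.0)
            pos = IntravitalPosition("m", 6.0, duration=float(tau),
                                     n_ctl=float(n_ctl), n_tc=100.0,
                                     tc_apoptosis=float(kills))
            vals.append({p.kind: p.value for p in intravital_rates(pos)}[KILLING])
        se = np.std(vals, ddof=1) / np.sqrt(n)
        assert abs(np.mean(vals) - rate) < 3 * se


class TestModelPredictions:
    def test_untreated_predictions_are_flat_at_g(self):
        p = ModelParameters(g=0.5, transfer_day=100.0)
        traj = simulate(p, np.linspace(0.0, 15.0, 16))
        k = {q.kind: q.value for q in model_predictions(traj, [9.0])}
        assert k[TC_MITOSIS] == pytest.approx(0.5)
        assert k[ET_RATIO] == 0.0
        assert k[GROWTH] == pytest.approx(0.5)

    def test_killing_prediction_is_the_constant_per_ctl_rate(self, act_only):
        traj = simulate(act_only, np.linspace(0.0, 15.0, 31))
        for day in (6.0, 9.0, 13.0):
            k = {q.kind: q.value for q in model_predictions(traj, [day])}
            assert k[KILLING] == 0.75

    def test_growth_identity_holds_along_trajectory(self, act_mab):
        # (1/T)dT/dt = g*T_p/T - k_e*E/T from cell conservation
        traj = simulate(act_mab, np.linspace(0.0, 15.0, 31))
        for day in (4.0, 6.0, 9.0, 14.0):
            k = {q.kind: q.value for q in model_predictions(traj, [day])}
            st = traj.state_at(day)
            assert k[GROWTH] == pytest.approx(
                k[TC_MITOSIS] - act_mab.k_e * st.E / st.T, abs=1e-6)

    def test_day_outside_span_raises(self, act_mab):
        traj = simulate(act_mab, np.linspace(0.0, 9.0, 10))
        with pytest.raises(ValueError):
            model_predictions(traj, [9.5])


class TestRecordsAndIO:
    def test_positions_before_transfer_rejected(self):
        pos = IntravitalPosition("m1", 6.0, 2.0, 3, 50)
        with pytest.raises(ValueError):
            MouseRecord("m1", "ACT-only", transfer_day=7.0, positions=(pos,))

    def test_volume_days_must_increase(self):
        with pytest.raises(ValueError):
            MouseRecord("m1", "no-ACT", None, volumes=((3.0, 0.1), (1.0, 0.05)))

    def test_cohort_round_trips_through_csv(self, tmp_path):
        mice = [
            MouseRecord(
                "m1", "ACT-only", 3.0,
                volumes=((1.0, 0.02), (3.0, 0.04), (6.0, 0.1)),
                positions=(IntravitalPosition("m1", 6.0, 2.0, 4, 50,
                                              tc_apoptosis=2, tc_mitosis=1,
                                              group="ACT-only"),),
            ),
            MouseRecord("m2", "no-ACT", None, volumes=((1.0, 0.02), (3.0, 0.05))),
        ]
        write_cohort(mice, tmp_path / "v.csv", tmp_path / "p.csv")
        back = read_cohort(tmp_path / "v.csv", tmp_path / "p.csv")
        assert {m.mouse_id for m in back} == {"m1", "m2"}
        m1 = next(m for m in back if m.mouse_id == "m1")
        assert m1.transfer_day == 3.0
        assert m1.volumes == ((1.0, 0.02), (3.0, 0.04), (6.0, 0.1))
        assert len(m1.positions) == 1 and m1.positions[0].n_ctl == 4
        m2 = next(m for m in back if m.mouse_id == "m2")
        assert m2.transfer_day is None

    def test_assemble_points_tags_condition_and_counts(self):
        mice = [MouseRecord(
            "m1", "ACT-only", 3.0,
            volumes=((1.0, 0.02), (3.0, 0.04), (6.0, 0.1)),
            positions=(IntravitalPosition("m1", 6.0, 2.0, 4, 50,
                                          tc_apoptosis=2, tc_mitosis=1),),
        )]
        pts = assemble_points(mice)
        assert all(pt.condition == ("ACT-only", 3.0) for pt in pts)
        kinds = by_kind(pts)
        assert len(kinds[GROWTH]) == 2
        assert len(kinds[KILLING]) == 1 and len(kinds[ET_RATIO]) == 1

    def test_assemble_points_can_average_et_per_mouse_day(self):
        positions = tuple(
            IntravitalPosition("m1", 6.0, 2.0, n_ctl, 100)
            for n_ctl in (2, 4, 6, 8)
        )
        mice = [MouseRecord("m1", "ACT-only", 3.0,
                            volumes=((1.0, 0.02), (3.0, 0.04)),
                            positions=positions)]
        pts = by_kind(assemble_points(mice, aggregate_et=True))
        assert len(pts[ET_RATIO]) == 1
        assert pts[ET_RATIO][0].value == pytest.approx(0.05)
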