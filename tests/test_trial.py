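"""Treadmill trial processing: energy expenditure, PWC, skin temperature, safety."""

import numpy as np
import pandas as pd
import pytest

import heatwork as hw
from heatwork.trial import (
    HIGH_CLOTHING,
    LOW_CLOTHING,
    RAMANATHAN_WEIGHTS,
    TrialTimeSeries,
    annotate_termination,
    read_trial_csv,
)


def _minute_ee_oracle(grade, velocity, rq, mass):
    """Two-part hand computation: mass-specific oxygen uptake, then kJ."""
    vo2 = 0.32 * grade + 3.28 + (1 + 0.19 * grade) * (2.66 * velocity**2)  # mL/kg/min
    litres = vo2 * mass / 1000.0
    kj_per_litre = 19.61 + (rq - 0.707) / 0.293 * 1.51
    return litres * kj_per_litre


def make_trial(velocity, grade, n=60, rectal=None, mass=77.0, **extra_cols):
    df = pd.DataFrame({
        "minute": np.arange(1, n + 1),
        "velocity_ms": np.full(n, velocity) if np.isscalar(velocity) else velocity,
        "grade_pct": np.full(n, grade) if np.isscalar(grade) else grade,
    })
    if rectal is not None:
        df["t_rectal_c"] = rectal
    for k, v in extra_cols.items():
        df[k] = v
    return TrialTimeSeries(df, body_mass=mass)


class TestEnergyEquivalent:
    def test_fat_anchor(self):
        assert hw.energy_equivalent(0.707) == 19.61

    def test_carbohydrate_anchor(self):
        assert hw.energy_equivalent(1.0) == pytest.approx(19.61 + 1.51)


class TestMinuteEE:
    @pytest.mark.parametrize(
        "grade,velocity,rq,mass,expected",
        [
            (0.0, 5.0 / 3.6, 0.85, 77.0, 13.2),   # level walk at 5 km/h
            (5.0, 1.25, 0.85, 70.0, 18.5),        # uphill walk
        ],
    )
    def test_hand_computed_values(self, grade, velocity, rq, mass, expected):
        got = hw.minute_ee(grade, velocity, rq, mass)
        assert got == pytest.approx(expected, abs=0.05)
        assert got == pytest.approx(_minute_ee_oracle(grade, velocity, rq, mass))

    def test_negative_grade_rejected(self):
        with pytest.raises(ValueError, match="grade"):
            hw.minute_ee(-2.0, 1.0)

    def test_strictly_increasing_in_each_argument(self):
        base = dict(grade=3.0, velocity=1.2, rq=0.85, body_mass=75.0)
        ref = hw.minute_ee(**base)
        for key, bump in [("grade", 1.0), ("velocity", 0.1), ("rq", 0.05), ("body_mass", 5.0)]:
            kw = dict(base)
            kw[key] += bump
            assert hw.minute_ee(**kw) > ref


class TestWorkEE:
    def test_constant_profile_sums_linearly(self):
        trial = make_trial(1.3, 2.0)
        per_min = hw.minute_ee(2.0, 1.3, 0.85, 77.0)
        assert hw.work_ee(trial) == pytest.approx(60 * per_min)

    def test_additive_over_partition(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(0.8, 1.6, 60)
        g = rng.uniform(0, 4, 60)
        full = make_trial(v, g)
        first = TrialTimeSeries(full.data.iloc[:30].copy(), body_mass=77.0)
        second = TrialTimeSeries(full.data.iloc[30:].reset_index(drop=True), body_mass=77.0)
        assert hw.work_ee(full) == pytest.approx(hw.work_ee(first) + hw.work_ee(second))

    def test_truncated_by_core_temperature(self):
        rectal = np.concatenate([np.linspace(37.0, 38.9, 30), np.full(30, 39.2)])
        trial = make_trial(1.3, 2.0, rectal=rectal)
        per_min = hw.minute_ee(2.0, 1.3, 0.85, 77.0)
        assert hw.work_ee(trial) == pytest.approx(31 * per_min)

    def test_rq_column_defaults_applied(self):
        rq = np.full(60, np.nan)
        rq[:10] = 0.9
        trial = make_trial(1.3, 0.0, rq=rq)
        expect = 10 * hw.minute_ee(0.0, 1.3, 0.9, 77.0) + 50 * hw.minute_ee(0.0, 1.3, 0.85, 77.0)
        assert hw.work_ee(trial) == pytest.approx(expect)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            TrialTimeSeries(pd.DataFrame(columns=["minute", "velocity_ms", "grade_pct"]),
                            body_mass=77.0)


class TestPWCPercent:
    def _result(self, ee):
        return hw.TrialResult(work_ee=ee, mean_tskin=None, terminated_early="none",
                              minutes_completed=60)

    def test_identity_and_zero(self):
        cool = self._result(1000.0)
        assert hw.pwc_percent(cool, cool) == 100.0
        assert hw.pwc_percent(self._result(0.0), cool) == 0.0

    def test_proportionality(self):
        cool = self._result(1000.0)
        assert hw.pwc_percent(self._result(720.0), cool) == pytest.approx(72.0)

    def test_above_reference_allowed(self):
        assert hw.pwc_percent(self._result(1100.0), self._result(1000.0)) == pytest.approx(110.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="cool"):
            hw.pwc_percent(self._result(500.0), self._result(0.0))


class TestMeanSkinTemp:
    def test_weights_sum_to_one(self):
        assert sum(RAMANATHAN_WEIGHTS.values()) == pytest.approx(1.0)
        assert hw.mean_skin_temp({"chest": 33, "arm": 33, "thigh": 33, "calf": 33}) == 33.0

    def test_weighted_combination(self):
        got = hw.mean_skin_temp({"chest": 34, "arm": 33, "thigh": 32, "calf": 31})
        assert got == pytest.approx(32.7)

    def test_missing_site_named(self):
        with pytest.raises(ValueError, match="thigh"):
            hw.mean_skin_temp({"chest": 34, "arm": 33, "calf": 31})


class TestTermination:
    def test_no_trigger(self):
        trial = make_trial(1.3, 0.0, rectal=np.linspace(37, 38.4, 60))
        assert annotate_termination(trial) == ("none", 60)

    def test_core_threshold_is_inclusive(self):
        rectal = np.full(60, 37.5)
        rectal[40] = 39.0  # minute 41
        trial = make_trial(1.3, 0.0, rectal=rectal)
        assert annotate_termination(trial) == ("core_39", 41)

    def test_speed_zero_after_first_minute(self):
        v = np.full(60, 1.2)
        v[24:] = 0.0  # minute 25
        trial = make_trial(v, 0.0)
        assert annotate_termination(trial) == ("speed_zero", 25)

    def test_standing_start_does_not_terminate(self):
        v = np.full(60, 1.2)
        v[0] = 0.0
        trial = make_trial(v, 0.0)
        assert annotate_termination(trial) == ("none", 60)

    def test_earliest_event_wins(self):
        v = np.full(60, 1.2)
        v[50:] = 0.0
        rectal = np.full(60, 37.0)
        rectal[30:] = 39.1
        trial = make_trial(v, 0.0, rectal=rectal)
        assert annotate_termination(trial) == ("core_39", 31)


class TestTrialContainer:
    def test_process_trial_bundles_everything(self):
        n = 60
        skin = {f"t_{s}_c": np.full(n, 33.0 + i) for i, s in
                enumerate(["chest", "arm", "thigh", "calf"])}
        trial = make_trial(1.3, 2.0, rectal=np.full(n, 37.5), **skin)
        res = hw.process_trial(trial)
        assert res.terminated_early == "none"
        assert res.minutes_completed == 60
        assert res.mean_tskin == pytest.approx(0.3 * (33 + 34) + 0.2 * (35 + 36))
        assert res.work_ee > 0

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError, match="velocities"):
            make_trial(-0.5, 0.0)
        with pytest.raises(ValueError, match="RQ"):
            make_trial(1.0, 0.0, rq=np.full(60, 1.4))
        with pytest.raises(ValueError, match="protocol limit"):
            make_trial(1.0, 0.0, n=61)

    def test_gap_truncates_with_warning(self):
        df = pd.DataFrame({
            "minute": [1, 2, 3, 7, 8],
            "velocity_ms": 1.2, "grade_pct": 0.0,
        })
        with pytest.warns(UserWarning, match="truncating"):
            trial = TrialTimeSeries(df, body_mass=77.0)
        assert len(trial) == 3

    def test_clothing_insulation_in_clo(self):
        assert LOW_CLOTHING.clo == pytest.approx(0.26, abs=0.005)
        assert HIGH_CLOTHING.clo == pytest.approx(0.86, abs=0.005)


class TestTrialIO:
    def test_csv_with_sidecar_round_trip(self, tmp_path):
        df = pd.DataFrame({
            "minute": np.arange(1, 11), "velocity_ms": 1.3, "grade_pct": 1.0,
        })
        csv = tmp_path / "hot.csv"
        df.to_csv(csv, index=False)
        (tmp_path / "hot.json").write_text(
            '{"body_mass_kg": 80.5, "ta_c": 40, "rh_pct": 20, "clothing": "high"}'
        )
        trial = read_trial_csv(csv)
        assert trial.body_mass == 80.5
        assert trial.condition.air_temp == 40
        assert trial.clothing is HIGH_CLOTHING

    def test_missing_body_mass_rejected(self, tmp_path):
        csv = tmp_path / "t.csv"
        pd.DataFrame({"minute": [1], "velocity_ms": [1.0], "grade_pct": [0.0]}).to_csv(csv, index=False)
        with pytest.raises(ValueError, match="body mass"):
            read_trial_csv(csv)
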