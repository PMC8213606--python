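"""Calibration data and synthetic treadmill trials.

``load_calibration`` ships the published group-mean calibration table: PWC
(% of the 15 degC reference) for 22 air-temperature/humidity combinations,
measured separately under low and high clothing coverage (42 cells; two
cells are absent and two 50 degC high-clothing cells are single-trial
means without an SD).  The pooled view averages the two clothing arms per
condition with equal weight.

``generate_trial`` emulates the fixed-heart-rate treadmill protocol so the
whole processing pipeline is testable without laboratory data.  It is a
phenomenological generator, not a thermophysiological model: heart rate
relaxes to the 130 beats/min target, skin temperature relaxes toward a
climate-dependent equilibrium (warmer with Ta and RH), and the work-rate
profile of the matched cool reference is attenuated by exp(-beta * excess
skin temperature), with beta solved numerically so that the cumulative
energy expenditure hits the requested target PWC.  Its contract is closure
(pipeline-recovered PWC equals the target at zero noise) and monotonicity
(generated skin temperature rises with Ta), nothing more.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .climate import ClimateCondition
from .models import SigmoidParams, TaRhParams, pwc_from_ta_rh, sigmoid
from .trial import (
    DEFAULT_RQ,
    HIGH_CLOTHING,
    LOW_CLOTHING,
    MAX_TRIAL_MINUTES,
    TrialTimeSeries,
    energy_equivalent,
)

__all__ = [
    "CalibrationTable",
    "load_calibration",
    "SyntheticTrialSpec",
    "Participant",
    "generate_trial",
    "generate_calibration_set",
    "CALIBRATION_SHA256",
]

_CAL_FILE = "calibration_pwc.csv"
CALIBRATION_SHA256 = "6c942c3b5cffcb96e15b2f47ef4c8e1be7fe26cd182d99fd62b2cacb7c45c866"

REFERENCE_CONDITION = ClimateCondition(air_temp=15.0, rel_humidity=50.0)


@dataclass(frozen=True)
class CalibrationTable:
    """The packaged calibration dataset (one row per condition x clothing)."""

    data: pd.DataFrame

    @property
    def n_conditions(self) -> int:
        return len(self.data[["ta_c", "rh_pct"]].drop_duplicates())

    def record(self, ta: float, rh: float, clothing: str) -> pd.Series:
        m = (
            (self.data["ta_c"] == ta)
            & (self.data["rh_pct"] == rh)
            & (self.data["clothing"] == clothing)
        )
        sub = self.data[m]
        if len(sub) != 1:
            raise KeyError(f"no unique record for ({ta}, {rh}, {clothing})")
        return sub.iloc[0]

    def pooled(self) -> pd.DataFrame:
        """Pooled PWC per condition: unweighted mean of the clothing arms.

        Conditions with a single clothing arm keep that arm's value
        (per-cell trial counts are unpublished, so arms are weighted
        equally rather than by n).
        """
        out = (
            self.data.groupby(["ta_c", "rh_pct"], as_index=False)["pwc_mean"]
            .mean()
            .rename(columns={"pwc_mean": "pwc_pct"})
        )
        return out.sort_values(["ta_c", "rh_pct"]).reset_index(drop=True)


def load_calibration(verify: bool = True) -> CalibrationTable:
    """Load the packaged calibration table, verifying its checksum."""
    raw = (resources.files("heatwork") / "data" / _CAL_FILE).read_bytes()
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != CALIBRATION_SHA256:
            raise RuntimeError(
                f"packaged calibration file is corrupt: sha256 {digest} != {CALIBRATION_SHA256}"
            )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), dtype={"clothing": str})
    df["singleton"] = df["singleton"].astype(bool)
    return CalibrationTable(df)


@dataclass(frozen=True)
class Participant:
    body_mass: float = 77.0   # kg, cohort mean
    fitness: float = 1.0      # scales the sustainable work rate at HR 130


@dataclass(frozen=True)
class SyntheticTrialSpec:
    """Specification of one synthetic trial; the seed fully determines output."""

    condition: ClimateCondition
    clothing: str = "low"
    participant: Participant = field(default_factory=Participant)
    target_pwc: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_pwc <= 100.0:
            raise ValueError("target_pwc must lie in (0, 100]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.clothing not in ("low", "high"):
            raise ValueError("clothing must be 'low' or 'high'")


# --- protocol constants (phenomenological, chosen to mimic the trial shape) ---
_V_MAX = 6.0 / 3.6          # m/s; grade engages only above this belt speed
_N_STEADY = 13.0            # mL/kg/min sustainable net VO2 at HR 130, fitness 1
_RAMP_TAU = 3.0             # min, work-rate ramp-in
_SKIN_TAU = 8.0             # min, skin-temperature relaxation
_SKIN_T0 = 33.0             # degC at entry
_HR_TARGET, _HR_REST, _HR_TAU = 130.0, 88.0, 3.5
_SITE_OFFSETS = {"chest": 0.4, "arm": 0.1, "thigh": -0.3, "calf": -0.6}


def _skin_equilibrium(cond: ClimateCondition, clothing: str) -> float:
    teq = 30.0 + 0.22 * (cond.air_temp - 15.0) + 0.02 * (cond.rel_humidity - 50.0)
    if clothing == "high":
        teq += 0.3
    return min(teq, 38.8)


def _skin_series(minutes: np.ndarray, teq: float) -> np.ndarray:
    return teq + (_SKIN_T0 - teq) * np.exp(-minutes / _SKIN_TAU)


def _invert_vo2(n: np.ndarray):
    """Split a net-VO2 target into (velocity, grade) under the speed-first rule.

    Below the 6 km/h threshold the grade stays 0 and speed carries the load;
    above it the speed saturates and grade takes over (linear in grade at
    fixed speed).  Targets below the standing intercept map to a stopped
    belt.
    """
    n = np.asarray(n, dtype=float)
    v = np.sqrt(np.clip(n - 3.28, 0.0, None) / 2.66)
    g = np.zeros_like(v)
    over = v > _V_MAX
    if np.any(over):
        base = 3.28 + 2.66 * _V_MAX**2
        slope = 0.32 + 0.19 * 2.66 * _V_MAX**2
        g[over] = (n[over] - base) / slope
        v[over] = _V_MAX
    return v, g


def _ee_from_profile(n: np.ndarray, body_mass: float) -> float:
    """Pipeline-equivalent cumulative EE of a net-VO2 profile, kJ.

    Applies the same standstill floor and speed-zero termination the trial
    processor would, so the generator's closure solve and the downstream
    pipeline agree exactly.
    """
    v, g = _invert_vo2(n)
    n_eff = 0.32 * g + 3.28 + (1 + 0.19 * g) * 2.66 * v**2
    zero = np.flatnonzero(v[1:] == 0.0) + 1
    stop = int(zero[0]) + 1 if zero.size else n_eff.size
    per_min = n_eff[:stop] * body_mass / 1000.0 * energy_equivalent(DEFAULT_RQ)
    return float(np.sum(per_min))


def _cool_profile(minutes: np.ndarray, participant: Participant) -> np.ndarray:
    n_ss = _N_STEADY * participant.fitness
    return n_ss * (1.0 - np.exp(-minutes / _RAMP_TAU))


def generate_trial(spec: SyntheticTrialSpec) -> TrialTimeSeries:
    """Generate one synthetic per-minute treadmill trial.

    The cool reference work-rate profile (a saturating ramp at the
    participant's sustainable rate) is attenuated minute by minute by
    exp(-beta * excess skin temperature over the reference climate); beta
    is solved so cumulative energy expenditure equals ``target_pwc`` % of
    the matched reference trial's.  With ``noise_sd`` > 0 the realised
    target is drawn from N(target_pwc, noise_sd) and per-minute jitter is
    added, both from the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    minutes = np.arange(1, MAX_TRIAL_MINUTES + 1, dtype=float)
    part = spec.participant

    n_cool = _cool_profile(minutes, part)
    cool_ee = _ee_from_profile(n_cool, part.body_mass)

    teq_ref = _skin_equilibrium(REFERENCE_CONDITION, spec.clothing)
    teq_hot = _skin_equilibrium(spec.condition, spec.clothing)
    tskin_ref = _skin_series(minutes, teq_ref)
    tskin_hot = _skin_series(minutes, teq_hot)
    excess = np.clip(tskin_hot - tskin_ref, 0.0, None)

    target = spec.target_pwc
    if spec.noise_sd > 0:
        target = float(np.clip(target + rng.normal(0.0, spec.noise_sd), 1.0, 110.0))
        jitter = np.exp(rng.normal(0.0, spec.noise_sd / 400.0, minutes.size))
    else:
        jitter = 1.0

    n_base = n_cool * jitter

    def recovered(beta: float) -> float:
        return 100.0 * _ee_from_profile(n_base * np.exp(-beta * excess), part.body_mass) / cool_ee

    if np.all(excess <= 1e-12) or recovered(0.0) <= target:
        # no thermal strain relative to the reference (or none needed):
        # scale the work-rate profile uniformly instead
        n_hot = n_base * (target / recovered(0.0))
    elif recovered(50.0) >= target:
        # even full attenuation leaves the two standstill minutes' worth of
        # energy; sub-percent targets saturate there
        n_hot = n_base * np.exp(-50.0 * excess)
    else:
        beta = brentq(lambda b: recovered(b) - target, 0.0, 50.0, xtol=1e-10)
        n_hot = n_base * np.exp(-beta * excess)

    v, g = _invert_vo2(n_hot)
    zero = np.flatnonzero(v[1:] == 0.0) + 1
    n_rows = int(zero[0]) + 1 if zero.size else minutes.size

    hr = _HR_TARGET - (_HR_TARGET - _HR_REST) * np.exp(-minutes / _HR_TAU)
    if spec.noise_sd > 0:
        hr = hr + np.clip(rng.normal(0.0, 1.5, minutes.size), -4.0, 4.0)
    # rectal temperature rises with cumulative work rate, mildly with climate
    n_eff = 0.32 * g + 3.28 + (1 + 0.19 * g) * 2.66 * v**2
    cum_frac = np.cumsum(n_eff) / np.sum(_cool_profile(minutes, part))
    t_re = 36.9 + 1.15 * cum_frac + 0.004 * max(spec.condition.air_temp - 35.0, 0.0) * minutes / 60.0

    df = pd.DataFrame(
        {
            "minute": minutes.astype(int),
            "velocity_ms": np.round(v, 4),
            "grade_pct": np.round(g, 4),
            "rq": DEFAULT_RQ,
            "hr_bpm": np.round(hr, 1),
            "t_rectal_c": np.round(t_re, 3),
            "t_chest_c": np.round(tskin_hot + _SITE_OFFSETS["chest"], 3),
            "t_arm_c": np.round(tskin_hot + _SITE_OFFSETS["arm"], 3),
            "t_thigh_c": np.round(tskin_hot + _SITE_OFFSETS["thigh"], 3),
            "t_calf_c": np.round(tskin_hot + _SITE_OFFSETS["calf"], 3),
        }
    ).iloc[:n_rows]
    clothing = LOW_CLOTHING if spec.clothing == "low" else HIGH_CLOTHING
    return TrialTimeSeries(
        df.reset_index(drop=True),
        body_mass=part.body_mass,
        condition=spec.condition,
        clothing=clothing,
        meta={"seed": spec.seed, "target_pwc": spec.target_pwc, "noise_sd": spec.noise_sd},
    )


def reference_spec(spec: SyntheticTrialSpec) -> SyntheticTrialSpec:
    """The matched cool-reference spec for a hot-trial spec (same participant)."""
    return SyntheticTrialSpec(
        condition=REFERENCE_CONDITION,
        clothing=spec.clothing,
        participant=spec.participant,
        target_pwc=100.0,
        noise_sd=0.0,
        seed=spec.seed,
    )


def generate_calibration_set(
    params: Union[TaRhParams, SigmoidParams],
    conditions: Sequence,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a calibration table from a known model (fuel for recovery tests).

    With :class:`TaRhParams`, ``conditions`` is a sequence of (Ta, RH)
    pairs and the output has columns ta_c/rh_pct/pwc_pct; with
    :class:`SigmoidParams` it is a sequence of index values and the output
    has columns x/pwc_pct.  PWC is the model evaluation plus seeded
    Gaussian noise of standard deviation ``noise_sd``.
    """
    rng = np.random.default_rng(seed)
    if isinstance(params, TaRhParams):
        arr = np.asarray(conditions, dtype=float)
        pwc, _ = pwc_from_ta_rh(arr[:, 0], arr[:, 1], params)
        pwc = pwc + rng.normal(0.0, noise_sd, size=pwc.shape) if noise_sd > 0 else pwc
        return pd.DataFrame({"ta_c": arr[:, 0], "rh_pct": arr[:, 1], "pwc_pct": pwc})
    if isinstance(params, SigmoidParams):
        x = np.asarray(conditions, dtype=float)
        pwc = sigmoid(x, params.pwc50, params.hillslope, params.top, params.bottom)
        pwc = pwc + rng.normal(0.0, noise_sd, size=pwc.shape) if noise_sd > 0 else pwc
        return pd.DataFrame({"x": x, "pwc_pct": pwc})
    raise TypeError("params must be TaRhParams or SigmoidParams")
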