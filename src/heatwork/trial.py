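"""Treadmill work-trial processing: energy expenditure, PWC and safety rules.

A trial is one hour (at most) of treadmill walking at a fixed target heart
rate of 130 beats/min: the treadmill controls speed and grade to hold the
heart rate, so work output falls as thermal strain rises.  PWC is the
cumulative net energy expenditure of a hot trial expressed as a percentage
of a matched cool-reference trial.

Net walking metabolism per minute follows the "minimum mechanics" model:

    VO2net = 0.32 G + 3.28 + (1 + 0.19 G) * 2.66 v**2   [mL/kg/min]

with G the treadmill grade in percent and v the belt speed in m/s.  The
mass-specific oxygen uptake is closed to kJ/min by multiplying with body
mass, converting mL to L, and applying the energy equivalent of oxygen

    19.61 + (RQ - 0.707) / 0.293 * 1.51   [kJ/L]

which spans the fat-only (19.61 at RQ 0.707) to carbohydrate-only (21.12 at
RQ 1.0) range.  The printed mass-specific form leaves the x body_mass/1000
closure implicit; it is applied explicitly here for dimensional
consistency.  VO2net is already net of resting metabolism -- no further
resting subtraction is performed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .climate import ClimateCondition

__all__ = [
    "TrialTimeSeries",
    "TrialResult",
    "ClothingEnsemble",
    "LOW_CLOTHING",
    "HIGH_CLOTHING",
    "minute_ee",
    "energy_equivalent",
    "work_ee",
    "pwc_percent",
    "mean_skin_temp",
    "annotate_termination",
    "process_trial",
    "read_trial_csv",
    "CORE_TEMP_LIMIT",
    "MAX_TRIAL_MINUTES",
    "RAMANATHAN_WEIGHTS",
    "DEFAULT_RQ",
]

CORE_TEMP_LIMIT = 39.0  # degC rectal; trial stops on reaching it
MAX_TRIAL_MINUTES = 60
DEFAULT_RQ = 0.85
RAMANATHAN_WEIGHTS = {"chest": 0.3, "arm": 0.3, "thigh": 0.2, "calf": 0.2}
SKIN_SITES = ("chest", "arm", "thigh", "calf")

# clo is the conventional clothing-insulation unit: 1 clo = 0.155 m2.K/W
M2KW_PER_CLO = 0.155


@dataclass(frozen=True)
class ClothingEnsemble:
    """Clothing worn during a trial, with its estimated thermal properties."""

    name: str
    insulation_m2kw: float
    evaporative_resistance_m2kpaw: Optional[float] = None

    @property
    def clo(self) -> float:
        return self.insulation_m2kw / M2KW_PER_CLO


LOW_CLOTHING = ClothingEnsemble("low", 0.04, 0.007)    # shorts, socks, trainers
HIGH_CLOTHING = ClothingEnsemble("high", 0.133, 0.024)  # coverall over t-shirt


@dataclass
class TrialTimeSeries:
    """Per-minute log of one treadmill trial.

    ``data`` holds one row per minute with columns ``minute``,
    ``velocity_ms``, ``grade_pct`` and optionally ``rq``, ``hr_bpm``,
    ``t_rectal_c`` and the four skin sites ``t_chest_c`` .. ``t_calf_c``.
    """

    data: pd.DataFrame
    body_mass: float
    condition: Optional[ClimateCondition] = None
    clothing: Optional[ClothingEnsemble] = None
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        for col in ("minute", "velocity_ms", "grade_pct"):
            if col not in df.columns:
                raise ValueError(f"trial log missing required column {col!r}")
        if len(df) == 0:
            raise ValueError("empty trial log")
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        if np.any(df["velocity_ms"].to_numpy() < 0):
            raise ValueError("velocities must be >= 0")
        if "rq" in df.columns:
            rq = df["rq"].dropna().to_numpy()
            if rq.size and (rq.min() < 0.7 or rq.max() > 1.0):
                raise ValueError("RQ must lie in [0.7, 1.0]")
        minutes = df["minute"].to_numpy()
        if np.any(np.diff(minutes) != 1):
            # sensor dropouts are not interpolated: truncate at the first gap
            gap = int(np.argmax(np.diff(minutes) != 1)) + 1
            warnings.warn(
                f"non-contiguous minute base; truncating at minute {int(minutes[gap - 1])}"
            )
            self.data = df.iloc[:gap].reset_index(drop=True)
        if len(self.data) > MAX_TRIAL_MINUTES:
            raise ValueError(f"trial exceeds the {MAX_TRIAL_MINUTES}-minute protocol limit")

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class TrialResult:
    """Processed trial: cumulative work EE, mean skin temperature, termination."""

    work_ee: float                  # kJ above resting, cumulative
    mean_tskin: Optional[float]     # degC, trial average (None without skin data)
    terminated_early: str           # none | core_39 | speed_zero
    minutes_completed: int


def energy_equivalent(rq) -> float:
    """Energy released per litre of oxygen, kJ/L, as a function of RQ."""
    rq = np.asarray(rq, dtype=float)
    out = 19.61 + (rq - 0.707) / 0.293 * 1.51
    return out if out.ndim else float(out)


def minute_ee(grade, velocity, rq=DEFAULT_RQ, body_mass: float = 77.0):
    """Gross-above-resting energy expenditure for one minute of walking, kJ/min.

    Parameters
    ----------
    grade : float
        Treadmill grade, percent (5 means 5 %); must be >= 0 -- the model
        was calibrated for level and uphill walking only.
    velocity : float
        Belt speed, m/s.
    rq : float
        Respiratory quotient (defaults to the assumed 0.85).
    body_mass : float
        Participant mass, kg.
    """
    g = np.asarray(grade, dtype=float)
    v = np.asarray(velocity, dtype=float)
    if np.any(g < 0):
        raise ValueError("grade must be >= 0 (level/uphill walking model)")
    vo2_net = 0.32 * g + 3.28 + (1.0 + 0.19 * g) * (2.66 * v**2)  # mL/kg/min
    litres_per_min = vo2_net * body_mass / 1000.0
    out = litres_per_min * energy_equivalent(rq)
    return out if np.ndim(out) else float(out)


def annotate_termination(trial: TrialTimeSeries):
    """Safety/termination annotation.

    Returns ``(reason, minutes_completed)`` with reason one of ``none``,
    ``core_39`` (rectal temperature reached 39.0 degC) or ``speed_zero``
    (the heart-rate controller drove the belt to a standstill after the
    first minute).  The earliest triggering minute wins.
    """
    df = trial.data
    n = len(df)
    stop = n
    reason = "none"
    if "t_rectal_c" in df.columns:
        hot = np.flatnonzero(df["t_rectal_c"].to_numpy() >= CORE_TEMP_LIMIT)
        if hot.size:
            stop, reason = int(hot[0]) + 1, "core_39"
    v = df["velocity_ms"].to_numpy()
    zero = np.flatnonzero(v[1:] == 0.0) + 1
    if zero.size and int(zero[0]) + 1 < stop:
        stop, reason = int(zero[0]) + 1, "speed_zero"
    return reason, stop


def work_ee(trial: TrialTimeSeries) -> float:
    """Cumulative work energy expenditure over the trial, kJ.

    Sums :func:`minute_ee` over completed minutes (early termination
    truncates the sum).  RQ defaults to 0.85 where not recorded.
    """
    _, stop = annotate_termination(trial)
    df = trial.data.iloc[:stop]
    rq = df["rq"].fillna(DEFAULT_RQ).to_numpy() if "rq" in df.columns else DEFAULT_RQ
    ee = minute_ee(df["grade_pct"].to_numpy(), df["velocity_ms"].to_numpy(),
                   rq, trial.body_mass)
    return float(np.sum(ee))


def pwc_percent(hot: TrialResult, cool: TrialResult) -> float:
    """Physical work capacity: 100 x hot work EE / cool work EE, %.

    Values above 100 are allowed (a trial can out-produce the reference).
    """
    if cool.work_ee <= 0:
        raise ValueError("cool reference trial has non-positive work EE")
    return 100.0 * hot.work_ee / cool.work_ee


def mean_skin_temp(skin_temps: Dict[str, float]) -> float:
    """Ramanathan 4-site mean skin temperature: 0.3(chest+arm) + 0.2(thigh+calf)."""
    for site in SKIN_SITES:
        if site not in skin_temps or skin_temps[site] is None:
            raise ValueError(f"missing skin temperature site {site!r}")
    return float(sum(RAMANATHAN_WEIGHTS[s] * skin_temps[s] for s in SKIN_SITES))


def _trial_mean_tskin(trial: TrialTimeSeries, stop: int) -> Optional[float]:
    cols = [f"t_{s}_c" for s in SKIN_SITES]
    if not all(c in trial.data.columns for c in cols):
        return None
    df = trial.data.iloc[:stop]
    per_min = [
        mean_skin_temp({s: row[f"t_{s}_c"] for s in SKIN_SITES})
        for _, row in df.iterrows()
    ]
    return float(np.mean(per_min))


def process_trial(trial: TrialTimeSeries) -> TrialResult:
    """Full per-trial pipeline: termination, cumulative EE, mean skin temperature."""
    reason, stop = annotate_termination(trial)
    return TrialResult(
        work_ee=work_ee(trial),
        mean_tskin=_trial_mean_tskin(trial, stop),
        terminated_early=reason,
        minutes_completed=stop,
    )


def read_trial_csv(path, meta_path=None) -> TrialTimeSeries:
    """Read a trial log CSV (and optional JSON sidecar with body mass/climate).

    The sidecar carries ``body_mass_kg`` plus optional ``ta_c``, ``rh_pct``
    and ``clothing`` (low/high); without one, body mass must appear as a
    ``body_mass_kg`` column in the CSV.
    """
    df = pd.read_csv(path)
    meta: Dict = {}
    if meta_path is not None:
        meta = json.loads(Path(meta_path).read_text())
    elif Path(path).with_suffix(".json").exists():
        meta = json.loads(Path(path).with_suffix(".json").read_text())
    if "body_mass_kg" in meta:
        mass = float(meta["body_mass_kg"])
    elif "body_mass_kg" in df.columns:
        mass = float(df["body_mass_kg"].iloc[0])
        df = df.drop(columns=["body_mass_kg"])
    else:
        raise ValueError("body mass not found in sidecar or CSV")
    cond = None
    if "ta_c" in meta and "rh_pct" in meta:
        cond = ClimateCondition(float(meta["ta_c"]), float(meta["rh_pct"]))
    clothing = {"low": LOW_CLOTHING, "high": HIGH_CLOTHING}.get(meta.get("clothing"))
    return TrialTimeSeries(df, body_mass=mass, condition=cond, clothing=clothing, meta=meta)
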