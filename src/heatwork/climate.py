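"""Thermal climate indices for occupational heat-stress assessment.

All calculators take dry-bulb air temperature in degrees Celsius and relative
humidity in percent (0-100) and return an equivalent temperature in degrees
Celsius.  They accept scalars or numpy arrays and broadcast like numpy ufuncs.

Implemented indices
-------------------
ambient_vapour_pressure
    Ambient water vapour pressure in kPa from air temperature and humidity.
wet_bulb
    Aspirated (psychrometric) wet-bulb temperature, the Bernard-Pourmoghani
    linearisation in vapour pressure and dry-bulb temperature.
humidex
    The Canadian apparent-temperature index of Masterton and Richardson.
heat_index
    The US heat index (Rothfusz nine-term regression), evaluated in degrees
    Fahrenheit internally and converted back to Celsius.
wbgt_indoor_estimate
    Indoor wet bulb globe temperature composed as 0.7 Tnwb + 0.3 Tg with the
    aspirated wet bulb standing in for the natural wet bulb.  An estimate for
    still indoor air, clearly flagged as such; measured WBGT should be used
    when a sensor is available.
utci
    A plug-in boundary for the Universal Thermal Climate Index: either a
    user-supplied precomputed value or a user-supplied evaluator of the
    published operational-procedure polynomial.  Never silently falls back.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

__all__ = [
    "ClimateCondition",
    "IndexValue",
    "ambient_vapour_pressure",
    "saturation_vapour_pressure",
    "wet_bulb",
    "humidex",
    "heat_index",
    "wbgt_indoor_estimate",
    "utci",
    "compute_index",
    "INDEX_FUNCTIONS",
]

# hard input guards; the models' own validity windows are narrower and are
# tracked separately via extrapolation flags
_TA_MIN, _TA_MAX = -20.0, 60.0


def _check_inputs(air_temp, rel_humidity) -> None:
    ta = np.asarray(air_temp, dtype=float)
    rh = np.asarray(rel_humidity, dtype=float)
    if np.any((rh < 0.0) | (rh > 100.0)):
        raise ValueError("rel_humidity must lie in [0, 100] %")
    if np.any((ta < _TA_MIN) | (ta > _TA_MAX)):
        raise ValueError(f"air_temp must lie in [{_TA_MIN}, {_TA_MAX}] degC")


@dataclass(frozen=True)
class ClimateCondition:
    """One thermal environment.

    Parameters
    ----------
    air_temp : float
        Dry-bulb air temperature, degC.
    rel_humidity : float
        Relative humidity, % (0-100).
    globe_temp : float, optional
        Black-globe temperature, degC.  When absent, indoor estimators
        substitute ``air_temp`` (valid for still air without radiant load).
    air_velocity : float, optional
        Air speed, m/s.  The calibration chamber was near-still (~0.2 m/s).
    radiant_temp : float, optional
        Mean radiant temperature, degC (only consumed by UTCI evaluators).
    """

    air_temp: float
    rel_humidity: float
    globe_temp: Optional[float] = None
    air_velocity: Optional[float] = None
    radiant_temp: Optional[float] = None

    def __post_init__(self) -> None:
        _check_inputs(self.air_temp, self.rel_humidity)


@dataclass(frozen=True)
class IndexValue:
    """A computed index value with extrapolation bookkeeping."""

    index_name: str
    value: float
    extrapolated: bool = False
    estimated: bool = False  # True when a proxy estimator (indoor WBGT) was used


def saturation_vapour_pressure(air_temp, *, as_printed: bool = False):
    """Saturation water vapour pressure over water, kPa.

    Uses exp(18.956 - 4030.18/(Ta + 235)).  That exponential yields
    hectopascals (about 73.7 at 40 degC, where saturation pressure is
    7.37 kPa), so the result is divided by 10 to obtain kilopascals -- the
    unit the wet-bulb formula's coefficients require.  Pass
    ``as_printed=True`` to skip the correction and get the raw hPa-scale
    figure.
    """
    ta = np.asarray(air_temp, dtype=float)
    e = np.exp(18.956 - 4030.18 / (ta + 235.0))
    if not as_printed:
        e = e / 10.0
    return e if e.ndim else float(e)


def ambient_vapour_pressure(air_temp, rel_humidity, *, as_printed: bool = False):
    """Ambient water vapour pressure, kPa.

    RH/100 times the saturation pressure at ``air_temp``.  Monotone
    increasing in both arguments.
    """
    _check_inputs(air_temp, rel_humidity)
    rh = np.asarray(rel_humidity, dtype=float)
    pa = saturation_vapour_pressure(air_temp, as_printed=as_printed) * rh / 100.0
    return pa if np.ndim(pa) else float(pa)


def wet_bulb(air_temp, rel_humidity):
    """Aspirated (psychrometric) wet-bulb temperature, degC.

    Twb = 0.376 + 5.79 Pa + (0.388 - 0.0465 Pa) Tdb with Pa in kPa.
    For RH < 100 the wet bulb reads below the dry bulb.
    """
    pa = ambient_vapour_pressure(air_temp, rel_humidity)
    ta = np.asarray(air_temp, dtype=float)
    twb = 0.376 + 5.79 * np.asarray(pa) + (0.388 - 0.0465 * np.asarray(pa)) * ta
    return twb if twb.ndim else float(twb)


def humidex(air_temp, rel_humidity):
    """Humidex (Masterton-Richardson), degC.

    Ta + 5/9 (e - 10) with e the ambient vapour pressure in hPa from the
    index's own embedded Magnus-type formula (deliberately not unified with
    :func:`ambient_vapour_pressure`).
    """
    _check_inputs(air_temp, rel_humidity)
    ta = np.asarray(air_temp, dtype=float)
    rh = np.asarray(rel_humidity, dtype=float)
    e_hpa = 6.112 * 10.0 ** (7.5 * ta / (237.7 + ta)) * rh / 100.0
    hx = ta + (5.0 / 9.0) * (e_hpa - 10.0)
    return hx if hx.ndim else float(hx)


def heat_index(air_temp, rel_humidity):
    """Heat index (Rothfusz regression), degC.

    The nine-term polynomial is evaluated on Ta in degrees Fahrenheit and the
    result converted back with (HI_F - 32) * 5/9.  The raw regression is used
    across the whole input range: no low- or high-humidity adjustment
    branches are applied, so values below the regression's meteorological
    comfort zone are a smooth extrapolation of the same polynomial.
    """
    _check_inputs(air_temp, rel_humidity)
    ta = np.asarray(air_temp, dtype=float)
    rh = np.asarray(rel_humidity, dtype=float)
    tf = ta * 9.0 / 5.0 + 32.0
    hi_f = (
        -42.379
        + 2.04901523 * tf
        + 10.14333127 * rh
        - 0.22475541 * tf * rh
        - 6.83783e-3 * tf**2
        - 5.481717e-2 * rh**2
        + 1.22874e-3 * tf**2 * rh
        + 8.5282e-4 * tf * rh**2
        - 1.99e-6 * tf**2 * rh**2
    )
    hi = (hi_f - 32.0) * 5.0 / 9.0
    return hi if hi.ndim else float(hi)


def wbgt_indoor_estimate(cond: ClimateCondition) -> IndexValue:
    """Indoor WBGT estimate, degC: 0.7 Tnwb + 0.3 Tg.

    The aspirated wet bulb stands in for the natural wet bulb -- a good proxy
    only in near-still air -- and the globe temperature defaults to the air
    temperature when not supplied (no radiant load).  The result is flagged
    ``estimated``; measured WBGT bypasses this function entirely.
    """
    tg = cond.globe_temp if cond.globe_temp is not None else cond.air_temp
    twb = wet_bulb(cond.air_temp, cond.rel_humidity)
    return IndexValue("wbgt", 0.7 * twb + 0.3 * tg, estimated=True)


class UTCIUnavailableError(RuntimeError):
    """Raised when UTCI is requested without an evaluator or precomputed value."""


def utci(
    cond: ClimateCondition,
    *,
    precomputed: Optional[float] = None,
    evaluator: Optional[Callable[[ClimateCondition], float]] = None,
) -> IndexValue:
    """Universal Thermal Climate Index, degC -- plug-in boundary.

    The UTCI operational polynomial (a sixth-order regression on air
    temperature, vapour pressure, wind and radiant temperature) is not
    reimplemented here.  Supply either a ``precomputed`` UTCI value or an
    ``evaluator`` callable wrapping a reference implementation.  With
    neither, an explicit :class:`UTCIUnavailableError` is raised -- the air
    temperature is never silently substituted.
    """
    if precomputed is not None:
        return IndexValue("utci", float(precomputed), estimated=False)
    if evaluator is not None:
        return IndexValue("utci", float(evaluator(cond)), estimated=True)
    raise UTCIUnavailableError(
        "UTCI unavailable: supply precomputed=<value> or evaluator=<callable>"
    )


INDEX_FUNCTIONS = {
    "wet_bulb": wet_bulb,
    "humidex": humidex,
    "heat_index": heat_index,
}


def compute_index(name: str, cond: ClimateCondition, **utci_kwargs) -> IndexValue:
    """Compute any registered index for a single condition.

    ``wet_bulb``, ``humidex`` and ``heat_index`` need only Ta/RH; ``wbgt``
    routes through the indoor estimator; ``utci`` through the plug-in
    boundary (see :func:`utci` for its keyword arguments).
    """
    if name in INDEX_FUNCTIONS:
        return IndexValue(name, float(INDEX_FUNCTIONS[name](cond.air_temp, cond.rel_humidity)))
    if name == "wbgt":
        return wbgt_indoor_estimate(cond)
    if name == "utci":
        return utci(cond, **utci_kwargs)
    known = sorted([*INDEX_FUNCTIONS, "wbgt", "utci"])
    raise KeyError(f"unknown index {name!r}; available: {', '.join(known)}")
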