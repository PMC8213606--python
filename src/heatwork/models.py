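"""Sigmoid physical-work-capacity (PWC) prediction equations.

PWC is the percentage of the work output achievable in a cool (15 degC)
reference climate.  Its decline with heat follows a fixed-asymptote sigmoid

    PWC(x) = 100 / (1 + (PWC50 / x) ** HillSlope)

where ``x`` is a heat-stress index (degC), ``PWC50`` the index value
eliciting 50 % PWC and ``HillSlope`` (negative for heat indices) the curve
steepness.  The upper and lower plateaus are fixed at 100 and 0 %.

For air temperature and relative humidity directly, PWC50 and HillSlope are
replaced by log-humidity models:

    PWC(Ta, RH) = 100 / (1 + ((a ln RH + b) / Ta) ** (c ln RH + d))

Coefficient sets are data, not code: they live in a versioned JSON registry
(:data:`DEFAULT_REGISTRY_PATH`) so clothing-specific or supplementary sets
can be loaded without code changes.  Every prediction carries an
extrapolation flag when evaluated outside the range its curve was
calibrated on; extrapolation is computed and flagged, never refused.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "SigmoidParams",
    "TaRhParams",
    "PerceptionParams",
    "ParameterRegistry",
    "load_registry",
    "sigmoid",
    "pwc_from_index",
    "pwc_from_ta_rh",
    "pwc_from_tskin",
    "sensation_from_tskin",
    "comfort_from_tskin",
    "pwc_matrix",
    "DEFAULT_REGISTRY_PATH",
]

DEFAULT_REGISTRY_PATH = resources.files("heatwork") / "data" / "parameters.json"


@dataclass(frozen=True)
class SigmoidParams:
    """One fixed-asymptote sigmoid PWC curve against a heat-stress index."""

    index_name: str
    pwc50: float
    hillslope: float
    top: float = 100.0
    bottom: float = 0.0
    valid_range: Tuple[float, float] = (-np.inf, np.inf)
    provenance: str = "user"
    r_squared: Optional[float] = None
    rmse: Optional[float] = None

    def __post_init__(self) -> None:
        if self.hillslope == 0:
            raise ValueError("hillslope must be nonzero")
        lo, hi = self.valid_range
        if not lo < hi:
            raise ValueError("valid_range must satisfy min < max")


@dataclass(frozen=True)
class TaRhParams:
    """Coefficients of the air-temperature/relative-humidity PWC model.

    ``a`` and ``b`` parameterise the numerator (PWC50) model
    ``a ln(RH) + b`` in degC; ``c`` and ``d`` the exponent (HillSlope) model
    ``c ln(RH) + d``.
    """

    a: float
    b: float
    c: float
    d: float
    ta_valid: Tuple[float, float] = (15.0, 50.0)
    rh_valid: Tuple[float, float] = (20.0, 80.0)
    provenance: str = "user"
    r_squared: Optional[float] = None
    rmse: Optional[float] = None

    def pwc50(self, rel_humidity):
        return self.a * np.log(rel_humidity) + self.b

    def hillslope(self, rel_humidity):
        return self.c * np.log(rel_humidity) + self.d


@dataclass(frozen=True)
class PerceptionParams:
    """Skin-temperature models for thermal sensation and comfort.

    sensation = coefficient * exp(rate * Tskin); comfort = slope * Tskin +
    intercept.  Valid for mean skin temperatures of 30-38 degC.
    """

    sensation_coefficient: float = 0.13
    sensation_rate: float = 0.15
    comfort_slope: float = 0.47
    comfort_intercept: float = -13.06
    tskin_valid: Tuple[float, float] = (30.0, 38.0)


@dataclass
class ParameterRegistry:
    """All shipped and user-loaded coefficient sets, keyed by index name."""

    sigmoid: dict = field(default_factory=dict)
    ta_rh: dict = field(default_factory=dict)
    perception: PerceptionParams = field(default_factory=PerceptionParams)
    source: str = "builtin"

    def get_sigmoid(self, index_name: str) -> SigmoidParams:
        try:
            return self.sigmoid[index_name]
        except KeyError:
            raise KeyError(
                f"no sigmoid parameter set {index_name!r}; "
                f"available: {', '.join(sorted(self.sigmoid))}"
            ) from None

    def get_ta_rh(self, name: str = "pooled") -> TaRhParams:
        try:
            return self.ta_rh[name]
        except KeyError:
            raise KeyError(
                f"no Ta/RH parameter set {name!r}; "
                f"available: {', '.join(sorted(self.ta_rh))}"
            ) from None

    def register(self, params: Union[SigmoidParams, TaRhParams], name: Optional[str] = None):
        if isinstance(params, SigmoidParams):
            self.sigmoid[name or params.index_name] = params
        elif isinstance(params, TaRhParams):
            self.ta_rh[name or "user"] = params
        else:  # pragma: no cover - defensive
            raise TypeError(f"cannot register {type(params).__name__}")


def load_registry(path: Union[str, Path, None] = None) -> ParameterRegistry:
    """Load a parameter registry from JSON (the packaged one by default)."""
    if path is None:
        raw = json.loads(DEFAULT_REGISTRY_PATH.read_text())
        source = "builtin"
    else:
        raw = json.loads(Path(path).read_text())
        source = str(path)
    reg = ParameterRegistry(source=source)
    for name, entry in raw.get("sigmoid", {}).items():
        reg.sigmoid[name] = SigmoidParams(
            index_name=name,
            pwc50=entry["pwc50"],
            hillslope=entry["hillslope"],
            top=entry.get("top", 100.0),
            bottom=entry.get("bottom", 0.0),
            valid_range=tuple(entry.get("valid_range", (-np.inf, np.inf))),
            provenance=entry.get("provenance", source),
            r_squared=entry.get("r_squared"),
            rmse=entry.get("rmse"),
        )
    for name, entry in raw.get("ta_rh", {}).items():
        reg.ta_rh[name] = TaRhParams(
            a=entry["a"],
            b=entry["b"],
            c=entry["c"],
            d=entry["d"],
            ta_valid=tuple(entry.get("ta_valid", (15.0, 50.0))),
            rh_valid=tuple(entry.get("rh_valid", (20.0, 80.0))),
            provenance=entry.get("provenance", source),
            r_squared=entry.get("r_squared"),
            rmse=entry.get("rmse"),
        )
    perc = raw.get("perception")
    if perc:
        reg.perception = PerceptionParams(
            sensation_coefficient=perc["sensation"]["coefficient"],
            sensation_rate=perc["sensation"]["rate"],
            comfort_slope=perc["comfort"]["slope"],
            comfort_intercept=perc["comfort"]["intercept"],
            tskin_valid=tuple(perc["sensation"].get("tskin_valid", (30.0, 38.0))),
        )
    return reg


_default_registry: Optional[ParameterRegistry] = None


def default_registry() -> ParameterRegistry:
    global _default_registry
    if _default_registry is None:
        _default_registry = load_registry()
    return _default_registry


def sigmoid(x, pwc50: float, hillslope: float, top: float = 100.0, bottom: float = 0.0):
    """The fixed-asymptote dose-response curve bottom + (top-bottom)/(1+(pwc50/x)^h)."""
    x = np.asarray(x, dtype=float)
    out = bottom + (top - bottom) / (1.0 + (pwc50 / x) ** hillslope)
    return out if out.ndim else float(out)


def pwc_from_index(x, params: Union[SigmoidParams, str]):
    """PWC (%) from a heat-stress index value.

    Parameters may be given as a :class:`SigmoidParams` or the name of a
    registered set.  Returns ``(pwc, extrapolated)``; both are arrays when
    ``x`` is an array.  ``x`` must be strictly positive (the power-law form
    is undefined at zero).
    """
    if isinstance(params, str):
        params = default_registry().get_sigmoid(params)
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("index value x must be > 0 (power-law sigmoid undefined)")
    pwc = sigmoid(x, params.pwc50, params.hillslope, params.top, params.bottom)
    lo, hi = params.valid_range
    extrap = (x < lo) | (x > hi)
    if np.ndim(pwc):
        return pwc, extrap
    return float(pwc), bool(extrap)


def pwc_from_ta_rh(air_temp, rel_humidity, params: Optional[TaRhParams] = None):
    """PWC (%) directly from air temperature (degC) and relative humidity (%).

    Evaluates the log-humidity sigmoid; returns ``(pwc, extrapolated)`` with
    the flag set outside the Ta 15-50 degC / RH 20-80 % calibration window.
    """
    if params is None:
        params = default_registry().get_ta_rh()
    ta = np.asarray(air_temp, dtype=float)
    rh = np.asarray(rel_humidity, dtype=float)
    if np.any(rh <= 0):
        raise ValueError("rel_humidity must be > 0 (log transform undefined)")
    if np.any(ta <= 0):
        raise ValueError("air_temp must be > 0 in the ratio form")
    pwc = 100.0 / (1.0 + (params.pwc50(rh) / ta) ** params.hillslope(rh))
    extrap = (
        (ta < params.ta_valid[0])
        | (ta > params.ta_valid[1])
        | (rh < params.rh_valid[0])
        | (rh > params.rh_valid[1])
    )
    if np.ndim(pwc):
        return pwc, extrap
    return float(pwc), bool(extrap)


def _warn_tskin(tskin, valid: Tuple[float, float]) -> None:
    import warnings

    t = np.asarray(tskin, dtype=float)
    if np.any((t < valid[0]) | (t > valid[1])):
        warnings.warn(
            f"skin temperature outside the calibrated range {valid[0]}-{valid[1]} degC",
            stacklevel=3,
        )


def pwc_from_tskin(tskin):
    """PWC (%) from mean skin temperature (degC); warns outside 30-38 degC."""
    params = default_registry().get_sigmoid("tskin")
    _warn_tskin(tskin, params.valid_range)
    return sigmoid(tskin, params.pwc50, params.hillslope)


def sensation_from_tskin(tskin, params: Optional[PerceptionParams] = None):
    """Thermal sensation (scale units) from mean skin temperature.

    Literal exponential model; note its raw magnitude at warm skin
    temperatures reflects the modified numeric scale used during
    calibration, not a standard 9-point sensation scale.
    """
    if params is None:
        params = default_registry().perception
    _warn_tskin(tskin, params.tskin_valid)
    t = np.asarray(tskin, dtype=float)
    out = params.sensation_coefficient * np.exp(params.sensation_rate * t)
    return out if out.ndim else float(out)


def comfort_from_tskin(tskin, params: Optional[PerceptionParams] = None):
    """Thermal comfort (scale units) from mean skin temperature (linear model)."""
    if params is None:
        params = default_registry().perception
    _warn_tskin(tskin, params.tskin_valid)
    t = np.asarray(tskin, dtype=float)
    out = params.comfort_slope * t + params.comfort_intercept
    return out if out.ndim else float(out)


def pwc_matrix(
    ta_grid: Optional[Sequence[float]] = None,
    rh_grid: Optional[Sequence[float]] = None,
    params: Optional[TaRhParams] = None,
    extrapolation_threshold: float = 25.0,
):
    """PWC over a Ta x RH grid with per-cell extrapolation flags.

    Default grid: Ta 15-50 degC step 1, RH 20-80 % step 5 (the calibration
    window).  Cells predicting PWC below ``extrapolation_threshold`` (25 %
    by default -- below the lowest observed group mean) are flagged as
    extrapolated, as are cells outside the validity window.

    Returns
    -------
    (ta_grid, rh_grid, pwc, extrapolated)
        ``pwc`` and ``extrapolated`` have shape ``(len(rh_grid), len(ta_grid))``.
    """
    ta_grid = np.arange(15.0, 51.0, 1.0) if ta_grid is None else np.asarray(ta_grid, float)
    rh_grid = np.arange(20.0, 81.0, 5.0) if rh_grid is None else np.asarray(rh_grid, float)
    ta2, rh2 = np.meshgrid(ta_grid, rh_grid)
    pwc, extrap = pwc_from_ta_rh(ta2, rh2, params)
    extrap = extrap | (pwc < extrapolation_threshold)
    return ta_grid, rh_grid, pwc, extrap


def matrix_to_frame(ta_grid, rh_grid, pwc, extrapolated):
    """Long-format DataFrame (ta_c, rh_pct, pwc_pct, extrapolated) for CSV export."""
    import pandas as pd

    ta2, rh2 = np.meshgrid(ta_grid, rh_grid)
    return pd.DataFrame(
        {
            "ta_c": ta2.ravel(),
            "rh_pct": rh2.ravel(),
            "pwc_pct": np.round(pwc.ravel(), 2),
            "extrapolated": extrapolated.ravel(),
        }
    )


def plot_matrix(ta_grid, rh_grid, pwc, extrapolated=None, ax=None):
    """Render the PWC matrix as a heatmap; hatches extrapolated cells."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    mesh = ax.pcolormesh(ta_grid, rh_grid, pwc, cmap="RdYlGn", vmin=0, vmax=100)
    if extrapolated is not None and np.any(extrapolated):
        ax.contourf(
            ta_grid, rh_grid, extrapolated.astype(float), levels=[0.5, 1.5],
            hatches=["//"], colors="none",
        )
    ax.set_xlabel("Air temperature (degC)")
    ax.set_ylabel("Relative humidity (%)")
    ax.figure.colorbar(mesh, ax=ax, label="Physical work capacity (%)")
    return ax
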