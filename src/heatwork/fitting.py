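"""Nonlinear least-squares fitting of the PWC dose-response models.

Two model classes in the statsmodels idiom -- construct from data, call
``fit()``, get a results object with estimates, uncertainties, goodness
metrics and a ``summary()`` table:

``SigmoidCapacityModel``
    Fixed-asymptote sigmoid PWC = 100 / (1 + (PWC50/x)^HillSlope) against a
    single heat-stress index.  Only PWC50 and HillSlope are free; the top
    and bottom plateaus are fixed at 100 and 0 %.

``TaRhCapacityModel``
    The air-temperature/log-humidity model
    PWC = 100 / (1 + ((a ln RH + b)/Ta)^(c ln RH + d)), fitted by the
    three-step tuning procedure: (1) independent sigmoid fits within
    humidity strata (20/50/80 % by default); (2) linear regressions of the
    per-stratum PWC50 and HillSlope on ln(RH); (3) a joint four-parameter
    nonlinear fit started from the step-2 slopes and intercepts.  All
    intermediate artifacts are kept on the results object.

Least squares is unweighted on absolute residuals (matching common
statistics-package defaults); the optimizer is scipy's trust-region
reflective with PWC50 bounded positive.  RMSE uses the population form
sqrt(SSres/n) by default, with a residual-degrees-of-freedom option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .models import SigmoidParams, TaRhParams, sigmoid

__all__ = [
    "goodness",
    "SigmoidCapacityModel",
    "SigmoidCapacityResults",
    "TaRhCapacityModel",
    "TaRhCapacityResults",
    "FitConvergenceError",
]


class FitConvergenceError(RuntimeError):
    """Raised when the optimizer fails; carries the optimizer's diagnostics."""


def goodness(y_obs, y_pred, *, ddof: int = 0) -> Tuple[Optional[float], float]:
    """Coefficient of determination and root-mean-square error.

    R^2 = 1 - SSres/SStot; RMSE = sqrt(SSres / (n - ddof)).  With zero
    variance in ``y_obs`` the R^2 is undefined and returned as None.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape:
        raise ValueError("y_obs and y_pred must have the same length")
    n = y_obs.size
    if n < 2:
        raise ValueError("need at least 2 points")
    ss_res = float(np.sum((y_obs - y_pred) ** 2))
    ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
    rmse = float(np.sqrt(ss_res / (n - ddof)))
    r2 = None if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return r2, rmse


def _summary_table(title: str, rows, stats) -> str:
    width = 58
    lines = [title.center(width), "=" * width]
    lines.append(f"{'':<12}{'coef':>12}{'std err':>12}")
    lines.append("-" * width)
    for name, val, se in rows:
        se_s = f"{se:.3f}" if se is not None and np.isfinite(se) else "nan"
        lines.append(f"{name:<12}{val:>12.4f}{se_s:>12}")
    lines.append("-" * width)
    for name, val in stats:
        lines.append(f"{name:<20}{val}")
    lines.append("=" * width)
    return "\n".join(lines)


class SigmoidCapacityModel:
    """Fixed-asymptote sigmoid dose-response model of PWC against an index.

    Parameters
    ----------
    pwc : array-like
        Observed physical work capacity, %.
    x : array-like
        Heat-stress index values (degC); must be strictly positive.
    index_name : str
        Label for the predictor (propagates into the fitted parameter set).
    top, bottom : float
        Fixed asymptotes (100 and 0 for every shipped curve).
    """

    def __init__(self, pwc, x, index_name: str = "index",
                 top: float = 100.0, bottom: float = 0.0):
        self.endog = np.asarray(pwc, dtype=float)
        self.exog = np.asarray(x, dtype=float)
        if self.endog.shape != self.exog.shape or self.endog.ndim != 1:
            raise ValueError("pwc and x must be 1-d arrays of equal length")
        if self.endog.size < 4:
            raise ValueError("need at least 4 points to fit two parameters")
        if np.any(self.exog <= 0):
            raise ValueError("all index values must be > 0")
        self.index_name = index_name
        self.top = top
        self.bottom = bottom

    @classmethod
    def from_dataframe(cls, data, x_col: str, y_col: str = "pwc_pct", **kw):
        return cls(data[y_col].to_numpy(), data[x_col].to_numpy(), index_name=x_col, **kw)

    def predict(self, params, x=None):
        x = self.exog if x is None else np.asarray(x, dtype=float)
        return sigmoid(x, params[0], params[1], self.top, self.bottom)

    def fit(self, start_params: Optional[Sequence[float]] = None,
            rmse_ddof: int = 0) -> "SigmoidCapacityResults":
        """Least-squares fit of (PWC50, HillSlope).

        Default start values are (median of x, -4): the midpoint of the
        observed index range with a moderately steep decline.
        """
        if start_params is None:
            start_params = (float(np.median(self.exog)), -4.0)
        y, x = self.endog, self.exog

        def resid(p):
            return sigmoid(x, p[0], p[1], self.top, self.bottom) - y

        sol = optimize.least_squares(
            resid, x0=np.asarray(start_params, float),
            bounds=([1e-9, -np.inf], [np.inf, np.inf]), method="trf",
        )
        if not sol.success:
            raise FitConvergenceError(
                f"sigmoid fit did not converge: {sol.message} (status {sol.status})"
            )
        pwc50, hillslope = sol.x
        yhat = self.predict(sol.x)
        r2, rmse = goodness(y, yhat, ddof=rmse_ddof)
        # covariance from the Jacobian at the solution (Gauss-Newton approx.)
        dof = max(y.size - 2, 1)
        s2 = float(np.sum(sol.fun**2)) / dof
        try:
            jtj_inv = np.linalg.pinv(sol.jac.T @ sol.jac)
            cov = s2 * jtj_inv
        except np.linalg.LinAlgError:  # pragma: no cover
            cov = np.full((2, 2), np.nan)
        return SigmoidCapacityResults(
            model=self,
            params=np.array([pwc50, hillslope]),
            cov_params=cov,
            r_squared=r2,
            rmse=rmse,
            n_points=y.size,
            converged=True,
            start_params=tuple(start_params),
        )


@dataclass
class SigmoidCapacityResults:
    """Results of a :class:`SigmoidCapacityModel` fit."""

    model: SigmoidCapacityModel
    params: np.ndarray  # (pwc50, hillslope)
    cov_params: np.ndarray
    r_squared: Optional[float]
    rmse: float
    n_points: int
    converged: bool
    start_params: Tuple[float, float]

    @property
    def pwc50(self) -> float:
        return float(self.params[0])

    @property
    def hillslope(self) -> float:
        return float(self.params[1])

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    def predict(self, x):
        return self.model.predict(self.params, x)

    def to_sigmoid_params(self, valid_range=None, provenance: str = "fitted") -> SigmoidParams:
        """Freeze the estimates into a registrable parameter set."""
        if valid_range is None:
            valid_range = (float(self.model.exog.min()), float(self.model.exog.max()))
        return SigmoidParams(
            index_name=self.model.index_name, pwc50=self.pwc50,
            hillslope=self.hillslope, top=self.model.top, bottom=self.model.bottom,
            valid_range=tuple(valid_range), provenance=provenance,
            r_squared=self.r_squared, rmse=self.rmse,
        )

    def summary(self) -> str:
        r2 = "undefined" if self.r_squared is None else f"{self.r_squared:.4f}"
        return _summary_table(
            f"Sigmoid PWC model [{self.model.index_name}]",
            [("PWC50", self.pwc50, self.bse[0]), ("HillSlope", self.hillslope, self.bse[1])],
            [("R-squared:", r2), ("RMSE (PWC %):", f"{self.rmse:.3f}"),
             ("N points:", self.n_points),
             ("Asymptotes:", f"top={self.model.top:g}, bottom={self.model.bottom:g} (fixed)")],
        )

    def plot(self, ax=None):
        """Data and fitted curve over the observed index range."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.model.exog
        ax.scatter(x, self.model.endog, s=25, label="observed")
        xg = np.linspace(x.min(), x.max(), 200)
        ax.plot(xg, self.predict(xg), "r-", label="fit")
        ax.set_xlabel(f"{self.model.index_name} (degC)")
        ax.set_ylabel("PWC (%)")
        ax.legend()
        return ax


def _eq_ta_rh(ta, rh, a, b, c, d):
    lnrh = np.log(rh)
    return 100.0 / (1.0 + ((a * lnrh + b) / ta) ** (c * lnrh + d))


@dataclass
class _LinearStep:
    """Step-2 artifact: a straight line parameter = slope*ln(RH) + intercept."""

    slope: float
    intercept: float
    points: Dict[float, float] = field(default_factory=dict)


class TaRhCapacityModel:
    """Air-temperature/log-humidity PWC model fitted by the three-step procedure.

    Parameters
    ----------
    pwc : array-like
        Observed PWC, %.
    air_temp, rel_humidity : array-like
        Nominal climate of each observation (degC, %).
    """

    def __init__(self, pwc, air_temp, rel_humidity):
        self.endog = np.asarray(pwc, dtype=float)
        self.ta = np.asarray(air_temp, dtype=float)
        self.rh = np.asarray(rel_humidity, dtype=float)
        if not (self.endog.shape == self.ta.shape == self.rh.shape):
            raise ValueError("pwc, air_temp, rel_humidity must have equal length")
        if np.unique(self.rh).size < 3:
            raise ValueError("need at least 3 distinct humidity levels")
        if np.any(self.rh <= 0) or np.any(self.ta <= 0):
            raise ValueError("air_temp and rel_humidity must be positive")

    @classmethod
    def from_dataframe(cls, data, y_col: str = "pwc_pct",
                       ta_col: str = "ta_c", rh_col: str = "rh_pct"):
        return cls(data[y_col].to_numpy(), data[ta_col].to_numpy(), data[rh_col].to_numpy())

    def predict(self, params, ta=None, rh=None):
        ta = self.ta if ta is None else np.asarray(ta, float)
        rh = self.rh if rh is None else np.asarray(rh, float)
        return _eq_ta_rh(ta, rh, *params)

    def fit(self, strata: Sequence[float] = (20.0, 50.0, 80.0),
            rh_band: float = 0.0, rmse_ddof: int = 0) -> "TaRhCapacityResults":
        """Run the three-step tuning procedure and the joint fit.

        ``strata`` are the humidity levels given their own step-1 sigmoid
        fits of PWC against air temperature; ``rh_band`` widens the stratum
        membership test to |RH - stratum| <= band for field data whose
        humidities are not exact.  Conditions outside every stratum still
        enter the joint step-3 fit.
        """
        # step 1: per-stratum sigmoid fits (PWC vs air temperature)
        step1: Dict[float, SigmoidCapacityResults] = {}
        for level in strata:
            m = np.abs(self.rh - level) <= rh_band if rh_band > 0 else self.rh == level
            if m.sum() < 4:
                warnings.warn(
                    f"humidity stratum {level:g}% has {int(m.sum())} points (<4); skipped"
                )
                continue
            step1[level] = SigmoidCapacityModel(
                self.endog[m], self.ta[m], index_name=f"air_temp@RH{level:g}"
            ).fit()
        if len(step1) < 2:
            raise FitConvergenceError(
                "fewer than 2 usable humidity strata; cannot seed the joint fit"
            )
        # step 2: linear models of PWC50 and HillSlope against ln(RH)
        lnrh = np.log(np.array(sorted(step1)))
        p50s = np.array([step1[k].pwc50 for k in sorted(step1)])
        slps = np.array([step1[k].hillslope for k in sorted(step1)])
        a0, b0 = np.polyfit(lnrh, p50s, 1)
        c0, d0 = np.polyfit(lnrh, slps, 1)
        step2 = {
            "pwc50": _LinearStep(a0, b0, dict(zip(sorted(step1), p50s))),
            "hillslope": _LinearStep(c0, d0, dict(zip(sorted(step1), slps))),
        }
        start = np.array([a0, b0, c0, d0])

        # step 3: joint nonlinear fit started from the step-2 coefficients
        y, ta, rh = self.endog, self.ta, self.rh

        def resid(p):
            return _eq_ta_rh(ta, rh, *p) - y

        sol = optimize.least_squares(resid, x0=start, method="trf")
        start_ss = float(np.sum(resid(start) ** 2))
        if not sol.success:
            raise FitConvergenceError(
                f"joint fit did not converge: {sol.message}; "
                f"step-2 start values were a={a0:.4g} b={b0:.4g} c={c0:.4g} d={d0:.4g}"
            )
        joint_ss = float(np.sum(sol.fun**2))
        if joint_ss > start_ss + 1e-9:  # pragma: no cover - optimizer sanity
            warnings.warn("joint fit worse than its start; keeping optimizer result")
        yhat = _eq_ta_rh(ta, rh, *sol.x)
        r2, rmse = goodness(y, yhat, ddof=rmse_ddof)
        dof = max(y.size - 4, 1)
        s2 = joint_ss / dof
        cov = s2 * np.linalg.pinv(sol.jac.T @ sol.jac)
        return TaRhCapacityResults(
            model=self, params=sol.x.copy(), cov_params=cov, r_squared=r2,
            rmse=rmse, n_points=y.size, converged=True,
            start_params=tuple(start), step1=step1, step2=step2,
        )


@dataclass
class TaRhCapacityResults:
    """Results of the three-step Ta/RH model fit, with all intermediates."""

    model: TaRhCapacityModel
    params: np.ndarray  # (a, b, c, d)
    cov_params: np.ndarray
    r_squared: Optional[float]
    rmse: float
    n_points: int
    converged: bool
    start_params: Tuple[float, float, float, float]
    step1: Dict[float, SigmoidCapacityResults]
    step2: Dict[str, _LinearStep]

    @property
    def a(self) -> float:
        return float(self.params[0])

    @property
    def b(self) -> float:
        return float(self.params[1])

    @property
    def c(self) -> float:
        return float(self.params[2])

    @property
    def d(self) -> float:
        return float(self.params[3])

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    def predict(self, ta, rh):
        return self.model.predict(self.params, ta, rh)

    def to_ta_rh_params(self, provenance: str = "fitted") -> TaRhParams:
        return TaRhParams(
            a=self.a, b=self.b, c=self.c, d=self.d,
            ta_valid=(float(self.model.ta.min()), float(self.model.ta.max())),
            rh_valid=(float(self.model.rh.min()), float(self.model.rh.max())),
            provenance=provenance, r_squared=self.r_squared, rmse=self.rmse,
        )

    def summary(self) -> str:
        r2 = "undefined" if self.r_squared is None else f"{self.r_squared:.4f}"
        rows = [(n, v, se) for n, v, se in zip("abcd", self.params, self.bse)]
        strata = ", ".join(f"{k:g}%" for k in sorted(self.step1))
        return _summary_table(
            "Ta/RH PWC model (three-step fit)",
            rows,
            [("R-squared:", r2), ("RMSE (PWC %):", f"{self.rmse:.3f}"),
             ("N points:", self.n_points), ("Strata:", strata),
             ("Start (step 2):", "(" + ", ".join(f"{v:.3g}" for v in self.start_params) + ")")],
        )
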