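"""Per-year pupping-season phenology from cumulative pup counts.

The cumulative count of pups first observed by day ``t`` closely follows
a three-parameter logistic

    y(t) = A / (1 + exp((m - t) / s)),

where ``A`` is the asymptotic season total, ``m`` the inflection (the
season midpoint: the day 50% of pups have been counted) and ``s > 0`` a
scale proportional to season length. ``LogisticSeasonCurve`` fits this
by bounded nonlinear (generalized) least squares; within-year serial
dependence can be absorbed by an AR(1) error process estimated by
two-stage iteration. Goodness of fit is Lin's concordance correlation
coefficient. The central 95% span of the fitted logistic CDF,
``2 s ln 39``, is reported as the season length.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import InsufficientDataError, ModelError

__all__ = [
    "LogisticSeasonCurve", "build_cumulative", "fit_season_curve",
    "season_length", "concordance", "summarize_seasons", "LogisticFit",
]

MIN_SURVEY_DAYS = 5


# ---------------------------------------------------------------------------
# cumulative series

def build_cumulative(records: pd.DataFrame, year: int) -> pd.DataFrame:
    """Cumulative pup counts per survey day for one year.

    ``records`` needs columns ``year`` and ``first_obs_date``; one point
    is returned per distinct survey day, with ``cum_count`` = number of
    pups first observed on or before that day.
    """
    sub = records.loc[records["year"] == year, "first_obs_date"]
    days, counts = np.unique(np.asarray(sub, dtype=float), return_counts=True)
    if len(days) < MIN_SURVEY_DAYS:
        raise InsufficientDataError(
            f"year {year}: {len(days)} survey day(s), need >= "
            f"{MIN_SURVEY_DAYS}"
        )
    return pd.DataFrame({
        "year": int(year),
        "day": days,
        "cum_count": np.cumsum(counts),
    })


# ---------------------------------------------------------------------------
# model

def _logistic(t, a, m, s):
    return a / (1.0 + np.exp(np.clip((m - t) / s, -700, 700)))


def concordance(observed: Sequence[float], fitted: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient.

    ``ccc = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)``
    with population (1/n) moments.
    """
    x = np.asarray(observed, dtype=float)
    y = np.asarray(fitted, dtype=float)
    if x.shape != y.shape:
        raise ModelError(
            f"length mismatch: {x.shape} observed vs {y.shape} fitted"
        )
    if x.size < 2:
        raise ModelError("concordance needs at least 2 points")
    vx, vy = x.var(), y.var()
    if vx == 0.0 and vy == 0.0:
        raise ModelError("concordance undefined: both sequences constant")
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2.0 * sxy / (vx + vy + (x.mean() - y.mean()) ** 2))


def season_length(fit, coverage: float = 0.95) -> float:
    """Central ``coverage`` span of the fitted logistic CDF, in days.

    ``t(p) = m + s ln(p / (1 - p))``, so the span is
    ``2 s ln((1 + coverage) / (1 - coverage))``; 95% gives ``2 s ln 39``.
    Accepts a fitted curve/result (attribute ``s``) or a bare scale.
    """
    s = getattr(fit, "s", fit)
    if not 0.0 < coverage < 1.0:
        raise ModelError(f"coverage must lie in (0, 1), got {coverage}")
    if s <= 0:
        raise ModelError(f"scale must be > 0, got {s}")
    return float(2.0 * s * math.log((1.0 + coverage) / (1.0 - coverage)))


@dataclasses.dataclass
class LogisticFit:
    """Per-year logistic season fit (A, m, s) with its error model."""

    year: int
    A: float
    m: float
    s: float
    rho: float
    sigma: float
    converged: bool
    ccc: float
    n_obs: int

    @property
    def length(self) -> float:
        return season_length(self, 0.95)


class LogisticSeasonCurve:
    """Three-parameter logistic season-curve estimator.

    Parameters
    ----------
    use_ar1:
        Estimate a first-order autoregressive residual process by
        two-stage iteration (OLS residual lag-1 autocorrelation, then a
        GLS refit on Cochrane–Orcutt-whitened residuals, iterated to
        convergence of rho).
    n_restarts:
        Jittered restarts of the bounded least-squares solver; the
        lowest-SSE solution wins.
    max_ar_iter, rho_tol:
        Iteration cap and convergence tolerance for the AR(1) stage.

    Fitted attributes: ``A_``, ``m_``, ``s_``, ``rho_``, ``sigma_``,
    ``ccc_``, ``converged_``, ``fitted_``.
    """

    def __init__(self, use_ar1: bool = True, n_restarts: int = 3,
                 max_ar_iter: int = 50, rho_tol: float = 1e-6):
        self.use_ar1 = use_ar1
        self.n_restarts = n_restarts
        self.max_ar_iter = max_ar_iter
        self.rho_tol = rho_tol

    # sklearn-style param plumbing
    def get_params(self, deep: bool = True) -> dict:
        return {
            "use_ar1": self.use_ar1, "n_restarts": self.n_restarts,
            "max_ar_iter": self.max_ar_iter, "rho_tol": self.rho_tol,
        }

    def set_params(self, **params) -> "LogisticSeasonCurve":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _start_values(self, t, y):
        a0 = float(y.max())
        m0 = float(t[np.argmin(np.abs(y - a0 / 2.0))])
        s0 = float(max((t.max() - t.min()) / 4.0, 1e-3))
        return a0, m0, s0

    def _solve(self, t, y, rho):
        """Bounded NLS on (optionally) AR(1)-whitened residuals."""
        def resid(theta):
            r = y - _logistic(t, *theta)
            if rho != 0.0:
                r = np.concatenate((
                    [r[0] * math.sqrt(1.0 - rho * rho)],
                    r[1:] - rho * r[:-1],
                ))
            return r

        a0, m0, s0 = self._start_values(t, y)
        span = t.max() - t.min()
        bounds = (
            [1e-6, t.min() - 2.0 * span, 1e-3],
            [10.0 * max(a0, 1.0), t.max() + 2.0 * span, 10.0 * span],
        )
        best = None
        jitter_rng = np.random.default_rng(0)  # deterministic restarts
        for i in range(max(self.n_restarts, 1)):
            if i == 0:
                x0 = [a0, m0, s0]
            else:
                x0 = [
                    a0 * float(jitter_rng.uniform(0.8, 1.2)),
                    m0 + float(jitter_rng.uniform(-0.1, 0.1)) * span,
                    s0 * float(jitter_rng.uniform(0.5, 2.0)),
                ]
            x0 = np.clip(x0, bounds[0], bounds[1])
            sol = least_squares(resid, x0, bounds=bounds, method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
            if best is None or sol.cost < best.cost:
                best = sol
        return best

    def fit(self, day: Iterable[float], cum_count: Iterable[float],
            year: int = 0) -> "LogisticSeasonCurve":
        t = np.asarray(day, dtype=float)
        y = np.asarray(cum_count, dtype=float)
        if t.size < MIN_SURVEY_DAYS:
            raise InsufficientDataError(
                f"{t.size} survey days, need >= {MIN_SURVEY_DAYS}"
            )
        if np.all(y == y[0]):
            raise ModelError("cumulative counts are constant; nothing to fit")
        order = np.argsort(t)
        t, y = t[order], y[order]

        rho = 0.0
        converged = True
        sol = self._solve(t, y, rho)
        if self.use_ar1:
            for it in range(self.max_ar_iter):
                r = y - _logistic(t, *sol.x)
                denom = float(np.sum(r[:-1] ** 2))
                rho_new = float(np.sum(r[1:] * r[:-1]) / denom) if denom > 0 else 0.0
                rho_new = float(np.clip(rho_new, -0.99, 0.99))
                if abs(rho_new - rho) < self.rho_tol:
                    rho = rho_new
                    break
                rho = rho_new
                sol = self._solve(t, y, rho)
            else:
                converged = False

        self.A_, self.m_, self.s_ = map(float, sol.x)
        self.rho_ = rho
        self.fitted_ = _logistic(t, self.A_, self.m_, self.s_)
        resid = y - self.fitted_
        dof = max(t.size - 3, 1)
        self.sigma_ = float(np.sqrt(np.sum(resid ** 2) / dof))
        self.converged_ = bool(converged and sol.success)
        self.ccc_ = concordance(y, self.fitted_)
        self._t = t
        self._year = int(year)
        return self

    def predict(self, day: Iterable[float]) -> np.ndarray:
        t = np.asarray(day, dtype=float)
        return _logistic(t, self.A_, self.m_, self.s_)

    def result_(self) -> LogisticFit:
        return LogisticFit(
            year=self._year, A=self.A_, m=self.m_, s=self.s_, rho=self.rho_,
            sigma=self.sigma_, converged=self.converged_, ccc=self.ccc_,
            n_obs=len(self._t),
        )


def fit_season_curve(series: pd.DataFrame, use_ar1: bool = True) -> LogisticFit:
    """Fit one year's cumulative series; thin wrapper over the estimator."""
    year = int(series["year"].iloc[0]) if "year" in series.columns else 0
    est = LogisticSeasonCurve(use_ar1=use_ar1)
    est.fit(series["day"], series["cum_count"], year=year)
    return est.result_()


def summarize_seasons(fits: Iterable[LogisticFit]) -> pd.DataFrame:
    """Season-summary table with one-year-lagged columns.

    Non-converged years are kept in the table but flagged and never used
    as a lag source (the following year's ``prev_*`` stay missing).
    """
    fits = sorted(fits, key=lambda f: f.year)
    years = [f.year for f in fits]
    if len(years) != len(set(years)):
        raise ModelError("duplicate years in season fits")
    if len(fits) < 2:
        raise InsufficientDataError("need >= 2 years to summarize seasons")
    rows = []
    by_year = {f.year: f for f in fits}
    for f in fits:
        prev = by_year.get(f.year - 1)
        usable = prev is not None and prev.converged
        rows.append({
            "year": f.year,
            "total": f.A,
            "midpoint": f.m,
            "length": f.length,
            "prev_total": prev.A if usable else np.nan,
            "prev_midpoint": prev.m if usable else np.nan,
            "prev_length": prev.length if usable else np.nan,
            "ccc": f.ccc,
            "converged": f.converged,
        })
    return pd.DataFrame(rows)


def fit_all_years(surveys: pd.DataFrame, use_ar1: bool = True) -> list[LogisticFit]:
    """Fit every year present in a survey table."""
    return [
        fit_season_curve(build_cumulative(surveys, y), use_ar1=use_ar1)
        for y in sorted(surveys["year"].unique())
    ]
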