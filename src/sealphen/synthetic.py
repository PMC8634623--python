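"""Synthetic colony generator with known ground truth.

Four generators, all driven by one :class:`~sealphen.config.SimConfig`
and an explicit seed (never global state):

* :func:`simulate_sst` — a monthly SST cell series: seasonal cosine plus
  an AR(1) anomaly.
* :func:`derive_true_season_params` — per-year true season parameters
  (A, m, s): the midpoint responds linearly to the winter SST anomaly
  with an AR(1) carry-over; totals step up after the change year.
* :func:`simulate_surveys` — pup birth dates drawn from the logistic
  distribution with the year's (m, s), observed at the next survey
  visit; exactly the cumulative curve the fitting module assumes.
* :func:`simulate_adult_histories` — a longitudinal adult-female
  population: pupping date declines with latent maternal age, and warm
  winters tilt attendance toward long-tenured females so that observed
  mean age rises with SST.

Fixed seeds give bit-identical output; each generator uses its own
deterministic child stream of ``config.rng_seed``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import SimConfig
from .errors import ConfigurationError
from .io import aggregate_quarterly

_STREAM_SST = 0
_STREAM_TRUTH = 1
_STREAM_SURVEY = 2
_STREAM_ADULTS = 3

#: age (years) at which the individual age effect plateaus: the linear
#: advance cannot continue into extreme old age, and grey seal females
#: rarely exceed ~35 years
AGE_EFFECT_PLATEAU = 35.0


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    ss = np.random.SeedSequence(config.rng_seed, spawn_key=(stream,))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# SST

def simulate_sst(config: SimConfig) -> pd.DataFrame:
    """Simulate the monthly SST cell series.

    Covers Jan(year_start - 1) .. Dec(last pupping year), so every
    quarter of every simulated season (including the first winter and
    previous autumn) is computable.

    Returns a DataFrame with columns ``year, month, sst``.
    """
    rng = _rng(config, _STREAM_SST)
    y0 = config.year_start - 1
    y1 = config.year_start + config.n_years - 1
    years = np.repeat(np.arange(y0, y1 + 1), 12)
    months = np.tile(np.arange(1, 13), y1 - y0 + 1)
    n = len(years)
    seasonal = np.array([config.seasonal_sst(m) for m in months])
    anomaly = np.zeros(n)
    rho = config.sst_anomaly_ar1
    sd = config.sst_anomaly_sd
    innov_sd = sd * math.sqrt(max(1.0 - rho * rho, 0.0))
    if sd > 0:
        anomaly[0] = rng.normal(0.0, sd)
        eps = rng.normal(0.0, innov_sd, n - 1)
        for t in range(1, n):
            anomaly[t] = rho * anomaly[t - 1] + eps[t - 1]
    return pd.DataFrame(
        {"year": years, "month": months, "sst": seasonal + anomaly}
    )


def winter_sst_by_year(sst: pd.DataFrame, config: SimConfig,
                       winter_convention: str = "lagged") -> pd.Series:
    """Winter (Dec–Feb) mean SST per pupping year, indexed by year."""
    q = aggregate_quarterly(sst, years=config.years,
                            winter_convention=winter_convention)
    w = q[q["quarter"] == "winter"].set_index("pupping_year")["mean_sst"]
    missing = [y for y in config.years if y not in w.index]
    if missing:
        raise ConfigurationError(
            f"winter SST not computable for pupping year(s) {missing}: "
            "monthly series does not cover Dec-Feb"
        )
    return w


# ---------------------------------------------------------------------------
# true season parameters

def derive_true_season_params(sst: pd.DataFrame,
                              config: SimConfig) -> pd.DataFrame:
    """Per-year ground-truth season parameters.

    ``m_true(y) = midpoint_base + midpoint_sst_slope * (winterSST(y) - ref)
    + midpoint_ar1 * (m_true(y-1) - midpoint_base) + noise``; totals follow
    ``total_mean`` with the change-year step and lognormal noise; scales
    are lognormal around ``scale_base``.

    Returns a DataFrame with columns
    ``year, A_true, m_true, s_true, winter_sst``.
    """
    rng = _rng(config, _STREAM_TRUTH)
    winter = winter_sst_by_year(sst, config)
    ref = config.winter_sst_reference
    rows = []
    m_prev = config.midpoint_base
    for y in config.years:
        forcing = config.midpoint_sst_slope * (winter[y] - ref)
        m = (config.midpoint_base + forcing
             + config.midpoint_ar1 * (m_prev - config.midpoint_base)
             + rng.normal(0.0, config.midpoint_noise_sd))
        mean_total = config.total_mean * (
            config.total_trend if y > config.change_year else 1.0
        )
        a = mean_total * math.exp(rng.normal(0.0, config.total_noise_sd))
        s = config.scale_base * math.exp(rng.normal(0.0, config.scale_noise_sd))
        rows.append((y, a, m, s, float(winter[y])))
        m_prev = m
    return pd.DataFrame(
        rows, columns=["year", "A_true", "m_true", "s_true", "winter_sst"]
    )


# ---------------------------------------------------------------------------
# surveys

def _survey_days(rng: np.random.Generator, config: SimConfig,
                 last_birth: float) -> np.ndarray:
    lo, hi = config.survey_interval_range
    days = [config.survey_start_day]
    # extend past the nominal end until every birth has a following visit
    stop = max(config.survey_end_day, math.ceil(last_birth))
    while days[-1] < stop:
        days.append(days[-1] + int(rng.integers(lo, hi + 1)))
    return np.asarray(days, dtype=int)


def simulate_surveys(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Simulate the pup survey record (one row per pup).

    Per year, ``N ~ Poisson(A_true)`` birth dates are drawn from the
    logistic distribution with location ``m_true`` and scale ``s_true``;
    each pup's first-observation date is its birth date rounded up to
    the next survey visit. Every drawn pup is recorded (the schedule is
    extended to cover late births), so per-year record counts equal the
    Poisson draws exactly.

    Returns a DataFrame with columns
    ``year, pup_id, first_obs_date, site, weaned`` plus a ground-truth
    ``birth_date`` metadata column (dropped when writing the survey CSV).
    """
    if truth.empty:
        raise ConfigurationError("truth table is empty")
    rng = _rng(config, _STREAM_SURVEY)
    frames = []
    for row in truth.itertuples(index=False):
        n = int(rng.poisson(row.A_true))
        births = rng.logistic(loc=row.m_true, scale=row.s_true, size=n)
        days = _survey_days(rng, config, births.max() if n else 0.0)
        idx = np.searchsorted(days, births, side="left")
        # births before the first survey are seen at the first survey
        first_obs = days[np.minimum(idx, len(days) - 1)]
        site = np.where(rng.random(n) < 0.72, "island", "mainland")
        weaned = rng.random(n) < 0.8
        frames.append(pd.DataFrame({
            "year": int(row.year),
            "pup_id": [f"{int(row.year)}-{i + 1:04d}" for i in range(n)],
            "first_obs_date": first_obs.astype(int),
            "site": site,
            "weaned": weaned,
            # ground-truth metadata for tests; not part of the CSV schema
            "birth_date": births,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# adult longitudinal histories

def simulate_adult_histories(sst: pd.DataFrame,
                             config: SimConfig) -> pd.DataFrame:
    """Simulate resighting/pupping histories of identifiable females.

    Mechanism: a pool of ``n_females`` adult females with latent ages;
    each season a female pups (and is identified) with probability
    ``breeding_prob``, exponentially tilted toward long-tenured females
    in warm winters so that the observed mean tenure rises by
    ``sst_age_slope`` years per °C of winter SST anomaly. Individual
    pupping date = season anchor + ``age_effect`` x latent age (centred,
    plateauing at extreme old age) + female intercept + noise —
    independent of SST at the individual level. Deaths are replaced by recruits at ``entry_age``. Tenure
    (years since first sighting) is computed from the sighting process,
    not from latent age; a burn-in period makes it near-stationary by
    the first emitted season.

    Returns a DataFrame with columns ``female_id, year, pup_date,
    years_since_first_sighting, latent_age`` (the last column is
    ground-truth metadata for tests).
    """
    if config.n_females < 2:
        raise ConfigurationError("n_females must be >= 2")
    rng = _rng(config, _STREAM_ADULTS)
    winter = winter_sst_by_year(sst, config)
    ref = config.winter_sst_reference

    mean_extra = config.adult_survival / (1.0 - config.adult_survival)
    nominal_mean_age = config.entry_age + mean_extra

    next_id = [0]
    first_year = config.year_start - config.burn_in_years

    def new_female(stationary: bool) -> dict:
        next_id[0] += 1
        if stationary:
            # stationary latent-age draw for the initial pool
            age = config.entry_age + rng.geometric(
                1.0 - config.adult_survival) - 1.0
        else:
            age = config.entry_age
        return {
            "id": f"F{next_id[0]:04d}",
            "age": float(age),
            "icept": rng.normal(0.0, config.indiv_intercept_sd),
            "first_seen": None,
        }

    pop = [new_female(stationary=True) for _ in range(config.n_females)]
    records = []
    for y in range(first_year, config.year_start + config.n_years):
        in_study = y >= config.year_start
        dsst = float(winter[y]) - ref if in_study and y in winter.index else 0.0
        year_eff = rng.normal(0.0, config.year_effect_sd)

        tenure = np.array([
            (y - f["first_seen"]) if f["first_seen"] is not None else 0.0
            for f in pop
        ])
        if config.sst_age_slope != 0.0 and dsst != 0.0:
            var = max(float(np.var(tenure)), 1.0)
            gamma = config.sst_age_slope / var
            w = np.exp(gamma * dsst * (tenure - tenure.mean()))
            p = np.clip(config.breeding_prob * w / w.mean(), 0.0, 1.0)
        else:
            p = np.full(len(pop), config.breeding_prob)

        breeds = rng.random(len(pop)) < p
        for f, b in zip(pop, breeds):
            if not b:
                continue
            if f["first_seen"] is None:
                f["first_seen"] = y
            if in_study:
                eff_age = min(f["age"], AGE_EFFECT_PLATEAU)
                date = (config.midpoint_base + year_eff
                        + config.age_effect * (eff_age - nominal_mean_age)
                        + f["icept"]
                        + rng.normal(0.0, config.pup_date_noise_sd))
                records.append((
                    f["id"], y, float(date), int(y - f["first_seen"]),
                    float(f["age"]),
                ))

        # age, survive, replace
        survives = rng.random(len(pop)) < config.adult_survival
        pop = [f for f, s in zip(pop, survives) if s]
        for f in pop:
            f["age"] += 1.0
        while len(pop) < config.n_females:
            pop.append(new_female(stationary=False))

    return pd.DataFrame(records, columns=[
        "female_id", "year", "pup_date", "years_since_first_sighting",
        "latent_age",
    ])


def simulate_all(config: SimConfig) -> dict[str, pd.DataFrame]:
    """Run all generators; returns a dict of named DataFrames."""
    sst = simulate_sst(config)
    truth = derive_true_season_params(sst, config)
    surveys = simulate_surveys(truth, config)
    adults = simulate_adult_histories(sst, config)
    quarterly = aggregate_quarterly(sst, years=config.years)
    return {
        "sst_monthly": sst,
        "truth": truth,
        "surveys": surveys,
        "adults": adults,
        "sst_quarterly": quarterly,
    }
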