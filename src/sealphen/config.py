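"""Simulation configuration.

All tunables of the synthetic-data generator live in :class:`SimConfig`.
Defaults emulate the monitored grey-seal colony the package is designed
around: 27 pupping seasons (1992–2018) surveyed every 1–3 days, yearly
totals near 200 pups doubling after 2009, season midpoints near day 88
(days since 1 July), and a winter sea-surface-temperature forcing of
-3.5 days of midpoint advance per °C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from .errors import ConfigurationError

#: Month (1-12) at which the seasonal SST cycle peaks (coastal seas lag air
#: temperature; the Irish Sea is warmest in August).
SST_PEAK_MONTH = 8


@dataclass
class SimConfig:
    """Ground-truth parameters of the synthetic colony.

    Parameters
    ----------
    n_years:
        Number of pupping seasons simulated.
    year_start:
        First pupping season (calendar year of its autumn).
    total_mean:
        Expected pups per season before the change year.
    total_trend:
        Multiplicative factor applied to the expected total for seasons
        after ``change_year`` (a step increase; 2.0 doubles the colony).
    change_year:
        Last season at the low level; seasons strictly after it get
        ``total_mean * total_trend``.
    total_noise_sd:
        SD of lognormal year-to-year noise on the expected total.
    midpoint_base:
        Long-run season midpoint, days since 1 July.
    midpoint_sst_slope:
        Days of midpoint shift per °C of winter SST anomaly (negative:
        warm winters advance the season).
    midpoint_ar1:
        Carry-over of last season's midpoint anomaly, in (-1, 1).
    midpoint_noise_sd:
        SD (days) of the midpoint innovation noise.
    scale_base:
        Logistic scale parameter of the season (days); the 95% season
        length is ``2 * s * ln(39)`` (~7.33 s).
    scale_noise_sd:
        SD of lognormal noise on the yearly scale.
    survey_interval_range:
        Inclusive (min, max) days between consecutive surveys.
    survey_start_day / survey_end_day:
        Nominal first and last survey days (days since 1 July). The
        schedule is extended past the nominal end until every pup born
        that season has a following survey, so no pup goes unrecorded.
    obs_noise_sd:
        SD of additive counting noise on per-survey cumulative counts
        (0 = exact counts).
    age_effect:
        Days of individual pupping-date shift per year of maternal age
        (negative: older mothers pup earlier).
    sst_age_slope:
        Years of mean maternal age gained per °C of winter SST anomaly
        (age-biased attendance in warm years).
    n_females:
        Identifiable adult females present at any time.
    adult_survival:
        Annual survival of adult females in the longitudinal simulation.
    breeding_prob:
        Baseline probability an adult female pups (and is identified) in
        a given season.
    entry_age:
        Latent age at which recruits join the adult pool.
    indiv_intercept_sd:
        SD (days) of each female's persistent pupping-date intercept.
    pup_date_noise_sd:
        SD (days) of within-female year-to-year pupping-date noise.
    year_effect_sd:
        SD (days) of an optional shared season-level wobble in
        individual pupping dates, independent of SST. Default 0: the
        season anchor is the deterministic base, so all year-to-year
        structure in individual dates flows through age composition.
    burn_in_years:
        Seasons simulated before ``year_start`` so that tenure (years
        since first sighting) is near its stationary distribution when
        records start being emitted.
    sst_mean / sst_seasonal_amplitude:
        Mean (°C) and seasonal cosine amplitude of the monthly SST cell
        series.
    sst_anomaly_sd / sst_anomaly_ar1:
        Stationary SD and month-to-month AR(1) coefficient of the SST
        anomaly process.
    rng_seed:
        Seed for all randomness; fixed seed gives bit-identical output.
    """

    n_years: int = 27
    year_start: int = 1992
    total_mean: float = 200.0
    total_trend: float = 2.0
    change_year: int = 2009
    total_noise_sd: float = 0.15
    midpoint_base: float = 88.0
    midpoint_sst_slope: float = -3.5
    midpoint_ar1: float = 0.3
    midpoint_noise_sd: float = 1.2
    scale_base: float = 10.0
    scale_noise_sd: float = 0.12
    survey_interval_range: tuple[int, int] = (1, 3)
    survey_start_day: int = 40
    survey_end_day: int = 183
    obs_noise_sd: float = 0.0
    age_effect: float = -1.0
    sst_age_slope: float = 1.0
    n_females: int = 40
    adult_survival: float = 0.9
    breeding_prob: float = 0.7
    entry_age: float = 5.0
    indiv_intercept_sd: float = 2.0
    pup_date_noise_sd: float = 3.0
    year_effect_sd: float = 0.0
    burn_in_years: int = 15
    sst_mean: float = 11.0
    sst_seasonal_amplitude: float = 3.0
    sst_anomaly_sd: float = 0.5
    sst_anomaly_ar1: float = 0.6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ConfigurationError("n_years must be >= 2")
        lo, hi = self.survey_interval_range
        if lo < 1 or hi < lo:
            raise ConfigurationError(
                "survey_interval_range must satisfy 1 <= min <= max"
            )
        if self.scale_base <= 0:
            raise ConfigurationError("scale_base must be > 0")
        if self.total_mean <= 0:
            raise ConfigurationError("total_mean must be > 0")
        if not -1.0 < self.midpoint_ar1 < 1.0:
            raise ConfigurationError("midpoint_ar1 must lie in (-1, 1)")
        if not -1.0 < self.sst_anomaly_ar1 < 1.0:
            raise ConfigurationError("sst_anomaly_ar1 must lie in (-1, 1)")
        if not 0.0 < self.adult_survival <= 0.999:
            raise ConfigurationError("adult_survival must lie in (0, 0.999]")
        if self.n_females < 2:
            raise ConfigurationError("n_females must be >= 2")
        for name in ("total_noise_sd", "midpoint_noise_sd", "scale_noise_sd",
                     "obs_noise_sd", "indiv_intercept_sd", "pup_date_noise_sd",
                     "year_effect_sd", "sst_anomaly_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @property
    def years(self) -> range:
        """Calendar years of the simulated pupping seasons."""
        return range(self.year_start, self.year_start + self.n_years)

    def seasonal_sst(self, month: int) -> float:
        """Deterministic seasonal component of monthly SST (°C)."""
        return self.sst_mean + self.sst_seasonal_amplitude * math.cos(
            2.0 * math.pi * (month - SST_PEAK_MONTH) / 12.0
        )

    @property
    def winter_sst_reference(self) -> float:
        """Expected winter (Dec–Feb) SST under the seasonal cycle (°C)."""
        return sum(self.seasonal_sst(m) for m in (12, 1, 2)) / 3.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["survey_interval_range"] = list(self.survey_interval_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "survey_interval_range" in d:
            d["survey_interval_range"] = tuple(d["survey_interval_range"])
        return cls(**d)
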