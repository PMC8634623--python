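"""Readers, writers and the quarterly SST aggregation.

CSV is the canonical interchange format. Dates are integer/float days
since 1 July of the pupping year (day 0 = 1 July). Quarterly SST means
are anchored around the pupping season: for pupping year ``y``,
``prev_autumn`` = Sep–Nov(y-1), ``winter`` = Dec(y-1)–Feb(y) (the winter
that follows the previous season's mating and precedes season y),
``spring`` = Mar–May(y), ``summer`` = Jun–Aug(y) and ``autumn`` =
Sep–Nov(y), the pupping season itself. A ``winter_convention="calendar"``
switch instead uses Jan, Feb and Dec of year y.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ConfigurationError

logger = logging.getLogger(__name__)

QUARTER_LABELS = ("prev_autumn", "winter", "spring", "summer", "autumn")

#: quarter -> sequence of (year offset relative to pupping year, month)
_QUARTER_MONTHS = {
    "prev_autumn": ((-1, 9), (-1, 10), (-1, 11)),
    "winter": ((-1, 12), (0, 1), (0, 2)),
    "spring": ((0, 3), (0, 4), (0, 5)),
    "summer": ((0, 6), (0, 7), (0, 8)),
    "autumn": ((0, 9), (0, 10), (0, 11)),
}
_QUARTER_MONTHS_CALENDAR = dict(
    _QUARTER_MONTHS, winter=((0, 1), (0, 2), (0, 12))
)

SURVEY_COLUMNS = ("year", "pup_id", "first_obs_date", "site", "weaned")
ADULT_COLUMNS = ("female_id", "year", "pup_date", "years_since_first_sighting")
SST_MONTHLY_COLUMNS = ("year", "month", "sst")
SST_QUARTERLY_COLUMNS = ("pupping_year", "quarter", "mean_sst")
SEASON_COLUMNS = (
    "year", "total", "midpoint", "length",
    "prev_total", "prev_midpoint", "prev_length",
)


# ---------------------------------------------------------------------------
# quarterly aggregation

def aggregate_quarterly(
    monthly: pd.DataFrame,
    years: Iterable[int] | None = None,
    winter_convention: str = "lagged",
) -> pd.DataFrame:
    """Aggregate a monthly SST series into pupping-season quarters.

    Parameters
    ----------
    monthly:
        DataFrame with columns ``year, month, sst``.
    years:
        Pupping years to report; defaults to every year for which at
        least one quarter is complete.
    winter_convention:
        ``"lagged"`` (default): winter of pupping year y is
        Dec(y-1)–Feb(y). ``"calendar"``: Jan, Feb and Dec of year y.

    Returns
    -------
    DataFrame with columns ``pupping_year, quarter, mean_sst``; quarters
    with any missing month are omitted with a warning.
    """
    _require_columns(monthly, SST_MONTHLY_COLUMNS[:3], "sst_monthly")
    if monthly.empty:
        raise SchemaError("monthly SST series is empty")
    if winter_convention == "lagged":
        qmonths = _QUARTER_MONTHS
    elif winter_convention == "calendar":
        qmonths = _QUARTER_MONTHS_CALENDAR
    else:
        raise ConfigurationError(
            f"unknown winter_convention {winter_convention!r}"
        )
    series = {
        (int(y), int(m)): float(v)
        for y, m, v in monthly[["year", "month", "sst"]].itertuples(index=False)
        if np.isfinite(v)
    }
    if years is None:
        present = sorted({y for (y, _m) in series})
        years = range(present[0], present[-1] + 1)
    rows = []
    for y in years:
        for quarter, months in qmonths.items():
            vals = [series.get((y + dy, m)) for dy, m in months]
            if any(v is None for v in vals):
                logger.warning(
                    "incomplete %s quarter for pupping year %d; omitted",
                    quarter, y,
                )
                continue
            rows.append((int(y), quarter, float(np.mean(vals))))
    return pd.DataFrame(rows, columns=list(SST_QUARTERLY_COLUMNS))


def quarter_of_month(year: int, month: int,
                     winter_convention: str = "lagged") -> tuple[int, str]:
    """Map a calendar (year, month) to its (pupping_year, quarter)."""
    qmonths = (_QUARTER_MONTHS if winter_convention == "lagged"
               else _QUARTER_MONTHS_CALENDAR)
    for quarter, months in qmonths.items():
        for dy, m in months:
            if m == month:
                return year - dy, quarter
    raise ValueError(f"month {month} outside 1-12")  # pragma: no cover


# ---------------------------------------------------------------------------
# gridded SST reader (optional xarray backend)

def read_sst_grid(path, cell_corner: tuple[float, float],
                  var: str = "sst") -> pd.DataFrame:
    """Extract the monthly series of one 1°x1° cell from a gridded file.

    The cell is addressed by its *northwest* corner (lat, lon); the cell
    centre is at (lat - 0.5, lon + 0.5). Masked / non-finite values come
    back as NaN in the ``sst`` column.
    """
    try:
        import xarray as xr
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading gridded SST files requires the optional xarray "
            "dependency (pip install sealphen[netcdf])"
        ) from exc

    lat_c = cell_corner[0] - 0.5
    lon_c = cell_corner[1] + 0.5
    with xr.open_dataset(path) as ds:
        if var not in ds:
            raise SchemaError(f"variable {var!r} not found in {path}")
        da = ds[var]
        lat_name = "latitude" if "latitude" in da.dims else "lat"
        lon_name = "longitude" if "longitude" in da.dims else "lon"
        lats = da[lat_name].values
        lons = da[lon_name].values
        if not (lats.min() <= lat_c <= lats.max()
                and lons.min() <= lon_c <= lons.max()):
            raise ConfigurationError(
                f"cell with NW corner {cell_corner} not in grid: "
                f"lat [{lats.min()}, {lats.max()}], "
                f"lon [{lons.min()}, {lons.max()}]"
            )
        cell = da.sel({lat_name: lat_c, lon_name: lon_c}, method="nearest",
                      tolerance=0.51)
        t = pd.DatetimeIndex(cell["time"].values)
        out = pd.DataFrame({
            "year": t.year.astype(int),
            "month": t.month.astype(int),
            "sst": np.asarray(cell.values, dtype=float),
        })
    return out


def write_sst_grid(path, monthly: pd.DataFrame,
                   cell_corner: tuple[float, float], var: str = "sst") -> None:
    """Write a single-cell gridded file (testing / round-trip helper)."""
    import xarray as xr

    _require_columns(monthly, SST_MONTHLY_COLUMNS, "sst_monthly")
    time = pd.to_datetime(
        {"year": monthly["year"], "month": monthly["month"], "day": 15}
    )
    da = xr.DataArray(
        monthly["sst"].to_numpy(dtype=float)[:, None, None],
        dims=("time", "latitude", "longitude"),
        coords={
            "time": time.to_numpy(),
            "latitude": [cell_corner[0] - 0.5],
            "longitude": [cell_corner[1] + 0.5],
        },
        name=var,
    )
    da.to_dataset().to_netcdf(path, engine="scipy")


# ---------------------------------------------------------------------------
# tabular schemas

def _require_columns(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")


def _coerce(df: pd.DataFrame, name: str, **dtypes) -> pd.DataFrame:
    df = df.copy()
    for col, dtype in dtypes.items():
        try:
            df[col] = df[col].astype(dtype)
        except (ValueError, TypeError) as exc:
            raise SchemaError(
                f"{name}: column {col!r} not coercible to {dtype}: {exc}"
            ) from exc
    return df


def validate_surveys(df: pd.DataFrame) -> pd.DataFrame:
    """Schema-validate a survey table (one row per pup)."""
    _require_columns(df, SURVEY_COLUMNS[:4], "surveys")
    df = _coerce(df, "surveys", year=int, first_obs_date=int, site=str)
    if "weaned" not in df.columns:
        df["weaned"] = True
    neg = df.index[df["first_obs_date"] < 0]
    if len(neg):
        raise SchemaError(
            f"surveys: negative first_obs_date at row {neg[0]} "
            "(dates are days since 1 July)"
        )
    dup = df.duplicated(subset=["year", "pup_id"])
    if dup.any():
        row = df.index[dup][0]
        raise SchemaError(f"surveys: duplicate (year, pup_id) at row {row}")
    return df


def validate_adults(df: pd.DataFrame) -> pd.DataFrame:
    """Schema-validate the adult-female longitudinal table."""
    _require_columns(df, ADULT_COLUMNS[:3], "adults")
    df = _coerce(df, "adults", year=int, pup_date=float, female_id=str)
    dup = df.duplicated(subset=["female_id", "year"])
    if dup.any():
        row = df.index[dup][0]
        raise SchemaError(f"adults: duplicate (female_id, year) at row {row}")
    if "years_since_first_sighting" not in df.columns:
        first = df.groupby("female_id")["year"].transform("min")
        df["years_since_first_sighting"] = df["year"] - first
    df = _coerce(df, "adults", years_since_first_sighting=int)
    bad = df.index[df["years_since_first_sighting"] < 0]
    if len(bad):
        raise SchemaError(
            f"adults: negative years_since_first_sighting at row {bad[0]}"
        )
    return df


def validate_sst_monthly(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, SST_MONTHLY_COLUMNS, "sst_monthly")
    df = _coerce(df, "sst_monthly", year=int, month=int, sst=float)
    bad = df.index[(df["month"] < 1) | (df["month"] > 12)]
    if len(bad):
        raise SchemaError(f"sst_monthly: month outside 1-12 at row {bad[0]}")
    return df


def validate_seasons(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, SEASON_COLUMNS[:4], "seasons")
    return _coerce(df, "seasons", year=int, total=float, midpoint=float,
                   length=float)


_VALIDATORS = {
    "surveys": validate_surveys,
    "adults": validate_adults,
    "sst_monthly": validate_sst_monthly,
    "seasons": validate_seasons,
}

_FLOAT_FORMATS = {
    "sst_monthly": "%.3f",
    "sst_quarterly": "%.3f",
}


def read_table(path, kind: str) -> pd.DataFrame:
    """Read and validate one of the package's CSV schemas."""
    df = pd.read_csv(path)
    if kind == "sst_quarterly":
        _require_columns(df, SST_QUARTERLY_COLUMNS, kind)
        return _coerce(df, kind, pupping_year=int, mean_sst=float)
    if kind not in _VALIDATORS:
        raise ConfigurationError(f"unknown table kind {kind!r}")
    return _VALIDATORS[kind](df)


def write_table(df: pd.DataFrame, path, kind: str) -> None:
    """Validate and write one of the package's CSV schemas."""
    if kind in _VALIDATORS:
        df = _VALIDATORS[kind](df)
    fmt = _FLOAT_FORMATS.get(kind, "%.6f")
    df.to_csv(path, index=False, float_format=fmt)
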