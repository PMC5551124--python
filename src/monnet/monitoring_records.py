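"""Annual-average QC for hourly monitoring data.

Two-stage averaging with completeness criteria: hourly values are averaged
into daily means only for days with at least 18 of 24 hourly values (75%),
and a site-year is eligible for an annual average only when

* at least 10 calendar months contain a daily average,
* at most 91 days (25% of the year) are missing, and
* fewer than 45 consecutive days are missing.

The annual mean is the unweighted mean of the valid daily averages and is
reported for every site regardless of eligibility, with the eligibility
flag alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = ["SiteAnnualSummary", "daily_averages", "site_eligibility",
           "annual_summaries"]

MIN_HOURS_PER_DAY = 18
MIN_MONTHS = 10
MAX_MISSING_DAYS = 91
MAX_CONSECUTIVE_MISSING = 45  # eligibility requires strictly fewer


@dataclass(frozen=True)
class SiteAnnualSummary:
    site_id: str
    year: int
    annual_mean: float
    n_valid_days: int
    n_missing_days: int
    max_consecutive_missing_days: int
    months_with_daily_average: int
    eligible: bool


def daily_averages(hourly: pd.DataFrame,
                   min_hours: int = MIN_HOURS_PER_DAY) -> pd.DataFrame:
    """Daily averages per site from an hourly table.

    ``hourly`` needs columns ``site_id``, ``datetime``, ``value`` (NaN or
    missing rows both count as missing hours).  A day gets a daily average
    iff it has at least ``min_hours`` present hourly values; otherwise its
    average is NaN.  Duplicate site-hour records raise ``ValueError``.

    Returns columns ``site_id``, ``date``, ``n_hours``, ``daily_avg``.
    """
    df = hourly.copy()
    df["datetime"] = pd.to_datetime(df["datetime"]).dt.floor("h")
    if df.duplicated(["site_id", "datetime"]).any():
        dups = df[df.duplicated(["site_id", "datetime"])]
        raise ValueError(
            f"duplicate site-hour records, e.g. {dups.iloc[0].tolist()}")
    df = df.dropna(subset=["value"])
    df["date"] = df["datetime"].dt.normalize()
    grouped = df.groupby(["site_id", "date"])["value"].agg(["count", "mean"])
    grouped.columns = ["n_hours", "daily_avg"]
    grouped.loc[grouped["n_hours"] < min_hours, "daily_avg"] = np.nan
    return grouped.reset_index()


def _max_run(missing: np.ndarray) -> int:
    # longest run of True in a boolean array
    best = run = 0
    for m in missing:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def site_eligibility(daily: pd.DataFrame,
                     year: int | None = None,
                     min_months: int = MIN_MONTHS,
                     max_missing_days: int = MAX_MISSING_DAYS,
                     max_consecutive: int = MAX_CONSECUTIVE_MISSING,
                     ) -> SiteAnnualSummary:
    """Apply the completeness criteria to one site's daily table.

    ``daily`` is the output of :func:`daily_averages` restricted to a
    single site; the year is inferred from the data when not given.
    Missing-day runs are evaluated within the calendar year only.
    """
    if daily.empty:
        raise ValueError("empty daily table")
    sites = daily["site_id"].unique()
    if len(sites) != 1:
        raise ValueError(f"expected one site, got {list(sites)}")
    dates = pd.to_datetime(daily["date"])
    years = dates.dt.year.unique()
    if year is None:
        if len(years) != 1:
            raise ValueError(f"multiple years in daily table: {sorted(years)}")
        year = int(years[0])
    calendar = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    valid = daily.loc[daily["daily_avg"].notna()]
    valid_days = pd.DatetimeIndex(pd.to_datetime(valid["date"]))
    has_avg = calendar.isin(valid_days)

    n_valid = int(has_avg.sum())
    n_missing = len(calendar) - n_valid
    months = int(pd.Series(calendar.month[has_avg]).nunique())
    max_consec = _max_run(~has_avg)
    eligible = (months >= min_months and n_missing <= max_missing_days
                and max_consec < max_consecutive)
    annual_mean = float(valid["daily_avg"].mean()) if n_valid else float("nan")
    return SiteAnnualSummary(
        site_id=str(sites[0]), year=year, annual_mean=annual_mean,
        n_valid_days=n_valid, n_missing_days=n_missing,
        max_consecutive_missing_days=max_consec,
        months_with_daily_average=months, eligible=eligible)


def annual_summaries(daily: pd.DataFrame, year: int | None = None,
                     **criteria) -> pd.DataFrame:
    """:func:`site_eligibility` for every site; one row per site."""
    rows = [asdict(site_eligibility(g, year=year, **criteria))
            for _, g in daily.groupby("site_id", sort=True)]
    return pd.DataFrame(rows)
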