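import numpy as np
import pandas as pd
import pytest

from monnet import CityConfig, generate_city

# Source densities matched to a 6 km x 6 km extent: same per-km2 intensity
# as the full-scale defaults, so proximities stay inside the truncation cap.
SMALL_SOURCES = {"major_road": 14, "bus_stop": 115, "construction": 17}


def small_city_config(seed=0, **overrides):
    base = dict(
        seed=seed,
        extent=(0.0, 0.0, 6000.0, 6000.0),
        n_current=37,
        n_subject=600,
        n_candidate=60,
        n_sources_by_kind=dict(SMALL_SOURCES),
        n_noise_covariates=6,
    )
    base.update(overrides)
    return CityConfig(**base)


@pytest.fixture(scope="session")
def small_city():
    return generate_city(small_city_config(seed=42))


@pytest.fixture(scope="session")
def blobs3():
    """Three well-separated Gaussian blobs in 2-D, with labels."""
    rng = np.random.default_rng(7)
    centers = np.array([[0.0, 0.0], [30.0, 0.0], [0.0, 30.0]])
    labels = np.repeat([0, 1, 2], 40)
    X = centers[labels] + rng.normal(0, 1.0, size=(120, 2))
    return X, labels


def make_hourly(site_id="S1", year=2010, day_hours=None):
    """Hourly table where ``day_hours`` maps day-of-year (1-based) to the
    number of present hours that day; unlisted days are fully missing."""
    records = []
    start = pd.Timestamp(f"{year}-01-01")
    for doy, n_hours in (day_hours or {}).items():
        day = start + pd.Timedelta(days=doy - 1)
        for h in range(n_hours):
            records.append({"site_id": site_id,
                            "datetime": day + pd.Timedelta(hours=h),
                            "value": 30.0})
    return pd.DataFrame(records)


def make_daily(site_id="S1", year=2010, valid_days=(), value=25.0):
    """Daily table with a valid daily average exactly on ``valid_days``
    (1-based day-of-year)."""
    start = pd.Timestamp(f"{year}-01-01")
    rows = [{"site_id": site_id,
             "date": start + pd.Timedelta(days=d - 1),
             "n_hours": 24, "daily_avg": value} for d in valid_days]
    if not rows:  # keep the frame non-empty but with no valid day
        rows = [{"site_id": site_id, "date": start, "n_hours": 0,
                 "daily_avg": np.nan}]
    return pd.DataFrame(rows)


def all_partitions(n):
    """Every set partition of range(n), as label arrays."""
    if n == 0:
        yield np.array([], dtype=int)
        return

    def rec(i, labels, n_used):
        if i == n:
            yield labels.copy()
            return
        for lab in range(n_used + 1):
            labels[i] = lab
            yield from rec(i + 1, labels, max(n_used, lab + 1))

    yield from rec(0, np.zeros(n, dtype=int), 0)


def pair_counting_ari(a, b):
    """Adjusted Rand by exhaustive enumeration of all unordered pairs."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    together_a = together_b = together_both = 0
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            n_pairs += 1
            sa = a[i] == a[j]
            sb = b[i] == b[j]
            together_a += sa
            together_b += sb
            together_both += sa and sb
    if n_pairs == 0:
        return 1.0
    expected = together_a * together_b / n_pairs
    max_index = (together_a + together_b) / 2
    if max_index == expected:
        return 0.0 if together_both != max_index else 1.0
    return (together_both - expected) / (max_index - expected)
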