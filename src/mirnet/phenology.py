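"""Dormancy-status metrics: chilling hours, bud break rate, qPCR utility.

Chilling accumulation uses the chilling-hour model: one chilling hour per
hourly temperature reading inside the (0, 7.2] degC band (exclusive at 0 so
frozen hours do not count; both bounds are configurable).  The endodormancy
release date is the first observation date at which the bud break rate -- the
percentage of buds flushing after a fixed forcing incubation -- reaches 50%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CH_LOW = 0.0
CH_HIGH = 7.2
RELEASE_BBR = 50.0


@dataclass(frozen=True)
class BudBreakObservation:
    """One forcing-test observation: flushed buds out of total on a date."""

    date: pd.Timestamp
    flushed: int
    total: int

    def __post_init__(self):
        if not 0 <= self.flushed <= self.total:
            raise ValueError("need 0 <= flushed <= total")
        if self.total == 0:
            raise ValueError("total buds must be positive")

    @property
    def bbr(self) -> float:
        """Bud break rate as a percentage."""
        return 100.0 * self.flushed / self.total


def check_hourly(series: pd.Series) -> pd.Series:
    """Validate a temperature series: strictly increasing timestamps.

    Returns the timestamps where the hourly spacing is broken (gaps); gaps are
    reported, not interpolated.
    """
    idx = series.index
    if not idx.is_monotonic_increasing or idx.has_duplicates:
        raise ValueError("timestamps must be strictly increasing")
    deltas = idx.to_series().diff().dropna()
    return deltas[deltas != pd.Timedelta(hours=1)].index.to_series()


def chilling_hours(
    series: pd.Series,
    start: pd.Timestamp | str | None = None,
    low: float = CH_LOW,
    high: float = CH_HIGH,
) -> pd.Series:
    """Cumulative chilling hours per timestamp.

    ``series`` maps hourly timestamps to temperatures (degC).  A reading
    counts when ``low < T <= high``.  Counting starts at ``start`` (default:
    first timestamp).  Missing hours are simply absent from the cumulative
    count.
    """
    if series.empty:
        raise ValueError("empty temperature series")
    check_hourly(series)
    if start is not None:
        series = series[series.index >= pd.Timestamp(start)]
        if series.empty:
            raise ValueError("series does not cover the start date")
    chill = (series.values > low) & (series.values <= high)
    return pd.Series(np.cumsum(chill.astype(int)), index=series.index)


def endodormancy_release_date(
    observations: list[BudBreakObservation],
    threshold: float = RELEASE_BBR,
) -> pd.Timestamp | None:
    """Earliest observation date with bud break rate >= threshold (%).

    Returns ``None`` when the threshold is never reached.
    """
    if not observations:
        raise ValueError("need at least one observation")
    for obs in sorted(observations, key=lambda o: o.date):
        if obs.bbr >= threshold:
            return obs.date
    return None


def delta_delta_ct(
    ct_target: float,
    ct_ref: float,
    ct_target_cal: float,
    ct_ref_cal: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference) - (Ct_target - Ct_reference) of the
    calibrator sample; the calibrator itself always evaluates to 1.
    """
    ddct = (ct_target - ct_ref) - (ct_target_cal - ct_ref_cal)
    return float(2.0 ** (-ddct))


def read_temperature_tsv(path) -> pd.Series:
    """Read a (timestamp, temp_c) TSV into an hourly temperature series."""
    df = pd.read_csv(path, sep="\t", parse_dates=["timestamp"])
    return pd.Series(df["temp_c"].values, index=pd.DatetimeIndex(df["timestamp"]))


def read_observations_tsv(path) -> list[BudBreakObservation]:
    """Read a (date, flushed, total) TSV into bud break observations."""
    df = pd.read_csv(path, sep="\t", parse_dates=["date"])
    return [
        BudBreakObservation(pd.Timestamp(r.date), int(r.flushed), int(r.total))
        for r in df.itertuples(index=False)
    ]
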