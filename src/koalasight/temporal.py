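"""Monthly time series and classical additive decomposition.

Sightings are aggregated to contiguous monthly counts and split into
trend + seasonal + random by the classical additive decomposition: the
trend is a centred moving average of order 12 (half-weight endpoints,
i.e. weights 1/24, 1/12 x 10, 1/24), the seasonal component is the
month-of-year mean of the detrended series re-centred to sum to zero,
and the random component is the exact remainder.  This is the textbook
procedure behind ``decompose()`` in base R.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MonthlySeries",
    "DecompositionResult",
    "monthly_counts",
    "period_aggregate",
    "decompose_additive",
]


@dataclass
class MonthlySeries:
    """Contiguous monthly counts starting at (year, month)."""

    start_year: int
    start_month: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("monthly counts must be non-negative")
        if not 1 <= self.start_month <= 12:
            raise ValueError("start_month must be 1..12")

    def __len__(self) -> int:
        return self.values.size

    def month_index(self) -> pd.PeriodIndex:
        return pd.period_range(
            start=f"{self.start_year}-{self.start_month:02d}",
            periods=len(self),
            freq="M",
        )

    def month_of_year(self) -> np.ndarray:
        return ((self.start_month - 1 + np.arange(len(self))) % 12) + 1

    def to_frame(self) -> pd.DataFrame:
        idx = self.month_index()
        return pd.DataFrame(
            {"year": idx.year, "month": idx.month, "observed": self.values}
        )


@dataclass
class DecompositionResult:
    """Additive split observed = trend + seasonal + random.

    ``trend`` is NaN in the first and last six months where the
    centred order-12 moving average is undefined; ``seasonal_effects``
    are the 12 month-of-year effects (January first) summing to zero.
    """

    series: MonthlySeries
    trend: np.ndarray
    seasonal: np.ndarray
    random: np.ndarray
    seasonal_effects: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        out = self.series.to_frame()
        out["trend"] = self.trend
        out["seasonal"] = self.seasonal
        out["random"] = self.random
        return out


def monthly_counts(
    records: pd.DataFrame,
    start: tuple[int, int] | None = None,
    end: tuple[int, int] | None = None,
) -> MonthlySeries:
    """Count cleaned sightings per calendar month over a period.

    Months with no sightings appear as zero.  When the requested
    period does not overlap the data span the series is zero-filled.
    """
    dates = pd.to_datetime(records["date"].astype(str)) if len(records) else pd.Series([], dtype="datetime64[ns]")
    if start is None:
        if dates.empty:
            raise ValueError("cannot infer period from an empty record set")
        start = (int(dates.dt.year.min()), int(dates.dt.month.min()))
    if end is None:
        if dates.empty:
            raise ValueError("cannot infer period from an empty record set")
        end = (int(dates.dt.year.max()), int(dates.dt.month.max()))
    idx = pd.period_range(
        start=f"{start[0]}-{start[1]:02d}", end=f"{end[0]}-{end[1]:02d}", freq="M"
    )
    if len(idx) == 0:
        raise ValueError("period end precedes period start")
    if dates.empty:
        counts = np.zeros(len(idx))
    else:
        per = dates.dt.to_period("M")
        vc = per.value_counts()
        counts = np.asarray([float(vc.get(p, 0)) for p in idx])
    return MonthlySeries(start_year=start[0], start_month=start[1], values=counts)


def period_aggregate(
    records: pd.DataFrame,
    period_breaks: list[tuple[int, int]] = [(1997, 2000), (2001, 2004), (2005, 2008), (2009, 2013)],
) -> pd.DataFrame:
    """Per-period, per-calendar-month sighting totals.

    ``period_breaks`` is a list of inclusive (first_year, last_year)
    spans.  Records falling in no period are tallied in an ``outside``
    row so the aggregation stays a partition of the input.
    """
    firsts = [a for a, _ in period_breaks]
    if firsts != sorted(firsts):
        raise ValueError("period_breaks must be ordered")
    dates = pd.to_datetime(records["date"].astype(str))
    years = dates.dt.year.to_numpy()
    months = dates.dt.month.to_numpy()
    labels = [f"{a}-{b}" for a, b in period_breaks]
    rows = []
    assigned = np.zeros(len(records), dtype=bool)
    for (a, b), label in zip(period_breaks, labels):
        in_period = (years >= a) & (years <= b)
        assigned |= in_period
        for m in range(1, 13):
            rows.append(
                {
                    "period": label,
                    "month": m,
                    "count": int(((months == m) & in_period).sum()),
                }
            )
    n_outside = int((~assigned).sum())
    for m in range(1, 13):
        rows.append(
            {
                "period": "outside",
                "month": m,
                "count": int(((months == m) & ~assigned).sum()),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_outside"] = n_outside
    return out


def _centered_ma12(values: np.ndarray) -> np.ndarray:
    """Centred moving average of order 12 with half-weight endpoints."""
    weights = np.full(13, 1.0 / 12.0)
    weights[0] = weights[-1] = 1.0 / 24.0
    trend = np.full(values.size, np.nan)
    if values.size >= 13:
        trend[6:-6] = np.convolve(values, weights[::-1], mode="valid")
    return trend


def decompose_additive(series: MonthlySeries) -> DecompositionResult:
    """Classical additive decomposition of a monthly series.

    Requires at least 24 months so every calendar month contributes at
    least one detrended value to the seasonal estimate.
    """
    y = series.values
    if y.size < 24:
        raise ValueError(
            f"series has {y.size} months; at least 24 are needed to "
            "estimate stable seasonal effects"
        )
    trend = _centered_ma12(y)
    detrended = y - trend
    moy = series.month_of_year()
    effects = np.empty(12)
    for m in range(1, 13):
        vals = detrended[moy == m]
        effects[m - 1] = np.nanmean(vals)
    effects -= effects.mean()
    seasonal = effects[moy - 1]
    random = y - trend - seasonal
    return DecompositionResult(
        series=series,
        trend=trend,
        seasonal=seasonal,
        random=random,
        seasonal_effects=effects,
    )
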