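"""Calendar time <-> accumulated thermal time (ATT) conversion.

Development is clocked in degree-days: each calendar day contributes an
increment that depends on its mean daytime temperature through a
temperature-response function.  The default response is linear above a base
temperature (increment = max(T - base, 0)); a tabulated custom response can
be supplied for nonlinear response curves whose parameters come from
external calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureRecord",
    "ThermalTimeResponse",
    "att_series",
    "calendar_from_att",
]


@dataclass(frozen=True)
class TemperatureRecord:
    date: object  # datetime.date / pd.Timestamp
    mean_daytime_temp: float


@dataclass(frozen=True)
class ThermalTimeResponse:
    """Daily degree-day increment as a function of mean daytime temperature.

    kind='linear-base': increment = max(T - base_temp, 0).
    kind='custom-tabulated': linear interpolation of a (temperature ->
    increment) table; increments must be non-negative.
    """

    kind: str = "linear-base"
    base_temp: float = 6.0
    table: pd.Series | None = None

    def __post_init__(self):
        if self.kind not in ("linear-base", "custom-tabulated"):
            raise ValueError(f"unknown response kind {self.kind!r}")
        if self.kind == "custom-tabulated":
            if self.table is None:
                raise ValueError("custom-tabulated response requires a table")
            if (self.table.to_numpy() < 0).any():
                raise ValueError("response increments must be >= 0")

    def daily_increment(self, temps) -> np.ndarray:
        t = np.asarray(temps, dtype=float)
        if self.kind == "linear-base":
            return np.maximum(t - self.base_temp, 0.0)
        tab = self.table.sort_index()
        return np.interp(t, tab.index.to_numpy(dtype=float), tab.to_numpy(dtype=float))


def _as_temp_series(temps) -> pd.Series:
    if isinstance(temps, pd.Series):
        s = temps.copy()
        s.index = pd.DatetimeIndex(s.index)
        return s.sort_index()
    recs = list(temps)
    return pd.Series(
        [r.mean_daytime_temp for r in recs],
        index=pd.DatetimeIndex([pd.Timestamp(r.date) for r in recs]),
    ).sort_index()


def att_series(temps, sowing, response: ThermalTimeResponse | None = None) -> pd.Series:
    """Cumulative degree-days per date, 0 at sowing.

    The increment of day d accrues for d > sowing (day-resolution input);
    dates must be contiguous from sowing to the end of the record.
    """
    response = response or ThermalTimeResponse()
    s = _as_temp_series(temps)
    if s.index.has_duplicates:
        raise ValueError("duplicate temperature dates")
    sowing = pd.Timestamp(sowing)
    if sowing not in s.index:
        raise ValueError("sowing date not covered by temperature record")
    gaps = np.diff(s.index.to_numpy()).astype("timedelta64[D]").astype(int)
    if np.any(gaps != 1):
        raise ValueError("temperature record has date gaps")
    after = s.loc[s.index >= sowing]
    inc = ThermalTimeResponse.daily_increment(response, after.to_numpy())
    att = np.concatenate([[0.0], np.cumsum(inc[1:])])
    return pd.Series(att, index=after.index, name="att_dd")


def calendar_from_att(series: pd.Series, att_value) -> float | np.ndarray:
    """Real-valued day offset since sowing at which the given ATT is reached
    (linear interpolation within the day; ties resolved to the earliest day).
    """
    att = np.asarray(series.to_numpy(), dtype=float)
    days = np.arange(len(att), dtype=float)
    v = np.asarray(att_value, dtype=float)
    if np.any(v < att[0]) or np.any(v > att[-1]):
        raise ValueError("att_value outside the range of the series")
    # earliest-day convention for flat stretches: searchsorted 'left'
    idx = np.clip(np.searchsorted(att, v, side="left"), 1, len(att) - 1)
    a0, a1 = att[idx - 1], att[idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(a1 > a0, (v - a0) / (a1 - a0), 0.0)
    out = np.where(v <= att[0], 0.0, days[idx - 1] + frac)
    return float(out) if np.isscalar(att_value) or np.ndim(att_value) == 0 else out


def att_at_day(series: pd.Series, day_offset) -> np.ndarray:
    """Inverse helper: ATT at a real-valued day offset since sowing."""
    att = series.to_numpy(dtype=float)
    days = np.arange(len(att), dtype=float)
    return np.interp(np.asarray(day_offset, dtype=float), days, att)
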