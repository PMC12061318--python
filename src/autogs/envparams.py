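"""Daily environmental parameters (EPs) from raw weather.

Nine EPs are tracked per environment and day:

========  =====================================================
DL        day length (h)
GDD       growing degree days, (capped Tmax + floored Tmin)/2 − Tbase (°F·day)
PRE       precipitation (mm)
PAR       photosynthetically active radiation (MJ m⁻² d⁻¹)
RH        relative humidity (%)
DTR       diurnal temperature range, raw Tmax − Tmin (°F)
PTS       photothermal sensitivity (see :data:`PTS_FORMULAS`)
PTR       photothermal ratio, GDD / DL
PTT       photothermal time, GDD × DL
========  =====================================================

Temperatures default to °F with maize constants (base 50 °F, cap 86 °F);
a °C mode (base 10, cap 30) is available for non-maize work.  GDD caps
Tmax at ``tcap`` and floors both temperatures at ``tbase`` so daily thermal
time is non-negative; DTR and PTS use the raw, unclipped temperatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import DuplicateError, GapError, InvalidRecordError, UndefinedStatisticError

logger = logging.getLogger(__name__)

EP_NAMES = ("DL", "GDD", "PRE", "PAR", "RH", "PTT", "PTR", "DTR", "PTS")

#: GDD constants by temperature unit: (tbase, tcap)
GDD_CONSTANTS = {"F": (50.0, 86.0), "C": (10.0, 30.0)}

WEATHER_COLUMNS = ["env_id", "date", "tmax", "tmin", "day_length", "rh", "pre", "par"]


@dataclass(frozen=True)
class DailyWeatherRecord:
    """One day's raw weather in one environment."""

    env_id: str
    date: pd.Timestamp
    tmax: float
    tmin: float
    day_length: float
    rh: float
    pre: float
    par: float

    def __post_init__(self):
        if self.tmax < self.tmin:
            raise InvalidRecordError(
                f"{self.env_id} {self.date.date()}: tmax ({self.tmax}) < tmin ({self.tmin})"
            )
        if not 0.0 <= self.day_length <= 24.0:
            raise InvalidRecordError(f"day_length {self.day_length} outside [0, 24]")
        if not 0.0 <= self.rh <= 100.0:
            raise InvalidRecordError(f"rh {self.rh} outside [0, 100]")
        if self.pre < 0:
            raise InvalidRecordError(f"negative precipitation {self.pre}")


@dataclass
class EPTable:
    """Daily values of the nine EPs for one environment, from sowing onwards.

    ``daily`` is indexed by date with one column per EP name plus the running
    ``cum_gdd`` column (cumulative GDD from sowing, non-decreasing).
    """

    env_id: str
    daily: pd.DataFrame
    sowing_date: pd.Timestamp = field(default=None)

    @property
    def cumulative_gdd(self) -> np.ndarray:
        return self.daily["cum_gdd"].to_numpy()

    def series(self, ep_name: str) -> pd.Series:
        if ep_name not in EP_NAMES:
            raise KeyError(f"unknown EP {ep_name!r}; expected one of {EP_NAMES}")
        return self.daily[ep_name]


def pts_literal(tmax, tmin, day_length):
    """(Tmax² − Tmin²) × DL² — the literal squared reading."""
    return (np.asarray(tmax, float) ** 2 - np.asarray(tmin, float) ** 2) * (
        np.asarray(day_length, float) ** 2
    )


def pts_halved(tmax, tmin, day_length):
    """(Tmax/2 − Tmin/2) × DL/2 — the subscript-halving reading."""
    return (np.asarray(tmax, float) / 2 - np.asarray(tmin, float) / 2) * (
        np.asarray(day_length, float) / 2
    )


#: Named PTS formulas; the printed formula is typographically ambiguous,
#: so the choice is a configuration knob.  ``literal`` is the default.
PTS_FORMULAS: dict[str, Callable] = {"literal": pts_literal, "halved": pts_halved}


def compute_gdd(tmax, tmin, tbase: float = 50.0, tcap: float = 86.0):
    """Daily growing degree days.

    Tmax is capped at ``tcap``; both temperatures are floored at ``tbase``
    before averaging, so the result is always ≥ 0.  Accepts scalars or
    arrays; raises :class:`InvalidRecordError` when any tmax < tmin.
    """
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if np.any(tmax < tmin):
        raise InvalidRecordError("tmax < tmin in GDD input")
    tmax_c = np.clip(tmax, tbase, tcap)
    tmin_c = np.maximum(tmin, tbase)
    out = (tmax_c + tmin_c) / 2.0 - tbase
    return out.item() if out.ndim == 0 else out


def compute_derived_eps(
    tmax,
    tmin,
    day_length,
    gdd,
    pts_formula: str | Callable = "literal",
) -> dict:
    """DTR, PTS, PTR and PTT for one day (or arrays of days).

    DTR and PTS use the raw temperatures; PTR = GDD/DL requires DL > 0
    (scalar DL = 0 raises; in array input the affected days become NaN with
    a warning).  PTT = GDD × DL is 0 at zero day length.
    """
    tmax = np.asarray(tmax, float)
    tmin = np.asarray(tmin, float)
    dl = np.asarray(day_length, float)
    gdd = np.asarray(gdd, float)
    pts_fn = PTS_FORMULAS[pts_formula] if isinstance(pts_formula, str) else pts_formula

    scalar = dl.ndim == 0
    if scalar and dl == 0:
        raise UndefinedStatisticError("PTR undefined at day_length = 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        ptr = np.where(dl > 0, gdd / np.where(dl > 0, dl, 1.0), np.nan)
    if not scalar and np.any(dl == 0):
        logger.warning("day_length = 0 on %d day(s); PTR set to NaN", int((dl == 0).sum()))
    out = {
        "DTR": tmax - tmin,
        "PTS": pts_fn(tmax, tmin, dl),
        "PTR": ptr,
        "PTT": gdd * dl,
    }
    if scalar:
        out = {k: np.asarray(v).item() for k, v in out.items()}
    return out


def _check_calendar(dates: pd.DatetimeIndex, env_id: str) -> None:
    dup = dates[dates.duplicated()]
    if len(dup):
        raise DuplicateError(f"{env_id}: duplicated dates {[str(d.date()) for d in dup[:5]]}")
    expected = pd.date_range(dates.min(), dates.max(), freq="D")
    missing = expected.difference(dates)
    if len(missing):
        raise GapError(f"{env_id}: missing days {[str(d.date()) for d in missing[:5]]}")


def build_ep_series(
    weather: pd.DataFrame | Sequence[DailyWeatherRecord],
    sowing_date,
    tbase: float = 50.0,
    tcap: float = 86.0,
    pts_formula: str | Callable = "literal",
) -> EPTable:
    """Convert one environment's daily weather into the nine EP series.

    ``weather`` is a DataFrame with columns ``env_id, date, tmax, tmin,
    day_length, rh, pre, par`` (or a sequence of records).  Days before
    ``sowing_date`` are dropped.  Missing individual field values are
    linearly interpolated with a warning; missing whole days raise
    :class:`GapError`, duplicated days :class:`DuplicateError`.
    """
    if not isinstance(weather, pd.DataFrame):
        weather = pd.DataFrame([r.__dict__ for r in weather])
    missing_cols = set(WEATHER_COLUMNS) - set(weather.columns)
    if missing_cols:
        raise InvalidRecordError(f"weather table missing columns {sorted(missing_cols)}")
    env_ids = weather["env_id"].unique()
    if len(env_ids) != 1:
        raise InvalidRecordError(
            f"build_ep_series expects one environment, got {list(env_ids)}"
        )
    env_id = env_ids[0]

    df = weather.copy()
    df["date"] = pd.to_datetime(df["date"])
    sowing_date = pd.Timestamp(sowing_date)
    df = df[df["date"] >= sowing_date].sort_values("date").set_index("date")
    if df.empty:
        raise InvalidRecordError(f"{env_id}: no weather on or after sowing {sowing_date.date()}")
    _check_calendar(df.index, env_id)

    value_cols = ["tmax", "tmin", "day_length", "rh", "pre", "par"]
    n_na = int(df[value_cols].isna().sum().sum())
    if n_na:
        logger.warning("%s: interpolating %d missing weather value(s)", env_id, n_na)
        df[value_cols] = df[value_cols].interpolate(limit_direction="both")

    if (df["tmax"] < df["tmin"]).any():
        bad = df.index[df["tmax"] < df["tmin"]][0]
        raise InvalidRecordError(f"{env_id} {bad.date()}: tmax < tmin")

    gdd = compute_gdd(df["tmax"].to_numpy(), df["tmin"].to_numpy(), tbase, tcap)
    derived = compute_derived_eps(
        df["tmax"].to_numpy(), df["tmin"].to_numpy(), df["day_length"].to_numpy(),
        gdd, pts_formula=pts_formula,
    )
    daily = pd.DataFrame(
        {
            "DL": df["day_length"].to_numpy(),
            "GDD": gdd,
            "PRE": df["pre"].to_numpy(),
            "PAR": df["par"].to_numpy(),
            "RH": df["rh"].to_numpy(),
            "PTT": derived["PTT"],
            "PTR": derived["PTR"],
            "DTR": derived["DTR"],
            "PTS": derived["PTS"],
        },
        index=df.index,
    )
    daily["cum_gdd"] = daily["GDD"].cumsum()
    return EPTable(env_id=env_id, daily=daily, sowing_date=sowing_date)


def build_all_ep_series(
    weather: pd.DataFrame,
    sowing_dates: dict | pd.Series | None = None,
    **kwargs,
) -> dict[str, EPTable]:
    """Per-environment :func:`build_ep_series` over a multi-environment table.

    ``sowing_dates`` maps env_id to sowing date; by default each
    environment's first recorded day is taken as sowing.
    """
    out = {}
    for env_id, sub in weather.groupby("env_id", sort=True):
        sow = (
            sowing_dates[env_id]
            if sowing_dates is not None
            else pd.to_datetime(sub["date"]).min()
        )
        out[env_id] = build_ep_series(sub, sow, **kwargs)
    return out


def ep_long_table(ep_tables: dict[str, EPTable]) -> pd.DataFrame:
    """Long-format (env_id, date, ep_name, value, cum_gdd) table for export."""
    frames = []
    for env_id, tbl in ep_tables.items():
        melted = tbl.daily[list(EP_NAMES)].reset_index(names="date").melt(
            id_vars="date", var_name="ep_name", value_name="value"
        )
        melted.insert(0, "env_id", env_id)
        cum = tbl.daily["cum_gdd"]
        melted["cum_gdd"] = melted["date"].map(cum).to_numpy()
        frames.append(melted)
    return pd.concat(frames, ignore_index=True)
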