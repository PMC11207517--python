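"""Photothermal index (TEP) accumulation from hourly greenhouse climate records.

TEP — the cumulative product of relative thermal effectiveness (RTE) and
photosynthetically active radiation (PAR) — is the driving variable for the
fruit-quality response models in :mod:`tepqual.models`.  The chain is

    hourly (T, PAR)  ->  RTE(T)          trapezoid on cardinal temperatures
                     ->  HTEP            RTE x PAR x 3600e-6   [MJ m-2 h-1]
                     ->  DTEP            sum of HTEP over a day [MJ m-2 d-1]
                     ->  TEP             running sum of DTEP    [MJ m-2]

PAR enters as a flux in W m-2; the 3600e-6 factor is exactly the
W m-2 -> MJ m-2 h-1 conversion.  Sensors reporting umol m-2 s-1 are
converted with the standard ~4.57 umol J-1 quantum ratio for PAR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConfigurationError, InputError

logger = logging.getLogger(__name__)

#: MJ accumulated per hour by a 1 W m-2 flux.
W_TO_MJ_PER_HOUR = 3600e-6

#: Quantum ratio of PAR: 1 W m-2 ~ 4.57 umol m-2 s-1 (McCree).
UMOL_PER_W_PAR = 4.57

#: Optimum climate during fruit ripening, as published summary statistics
#: (mean, sd).  Reference constants only — not used in any computation.
OPTIMUM_RIPENING_ENVIRONMENT = {
    "daily_mean_temp_c": (18.69, 1.35),
    "daytime_mean_temp_c": (26.30, 2.67),
    "night_mean_temp_c": (14.30, 1.21),
    "par_umol_m2_s": (592.34, 88.74),
    "insolation_h_per_day": (9.86, 0.94),
}


@dataclass(frozen=True)
class CardinalTemperatures:
    """The four temperature thresholds bounding the thermal response.

    Defaults are the fruit-ripening values for greenhouse tomato:
    lower critical 15, lower optimum 22, upper optimum 28, upper
    critical 35 degC.
    """

    t_b: float = 15.0
    t_ob: float = 22.0
    t_ou: float = 28.0
    t_m: float = 35.0

    def __post_init__(self):
        if not (self.t_b < self.t_ob < self.t_ou < self.t_m):
            raise ConfigurationError(
                "cardinal temperatures must satisfy t_b < t_ob < t_ou < t_m, "
                f"got ({self.t_b}, {self.t_ob}, {self.t_ou}, {self.t_m})"
            )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.t_b, self.t_ob, self.t_ou, self.t_m)


DEFAULT_CARDINALS = CardinalTemperatures()


@dataclass(frozen=True)
class TepSeries:
    """Daily and cumulative TEP for a climate series.

    ``cumulative[k]`` is the TEP accumulated from ``origin_date`` through
    the end of day ``dates[k]`` (accumulation starts from zero at the
    origin), so ``cumulative[k] = cumulative[k-1] + daily[k]``.
    """

    dates: tuple
    daily: np.ndarray
    cumulative: np.ndarray
    origin_date: date

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def final(self) -> float:
        """Total TEP accumulated over the series (MJ m-2)."""
        return float(self.cumulative[-1]) if len(self) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": list(self.dates),
                "dtep_mj_m2": self.daily,
                "tep_mj_m2": self.cumulative,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def relative_thermal_effectiveness(temperature, cardinals: CardinalTemperatures = DEFAULT_CARDINALS):
    """Trapezoidal thermal response of growth to hourly mean temperature.

    Zero below ``t_b`` and above ``t_m``, one on the optimum plateau
    ``[t_ob, t_ou]``, linear ramps in between; continuous and piecewise
    linear, with values in [0, 1].  Accepts scalars or arrays.
    """
    t = np.asarray(temperature, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InputError("temperature must be finite")
    c = cardinals.as_tuple()
    rte = np.interp(t, c, [0.0, 1.0, 1.0, 0.0], left=0.0, right=0.0)
    return float(rte) if np.isscalar(temperature) else rte


def hourly_tep(rte, par):
    """Hourly TEP increment (MJ m-2 h-1) from an RTE fraction and PAR flux (W m-2)."""
    rte = np.asarray(rte, dtype=float)
    par = np.asarray(par, dtype=float)
    if np.any(par < 0):
        raise InputError("par must be non-negative")
    if np.any((rte < 0) | (rte > 1)):
        raise InputError("rte must lie in [0, 1]")
    out = rte * par * W_TO_MJ_PER_HOUR
    return float(out) if out.ndim == 0 else out


def par_umol_to_w(par_umol, umol_per_w: float = UMOL_PER_W_PAR):
    """Convert a PAR photon flux (umol m-2 s-1) to an energy flux (W m-2)."""
    return np.asarray(par_umol, dtype=float) / umol_per_w


def read_climate_csv(path, par_unit: str = "w_m2") -> pd.DataFrame:
    """Read an hourly (or finer) climate CSV with columns timestamp, temp_c, par.

    ``par_unit`` selects the sensor unit: ``"w_m2"`` (flux, used as is) or
    ``"umol_m2_s"`` (photon flux, converted via the quantum ratio).
    """
    frame = pd.read_csv(path)
    missing = {"timestamp", "temp_c", "par"} - set(frame.columns)
    if missing:
        raise InputError(f"climate CSV lacks columns: {sorted(missing)}")
    frame = frame.copy()
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    if par_unit == "umol_m2_s":
        frame["par"] = par_umol_to_w(frame["par"].to_numpy())
    elif par_unit != "w_m2":
        raise ConfigurationError(f"unknown PAR unit {par_unit!r}")
    _check_sorted(frame)
    if (frame["par"] < 0).any():
        raise InputError("negative PAR in climate CSV")
    return frame[["timestamp", "temp_c", "par"]]


def _check_sorted(frame: pd.DataFrame) -> None:
    ts = frame["timestamp"]
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise InputError("climate series must be strictly ascending in time")


def resample_hourly(frame: pd.DataFrame) -> pd.DataFrame:
    """Average sub-hourly records to hourly means (the resolution RTE is defined on)."""
    _check_sorted(frame)
    hours = frame["timestamp"].dt.floor("h")
    out = (
        frame.assign(timestamp=hours)
        .groupby("timestamp", as_index=False)[["temp_c", "par"]]
        .mean()
    )
    return out


def daily_tep(frame: pd.DataFrame, cardinals: CardinalTemperatures = DEFAULT_CARDINALS) -> float:
    """DTEP (MJ m-2 d-1): sum of hourly TEP over one calendar day of records."""
    if len(frame) == 0:
        logger.warning("daily_tep called on an empty day; treating as a gap (0)")
        return 0.0
    days = frame["timestamp"].dt.normalize().unique()
    if len(days) > 1:
        raise InputError(f"records span {len(days)} dates; daily_tep expects one")
    hours = frame["timestamp"].dt.floor("h")
    if hours.duplicated().any():
        raise InputError("duplicated hours within the day")
    rte = relative_thermal_effectiveness(frame["temp_c"].to_numpy(), cardinals)
    return float(np.sum(hourly_tep(rte, frame["par"].to_numpy())))


def accumulate_tep(
    frame: pd.DataFrame,
    cardinals: CardinalTemperatures = DEFAULT_CARDINALS,
    origin_date: date | None = None,
    strict: bool = False,
    max_gap_fraction: float = 0.05,
) -> TepSeries:
    """Accumulate a full climate series into daily and cumulative TEP.

    Sub-hourly records are averaged to hourly means first.  Accumulation
    starts from zero at ``origin_date`` (default: first date in the series);
    days before the origin are dropped.  Missing hours contribute zero and
    are reported through logging; with ``strict=True`` a series with more
    than ``max_gap_fraction`` missing hours is rejected.
    """
    if len(frame) == 0:
        raise InputError("empty climate series")
    hourly = resample_hourly(frame)
    dates = hourly["timestamp"].dt.date
    first, last = dates.iloc[0], dates.iloc[-1]
    if origin_date is None:
        origin_date = first
    if not (first <= origin_date <= last):
        raise InputError(f"origin_date {origin_date} outside series span [{first}, {last}]")

    hourly = hourly[dates >= origin_date]
    rte = relative_thermal_effectiveness(hourly["temp_c"].to_numpy(), cardinals)
    htep = hourly_tep(rte, hourly["par"].to_numpy())
    by_day = pd.Series(htep, index=hourly["timestamp"].dt.date).groupby(level=0)
    day_index = by_day.sum().index
    daily = by_day.sum().to_numpy()

    n_days = (pd.Timestamp(day_index[-1]) - pd.Timestamp(day_index[0])).days + 1
    n_expected = 24 * n_days
    n_missing = n_expected - len(hourly)
    if n_missing > 0:
        frac = n_missing / n_expected
        logger.warning("climate series has %d missing hours (%.1f%%)", n_missing, 100 * frac)
        if strict and frac > max_gap_fraction:
            raise InputError(
                f"{n_missing} missing hours ({frac:.1%}) exceeds the strict-mode "
                f"limit of {max_gap_fraction:.0%}"
            )
    # calendar days entirely absent from the records also count as gaps
    if len(day_index) < n_days:
        logger.warning("%d whole days absent from the series", n_days - len(day_index))

    return TepSeries(
        dates=tuple(day_index),
        daily=daily,
        cumulative=np.cumsum(daily),
        origin_date=origin_date,
    )


class TepAccumulator(TransformerMixin, BaseEstimator):
    """Transformer turning an hourly climate frame into a daily TEP frame.

    Parameters
    ----------
    cardinals : tuple of 4 floats
        (t_b, t_ob, t_ou, t_m) in degC; defaults to the ripening-period values.
    origin_date : datetime.date or None
        Day at which accumulation starts from zero (None: first day).
    par_unit : {"w_m2", "umol_m2_s"}
        Unit of the ``par`` column.
    strict : bool
        Reject series with more than ``max_gap_fraction`` missing hours.
    """

    def __init__(self, cardinals=(15.0, 22.0, 28.0, 35.0), origin_date=None,
                 par_unit="w_m2", strict=False, max_gap_fraction=0.05):
        self.cardinals = cardinals
        self.origin_date = origin_date
        self.par_unit = par_unit
        self.strict = strict
        self.max_gap_fraction = max_gap_fraction

    def fit(self, X: pd.DataFrame, y=None):
        self.cardinals_ = CardinalTemperatures(*self.cardinals)
        if self.par_unit not in ("w_m2", "umol_m2_s"):
            raise ConfigurationError(f"unknown PAR unit {self.par_unit!r}")
        self.n_records_ = len(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "cardinals_"):
            self.fit(X)
        frame = X.copy()
        if self.par_unit == "umol_m2_s":
            frame["par"] = par_umol_to_w(frame["par"].to_numpy())
        series = accumulate_tep(
            frame,
            cardinals=self.cardinals_,
            origin_date=self.origin_date,
            strict=self.strict,
            max_gap_fraction=self.max_gap_fraction,
        )
        return series.to_frame()

    def accumulate(self, X: pd.DataFrame) -> TepSeries:
        """Like :meth:`transform` but returning the richer :class:`TepSeries`."""
        self.fit(X)
        frame = X.copy()
        if self.par_unit == "umol_m2_s":
            frame["par"] = par_umol_to_w(frame["par"].to_numpy())
        return accumulate_tep(
            frame,
            cardinals=self.cardinals_,
            origin_date=self.origin_date,
            strict=self.strict,
            max_gap_fraction=self.max_gap_fraction,
        )
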