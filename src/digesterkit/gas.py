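"""Gas-sensor fusion, volume normalization, smoothing, and cycle segmentation.

A displacement gas meter reports volumetric flow at its own temperature and
pressure; an infrared sensor reports the CH4 fraction of the same stream.
This module fuses the two into a methane-rate series at dry normal conditions
(0 degC = 273.15 K, 1 atm = 1013.25 hPa), smooths it, and cuts it into daily
feeding cycles so that the kinetics of each cycle can be modelled.

Volume normalization uses the ideal-gas scaling

    V_n = V * (p - p_w * saturated) / p0 * T0 / T,

where the water-vapour partial pressure ``p_w`` (subtracted only for streams
flagged water-saturated) comes from the Magnus formula, accurate to well
under 1% between 0 and 60 degC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid, trapezoid

logger = logging.getLogger(__name__)

__all__ = [
    "T0_K",
    "P0_HPA",
    "GasTimeSeries",
    "FeedingSchedule",
    "DailyCycle",
    "magnus_svp",
    "normalize_volume",
    "methane_rate",
    "align_fraction",
    "running_mean",
    "segment_cycles",
    "daily_yield",
]

#: Normal-condition reference temperature (K) and pressure (hPa).
T0_K = 273.15
P0_HPA = 1013.25


def magnus_svp(temperature_c):
    """Saturation vapour pressure of water (hPa) by the Magnus formula.

    p_w = 6.1094 * exp(17.625 T / (T + 243.04)), T in degC.
    """
    t = np.asarray(temperature_c, dtype=float)
    return 6.1094 * np.exp(17.625 * t / (t + 243.04))


def normalize_volume(flow, temperature_c, pressure_hpa, water_saturated):
    """Re-calculate a volumetric flow to dry normal conditions (0 degC, 1 atm).

    Parameters
    ----------
    flow : array_like
        Volumetric rate (mL/min) at measurement conditions; must be >= 0.
    temperature_c : array_like
        Gas temperature in degC (> -273.15).
    pressure_hpa : array_like
        Absolute pressure in hPa (> 0; above the saturation vapour pressure
        whenever the stream is flagged saturated).
    water_saturated : array_like of bool
        Whether the stream is water-saturated; only then is the vapour
        partial pressure subtracted.

    Returns
    -------
    Normalized flow (mL/min at dry normal conditions), same shape as input.
    """
    flow = np.asarray(flow, dtype=float)
    t = np.asarray(temperature_c, dtype=float)
    p = np.asarray(pressure_hpa, dtype=float)
    sat = np.asarray(water_saturated, dtype=bool)

    if np.any(flow < 0):
        raise ValueError("flow: negative volumetric rates are non-physical")
    if np.any(t <= -T0_K):
        raise ValueError("temperature: values at or below absolute zero")
    if np.any(p <= 0):
        raise ValueError("pressure: non-positive absolute pressure")
    p_w = magnus_svp(t)
    if np.any(sat & (p <= p_w)):
        raise ValueError(
            "pressure: at or below the water saturation pressure for a "
            "saturated stream"
        )
    dry = p - np.where(sat, p_w, 0.0)
    factor = (dry / P0_HPA) * (T0_K / (t + T0_K))
    out = flow * factor
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class GasTimeSeries:
    """Fused gas-meter / CH4-sensor stream.

    ``time`` is minutes since experiment start (strictly increasing),
    ``flow`` the raw volumetric rate (mL/min) at the measurement conditions
    stored alongside, and ``ch4_fraction`` the unitless CH4 content in [0, 1].
    """

    time: np.ndarray
    flow: np.ndarray
    ch4_fraction: np.ndarray
    temperature_c: np.ndarray
    pressure_hpa: np.ndarray
    water_saturated: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        n = None
        for name in (
            "time",
            "flow",
            "ch4_fraction",
            "temperature_c",
            "pressure_hpa",
        ):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.ndim != 1:
                raise ValueError(f"{name} must be 1-D")
            if n is None:
                n = a.size
            elif a.size != n:
                raise ValueError("all fields must have equal length")
            arrays[name] = a
        sat = np.asarray(self.water_saturated)
        if sat.ndim == 0:
            sat = np.full(n, bool(sat))
        arrays["water_saturated"] = sat.astype(bool)
        if np.any(np.diff(arrays["time"]) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(arrays["flow"] < 0):
            raise ValueError("flow must be >= 0 mL/min")
        frac = arrays["ch4_fraction"]
        if np.any((frac < 0) | (frac > 1)):
            raise ValueError("ch4_fraction must lie in [0, 1]")
        if np.any(arrays["temperature_c"] <= -T0_K):
            raise ValueError("temperature must exceed absolute zero")
        for name, a in arrays.items():
            object.__setattr__(self, name, a)

    def __len__(self) -> int:
        return self.time.size

    def normalized_flow(self) -> np.ndarray:
        """Flow at dry normal conditions (mL/min)."""
        return normalize_volume(
            self.flow, self.temperature_c, self.pressure_hpa, self.water_saturated
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.time,
                "flow_ml_min": self.flow,
                "ch4_fraction": self.ch4_fraction,
                "temperature_c": self.temperature_c,
                "pressure_hpa": self.pressure_hpa,
                "water_saturated": self.water_saturated,
            }
        )

    def to_csv(self, path_or_buf=None, sep: str = ","):
        return self.to_frame().to_csv(path_or_buf, sep=sep, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, columns: dict[str, str] | None = None):
        """Build a series from a delimited-text table.

        ``columns`` maps canonical names (time, flow, ch4_fraction,
        temperature_c, pressure_hpa, water_saturated) to the table's column
        names; identity by default.
        """
        columns = columns or {}

        def col(name, default=None):
            key = columns.get(name, _CANONICAL.get(name, name))
            if key in df.columns:
                return df[key].to_numpy()
            if default is not None:
                return default
            raise ValueError(f"missing required column for {name!r}")

        n = len(df)
        return cls(
            time=col("time"),
            flow=col("flow"),
            ch4_fraction=col("ch4_fraction"),
            temperature_c=col("temperature_c", np.zeros(n)),
            pressure_hpa=col("pressure_hpa", np.full(n, P0_HPA)),
            water_saturated=col("water_saturated", np.zeros(n, dtype=bool)),
        )

    @classmethod
    def from_csv(cls, path_or_buf, sep: str = ",", columns=None):
        return cls.from_frame(pd.read_csv(path_or_buf, sep=sep), columns)


_CANONICAL = {
    "time": "time_min",
    "flow": "flow_ml_min",
    "ch4_fraction": "ch4_fraction",
    "temperature_c": "temperature_c",
    "pressure_hpa": "pressure_hpa",
    "water_saturated": "water_saturated",
}


@dataclass(frozen=True)
class FeedingSchedule:
    """Daily feeding regime of a CSTR.

    ``feed_times`` are minutes since experiment start, one pulse per day.
    The feed COD concentration is OLR x HRT by the CSTR mass balance.
    """

    feed_times: np.ndarray
    reactor_volume_l: float
    hrt_days: float
    olr: float

    def __post_init__(self) -> None:
        times = np.asarray(self.feed_times, dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError("feed_times must be strictly increasing")
        if self.hrt_days <= 0:
            raise ValueError("HRT must be > 0 days")
        if self.olr <= 0:
            raise ValueError("OLR must be > 0 gCOD/L/d")
        if self.reactor_volume_l <= 0:
            raise ValueError("reactor volume must be > 0 L")
        object.__setattr__(self, "feed_times", times)

    @property
    def feed_cod(self) -> float:
        """Feed COD concentration, gCOD per L of feed (= OLR x HRT)."""
        return self.olr * self.hrt_days

    @property
    def daily_cod_g(self) -> float:
        """COD fed per day, g (= OLR x reactor volume)."""
        return self.olr * self.reactor_volume_l


def align_fraction(flow_time, ch4_time, ch4_fraction) -> np.ndarray:
    """Linearly interpolate a CH4-fraction stream onto the flow grid.

    Extrapolation is refused: the flow grid must lie inside the CH4 sensor's
    time range.
    """
    flow_time = np.asarray(flow_time, dtype=float)
    ch4_time = np.asarray(ch4_time, dtype=float)
    ch4_fraction = np.asarray(ch4_fraction, dtype=float)
    if flow_time[0] < ch4_time[0] or flow_time[-1] > ch4_time[-1]:
        raise ValueError(
            "flow and CH4 time ranges do not overlap fully; extrapolating "
            "the CH4 fraction is not allowed"
        )
    return np.interp(flow_time, ch4_time, ch4_fraction)


def methane_rate(
    series: GasTimeSeries,
    ch4_time=None,
    ch4_fraction=None,
) -> np.ndarray:
    """Methane production rate, mL/min at dry normal conditions.

    Element-wise product of the normalized flow and the CH4 fraction.  If a
    separate sensor stream (``ch4_time``, ``ch4_fraction``) is given it is
    first aligned to the flow grid by linear interpolation.
    """
    if (ch4_time is None) != (ch4_fraction is None):
        raise ValueError("provide both ch4_time and ch4_fraction, or neither")
    if ch4_time is not None:
        frac = align_fraction(series.time, ch4_time, ch4_fraction)
    else:
        frac = series.ch4_fraction
    return series.normalized_flow() * frac


def running_mean(values, window: float = 15.0, times=None) -> np.ndarray:
    """Centred moving average over ``window`` minutes with truncated edges.

    The output grid equals the input grid; near the edges the window is
    truncated to the available samples.  The sampling interval is taken as
    the median time step (1 min if ``times`` is omitted).  A window shorter
    than the sampling interval passes the data through with a warning.
    """
    values = np.asarray(values, dtype=float)
    if window <= 0:
        raise ValueError("window must be > 0 minutes")
    if times is None:
        dt = 1.0
    else:
        times = np.asarray(times, dtype=float)
        if times.size != values.size:
            raise ValueError("times and values must have equal length")
        dt = float(np.median(np.diff(times))) if times.size > 1 else 1.0
    half = int(round(window / dt)) // 2
    if half < 1:
        logger.warning(
            "running_mean window (%.3g min) is below the sampling interval "
            "(%.3g min); returning the series unchanged",
            window,
            dt,
        )
        return values.copy()
    kernel = np.ones(2 * half + 1)
    sums = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones_like(values), kernel, mode="same")
    return sums / counts


@dataclass(frozen=True)
class DailyCycle:
    """One feeding cycle: methane kinetics relative to the feed pulse.

    ``t_rel`` is minutes after feeding (within [0, 1440]), ``ch4_rate`` the
    normalized methane rate (mL/min), ``ch4_cumulative`` its trapezoid
    integral from the feed (mL).  ``incomplete`` flags cycles with internal
    data gaps; those are excluded from breakpoint trending.
    """

    cycle_day: int
    t_rel: np.ndarray
    ch4_rate: np.ndarray
    ch4_cumulative: np.ndarray
    incomplete: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.t_rel, dtype=float)
        r = np.asarray(self.ch4_rate, dtype=float)
        c = np.asarray(self.ch4_cumulative, dtype=float)
        if not (t.size == r.size == c.size):
            raise ValueError("t_rel, ch4_rate, ch4_cumulative must align")
        if t.size and (t[0] < 0 or t[-1] > 1440 + 1e-9):
            raise ValueError("t_rel must lie within one feeding interval")
        if np.any(np.diff(c) < -1e-9):
            raise ValueError("cumulative CH4 must be non-decreasing")
        object.__setattr__(self, "t_rel", t)
        object.__setattr__(self, "ch4_rate", r)
        object.__setattr__(self, "ch4_cumulative", c)

    def __len__(self) -> int:
        return self.t_rel.size

    @property
    def total_ch4_ml(self) -> float:
        return float(self.ch4_cumulative[-1]) if len(self) else 0.0


def segment_cycles(
    series: GasTimeSeries,
    schedule: FeedingSchedule,
    max_cycle_minutes: float = 1440.0,
    gap_minutes: float = 30.0,
    ch4_time=None,
    ch4_fraction=None,
) -> list[DailyCycle]:
    """Cut a gas series into per-feed daily cycles.

    One cycle per feed event falling inside the series span; each cycle runs
    from its feed to the next feed, capped at ``max_cycle_minutes``.  Samples
    are partitioned half-open, ``[feed, end)``, so every in-span sample
    belongs to exactly one cycle.  Cycles with an internal gap longer than
    ``gap_minutes`` are flagged incomplete.
    """
    feeds = schedule.feed_times
    if np.any(np.diff(feeds) < 60.0):
        raise ValueError("overlapping feed events: feeds less than 60 min apart")
    rate = methane_rate(series, ch4_time, ch4_fraction)
    t = series.time
    in_span = feeds[(feeds >= t[0] - 1e-9) & (feeds <= t[-1])]
    if in_span.size == 0:
        raise ValueError("no feed time falls inside the series span")
    cycles: list[DailyCycle] = []
    for i, t_feed in enumerate(in_span):
        idx = np.searchsorted(feeds, t_feed)
        t_next = feeds[idx + 1] if idx + 1 < feeds.size else np.inf
        t_end = min(t_feed + max_cycle_minutes, t_next)
        mask = (t >= t_feed) & (t < t_end)
        tc = t[mask] - t_feed
        rc = rate[mask]
        if tc.size == 0:
            continue
        gaps = np.diff(np.concatenate([[0.0], tc]))
        expected_span = min(max_cycle_minutes, t_end - t_feed)
        incomplete = bool(
            np.any(gaps > gap_minutes) or (expected_span - tc[-1]) > gap_minutes
        )
        cumulative = cumulative_trapezoid(rc, tc, initial=0.0)
        cycles.append(
            DailyCycle(
                cycle_day=int(t_feed // 1440),
                t_rel=tc,
                ch4_rate=rc,
                ch4_cumulative=cumulative,
                incomplete=incomplete,
            )
        )
    return cycles


def daily_yield(daily_ch4_ml: float, schedule: FeedingSchedule) -> float:
    """Methane yield, mL CH4 per g COD fed: daily CH4 / (OLR x volume)."""
    if daily_ch4_ml < 0:
        raise ValueError("daily CH4 must be >= 0 mL")
    denom = schedule.daily_cod_g
    if denom <= 0:
        raise ValueError("schedule implies zero daily COD load")
    return daily_ch4_ml / denom
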