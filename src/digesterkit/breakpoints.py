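"""Two-segment methane-kinetics regression and breakpoint drift trending.

After each feeding pulse, cumulative methane production rises steeply while
fermentation intermediates are being turned over and then settles onto a
shallow residual slope once the volatile fatty acids are depleted.  The time
of that transition — the *breakpoint*, where two fitted lines intersect — is
the monitored statistic: day-by-day drift of the breakpoint towards the end
of the 24-h feeding window precedes VFA accumulation and is usable as an
early warning of trace-element limitation.

The model is a continuous piecewise-linear function with one free knot k,

    y(t) = b0 + b1 * t + b2 * (t - k)_+ ,

fitted by least squares on cumulative methane versus minutes after feeding.
For each candidate knot the problem is linear; the knot itself is found by
an exhaustive scan over the observed sample times (excluding a few samples
at each edge) followed by golden-section refinement between the neighbouring
grid points.  The scan is exact — it evaluates the profiled SSE at every
candidate — and is vectorised via prefix sums, so it stays cheap at minute
resolution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gas import DailyCycle

logger = logging.getLogger(__name__)

__all__ = [
    "TwoSegmentRegression",
    "TwoSegmentRegressionResults",
    "BreakpointFit",
    "BreakpointTrend",
    "fit_two_segment",
    "breakpoint_series",
    "detect_drift",
]

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


class TwoSegmentRegression:
    """Continuous two-piece linear least squares with an unknown knot.

    Parameters
    ----------
    t, y : array_like
        Abscissa (strictly increasing) and response.  At least 8 samples.
    edge_exclude : int
        Number of samples excluded from the candidate-knot grid at each
        edge, so both segments always contain a handful of points.
    degenerate_tol : float
        Minimum relative SSE improvement over a single straight line for
        the two-segment structure to count as real.
    """

    def __init__(self, t, y, edge_exclude: int = 3, degenerate_tol: float = 0.01):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if t.size < 8:
            raise ValueError(f"need at least 8 samples, got {t.size}")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing")
        if edge_exclude < 1:
            raise ValueError("edge_exclude must be >= 1")
        if t.size - 2 * edge_exclude < 2:
            raise ValueError("too few interior samples for the candidate grid")
        self.t = t
        self.y = y
        self.edge_exclude = int(edge_exclude)
        self.degenerate_tol = float(degenerate_tol)
        # prefix sums for O(1) suffix aggregates at any knot
        self._ct = np.concatenate([[0.0], np.cumsum(t)])
        self._ctt = np.concatenate([[0.0], np.cumsum(t * t)])
        self._cy = np.concatenate([[0.0], np.cumsum(y)])
        self._cty = np.concatenate([[0.0], np.cumsum(t * y)])
        self._syy = float(np.sum(y * y))

    @property
    def nobs(self) -> int:
        return self.t.size

    @property
    def knot_grid(self) -> np.ndarray:
        """Candidate knots: observed sample times minus the excluded edges."""
        e = self.edge_exclude
        return self.t[e : self.t.size - e]

    # -- linear algebra -----------------------------------------------------

    def _suffix(self, k):
        """Aggregates over samples with t > k (vectorised in k)."""
        n = self.t.size
        j = np.searchsorted(self.t, k, side="right")
        m = n - j
        st = self._ct[n] - self._ct[j]
        stt = self._ctt[n] - self._ctt[j]
        sy = self._cy[n] - self._cy[j]
        sty = self._cty[n] - self._cty[j]
        return m, st, stt, sy, sty

    def _normal_equations(self, k):
        """Stacked normal equations of y ~ 1 + t + (t-k)_+ for knots k."""
        k = np.asarray(k, dtype=float)
        n = self.t.size
        m, tsuf, ttsuf, ysuf, tysuf = self._suffix(k)
        su = tsuf - m * k
        stu = ttsuf - k * tsuf
        suu = ttsuf - 2.0 * k * tsuf + m * k * k
        suy = tysuf - k * ysuf
        shape = k.shape + (3, 3)
        A = np.empty(shape)
        A[..., 0, 0] = n
        A[..., 0, 1] = A[..., 1, 0] = self._ct[n]
        A[..., 0, 2] = A[..., 2, 0] = su
        A[..., 1, 1] = self._ctt[n]
        A[..., 1, 2] = A[..., 2, 1] = stu
        A[..., 2, 2] = suu
        b = np.empty(k.shape + (3,))
        b[..., 0] = self._cy[n]
        b[..., 1] = self._cty[n]
        b[..., 2] = suy
        return A, b

    def sse_at_knot(self, k: float) -> tuple[float, np.ndarray]:
        """Profiled SSE and coefficients (b0, b1, b2) at a fixed knot."""
        A, b = self._normal_equations(np.asarray(k, dtype=float))
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(A, b, rcond=None)
        sse = self._syy - float(beta @ b)
        return max(sse, 0.0), beta

    def _grid_scan(self) -> tuple[int, np.ndarray]:
        grid = self.knot_grid
        A, b = self._normal_equations(grid)
        # guard against exactly singular systems (e.g. duplicated times)
        det = np.linalg.det(A)
        ok = np.abs(det) > 0
        beta = np.zeros_like(b)
        if np.any(ok):
            beta[ok] = np.linalg.solve(A[ok], b[ok][..., None])[..., 0]
        sse = self._syy - np.einsum("ki,ki->k", beta, b)
        sse = np.where(ok, np.maximum(sse, 0.0), np.inf)
        # earliest knot among numerically tied optima (conservative: alarms early)
        best = int(np.flatnonzero(sse <= sse.min() * (1 + 1e-12))[0])
        return best, sse

    def sse_single_line(self) -> float:
        """SSE of the ordinary one-line least-squares fit."""
        X = np.column_stack([np.ones_like(self.t), self.t])
        _, res, *_ = np.linalg.lstsq(X, self.y, rcond=None)
        if res.size:
            return float(res[0])
        fit = X @ np.linalg.lstsq(X, self.y, rcond=None)[0]
        return float(np.sum((self.y - fit) ** 2))

    def _refine(self, lo: float, hi: float, k0: float) -> float:
        """Golden-section minimisation of the profiled SSE on [lo, hi]."""
        a, b = lo, hi
        c = b - _GOLDEN * (b - a)
        d = a + _GOLDEN * (b - a)
        fc = self.sse_at_knot(c)[0]
        fd = self.sse_at_knot(d)[0]
        for _ in range(100):
            if b - a < 1e-10 * max(1.0, abs(hi)):
                break
            if fc < fd:
                b, d, fd = d, c, fc
                c = b - _GOLDEN * (b - a)
                fc = self.sse_at_knot(c)[0]
            else:
                a, c, fc = c, d, fd
                d = a + _GOLDEN * (b - a)
                fd = self.sse_at_knot(d)[0]
        k = (a + b) / 2.0
        # keep the grid optimum unless refinement strictly improves the SSE
        fk = self.sse_at_knot(k)[0]
        f0 = self.sse_at_knot(k0)[0]
        return k if fk < f0 - 1e-12 * max(f0, 1.0) else k0

    def fit(self, refine: bool = True) -> "TwoSegmentRegressionResults":
        best, sse_grid = self._grid_scan()
        grid = self.knot_grid
        knot = float(grid[best])
        if refine:
            lo = float(grid[best - 1]) if best > 0 else knot
            hi = float(grid[best + 1]) if best < grid.size - 1 else knot
            if hi > lo:
                knot = self._refine(lo, hi, knot)
        sse, beta = self.sse_at_knot(knot)
        sse_single = self.sse_single_line()
        if sse_single <= 1e-12 * max(self._syy, 1.0):
            degenerate = True
        else:
            degenerate = (sse_single - sse) / sse_single < self.degenerate_tol
        dt = float(np.median(np.diff(self.t)))
        censored = (
            knot <= grid[0] + dt * (1 + 1e-9) or knot >= grid[-1] - dt * (1 + 1e-9)
        )
        return TwoSegmentRegressionResults(
            model=self,
            params=np.asarray(beta, dtype=float),
            knot=knot,
            sse=sse,
            sse_single=sse_single,
            censored=bool(censored),
            degenerate=bool(degenerate),
        )


@dataclass(frozen=True)
class TwoSegmentRegressionResults:
    """Fit results: coefficients, the knot, and the fit diagnostics.

    ``params`` holds (intercept, slope of the active segment, slope change
    at the knot); the residual-segment slope is their sum.
    """

    model: TwoSegmentRegression
    params: np.ndarray
    knot: float
    sse: float
    sse_single: float
    censored: bool
    degenerate: bool

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def slope_active(self) -> float:
        return float(self.params[1])

    @property
    def slope_residual(self) -> float:
        return float(self.params[1] + self.params[2])

    def predict(self, t=None) -> np.ndarray:
        t = self.model.t if t is None else np.asarray(t, dtype=float)
        u = np.clip(t - self.knot, 0.0, None)
        return self.params[0] + self.params[1] * t + self.params[2] * u

    def summary(self) -> str:
        lines = [
            "Two-segment linear regression",
            "=" * 45,
            f"{'observations':<28}{self.nobs:>17d}",
            f"{'knot (min after feeding)':<28}{self.knot:>17.2f}",
            f"{'slope, active segment':<28}{self.slope_active:>17.5g}",
            f"{'slope, residual segment':<28}{self.slope_residual:>17.5g}",
            f"{'intercept':<28}{self.intercept:>17.5g}",
            f"{'SSE (two segments)':<28}{self.sse:>17.5g}",
            f"{'SSE (single line)':<28}{self.sse_single:>17.5g}",
            f"{'censored':<28}{str(self.censored):>17}",
            f"{'degenerate':<28}{str(self.degenerate):>17}",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class BreakpointFit:
    """Per-cycle breakpoint extracted from the two-segment fit."""

    cycle_day: int
    knot: float
    slope_active: float
    slope_residual: float
    intercept: float
    sse: float
    censored: bool
    degenerate: bool

    @classmethod
    def from_results(cls, day: int, res: TwoSegmentRegressionResults):
        return cls(
            cycle_day=day,
            knot=res.knot,
            slope_active=res.slope_active,
            slope_residual=res.slope_residual,
            intercept=res.intercept,
            sse=res.sse,
            censored=res.censored,
            degenerate=res.degenerate,
        )


def fit_two_segment(cycle: DailyCycle, refine: bool = True) -> BreakpointFit:
    """Fit the two-segment model to one cycle's cumulative methane curve."""
    if len(cycle) < 8:
        raise ValueError("cycle has fewer than 8 samples")
    if np.any(np.diff(cycle.ch4_cumulative) < -1e-9):
        raise ValueError("cumulative CH4 is not monotone non-decreasing")
    model = TwoSegmentRegression(cycle.t_rel, cycle.ch4_cumulative)
    return BreakpointFit.from_results(cycle.cycle_day, model.fit(refine=refine))


@dataclass(frozen=True)
class BreakpointTrend:
    """Day-by-day breakpoint trajectory with censoring.

    Censored entries (knot pushed against the window edge) are recorded at
    the window cap so that "drifted out of the 24-h window" is represented
    without extrapolating.
    """

    days: np.ndarray
    knots: np.ndarray
    censored: np.ndarray

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=int)
        knots = np.asarray(self.knots, dtype=float)
        cens = np.asarray(self.censored, dtype=bool)
        if not (days.size == knots.size == cens.size):
            raise ValueError("days, knots, censored must align")
        if np.any(np.diff(days) <= 0):
            raise ValueError("entries must be sorted by day")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "censored", cens)

    def __len__(self) -> int:
        return self.days.size

    def drift_slopes(self, window: int = 7) -> np.ndarray:
        """Trailing least-squares slope (min/day) of knot vs day per entry.

        Uses the entries within ``(day - window, day]``; NaN where fewer
        than 3 entries are available.
        """
        slopes = np.full(len(self), np.nan)
        for i, day in enumerate(self.days):
            mask = (self.days > day - window) & (self.days <= day)
            if mask.sum() >= 3:
                x = self.days[mask].astype(float)
                y = self.knots[mask]
                slopes[i] = np.polyfit(x, y, 1)[0]
        return slopes

    def to_frame(self, window: int = 7) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.days,
                "knot_min": self.knots,
                "censored": self.censored,
                "drift_slope_min_per_day": self.drift_slopes(window),
            }
        )


def breakpoint_series(
    cycles: list[DailyCycle],
    refine: bool = True,
    window_cap: float = 1440.0,
) -> BreakpointTrend:
    """Fit every usable cycle and assemble the breakpoint trend.

    Incomplete cycles (data gaps) and degenerate fits are skipped; censored
    fits are recorded with the knot at the window cap.
    """
    days, knots, cens = [], [], []
    for cycle in cycles:
        if cycle.incomplete or len(cycle) < 8:
            continue
        fit = fit_two_segment(cycle, refine=refine)
        if fit.degenerate:
            continue
        days.append(fit.cycle_day)
        knots.append(window_cap if fit.censored else fit.knot)
        cens.append(fit.censored)
    if not days:
        logger.warning("all cycles degenerate or unusable; empty breakpoint trend")
    order = np.argsort(days)
    return BreakpointTrend(
        days=np.asarray(days)[order] if days else np.empty(0, dtype=int),
        knots=np.asarray(knots)[order] if days else np.empty(0),
        censored=np.asarray(cens)[order] if days else np.empty(0, dtype=bool),
    )


def detect_drift(
    trend: BreakpointTrend,
    window: int = 7,
    slope_threshold: float = 15.0,
    level_threshold: float = 1200.0,
    consecutive: int = 3,
) -> int | None:
    """First day at which the breakpoint trend raises the early-warning alarm.

    The alarm fires on the first entry where either the trailing drift slope
    has exceeded ``slope_threshold`` (min/day) for ``consecutive`` entries in
    a row, or the breakpoint itself exceeds ``level_threshold`` (minutes).
    Deterministic given its inputs; returns None when no alarm is raised.
    """
    if len(trend) == 0:
        return None
    slopes = trend.drift_slopes(window)
    run = 0
    for i in range(len(trend)):
        if trend.knots[i] > level_threshold:
            return int(trend.days[i])
        run = run + 1 if np.isfinite(slopes[i]) and slopes[i] > slope_threshold else 0
        if run >= consecutive:
            return int(trend.days[i])
    return None
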