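"""Colony-count arithmetic, growth windows, and impedance–CFU correlation.

Plated colony counts become log10(CFU/mL) values ("CFU count" throughout the
package); during the exponential growth phase the magnitude of the fitted
fractional supercapacitor, −b0, tracks the CFU count approximately linearly,
so an ordinary least-squares line of replicate-mean −b0 against log10 CFU/mL
summarises how well impedance predicts growth.  Because cultures exposed to
Pb(II) show |b0| values orders of magnitude above unexposed ones, a simple
log-magnitude threshold also classifies Pb(II) presence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthSeries",
    "PbSeries",
    "CorrelationResult",
    "log_cfu_from_plate",
    "exponential_window",
    "correlate_supercap_cfu",
    "classify_pb_presence",
    "pb_threshold",
    "read_growth",
    "read_pb",
    "DEFAULT_PLATED_VOLUME_ML",
]

#: Spread-plate volume assumed when only colony counts are given (mL).
DEFAULT_PLATED_VOLUME_ML = 0.1

#: Matching tolerance between fit times and CFU sampling times (hours).
DEFAULT_MATCH_TOL_H = 0.5


@dataclass
class GrowthSeries:
    """Time-stamped log10(CFU/mL) for one reactor."""

    time_h: np.ndarray
    log_cfu: np.ndarray
    reactor_id: str = "r1"
    condition: str = "without_pb"

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        y = np.asarray(self.log_cfu, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("time and log_cfu must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be strictly ascending")
        if not np.all(np.isfinite(y)):
            raise ValueError("log_cfu values must be finite")
        self.time_h, self.log_cfu = t, y


@dataclass
class PbSeries:
    """Time-stamped residual dissolved Pb(II) concentration (mg/L)."""

    time_h: np.ndarray
    pb_mg_per_l: np.ndarray
    reactor_id: str = "r1"

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        c = np.asarray(self.pb_mg_per_l, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("time and concentration must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be strictly ascending")
        if np.any(c < 0):
            raise ValueError("Pb(II) concentrations must be non-negative")
        self.time_h, self.pb_mg_per_l = t, c


@dataclass
class CorrelationResult:
    """OLS line of replicate-mean −b0 against log10(CFU/mL) in a window."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    window: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n": self.n,
            "window": list(self.window),
        }


def log_cfu_from_plate(
    colony_count: int,
    dilution_factor: float,
    plated_volume_ml: float = DEFAULT_PLATED_VOLUME_ML,
) -> float:
    """log10(CFU/mL) from a spread-plate colony count.

    ``dilution_factor`` is the fraction of original sample in the plated
    dilution (e.g. 1e-6 for a 10⁻⁶ dilution).  A count of zero returns a
    finite below-detection sentinel — log10 of half a colony per plated
    volume, the conventional half-detection-limit stand-in — rather than −∞.
    """
    if colony_count < 0 or colony_count != int(colony_count):
        raise ValueError("colony count must be a non-negative integer")
    if not 0 < dilution_factor <= 1:
        raise ValueError("dilution factor must lie in (0, 1]")
    if plated_volume_ml <= 0:
        raise ValueError("plated volume must be positive")
    effective = colony_count if colony_count > 0 else 0.5
    return math.log10(effective / (dilution_factor * plated_volume_ml))


def exponential_window(
    series: GrowthSeries,
    mode: Literal["manual", "auto"] = "manual",
    window: tuple[float, float] = (0.0, 6.0),
    slope_fraction: float = 0.5,
) -> tuple[float, float]:
    """Select the exponential-growth time window of a culture.

    ``manual`` (default) simply returns the configured window — the first
    sampling periods of a rapidly growing culture, up to 6 h by default.
    ``auto`` scans the per-step slopes of log_cfu and returns the maximal
    contiguous run of steps whose slope is at least ``slope_fraction`` of
    the maximum observed slope.
    """
    if series.time_h.size < 3:
        raise ValueError("need at least 3 samples to define a growth window")
    if mode == "manual":
        return (float(window[0]), float(window[1]))
    if mode != "auto":
        raise ValueError(f"unknown window mode {mode!r}")

    slopes = np.diff(series.log_cfu) / np.diff(series.time_h)
    threshold = slope_fraction * slopes.max()
    good = slopes >= threshold
    # longest contiguous run of qualifying steps
    best_len, best_start = 0, 0
    i = 0
    while i < good.size:
        if good[i]:
            j = i
            while j < good.size and good[j]:
                j += 1
            if j - i > best_len:
                best_len, best_start = j - i, i
            i = j
        else:
            i += 1
    if best_len == 0:  # flat series: fall back to the full range
        return (float(series.time_h[0]), float(series.time_h[-1]))
    return (float(series.time_h[best_start]), float(series.time_h[best_start + best_len]))


def correlate_supercap_cfu(
    fit_table: pd.DataFrame,
    growth: GrowthSeries,
    window: tuple[float, float],
    match_tol_h: float = DEFAULT_MATCH_TOL_H,
) -> CorrelationResult:
    """Regress replicate-mean −b0 on log10(CFU/mL) inside a time window.

    ``fit_table`` is a time-course summary with columns ``time_h`` and
    ``b0_mean`` (one condition only).  Fit times are matched to CFU sampling
    times by nearest neighbour within ``match_tol_h`` hours.  Returns the
    OLS slope/intercept of y = −b0 against x = log_cfu and the coefficient
    of determination.
    """
    t0, t1 = window
    sub = fit_table[(fit_table["time_h"] >= t0) & (fit_table["time_h"] <= t1)]
    if "condition" in sub.columns and sub["condition"].nunique() > 1:
        raise ValueError("fit_table mixes conditions; filter to one condition first")

    xs, ys = [], []
    for _, row in sub.iterrows():
        dt = np.abs(growth.time_h - row["time_h"])
        k = int(np.argmin(dt))
        if dt[k] <= match_tol_h:
            xs.append(growth.log_cfu[k])
            ys.append(-row["b0_mean"])
    if len(xs) < 2:
        raise ValueError("fewer than 2 matched (fit, CFU) time points inside the window")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: log_cfu is constant inside the window")
    res = stats.linregress(x, y)
    return CorrelationResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(xs),
        window=(float(t0), float(t1)),
    )


def pb_threshold(b0_with_pb: Sequence[float], b0_without_pb: Sequence[float]) -> float:
    """Classification threshold on log10|b0|: midpoint of the class means."""
    wp = np.log10(np.abs(np.asarray(b0_with_pb, dtype=float)))
    wo = np.log10(np.abs(np.asarray(b0_without_pb, dtype=float)))
    if wp.size == 0 or wo.size == 0:
        raise ValueError("both classes (with and without Pb) are required for training")
    return float((wp.mean() + wo.mean()) / 2.0)


def classify_pb_presence(
    b0_with_pb: Sequence[float],
    b0_without_pb: Sequence[float],
    b0_query: float,
) -> str:
    """Classify a reactor as Pb-exposed from its supercapacitor magnitude.

    Training magnitudes from exposed and unexposed cultures set a threshold
    at the midpoint of the two class means of log10|b0|; a query strictly on
    the exposed side is ``"pb_present"``.  A query exactly on the threshold
    is ``"pb_absent"`` by convention.  The rule is monotone in |b0|.
    """
    thr = pb_threshold(b0_with_pb, b0_without_pb)
    wp_mean = float(np.mean(np.log10(np.abs(np.asarray(b0_with_pb, dtype=float)))))
    q = math.log10(abs(b0_query))
    if wp_mean > thr:  # exposed class has the larger magnitudes
        return "pb_present" if q > thr else "pb_absent"
    return "pb_present" if q < thr else "pb_absent"


# ------------------------------------------------------------------- I/O


def read_growth(path: str | Path, plated_volume_ml: float = DEFAULT_PLATED_VOLUME_ML) -> list[GrowthSeries]:
    """Read a growth CSV into per-reactor series.

    Accepts either a ``log_cfu`` column directly or raw plate data
    (``colony_count`` + ``dilution_factor``), alongside ``time_h``,
    ``reactor_id`` and ``condition``.
    """
    df = pd.read_csv(path)
    required = {"time_h", "reactor_id", "condition"}
    if not required <= set(df.columns):
        raise ValueError(f"growth CSV missing columns: {sorted(required - set(df.columns))}")
    if "log_cfu" not in df.columns:
        if not {"colony_count", "dilution_factor"} <= set(df.columns):
            raise ValueError("growth CSV needs either log_cfu or colony_count+dilution_factor")
        df = df.assign(
            log_cfu=[
                log_cfu_from_plate(int(c), float(d), plated_volume_ml)
                for c, d in zip(df["colony_count"], df["dilution_factor"])
            ]
        )
    out = []
    for (reactor, condition), g in df.groupby(["reactor_id", "condition"], sort=True):
        g = g.sort_values("time_h")
        out.append(
            GrowthSeries(
                g["time_h"].to_numpy(float),
                g["log_cfu"].to_numpy(float),
                reactor_id=str(reactor),
                condition=str(condition),
            )
        )
    return out


def read_pb(path: str | Path) -> list[PbSeries]:
    """Read a residual-Pb(II) CSV (time_h, reactor_id, pb_mg_per_l)."""
    df = pd.read_csv(path)
    required = {"time_h", "reactor_id", "pb_mg_per_l"}
    if not required <= set(df.columns):
        raise ValueError(f"Pb CSV missing columns: {sorted(required - set(df.columns))}")
    out = []
    for reactor, g in df.groupby("reactor_id", sort=True):
        g = g.sort_values("time_h")
        out.append(
            PbSeries(
                g["time_h"].to_numpy(float),
                g["pb_mg_per_l"].to_numpy(float),
                reactor_id=str(reactor),
            )
        )
    return out
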