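"""Exponential kinetics: mRNA decay after transcription shut-off, culture
doubling times, and doubling-time-normalized protein stability."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DecayFit",
    "DoublingTime",
    "fit_exponential_decay",
    "fit_doubling_time",
    "normalized_stability",
]


@dataclass(frozen=True)
class DecayFit:
    """Result of a single-exponential fit N(t) = N0 · exp(-k·t).

    ``half_life`` is ln2/k in minutes, or ``None`` when the fitted rate is
    non-positive (no decay detected).
    """

    k: float
    n0: float
    half_life: float | None
    rss: float
    n_points: int

    @property
    def decay_detected(self) -> bool:
        return self.half_life is not None


@dataclass(frozen=True)
class DoublingTime:
    """Population doubling time from the exponential phase of a growth curve."""

    dt_h: float
    slope: float  # d ln(OD) / dt, per hour
    window: tuple[float, float]  # time span (h) of the fitted points
    r_squared: float
    n_points: int


def fit_exponential_decay(
    table: pd.DataFrame,
    time_col: str = "time_min",
    value_col: str = "rel_conc",
    fix_n0: bool = False,
) -> DecayFit:
    """Fit N(t) = N0 · exp(-k·t) to pooled decay measurements.

    All replicate points are fitted jointly (not replicate means).  N0 is a
    free parameter by default, because the t=0 normalization itself uses a
    noisy measurement; ``fix_n0=True`` constrains N0 = 1.  The nonlinear
    least-squares fit is initialized from a log-linear regression.

    Requires at least 3 distinct time points.  If the fitted rate is
    non-positive the fit is returned with ``half_life=None`` rather than
    raising: "no decay detected" is a legitimate outcome.
    """
    t = np.asarray(table[time_col], dtype=float)
    y = np.asarray(table[value_col], dtype=float)
    if np.unique(t).size < 3:
        raise ValueError("need at least 3 distinct time points")
    if np.any(y <= 0):
        raise ValueError("relative concentrations must be positive")

    slope, intercept = np.polyfit(t, np.log(y), 1)
    k0 = max(-slope, 1e-6)
    n0_init = float(np.exp(intercept))

    if fix_n0:
        def model(tt, k):
            return np.exp(-k * tt)
        popt, _ = optimize.curve_fit(model, t, y, p0=[k0], maxfev=10000)
        k, n0 = float(popt[0]), 1.0
    else:
        def model(tt, n0, k):
            return n0 * np.exp(-k * tt)
        popt, _ = optimize.curve_fit(model, t, y, p0=[n0_init, k0], maxfev=10000)
        n0, k = float(popt[0]), float(popt[1])

    rss = float(np.sum((y - n0 * np.exp(-k * t)) ** 2))
    half_life = float(np.log(2.0) / k) if k > 0 else None
    return DecayFit(k=k, n0=n0, half_life=half_life, rss=rss, n_points=t.size)


def fit_doubling_time(
    curve: pd.DataFrame,
    time_col: str = "time_h",
    od_col: str = "od600",
    window: tuple[float, float] | None = None,
    min_window_points: int = 4,
) -> DoublingTime:
    """Doubling time DT = ln2 / slope of log(OD600) against time.

    If no window is given, the exponential phase is located automatically as
    the contiguous window of at least ``min_window_points`` points whose
    log-linear fit has the highest R² (longest window on ties, so noiseless
    exponentials use every point).  A window must have a positive growth
    slope; if none does, the curve is not growing and an error is raised.
    """
    t = np.asarray(curve[time_col], dtype=float)
    od = np.asarray(curve[od_col], dtype=float)
    order = np.argsort(t)
    t, od = t[order], od[order]
    if np.any(od <= 0):
        raise ValueError("OD values must be positive")
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        if sel.sum() < 3:
            raise ValueError("need at least 3 points in the fit window")
        return _window_fit(t[sel], np.log(od[sel]))

    n = t.size
    if n < 3:
        raise ValueError("need at least 3 points")
    log_od = np.log(od)
    width = min(min_window_points, n)
    best: tuple[float, int, int] | None = None  # (r2, length, start)
    for i in range(n):
        for j in range(i + width, n + 1):
            res = stats.linregress(t[i:j], log_od[i:j])
            if res.slope <= 0:
                continue
            key = (round(res.rvalue**2, 12), j - i, -i)
            if best is None or key > best[0]:
                best = (key, i, j)
    if best is None:
        raise ValueError("no window with positive growth: OD is not increasing")
    _, i, j = best
    return _window_fit(t[i:j], log_od[i:j])


def _window_fit(t: np.ndarray, log_od: np.ndarray) -> DoublingTime:
    res = stats.linregress(t, log_od)
    if res.slope <= 0:
        raise ValueError("non-positive growth slope in the fit window")
    return DoublingTime(
        dt_h=float(np.log(2.0) / res.slope),
        slope=float(res.slope),
        window=(float(t[0]), float(t[-1])),
        r_squared=float(res.rvalue**2),
        n_points=t.size,
    )


def normalized_stability(protein_half_life: float, doubling_time: float) -> float:
    """Protein half-life expressed in units of the culture doubling time.

    Dividing by the doubling time removes the trivial dilution-by-growth
    component, making stabilities comparable across media with very
    different growth rates.  Both inputs must be in the same time unit.
    """
    if protein_half_life <= 0 or doubling_time <= 0:
        raise ValueError("half-life and doubling time must be positive")
    return protein_half_life / doubling_time
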