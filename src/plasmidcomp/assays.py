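"""Estimators for conjugation and growth assays.

Transfer efficiency follows the end-point mass-action estimator
``gamma = T / (D * R * t)`` (mL/cell/h), with ``T``, ``D``, ``R`` the plated
densities of transconjugants, donors and recipients (cells/mL) and ``t`` the
incubation time in hours.  When no transconjugant colony is observed the
density corresponding to half a colony on the plate is substituted and the
estimate is flagged as a censored upper bound.

Maximal growth rate uses the sliding-window log-linear procedure: ordinary
least squares of log(OD) on time over every window of ``h`` consecutive
readings inside a fit range (default 2-10 h post-inoculation, ``h = 8``),
returning the steepest slope and its window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

__all__ = [
    "ConjugationCounts",
    "TransferEfficiency",
    "PlateDensity",
    "GrowthCurve",
    "GrowthRateEstimate",
    "transfer_efficiency",
    "density_from_plate",
    "max_growth_rate",
    "proportion_timeseries",
]


@dataclass(frozen=True)
class ConjugationCounts:
    """End-point densities of a conjugation assay (cells/mL).

    ``detection_limit`` is the density equivalent to 0.5 colonies on the
    transconjugant plate; it replaces ``transconjugant`` when the latter
    derives from zero colonies (``transconjugant_censored=True``).
    """

    donor: float
    recipient: float
    transconjugant: float
    time_h: float
    detection_limit: float | None = None
    transconjugant_censored: bool = False

    def __post_init__(self) -> None:
        if min(self.donor, self.recipient, self.transconjugant) < 0:
            raise ValueError("densities must be >= 0")
        if self.time_h <= 0:
            raise ValueError("incubation time must be > 0")


@dataclass(frozen=True)
class TransferEfficiency:
    """Estimated conjugative transfer rate constant (mL/cell/h)."""

    gamma_transfer: float
    censored: bool = False  # True: upper bound from the 0.5-colony rule


@dataclass(frozen=True)
class PlateDensity:
    """A cell density back-calculated from a plate count (cells/mL)."""

    value: float
    censored: bool = False
    colonies: int | None = None


def density_from_plate(
    colonies: int, dilution: float, volume_ml: float
) -> PlateDensity:
    """Cell density from a colony count: ``colonies * dilution / volume``.

    Zero colonies yield the 0.5-colony detection-threshold density with a
    censored flag.
    """
    if colonies < 0:
        raise ValueError("colony count must be >= 0")
    if dilution < 1:
        raise ValueError("dilution factor must be >= 1")
    if volume_ml <= 0:
        raise ValueError("plated volume must be > 0")
    if colonies == 0:
        return PlateDensity(0.5 * dilution / volume_ml, censored=True, colonies=0)
    return PlateDensity(colonies * dilution / volume_ml, colonies=colonies)


def transfer_efficiency(counts: ConjugationCounts) -> TransferEfficiency:
    """End-point transfer efficiency ``gamma = T / (D * R * t)``.

    Uses the measured end-point donor and recipient densities in the
    denominator.  A zero transconjugant density is replaced by the assay's
    detection limit (0.5-colony density) and flagged censored.
    """
    if counts.donor <= 0 or counts.recipient <= 0:
        raise ValueError("donor and recipient densities must be > 0")
    t_density = counts.transconjugant
    censored = counts.transconjugant_censored
    if t_density == 0:
        if counts.detection_limit is None:
            raise ValueError(
                "zero transconjugant density requires a detection limit "
                "for the 0.5-colony rule"
            )
        t_density = counts.detection_limit
        censored = True
    gamma = t_density / (counts.donor * counts.recipient * counts.time_h)
    return TransferEfficiency(gamma_transfer=gamma, censored=censored)


@dataclass
class GrowthCurve:
    """An optical-density time series from one well."""

    times: np.ndarray  # hours
    od: np.ndarray
    blank: float = 0.0
    well: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape:
            raise ValueError("times and od must have the same shape")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.od)):
            raise ValueError("od readings must be finite")


@dataclass(frozen=True)
class GrowthRateEstimate:
    """Maximal exponential growth rate from a sliding-window log-linear fit."""

    mu_max: float  # per hour
    window_start: float  # hours
    window_end: float
    slope_se: float
    r_squared: float
    n_points: int


def _window_ols(t: np.ndarray, logod: np.ndarray, h: int):
    """Vectorised OLS slope over every window of h consecutive points."""
    tw = np.lib.stride_tricks.sliding_window_view(t, h)
    yw = np.lib.stride_tricks.sliding_window_view(logod, h)
    tm = tw.mean(axis=1, keepdims=True)
    ym = yw.mean(axis=1, keepdims=True)
    sxx = ((tw - tm) ** 2).sum(axis=1)
    sxy = ((tw - tm) * (yw - ym)).sum(axis=1)
    return sxy / sxx


def max_growth_rate(
    curve: GrowthCurve,
    fit_start: float = 2.0,
    fit_end: float = 10.0,
    h: int = 8,
) -> GrowthRateEstimate:
    """Maximal slope of log(OD) over sliding windows of ``h`` readings.

    Readings are blank-subtracted; values at or below ``blank + 1e-4`` are
    excluded before the log transform (positivity floor) and windows then
    slide over the retained readings — each window covers ``h`` consecutive
    retained points.  The window with the steepest slope gives ``mu_max``
    (per hour) together with its OLS diagnostics.
    """
    in_range = (curve.times >= fit_start) & (curve.times <= fit_end)
    if in_range.sum() < h:
        raise ValueError(
            f"need at least h={h} readings within [{fit_start}, {fit_end}] h"
        )
    net = curve.od[in_range] - curve.blank
    keep = net > 1e-4
    if keep.sum() < h:
        raise ValueError("too few readings above blank for a log-linear fit")
    t = curve.times[in_range][keep]
    logod = np.log(net[keep])
    slopes = _window_ols(t, logod, h)
    i = int(np.argmax(slopes))
    slope = float(slopes[i])
    t_win, y_win = t[i : i + h], logod[i : i + h]
    # diagnostics for the winning window
    A = np.vstack([t_win, np.ones_like(t_win)]).T
    coef, residuals, *_ = np.linalg.lstsq(A, y_win, rcond=None)
    ss_res = float(residuals[0]) if residuals.size else 0.0
    ss_tot = float(((y_win - y_win.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = len(t_win) - 2
    sxx = float(((t_win - t_win.mean()) ** 2).sum())
    se = math.sqrt(ss_res / dof / sxx) if dof > 0 and sxx > 0 else 0.0
    return GrowthRateEstimate(
        mu_max=slope,
        window_start=float(t_win[0]),
        window_end=float(t_win[-1]),
        slope_se=se,
        r_squared=r2,
        n_points=len(t_win),
    )


def proportion_timeseries(
    selective_density,
    nonselective_density,
    selective_colonies=None,
    nonselective_colonies=None,
    confidence: float = 0.95,
):
    """Fraction of marker-carrying cells per timepoint, with binomial CIs.

    ``selective_density / nonselective_density`` capped at 1.  When paired
    colony counts are supplied, an exact (Clopper-Pearson) binomial interval
    is computed from them, treating the selective count as successes out of
    the nonselective count.  Returns a DataFrame with columns ``fraction``,
    ``ci_low``, ``ci_high``.
    """
    import pandas as pd

    sel = np.asarray(selective_density, dtype=float)
    non = np.asarray(nonselective_density, dtype=float)
    if sel.shape != non.shape:
        raise ValueError("selective and nonselective series must align")
    if np.any(non <= 0):
        raise ValueError("nonselective density must be > 0")
    frac = np.minimum(sel / non, 1.0)
    lows = np.full(sel.shape, np.nan)
    highs = np.full(sel.shape, np.nan)
    if selective_colonies is not None and nonselective_colonies is not None:
        for i, (k, n) in enumerate(zip(selective_colonies, nonselective_colonies)):
            if n and n > 0:
                ci = binomtest(min(int(k), int(n)), int(n)).proportion_ci(
                    confidence_level=confidence, method="exact"
                )
                lows[i], highs[i] = ci.low, ci.high
    return pd.DataFrame({"fraction": frac, "ci_low": lows, "ci_high": highs})
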