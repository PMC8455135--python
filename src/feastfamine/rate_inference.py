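"""Estimators that parameterize the feast/famine model from assay data.

Covers the four experimental readouts the model consumes:

* maximal proliferation rate from plate-reader growth curves (peak of the
  smoothed derivative of the growth data, in specific or absolute mode);
* exponential death constant from chronological-lifespan CFU series
  (log-linear regression of viability against day);
* per-generation selection coefficient from marker-competition trajectories
  (least-squares slope of the log marker odds against generations);
* median replicative lifespan from per-mother division counts.

Estimates per replicate culture are pooled into a :class:`RateDistribution`,
the empirical sampling pool used by the Monte Carlo ensemble.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthCurve",
    "ViabilitySeries",
    "LifespanSample",
    "CompetitionTrajectory",
    "FitnessEstimate",
    "RateDistribution",
    "estimate_growth_constant",
    "estimate_decay_constant",
    "estimate_selection_coefficient",
    "median_survival",
    "build_rate_distribution",
]


@dataclass
class GrowthCurve:
    """A single well's OD600 time series."""

    times: np.ndarray  # hours, strictly increasing
    od: np.ndarray
    strain: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape or self.times.ndim != 1:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if self.times.size < 5:
            raise ValueError("growth-rate estimation needs at least 5 timepoints")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("optical density must be non-negative")


@dataclass
class ViabilitySeries:
    """Chronological-lifespan viability: CFU counts over days of starvation."""

    days: np.ndarray
    cfu: np.ndarray  # dilution-corrected colony-forming units per volume
    dilution: np.ndarray | None = None
    strain: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.cfu = np.asarray(self.cfu, dtype=float)
        if self.days.shape != self.cfu.shape or self.days.ndim != 1:
            raise ValueError("days and cfu must be 1-D arrays of equal length")
        if self.days.size < 3:
            raise ValueError("decay estimation needs at least 3 timepoints")
        if np.any(np.diff(self.days) <= 0) or self.days[0] < 0:
            raise ValueError("days must be non-negative and increasing")
        if np.any(self.cfu < 0):
            raise ValueError("CFU counts must be non-negative")


@dataclass
class LifespanSample:
    """Replicative lifespans: one completed division count per mother cell."""

    divisions: np.ndarray
    strain: str = ""

    def __post_init__(self) -> None:
        self.divisions = np.asarray(self.divisions)
        if self.divisions.size == 0:
            raise ValueError("lifespan sample must be non-empty")
        if np.any(self.divisions < 0) or np.any(self.divisions != np.floor(self.divisions)):
            raise ValueError("division counts must be non-negative integers")
        self.divisions = self.divisions.astype(int)


@dataclass
class CompetitionTrajectory:
    """Marker fraction of a competing sub-population over generations."""

    generations: np.ndarray
    marker_fraction: np.ndarray  # strictly inside (0, 1)
    mix_id: str = ""

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=float)
        self.marker_fraction = np.asarray(self.marker_fraction, dtype=float)
        if self.generations.shape != self.marker_fraction.shape:
            raise ValueError("generations and fractions must have equal length")
        if np.any(np.diff(self.generations) <= 0) or self.generations[0] < 0:
            raise ValueError("generations must be non-negative and increasing")
        if np.any((self.marker_fraction <= 0) | (self.marker_fraction >= 1)):
            raise ValueError(
                "marker fractions must lie strictly in (0, 1); use from_counts "
                "with continuity correction for saturated counts"
            )

    @classmethod
    def from_counts(
        cls,
        generations: np.ndarray,
        resistant: np.ndarray,
        total: np.ndarray,
        mix_id: str = "",
        continuity: bool = True,
    ) -> "CompetitionTrajectory":
        """Build from raw (resistant, total) colony counts.

        With ``continuity`` the Haldane–Anscombe correction
        (r + 0.5) / (n + 1) keeps fractions off the 0/1 boundary.
        """
        r = np.asarray(resistant, dtype=float)
        n = np.asarray(total, dtype=float)
        if np.any(n < 1) or np.any(r < 0) or np.any(r > n):
            raise ValueError("need 0 <= resistant <= total and total >= 1")
        frac = (r + 0.5) / (n + 1.0) if continuity else r / n
        return cls(np.asarray(generations, dtype=float), frac, mix_id=mix_id)


@dataclass(frozen=True)
class FitnessEstimate:
    """Selection coefficient (per-generation log-fitness difference)."""

    s: float
    stderr: float
    intercept: float


@dataclass
class RateDistribution:
    """Empirical sample of rate constants across replicate cultures."""

    values: np.ndarray
    strain: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("rate distribution must be non-empty")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("rates must be finite")
        if np.any(self.values < 0):
            raise ValueError("rates must be non-negative")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        # sample SD; a single replicate gives a degenerate (zero-spread) pool
        if self.values.size < 2:
            return 0.0
        return float(np.std(self.values, ddof=1))


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges use the available shorter window."""
    if window <= 1:
        return y.astype(float)
    kernel = np.ones(window)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y, dtype=float), kernel, mode="same")
    return num / den


def estimate_growth_constant(
    curve: GrowthCurve,
    method: str = "specific",
    window: int = 5,
    min_od: float = 0.0,
) -> tuple[float, float]:
    """Maximal proliferation rate as the peak of the derivative of growth data.

    Parameters
    ----------
    curve : GrowthCurve
    method : {"specific", "absolute"}
        ``"specific"`` returns the peak of the smoothed d(ln OD)/dt — the
        exponential growth constant the feast/famine model consumes (1/h).
        ``"absolute"`` returns the peak of the smoothed d(OD)/dt (OD/h).
    window : int
        Odd width (points) of the centered moving average applied to the OD
        series before differentiation and again to the derivative.  Scale
        with sampling density; 5 suits sparse curves, 15 suits 10-minute
        plate-reader sampling.
    min_od : float
        Ignore timepoints whose smoothed OD is below this floor (instrument
        noise dominates the log-derivative near the detection limit).  For a
        logistic curve the specific rate at the floor is mu*(1 - od/K), so a
        common floor rescales all strains identically.

    Returns
    -------
    (max_rate, time_of_max)
    """
    if method not in ("specific", "absolute"):
        raise ValueError(f"unknown method {method!r}")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if np.all(curve.od == 0):
        raise ValueError("all-zero OD series")
    smoothed = _moving_average(curve.od, window)
    if method == "specific":
        keep = smoothed > max(min_od, 0.0)
        if keep.sum() < 3:
            raise ValueError("too few points above the OD floor")
        t = curve.times[keep]
        y = np.log(smoothed[keep])
    else:
        t = curve.times
        y = smoothed
    deriv = np.gradient(y, t)
    deriv = _moving_average(deriv, window)
    i = int(np.argmax(deriv))
    return float(deriv[i]), float(t[i])


def estimate_decay_constant(series: ViabilitySeries) -> float:
    """Exponential death constant from log-linear viability decay.

    Fits ln(CFU) against day by least squares and returns the negated slope
    (per day); positive for a dying culture.  Zero counts are dropped with a
    warning — the model class is log-linear and log(0) is undefined.
    """
    positive = series.cfu > 0
    if positive.sum() == 0:
        raise ValueError("all-zero viability series cannot be fit")
    if not np.all(positive):
        warnings.warn(
            f"dropping {int((~positive).sum())} zero-CFU timepoint(s) before "
            "log-linear fit",
            stacklevel=2,
        )
    if positive.sum() < 3:
        raise ValueError("need at least 3 positive CFU timepoints")
    fit = stats.linregress(series.days[positive], np.log(series.cfu[positive]))
    return float(-fit.slope)


def estimate_selection_coefficient(traj: CompetitionTrajectory) -> FitnessEstimate:
    """Per-generation selection coefficient from the log marker odds.

    Under constant selection the marker fraction follows
    ln(f/(1-f)) = logit(f0) + s*g, so s is the least-squares slope of the
    logit against generation.
    """
    if traj.generations.size < 3:
        raise ValueError("need at least 3 timepoints to fit a selection coefficient")
    logit = np.log(traj.marker_fraction / (1.0 - traj.marker_fraction))
    fit = stats.linregress(traj.generations, logit)
    return FitnessEstimate(
        s=float(fit.slope), stderr=float(fit.stderr), intercept=float(fit.intercept)
    )


def median_survival(sample: LifespanSample) -> tuple[float, pd.DataFrame]:
    """Median replicative lifespan and the empirical survival curve.

    Returns the standard sample median (midpoint convention for even n) and
    a table of the fraction of mothers still alive at each integer division
    count (the empirical complementary CDF, evaluated at 0..max).
    """
    divisions = sample.divisions
    median = float(np.median(divisions))
    grid = np.arange(0, divisions.max() + 1)
    alive = np.array([(divisions >= d).mean() for d in grid])
    curve = pd.DataFrame({"divisions": grid, "fraction_alive": alive})
    return median, curve


def build_rate_distribution(
    estimates, strain: str = "", condition: str = ""
) -> RateDistribution:
    """Pool per-replicate rate estimates into an empirical sampling pool."""
    return RateDistribution(np.asarray(list(estimates), dtype=float), strain, condition)
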