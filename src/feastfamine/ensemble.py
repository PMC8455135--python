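"""Monte Carlo propagation of rate uncertainty into competition predictions.

Growth and death constants are drawn (with replacement, by default) from the
empirical per-replicate :class:`~feastfamine.rate_inference.RateDistribution`
pools, the deterministic recursion is run for each draw under a serial-passage
competition protocol, and the ensemble of predicted LF-DY population fractions
is summarized by its per-generation median and 2.5–97.5 percentile band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rate_inference import CompetitionTrajectory, RateDistribution

__all__ = [
    "CompetitionProtocol",
    "EnsembleSpec",
    "EnsembleSummary",
    "CoverageReport",
    "sample_rates",
    "simulate_competition",
    "summarize_ensemble",
    "compare_to_observed",
    "run_ensemble",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class CompetitionProtocol:
    """Serial-passage schedule for a marker competition.

    Each passage regrows the mixed culture for ``generations_per_passage``
    bulk doublings (a 1:1000 dilution corresponds to ~10), optionally
    followed by ``starvation_time`` of stationary starvation (same time unit as the
    death-rate draws; days for CLS-derived rates).  Generation
    time within a draw is set by the reference (strategy-0) strain:
    t_gen = ln2 / mu0.
    """

    generations_per_passage: int = 10
    n_passages: int = 10
    starvation_time: float = 0.0

    def __post_init__(self) -> None:
        if self.generations_per_passage < 1 or self.n_passages < 0:
            raise ValueError("invalid passage counts")
        if self.starvation_time < 0:
            raise ValueError("starvation duration must be non-negative")

    @property
    def generations(self) -> np.ndarray:
        g = self.generations_per_passage
        return np.arange(0, self.n_passages * g + 1, g, dtype=float)


@dataclass
class EnsembleSpec:
    """Inputs for one Monte Carlo run: pools, protocol, draw count, seed."""

    growth0: RateDistribution
    growth1: RateDistribution
    death0: RateDistribution
    death1: RateDistribution
    protocol: CompetitionProtocol = field(default_factory=CompetitionProtocol)
    n_draws: int = 1000  # standard ensemble size
    seed: int = 0
    start_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("need at least one draw")
        if not 0.0 < self.start_fraction < 1.0:
            raise ValueError("start fraction must lie in (0, 1)")


@dataclass
class EnsembleSummary:
    """Per-generation median and 95% band of the LF-DY fraction."""

    generations: np.ndarray
    median: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    trajectories: np.ndarray | None = None  # draws x timepoints, optional

    def __post_init__(self) -> None:
        for name in ("generations", "median", "lo95", "hi95"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.generations.size
        if not (self.median.size == self.lo95.size == self.hi95.size == n):
            raise ValueError("summary arrays must share one generation grid")
        if np.any(self.lo95 > self.median) or np.any(self.median > self.hi95):
            raise ValueError("interval ordering violated (lo <= median <= hi)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generations,
                "median": self.median,
                "lo95": self.lo95,
                "hi95": self.hi95,
            }
        )


@dataclass
class CoverageReport:
    """Observed competition points checked against the ensemble band."""

    table: pd.DataFrame  # generation, observed, median, lo95, hi95, residual, inside

    @property
    def coverage(self) -> float:
        return float(self.table["inside"].mean())


def sample_rates(dist: RateDistribution, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` rates with replacement from the empirical pool."""
    if n < 1:
        raise ValueError("need at least one draw")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.choice(dist.values, size=n, replace=True)


def simulate_competition(
    mu0: np.ndarray,
    mu1: np.ndarray,
    delta0: np.ndarray,
    delta1: np.ndarray,
    protocol: CompetitionProtocol,
    start_fraction: float = 0.5,
) -> np.ndarray:
    """Run the recursion for each parameter draw; return draws x timepoints.

    Within one passage the log population ratio changes by
    (mu1 - mu0) * g * t_gen during regrowth (t_gen = ln2/mu0) and by
    -(delta1 - delta0) * starvation_time during the stationary interval.
    Fractions x1/(x0+x1) are recorded at each passage boundary.
    """
    mu0, mu1, delta0, delta1 = (
        np.atleast_1d(np.asarray(a, dtype=float)) for a in (mu0, mu1, delta0, delta1)
    )
    n = mu0.size
    if n == 0:
        raise ValueError("empty draw set")
    if not (mu1.size == delta0.size == delta1.size == n):
        raise ValueError("draw arrays must have equal length")
    if np.any(mu0 <= 0):
        raise ValueError("reference growth rate must be positive to define generations")
    if not 0.0 < start_fraction < 1.0:
        raise ValueError("start fraction must lie in (0, 1)")

    t_gen = LN2 / mu0
    per_passage = (mu1 - mu0) * protocol.generations_per_passage * t_gen - (
        delta1 - delta0
    ) * protocol.starvation_time
    passages = np.arange(protocol.n_passages + 1, dtype=float)
    logit0 = np.log(start_fraction / (1.0 - start_fraction))
    logits = logit0 + per_passage[:, None] * passages[None, :]
    return 1.0 / (1.0 + np.exp(-logits))


def summarize_ensemble(
    trajectories: np.ndarray,
    generations: np.ndarray | None = None,
    keep_trajectories: bool = False,
) -> EnsembleSummary:
    """Per-timepoint median and empirical 2.5/97.5 percentiles."""
    traj = np.asarray(trajectories, dtype=float)
    if traj.ndim != 2 or traj.shape[0] < 1:
        raise ValueError("need a draws x timepoints array with at least one draw")
    if generations is None:
        generations = np.arange(traj.shape[1], dtype=float)
    generations = np.asarray(generations, dtype=float)
    if generations.size != traj.shape[1]:
        raise ValueError("generation grid must match trajectory length")
    lo, med, hi = np.percentile(traj, [2.5, 50.0, 97.5], axis=0)
    return EnsembleSummary(
        generations, med, lo, hi, trajectories=traj if keep_trajectories else None
    )


def compare_to_observed(
    summary: EnsembleSummary, observed: CompetitionTrajectory
) -> CoverageReport:
    """Check observed marker fractions against the predicted 95% band.

    Observed generations inside the summary's range are evaluated against the
    linearly interpolated band; the report carries per-point residuals from
    the median and inside/outside flags.
    """
    g = observed.generations
    lo_g, hi_g = summary.generations.min(), summary.generations.max()
    keep = (g >= lo_g) & (g <= hi_g)
    if not np.any(keep):
        raise ValueError("observed generations do not overlap the ensemble grid")
    g = g[keep]
    f = observed.marker_fraction[keep]
    med = np.interp(g, summary.generations, summary.median)
    lo = np.interp(g, summary.generations, summary.lo95)
    hi = np.interp(g, summary.generations, summary.hi95)
    table = pd.DataFrame(
        {
            "generation": g,
            "observed": f,
            "median": med,
            "lo95": lo,
            "hi95": hi,
            "residual": f - med,
            "inside": (f >= lo) & (f <= hi),
        }
    )
    return CoverageReport(table)


def run_ensemble(spec: EnsembleSpec, keep_trajectories: bool = False) -> EnsembleSummary:
    """Sample rate pools, simulate every draw, and summarize the ensemble."""
    rng = np.random.default_rng(spec.seed)
    mu0 = sample_rates(spec.growth0, spec.n_draws, rng)
    mu1 = sample_rates(spec.growth1, spec.n_draws, rng)
    d0 = sample_rates(spec.death0, spec.n_draws, rng)
    d1 = sample_rates(spec.death1, spec.n_draws, rng)
    traj = simulate_competition(mu0, mu1, d0, d1, spec.protocol, spec.start_fraction)
    return summarize_ensemble(
        traj, spec.protocol.generations, keep_trajectories=keep_trajectories
    )
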