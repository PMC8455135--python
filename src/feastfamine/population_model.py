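"""Deterministic grow/starve recursion model for two heritable strategies.

Two sub-populations share a culture: a "live slow, die old" (LS-DO) strategy
with growth constant ``mu0`` and death constant ``delta0``, and a "live fast,
die young" (LF-DY) strategy with ``mu1``/``delta1``.  The environment
alternates between a nutrient-replete phase of duration ``tau_grow`` (growth
is exponential, lag and stationary kinetics are neglected because they do not
move the ratio) and a starvation phase of duration ``tau_starve``
(exponential post-mitotic death).  Only the *ratio* of the two populations is
meaningful; carrying capacity is deliberately not modelled.

All internal arithmetic is in natural-log abundance space so that hundreds of
cycles cannot overflow; phase-space grids export log10 ratios for plotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StrategyRates",
    "EnvironmentCycle",
    "PopulationPair",
    "CycleTrajectory",
    "PhaseSpaceGrid",
    "grow_phase",
    "starve_phase",
    "run_cycles",
    "analytic_log_ratio",
    "equal_fitness_boundary",
    "duration_phase_space",
    "advantage_phase_space",
]

LOG10 = math.log(10.0)


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class StrategyRates:
    """Exponential growth and death constants for one heritable strategy.

    Parameters
    ----------
    mu : float
        Growth constant during nutrient repletion (per hour, or dimensionless
        when rates are normalized to a baseline of 1).
    delta : float
        Death constant during starvation (same time unit as ``mu``).
    label : str
        Strategy name, e.g. ``"LS-DO"`` (naive) or ``"LF-DY"`` (prion).
    """

    mu: float
    delta: float
    label: str = ""

    def __post_init__(self) -> None:
        _require_finite("mu", self.mu)
        _require_finite("delta", self.delta)
        if self.mu < 0 or self.delta < 0:
            raise ValueError("rate constants must be non-negative")


@dataclass(frozen=True)
class EnvironmentCycle:
    """One feast/famine schedule: repletion tau1, starvation tau2, N cycles."""

    tau_grow: float
    tau_starve: float
    n_cycles: int

    def __post_init__(self) -> None:
        _require_finite("tau_grow", self.tau_grow)
        _require_finite("tau_starve", self.tau_starve)
        if self.tau_grow < 0 or self.tau_starve < 0:
            raise ValueError("phase durations must be non-negative")
        if int(self.n_cycles) != self.n_cycles or self.n_cycles < 0:
            raise ValueError("n_cycles must be a non-negative integer")


@dataclass(frozen=True)
class PopulationPair:
    """Natural-log abundances of the two sub-populations."""

    log_x0: float
    log_x1: float

    def __post_init__(self) -> None:
        _require_finite("log_x0", self.log_x0)
        _require_finite("log_x1", self.log_x1)

    @property
    def log_ratio(self) -> float:
        """log(x1/x0), the tracked quantity of the model."""
        return self.log_x1 - self.log_x0

    @property
    def fraction(self) -> float:
        """LF-DY fraction x1/(x0+x1), computed stably from the log ratio."""
        return 1.0 / (1.0 + math.exp(-self.log_ratio))


@dataclass
class CycleTrajectory:
    """Snapshots at the start and after every grow/starve phase.

    ``snapshots[0]`` is the initial state; phases alternate grow, starve,
    grow, ... so the length is ``2 * n_cycles + 1``.
    """

    snapshots: list[PopulationPair]
    cycle: EnvironmentCycle

    def __post_init__(self) -> None:
        expected = 2 * self.cycle.n_cycles + 1
        if len(self.snapshots) != expected:
            raise ValueError(
                f"expected {expected} snapshots for {self.cycle.n_cycles} cycles, "
                f"got {len(self.snapshots)}"
            )

    @property
    def log_ratio(self) -> np.ndarray:
        return np.array([s.log_ratio for s in self.snapshots])

    @property
    def final(self) -> PopulationPair:
        return self.snapshots[-1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: cycle, phase, log_x0, log_x1, log_ratio."""
        rows = []
        for i, snap in enumerate(self.snapshots):
            if i == 0:
                cyc, phase = 0, "start"
            else:
                cyc = (i + 1) // 2
                phase = "grow" if i % 2 == 1 else "starve"
            rows.append(
                {
                    "cycle": cyc,
                    "phase": phase,
                    "log_x0": snap.log_x0,
                    "log_x1": snap.log_x1,
                    "log_ratio": snap.log_ratio,
                }
            )
        return pd.DataFrame(rows)


def grow_phase(
    pop: PopulationPair, rates0: StrategyRates, rates1: StrategyRates, tau: float
) -> PopulationPair:
    """Advance both sub-populations through a nutrient-replete phase.

    Each grows exponentially at its own rate: log x -> log x + mu * tau.
    """
    if tau < 0:
        raise ValueError("phase duration tau must be non-negative")
    return PopulationPair(pop.log_x0 + rates0.mu * tau, pop.log_x1 + rates1.mu * tau)


def starve_phase(
    pop: PopulationPair, rates0: StrategyRates, rates1: StrategyRates, tau: float
) -> PopulationPair:
    """Advance both sub-populations through a starvation phase.

    Each decays exponentially at its own death rate: log x -> log x - delta * tau.
    """
    if tau < 0:
        raise ValueError("phase duration tau must be non-negative")
    return PopulationPair(
        pop.log_x0 - rates0.delta * tau, pop.log_x1 - rates1.delta * tau
    )


def run_cycles(
    start: PopulationPair,
    rates0: StrategyRates,
    rates1: StrategyRates,
    cycle: EnvironmentCycle,
) -> CycleTrajectory:
    """Iterate the grow-then-starve recursion for ``cycle.n_cycles`` cycles."""
    snapshots = [start]
    pop = start
    for _ in range(cycle.n_cycles):
        pop = grow_phase(pop, rates0, rates1, cycle.tau_grow)
        snapshots.append(pop)
        pop = starve_phase(pop, rates0, rates1, cycle.tau_starve)
        snapshots.append(pop)
    return CycleTrajectory(snapshots, cycle)


def analytic_log_ratio(
    rates0: StrategyRates,
    rates1: StrategyRates,
    cycle: EnvironmentCycle,
    start_log_ratio: float = 0.0,
) -> float:
    """Closed-form final log(x1/x0) after N feast/famine cycles.

    One cycle multiplies the ratio by
    exp[(mu1*tau1 - delta1*tau2) - (mu0*tau1 - delta0*tau2)], so the log
    ratio changes linearly in the cycle count:

        log ratio(N) = log ratio(0)
                       + N * [(mu1 - mu0) * tau1 - (delta1 - delta0) * tau2]
    """
    per_cycle = (rates1.mu - rates0.mu) * cycle.tau_grow - (
        rates1.delta - rates0.delta
    ) * cycle.tau_starve
    return start_log_ratio + cycle.n_cycles * per_cycle


def equal_fitness_boundary(delta_mu: float, delta_delta: float) -> float:
    """Duration ratio tau2/tau1 at which the two strategies are equally fit.

    Setting the per-cycle change delta_mu*tau1 - delta_delta*tau2 to zero
    gives tau2/tau1 = delta_mu/delta_delta.
    """
    if delta_delta <= 0:
        raise ValueError("equal-fitness boundary undefined for non-positive death cost")
    return delta_mu / delta_delta


@dataclass
class PhaseSpaceGrid:
    """Matrix of log10 final population ratios over two scanned axes.

    ``values[i, j]`` corresponds to ``axis1[i]``, ``axis2[j]``.
    """

    axis1: np.ndarray
    axis2: np.ndarray
    values: np.ndarray
    axis1_name: str = "axis1"
    axis2_name: str = "axis2"

    def __post_init__(self) -> None:
        self.axis1 = np.asarray(self.axis1, dtype=float)
        self.axis2 = np.asarray(self.axis2, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.axis1.size == 0 or self.axis2.size == 0:
            raise ValueError("phase-space axes must be non-empty")
        if self.values.shape != (self.axis1.size, self.axis2.size):
            raise ValueError("grid shape must match axis lengths")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid entries must be finite")

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: axis1, axis2, log10_ratio."""
        a1, a2 = np.meshgrid(self.axis1, self.axis2, indexing="ij")
        return pd.DataFrame(
            {
                self.axis1_name: a1.ravel(),
                self.axis2_name: a2.ravel(),
                "log10_ratio": self.values.ravel(),
            }
        )


def duration_phase_space(
    rates0: StrategyRates,
    rates1: StrategyRates,
    tau_grow_values: np.ndarray,
    tau_starve_values: np.ndarray,
    n_cycles: int = 30,
) -> PhaseSpaceGrid:
    """Scan repletion/starvation durations at fixed strategy rates.

    Each cell holds log10(x1/x0) after ``n_cycles`` from equal starting
    populations, via the closed form.  With a growth advantage balanced by an
    equal death cost the tau1 == tau2 diagonal is exactly zero.
    """
    t1 = np.asarray(tau_grow_values, dtype=float)
    t2 = np.asarray(tau_starve_values, dtype=float)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("phase-space axes must be non-empty")
    if np.any(t1 < 0) or np.any(t2 < 0):
        raise ValueError("durations must be non-negative")
    dmu = rates1.mu - rates0.mu
    ddelta = rates1.delta - rates0.delta
    values = n_cycles * (dmu * t1[:, None] - ddelta * t2[None, :]) / LOG10
    return PhaseSpaceGrid(t1, t2, values, "tau_grow", "tau_starve")


def advantage_phase_space(
    growth_advantages: np.ndarray,
    death_costs: np.ndarray,
    cycle: EnvironmentCycle,
    baseline_rate: float = 1.0,
) -> PhaseSpaceGrid:
    """Scan the LF-DY growth advantage and death-rate cost at fixed durations.

    Advantages and costs are additive offsets on rates normalized to a
    baseline of ``baseline_rate`` per unit time (so 0.01 means "1%" relative
    to a unit baseline).
    """
    adv = np.asarray(growth_advantages, dtype=float)
    cost = np.asarray(death_costs, dtype=float)
    if adv.size == 0 or cost.size == 0:
        raise ValueError("phase-space axes must be non-empty")
    if np.any(baseline_rate + adv < 0) or np.any(baseline_rate + cost < 0):
        raise ValueError("offsets must keep rates non-negative")
    values = (
        cycle.n_cycles
        * (adv[:, None] * cycle.tau_grow - cost[None, :] * cycle.tau_starve)
        / LOG10
    )
    return PhaseSpaceGrid(adv, cost, values, "growth_advantage", "death_cost")
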