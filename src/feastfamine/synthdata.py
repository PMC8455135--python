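"""Seeded generators emulating the study's assay data.

Each generator is a pure function of its spec dataclass (parameters + seed):
the same spec always yields the same tables.  Defaults encode the study
conditions: a ~60% maximal-growth-rate advantage for the prion strain
(0.56 vs 0.35 per hour), chronological-lifespan decay over 80 days with
eight replicates, replicative-lifespan medians of 30 (naive) and 23 (prion)
divisions at n=280 mothers, a ~1%-per-generation selection coefficient
sampled every 10 generations, a polysome:monosome area ratio of 3.2, a
1.5-fold rare-codon luciferase effect over eight replicate wells, and cell
areas calibrated to mean 22.01 (naive) vs 25.36 µm² (prion).

Distribution families (logistic growth, Poisson colony counts, discretized
Gompertz lifespans, binomial marker counts, Gaussian gradient peaks,
lognormal expression noise) are the package's own modelling choices and are
recorded in the serialized spec written next to each fixture.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .phenotypes import CellSizeSample, PolysomeTrace
from .rate_inference import (
    CompetitionTrajectory,
    GrowthCurve,
    LifespanSample,
    ViabilitySeries,
)

__all__ = [
    "GrowthCurveSpec",
    "ViabilitySpec",
    "LifespanSpec",
    "CompetitionSpec",
    "PolysomeSpec",
    "LuciferaseSpec",
    "ScreenSpec",
    "CellAreaSpec",
    "spec_to_dict",
    "gen_growth_curves",
    "gen_viability_series",
    "gen_lifespans",
    "gen_competition",
    "gen_polysome_trace",
    "gen_luciferase_plate",
    "gen_screen",
    "gen_cell_areas",
]


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def spec_to_dict(spec) -> dict:
    """Serializable record of a generator spec (for fixture sidecar files)."""
    d = _plain(dataclasses.asdict(spec))
    d["generator"] = type(spec).__name__
    return d


# ---------------------------------------------------------------- growth


@dataclass(frozen=True)
class GrowthCurveSpec:
    """Logistic plate-reader growth curves with additive OD noise.

    ``mu`` maps strain label -> true maximal specific growth rate (1/h).
    """

    mu: Mapping[str, float] = field(
        default_factory=lambda: {"naive": 0.35, "prion": 0.56}
    )
    carrying_capacity: float = 1.5  # OD600 at saturation
    inoculum: float = 0.01  # OD600 at t=0
    t_max: float = 48.0  # hours
    dt: float = 1.0 / 6.0  # 10-minute plate-reader sampling
    noise_sd: float = 0.003  # additive OD noise
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.mu.values()):
            raise ValueError("growth rates must be positive")
        if not 0 < self.inoculum < self.carrying_capacity:
            raise ValueError("need carrying capacity > inoculum > 0")
        if self.noise_sd < 0 or self.n_replicates < 1 or self.dt <= 0:
            raise ValueError("invalid sampling spec")


def gen_growth_curves(spec: GrowthCurveSpec) -> list[GrowthCurve]:
    """Sample logistic OD trajectories x(t) = K / (1 + ((K-x0)/x0) e^{-mu t})."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.t_max + spec.dt / 2, spec.dt)
    K, x0 = spec.carrying_capacity, spec.inoculum
    curves = []
    for strain, mu in spec.mu.items():
        for rep in range(spec.n_replicates):
            od = K / (1.0 + ((K - x0) / x0) * np.exp(-mu * t))
            if spec.noise_sd > 0:
                od = np.clip(od + rng.normal(0.0, spec.noise_sd, t.size), 1e-6, None)
            curves.append(GrowthCurve(t, od, strain=strain, replicate=f"r{rep + 1}"))
    return curves


# ---------------------------------------------------------------- viability


@dataclass(frozen=True)
class ViabilitySpec:
    """Chronological-lifespan CFU series with Poisson colony-count noise.

    Each timepoint is plated at the dilution that brings the expected colony
    count near ``target_colonies`` (as experimenters dilute into a countable
    range); observed counts are Poisson and rescaled by that dilution.
    """

    delta: Mapping[str, float] = field(
        default_factory=lambda: {"naive": 0.05, "prion": 0.08}
    )  # per day
    n0: float = 1e7  # viable cells per volume at day 0
    days: tuple = tuple(range(0, 81, 10))
    target_colonies: float = 200.0
    poisson_noise: bool = True
    n_replicates: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n0 <= 0 or any(d < 0 for d in self.delta.values()):
            raise ValueError("need N0 > 0 and delta >= 0")
        if self.target_colonies <= 0 or self.n_replicates < 1:
            raise ValueError("invalid viability spec")


def gen_viability_series(spec: ViabilitySpec) -> list[ViabilitySeries]:
    """Exponentially decaying viability; counts Poisson around expectation."""
    rng = np.random.default_rng(spec.seed)
    days = np.asarray(spec.days, dtype=float)
    series = []
    for strain, delta in spec.delta.items():
        for rep in range(spec.n_replicates):
            expected = spec.n0 * np.exp(-delta * days)
            dilution = np.maximum(expected / spec.target_colonies, 1.0)
            if spec.poisson_noise:
                counts = rng.poisson(expected / dilution)
                cfu = counts * dilution
            else:
                cfu = expected
            series.append(
                ViabilitySeries(
                    days,
                    cfu,
                    dilution=dilution,
                    strain=strain,
                    replicate=f"r{rep + 1}",
                )
            )
    return series


# ---------------------------------------------------------------- lifespans


@dataclass(frozen=True)
class LifespanSpec:
    """Replicative lifespans from a discretized Gompertz distribution.

    The Gompertz scale is calibrated so the continuous median equals the
    target median for each strain; draws are rounded to integer divisions.
    """

    median: Mapping[str, float] = field(
        default_factory=lambda: {"naive": 30.0, "prion": 23.0}
    )
    shape: float = 0.15  # Gompertz aging-rate parameter (per division)
    n_cells: int = 280
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.median.values()):
            raise ValueError("target medians must be positive")
        if self.shape <= 0 or self.n_cells < 1:
            raise ValueError("invalid lifespan spec")


def _gompertz_draws(rng: np.random.Generator, a: float, median: float, n: int) -> np.ndarray:
    # survival S(t) = exp(-(b/a)(e^{at}-1)); b set so S(median) = 1/2
    b = a * np.log(2.0) / np.expm1(a * median)
    u = rng.uniform(size=n)
    t = np.log1p(-(a / b) * np.log1p(-u)) / a
    return np.rint(t).astype(int)


def gen_lifespans(spec: LifespanSpec) -> list[LifespanSample]:
    rng = np.random.default_rng(spec.seed)
    return [
        LifespanSample(
            _gompertz_draws(rng, spec.shape, median, spec.n_cells), strain=strain
        )
        for strain, median in spec.median.items()
    ]


# ---------------------------------------------------------------- competition


@dataclass(frozen=True)
class CompetitionSpec:
    """Logit-linear marker drift with binomial colony-count sampling."""

    s: float = 0.01  # per-generation log-fitness difference
    f0: float = 0.5  # starting marker fraction
    generations: tuple = tuple(range(0, 101, 10))
    n_colonies: int = 1000  # colonies scored per timepoint
    binomial_noise: bool = True
    n_mixes: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.f0 < 1:
            raise ValueError("starting fraction must lie in (0, 1)")
        if not np.isfinite(self.s) or self.n_colonies < 1 or self.n_mixes < 1:
            raise ValueError("invalid competition spec")


def gen_competition(spec: CompetitionSpec) -> list[CompetitionTrajectory]:
    """True fraction follows logit(f) = logit(f0) + s*g; counts are binomial."""
    rng = np.random.default_rng(spec.seed)
    g = np.asarray(spec.generations, dtype=float)
    logit = np.log(spec.f0 / (1 - spec.f0)) + spec.s * g
    f_true = 1.0 / (1.0 + np.exp(-logit))
    out = []
    for mix in range(spec.n_mixes):
        if spec.binomial_noise:
            resistant = rng.binomial(spec.n_colonies, f_true)
            out.append(
                CompetitionTrajectory.from_counts(
                    g, resistant, np.full(g.size, spec.n_colonies), mix_id=f"m{mix + 1}"
                )
            )
        else:
            out.append(CompetitionTrajectory(g, f_true, mix_id=f"m{mix + 1}"))
    return out


# ---------------------------------------------------------------- polysome


@dataclass(frozen=True)
class PolysomeSpec:
    """Gaussian-peak gradient trace on a linear baseline.

    Peak areas are set so the summed polysome area is
    ``polysome_monosome_ratio`` times the monosome area.
    """

    monosome_area: float = 1.0
    polysome_monosome_ratio: float = 3.2
    small_subunit_area: float = 0.25  # 40S
    large_subunit_area: float = 0.4  # 60S
    disome_area: float = 0.8
    n_polysome_peaks: int = 4
    peak_sd: float = 0.9  # mm along the gradient
    baseline_intercept: float = 0.05
    baseline_slope: float = 1e-4  # A260 per mm; zeroing removes only an offset
    x_max: float = 60.0
    n_points: int = 1200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.monosome_area <= 0 or self.polysome_monosome_ratio < 0:
            raise ValueError("peak areas must be non-negative, monosome positive")
        if self.peak_sd <= 0 or self.n_polysome_peaks < 1 or self.n_points < 10:
            raise ValueError("invalid trace spec")


def gen_polysome_trace(spec: PolysomeSpec) -> PolysomeTrace:
    """Build the trace and its peak-boundary annotations."""
    x = np.linspace(0.0, spec.x_max, spec.n_points)
    centers = {"40S": 8.0, "60S": 12.0, "monosome": 18.0, "disome": 25.0}
    areas = {
        "40S": spec.small_subunit_area,
        "60S": spec.large_subunit_area,
        "monosome": spec.monosome_area,
        "disome": spec.disome_area,
    }
    poly_total = spec.polysome_monosome_ratio * spec.monosome_area
    # heavier polysome peaks decay geometrically in area
    raw = np.array([0.8**i for i in range(spec.n_polysome_peaks)])
    poly_areas = poly_total * raw / raw.sum()
    for i in range(spec.n_polysome_peaks):
        centers[f"polysome_{i + 1}"] = 31.0 + 5.0 * i
        areas[f"polysome_{i + 1}"] = float(poly_areas[i])

    span = min(np.diff(sorted(centers.values()))) / 2.0
    if spec.peak_sd > span:
        raise ValueError("peaks overlap degenerately; reduce peak_sd")

    y = spec.baseline_intercept + spec.baseline_slope * x
    for name, c in centers.items():
        a = areas[name]
        y = y + a / (spec.peak_sd * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((x - c) / spec.peak_sd) ** 2
        )
    # ±2.5 SD truncates every peak proportionally, so the area *ratio* is exact
    half = 2.5 * spec.peak_sd
    regions = {
        name: (c - half, c + half) for name, c in centers.items() if name != "40S" and name != "60S"
    }
    return PolysomeTrace(x, y, regions=regions, label="synthetic")


# ---------------------------------------------------------------- luciferase


@dataclass(frozen=True)
class LuciferaseSpec:
    """Dual-reporter plate with lognormal multiplicative well noise."""

    fold: float = 1.5  # true prion:naive ratio of firefly/Renilla
    variant: str = "rare_codon"
    n_wells: int = 8
    renilla_mean: float = 1e5
    base_ratio: float = 0.2  # naive firefly/Renilla
    noise_sd: float = 0.05  # SD of log multiplicative noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold <= 0 or self.base_ratio <= 0 or self.renilla_mean <= 0:
            raise ValueError("folds and signals must be positive")
        if self.noise_sd < 0 or self.n_wells < 1:
            raise ValueError("invalid plate spec")


def gen_luciferase_plate(spec: LuciferaseSpec) -> pd.DataFrame:
    """Columns: well, genotype, variant, firefly, renilla, od600."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for genotype, fold in (("naive", 1.0), ("prion", spec.fold)):
        for w in range(spec.n_wells):
            noise = (
                rng.lognormal(0.0, spec.noise_sd, size=2)
                if spec.noise_sd > 0
                else np.ones(2)
            )
            renilla = spec.renilla_mean * noise[0]
            firefly = spec.base_ratio * fold * renilla * noise[1]
            rows.append(
                {
                    "well": f"{genotype[0].upper()}{w + 1}",
                    "genotype": genotype,
                    "variant": spec.variant,
                    "firefly": firefly,
                    "renilla": renilla,
                    "od600": 0.6,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- screen


@dataclass(frozen=True)
class ScreenSpec:
    """Two-background GFP/OD screen with shared lognormal baselines.

    ``effects`` maps protein name -> Z offset applied in the test (prion)
    background, expressed in population-SD units of the raw GFP/OD scale.
    """

    n_proteins: int = 200
    n_replicates: int = 4
    effects: Mapping[str, float] = field(default_factory=dict)
    baseline_log_mean: float = 7.0
    baseline_log_sd: float = 1.0
    noise_sd: float = 0.02  # per-well multiplicative (log) noise
    gain_sd: float = 0.1  # per-replicate multiplicative gain spread (log)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 10:
            raise ValueError("screen needs at least 10 proteins")
        if self.n_replicates < 2:
            raise ValueError("screen needs at least 2 replicates per background")
        if min(self.noise_sd, self.gain_sd, self.baseline_log_sd) < 0:
            raise ValueError("noise SDs must be non-negative")


def gen_screen(spec: ScreenSpec) -> pd.DataFrame:
    """Long table: protein, background, replicate, gfp, od600."""
    rng = np.random.default_rng(spec.seed)
    proteins = [f"P{i + 1:04d}" for i in range(spec.n_proteins)]
    unknown = set(spec.effects) - set(proteins)
    if unknown:
        raise ValueError(f"effects reference unknown proteins: {sorted(unknown)}")
    base = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_proteins)
    pop_sd = float(np.std(base, ddof=1))
    shifted = base.copy()
    for prot, z in spec.effects.items():
        shifted[proteins.index(prot)] = max(base[proteins.index(prot)] + z * pop_sd, 1e-9)
    rows = []
    for background, levels in (("naive", base), ("prion", shifted)):
        for rep in range(spec.n_replicates):
            gain = rng.lognormal(0.0, spec.gain_sd) if spec.gain_sd > 0 else 1.0
            noise = (
                rng.lognormal(0.0, spec.noise_sd, spec.n_proteins)
                if spec.noise_sd > 0
                else np.ones(spec.n_proteins)
            )
            values = levels * gain * noise
            for p, v in zip(proteins, values):
                rows.append(
                    {
                        "protein": p,
                        "background": background,
                        "replicate": f"r{rep + 1}",
                        "gfp": v,
                        "od600": 1.0,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- cell areas


@dataclass(frozen=True)
class CellAreaSpec:
    """Per-cell projected areas, lognormal (default) or Gaussian."""

    mean: Mapping[str, float] = field(
        default_factory=lambda: {"naive": 22.01, "prion": 25.36}
    )  # µm²
    sd: Mapping[str, float] = field(
        default_factory=lambda: {"naive": 5.5, "prion": 7.0}
    )
    n_cells: Mapping[str, int] = field(
        default_factory=lambda: {"naive": 4678, "prion": 5501}
    )
    distribution: str = "lognormal"  # or "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.mean.values()) or any(s < 0 for s in self.sd.values()):
            raise ValueError("need positive means and non-negative SDs")
        if any(n < 1 for n in self.n_cells.values()):
            raise ValueError("need at least one cell per strain")
        if self.distribution not in ("lognormal", "normal"):
            raise ValueError("distribution must be lognormal or normal")


def gen_cell_areas(spec: CellAreaSpec) -> list[CellSizeSample]:
    """Draws moment-matched to the specified per-strain mean and SD."""
    rng = np.random.default_rng(spec.seed)
    samples = []
    for strain in spec.mean:
        m, s, n = spec.mean[strain], spec.sd[strain], spec.n_cells[strain]
        if spec.distribution == "lognormal":
            sigma2 = np.log1p((s / m) ** 2)
            mu = np.log(m) - sigma2 / 2
            areas = rng.lognormal(mu, np.sqrt(sigma2), n)
        else:
            areas = np.clip(rng.normal(m, s, n), 1e-6, None)
        samples.append(CellSizeSample(areas, strain=strain))
    return samples
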