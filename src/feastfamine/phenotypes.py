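"""Bespoke phenotype quantifications for the fast-growth prion state.

Implements the study-specific summary rules around the core model:
large-cell threshold statistics, sphere-volume conversion of projected cell
areas, G1/budding reduction, polysome-to-monosome area ratios with the
valley-zeroing rule, dual-luciferase plate normalization, GFP-screen Z-score
differential calls, and positional codon-adaptation-index (CAI) profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "CellSizeSample",
    "PolysomeTrace",
    "CodingSequence",
    "large_cell_stats",
    "sphere_volume_stats",
    "budding_reduction",
    "polysome_monosome_ratio",
    "normalize_luciferase",
    "screen_zscore_differential",
    "relative_adaptiveness",
    "cai_profile",
]


@dataclass
class CellSizeSample:
    """Projected cell areas (µm²) for one strain/replicate population."""

    areas: np.ndarray
    strain: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.size == 0:
            raise ValueError("cell-size sample must be non-empty")
        if np.any(self.areas <= 0):
            raise ValueError("cell areas must be positive")


def large_cell_stats(
    naive: CellSizeSample, test: CellSizeSample
) -> tuple[float, dict[str, float]]:
    """Large-cell threshold and the fraction of large cells per sample.

    The threshold is one sample standard deviation above the naive mean area;
    a cell is "large" when its area is at or above the threshold.  Returns
    ``(threshold, {"naive": frac, "test": frac})``.
    """
    if naive.areas.size < 2:
        raise ValueError("naive sample needs at least 2 cells")
    sd = float(np.std(naive.areas, ddof=1))
    if sd == 0:
        raise ValueError("degenerate naive sample (zero spread)")
    threshold = float(np.mean(naive.areas)) + sd
    return threshold, {
        "naive": float((naive.areas >= threshold).mean()),
        "test": float((test.areas >= threshold).mean()),
    }


def sphere_volume_stats(
    mean_area_a: float, mean_area_b: float
) -> tuple[float, float, float]:
    """Radii and percent volume difference from mean projected areas.

    Approximating the cell as a sphere whose projection has the observed
    area, radius = sqrt(area/pi) and volume scales as area^(3/2), so the
    percent volume difference of b over a is 100*((area_b/area_a)^1.5 - 1).
    """
    if mean_area_a <= 0 or mean_area_b <= 0:
        raise ValueError("areas must be positive")
    radius_a = math.sqrt(mean_area_a / math.pi)
    radius_b = math.sqrt(mean_area_b / math.pi)
    pct = 100.0 * ((mean_area_b / mean_area_a) ** 1.5 - 1.0)
    return radius_a, radius_b, pct


def budding_reduction(fraction_naive: float, fraction_test: float) -> float:
    """Relative percent reduction of the unbudded (G1) fraction."""
    if not 0 < fraction_naive <= 100 or not 0 < fraction_test <= 100:
        raise ValueError("G1 fractions must lie in (0, 100] percent")
    return 100.0 * (fraction_naive - fraction_test) / fraction_naive


@dataclass
class PolysomeTrace:
    """Sucrose-gradient absorbance trace with annotated peak regions.

    ``regions`` maps region names to (lo, hi) position intervals.  The keys
    ``"monosome"`` and ``"disome"`` are required; every key starting with
    ``"polysome"`` is integrated as part of the polysome signal.
    """

    positions: np.ndarray
    absorbance: np.ndarray
    regions: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.positions.shape != self.absorbance.shape or self.positions.ndim != 1:
            raise ValueError("positions and absorbance must be 1-D and equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")

    def polysome_regions(self) -> list[tuple[float, float]]:
        return [v for k, v in self.regions.items() if k.startswith("polysome")]


def _region_area(
    positions: np.ndarray, signal: np.ndarray, region: tuple[float, float]
) -> float:
    lo, hi = region
    mask = (positions >= lo) & (positions <= hi)
    if mask.sum() < 2:
        raise ValueError(f"region {region} covers fewer than 2 trace points")
    return float(np.trapezoid(signal[mask], positions[mask]))


def polysome_monosome_ratio(trace: PolysomeTrace) -> float:
    """Polysome/monosome area ratio with the valley-zeroing rule.

    The lowest absorbance between the monosome and disome peak centers
    defines zero; the whole trace is shifted by that value (negatives clipped
    to zero) and the trapezoidal area over the polysome region(s) is divided
    by the area over the monosome region.
    """
    for key in ("monosome", "disome"):
        if key not in trace.regions:
            raise ValueError(f"trace is missing the {key!r} region annotation")
    poly = trace.polysome_regions()
    if not poly:
        raise ValueError("trace has no polysome region annotations")
    mono_lo, mono_hi = trace.regions["monosome"]
    di_lo, di_hi = trace.regions["disome"]
    valley_lo = 0.5 * (mono_lo + mono_hi)
    valley_hi = 0.5 * (di_lo + di_hi)
    mask = (trace.positions >= valley_lo) & (trace.positions <= valley_hi)
    if not np.any(mask):
        raise ValueError("no trace points between monosome and disome peaks")
    baseline = float(trace.absorbance[mask].min())
    signal = np.clip(trace.absorbance - baseline, 0.0, None)
    mono_area = _region_area(trace.positions, signal, trace.regions["monosome"])
    if mono_area <= 0:
        raise ValueError("zero monosome area after baseline subtraction")
    poly_area = sum(_region_area(trace.positions, signal, r) for r in poly)
    return poly_area / mono_area


def normalize_luciferase(
    plate: pd.DataFrame, naive_label: str = "naive"
) -> pd.DataFrame:
    """Control-normalized reporter output, scaled so naive means equal 1.0.

    ``plate`` needs columns genotype, variant, firefly, renilla.  Each well's
    firefly signal is divided by its co-expressed Renilla control; per
    (variant, genotype) means are then divided by the naive-genotype mean of
    the same reporter variant.

    Returns a table with columns variant, genotype, normalized (naive = 1.0),
    n_wells.
    """
    required = {"genotype", "variant", "firefly", "renilla"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    if np.any(plate["renilla"] <= 0):
        raise ValueError("Renilla control luminescence must be positive in every well")
    df = plate.copy()
    df["ratio"] = df["firefly"] / df["renilla"]
    means = (
        df.groupby(["variant", "genotype"], sort=True)["ratio"]
        .agg(["mean", "size"])
        .reset_index()
    )
    out_rows = []
    for variant, grp in means.groupby("variant", sort=True):
        naive_rows = grp[grp["genotype"] == naive_label]
        if naive_rows.empty:
            raise ValueError(f"variant {variant!r} has no {naive_label!r} wells")
        naive_mean = float(naive_rows["mean"].iloc[0])
        for _, row in grp.iterrows():
            out_rows.append(
                {
                    "variant": variant,
                    "genotype": row["genotype"],
                    "normalized": row["mean"] / naive_mean,
                    "n_wells": int(row["size"]),
                }
            )
    return pd.DataFrame(out_rows)


def screen_zscore_differential(
    screen: pd.DataFrame,
    naive_label: str = "naive",
    test_label: str = "prion",
    call_threshold: float = 1.0,
    robustness_threshold: float = 1.0,
) -> pd.DataFrame:
    """Differential calls from a two-background GFP/OD reporter screen.

    ``screen`` needs columns protein, background, replicate, and either a
    precomputed ``value`` column or ``gfp`` and ``od600`` (value = gfp/od600).
    Within each background, each replicate's values are Z-scored across
    proteins; a protein's background score is the mean of its replicate Zs.
    A protein is *robust* when its replicate-to-replicate Z standard
    deviation is below ``robustness_threshold`` in both backgrounds, and is
    called up/down when robust and |Z_test - Z_naive| >= ``call_threshold``.

    Returns a per-protein table: z_naive, z_test, delta_z, robust, call.
    """
    df = screen.copy()
    required = {"protein", "background", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"screen table missing columns: {sorted(missing)}")
    if "value" not in df.columns:
        if not {"gfp", "od600"}.issubset(df.columns):
            raise ValueError("screen table needs a value column or gfp and od600")
        if np.any(df["od600"] <= 0):
            raise ValueError("OD600 must be positive")
        df["value"] = df["gfp"] / df["od600"]
    if not np.all(np.isfinite(df["value"])):
        raise ValueError("screen values must be finite")

    stats = {}
    for background in (naive_label, test_label):
        sub = df[df["background"] == background]
        if sub.empty:
            raise ValueError(f"no rows for background {background!r}")
        wide = sub.pivot_table(
            index="protein", columns="replicate", values="value", aggfunc="mean"
        )
        if wide.shape[1] < 2:
            raise ValueError(f"background {background!r} needs >= 2 replicates")
        mu = wide.mean(axis=0)
        sigma = wide.std(axis=0, ddof=1)
        if np.any(sigma == 0) or sigma.isna().any():
            raise ValueError(
                f"a replicate in background {background!r} has zero variance "
                "across proteins"
            )
        z = (wide - mu) / sigma
        stats[background] = pd.DataFrame(
            {"z": z.mean(axis=1), "z_sd": z.std(axis=1, ddof=1)}
        )

    merged = stats[naive_label].join(
        stats[test_label], lsuffix="_naive", rsuffix="_test", how="inner"
    )
    merged["delta_z"] = merged["z_test"] - merged["z_naive"]
    merged["robust"] = (merged["z_sd_naive"] < robustness_threshold) & (
        merged["z_sd_test"] < robustness_threshold
    )
    calls = np.where(
        merged["robust"] & (merged["delta_z"] >= call_threshold),
        "up",
        np.where(
            merged["robust"] & (merged["delta_z"] <= -call_threshold),
            "down",
            "unchanged",
        ),
    )
    merged["call"] = calls
    merged.index.name = "protein"
    return merged.rename(
        columns={"z_naive": "z_naive", "z_test": "z_test"}
    )[["z_naive", "z_test", "delta_z", "z_sd_naive", "z_sd_test", "robust", "call"]]


_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOP_CODONS = set(_STANDARD_TABLE.stop_codons)


@dataclass
class CodingSequence:
    """A coding nucleotide sequence split into codons for CAI profiling."""

    sequence: str
    identifier: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        if len(seq) % 3 != 0:
            raise ValueError(
                f"{self.identifier or 'sequence'}: length {len(seq)} not divisible by 3"
            )
        if set(seq) - set("ACGT"):
            raise ValueError(f"{self.identifier or 'sequence'}: non-ACGT characters")
        self.sequence = seq

    @property
    def codons(self) -> list[str]:
        codons = [self.sequence[i : i + 3] for i in range(0, len(self.sequence), 3)]
        # a single trailing stop codon is not part of the translated profile
        if codons and codons[-1] in _STOP_CODONS:
            codons = codons[:-1]
        return codons


def relative_adaptiveness(usage: Mapping[str, float]) -> dict[str, float]:
    """Sharp–Li relative adaptiveness weights from a codon-usage table.

    Within each synonymous family the most-used codon gets weight 1 and the
    others their usage relative to it.  Codons with zero recorded usage are
    clamped to 0.01 so geometric means stay positive.  Stop codons are
    excluded.
    """
    weights: dict[str, float] = {}
    families: dict[str, list[str]] = {}
    for codon, aa in _STANDARD_TABLE.forward_table.items():
        families.setdefault(aa, []).append(codon)
    for codons in families.values():
        counts = {c: float(usage.get(c, 0.0)) for c in codons}
        top = max(counts.values())
        if top <= 0:
            continue  # family absent from the usage table; leave it unweighted
        for c, v in counts.items():
            weights[c] = max(v / top, 0.01)
    if not weights:
        raise ValueError("usage table contains no recognized codons")
    return weights


def cai_profile(
    seqs: Sequence[CodingSequence],
    weights: Mapping[str, float],
    window: int = 11,
    positions: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Positional CAI profile averaged over a set of coding sequences.

    For each sequence, the CAI at codon position ``p`` (1-based residue
    number) is the geometric mean of the relative-adaptiveness weights over a
    ``window``-codon window centered at ``p`` (clipped at the sequence ends).
    The profile value at ``p`` is the arithmetic mean over all sequences long
    enough to cover ``p``.

    Returns a table with columns position, mean_cai, n_sequences.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not seqs:
        raise ValueError("need at least one sequence")
    per_seq: list[np.ndarray] = []
    for seq in seqs:
        codons = seq.codons
        try:
            logw = np.array([math.log(weights[c]) for c in codons])
        except KeyError as err:
            raise ValueError(
                f"{seq.identifier or 'sequence'}: no weight for codon {err.args[0]}"
            ) from None
        n = len(codons)
        left = (window - 1) // 2
        right = window // 2
        profile = np.empty(n)
        for i in range(n):
            lo = max(0, i - left)
            hi = min(n, i + right + 1)
            profile[i] = math.exp(logw[lo:hi].mean())
        per_seq.append(profile)

    max_len = max(p.size for p in per_seq)
    if positions is None:
        positions = range(1, max_len + 1)
    rows = []
    for pos in positions:
        if pos < 1:
            raise ValueError("positions are 1-based residue numbers")
        vals = [p[pos - 1] for p in per_seq if p.size >= pos]
        if vals:
            rows.append(
                {"position": pos, "mean_cai": float(np.mean(vals)), "n_sequences": len(vals)}
            )
    return pd.DataFrame(rows)
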