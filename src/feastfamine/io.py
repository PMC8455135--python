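"""Typed CSV/FASTA table I/O shared by the CLI and the analysis modules.

Schemas are named column sets; ``load_table`` validates headers
case-insensitively, coerces numeric columns, and raises a schema-violation
error naming the offending column or row.  Extra columns are kept with a
warning (tolerant-reader contract).  Plate-reader wide format (first column
time-like, one column per well) is auto-detected for growth curves.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .phenotypes import CellSizeSample, CodingSequence, PolysomeTrace
from .rate_inference import (
    CompetitionTrajectory,
    GrowthCurve,
    LifespanSample,
    ViabilitySeries,
)

__all__ = [
    "SCHEMAS",
    "SchemaError",
    "load_table",
    "load_growth_curves",
    "load_viability_series",
    "load_lifespans",
    "load_competitions",
    "load_cell_areas",
    "load_polysome_trace",
    "load_codon_weights",
    "load_coding_sequences",
]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


# schema name -> (required columns, numeric columns)
SCHEMAS: Mapping[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "growth": (("time_h", "od", "strain", "replicate"), ("time_h", "od")),
    "viability": (
        ("day", "cfu", "dilution", "strain", "replicate"),
        ("day", "cfu", "dilution"),
    ),
    "lifespan": (("strain", "divisions"), ("divisions",)),
    "competition": (
        ("generation", "resistant", "total", "mix_id"),
        ("generation", "resistant", "total"),
    ),
    "areas": (("cell_id", "area_um2", "strain", "replicate"), ("area_um2",)),
    "polysome": (("position", "a260"), ("position", "a260")),
    "luciferase": (
        ("well", "genotype", "variant", "firefly", "renilla", "od600"),
        ("firefly", "renilla", "od600"),
    ),
    "screen": (
        ("protein", "background", "replicate", "gfp", "od600"),
        ("gfp", "od600"),
    ),
    "codon_weights": (("codon", "weight"), ("weight",)),
}


def load_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Header matching is case-insensitive; returned columns are lower-case.
    Raises :class:`SchemaError` naming any missing column or non-numeric cell.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise SchemaError(f"{path}: table has no data rows")
    df.columns = [str(c).strip().lower() for c in df.columns]
    required, numeric = SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing} for schema {schema!r}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: keeping unrecognized column(s) {extra}", stacklevel=2)
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at data row {row}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise SchemaError(f"{path}: empty cell in column {col!r} at data row {row}")
        df[col] = coerced
    return df


def _is_wide_growth(df: pd.DataFrame) -> bool:
    first = str(df.columns[0]).lower()
    return first in ("time", "time_h", "t", "hours") and "od" not in df.columns


def load_growth_curves(path: str | Path) -> list[GrowthCurve]:
    """Load growth curves from long format or plate-reader wide format."""
    raw = pd.read_csv(path, comment="#")
    raw.columns = [str(c).strip().lower() for c in raw.columns]
    if _is_wide_growth(raw):
        t = pd.to_numeric(raw.iloc[:, 0], errors="raise").to_numpy(float)
        curves = []
        for well in raw.columns[1:]:
            od = pd.to_numeric(raw[well], errors="raise").to_numpy(float)
            curves.append(GrowthCurve(t, od, strain=well, replicate=well))
        return curves
    df = load_table(path, "growth")
    curves = []
    for (strain, rep), grp in df.groupby(["strain", "replicate"], sort=True):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                grp["time_h"].to_numpy(),
                grp["od"].to_numpy(),
                strain=str(strain),
                replicate=str(rep),
            )
        )
    return curves


def load_viability_series(path: str | Path) -> list[ViabilitySeries]:
    df = load_table(path, "viability")
    out = []
    for (strain, rep), grp in df.groupby(["strain", "replicate"], sort=True):
        grp = grp.sort_values("day")
        out.append(
            ViabilitySeries(
                grp["day"].to_numpy(),
                grp["cfu"].to_numpy(),
                dilution=grp["dilution"].to_numpy(),
                strain=str(strain),
                replicate=str(rep),
            )
        )
    return out


def load_lifespans(path: str | Path) -> list[LifespanSample]:
    df = load_table(path, "lifespan")
    return [
        LifespanSample(grp["divisions"].to_numpy(), strain=str(strain))
        for strain, grp in df.groupby("strain", sort=True)
    ]


def load_competitions(path: str | Path) -> list[CompetitionTrajectory]:
    df = load_table(path, "competition")
    out = []
    for mix, grp in df.groupby("mix_id", sort=True):
        grp = grp.sort_values("generation")
        out.append(
            CompetitionTrajectory.from_counts(
                grp["generation"].to_numpy(),
                grp["resistant"].to_numpy(),
                grp["total"].to_numpy(),
                mix_id=str(mix),
            )
        )
    return out


def load_cell_areas(path: str | Path) -> list[CellSizeSample]:
    df = load_table(path, "areas")
    return [
        CellSizeSample(grp["area_um2"].to_numpy(), strain=str(strain))
        for strain, grp in df.groupby("strain", sort=True)
    ]


def load_polysome_trace(path: str | Path, annotations: Mapping[str, tuple[float, float]]) -> PolysomeTrace:
    """Load a trace CSV; peak-boundary annotations are supplied separately
    (e.g., parsed from a YAML sidecar)."""
    df = load_table(path, "polysome")
    df = df.sort_values("position")
    regions = {str(k): (float(v[0]), float(v[1])) for k, v in annotations.items()}
    return PolysomeTrace(df["position"].to_numpy(), df["a260"].to_numpy(), regions=regions)


def load_codon_weights(path: str | Path) -> dict[str, float]:
    df = load_table(path, "codon_weights")
    weights = {}
    for _, row in df.iterrows():
        codon = str(row["codon"]).upper().replace("U", "T")
        w = float(row["weight"])
        if not 0 < w <= 1:
            raise SchemaError(f"{path}: weight for {codon} must lie in (0, 1]")
        weights[codon] = w
    return weights


def load_coding_sequences(path: str | Path) -> list[CodingSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SchemaError(f"{path}: no FASTA records found")
    return [CodingSequence(str(r.seq), identifier=r.id) for r in records]
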