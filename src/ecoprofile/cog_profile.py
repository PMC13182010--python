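"""Per-genome COG category counts, Z-scores, and coefficient-of-variation bands.

For each genome the number of genes assigned to each COG category letter is
counted; genes with no category go to a derived "unknown" column.  Z-scores
standardise each category across genomes (z = (x − µ) / σ); the CV bands
split categories into low / intermediate / high variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import UNKNOWN_CATEGORY, AnnotationTable, ValidationError


@dataclass
class COGCountMatrix:
    """Genome × category gene-count matrix (includes the "unknown" column)."""

    counts: pd.DataFrame  # index = genome_ids, columns = category letters + "unknown"

    @property
    def genome_ids(self) -> list:
        return list(self.counts.index)

    @property
    def categories(self) -> list:
        return list(self.counts.columns)


def count_cog_categories(tables: list, policy: str = "per_letter") -> COGCountMatrix:
    """Count genes per COG category per genome.

    policy="per_letter": a gene carrying k category letters increments k
    cells (the eggNOG convention).  policy="first_letter": only the
    alphabetically first letter is counted.  Genes with no letters increment
    the "unknown" column.
    """
    if not tables:
        raise ValidationError("need at least one annotation table")
    ids = [t.genome_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValidationError("genome_ids must be distinct")
    if policy not in ("per_letter", "first_letter"):
        raise ValidationError(f"unknown counting policy {policy!r}")

    letters = sorted({c for t in tables for r in t for c in r.cog_categories})
    columns = letters + [UNKNOWN_CATEGORY]
    counts = pd.DataFrame(0, index=ids, columns=columns, dtype=int)
    for t in tables:
        for r in t:
            if not r.cog_categories:
                counts.loc[t.genome_id, UNKNOWN_CATEGORY] += 1
            elif policy == "per_letter":
                for c in r.cog_categories:
                    counts.loc[t.genome_id, c] += 1
            else:
                counts.loc[t.genome_id, min(r.cog_categories)] += 1
    return COGCountMatrix(counts)


def zscore_matrix(counts: COGCountMatrix, ddof: int = 0) -> pd.DataFrame:
    """Standardise each category column: z = (x − µ) / σ.

    σ is the population standard deviation by default (ddof=0, configurable
    to the sample convention).  Categories with σ = 0 get all-zero z-values.
    Needs at least two genomes.
    """
    df = counts.counts
    if len(df) < 2:
        raise ValidationError("z-scores require at least 2 genomes")
    mu = df.mean(axis=0)
    sigma = df.std(axis=0, ddof=ddof)
    z = df.sub(mu, axis=1).div(sigma.where(sigma > 0, np.inf), axis=1)
    return z.astype(float)


def cv_banding(
    counts: COGCountMatrix, low_max: float = 5.0, high_min: float = 10.0
) -> pd.DataFrame:
    """Coefficient of variation (percent) per category with banding.

    CV = 100·σ/µ with population σ.  CV ≤ low_max → "low" (inclusive);
    CV ≥ high_min → "high" (inclusive); otherwise "intermediate".
    Categories with µ = 0 are flagged "undefined".
    """
    df = counts.counts
    if len(df) < 2:
        raise ValidationError("CV requires at least 2 genomes")
    mu = df.mean(axis=0)
    sigma = df.std(axis=0, ddof=0)
    cv = 100.0 * sigma / mu.where(mu > 0, np.nan)

    def band(v: float) -> str:
        if np.isnan(v):
            return "undefined"
        if v <= low_max:
            return "low"
        if v >= high_min:
            return "high"
        return "intermediate"

    return pd.DataFrame({"cv": cv, "band": cv.map(band)})


def to_long_format(
    counts: COGCountMatrix, z: pd.DataFrame = None, cv: pd.DataFrame = None
) -> pd.DataFrame:
    """Heatmap-ready long table: genome, category, count [, z, cv_band]."""
    long = counts.counts.stack().rename("count").reset_index()
    long.columns = ["genome", "category", "count"]
    if z is not None:
        zl = z.stack().rename("z").reset_index()
        zl.columns = ["genome", "category", "z"]
        long = long.merge(zl, on=["genome", "category"], how="left")
    if cv is not None:
        long = long.merge(
            cv["band"].rename("cv_band"),
            left_on="category",
            right_index=True,
            how="left",
        )
    return long
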