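"""Copiotroph–oligotroph trophic-strategy scoring and the Sugar-Acid Preference index.

The landmark scheme compares a genome's normalised gene count in each of 33
COG (sub)categories against two reference values — an "average copiotroph"
and an "average oligotroph".  Fourteen categories are positively associated
with copiotrophy (higher counts → more copiotrophic, direction ``+``), the
other nineteen are the opposite (direction ``-``).  A genome is called
copiotrophic in a category when its value lies strictly beyond the
copiotroph landmark on the copiotrophic side, oligotrophic when strictly
beyond the oligotroph landmark on the oligotrophic side, and indeterminate
in between (ties included).

The SAP index summarises carbon-source orientation from the relative
abundance of sugar-metabolism (S) and acid-metabolism (A) genes:

    SAP = tanh(s·S + a·A),   s = 60.76,  a = −20.21

so SAP → +1 for sugar specialists and → −1 for acid specialists.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
import yaml

from .cog_profile import COGCountMatrix
from .model import AnnotationTable, GenomeRecord, ValidationError

COG_ID_RE = re.compile(r"^COG_?(\d+)$")

COPIOTROPH = "copiotroph"
OLIGOTROPH = "oligotroph"
INDETERMINATE = "indeterminate"

#: Default SAP coefficients (sugar weight positive, acid weight negative).
SAP_S = 60.76
SAP_A = -20.21


@dataclass(frozen=True)
class LandmarkEntry:
    """Reference values of one scored category.

    direction '+' means higher counts indicate copiotrophy; '-' the
    opposite.  Values are on the normalisation scale given by ``unit``
    (counts per Mb or per ORF).
    """

    category_id: str
    direction: str
    oligotroph_value: Optional[float] = None
    copiotroph_value: Optional[float] = None
    unit: str = "per_mb"

    def __post_init__(self) -> None:
        if self.direction not in ("+", "-"):
            raise ValidationError(
                f"landmark {self.category_id!r}: direction must be '+' or '-'"
            )
        if (
            self.oligotroph_value is not None
            and self.copiotroph_value is not None
            and self.oligotroph_value == self.copiotroph_value
        ):
            raise ValidationError(
                f"landmark {self.category_id!r}: reference values must differ"
            )

    @property
    def has_values(self) -> bool:
        return self.oligotroph_value is not None and self.copiotroph_value is not None


@dataclass
class TrophicLandmarkSet:
    entries: dict = field(default_factory=dict)  # category_id -> LandmarkEntry

    def __iter__(self):
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_yaml(cls, path) -> "TrophicLandmarkSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        entries = {}
        for item in raw.get("landmarks", []):
            e = LandmarkEntry(
                category_id=str(item["category"]),
                direction=str(item["direction"]),
                oligotroph_value=item.get("oligotroph_value"),
                copiotroph_value=item.get("copiotroph_value"),
                unit=str(item.get("unit", raw.get("unit", "per_mb"))),
            )
            if e.category_id in entries:
                raise ValidationError(f"duplicate landmark {e.category_id!r}")
            entries[e.category_id] = e
        return cls(entries)


@dataclass(frozen=True)
class TrophicCall:
    genome_id: str
    category_id: str
    normalized_value: float
    call: str


@dataclass(frozen=True)
class TrophicSummary:
    genome_id: str
    n_copiotroph: int
    n_oligotroph: int
    n_indeterminate: int
    overall_label: str


@dataclass(frozen=True)
class SAPConfig:
    sugar_ko_set: frozenset
    acid_ko_set: frozenset
    s: float = SAP_S
    a: float = SAP_A

    def __post_init__(self) -> None:
        if not self.sugar_ko_set or not self.acid_ko_set:
            raise ValidationError("SAP KO sets must be non-empty")
        if self.sugar_ko_set & self.acid_ko_set:
            raise ValidationError("sugar and acid KO sets must be disjoint")

    @classmethod
    def from_yaml(cls, path) -> "SAPConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            sugar_ko_set=frozenset(raw.get("sugar_kos", [])),
            acid_ko_set=frozenset(raw.get("acid_kos", [])),
            s=float(raw.get("s", SAP_S)),
            a=float(raw.get("a", SAP_A)),
        )


@dataclass(frozen=True)
class SAPResult:
    genome_id: str
    S: float
    A: float
    sap: float


def count_landmark_categories(
    tables: list, landmarks: TrophicLandmarkSet
) -> pd.DataFrame:
    """Genome × landmark-category count matrix.

    General single-letter categories count genes carrying that letter;
    specific ``COG_nnnn`` categories count genes carrying that COG family id.
    """
    ids = [t.genome_id for t in tables]
    cats = sorted(landmarks.entries)
    counts = pd.DataFrame(0, index=ids, columns=cats, dtype=int)
    for t in tables:
        for cat in cats:
            m = COG_ID_RE.match(cat)
            if m:
                cog_id = f"COG{int(m.group(1)):04d}"
                n = sum(1 for r in t if cog_id in r.cog_ids)
            else:
                n = sum(1 for r in t if cat in r.cog_categories)
            counts.loc[t.genome_id, cat] = n
    return counts


def normalize_category_counts(
    counts, genomes: list, unit: str = "per_mb"
) -> pd.DataFrame:
    """Express counts relative to genome size (per_mb) or ORF total (per_orf)."""
    df = counts.counts if isinstance(counts, COGCountMatrix) else counts
    by_id = {g.genome_id: g for g in genomes}
    missing = set(df.index) - set(by_id)
    if missing:
        raise ValidationError(f"no GenomeRecord for genomes {sorted(missing)}")
    if unit == "per_mb":
        denom = pd.Series({gid: by_id[gid].size_mb for gid in df.index})
    elif unit == "per_orf":
        denom = pd.Series({gid: by_id[gid].total_orfs for gid in df.index})
        if (denom <= 0).any():
            raise ValidationError("per_orf normalisation needs total_orfs > 0")
    else:
        raise ValidationError(f"unknown normalisation unit {unit!r}")
    out = df.div(denom, axis=0).astype(float)
    out.attrs["unit"] = unit
    return out


def call_trophic_category(
    value: float, entry: LandmarkEntry, genome_id: str = ""
) -> TrophicCall:
    """Call one category against its landmark pair.

    Strictly beyond the copiotroph landmark on the copiotrophic side →
    copiotroph; strictly beyond the oligotroph landmark on the oligotrophic
    side → oligotroph; otherwise (ties included) indeterminate.
    """
    if not entry.has_values:
        raise ValidationError(
            f"landmark {entry.category_id!r} has placeholder values; "
            "supply a filled-in landmark file"
        )
    if entry.direction == "+":
        if value > entry.copiotroph_value:
            call = COPIOTROPH
        elif value < entry.oligotroph_value:
            call = OLIGOTROPH
        else:
            call = INDETERMINATE
    else:
        if value < entry.copiotroph_value:
            call = COPIOTROPH
        elif value > entry.oligotroph_value:
            call = OLIGOTROPH
        else:
            call = INDETERMINATE
    return TrophicCall(genome_id, entry.category_id, float(value), call)


def score_genomes(
    normalized: pd.DataFrame, landmarks: TrophicLandmarkSet
) -> list:
    """All per-genome, per-category trophic calls for a normalised matrix."""
    calls = []
    for gid in normalized.index:
        for cat, entry in landmarks.entries.items():
            if cat not in normalized.columns:
                continue
            calls.append(
                call_trophic_category(normalized.loc[gid, cat], entry, genome_id=gid)
            )
    return calls


def summarize_trophic(calls: Iterable[TrophicCall], genome_id: str = "") -> TrophicSummary:
    """Tally per-category calls into an overall label.

    Unanimous → copiotroph / oligotroph; strict majority without unanimity →
    "moderate copiotroph" / "moderate oligotroph"; ties → indeterminate.
    """
    calls = list(calls)
    n_c = sum(1 for c in calls if c.call == COPIOTROPH)
    n_o = sum(1 for c in calls if c.call == OLIGOTROPH)
    n_i = len(calls) - n_c - n_o
    total = len(calls)
    if total and n_c == total:
        label = COPIOTROPH
    elif total and n_o == total:
        label = OLIGOTROPH
    elif n_c > n_o:
        label = "moderate copiotroph"
    elif n_o > n_c:
        label = "moderate oligotroph"
    else:
        label = INDETERMINATE
    return TrophicSummary(genome_id, n_c, n_o, n_i, label)


def summarize_tallies(
    n_copiotroph: int, n_oligotroph: int, n_indeterminate: int, genome_id: str = ""
) -> TrophicSummary:
    """Overall label straight from category tallies (same rule as above)."""
    fake = (
        [TrophicCall(genome_id, "", 0.0, COPIOTROPH)] * n_copiotroph
        + [TrophicCall(genome_id, "", 0.0, OLIGOTROPH)] * n_oligotroph
        + [TrophicCall(genome_id, "", 0.0, INDETERMINATE)] * n_indeterminate
    )
    return summarize_trophic(fake, genome_id=genome_id)


def mean_profile(normalized: pd.DataFrame) -> pd.DataFrame:
    """Across-genome mean of the normalised matrix (one "mean-of-genomes" row)."""
    return normalized.mean(axis=0).to_frame().T.set_axis(["mean-of-genomes"])


def compute_sap(
    annotation: AnnotationTable, genome: GenomeRecord, cfg: SAPConfig
) -> SAPResult:
    """Sugar-Acid Preference index of one genome.

    S (resp. A) is the fraction of ORFs whose KO lies in the configured
    sugar (resp. acid) KO set; SAP = tanh(s·S + a·A) ∈ (−1, 1).
    """
    if genome.total_orfs <= 0:
        raise ValidationError(
            f"genome {genome.genome_id!r}: total_orfs must be > 0 for SAP"
        )
    n_sugar = len(annotation.genes_with_ko(cfg.sugar_ko_set))
    n_acid = len(annotation.genes_with_ko(cfg.acid_ko_set))
    S = n_sugar / genome.total_orfs
    A = n_acid / genome.total_orfs
    return SAPResult(genome.genome_id, S, A, sap_index(S, A, cfg.s, cfg.a))


#: Largest double strictly below 1; tanh saturates to exactly 1.0 for
#: arguments beyond ~19, so the index is clamped into the open interval.
_ONE_MINUS = math.nextafter(1.0, 0.0)


def sap_index(S: float, A: float, s: float = SAP_S, a: float = SAP_A) -> float:
    """SAP = tanh(s·S + a·A) on raw fractions S, A ∈ [0, 1].

    The index lies strictly inside (−1, 1); values saturating to ±1 in
    floating point are clamped to the nearest representable interior value.
    """
    return max(-_ONE_MINUS, min(_ONE_MINUS, math.tanh(s * S + a * A)))
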