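"""Core data model shared by all pipeline stages.

The universal input is a per-genome table of gene-level functional labels
(COG category letters, COG family ids, KEGG KOs).  Everything downstream —
trophic scoring, transporter completeness, trait panels, machinery
adjudication — consumes :class:`AnnotationTable` plus a :class:`GenomeRecord`
carrying genome size and ORF totals used for normalisation.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

#: Recognised COG functional-category letters (the full one-letter alphabet
#: used by the COG database; letters outside this set are dropped at parse
#: time with a warning).
COG_ALPHABET = frozenset(string.ascii_uppercase)

#: Sentinel category for genes with no COG assignment.  Never stored on a
#: gene; derived when counting.
UNKNOWN_CATEGORY = "unknown"

ASSEMBLY_LEVELS = ("contig", "scaffold", "chromosome")


class ValidationError(ValueError):
    """Input violates a structural invariant (duplicate ids, bad tokens...)."""


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


@dataclass(frozen=True)
class GenomeRecord:
    """Genome-level metadata.

    size_mb is the assembly length in megabases, total_orfs the number of
    predicted coding sequences; both are used as normalisation denominators.
    """

    genome_id: str
    size_mb: float
    total_orfs: int = 0
    assembly_level: str = "contig"
    label: str = ""

    def __post_init__(self) -> None:
        if self.size_mb <= 0:
            raise ValidationError(
                f"genome {self.genome_id!r}: size_mb must be > 0, got {self.size_mb}"
            )
        if self.total_orfs < 0:
            raise ValidationError(
                f"genome {self.genome_id!r}: total_orfs must be >= 0"
            )
        if self.assembly_level not in ASSEMBLY_LEVELS:
            raise ValidationError(
                f"genome {self.genome_id!r}: assembly_level must be one of "
                f"{ASSEMBLY_LEVELS}, got {self.assembly_level!r}"
            )


@dataclass(frozen=True)
class GeneAnnotation:
    """Functional labels of one gene.

    cog_categories holds single-letter category codes (possibly empty —
    such genes count toward the derived "unknown" category).  rank is the
    0-based gene order along the replicon, standing in for coordinates.
    """

    gene_id: str
    cog_categories: frozenset = frozenset()
    cog_ids: frozenset = frozenset()
    ko_id: Optional[str] = None
    product: str = ""
    rank: int = 0

    def __post_init__(self) -> None:
        bad = set(self.cog_categories) - COG_ALPHABET
        if bad:
            raise ValidationError(
                f"gene {self.gene_id!r}: unrecognised COG category letters {sorted(bad)}"
            )
        if self.rank < 0:
            raise ValidationError(f"gene {self.gene_id!r}: rank must be >= 0")


@dataclass
class AnnotationTable:
    """All gene annotations of one genome, with unique gene ids."""

    genome_id: str
    rows: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for row in self.rows:
            if row.gene_id in seen:
                raise ValidationError(
                    f"genome {self.genome_id!r}: duplicate gene_id {row.gene_id!r}"
                )
            seen.add(row.gene_id)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def gene(self, gene_id: str) -> GeneAnnotation:
        for row in self.rows:
            if row.gene_id == gene_id:
                return row
        raise KeyError(gene_id)

    def merge_ko(self, ko_map: dict) -> "AnnotationTable":
        """Return a copy with KO assignments merged in by gene_id.

        Genes absent from ``ko_map`` keep their current ko_id; genes present
        with a None value have their ko_id cleared.  Order independent with
        respect to COG parsing.
        """
        new_rows = []
        for row in self.rows:
            if row.gene_id in ko_map:
                new_rows.append(replace(row, ko_id=ko_map[row.gene_id]))
            else:
                new_rows.append(row)
        return AnnotationTable(self.genome_id, new_rows)

    def genes_with_ko(self, ko_set: Iterable[str]) -> list:
        ko_set = set(ko_set)
        return [r for r in self.rows if r.ko_id in ko_set]

    def genes_with_cog_id(self, cog_id_set: Iterable[str]) -> list:
        cog_id_set = set(cog_id_set)
        return [r for r in self.rows if r.cog_ids & cog_id_set]


@dataclass
class SimilarityMatrices:
    """Square ANI and dDDH percentage matrices over the same genome set.

    Both matrices are symmetric with a diagonal of 100 after ingestion.
    """

    genome_ids: list
    ani: np.ndarray
    dddh: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.genome_ids)
        for name, m in (("ani", self.ani), ("dddh", self.dddh)):
            m = np.asarray(m, dtype=float)
            if m.shape != (n, n):
                raise ValidationError(f"{name} matrix is not {n}x{n}")
            if np.any(m < 0) or np.any(m > 100):
                raise ValidationError(f"{name} matrix has entries outside [0, 100]")
            if not np.allclose(m, m.T, atol=1e-9):
                raise ValidationError(f"{name} matrix is not symmetric")
            if not np.allclose(np.diag(m), 100.0, atol=1e-9):
                raise ValidationError(f"{name} matrix diagonal is not 100")
        self.ani = np.asarray(self.ani, dtype=float)
        self.dddh = np.asarray(self.dddh, dtype=float)

    def pair(self, a: str, b: str) -> tuple:
        i, j = self.genome_ids.index(a), self.genome_ids.index(b)
        return float(self.ani[i, j]), float(self.dddh[i, j])
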