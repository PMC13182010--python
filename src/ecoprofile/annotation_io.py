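"""Readers and writers for annotation-tool output dialects.

Supported inputs:

* eggNOG-mapper ``.annotations`` TSV (``#``-prefixed comments, a header row
  starting with ``#query``): gene ids, COG category letter strings, COG
  family ids (parsed from the orthologous-group column) and KEGG KOs.
* BlastKOALA-style two-column gene → KO TSV (blank KO allowed).
* Labelled square TSV matrices of ANI / dDDH percentages.
* A canonical internal TSV used for round-tripping annotation tables.

The parsers never execute annotation tools; they only consume their output.
"""

from __future__ import annotations

import logging
import re
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .model import (
    COG_ALPHABET,
    AnnotationTable,
    FormatError,
    GeneAnnotation,
    GenomeRecord,
    SimilarityMatrices,
    ValidationError,
)

logger = logging.getLogger(__name__)

KO_PATTERN = re.compile(r"^K\d{5}$")
COG_ID_PATTERN = re.compile(r"\b(COG\d{4})\b")

#: Canonical internal TSV column order.
CANONICAL_COLUMNS = ("gene_id", "cog_categories", "cog_ids", "ko_id", "product", "rank")

_MISSING = {"", "-", "nan", "NA"}


def _split_categories(token: str, gene_id: str) -> frozenset:
    """Split a multi-letter COG category string into single letters.

    Letters outside the COG alphabet are dropped with a warning (the
    analysis only considers the prokaryotic COG categories).
    """
    if token is None or token.strip() in _MISSING:
        return frozenset()
    letters = set(token.strip())
    bad = letters - COG_ALPHABET
    if bad:
        logger.warning(
            "gene %s: dropping unrecognised COG category letters %s",
            gene_id,
            sorted(bad),
        )
    return frozenset(letters & COG_ALPHABET)


def _parse_kos(token: Optional[str]) -> Optional[str]:
    """First KO from an eggNOG ``KEGG_ko`` field like ``ko:K03406,ko:K05874``."""
    if token is None or str(token).strip() in _MISSING:
        return None
    first = str(token).split(",")[0].strip()
    ko = first.removeprefix("ko:")
    return ko if KO_PATTERN.match(ko) else None


def read_eggnog_table(path, genome_id: str) -> AnnotationTable:
    """Parse an eggNOG-mapper ``.annotations`` TSV into an AnnotationTable.

    Requires the ``#query`` and ``COG_category`` columns; COG family ids are
    pulled from the ``eggNOG_OGs`` column when present, KOs from ``KEGG_ko``.
    Gene rank is the 0-based data-row order.
    """
    header = None
    data_rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                # eggNOG-mapper writes the header as a comment line.
                if line.startswith("#query"):
                    header = line.lstrip("#").split("\t")
                continue
            if header is None:
                header = line.split("\t")
                continue
            data_rows.append(line.split("\t"))

    if header is None:
        if not data_rows:
            return AnnotationTable(genome_id, [])
        raise FormatError(f"{path}: no header line found")

    header = [h.lstrip("#") for h in header]
    for col in ("query", "COG_category"):
        if col not in header:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    idx = {name: i for i, name in enumerate(header)}

    def cell(fields, col):
        i = idx.get(col)
        if i is None or i >= len(fields):
            return None
        return fields[i]

    rows = []
    for rank, fields in enumerate(data_rows):
        gene_id = cell(fields, "query")
        if gene_id is None or not gene_id.strip():
            raise FormatError(f"{path}: data row {rank} has no query id")
        gene_id = gene_id.strip()
        cats = _split_categories(cell(fields, "COG_category"), gene_id)
        ogs = cell(fields, "eggNOG_OGs") or ""
        cog_ids = frozenset(COG_ID_PATTERN.findall(ogs))
        ko = _parse_kos(cell(fields, "KEGG_ko"))
        product = (cell(fields, "Description") or "").strip()
        if product in _MISSING:
            product = ""
        rows.append(
            GeneAnnotation(
                gene_id=gene_id,
                cog_categories=cats,
                cog_ids=cog_ids,
                ko_id=ko,
                product=product,
                rank=rank,
            )
        )
    return AnnotationTable(genome_id, rows)


def read_ko_table(path, genome_id: str) -> AnnotationTable:
    """Parse a two-column gene → KO TSV (BlastKOALA dialect).

    Blank KO fields are allowed and yield rows with no KO.  Malformed KO
    tokens raise a ValidationError listing the offending rows.
    """
    rows = []
    bad_rows = []
    seen = set()
    with open(path) as fh:
        for rank, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            gene_id = parts[0].strip()
            token = parts[1].strip() if len(parts) > 1 else ""
            if gene_id in seen:
                raise ValidationError(f"{path}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            ko: Optional[str] = None
            if token:
                if not KO_PATTERN.match(token):
                    bad_rows.append((rank, line))
                    continue
                ko = token
            rows.append(GeneAnnotation(gene_id=gene_id, ko_id=ko, rank=len(rows)))
    if bad_rows:
        detail = "; ".join(f"line {r}: {t!r}" for r, t in bad_rows[:10])
        raise ValidationError(f"{path}: malformed KO tokens ({detail})")
    return AnnotationTable(genome_id, rows)


def merge_annotation_tables(cog_table: AnnotationTable, ko_table: AnnotationTable) -> AnnotationTable:
    """Merge a KO table into a COG-annotated table by gene id.

    KO assignments from ``ko_table`` overwrite any already present; genes
    found only in ``ko_table`` are appended (COG-less), so merge order of
    the two source files does not change the result.
    """
    ko_map = {r.gene_id: r.ko_id for r in ko_table if r.ko_id is not None}
    merged = cog_table.merge_ko(ko_map)
    have = {r.gene_id for r in merged}
    extra = [r for r in ko_table if r.gene_id not in have]
    if extra:
        base = max((r.rank for r in merged), default=-1) + 1
        extra = [
            GeneAnnotation(r.gene_id, ko_id=r.ko_id, rank=base + i)
            for i, r in enumerate(extra)
        ]
    return AnnotationTable(merged.genome_id, merged.rows + extra)


def _read_labeled_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if df.shape[0] != df.shape[1]:
        raise ValidationError(f"{path}: matrix is not square ({df.shape})")
    if set(df.index) != set(df.columns):
        raise ValidationError(f"{path}: row and column labels differ")
    df = df.loc[df.index, df.index]
    vals = df.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValidationError(f"{path}: matrix contains missing values")
    if (vals < 0).any() or (vals > 100).any():
        raise ValidationError(f"{path}: entries outside [0, 100]")
    return df


def read_similarity_matrices(ani_path, dddh_path) -> SimilarityMatrices:
    """Read labelled square ANI and dDDH TSV matrices.

    Labels must be identical across both files (order may differ; the dDDH
    matrix is aligned to the ANI order).  Matrices are symmetrised by the
    arithmetic mean of (i, j) and (j, i) and the diagonal forced to 100.
    """
    ani = _read_labeled_matrix(ani_path)
    dddh = _read_labeled_matrix(dddh_path)
    if set(ani.index) != set(dddh.index):
        raise ValidationError(
            f"label mismatch between {ani_path} and {dddh_path}"
        )
    dddh = dddh.loc[ani.index, ani.index]

    def _sym(df: pd.DataFrame) -> np.ndarray:
        m = df.to_numpy(dtype=float)
        m = (m + m.T) / 2.0
        np.fill_diagonal(m, 100.0)
        return m

    return SimilarityMatrices(list(ani.index), _sym(ani), _sym(dddh))


def write_annotation_table(table: AnnotationTable, path) -> None:
    """Write the canonical internal annotation TSV (documented column order)."""
    records = [
        {
            "gene_id": r.gene_id,
            "cog_categories": "".join(sorted(r.cog_categories)),
            "cog_ids": ",".join(sorted(r.cog_ids)),
            "ko_id": r.ko_id or "",
            "product": r.product,
            "rank": r.rank,
        }
        for r in table
    ]
    df = pd.DataFrame(records, columns=list(CANONICAL_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def read_annotation_table(path, genome_id: str) -> AnnotationTable:
    """Read the canonical internal annotation TSV back into memory."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(CANONICAL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    rows = [
        GeneAnnotation(
            gene_id=rec.gene_id,
            cog_categories=frozenset(rec.cog_categories),
            cog_ids=frozenset(c for c in rec.cog_ids.split(",") if c),
            ko_id=rec.ko_id or None,
            product=rec.product,
            rank=int(rec.rank),
        )
        for rec in df.itertuples()
    ]
    return AnnotationTable(genome_id, rows)


def load_genome_config(path) -> list:
    """Load a YAML genome listing into (GenomeRecord, paths dict) pairs.

    Expected layout::

        genomes:
          - id: spo1_1
            size_mb: 4.8
            total_orfs: 4257
            assembly_level: chromosome
            eggnog: annotations/spo1_1.annotations
            ko: annotations/spo1_1.ko.tsv
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    genomes = cfg.get("genomes")
    if not genomes:
        raise ValidationError(f"{path}: config lists no genomes")
    out = []
    seen = set()
    for g in genomes:
        gid = str(g["id"])
        if gid in seen:
            raise ValidationError(f"{path}: duplicate genome id {gid!r}")
        seen.add(gid)
        rec = GenomeRecord(
            genome_id=gid,
            size_mb=float(g["size_mb"]),
            total_orfs=int(g.get("total_orfs", 0)),
            assembly_level=str(g.get("assembly_level", "contig")),
            label=str(g.get("label", "")),
        )
        paths = {k: g[k] for k in ("eggnog", "ko", "dbcan", "detections") if k in g}
        out.append((rec, paths))
    return out
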