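"""Completeness adjudication for multi-gene machineries.

Secretion systems (T1SS–T6SS, T4SS subtypes), flagellum and type IV pili
are detected externally (MacSyFinder-style scanners plus BRITE hierarchy
screens); this module consumes their detection tables and adjudicates each
system copy:

* roles are unioned across the scanner and the BRITE screen;
* still-missing roles may be filled by an externally supplied homology
  "rescue" table, restricted to the cluster neighbourhood (up to a window
  of genes up- and downstream of the detected cluster);
* the provenance code records how completeness was reached, following the
  a–f scheme used for secretion-system reporting:

  ==== =====================================================================
  code meaning
  ==== =====================================================================
  a    complete by scanner, confirmed by the BRITE screen
  b    highly incomplete (missing fraction above threshold), not rescued
  c    incomplete by ConjScan, completed by homology rescue
  d    incomplete (below the highly-incomplete threshold), not rescued
  e    incomplete by TXSScan, completed by homology rescue
  f    incomplete by scanner, but complete in the BRITE screen
  ==== =====================================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
import yaml

from .model import ValidationError

STATUS_COMPLETE_SCAN = "complete_scan_confirmed"
STATUS_COMPLETE_RESCUE = "complete_after_rescue"
STATUS_COMPLETE_BRITE = "complete_brite_only"
STATUS_INCOMPLETE = "incomplete"
STATUS_HIGHLY_INCOMPLETE = "highly_incomplete"
STATUS_ABSENT = "absent"


@dataclass(frozen=True)
class MachineryModel:
    """A machinery as its mandatory (and accessory) gene roles."""

    model_id: str
    mandatory_genes: frozenset
    accessory_genes: frozenset = frozenset()
    highly_incomplete_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if not self.mandatory_genes:
            raise ValidationError(f"{self.model_id}: no mandatory genes")
        if self.mandatory_genes & self.accessory_genes:
            raise ValidationError(
                f"{self.model_id}: mandatory and accessory roles overlap"
            )

    @property
    def n_total(self) -> int:
        return len(self.mandatory_genes)


@dataclass(frozen=True)
class DetectionRecord:
    """Roles detected for one system copy by one source."""

    genome_id: str
    model_id: str
    detected_roles: frozenset
    source: str = "scan"  # "scan" | "brite" | "rescue"
    scanner: str = "txsscan"  # "txsscan" | "conjscan"
    copy_index: int = 0
    cluster_gene_ranks: Optional[tuple] = None


@dataclass(frozen=True)
class MachineryStatus:
    genome_id: str
    model_id: str
    copy_index: int
    status: str
    missing_roles: frozenset
    provenance_code: str
    scanner: str = "txsscan"


def read_detection_table(path) -> list:
    """Read a system-detection TSV (scanner/BRITE output digest).

    Columns: genome_id, model_id, copy_index, source, scanner,
    detected_roles (comma-separated), cluster_ranks (comma-separated,
    optional/blank).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"genome_id", "model_id", "detected_roles"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for rec in df.itertuples():
        ranks = getattr(rec, "cluster_ranks", "")
        records.append(
            DetectionRecord(
                genome_id=rec.genome_id,
                model_id=rec.model_id,
                detected_roles=frozenset(
                    r for r in rec.detected_roles.split(",") if r
                ),
                source=getattr(rec, "source", "scan") or "scan",
                scanner=getattr(rec, "scanner", "txsscan") or "txsscan",
                copy_index=int(getattr(rec, "copy_index", 0) or 0),
                cluster_gene_ranks=tuple(int(x) for x in ranks.split(",") if x)
                or None,
            )
        )
    return records


def write_detection_table(records: Iterable[DetectionRecord], path) -> None:
    rows = [
        {
            "genome_id": d.genome_id,
            "model_id": d.model_id,
            "copy_index": d.copy_index,
            "source": d.source,
            "scanner": d.scanner,
            "detected_roles": ",".join(sorted(d.detected_roles)),
            "cluster_ranks": ",".join(map(str, d.cluster_gene_ranks or ())),
        }
        for d in records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "genome_id", "model_id", "copy_index", "source", "scanner",
            "detected_roles", "cluster_ranks",
        ],
    ).to_csv(path, sep="\t", index=False)


def load_machinery_models(path) -> list:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    models = []
    for m in raw.get("models", []):
        models.append(
            MachineryModel(
                model_id=str(m["id"]),
                mandatory_genes=frozenset(str(g) for g in m["mandatory"]),
                accessory_genes=frozenset(str(g) for g in m.get("accessory", [])),
                highly_incomplete_fraction=float(
                    m.get("highly_incomplete_fraction", 1.0 / 3.0)
                ),
            )
        )
    return models


def adjudicate(
    detections: Iterable[DetectionRecord],
    model: MachineryModel,
    rescue_hits: Optional[Iterable[str]] = None,
) -> MachineryStatus:
    """Adjudicate one system copy from its detection records.

    All detections must share genome, model and copy index.  Scanner and
    BRITE roles are unioned; rescue hits (roles recovered by homology in
    the cluster neighbourhood) fill remaining gaps.  The status/provenance
    rules are described in the module docstring.
    """
    detections = list(detections)
    if not detections:
        raise ValidationError("no detection records")
    genomes = {d.genome_id for d in detections}
    models = {d.model_id for d in detections}
    copies = {d.copy_index for d in detections}
    if len(genomes) > 1 or len(models) > 1 or len(copies) > 1:
        raise ValidationError("detections must share genome, model and copy")
    if models != {model.model_id}:
        raise ValidationError(
            f"detections are for {models}, not model {model.model_id!r}"
        )
    known = model.mandatory_genes | model.accessory_genes
    for d in detections:
        bad = d.detected_roles - known
        if bad:
            raise ValidationError(
                f"{model.model_id}: unknown detected roles {sorted(bad)}"
            )
    rescue = frozenset(rescue_hits or ())
    bad = rescue - known
    if bad:
        raise ValidationError(f"{model.model_id}: unknown rescue roles {sorted(bad)}")

    scan_roles = frozenset().union(
        *[d.detected_roles for d in detections if d.source == "scan"], frozenset()
    )
    brite_roles = frozenset().union(
        *[d.detected_roles for d in detections if d.source == "brite"], frozenset()
    )
    scanner = next((d.scanner for d in detections if d.source == "scan"), "txsscan")
    genome_id = detections[0].genome_id
    copy_index = detections[0].copy_index

    mand = model.mandatory_genes
    scan_complete = mand <= scan_roles
    brite_complete = mand <= brite_roles
    union_roles = scan_roles | brite_roles
    union_missing = mand - union_roles
    after_rescue = union_missing - rescue

    if scan_complete:
        status, code = STATUS_COMPLETE_SCAN, "a"
        missing = frozenset()
    elif not union_missing:
        # scanner incomplete but the BRITE screen supplies the rest
        status, code = STATUS_COMPLETE_BRITE, "f"
        missing = frozenset()
    elif not after_rescue:
        status = STATUS_COMPLETE_RESCUE
        code = "c" if scanner == "conjscan" else "e"
        missing = frozenset()
    else:
        missing = after_rescue
        fraction = len(missing) / model.n_total
        if fraction > model.highly_incomplete_fraction:
            status, code = STATUS_HIGHLY_INCOMPLETE, "b"
        else:
            status, code = STATUS_INCOMPLETE, "d"
    return MachineryStatus(
        genome_id=genome_id,
        model_id=model.model_id,
        copy_index=copy_index,
        status=status,
        missing_roles=missing,
        provenance_code=code,
        scanner=scanner,
    )


def neighborhood_window(
    cluster_gene_ranks: Iterable[int],
    n_genes: int,
    window: int = 10,
    circular: bool = False,
) -> set:
    """Candidate gene ranks within ``window`` positions of a detected cluster.

    The window extends from the cluster's minimum and maximum rank, excludes
    cluster members, truncates at replicon ends when linear and wraps
    (modular arithmetic) when circular.
    """
    ranks = sorted(set(cluster_gene_ranks))
    if not ranks:
        raise ValidationError("empty cluster")
    if window < 0:
        raise ValidationError("window must be >= 0")
    if ranks[0] < 0 or ranks[-1] >= n_genes:
        raise ValidationError("cluster ranks outside replicon")
    lo, hi = ranks[0], ranks[-1]
    cluster = set(ranks)
    if circular:
        candidates = {(lo - k) % n_genes for k in range(1, window + 1)}
        candidates |= {(hi + k) % n_genes for k in range(1, window + 1)}
    else:
        candidates = set(range(max(0, lo - window), lo))
        candidates |= set(range(hi + 1, min(n_genes, hi + window + 1)))
    return candidates - cluster


def summarize_machineries(
    statuses: Iterable[MachineryStatus], models: Iterable[MachineryModel] = ()
) -> pd.DataFrame:
    """Genome × model table of copy counts with provenance codes.

    Cells read like the published secretion-system tables, e.g. "1a+1b";
    models with no complete or partial copy show "0".
    """
    statuses = list(statuses)
    genomes = sorted({s.genome_id for s in statuses})
    model_ids = sorted({s.model_id for s in statuses} | {m.model_id for m in models})
    table = pd.DataFrame("0", index=genomes, columns=model_ids, dtype=object)
    cells: dict = {}
    for s in statuses:
        if s.status == STATUS_ABSENT:
            continue
        cells.setdefault((s.genome_id, s.model_id), []).append(s.provenance_code)
    for (gid, mid), codes in cells.items():
        parts = [f"1{c}" for c in sorted(codes)]
        table.loc[gid, mid] = "+".join(parts)
    return table


def copy_counts(statuses: Iterable[MachineryStatus], complete_only: bool = True) -> pd.DataFrame:
    """Genome × model integer copy counts (complete copies by default)."""
    complete = {STATUS_COMPLETE_SCAN, STATUS_COMPLETE_RESCUE, STATUS_COMPLETE_BRITE}
    statuses = list(statuses)
    genomes = sorted({s.genome_id for s in statuses})
    model_ids = sorted({s.model_id for s in statuses})
    out = pd.DataFrame(0, index=genomes, columns=model_ids, dtype=int)
    for s in statuses:
        if complete_only and s.status not in complete:
            continue
        if s.status == STATUS_ABSENT:
            continue
        out.loc[s.genome_id, s.model_id] += 1
    return out
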