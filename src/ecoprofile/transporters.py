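"""Sugar-transporter completeness, capability inference and density ranking.

A transporter system is adjudicated complete only when every required
machinery role is matched by at least one gene: for ABC importers the
substrate-binding protein (SBP), transmembrane domains (TMD) and
nucleotide-binding domain (NBD/ATPase); for PTS systems the enzyme I (EI),
the phosphocarrier HPr, and the substrate-specific enzyme II complex (EII).
A complete system is taken as evidence the genome can transport the
corresponding sugar.  Transporter gene totals are expressed per megabase
and ranked against an external reference distribution of densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

import numpy as np
import yaml

from .model import AnnotationTable, ValidationError

ABC_ROLES = ("SBP", "TMD", "NBD")
PTS_ROLES = ("EI", "HPr", "EII")
#: PTS roles encoded once per genome and shared by all EII complexes.
PTS_GLOBAL_ROLES = frozenset({"EI", "HPr"})


@dataclass(frozen=True)
class TransporterSystemDef:
    """One named transporter system: substrate + role → acceptable-KO map."""

    system_id: str
    kind: str  # "ABC" | "PTS"
    substrate: str
    roles: dict  # role_name -> frozenset of KO ids

    def __post_init__(self) -> None:
        if self.kind not in ("ABC", "PTS"):
            raise ValidationError(f"{self.system_id}: kind must be ABC or PTS")
        expected = ABC_ROLES if self.kind == "ABC" else PTS_ROLES
        if set(self.roles) != set(expected):
            raise ValidationError(
                f"{self.system_id}: roles must be exactly {expected}, got {sorted(self.roles)}"
            )
        for role, kos in self.roles.items():
            if not kos:
                raise ValidationError(f"{self.system_id}: role {role} has no KO ids")
        if not self.substrate:
            raise ValidationError(f"{self.system_id}: substrate must be non-empty")


@dataclass(frozen=True)
class SystemCompleteness:
    genome_id: str
    system_id: str
    status: str  # "complete" | "incomplete"
    present_roles: frozenset
    missing_roles: frozenset
    supporting_genes: dict  # role -> tuple of gene ids


@dataclass(frozen=True)
class DensityReport:
    genome_id: str
    n_transporter_genes: int
    size_mb: float
    density_per_mb: float          # raw value
    density_display: float         # 1-decimal, half-up
    reference_percentile: Optional[float] = None


def load_transporter_defs(path) -> list:
    """Load the curated system definitions YAML (role → KO-id map per system)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    defs = []
    for item in raw.get("systems", []):
        defs.append(
            TransporterSystemDef(
                system_id=str(item["id"]),
                kind=str(item["kind"]),
                substrate=str(item["substrate"]),
                roles={r: frozenset(k) for r, k in item["roles"].items()},
            )
        )
    return defs


def assess_system(
    annotation: AnnotationTable, sysdef: TransporterSystemDef
) -> SystemCompleteness:
    """Adjudicate one system: a role is present iff ≥1 gene's KO matches it."""
    present, missing = set(), set()
    supporting = {}
    for role, kos in sysdef.roles.items():
        genes = tuple(r.gene_id for r in annotation.genes_with_ko(kos))
        supporting[role] = genes
        (present if genes else missing).add(role)
    return SystemCompleteness(
        genome_id=annotation.genome_id,
        system_id=sysdef.system_id,
        status="complete" if not missing else "incomplete",
        present_roles=frozenset(present),
        missing_roles=frozenset(missing),
        supporting_genes=supporting,
    )


def assess_all(annotation: AnnotationTable, defs: Iterable[TransporterSystemDef]) -> list:
    return [assess_system(annotation, d) for d in defs]


def infer_sugar_capabilities(
    completeness: Iterable[SystemCompleteness], defs: Iterable[TransporterSystemDef]
) -> dict:
    """Per-genome transportable-sugar sets, split by transporter kind.

    A substrate is included iff at least one system for it is complete.
    Returns {genome_id: {"ABC": set, "PTS": set}}.
    """
    by_id = {d.system_id: d for d in defs}
    out: dict = {}
    for c in completeness:
        entry = out.setdefault(c.genome_id, {"ABC": set(), "PTS": set()})
        if c.status == "complete":
            d = by_id[c.system_id]
            entry[d.kind].add(d.substrate)
    return out


def tally_sugar_transporter_genes(
    completeness: Iterable[SystemCompleteness],
    defs: Iterable[TransporterSystemDef],
    count_global_once: bool = True,
) -> dict:
    """Count genes supporting complete sugar-transport systems.

    Per genome, returns {"ABC": n, "PTS": n, "total": n}.  With
    count_global_once (default) gene ids are deduplicated across systems,
    so the genome-global PTS roles (EI, HPr) contribute once per genome;
    with False every complete system re-counts its EI/HPr supporting genes,
    the alternative counting convention for per-system tallies.
    """
    by_id = {d.system_id: d for d in defs}
    distinct: dict = {}
    dup_extra: dict = {}
    for c in completeness:
        if c.status != "complete":
            continue
        d = by_id[c.system_id]
        entry = distinct.setdefault(c.genome_id, {"ABC": set(), "PTS": set()})
        for role, genes in c.supporting_genes.items():
            before = len(entry[d.kind])
            entry[d.kind].update(genes)
            if d.kind == "PTS" and role in PTS_GLOBAL_ROLES:
                # genes already seen in another system: extra per-system uses
                already = before + len(genes) - len(entry[d.kind])
                dup_extra[c.genome_id] = dup_extra.get(c.genome_id, 0) + already
    tallies = {}
    for gid, entry in distinct.items():
        n_abc = len(entry["ABC"])
        n_pts = len(entry["PTS"])
        if not count_global_once:
            n_pts += dup_extra.get(gid, 0)
        tallies[gid] = {"ABC": n_abc, "PTS": n_pts, "total": n_abc + n_pts}
    return tallies


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero at the given decimal (presentation rule)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def transporter_density(
    n_genes: int, size_mb: float, genome_id: str = ""
) -> DensityReport:
    """Transporter genes per megabase, with 1-decimal half-up presentation."""
    if n_genes < 0:
        raise ValidationError("n_genes must be >= 0")
    if size_mb <= 0:
        raise ValidationError("size_mb must be > 0")
    raw = n_genes / size_mb
    return DensityReport(
        genome_id=genome_id,
        n_transporter_genes=n_genes,
        size_mb=size_mb,
        density_per_mb=raw,
        density_display=round_half_up(raw, 1),
    )


def rank_against_reference(
    density: float, reference: list, bin_width: int = 5
) -> dict:
    """Percentile of a density within a reference distribution, plus bins.

    percentile = fraction of reference values strictly below ``density``.
    Histogram bins of width ``bin_width`` starting at 0 are returned for
    distribution plots (edges 0, 5, 10, ...).
    """
    if not reference:
        raise ValidationError("reference distribution is empty")
    ref = np.asarray(reference, dtype=float)
    percentile = float(np.mean(ref < density))
    top = max(float(ref.max()), density)
    edges = np.arange(0, np.ceil(top / bin_width) * bin_width + bin_width, bin_width)
    hist, edges = np.histogram(ref, bins=edges)
    return {
        "percentile": percentile,
        "median": float(np.median(ref)),
        "bin_edges": edges.tolist(),
        "bin_counts": hist.tolist(),
    }
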