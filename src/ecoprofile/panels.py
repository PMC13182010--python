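"""Ecological gene-panel screens.

A panel is a list of markers (matched by KO id, COG family id, or gene
symbol against the product text), optionally grouped into subsystems that
are complete only when every member marker has at least one copy.  Panel
verdicts follow a configurable rule — e.g. the osmoadaptation panel is
satisfied when at least one osmoprotectant transport or biosynthesis
subsystem is complete; the nitrate-reduction panel requires the full
napA/napB/nirB/nirD set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import yaml

from .model import AnnotationTable, ValidationError

MATCH_MODES = ("ko", "cog_id", "gene_symbol")
VERDICT_RULES = ("any_complete_subsystem", "all_required", "report_only")


@dataclass(frozen=True)
class Marker:
    """One screened gene: a name plus the ids that count as a hit."""

    name: str
    match_by: str
    accepted_ids: frozenset
    subsystem: Optional[str] = None

    def __post_init__(self) -> None:
        if self.match_by not in MATCH_MODES:
            raise ValidationError(
                f"marker {self.name!r}: match_by must be one of {MATCH_MODES}"
            )
        if not self.accepted_ids:
            raise ValidationError(f"marker {self.name!r}: accepted_ids is empty")


@dataclass(frozen=True)
class GenePanel:
    panel_id: str
    markers: tuple
    verdict_rule: str = "report_only"

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValidationError(f"panel {self.panel_id!r}: duplicate marker names")
        if self.verdict_rule not in VERDICT_RULES:
            raise ValidationError(
                f"panel {self.panel_id!r}: unknown verdict rule {self.verdict_rule!r}"
            )


@dataclass(frozen=True)
class PanelResult:
    genome_id: str
    panel_id: str
    marker_copies: dict      # marker name -> copy number
    subsystem_complete: dict  # subsystem label -> bool
    verdict: Optional[bool]


def load_panels(path) -> list:
    """Load panel definitions from YAML (a list under the ``panels`` key)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    panels = []
    for p in raw.get("panels", []):
        markers = tuple(
            Marker(
                name=str(m["name"]),
                match_by=str(m.get("match_by", "ko")),
                accepted_ids=frozenset(str(i) for i in m["ids"]),
                subsystem=m.get("subsystem"),
            )
            for m in p["markers"]
        )
        panels.append(
            GenePanel(
                panel_id=str(p["id"]),
                markers=markers,
                verdict_rule=str(p.get("verdict_rule", "report_only")),
            )
        )
    return panels


def _marker_copies(annotation: AnnotationTable, marker: Marker) -> int:
    if marker.match_by == "ko":
        return len(annotation.genes_with_ko(marker.accepted_ids))
    if marker.match_by == "cog_id":
        return len(annotation.genes_with_cog_id(marker.accepted_ids))
    # gene_symbol: substring match against the free-text product field;
    # annotation-tool dependent, so off by default in shipped panels.
    ids = {i.lower() for i in marker.accepted_ids}
    return sum(
        1 for r in annotation if any(tok in r.product.lower() for tok in ids)
    )


def screen_panel(annotation: AnnotationTable, panel: GenePanel) -> PanelResult:
    """Count marker copies, adjudicate subsystems, apply the verdict rule."""
    copies = {m.name: _marker_copies(annotation, m) for m in panel.markers}
    subsystems: dict = {}
    for m in panel.markers:
        if m.subsystem is None:
            continue
        ok = copies[m.name] >= 1
        subsystems[m.subsystem] = subsystems.get(m.subsystem, True) and ok
    if panel.verdict_rule == "any_complete_subsystem":
        verdict: Optional[bool] = any(subsystems.values()) if subsystems else False
    elif panel.verdict_rule == "all_required":
        verdict = all(v >= 1 for v in copies.values())
    else:
        verdict = None
    return PanelResult(annotation.genome_id, panel.panel_id, copies, subsystems, verdict)


@dataclass(frozen=True)
class ComplexMarker:
    """An enzyme or complex identified by one or more COG family ids.

    Multi-id complexes count min(copies of each member): all listed ids
    must be present for the complex to count once.
    """

    name: str
    cog_ids: tuple
    group: str = ""

    def __post_init__(self) -> None:
        if not self.cog_ids:
            raise ValidationError(f"complex {self.name!r}: no COG ids")


def oxidative_profile(
    annotation: AnnotationTable, markers: Iterable[ComplexMarker]
) -> PanelResult:
    """ROS-defence enzymes and high-affinity oxidase complexes by COG id.

    Copy number of a multi-COG complex is the minimum copy count over its
    member families (a complex is absent if any member is missing).  The
    microaerophily flag (verdict) is true iff at least one high-affinity
    cytochrome complex (group "high_affinity") is present.
    """
    copies = {}
    groups = {}
    for m in markers:
        per_id = [len(annotation.genes_with_cog_id({cid})) for cid in m.cog_ids]
        copies[m.name] = min(per_id)
        if m.group:
            groups.setdefault(m.group, []).append(copies[m.name] >= 1)
    high_affinity = groups.get("high_affinity", [])
    verdict = any(high_affinity) if high_affinity else None
    subsystem_complete = {g: any(v) for g, v in groups.items()}
    return PanelResult(annotation.genome_id, "oxidative", copies, subsystem_complete, verdict)


def load_complex_markers(path) -> list:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return [
        ComplexMarker(
            name=str(m["name"]),
            cog_ids=tuple(str(c) for c in m["cog_ids"]),
            group=str(m.get("group", "")),
        )
        for m in raw.get("complexes", [])
    ]


def count_mcps(
    annotation: AnnotationTable, mcp_ids: Iterable[str], aer_ids: Iterable[str]
) -> tuple:
    """(number of methyl-accepting chemotaxis proteins, aerotaxis sensor present)."""
    mcp_ids, aer_ids = set(mcp_ids), set(aer_ids)
    if not mcp_ids or not aer_ids:
        raise ValidationError("MCP and Aer id sets must be non-empty")
    n_mcp = len(annotation.genes_with_ko(mcp_ids))
    aer_present = len(annotation.genes_with_ko(aer_ids)) > 0
    return n_mcp, aer_present
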