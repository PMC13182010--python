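"""Species delineation from ANI and dDDH matrices under dual thresholds.

Two genomes are conspecific when their pairwise similarity exceeds the
conventional species thresholds — 95% average nucleotide identity and 70%
digital DNA–DNA hybridisation — and putative species are the connected
components of the resulting pass graph.  The per-pair decision record is
kept so non-clique components (a genome passing with one member but not
another) are visible to the user.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .model import SimilarityMatrices, ValidationError


@dataclass(frozen=True)
class DelineationConfig:
    ani_threshold: float = 95.0
    dddh_threshold: float = 70.0
    combine_rule: str = "both"   # "both" | "either"
    strict: bool = True          # strict > at thresholds (">= " when False)

    def __post_init__(self) -> None:
        for name, t in (("ani", self.ani_threshold), ("dddh", self.dddh_threshold)):
            if not (0 < t < 100):
                raise ValidationError(f"{name} threshold must be in (0, 100)")
        if self.combine_rule not in ("both", "either"):
            raise ValidationError("combine_rule must be 'both' or 'either'")


@dataclass
class SpeciesClusterSet:
    clusters: list                 # list of frozensets of genome ids
    pair_decisions: pd.DataFrame   # columns: a, b, ani, dddh, ani_pass, dddh_pass, linked

    def cluster_of(self, genome_id: str) -> frozenset:
        for c in self.clusters:
            if genome_id in c:
                return c
        raise KeyError(genome_id)


def delineate(
    matrices: SimilarityMatrices, cfg: DelineationConfig = DelineationConfig()
) -> SpeciesClusterSet:
    """Cluster genomes into putative species.

    An edge links genomes i, j when ANI and dDDH both (or either, per
    combine_rule) exceed their thresholds; clusters are connected
    components, singletons allowed.
    """
    ids = matrices.genome_ids
    g = nx.Graph()
    g.add_nodes_from(ids)
    records = []
    cmp = (lambda v, t: v > t) if cfg.strict else (lambda v, t: v >= t)
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            b = ids[j]
            ani = float(matrices.ani[i, j])
            dddh = float(matrices.dddh[i, j])
            ani_pass = cmp(ani, cfg.ani_threshold)
            dddh_pass = cmp(dddh, cfg.dddh_threshold)
            linked = (
                (ani_pass and dddh_pass)
                if cfg.combine_rule == "both"
                else (ani_pass or dddh_pass)
            )
            if linked:
                g.add_edge(a, b)
            records.append(
                {
                    "a": a,
                    "b": b,
                    "ani": ani,
                    "dddh": dddh,
                    "ani_pass": ani_pass,
                    "dddh_pass": dddh_pass,
                    "linked": linked,
                }
            )
    clusters = sorted(
        (frozenset(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), min(c)),
    )
    return SpeciesClusterSet(
        clusters=clusters,
        pair_decisions=pd.DataFrame(
            records, columns=["a", "b", "ani", "dddh", "ani_pass", "dddh_pass", "linked"]
        ),
    )


def membership_frame(clusters: SpeciesClusterSet) -> pd.DataFrame:
    """Genome → cluster-id table (clusters numbered by size then lexical min)."""
    rows = [
        {"genome": gid, "cluster": k}
        for k, c in enumerate(clusters.clusters)
        for gid in sorted(c)
    ]
    return pd.DataFrame(rows, columns=["genome", "cluster"])
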