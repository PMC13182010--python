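"""Synthetic annotation, detection, CAZyme and similarity-matrix generators.

Every pipeline stage is testable without downloading genomes: the
generators emit tables in the dialects the readers consume, with a
controlled statistical structure —

* per-category gene counts are landmark-centred Poisson draws, so a
  planted "copiotroph" archetype sits beyond the copiotroph landmark in
  (nearly) every scored category and is recoverable by the trophic scorer;
* gene-panel markers are injected by presence-probability toggles;
* machinery scenarios plant a chosen set of missing roles (optionally with
  a homology rescue table);
* similarity matrices have block structure: within-species blocks drawn
  above the ANI/dDDH thresholds, between-block pairs below.

All draws are deterministic under a fixed seed; each genome gets its own
RNG stream derived from (seed, genome id), so adding a genome to a cohort
does not perturb the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .cazymes import CazymeCounts
from .machinery import DetectionRecord, MachineryModel
from .model import (
    COG_ALPHABET,
    AnnotationTable,
    GeneAnnotation,
    GenomeRecord,
    SimilarityMatrices,
    ValidationError,
)
from .panels import GenePanel
from .trophic import COG_ID_RE, LandmarkEntry, TrophicLandmarkSet

ARCHETYPES = ("copiotroph", "oligotroph", "moderate", "custom")

#: Margin by which planted archetype means sit beyond their landmark.
ARCHETYPE_MARGIN = 0.6

#: Fraction of categories planted on the copiotroph side for the
#: "moderate" archetype (the rest sit between the landmarks).
MODERATE_COPIO_FRACTION = 0.65

_BACKGROUND_LETTERS = sorted(COG_ALPHABET - {"X"})
_UNASSIGNED_FRACTION = 0.04  # genes with no COG category at all


def derive_rng(seed: int, stream_id: str) -> np.random.Generator:
    """Independent RNG stream for one genome, derived from the cohort seed."""
    sub = zlib.crc32(stream_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, sub])


@dataclass
class SyntheticGenomeSpec:
    genome_id: str
    size_mb: float = 4.5
    archetype: str = "moderate"
    seed: int = 0
    panel_toggles: dict = field(default_factory=dict)
    machinery_scenarios: dict = field(default_factory=dict)
    cazyme_profile: dict = field(default_factory=dict)
    n_background_genes: int = 3000
    category_means: Optional[dict] = None  # required for archetype "custom"
    moderate_copio_fraction: float = MODERATE_COPIO_FRACTION

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValidationError(f"unknown archetype {self.archetype!r}")
        if self.archetype == "custom" and not self.category_means:
            raise ValidationError("custom archetype requires explicit category_means")
        for name, frac in self.panel_toggles.items():
            if not (0 <= frac <= 1):
                raise ValidationError(f"panel toggle {name!r} outside [0, 1]")


@dataclass
class SyntheticCohortSpec:
    genomes: list                      # list of SyntheticGenomeSpec
    species_blocks: list = field(default_factory=list)
    # each block: {"members": [...], "ani": (mean, sd), "dddh": (mean, sd)}
    between: dict = field(
        default_factory=lambda: {"ani": (80.0, 1.0), "dddh": (25.0, 2.0)}
    )
    seed: int = 0


def synthetic_landmarks(
    seed: int = 0, n: int = 33, n_positive: int = 14, unit: str = "per_mb"
) -> TrophicLandmarkSet:
    """A fully-valued synthetic landmark set (33 categories, 14 '+' / 19 '−').

    Values are plausible per-Mb gene densities; they stand in for the
    published reference landmarks, which are not redistributable, and are
    labelled synthetic.  Category ids mix general letters and specific
    COG-family ids, as the real scheme does.
    """
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    letters = ["G", "I", "Q", "K", "V", "T", "N", "E"]
    ids = letters[: min(len(letters), n)]
    k = 1000
    while len(ids) < n:
        ids.append(f"COG_{k}")
        k += 137
    entries = {}
    for i, cat in enumerate(ids[:n]):
        direction = "+" if i < n_positive else "-"
        low = float(rng.uniform(4.0, 14.0))
        high = low * float(rng.uniform(1.8, 2.6))
        if direction == "+":
            oligo, copio = low, high
        else:
            copio, oligo = low, high
        entries[cat] = LandmarkEntry(cat, direction, oligo, copio, unit)
    return TrophicLandmarkSet(entries)


def _target_mean(entry: LandmarkEntry, archetype: str, on_copio_side: bool) -> float:
    """Per-Mb Poisson mean planting a category on the requested side."""
    o, c = entry.oligotroph_value, entry.copiotroph_value
    mid = (o + c) / 2.0
    if archetype == "moderate" and not on_copio_side:
        return mid
    copio_side = archetype == "copiotroph" or (archetype == "moderate" and on_copio_side)
    if entry.direction == "+":
        return c * (1 + ARCHETYPE_MARGIN) if copio_side else o * (1 - ARCHETYPE_MARGIN)
    return c * (1 - ARCHETYPE_MARGIN) if copio_side else o * (1 + ARCHETYPE_MARGIN)


def generate_annotation(
    spec: SyntheticGenomeSpec,
    landmarks: TrophicLandmarkSet,
    panels: Iterable[GenePanel] = (),
) -> AnnotationTable:
    """Emulate one genome's annotation table.

    Landmark-category gene counts are Poisson draws centred on means chosen
    by archetype (per-Mb mean × genome size); panel marker genes are
    injected per presence toggles; the remainder are background genes with
    random category letters, a small fraction left unassigned.
    """
    rng = derive_rng(spec.seed, spec.genome_id)
    rows: list = []
    counter = 0

    def new_gene(**kw) -> None:
        nonlocal counter
        rows.append(
            GeneAnnotation(gene_id=f"{spec.genome_id}_g{counter:05d}", rank=counter, **kw)
        )
        counter += 1

    cats = sorted(landmarks.entries)
    n_copio_side = int(round(spec.moderate_copio_fraction * len(cats)))
    copio_side_cats = set(cats[:n_copio_side])  # deterministic assignment
    for cat in cats:
        entry = landmarks.entries[cat]
        if spec.archetype == "custom":
            mean_per_mb = float(spec.category_means[cat])
        else:
            mean_per_mb = _target_mean(entry, spec.archetype, cat in copio_side_cats)
        count = int(rng.poisson(max(mean_per_mb, 0.0) * spec.size_mb))
        m = COG_ID_RE.match(cat)
        for _ in range(count):
            if m:
                new_gene(cog_ids=frozenset({f"COG{int(m.group(1)):04d}"}))
            else:
                new_gene(cog_categories=frozenset({cat}))

    for panel in panels:
        for marker in panel.markers:
            frac = spec.panel_toggles.get(
                marker.name,
                spec.panel_toggles.get(
                    marker.subsystem or "", spec.panel_toggles.get(panel.panel_id, 0.0)
                ),
            )
            if frac > 0 and rng.random() < frac:
                an_id = sorted(marker.accepted_ids)[0]
                if marker.match_by == "ko":
                    new_gene(ko_id=an_id)
                elif marker.match_by == "cog_id":
                    new_gene(cog_ids=frozenset({an_id}))
                else:
                    new_gene(product=an_id)

    # background genes only use letters outside the scored landmark set, so
    # they do not perturb the planted per-category structure
    scored_letters = {c for c in cats if not COG_ID_RE.match(c)}
    bg_letters = [l for l in _BACKGROUND_LETTERS if l not in scored_letters] or ["S"]
    n_unassigned = int(round(spec.n_background_genes * _UNASSIGNED_FRACTION))
    for _ in range(spec.n_background_genes - n_unassigned):
        letter = bg_letters[int(rng.integers(len(bg_letters)))]
        new_gene(cog_categories=frozenset({letter}))
    for _ in range(n_unassigned):
        new_gene()

    return AnnotationTable(spec.genome_id, rows)


def genome_record_for(spec: SyntheticGenomeSpec, table: AnnotationTable) -> GenomeRecord:
    """GenomeRecord matching a generated table (ORF total = table length)."""
    return GenomeRecord(
        genome_id=spec.genome_id,
        size_mb=spec.size_mb,
        total_orfs=len(table),
        assembly_level="contig",
        label="synthetic",
    )


def generate_similarity(cohort: SyntheticCohortSpec) -> SimilarityMatrices:
    """Block-structured ANI/dDDH matrices from a cohort's species blocks."""
    ids = [g.genome_id for g in cohort.genomes]
    block_of = {}
    for k, block in enumerate(cohort.species_blocks):
        for gid in block["members"]:
            if gid not in ids:
                raise ValidationError(f"block member {gid!r} not in cohort")
            if gid in block_of:
                raise ValidationError(f"genome {gid!r} in two species blocks")
            block_of[gid] = k
    rng = derive_rng(cohort.seed, "similarity")
    n = len(ids)
    ani = np.full((n, n), 100.0)
    dddh = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            same = (
                ids[i] in block_of
                and ids[j] in block_of
                and block_of[ids[i]] == block_of[ids[j]]
            )
            dists = (
                cohort.species_blocks[block_of[ids[i]]] if same else cohort.between
            )
            for name, m in (("ani", ani), ("dddh", dddh)):
                mean, sd = dists[name]
                v = float(np.clip(rng.normal(mean, sd) if sd > 0 else mean, 0.0, 100.0))
                m[i, j] = m[j, i] = v
    return SimilarityMatrices(ids, ani, dddh)


def generate_machinery_detections(
    spec: SyntheticGenomeSpec, models: Iterable[MachineryModel]
) -> tuple:
    """Detection records planting the spec's missing-role scenarios.

    Scenario values are either a collection of missing role names or a
    mapping {"missing": [...], "rescue": [...]} when some missing roles
    should appear in the emitted rescue table.  Cluster gene ranks are
    placed contiguously.  Returns (detections, rescue_hits) with
    rescue_hits keyed by model_id.
    """
    by_id = {m.model_id: m for m in models}
    detections = []
    rescue_hits: dict = {}
    next_rank = 0
    for model_id in sorted(spec.machinery_scenarios):
        scenario = spec.machinery_scenarios[model_id]
        if model_id not in by_id:
            raise ValidationError(f"scenario references unknown model {model_id!r}")
        model = by_id[model_id]
        if isinstance(scenario, dict):
            missing = frozenset(scenario.get("missing", ()))
            rescue = frozenset(scenario.get("rescue", ()))
        else:
            missing, rescue = frozenset(scenario), frozenset()
        bad = (missing | rescue) - model.mandatory_genes
        if bad:
            raise ValidationError(f"{model_id}: scenario roles {sorted(bad)} unknown")
        detected = model.mandatory_genes - missing
        ranks = tuple(range(next_rank, next_rank + max(len(detected), 1)))
        next_rank = ranks[-1] + 20
        detections.append(
            DetectionRecord(
                genome_id=spec.genome_id,
                model_id=model_id,
                detected_roles=detected,
                source="scan",
                cluster_gene_ranks=ranks,
            )
        )
        if rescue:
            rescue_hits[model_id] = rescue
    return detections, rescue_hits


def generate_cazyme_counts(spec: SyntheticGenomeSpec) -> CazymeCounts:
    """Poisson family counts around the spec's per-family means."""
    rng = derive_rng(spec.seed, spec.genome_id + "/cazymes")
    counts = {
        fam: int(rng.poisson(float(mean)))
        for fam, mean in sorted(spec.cazyme_profile.items())
    }
    return CazymeCounts(spec.genome_id, counts)


def synthetic_reference_densities(
    seed: int = 0, n: int = 150, median: float = 51.4, spread: float = 18.0
) -> list:
    """A synthetic stand-in for an external reference density distribution.

    Normal draws re-centred so the sample median equals ``median`` exactly;
    clipped at 1 per Mb.  Labelled synthetic: it emulates only the location
    of a curated reference distribution, not its shape.
    """
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    draws = rng.normal(median, spread, size=n)
    draws = draws - np.median(draws) + median
    return np.clip(draws, 1.0, None).tolist()


# ---------------------------------------------------------------------------
# Fixture writers (the dialects annotation_io / cazymes read)

EGGNOG_HEADER = [
    "#query",
    "seed_ortholog",
    "evalue",
    "score",
    "eggNOG_OGs",
    "max_annot_lvl",
    "COG_category",
    "Description",
    "Preferred_name",
    "GOs",
    "EC",
    "KEGG_ko",
]


def write_eggnog_file(table: AnnotationTable, path) -> None:
    """Write a table in the eggNOG-mapper ``.annotations`` dialect."""
    with open(path, "w") as fh:
        fh.write("## synthetic annotation fixture\n")
        fh.write("\t".join(EGGNOG_HEADER) + "\n")
        for r in sorted(table.rows, key=lambda r: r.rank):
            ogs = ",".join(f"{c}@1|root" for c in sorted(r.cog_ids)) or "-"
            cats = "".join(sorted(r.cog_categories)) or "-"
            ko = f"ko:{r.ko_id}" if r.ko_id else "-"
            fh.write(
                "\t".join(
                    [
                        r.gene_id,
                        "seed",
                        "1e-50",
                        "200.0",
                        ogs,
                        "2|Bacteria",
                        cats,
                        r.product or "-",
                        "-",
                        "-",
                        "-",
                        ko,
                    ]
                )
                + "\n"
            )


def write_ko_file(table: AnnotationTable, path) -> None:
    """Write a two-column gene → KO TSV (BlastKOALA dialect)."""
    with open(path, "w") as fh:
        for r in sorted(table.rows, key=lambda r: r.rank):
            fh.write(f"{r.gene_id}\t{r.ko_id or ''}\n")


def write_dbcan_overview(counts: CazymeCounts, path) -> None:
    """Write family counts as a dbCAN overview-style table (one gene/row)."""
    with open(path, "w") as fh:
        fh.write("Gene ID\tHMMER\tdbCAN_sub\tDIAMOND\t#ofTools\n")
        i = 0
        for fam in sorted(counts.counts):
            for _ in range(counts.counts[fam]):
                fh.write(f"{counts.genome_id}_cz{i:04d}\t{fam}\t{fam}\t{fam}\t3\n")
                i += 1


def write_similarity_matrix(ids: list, matrix: np.ndarray, path) -> None:
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(path, sep="\t")
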