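"""Orchestration: run every stage over a genome cohort into GenomeProfile reports.

The pipeline config is a YAML file naming the genomes (id, size, ORF total,
annotation file paths) and, optionally, the resource files each stage needs
(landmarks, SAP config, transporter definitions, panels, machinery models,
polymer map, ANI/dDDH matrices).  Stages with missing inputs are skipped
with a recorded reason rather than failing the whole run.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path

import yaml

from . import annotation_io, cazymes, cog_profile, machinery, panels as panels_mod
from . import species as species_mod
from . import transporters as transporters_mod
from . import trophic as trophic_mod
from .model import ValidationError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"


def default_data_path(name: str) -> Path:
    """Path of a config file shipped with the package."""
    return Path(resources.files("ecoprofile").joinpath("data", name))


def _skip(reason: str) -> dict:
    return {"skipped": True, "reason": reason}


def run_profile(config_path, out_dir=None) -> dict:
    """Run all stages over the cohort described by a pipeline YAML config.

    Returns {"profiles": [GenomeProfile dicts], "cohort": {...}} and, when
    ``out_dir`` is given, writes profiles as JSON plus cohort-level TSV
    matrices there.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not cfg.get("genomes"):
        raise ValidationError(f"{config_path}: config names no genomes")
    base = config_path.parent

    def respath(key, default_name=None):
        if key in cfg:
            p = Path(cfg[key])
            return p if p.is_absolute() else base / p
        if default_name is not None:
            return default_data_path(default_name)
        return None

    genomes = annotation_io.load_genome_config(config_path)
    tables = {}
    for rec, paths in genomes:
        table = None
        if "eggnog" in paths:
            table = annotation_io.read_eggnog_table(base / paths["eggnog"], rec.genome_id)
        if "ko" in paths:
            ko = annotation_io.read_ko_table(base / paths["ko"], rec.genome_id)
            table = ko if table is None else annotation_io.merge_annotation_tables(table, ko)
        if table is None:
            raise ValidationError(
                f"genome {rec.genome_id!r}: needs at least one annotation input"
            )
        tables[rec.genome_id] = table
    records = {rec.genome_id: rec for rec, _ in genomes}
    ordered = [rec.genome_id for rec, _ in genomes]

    profiles = {
        gid: {"schema_version": SCHEMA_VERSION, "genome_id": gid} for gid in ordered
    }
    cohort: dict = {"schema_version": SCHEMA_VERSION, "n_genomes": len(ordered)}

    # --- COG counts / Z / CV -------------------------------------------------
    counts = cog_profile.count_cog_categories(list(tables.values()))
    for gid in ordered:
        profiles[gid]["cog_counts"] = counts.counts.loc[gid].to_dict()
    if len(ordered) >= 2:
        z = cog_profile.zscore_matrix(counts)
        cv = cog_profile.cv_banding(counts)
        for gid in ordered:
            profiles[gid]["cog_zscores"] = z.loc[gid].round(6).to_dict()
        cohort["cv_bands"] = cv["band"].to_dict()
    else:
        for gid in ordered:
            profiles[gid]["cog_zscores"] = _skip("requires >= 2 genomes")
        cohort["cv_bands"] = _skip("requires >= 2 genomes")

    # --- trophic scoring -----------------------------------------------------
    lm_path = respath("landmarks")
    if lm_path is None:
        for gid in ordered:
            profiles[gid]["trophic"] = _skip("no landmarks file configured")
        cohort["trophic_mean"] = _skip("no landmarks file configured")
    else:
        landmarks = trophic_mod.TrophicLandmarkSet.from_yaml(lm_path)
        usable = trophic_mod.TrophicLandmarkSet(
            {k: e for k, e in landmarks.entries.items() if e.has_values}
        )
        if not len(usable):
            reason = "landmark file has only placeholder values"
            for gid in ordered:
                profiles[gid]["trophic"] = _skip(reason)
            cohort["trophic_mean"] = _skip(reason)
        else:
            lmc = trophic_mod.count_landmark_categories(list(tables.values()), usable)
            unit = cfg.get("normalization_unit", "per_mb")
            normalized = trophic_mod.normalize_category_counts(
                lmc, list(records.values()), unit=unit
            )
            for gid in ordered:
                calls = [
                    trophic_mod.call_trophic_category(
                        normalized.loc[gid, cat], e, genome_id=gid
                    )
                    for cat, e in usable.entries.items()
                ]
                s = trophic_mod.summarize_trophic(calls, genome_id=gid)
                profiles[gid]["trophic"] = {
                    "unit": unit,
                    "calls": {c.category_id: c.call for c in calls},
                    "n_copiotroph": s.n_copiotroph,
                    "n_oligotroph": s.n_oligotroph,
                    "n_indeterminate": s.n_indeterminate,
                    "overall_label": s.overall_label,
                }
            mean_norm = trophic_mod.mean_profile(normalized)
            mean_calls = [
                trophic_mod.call_trophic_category(
                    mean_norm.iloc[0][cat], e, genome_id="mean-of-genomes"
                )
                for cat, e in usable.entries.items()
            ]
            ms = trophic_mod.summarize_trophic(mean_calls, genome_id="mean-of-genomes")
            cohort["trophic_mean"] = {
                "n_copiotroph": ms.n_copiotroph,
                "n_oligotroph": ms.n_oligotroph,
                "n_indeterminate": ms.n_indeterminate,
                "overall_label": ms.overall_label,
            }

    # --- SAP -----------------------------------------------------------------
    sap_path = respath("sap", "sap_config.yaml")
    sap_cfg = trophic_mod.SAPConfig.from_yaml(sap_path)
    for gid in ordered:
        rec = records[gid]
        if rec.total_orfs <= 0:
            profiles[gid]["sap"] = _skip("total_orfs not provided")
            continue
        r = trophic_mod.compute_sap(tables[gid], rec, sap_cfg)
        profiles[gid]["sap"] = {"S": r.S, "A": r.A, "sap": r.sap}

    # --- transporters --------------------------------------------------------
    defs = transporters_mod.load_transporter_defs(
        respath("transporters", "transporter_defs.yaml")
    )
    all_completeness = []
    for gid in ordered:
        comp = transporters_mod.assess_all(tables[gid], defs)
        all_completeness.extend(comp)
        caps = transporters_mod.infer_sugar_capabilities(comp, defs).get(
            gid, {"ABC": set(), "PTS": set()}
        )
        profiles[gid]["transporters"] = {
            "systems": {
                c.system_id: {
                    "status": c.status,
                    "missing_roles": sorted(c.missing_roles),
                }
                for c in comp
            },
            "abc_sugars": sorted(caps["ABC"]),
            "pts_sugars": sorted(caps["PTS"]),
        }
    tallies = transporters_mod.tally_sugar_transporter_genes(all_completeness, defs)
    for gid in ordered:
        profiles[gid]["transporters"]["sugar_gene_tally"] = tallies.get(
            gid, {"ABC": 0, "PTS": 0, "total": 0}
        )

    # --- trait panels --------------------------------------------------------
    panel_defs = panels_mod.load_panels(respath("panels", "panels.yaml"))
    ox_markers = panels_mod.load_complex_markers(respath("oxidative", "oxidative.yaml"))
    for gid in ordered:
        results = {}
        for p in panel_defs:
            r = panels_mod.screen_panel(tables[gid], p)
            results[p.panel_id] = {
                "marker_copies": r.marker_copies,
                "subsystem_complete": r.subsystem_complete,
                "verdict": r.verdict,
            }
        ox = panels_mod.oxidative_profile(tables[gid], ox_markers)
        results["oxidative"] = {
            "marker_copies": ox.marker_copies,
            "microaerophile_flag": ox.verdict,
        }
        profiles[gid]["panels"] = results

    # --- machineries ---------------------------------------------------------
    models = machinery.load_machinery_models(
        respath("machinery_models", "machinery_models.yaml")
    )
    model_by_id = {m.model_id: m for m in models}
    statuses = []
    any_detections = False
    for rec, paths in genomes:
        if "detections" not in paths:
            profiles[rec.genome_id]["machineries"] = _skip("no detection table configured")
            continue
        any_detections = True
        dets = machinery.read_detection_table(base / paths["detections"])
        groups: dict = {}
        for d in dets:
            groups.setdefault((d.model_id, d.copy_index), []).append(d)
        g_statuses = []
        for (model_id, _copy), group in sorted(groups.items()):
            if model_id not in model_by_id:
                logger.warning("skipping detections for unknown model %s", model_id)
                continue
            g_statuses.append(machinery.adjudicate(group, model_by_id[model_id]))
        statuses.extend(g_statuses)
        profiles[rec.genome_id]["machineries"] = {
            f"{s.model_id}[{s.copy_index}]": {
                "status": s.status,
                "code": s.provenance_code,
                "missing_roles": sorted(s.missing_roles),
            }
            for s in g_statuses
        }
    if any_detections and statuses:
        cohort["machinery_matrix"] = machinery.summarize_machineries(
            statuses, models
        ).to_dict()

    # --- CAZymes -------------------------------------------------------------
    polymer_map = cazymes.load_polymer_map(respath("polymer_map", "polymer_map.yaml"))
    for rec, paths in genomes:
        if "dbcan" not in paths:
            profiles[rec.genome_id]["cazymes"] = _skip("no dbCAN overview configured")
            continue
        cz = cazymes.read_dbcan_overview(base / paths["dbcan"], rec.genome_id)
        prof = cazymes.polymer_profile(cz, polymer_map)
        profiles[rec.genome_id]["cazymes"] = {
            "family_counts": cz.counts,
            "polymer_totals": prof["totals"],
        }

    # --- species delineation -------------------------------------------------
    ani_path, dddh_path = respath("ani"), respath("dddh")
    if ani_path is None or dddh_path is None:
        for gid in ordered:
            profiles[gid]["species_cluster"] = _skip("no ANI/dDDH matrices configured")
    else:
        matrices = annotation_io.read_similarity_matrices(ani_path, dddh_path)
        dcfg = species_mod.DelineationConfig(
            ani_threshold=float(cfg.get("ani_threshold", 95.0)),
            dddh_threshold=float(cfg.get("dddh_threshold", 70.0)),
        )
        clusters = species_mod.delineate(matrices, dcfg)
        member = species_mod.membership_frame(clusters).set_index("genome")["cluster"]
        for gid in ordered:
            profiles[gid]["species_cluster"] = (
                int(member[gid]) if gid in member.index else _skip("not in matrices")
            )
        cohort["species_clusters"] = [sorted(c) for c in clusters.clusters]
        cohort["species_thresholds"] = {
            "ani": dcfg.ani_threshold,
            "dddh": dcfg.dddh_threshold,
        }

    result = {"profiles": [profiles[gid] for gid in ordered], "cohort": cohort}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for gid in ordered:
            with open(out / f"{gid}.profile.json", "w") as fh:
                json.dump(profiles[gid], fh, indent=2, sort_keys=True, default=str)
        with open(out / "cohort.json", "w") as fh:
            json.dump(cohort, fh, indent=2, sort_keys=True, default=str)
        counts.counts.to_csv(out / "cog_counts.tsv", sep="\t")
    return result
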