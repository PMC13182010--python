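"""Synthetic-data generators: determinism, planted-structure recovery."""

import numpy as np
import pytest

from ecoprofile import machinery, species, synthetic, trophic
from ecoprofile.model import ValidationError


def score_archetype(archetype, seed, landmarks):
    spec = synthetic.SyntheticGenomeSpec("g", archetype=archetype, seed=seed)
    table = synthetic.generate_annotation(spec, landmarks)
    rec = synthetic.genome_record_for(spec, table)
    counts = trophic.count_landmark_categories([table], landmarks)
    normalized = trophic.normalize_category_counts(counts, [rec], unit="per_mb")
    calls = trophic.score_genomes(normalized, landmarks)
    return trophic.summarize_trophic(calls, "g")


class TestLandmarks:
    def test_default_set_shape(self, landmarks):
        assert len(landmarks) == 33
        dirs = [e.direction for e in landmarks]
        assert dirs.count("+") == 14 and dirs.count("-") == 19
        assert all(e.has_values for e in landmarks)

    def test_template_file_loads_with_placeholders(self):
        from ecoprofile.pipeline import default_data_path

        tpl = trophic.TrophicLandmarkSet.from_yaml(
            default_data_path("landmarks_template.yaml")
        )
        assert len(tpl) == 33
        assert all(not e.has_values for e in tpl)


class TestGenerateAnnotation:
    def test_deterministic_under_fixed_seed(self, landmarks):
        spec = synthetic.SyntheticGenomeSpec("g", archetype="moderate", seed=5)
        t1 = synthetic.generate_annotation(spec, landmarks)
        t2 = synthetic.generate_annotation(spec, landmarks)
        assert t1.rows == t2.rows

    def test_other_genomes_unperturbed_by_additions(self, landmarks):
        a = synthetic.SyntheticGenomeSpec("a", seed=5)
        t_alone = synthetic.generate_annotation(a, landmarks)
        # generating another genome with the same seed does not change "a"
        b = synthetic.SyntheticGenomeSpec("b", seed=5)
        synthetic.generate_annotation(b, landmarks)
        t_again = synthetic.generate_annotation(a, landmarks)
        assert t_alone.rows == t_again.rows

    def test_copiotroph_archetype_recovered(self, landmarks):
        s = score_archetype("copiotroph", 1, landmarks)
        assert s.n_copiotroph >= 0.9 * 33

    def test_oligotroph_archetype_recovered(self, landmarks):
        s = score_archetype("oligotroph", 1, landmarks)
        assert s.n_oligotroph >= 0.9 * 33

    def test_moderate_archetype_gets_moderate_label(self, landmarks):
        s = score_archetype("moderate", 1, landmarks)
        assert s.overall_label == "moderate copiotroph"
        assert 0 < s.n_copiotroph < 33

    def test_custom_without_means_rejected(self):
        with pytest.raises(ValidationError):
            synthetic.SyntheticGenomeSpec("g", archetype="custom")

    def test_panel_toggles_all_zero_means_no_panel_hits(self, landmarks, default_panels):
        from ecoprofile import panels as panels_mod

        spec = synthetic.SyntheticGenomeSpec("g", seed=3)
        table = synthetic.generate_annotation(spec, landmarks, panels=default_panels)
        for p in default_panels:
            r = panels_mod.screen_panel(table, p)
            if p.verdict_rule != "report_only":
                assert not r.verdict
            assert all(v == 0 for v in r.marker_copies.values())

    def test_panel_toggle_one_injects_marker(self, landmarks, default_panels):
        from ecoprofile import panels as panels_mod

        spec = synthetic.SyntheticGenomeSpec(
            "g", seed=3,
            panel_toggles={"glycine_betaine_transport": 1.0},
        )
        table = synthetic.generate_annotation(spec, landmarks, panels=default_panels)
        osmo = next(p for p in default_panels if p.panel_id == "osmoadaptation")
        r = panels_mod.screen_panel(table, osmo)
        assert r.subsystem_complete["glycine_betaine_transport"] is True
        assert r.verdict is True


class TestGenerateSimilarity:
    def cohort(self, seed=0, sd=0.1):
        genomes = [synthetic.SyntheticGenomeSpec(f"g{i}", seed=seed) for i in range(5)]
        blocks = [{"members": ["g0", "g1", "g2"], "ani": (98.5, sd), "dddh": (89.0, sd)}]
        return synthetic.SyntheticCohortSpec(genomes, blocks, seed=seed)

    def test_block_recovered_by_delineation(self):
        sm = synthetic.generate_similarity(self.cohort(seed=2))
        out = species.delineate(sm)
        assert out.cluster_of("g0") == frozenset({"g0", "g1", "g2"})
        assert len(out.clusters) == 3

    def test_zero_variance_gives_exact_constants(self):
        sm = synthetic.generate_similarity(self.cohort(seed=2, sd=0.0))
        assert sm.pair("g0", "g1") == (98.5, 89.0)

    def test_singleton_cohort(self):
        c = synthetic.SyntheticCohortSpec(
            [synthetic.SyntheticGenomeSpec("solo")], [], seed=1
        )
        sm = synthetic.generate_similarity(c)
        assert sm.genome_ids == ["solo"] and sm.ani.shape == (1, 1)


class TestGenerateMachineryDetections:
    def test_no_missing_roles_adjudicates_complete(self, machinery_models):
        spec = synthetic.SyntheticGenomeSpec(
            "g", machinery_scenarios={"T2SS": set()}
        )
        dets, rescue = synthetic.generate_machinery_detections(spec, machinery_models)
        model = next(m for m in machinery_models if m.model_id == "T2SS")
        s = machinery.adjudicate(dets, model)
        assert s.status == "complete_scan_confirmed" and s.provenance_code == "a"
        assert rescue == {}

    def test_six_of_thirteen_missing_highly_incomplete(self, machinery_models):
        model = next(m for m in machinery_models if m.model_id == "T2SS")
        missing = set(sorted(model.mandatory_genes)[:6])
        spec = synthetic.SyntheticGenomeSpec("g", machinery_scenarios={"T2SS": missing})
        dets, _ = synthetic.generate_machinery_detections(spec, machinery_models)
        s = machinery.adjudicate(dets, model)
        assert s.status == "highly_incomplete" and s.provenance_code == "b"

    def test_rescued_role_completes(self, machinery_models):
        model = next(m for m in machinery_models if m.model_id == "T2SS")
        role = sorted(model.mandatory_genes)[0]
        spec = synthetic.SyntheticGenomeSpec(
            "g", machinery_scenarios={"T2SS": {"missing": {role}, "rescue": {role}}}
        )
        dets, rescue = synthetic.generate_machinery_detections(spec, machinery_models)
        s = machinery.adjudicate(dets, model, rescue_hits=rescue["T2SS"])
        assert s.status == "complete_after_rescue"


class TestReferenceDensities:
    def test_median_and_size(self):
        ref = synthetic.synthetic_reference_densities(seed=0, n=150)
        assert len(ref) == 150
        assert float(np.median(ref)) == pytest.approx(51.4, abs=1e-9)

    def test_deterministic(self):
        assert synthetic.synthetic_reference_densities(seed=9) == \
            synthetic.synthetic_reference_densities(seed=9)
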