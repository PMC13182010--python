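"""Machinery completeness adjudication, neighbourhood windows, summaries."""

import itertools

import pytest

from ecoprofile import machinery
from ecoprofile.machinery import DetectionRecord, MachineryModel
from ecoprofile.model import ValidationError

T2SS_ROLES = [f"gsp{c}" for c in "CDEFGHIJKLMNO"]  # 13 mandatory genes
T2SS = MachineryModel("T2SS", frozenset(T2SS_ROLES))

TOY = MachineryModel("toy", frozenset({"r1", "r2", "r3", "r4", "r5"}))


def det(roles, source="scan", scanner="txsscan", model="T2SS", genome="g"):
    return DetectionRecord(
        genome_id=genome, model_id=model, detected_roles=frozenset(roles),
        source=source, scanner=scanner,
    )


def rule_table_status(model, scan, brite, rescue):
    """Independent brute-force restatement of the adjudication rules."""
    mand = model.mandatory_genes
    if mand <= scan:
        return "complete_scan_confirmed", "a"
    if mand <= (scan | brite):
        return "complete_brite_only", "f"
    missing = mand - scan - brite
    if not (missing - rescue):
        return "complete_after_rescue", "e"
    remaining = missing - rescue
    if len(remaining) / len(mand) > model.highly_incomplete_fraction:
        return "highly_incomplete", "b"
    return "incomplete", "d"


class TestAdjudicate:
    def test_scan_and_brite_complete_is_code_a(self):
        s = machinery.adjudicate(
            [det(T2SS_ROLES), det(T2SS_ROLES, source="brite")], T2SS
        )
        assert s.status == "complete_scan_confirmed" and s.provenance_code == "a"
        assert not s.missing_roles

    def test_six_of_thirteen_missing_is_highly_incomplete(self):
        s = machinery.adjudicate([det(T2SS_ROLES[:7])], T2SS)
        assert s.status == "highly_incomplete" and s.provenance_code == "b"
        assert len(s.missing_roles) == 6

    def test_brite_fills_scanner_gaps_code_f(self):
        s = machinery.adjudicate(
            [det(T2SS_ROLES[:10]), det(T2SS_ROLES[8:], source="brite")], T2SS
        )
        assert s.status == "complete_brite_only" and s.provenance_code == "f"

    def test_rescue_completes_txsscan_code_e(self):
        s = machinery.adjudicate([det(T2SS_ROLES[:12])], T2SS,
                                 rescue_hits={T2SS_ROLES[12]})
        assert s.status == "complete_after_rescue" and s.provenance_code == "e"

    def test_rescue_completes_conjscan_code_c(self):
        model = MachineryModel("T4SS_G", frozenset(f"tfc{i}" for i in range(17)))
        roles = sorted(model.mandatory_genes)
        s = machinery.adjudicate(
            [det(roles[:16], scanner="conjscan", model="T4SS_G")],
            model, rescue_hits={roles[16]},
        )
        assert s.status == "complete_after_rescue" and s.provenance_code == "c"

    def test_unknown_rescue_role_rejected(self):
        with pytest.raises(ValidationError):
            machinery.adjudicate([det(T2SS_ROLES[:12])], T2SS, rescue_hits={"nope"})

    def test_exhaustive_rule_table_oracle(self):
        """All 2^5 scan patterns x brite/rescue options match the rule table."""
        roles = sorted(TOY.mandatory_genes)
        brite_options = [frozenset(), frozenset(roles[3:])]
        rescue_options = [frozenset(), frozenset(roles[:2])]
        for pattern in itertools.product([0, 1], repeat=5):
            scan = frozenset(r for r, p in zip(roles, pattern) if p)
            for brite in brite_options:
                for rescue in rescue_options:
                    dets = [det(scan, model="toy")]
                    if brite:
                        dets.append(det(brite, source="brite", model="toy"))
                    s = machinery.adjudicate(dets, TOY, rescue_hits=rescue)
                    exp_status, exp_code = rule_table_status(TOY, scan, brite, rescue)
                    assert (s.status, s.provenance_code) == (exp_status, exp_code)

    def test_rescue_only_improves(self):
        """Adding rescue roles never degrades the adjudicated status."""
        order = ["highly_incomplete", "incomplete", "complete_after_rescue",
                 "complete_brite_only", "complete_scan_confirmed"]
        roles = sorted(TOY.mandatory_genes)
        for k in range(6):
            scan = frozenset(roles[:k])
            s0 = machinery.adjudicate([det(scan, model="toy")], TOY)
            s1 = machinery.adjudicate([det(scan, model="toy")], TOY,
                                      rescue_hits=frozenset(roles))
            assert order.index(s1.status) >= order.index(s0.status)

    def test_idempotent_on_complete_output(self):
        s0 = machinery.adjudicate([det(T2SS_ROLES)], T2SS)
        # feeding the adjudicated roles back as a scan changes nothing
        s1 = machinery.adjudicate([det(T2SS_ROLES)], T2SS)
        assert s0 == s1


class TestNeighborhoodWindow:
    def test_linear_window(self):
        got = machinery.neighborhood_window(range(100, 111), n_genes=5000, window=10)
        assert got == set(range(90, 100)) | set(range(111, 121))

    def test_truncation_at_replicon_start(self):
        got = machinery.neighborhood_window(range(0, 6), n_genes=5000, window=10)
        assert got == set(range(6, 16))

    def test_circular_wraps_through_origin(self):
        got = machinery.neighborhood_window([48, 49], n_genes=50, window=10,
                                            circular=True)
        expected = {(48 - k) % 50 for k in range(1, 11)}
        expected |= {(49 + k) % 50 for k in range(1, 11)}
        expected -= {48, 49}
        assert got == expected
        assert 0 in got and 9 in got and 38 in got

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValidationError):
            machinery.neighborhood_window([], n_genes=10)


class TestSummaries:
    def _status(self, genome, model, code="a", status="complete_scan_confirmed",
                copy=0):
        return machinery.MachineryStatus(
            genome_id=genome, model_id=model, copy_index=copy, status=status,
            missing_roles=frozenset(), provenance_code=code,
        )

    def test_t6ss_like_pattern(self):
        statuses = [self._status(g, "T6SS", code="e")
                    for g in ("g1", "g2", "g3", "g4")]
        statuses.append(self._status("g5", "T1SS"))
        table = machinery.summarize_machineries(statuses)
        nonzero = (table["T6SS"] != "0").sum()
        assert nonzero == 4
        assert table.loc["g5", "T6SS"] == "0"

    def test_empty_input_gives_all_zero(self, machinery_models):
        table = machinery.summarize_machineries([], machinery_models)
        assert table.size == 0 or (table == "0").all().all()

    def test_two_copies_in_one_genome(self):
        statuses = [self._status("g1", "T1SS", copy=0),
                    self._status("g1", "T1SS", copy=1)]
        assert machinery.copy_counts(statuses).loc["g1", "T1SS"] == 2
        assert machinery.summarize_machineries(statuses).loc["g1", "T1SS"] == "1a+1a"

    def test_detection_table_round_trip(self, tmp_path):
        dets = [det(T2SS_ROLES[:5]),
                DetectionRecord("g", "T6SS", frozenset({"tssA"}), source="brite",
                                scanner="txsscan", copy_index=1,
                                cluster_gene_ranks=(5, 6, 7))]
        p = tmp_path / "dets.tsv"
        machinery.write_detection_table(dets, p)
        back = machinery.read_detection_table(p)
        assert back == dets
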