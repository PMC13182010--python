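"""Parsing of annotation-tool output dialects and similarity matrices."""

import numpy as np
import pandas as pd
import pytest

from ecoprofile import annotation_io
from ecoprofile.model import FormatError, ValidationError

EGGNOG_HEADER = (
    "#query\tseed_ortholog\tevalue\tscore\teggNOG_OGs\tmax_annot_lvl\t"
    "COG_category\tDescription\tPreferred_name\tGOs\tEC\tKEGG_ko\n"
)


def write_eggnog(path, rows):
    with open(path, "w") as fh:
        fh.write("## comment line\n")
        fh.write(EGGNOG_HEADER)
        for r in rows:
            fh.write("\t".join(r) + "\n")


def eggnog_row(gene, cats="-", ogs="-", ko="-"):
    return [gene, "s", "1e-10", "50", ogs, "2|Bacteria", cats, "-", "-", "-", "-", ko]


class TestEggnogReader:
    def test_empty_data_section_yields_empty_table(self, tmp_path):
        p = tmp_path / "empty.annotations"
        write_eggnog(p, [])
        table = annotation_io.read_eggnog_table(p, "g")
        assert len(table) == 0

    def test_category_strings_split_into_letter_sets(self, tmp_path):
        p = tmp_path / "t.annotations"
        write_eggnog(
            p,
            [
                eggnog_row("a1", cats="G"),
                eggnog_row("a2", cats="GT"),
                eggnog_row("a3", cats="-"),
            ],
        )
        table = annotation_io.read_eggnog_table(p, "g")
        assert [r.cog_categories for r in table] == [
            frozenset("G"),
            frozenset("GT"),
            frozenset(),
        ]
        assert [r.rank for r in table] == [0, 1, 2]

    def test_missing_ko_field_keeps_row_without_ko(self, tmp_path):
        p = tmp_path / "t.annotations"
        write_eggnog(p, [eggnog_row("a1", cats="G", ko="-")])
        table = annotation_io.read_eggnog_table(p, "g")
        assert table.gene("a1").ko_id is None

    def test_cog_ids_and_kos_parsed(self, tmp_path):
        p = tmp_path / "t.annotations"
        write_eggnog(
            p,
            [eggnog_row("a1", cats="G", ogs="COG1263@1|root,2Z7JQ@2|Bacteria",
                        ko="ko:K02777,ko:K02778")],
        )
        r = annotation_io.read_eggnog_table(p, "g").gene("a1")
        assert r.cog_ids == frozenset({"COG1263"})
        assert r.ko_id == "K02777"

    def test_missing_mandatory_column_names_it(self, tmp_path):
        p = tmp_path / "bad.annotations"
        with open(p, "w") as fh:
            fh.write("#query\tDescription\n")
            fh.write("a1\tfoo\n")
        with pytest.raises(FormatError, match="COG_category"):
            annotation_io.read_eggnog_table(p, "g")

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = tmp_path / "dup.annotations"
        write_eggnog(p, [eggnog_row("a1"), eggnog_row("a1")])
        with pytest.raises(ValidationError, match="duplicate"):
            annotation_io.read_eggnog_table(p, "g")

    def test_unrecognised_letters_dropped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "t.annotations"
        write_eggnog(p, [eggnog_row("a1", cats="G#")])
        with caplog.at_level("WARNING"):
            table = annotation_io.read_eggnog_table(p, "g")
        assert table.gene("a1").cog_categories == frozenset("G")
        assert any("unrecognised" in m for m in caplog.messages)


class TestKoReader:
    def test_single_row(self, tmp_path):
        p = tmp_path / "ko.tsv"
        p.write_text("g1\tK03406\n")
        table = annotation_io.read_ko_table(p, "g")
        assert len(table) == 1 and table.gene("g1").ko_id == "K03406"

    def test_blank_ko_retained_without_assignment(self, tmp_path):
        p = tmp_path / "ko.tsv"
        p.write_text("g1\t\n")
        table = annotation_io.read_ko_table(p, "g")
        assert len(table) == 1 and table.gene("g1").ko_id is None

    def test_five_rows_two_blanks(self, tmp_path):
        p = tmp_path / "ko.tsv"
        p.write_text(
            "g1\tK00001\ng2\t\ng3\tK00002\ng4\t\ng5\tK00003\n"
        )
        table = annotation_io.read_ko_table(p, "g")
        assert len(table) == 5
        assert sum(1 for r in table if r.ko_id) == 3

    def test_malformed_ko_token_listed(self, tmp_path):
        p = tmp_path / "ko.tsv"
        p.write_text("g1\tK123\ng2\tfoo\n")
        with pytest.raises(ValidationError, match="malformed KO"):
            annotation_io.read_ko_table(p, "g")


class TestSimilarityMatrices:
    def _write(self, path, ids, m):
        pd.DataFrame(m, index=ids, columns=ids).to_csv(path, sep="\t")

    def test_singleton_matrix(self, tmp_path):
        a, d = tmp_path / "a.tsv", tmp_path / "d.tsv"
        self._write(a, ["x"], [[100.0]])
        self._write(d, ["x"], [[100.0]])
        sm = annotation_io.read_similarity_matrices(a, d)
        assert sm.genome_ids == ["x"] and sm.ani[0, 0] == 100.0

    def test_asymmetric_pair_mean_symmetrized(self, tmp_path):
        a, d = tmp_path / "a.tsv", tmp_path / "d.tsv"
        self._write(a, ["x", "y"], [[100, 98.4], [98.6, 100]])
        self._write(d, ["x", "y"], [[100, 70], [70, 100]])
        sm = annotation_io.read_similarity_matrices(a, d)
        assert sm.ani[0, 1] == pytest.approx(98.5)
        assert sm.ani[1, 0] == pytest.approx(98.5)

    def test_permuted_labels_aligned_to_ani_order(self, tmp_path):
        a, d = tmp_path / "a.tsv", tmp_path / "d.tsv"
        self._write(a, ["x", "y", "z"],
                    [[100, 90, 80], [90, 100, 85], [80, 85, 100]])
        # dDDH file with rows/cols in a different order
        self._write(d, ["z", "x", "y"],
                    [[100, 20, 30], [20, 100, 25], [30, 25, 100]])
        sm = annotation_io.read_similarity_matrices(a, d)
        assert sm.genome_ids == ["x", "y", "z"]
        # dddh(x, z) must equal the permuted file's value for (z, x) = 20
        assert sm.pair("x", "z")[1] == pytest.approx(20.0)
        assert sm.pair("x", "y")[1] == pytest.approx(25.0)

    def test_label_mismatch_rejected(self, tmp_path):
        a, d = tmp_path / "a.tsv", tmp_path / "d.tsv"
        self._write(a, ["x", "y"], [[100, 90], [90, 100]])
        self._write(d, ["x", "w"], [[100, 20], [20, 100]])
        with pytest.raises(ValidationError, match="label"):
            annotation_io.read_similarity_matrices(a, d)

    def test_out_of_range_entries_rejected(self, tmp_path):
        a, d = tmp_path / "a.tsv", tmp_path / "d.tsv"
        self._write(a, ["x", "y"], [[100, 101], [101, 100]])
        self._write(d, ["x", "y"], [[100, 20], [20, 100]])
        with pytest.raises(ValidationError, match=r"\[0, 100\]"):
            annotation_io.read_similarity_matrices(a, d)


class TestCanonicalRoundTrip:
    def test_round_trip_exact(self, tmp_path):
        from tests.conftest import make_table

        table = make_table(
            "g",
            [
                ("a1", {"cog_categories": "GT", "cog_ids": {"COG1263"},
                        "ko_id": "K02777", "product": "PTS IIC"}),
                ("a2", {}),
            ],
        )
        p = tmp_path / "canon.tsv"
        annotation_io.write_annotation_table(table, p)
        back = annotation_io.read_annotation_table(p, "g")
        assert back.rows == table.rows

    def test_ko_merge_order_independent(self, tmp_path):
        p = tmp_path / "t.annotations"
        write_eggnog(p, [eggnog_row("a1", cats="G"), eggnog_row("a2", cats="T")])
        k = tmp_path / "ko.tsv"
        k.write_text("a1\tK00001\na3\tK00002\n")
        cog = annotation_io.read_eggnog_table(p, "g")
        ko = annotation_io.read_ko_table(k, "g")
        merged = annotation_io.merge_annotation_tables(cog, ko)
        assert merged.gene("a1").ko_id == "K00001"
        assert merged.gene("a1").cog_categories == frozenset("G")
        assert merged.gene("a3").ko_id == "K00002"  # KO-only gene appended
        assert len(merged) == 3
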