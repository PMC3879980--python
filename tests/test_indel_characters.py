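"""Alignment reading, indel calling, character-matrix assembly."""

import pytest

from ringroot import datasets
from ringroot.indel_characters import (
    AlignmentBlock,
    SeqLabel,
    build_character_matrix,
    call_indels,
    indel_calls_to_tsv,
    read_alignment,
    read_label_table,
)


def _mini_block(rows: dict[str, str], groups: dict[str, str] | None = None) -> AlignmentBlock:
    labels = {
        sid: SeqLabel(seq_id=sid, taxon=sid, supergroup=(groups or {}).get(sid, sid),
                      gene="g")
        for sid in rows
    }
    return AlignmentBlock(sequences=rows, labels=labels)


class TestReadAlignment:
    def _write(self, tmp_path, fasta, labels):
        fa = tmp_path / "aln.fasta"
        fa.write_text(fasta)
        tsv = tmp_path / "labels.tsv"
        tsv.write_text("seq_id\ttaxon\tsupergroup\tgene\tpresent\n" + labels)
        return fa, tsv

    def test_reads_block_with_absences(self, tmp_path):
        fa, tsv = self._write(
            tmp_path,
            ">s1\nMKV-AL\n>s2\nMKVRAL\n",
            "s1\tt1\tA\tg\t1\ns2\tt2\tD\tg\t1\nabs1\tt3\tH\tg\t0\n",
        )
        block = read_alignment(fa, read_label_table(tsv))
        assert block.n_columns == 6
        assert [l.supergroup for l in block.absences] == ["H"]

    def test_empty_file_rejected(self, tmp_path):
        fa = tmp_path / "empty.fasta"
        fa.write_text("")
        with pytest.raises(ValueError, match="no sequences"):
            read_alignment(fa, [])

    def test_ragged_rows_rejected(self, tmp_path):
        fa, tsv = self._write(
            tmp_path, ">s1\nMKVAL\n>s2\nMK\n", "s1\tt1\tA\tg\t1\ns2\tt2\tD\tg\t1\n"
        )
        with pytest.raises(ValueError, match="ragged"):
            read_alignment(fa, read_label_table(tsv))

    def test_unknown_symbols_rejected(self, tmp_path):
        fa, tsv = self._write(tmp_path, ">s1\nMKO@L\n", "s1\tt1\tA\tg\t1\n")
        with pytest.raises(ValueError, match="unknown symbols"):
            read_alignment(fa, read_label_table(tsv))

    def test_unlabelled_sequence_rejected(self, tmp_path):
        fa, tsv = self._write(tmp_path, ">s1\nMKVAL\n", "other\tt1\tA\tg\t1\n")
        with pytest.raises(ValueError, match="missing from the label"):
            read_alignment(fa, read_label_table(tsv))

    def test_duplicate_labels_rejected(self, tmp_path):
        fa, tsv = self._write(
            tmp_path, ">s1\nMKVAL\n", "s1\tt1\tA\tg\t1\ns1\tt1\tA\tg\t1\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_label_table(tsv)


class TestCallIndels:
    def test_packaged_parc_gyra_block_has_one_width4_indel(self):
        block = datasets.parc_gyra_block()
        calls = call_indels(block, min_width=2, purity=1.0)
        assert len(calls) == 1
        call = calls[0]
        assert call.width == 4
        assert call.residue_rows == frozenset({"GyrA_Actino"})
        assert call.residue_groups == frozenset({"A"})
        assert len(call.gap_rows) == 10

    def test_gap_free_alignment_yields_nothing(self):
        block = _mini_block({"a": "MKVAL", "b": "MKVAL"})
        assert call_indels(block) == []

    def test_planted_block_recovered_with_groups(self):
        rows = {
            "h": "MKVAL------QRST",
            "e": "MKVAL------QRST",
            "a": "MKVALDEDEDEQRST",
            "d": "MKVALDEDEDEQRST",
        }
        calls = call_indels(_mini_block(rows, {"h": "H", "e": "E", "a": "A", "d": "D"}))
        assert len(calls) == 1
        assert calls[0].width == 6
        assert calls[0].gap_groups == frozenset({"H", "E"})
        assert (calls[0].start, calls[0].end) == (5, 11)

    def test_min_width_suppresses_single_columns(self):
        rows = {"a": "MK-AL", "b": "MKVAL"}
        assert call_indels(_mini_block(rows), min_width=2) == []
        assert len(call_indels(_mini_block(rows), min_width=1)) == 1

    def test_maximality_at_full_purity(self):
        """Each reported range is exactly uniform; widening breaks it."""
        block = datasets.parc_gyra_block()
        call = call_indels(block)[0]
        for col in range(call.start, call.end):
            for row in call.gap_rows:
                assert block.sequences[row][col] == "-"
            for row in call.residue_rows:
                assert block.sequences[row][col] != "-"
        for col in (call.start - 1, call.end):
            if 0 <= col < block.n_columns:
                gaps = {r for r in block.row_ids if block.sequences[r][col] == "-"}
                assert gaps != call.gap_rows

    def test_row_order_independence(self):
        block = datasets.parc_gyra_block()
        reordered = AlignmentBlock(
            sequences=dict(reversed(list(block.sequences.items()))),
            labels=block.labels,
            absences=block.absences,
        )
        assert call_indels(block) == call_indels(reordered)

    def test_purity_below_one_tolerates_a_noisy_cell(self):
        rows = {
            "a": "MKVAL--------QR",
            "b": "MKVAL---A----QR",  # one stray residue inside the gap block
            "c": "MKVALDEDEDEDEQR",
        }
        strict = call_indels(_mini_block(rows), min_width=3, purity=1.0)
        assert not any(c.width >= 8 for c in strict)
        loose = call_indels(_mini_block(rows), min_width=3, purity=0.85)
        assert len(loose) == 1
        assert loose[0].gap_rows == frozenset({"a", "b"})

    def test_parameter_validation(self):
        block = _mini_block({"a": "MK-AL", "b": "MKVAL"})
        with pytest.raises(ValueError):
            call_indels(block, min_width=0)
        with pytest.raises(ValueError):
            call_indels(block, purity=0.4)

    def test_calls_tsv_output(self, tmp_path):
        calls = call_indels(datasets.parc_gyra_block())
        path = tmp_path / "calls.tsv"
        indel_calls_to_tsv(calls, path)
        lines = path.read_text().strip().split("\n")
        assert lines[0].startswith("start\tend\twidth")
        assert lines[1].split("\t")[:3] == ["36", "40", "4"]


class TestBuildCharacterMatrix:
    def test_fixture_pipeline_yields_published_distributions(self):
        m = datasets.paralog_character_matrix()
        rows = {c: m.presence(c) for c in m.characters}
        assert rows["ParC"] == {"A": 1, "D": 1, "B": 1, "C": 1, "E": 0, "H": 0}
        assert rows["GGGPS"] == {"A": 0, "D": 0, "B": 1, "C": 1, "E": 1, "H": 1}
        assert all(v == 1 for v in rows["GyrA"].values())
        assert all(v == 1 for v in rows["HisF"].values())

    def test_indel_rows_added_unpolarized(self):
        m = datasets.paralog_character_matrix(include_indels=True)
        indel_rows = [c for c in m.characters if "indel" in c]
        assert len(indel_rows) == 1
        row = m.presence(indel_rows[0])
        assert row == {"A": 1, "D": 0, "B": 0, "C": 0, "E": 0, "H": 0}

    def test_single_block_no_indels(self):
        block = datasets.gggps_hisf_block()
        m = build_character_matrix(
            [block], None, datasets.SIX_TAXA, expand=datasets.TABLE12_EXPAND
        )
        assert sorted(m.characters) == ["GGGPS", "HisF"]

    def test_unknown_supergroup_rejected(self):
        block = _mini_block({"s": "MKVAL"}, {"s": "Z"})
        with pytest.raises(ValueError, match="not in the declared"):
            build_character_matrix([block], None, ("A", "D"))

    def test_planted_simulation_roundtrip(self):
        """Characters planted by the generator come back out of the caller."""
        from ringroot.synthetic_data import default_config, simulate_alignment

        cfg = default_config(seed=21)
        char = {"A": 0, "D": 1, "F": 1, "H": 1, "E": 1}
        seqs, truth = simulate_alignment(char, cfg, width=4)
        block = _mini_block(seqs)
        calls = call_indels(block, min_width=2, purity=1.0)
        spans = [(c.start, c.end) for c in calls]
        assert (truth["start"], truth["end"]) in spans
        matching = [c for c in calls if (c.start, c.end) == (truth["start"], truth["end"])]
        assert matching[0].gap_rows == frozenset(truth["gap_taxa"])
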