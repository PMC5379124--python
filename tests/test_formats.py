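import logging

import pytest

from ltrlayers import formats
from ltrlayers.classify import Element
from ltrlayers.defrag import Candidate
from ltrlayers.formats import (
    Fragment,
    LibraryEntry,
    LibraryFormatError,
    RepeatMaskerParseError,
    parse_library_fasta,
    parse_repeatmasker_out,
    write_gff3,
    write_repeatmasker_out,
)
from ltrlayers.linker import Chain

from conftest import make_candidate, make_fragment


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


class TestParseLibraryFasta:
    def test_basic_entry(self, tmp_path):
        path = tmp_path / "lib.fa"
        write_fasta(path, [("Osr1_IN", "A" * 1000)])
        entries = parse_library_fasta(path)
        assert len(entries) == 1
        e = entries[0]
        assert e.family_id == "Osr1"
        assert e.part == "IN"
        assert e.length == 1000
        assert e.name == "Osr1_IN"

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.fa"
        path.write_text("")
        assert parse_library_fasta(path) == []

    def test_pipe_in_header_rejected(self, tmp_path):
        path = tmp_path / "lib.fa"
        write_fasta(path, [("Osr1|LTR", "ACGT")])
        with pytest.raises(LibraryFormatError, match=r"Osr1\|LTR"):
            parse_library_fasta(path)

    def test_whitespace_in_header_rejected(self, tmp_path):
        path = tmp_path / "lib.fa"
        path.write_text(">Osr1 LTR\nACGT\n")
        with pytest.raises(LibraryFormatError, match="whitespace"):
            parse_library_fasta(path)

    def test_missing_suffix_rejected(self, tmp_path):
        path = tmp_path / "lib.fa"
        write_fasta(path, [("Osr1", "ACGT")])
        with pytest.raises(LibraryFormatError, match="Osr1"):
            parse_library_fasta(path)

    def test_unpaired_family_warns_but_kept(self, tmp_path, caplog):
        path = tmp_path / "lib.fa"
        write_fasta(path, [("Osr1_LTR", "ACGT"), ("Osr1_IN", "ACGT"), ("Osr2_LTR", "ACGT")])
        with caplog.at_level(logging.WARNING):
            entries = parse_library_fasta(path)
        assert len(entries) == 3
        assert "Osr2" in caplog.text
        assert formats.unpaired_families(entries) == ["Osr2"]

    def test_duplicate_entry_rejected_on_index(self):
        entries = [
            LibraryEntry("Osr1", "IN", "ACGT"),
            LibraryEntry("Osr1", "IN", "ACGTA"),
        ]
        with pytest.raises(LibraryFormatError, match="duplicate"):
            formats.library_index(entries)


class TestParseRepeatMaskerOut:
    def test_minimal_plus_record(self, tmp_path):
        path = tmp_path / "rm.out"
        frag = make_fragment(1001, 1500, "Osr1", "IN", 1, 500, score=1200.0)
        write_repeatmasker_out([frag], path)
        parsed = parse_repeatmasker_out(path)
        assert parsed == [frag]

    def test_header_only(self, tmp_path):
        path = tmp_path / "rm.out"
        write_repeatmasker_out([], path)
        assert parse_repeatmasker_out(path) == []

    def test_c_strand_normalization(self, tmp_path):
        # C-strand repeat columns arrive as (left) end begin
        path = tmp_path / "rm.out"
        path.write_text(
            "  1200  2.0  0.0  0.0  chr1  5001  5300 (1000) C Osr1_LTR "
            "LTR/unknown (0)    300      1 1\n"
        )
        (frag,) = parse_repeatmasker_out(path)
        assert frag.strand == "-"
        assert (frag.c_start, frag.c_end) == (1, 300)
        assert (frag.g_start, frag.g_end) == (5001, 5300)

    def test_round_trip_field_by_field(self, tmp_path):
        frags = [
            make_fragment(1001, 1500, "Osr1", "IN", 1, 500, score=900.0, divergence=2.5),
            make_fragment(2001, 2300, "Osr2", "LTR", 1, 300, strand="-", score=640.0),
            make_fragment(100, 350, "FamX", "LTR", 50, 300, strand="-", divergence=12.3),
        ]
        path = tmp_path / "rm.out"
        write_repeatmasker_out(
            frags, path, genome_lengths={"chr1": 10_000},
            consensus_lengths={("Osr1", "IN"): 1000},
        )
        assert parse_repeatmasker_out(path) == frags

    def test_unparseable_record_names_line(self, tmp_path):
        path = tmp_path / "rm.out"
        path.write_text("hdr\n\n1200 2.0 0.0 0.0 chr1 xx 1500\n")
        with pytest.raises(RepeatMaskerParseError, match="line 3"):
            parse_repeatmasker_out(path)

    def test_unsuffixed_repeat_skipped(self, tmp_path, caplog):
        path = tmp_path / "rm.out"
        path.write_text(
            "  1200  2.0  0.0  0.0  chr1  1001  1500 (100) + SINE1 "
            "SINE 1 500 (0) 1\n"
            "  1200  2.0  0.0  0.0  chr1  2001  2500 (100) + Osr1_IN "
            "LTR/unknown 1 500 (500) 2\n"
        )
        with caplog.at_level(logging.WARNING):
            parsed = parse_repeatmasker_out(path)
        assert len(parsed) == 1
        assert parsed[0].family_id == "Osr1"
        assert "SINE1" in caplog.text

    def test_consensus_overrun_reported_not_clamped(self, tmp_path, caplog):
        path = tmp_path / "rm.out"
        frag = make_fragment(1001, 2200, "Osr1", "IN", 1, 1200)
        write_repeatmasker_out([frag], path)
        library = [LibraryEntry("Osr1", "IN", "A" * 1000)]
        with caplog.at_level(logging.WARNING):
            (parsed,) = parse_repeatmasker_out(path, library=library)
        assert parsed.c_end == 1200  # untouched
        assert "exceeds consensus length" in caplog.text


def _element(eid, cands, layer=1, ts="LTR", cat="SoloLTR", host=None):
    chain = Chain(members=cands, contig_id=cands[0].contig_id, strand=cands[0].strand)
    return Element(
        chain=chain, layer=layer, type_string=ts, category=cat,
        element_id=eid, host=host,
    )


def _parse_gff(path):
    features = []
    for line in open(path):
        if line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        attrs = dict(kv.split("=", 1) for kv in cols[8].split(";"))
        features.append((cols[0], cols[2], int(cols[3]), int(cols[4]), attrs))
    return features


class TestWriteGff3:
    def test_empty(self, tmp_path):
        path = tmp_path / "out.gff3"
        write_gff3([], path)
        assert path.read_text() == "##gff-version 3\n"

    def test_nested_parent_attribute(self, tmp_path):
        host = _element("elem_1", [make_candidate(1000, 5000)], ts="LTR-IN-LTR", cat="Normal")
        child = _element(
            "elem_2", [make_candidate(2000, 2400, family="Osr2", part="LTR")],
            layer=2, host=host,
        )
        path = tmp_path / "out.gff3"
        write_gff3([host, child], path)
        feats = _parse_gff(path)
        regions = {a["ID"]: a for _, t, _, _, a in feats if t == "repeat_region"}
        assert regions["elem_2"]["Parent"] == "elem_1"
        assert "Parent" not in regions["elem_1"]
        assert regions["elem_2"]["layer"] == "2"

    def test_round_trip_spans(self, tmp_path):
        elems = [
            _element("elem_1", [make_candidate(100, 400), make_candidate(900, 1300)]),
            _element("elem_2", [make_candidate(5000, 5600)]),
        ]
        path = tmp_path / "out.gff3"
        write_gff3(elems, path)
        feats = _parse_gff(path)
        regions = [(s, e) for _, t, s, e, _ in feats if t == "repeat_region"]
        assert regions == [(100, 1300), (5000, 5600)]
        parts = [(s, e) for _, t, s, e, _ in feats if t == "match_part"]
        assert parts == [(100, 400), (900, 1300), (5000, 5600)]


class TestWriteTypeTables:
    def _summary(self):
        from ltrlayers.classify import summarize

        elems = [
            _element("elem_1", [make_candidate(100, 4000)], 1, "LTR-IN-LTR", "Normal"),
            _element("elem_2", [make_candidate(9000, 9400)], 1, "LTR", "SoloLTR"),
            _element("elem_3", [make_candidate(1500, 1900, family="Osr2")], 2, "LTR", "SoloLTR"),
        ]
        return summarize(elems)

    def test_single_normal(self, tmp_path):
        from ltrlayers.classify import summarize

        summary = summarize(
            [_element("elem_1", [make_candidate(100, 4000)], 1, "LTR-IN-LTR", "Normal")]
        )
        formats.write_type_tables(summary, tmp_path)
        rows = (tmp_path / "type.num.1").read_text().splitlines()
        assert rows == ["type\tcount", "LTR-IN-LTR\t1"]

    def test_layer_files(self, tmp_path):
        formats.write_type_tables(self._summary(), tmp_path)
        assert (tmp_path / "type.num.1").exists()
        assert (tmp_path / "type.num.2").exists()
        assert (tmp_path / "type.all.2").exists()
        assert not (tmp_path / "type.num.3").exists()

    def test_counts_match_rows(self, tmp_path):
        formats.write_type_tables(self._summary(), tmp_path)
        for layer in (1, 2):
            num = (tmp_path / f"type.num.{layer}").read_text().splitlines()[1:]
            total = sum(int(r.split("\t")[1]) for r in num)
            rows = (tmp_path / f"type.all.{layer}").read_text().splitlines()[1:]
            assert total == len(rows)
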