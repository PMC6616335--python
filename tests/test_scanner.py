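"""Hybrid pattern construction, stwintron scanning, curation, GFF3 IO."""

import io

import pytest

import stwinscan as sw
from stwinscan.motifs import matches_at, reverse_complement
from stwinscan.rules import RELAXED
from stwinscan.scanner import (
    D56,
    StwintronClass,
    build_stwintron_pattern,
    curate_orf_context,
    read_calls_gff,
    rejoined_external,
    scan_for_stwintrons,
    write_calls_gff,
)

from conftest import D56_SCREEN


class TestPatternConstruction:
    def test_d56_serializes_to_the_screen_string(self):
        pat = build_stwintron_pattern(D56)
        assert pat.serialize() == D56_SCREEN

    def test_d12_hybrid_elements(self):
        pat = build_stwintron_pattern(StwintronClass("D", 1))
        assert pat.elements[0].pattern == "GGTRWGH"  # 1-nt prefix + donor
        assert pat.elements[0].length == 7
        assert pat.elements[2].pattern == "HAGTRWGH"  # acceptor + 5-nt suffix
        assert pat.elements[2].length == 8

    def test_a23_acceptor_class(self):
        pat = build_stwintron_pattern(StwintronClass("A", 2))
        # external donor and BP lead; interrupted acceptor pieces flank the
        # internal intron; pattern ends on acceptor + 1-nt suffix
        assert pat.elements[0].pattern == "GTRWGH"
        assert pat.elements[1].pattern == "DYTRAY"
        assert pat.elements[2].pattern == "HAGTRWGH"
        assert pat.elements[4].pattern == "HAGG"
        assert pat.serialize().endswith("HAGG")

    def test_l_class_is_hypothetical(self):
        cls = StwintronClass("L", 3)
        assert cls.hypothetical
        assert not D56.hypothetical
        pat = build_stwintron_pattern(cls)
        assert pat.elements[1].pattern == "DYTGTRWGH"

    @pytest.mark.parametrize("kind,split", [("D", 0), ("D", 6), ("A", 3), ("L", 6), ("X", 1)])
    def test_invalid_class_rejected(self, kind, split):
        with pytest.raises(ValueError):
            StwintronClass(kind, split)


class TestScan:
    def test_recovers_planted_call_exactly(self, plain_fixture):
        genome, truth = plain_fixture
        calls = scan_for_stwintrons(genome, D56, seq_id="fixture")
        assert calls == list(truth.stwintrons)

    @pytest.mark.parametrize("cls", [StwintronClass("D", 1), StwintronClass("A", 1),
                                     StwintronClass("A", 2), StwintronClass("L", 3)])
    def test_class_exclusivity(self, plain_fixture, cls):
        genome, _ = plain_fixture
        assert scan_for_stwintrons(genome, cls) == []

    def test_low_complexity_sequence_is_empty(self):
        assert scan_for_stwintrons("A" * 500, D56) == []

    def test_rejoined_external_matches_uninterrupted_consensus(self, plain_fixture):
        """After internal excision the external intron starts with a full
        donor match and ends in AG."""
        genome, truth = plain_fixture
        for call in scan_for_stwintrons(genome, D56):
            rejoined, ext = rejoined_external(call, genome)
            assert matches_at(RELAXED.donor, rejoined, ext.donor_span[0])
            s, e = ext.intron_span
            assert rejoined[s : s + 2] == "GT"
            assert rejoined[e - 2 : e] == "AG"

    def test_reverse_strand_reporting(self, plain_fixture):
        genome, truth = plain_fixture
        rc = reverse_complement(genome)
        calls = scan_for_stwintrons(rc, D56, strand="-")
        assert len(calls) == 1
        assert calls[0].strand == "-"
        L = len(genome)
        s, e = truth.stwintrons[0].total_span
        assert calls[0].total_span == (L - e, L - s)
        # the feature is not found on the forward strand of the complement
        assert scan_for_stwintrons(rc, D56, strand="+") == []
        both = scan_for_stwintrons(rc, D56, strand="both")
        assert both == calls


class TestOrfCuration:
    def test_coding_fixture_retained_with_planted_phase(self):
        genome, truth = sw.plant_stwintron(
            sw.FixtureSpec(seed=7, coding="clean", phase=1)
        )
        calls = scan_for_stwintrons(genome, D56, seq_id="fixture")
        kept = curate_orf_context(calls, genome, window=60)
        assert len(kept) == 1
        assert kept[0].orf_phases == (1,)

    @pytest.mark.parametrize("phase", [0, 2])
    def test_other_phases(self, phase):
        genome, _ = sw.plant_stwintron(
            sw.FixtureSpec(seed=9, coding="clean", phase=phase)
        )
        calls = scan_for_stwintrons(genome, D56)
        kept = curate_orf_context(calls, genome, window=60)
        assert kept and kept[0].orf_phases == (phase,)

    def test_stops_in_all_frames_removes_call(self):
        genome, _ = sw.plant_stwintron(sw.FixtureSpec(seed=7, coding="stops"))
        calls = scan_for_stwintrons(genome, D56)
        assert calls  # the scan itself still sees the stwintron
        assert curate_orf_context(calls, genome, window=60) == []

    def test_empty_and_bad_window(self):
        assert curate_orf_context([], "ACGT" * 50, window=60) == []
        with pytest.raises(ValueError):
            curate_orf_context([], "ACGT", window=2)


class TestGff:
    def test_structure_one_call(self, plain_fixture):
        genome, truth = plain_fixture
        buf = io.StringIO()
        write_calls_gff(truth.stwintrons, "fixture", buf)
        lines = [l for l in buf.getvalue().splitlines() if not l.startswith("#")]
        types = [l.split("\t")[2] for l in lines]
        assert types.count("twin_intron") == 1
        assert types.count("intron") == 2
        assert sum(t in ("splice_donor", "branch_point", "splice_acceptor") for t in types) == 5
        # 1-based inclusive conversion
        parent = lines[0].split("\t")
        s, e = truth.stwintrons[0].total_span
        assert (int(parent[3]), int(parent[4])) == (s + 1, e)

    def test_round_trip(self, aniger_fixture):
        genome, truth = aniger_fixture
        buf = io.StringIO()
        write_calls_gff(truth.stwintrons, "alt_a_niger", buf)
        buf.seek(0)
        back = read_calls_gff(buf)
        assert back == sorted(truth.stwintrons, key=lambda c: (c.strand, c.total_span))

    def test_empty_gff_has_version_pragma(self):
        buf = io.StringIO()
        write_calls_gff([], "x", buf)
        assert buf.getvalue() == "##gff-version 3\n"
        buf.seek(0)
        assert read_calls_gff(buf) == []

    def test_gffutils_cross_check(self, plain_fixture, tmp_path):
        """An independent GFF3 parser sees the same feature hierarchy."""
        gffutils = pytest.importorskip("gffutils")
        genome, truth = plain_fixture
        path = tmp_path / "calls.gff3"
        with open(path, "w") as fh:
            write_calls_gff(truth.stwintrons, "fixture", fh)
        db = gffutils.create_db(str(path), ":memory:")
        parents = list(db.features_of_type("twin_intron"))
        assert len(parents) == 1
        children = list(db.children(parents[0]))
        assert len(children) == 7  # 2 introns + 5 elements
        s, e = truth.stwintrons[0].total_span
        assert (parents[0].start, parents[0].end) == (s + 1, e)
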