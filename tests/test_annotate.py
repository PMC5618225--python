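import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdsrna._dna import revcomp
from mdsrna.annotate import (
    AnchoredCoord,
    annotate_genome,
    annotate_preprotoxin,
    find_polyA_runs,
    from_paper_coord,
    locate_anchor,
    parse_paper_coord,
    scan_kex2_sites,
    scan_nglyc_sites,
    scan_tre_stemloop,
    to_paper_coord,
    write_gff3,
)
from mdsrna.simulate import GenomeSpec, generate_genome


class TestAnchor:
    def test_anchor_at_origin(self):
        genome = "GAAAAA" + "C" * 200
        assert locate_anchor(genome, policy="first") == 0

    def test_m2_4_like_offset(self, small_genome):
        genome, truth = small_genome
        assert locate_anchor(genome) == 87

    def test_orf_proximal_occurrence_wins(self):
        rng = np.random.default_rng(1)
        orf = "ATG" + "GCT" * 80 + "TAA"
        decoy5 = "".join(rng.choice(list("CT"), 30)) + "GAAAAA" + "".join(
            rng.choice(list("CT"), 30)
        )
        genome = decoy5 + "GAAAAA" + "CCTTGGCCTTGGCC" + orf + "".join(
            rng.choice(list("CT"), 300)
        )
        assert locate_anchor(genome) == len(decoy5)
        assert locate_anchor(genome, policy="first") == 30

    def test_absent_anchor_is_none(self):
        assert locate_anchor("CCCTTTCCCTTT" * 30) is None


class TestPaperCoords:
    def test_m2_4_examples(self):
        assert str(to_paper_coord(87, 87)) == "1"
        assert str(to_paper_coord(86, 87)) == "(-)1"
        assert str(to_paper_coord(0, 87)) == "(-)87"

    def test_plus_class_past_legacy_end(self):
        assert str(to_paper_coord(1679, 87, 1678)) == "(+)1"
        assert str(to_paper_coord(1678, 87, 1678)) == "1592"

    def test_no_zero_label(self):
        with pytest.raises(ValueError):
            AnchoredCoord(0)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=3000),
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=0, max_value=3000),
    )
    def test_bijection_fuzz(self, index, anchor, legacy_offset):
        legacy3 = anchor + legacy_offset
        coord = to_paper_coord(index, anchor, legacy3)
        assert coord.n >= 1
        assert from_paper_coord(coord, anchor, legacy3) == index
        assert from_paper_coord(parse_paper_coord(str(coord)), anchor, legacy3) == index

    def test_adjacency_across_anchor(self):
        # (-)1 and 1 are adjacent indices; no zero in between
        assert from_paper_coord(AnchoredCoord(1, "minus"), 87) == 86
        assert from_paper_coord(AnchoredCoord(1, "core"), 87) == 87

    def test_extra5_insertion_shifts_anchor_only(self):
        genome = "GAAAAA" + "ATG" + "GCT" * 70 + "TAA" + "C" * 100
        insert = "TTCCTTCC"
        shifted = insert + genome
        a1 = locate_anchor(genome)
        a2 = locate_anchor(shifted)
        assert a2 == a1 + len(insert)
        for i in range(len(genome)):
            assert str(to_paper_coord(i, a1)) == str(to_paper_coord(i + len(insert), a2))


class TestPolyA:
    def test_single_pure_run(self):
        genome = "C" * 90 + "A" * 20 + "C" * 90
        runs = find_polyA_runs(genome, min_run=12, purity=0.9)
        assert len(runs) == 1
        assert (runs[0].start, runs[0].end, runs[0].a_fraction) == (90, 110, 1.0)

    def test_two_runs_in_order(self):
        genome = "C" * 60 + "A" * 15 + "C" * 40 + "A" * 18 + "C" * 60
        runs = find_polyA_runs(genome, min_run=12, purity=0.9)
        assert [(r.start, r.end) for r in runs] == [(60, 75), (115, 133)]

    def test_impure_run_fraction(self):
        genome = "C" * 60 + "AAAAACAAAAA" + "C" * 60
        runs = find_polyA_runs(genome, min_run=11, purity=0.9)
        assert len(runs) == 1
        assert runs[0].length == 11
        assert runs[0].a_fraction == pytest.approx(10 / 11)

    def test_terminal_runs_not_central(self):
        genome = "A" * 30 + "C" * 200 + "A" * 30
        assert find_polyA_runs(genome, min_run=12, purity=0.9) == []


class TestPreprotoxin:
    def test_kex2_dibasic_scan(self):
        assert scan_kex2_sites("APRKRDA") == [5]
        assert scan_kex2_sites("ARRB") == [3]
        assert scan_kex2_sites("AKKB") == []  # KK is not a Kex2 site

    def test_nglyc_rule_boundary(self):
        assert scan_nglyc_sites("ANPSA") == []  # X = P excluded
        assert scan_nglyc_sites("ANASA") == [2]
        assert scan_nglyc_sites("ANAT") == [2]

    def test_planted_orf_recovered(self, small_genome):
        genome, truth = small_genome
        feats = annotate_preprotoxin(genome)
        assert (feats.orf_start, feats.orf_end) == truth.orf
        assert set(truth.kex2_aa_positions) <= set(feats.kex2_sites)
        assert set(truth.nglyc_aa_positions) <= set(feats.nglyc_sites)

    def test_no_orf_status(self):
        # stop-rich sequence: no 60-codon ORF anywhere
        genome = "TAATGATAG" * 60
        assert annotate_preprotoxin(genome) is None


class TestStemLoop:
    def test_perfect_gc_hairpin_found(self):
        genome = "C" * 40 + "GGGGC" + "AAAA" + "GCCCC" + "T" * 20
        sl = scan_tre_stemloop(genome, window_3prime=120, min_stem=4)
        assert sl is not None
        assert sl.stem_length == 5 and sl.loop_length == 4
        assert sl.dG_kj < 0

    def test_gc_stem_beats_at_stem_at_equal_geometry(self):
        gc = "T" * 30 + "GCGCGC" + "AAAA" + "GCGCGC"[::-1].translate(
            str.maketrans("GC", "CG")
        ) + "T" * 30
        at = "G" * 30 + "ATATAT" + "CCCC" + "ATATAT"[::-1].translate(
            str.maketrans("AT", "TA")
        ) + "G" * 30
        sl_gc = scan_tre_stemloop(gc, window_3prime=80, min_stem=6)
        sl_at = scan_tre_stemloop(at, window_3prime=80, min_stem=6)
        assert sl_gc is not None
        assert sl_at is None or sl_gc.dG_kj < sl_at.dG_kj

    def test_elongating_stem_lowers_energy(self):
        def hairpin_dg(stem):
            arm = "G" * stem
            genome = "T" * 30 + arm + "AAAA" + "C" * stem + "T" * 5
            sl = scan_tre_stemloop(genome, window_3prime=80, min_stem=4)
            return sl.dG_kj

        energies = [hairpin_dg(s) for s in (4, 6, 8, 10)]
        assert energies == sorted(energies, reverse=True)
        assert all(e < 0 for e in energies)

    def test_none_found_in_unstructured_sequence(self):
        assert scan_tre_stemloop("A" * 200, window_3prime=120, min_stem=4) is None


class TestWholeGenomeAnnotation:
    def test_planted_features_recovered(self):
        spec = GenomeSpec(
            total_length=1900,
            extra5_length=60,
            extra3_length=40,
            polyA_runs=[(30, 0.9), (26, 0.92)],
            seed=13,
        )
        genome, truth = generate_genome(spec)
        ann = annotate_genome(genome, "g", hairpin_window=160)
        assert ann.anchor == truth.anchor
        assert (ann.orf.orf_start, ann.orf.orf_end) == truth.orf
        assert [(r.start, r.end) for r in ann.polya] == truth.polyA
        sl = ann.stemloop
        assert sl is not None
        assert sl.arm5_start < truth.tre[1] and sl.arm3_end > truth.tre[0]

    def test_gff3_output(self, small_genome, tmp_path):
        genome, truth = small_genome
        ann = annotate_genome(genome, "m2_4_like", hairpin_window=160)
        out = tmp_path / "ann.gff3"
        write_gff3(ann, out)
        text = out.read_text()
        assert text.startswith("##gff-version 3")
        assert "anchor" in text and "ORF" in text and "polyA" in text
        assert "paper_coord=" in text
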