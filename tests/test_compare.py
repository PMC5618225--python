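import random

import numpy as np
import pytest

from mdsrna._dna import hamming
from mdsrna.compare import (
    Variant,
    call_coding_consequences,
    find_repeated_motif,
    global_align,
    local_align,
    local_identity_scan,
    parse_variant_label,
    partition_core_extra,
)
from mdsrna.simulate import GenomeSpec, generate_genome
from oracles import enumerate_best_score, gotoh_score


def rnd_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestAlignment:
    def test_identical_sequences(self):
        res = global_align("ACGTACGT", "ACGTACGT")
        assert res.identity == 1.0 and res.score == 8

    def test_single_mismatch_identity(self):
        assert global_align("ACGT", "ACGA").identity == 0.75

    def test_dp_oracle_validated_by_enumeration(self):
        random.seed(1)
        for _ in range(60):
            a = "".join(random.choice("ACGT") for _ in range(random.randint(1, 5)))
            b = "".join(random.choice("ACGT") for _ in range(random.randint(1, 5)))
            assert gotoh_score(a, b) == pytest.approx(enumerate_best_score(a, b))

    def test_scores_match_independent_dp(self):
        random.seed(2)
        for _ in range(300):
            a = "".join(random.choice("ACGT") for _ in range(random.randint(1, 8)))
            b = "".join(random.choice("ACGT") for _ in range(random.randint(1, 8)))
            assert global_align(a, b).score == pytest.approx(gotoh_score(a, b))

    def test_local_self_alignment(self):
        seq = "ACGTACGTGGCC"
        res = local_align(seq, seq)
        assert res.identity == 1.0 and res.score == len(seq)


class TestVariants:
    @pytest.mark.parametrize(
        "variant",
        [
            Variant(689, "C", "T", "SNV"),
            Variant(1110, "", "T", "ins"),
            Variant(1416, "A", "", "del"),
        ],
    )
    def test_label_round_trip(self, variant):
        parsed = parse_variant_label(variant.label)
        assert (parsed.ref_pos, parsed.ref, parsed.alt, parsed.kind) == (
            variant.ref_pos,
            variant.ref,
            variant.alt,
            variant.kind,
        )

    def test_paper_style_snv_label(self):
        assert Variant(689, "C", "T", "SNV").label == "689C > T"


class TestPartition:
    def test_planted_composition_recovered(self, rng):
        ref = rnd_dna(rng, 600)
        x, y = rnd_dna(rng, 80), rnd_dna(rng, 50)
        comp = partition_core_extra(x + ref + y, ref)
        assert comp.status == "ok"
        assert comp.extra5 == (0, 80)
        assert comp.core == (80, 680)
        assert comp.extra3 == (680, 730)
        assert comp.core_identity == 1.0
        assert comp.variants == []

    def test_identical_cores_both_end_extras_zero_variants(self, rng):
        # two isotypes sharing an identical core, one with extras at both ends
        core = rnd_dna(rng, 700)
        comp = partition_core_extra(rnd_dna(rng, 64) + core + rnd_dna(rng, 66), core)
        assert comp.status == "ok" and comp.variants == []
        assert comp.core_identity == 1.0

    def test_sixteen_planted_snvs_catalogued(self, rng):
        ref = rnd_dna(rng, 900)
        q = list(rnd_dna(rng, 40) + ref + rnd_dna(rng, 30))
        swap = {"A": "C", "C": "T", "G": "A", "T": "G"}
        positions = sorted(rng.choice(np.arange(50, 850), size=16, replace=False))
        for p in positions:
            q[40 + p] = swap[q[40 + p]]
        comp = partition_core_extra("".join(q), ref)
        assert comp.status == "ok"
        assert len(comp.variants) == 16
        assert [v.ref_pos for v in comp.variants] == [int(p) + 1 for p in positions]
        assert all(v.kind == "SNV" for v in comp.variants)

    def test_unrelated_sequence_rejected(self, rng):
        comp = partition_core_extra(rnd_dna(rng, 500), rnd_dna(rng, 400))
        assert comp.status == "not_same_virus_type"


class TestCodingConsequences:
    REF = "TT" + "ATG" + "GCTAAACGT" + "TAA" + "CCCCC"  # ORF at [2, 17)

    def test_missense_label(self):
        v = Variant(10, "A", "T", "SNV")  # codon 3 AAA->ATA: K>I
        call_coding_consequences([v], 2, 17, self.REF)
        assert v.consequence == "3K > I"

    def test_synonymous_third_position(self):
        v = Variant(11, "A", "G", "SNV")  # AAA->AAG both K
        call_coding_consequences([v], 2, 17, self.REF)
        assert v.consequence == "synonymous"

    def test_downstream_of_stop_noncoding(self):
        v = Variant(19, "C", "T", "SNV")
        call_coding_consequences([v], 2, 17, self.REF)
        assert v.consequence == "noncoding"


class TestMotifDiscovery:
    def test_exact_copies_across_three_genomes(self, rng):
        cons = rnd_dna(rng, 24)
        genomes = {
            f"g{i}": rnd_dna(rng, 150) + cons + rnd_dna(rng, 150) for i in range(3)
        }
        fams = find_repeated_motif(genomes, min_genomes=2)
        assert len(fams) == 1
        assert len(fams[0].hits) == 3
        assert all(h.matches == 24 for h in fams[0].hits)

    def test_mzb_like_copy_numbers_and_labels(self, rng):
        cons = rnd_dna(rng, 24)

        def mutated(n):
            copy = list(cons)
            for p in rng.choice(24, size=n, replace=False):
                copy[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[p]]
            return "".join(copy)

        five = rnd_dna(rng, 60)
        for _ in range(5):
            five += mutated(2) + rnd_dna(rng, 20)
        other = rnd_dna(rng, 100) + mutated(1) + rnd_dna(rng, 80)
        fams = find_repeated_motif({"mzb_like": five, "m1_like": other})
        assert len(fams) == 1
        fam = fams[0]
        assert fam.copy_count("mzb_like") == 5
        assert fam.copy_count("m1_like") == 1
        labels = [h.label for h in fam.hits if h.genome_id == "mzb_like"]
        assert labels == ["A", "B", "C", "D", "E"]

    def test_decoy_past_mismatch_budget_excluded(self, rng):
        cons = rnd_dna(rng, 24)
        decoy = list(cons)
        # interior mismatch positions, so no shifted window can fall back
        # inside the Hamming budget
        for p in rng.choice(np.arange(2, 22), size=5, replace=False):
            decoy[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[decoy[p]]
        genomes = {
            "a": rnd_dna(rng, 100) + cons + rnd_dna(rng, 100),
            "b": rnd_dna(rng, 100) + "".join(decoy) + rnd_dna(rng, 100),
        }
        fams = find_repeated_motif(genomes, max_mismatch=4, min_genomes=2)
        assert fams == []

    def test_region_restriction(self, rng):
        cons = rnd_dna(rng, 24)
        g1 = cons + rnd_dna(rng, 200) + cons
        g2 = rnd_dna(rng, 100) + cons
        fams = find_repeated_motif(
            {"a": g1, "b": g2},
            regions={"a": (200, len(g1)), "b": (0, len(g2))},
        )
        assert len(fams) == 1
        assert fams[0].copy_count("a") == 1  # the 5' copy is outside the region


class TestLocalIdentityScan:
    def test_self_identity(self, rng):
        region = rnd_dna(rng, 120)
        blk = local_identity_scan(region, region, min_length=20)
        assert blk.identity == 1.0
        assert blk.aligned_length == 120

    def test_planted_block_at_eighty_percent(self, rng):
        block_a = rnd_dna(rng, 30)
        block_b = list(block_a)
        for p in (3, 8, 13, 18, 23, 27):  # 6/30 interior mismatches -> 80%
            block_b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[block_b[p]]
        a = rnd_dna(rng, 90) + block_a + rnd_dna(rng, 80)
        b = rnd_dna(rng, 70) + "".join(block_b) + rnd_dna(rng, 100)
        blk = local_identity_scan(a, b, min_length=20)
        assert blk is not None
        assert 0.72 <= blk.identity <= 0.9
        assert blk.a_start < 120 and blk.a_end > 90  # overlaps the planted block

    def test_unrelated_regions_low_identity_or_none(self):
        hits = []
        for seed in range(10):
            r = np.random.default_rng(seed + 40)
            blk = local_identity_scan(rnd_dna(r, 200), rnd_dna(r, 200), min_length=20)
            if blk is not None:
                hits.append(blk.identity)
        assert all(h <= 0.9 for h in hits)
        assert len(hits) < 10  # usually no block of >= 20 columns at all
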