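"""Filter cascade, construct design, 15-mer tiling, ELISpot scoring."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tumorchar import neoantigen as neo
from tumorchar.io_core import VariantCall

# independent codon table for frameshift-tail verification
CODON_TABLE = {}
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            CODON_TABLE[_b1 + _b2 + _b3] = _AAS[16 * _i + 4 * _j + _k]


def oracle_translate(cds):
    return "".join(CODON_TABLE[cds[i:i + 3]] for i in range(0, len(cds) - 2, 3))


def record(
    consequence="missense",
    both=True,
    mean_expr=5.0,
    dna_vaf=0.4,
    rna_vaf=0.3,
    control=0.0,
    pos=1,
    indel=False,
    sanger=None,
):
    ref, alt = ("A", "AG") if indel else ("A", "T")
    v = VariantCall(
        "chr1", pos, ref, alt,
        dna_alt=int(dna_vaf * 100), dna_depth=100,
        rna_alt=int(rna_vaf * 100), rna_depth=100,
    )
    v.consequence = consequence
    return neo.CandidateRecord(
        variant=v,
        present_in_both_replicates=both,
        mean_expression=mean_expr,
        control_rna_vaf=control,
        sanger_confirmed=sanger,
    )


class TestSnvCascade:
    def test_record_passing_all_criteria_is_retained(self):
        passing, rejections = neo.filter_snv_candidates([record()])
        assert len(passing) == 1
        assert all(v == 0 for v in rejections.values())

    def test_rna_vaf_boundary_is_strict(self):
        passing, rejections = neo.filter_snv_candidates(
            [record(rna_vaf=0.10)]
        )
        assert passing == []
        assert rejections["vi_rna_vaf"] == 1

    def test_twelve_record_truth_table(self):
        """Passing set must match independent manual evaluation of all
        seven criteria."""
        records = [
            record(pos=1),                                    # pass
            record(pos=2, both=False),                        # fail i
            record(pos=3, consequence="UTR"),                 # fail ii
            record(pos=4, consequence="synonymous"),          # fail iii
            record(pos=5, consequence="stop_gain"),           # fail iii
            record(pos=6, mean_expr=0.0),                     # fail iv
            record(pos=7, dna_vaf=0.0),                       # fail v
            record(pos=8, rna_vaf=0.10),                      # fail vi
            record(pos=9, rna_vaf=0.11),                      # pass
            record(pos=10, control=0.2),                      # fail vii
            record(pos=11, both=False, rna_vaf=0.0),          # fail i (first)
            record(pos=12, rna_vaf=0.5, dna_vaf=0.01),        # pass
        ]
        manual_pass = {1, 9, 12}
        passing, rejections = neo.filter_snv_candidates(records)
        assert {r.variant.pos for r in passing} == manual_pass
        assert rejections == {
            "i_both_replicates": 2,
            "ii_non_utr": 1,
            "iii_nonsynonymous": 2,
            "iv_expressed": 1,
            "v_dna_vaf": 1,
            "vi_rna_vaf": 1,
            "vii_control_rna_vaf": 1,
        }

    def test_missing_control_vaf_undecidable(self):
        rec = record()
        rec.control_rna_vaf = None
        with pytest.raises(ValueError, match="vii"):
            neo.filter_snv_candidates([rec])

    def test_cascade_is_monotone_in_thresholds(self):
        rng = np.random.default_rng(2)
        records = [
            record(
                pos=i + 1,
                rna_vaf=float(rng.uniform(0, 0.3)),
                dna_vaf=float(rng.uniform(0, 0.3)),
                mean_expr=float(rng.uniform(0, 2)),
            )
            for i in range(40)
        ]
        base, _ = neo.filter_snv_candidates(records)
        for relaxed in (
            {"min_rna_vaf": 0.05},
            {"min_dna_vaf": -0.01},
            {"min_mean_expression": -1.0},
            {"max_control_rna_vaf": 0.5},
        ):
            looser, _ = neo.filter_snv_candidates(records, relaxed)
            assert {r.variant.pos for r in base} <= {
                r.variant.pos for r in looser
            }


class TestIndelCascade:
    def test_low_rna_vaf_retained(self):
        passing, _ = neo.filter_indel_candidates(
            [record(rna_vaf=0.05, consequence="frameshift", indel=True)]
        )
        assert len(passing) == 1

    def test_zero_rna_vaf_rejected(self):
        passing, rejections = neo.filter_indel_candidates(
            [record(rna_vaf=0.0, consequence="frameshift", indel=True)]
        )
        assert passing == [] and rejections["vi_rna_vaf"] == 1

    def test_sanger_confirmation_leaves_two_of_three(self):
        records = [
            record(pos=1, consequence="frameshift", indel=True, sanger=True),
            record(pos=2, consequence="inframe_indel", indel=True, sanger=True),
            record(pos=3, consequence="frameshift", indel=True, sanger=False),
        ]
        passing, rejections = neo.filter_indel_candidates(
            records, require_sanger=True
        )
        assert {r.variant.pos for r in passing} == {1, 2}
        assert rejections["sanger"] == 1


class TestConstructs:
    WT_CDS = (
        "ATG" + "GCT" * 40 + "TGGAAACCC" + "GAT" * 40 + "TAA"
    )  # M + A*40 + WKP + D*40

    def test_internal_snv_gives_27mer_with_centre_mutation(self):
        # mutate the Trp (protein position 42, codon TGG at nt 124-126)
        mut = self.WT_CDS[:124] + "A" + self.WT_CDS[125:]  # TGG -> TAG? no: G>A at middle gives TAG stop; use first base
        mut = self.WT_CDS[:123] + "C" + self.WT_CDS[124:]  # TGG -> CGG (W->R)
        construct = neo.build_construct(("k",), "SNV", self.WT_CDS, mut)
        assert len(construct.sequence) == 27
        assert construct.mutant_positions == [14]
        assert construct.sequence[13] == "R"

    def test_snv_near_n_terminus_truncates_left_flank(self):
        # mutate protein position 1 (M -> L via ATG -> CTG)
        mut = "C" + self.WT_CDS[1:]
        construct = neo.build_construct(("k",), "SNV", self.WT_CDS, mut)
        assert len(construct.sequence) == 14
        assert construct.mutant_positions == [1]
        assert construct.sequence[0] == "L"

    def test_frameshift_tail_matches_independent_translation(self):
        # delete one base inside codon 42 -> frameshift
        mut = self.WT_CDS[:124] + self.WT_CDS[125:]
        construct = neo.build_construct(("k",), "frameshift", self.WT_CDS, mut)
        oracle_mut = oracle_translate(mut)
        oracle_wt = oracle_translate(self.WT_CDS)
        prefix = 0
        while (
            prefix < min(len(oracle_wt), len(oracle_mut))
            and oracle_wt[prefix] == oracle_mut[prefix]
        ):
            prefix += 1
        novel = oracle_mut[prefix:].split("*", 1)[0]
        assert construct.sequence.endswith(novel)
        assert construct.sequence[:15] == oracle_wt[prefix - 15 : prefix]
        assert construct.mutation_class == "frameshift"

    def test_inframe_indel_has_15_aa_flanks(self):
        # insert one codon (GGG -> +Gly) after codon 42
        mut = self.WT_CDS[:126] + "GGG" + self.WT_CDS[126:]
        construct = neo.build_construct(("k",), "inframe_indel", self.WT_CDS, mut)
        # altered segment is a single inserted residue with 15-aa flanks
        assert len(construct.sequence) <= 31
        p = construct.mutant_positions[0]
        assert construct.sequence[p - 1] in "G"

    def test_frameshift_without_stop_is_flagged(self):
        wt = "ATG" + "GCT" * 20 + "TAA"
        mut = wt[:10] + wt[11:]  # frameshift, tail may never hit a stop
        construct = neo.build_construct(("k",), "frameshift", wt, mut)
        oracle_mut = oracle_translate(mut)
        assert construct.truncated_no_stop == ("*" not in oracle_mut)


class TestTiling:
    def test_snv_construct_tiles_cover_mutation(self):
        tiles = neo.tile_peptides("A" * 13 + "M" + "B" * 13)
        assert [t.start for t in tiles] == [1, 5, 9, 13]
        assert all(len(t.sequence) == 15 for t in tiles)
        assert tiles[-1].start + 14 == 27
        for t in tiles:
            assert t.start <= 14 <= t.start + 14
            assert "M" in t.sequence

    def test_exact_k_single_tile(self):
        tiles = neo.tile_peptides("P" * 15)
        assert len(tiles) == 1 and tiles[0].start == 1

    def test_short_construct_single_tile(self):
        tiles = neo.tile_peptides("PEPTIDE")
        assert tiles == [neo.PeptideTile("PEPTIDE", 1)]

    def test_anchored_tail_tile(self):
        tiles = neo.tile_peptides("X" * 29)
        assert [t.start for t in tiles] == [1, 5, 9, 13, 15]

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError):
            neo.tile_peptides("A" * 20, k=10, overlap=10)

    @given(st.integers(1, 200))
    def test_full_residue_coverage(self, length):
        seq = "".join(
            "ACDEFGHIKLMNPQRSTVWY"[i % 20] for i in range(length)
        )
        tiles = neo.tile_peptides(seq)
        covered = set()
        for t in tiles:
            assert seq[t.start - 1 : t.start - 1 + len(t.sequence)] == t.sequence
            covered.update(range(t.start, t.start + len(t.sequence)))
        assert covered == set(range(1, length + 1))
        regular = [t for t in tiles[:-1]] if length > 15 else tiles
        for a, b in itertools.pairwise(tiles):
            if b.start - a.start == 4:
                assert len(a.sequence) == len(b.sequence) == 15


class TestElispot:
    def test_fold_two_point_five_is_positive(self):
        (res,) = neo.call_positive({"c": [25, 25, 25]}, [10, 10])
        assert res.positive and res.fold_over_background == pytest.approx(2.5)

    def test_fold_exactly_two_is_negative(self):
        (res,) = neo.call_positive({"c": [20, 20]}, [10, 10])
        assert res.fold_over_background == pytest.approx(2.0)
        assert not res.positive

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            neo.call_positive({"c": [5]}, [0, 0])

    def test_summary_counts(self):
        results = []
        for i in range(49):
            spots = [60] if i < 22 else [10]
            subtype = "CD4" if i < 15 else ("both" if i < 17 else "untested")
            r = neo.call_positive({f"c{i}": spots}, [10], {f"c{i}": subtype})[0]
            if i < 15:
                r.wt_tested = True
                r.wt_positive = i >= 10  # 10 of 15 tested WT are negative
            results.append(r)
        summary = neo.immunogenicity_summary(results)
        assert summary["n_tested"] == 49
        assert summary["n_positive"] == 22
        assert summary["pct_positive"] == 45
        assert summary["n_cd4"] == 15
        assert summary["n_both"] == 2
        assert summary["n_mutation_specific"] == 10

    def test_all_negative(self):
        results = neo.call_positive({"a": [5], "b": [8]}, [10])
        assert neo.immunogenicity_summary(results)["pct_positive"] == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            neo.immunogenicity_summary([])
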