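"""Replicate consensus, consequence annotation, expression summaries."""

from __future__ import annotations

import numpy as np
import pytest

from tumorchar import consensus as cns
from tumorchar.io_core import VariantCall

# independent codon-table oracle (hand-written, not Biopython)
CODON_TABLE = {}
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            CODON_TABLE[_b1 + _b2 + _b3] = _AAS[16 * _i + 4 * _j + _k]

_RC = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def oracle_translate(cds: str) -> str:
    return "".join(CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds) - 2, 3))


def snv(chrom, pos, ref, alt, **kw):
    return VariantCall(chrom, pos, ref, alt, **kw)


def keyed(keys):
    return [VariantCall("chr1", pos, "A", "T") for pos in keys]


class TestConsensusSets:
    def test_inclusion_exclusion_matches_printed_sizes(self):
        shared = set(range(1, 887))
        rep_a = keyed(sorted(shared | set(range(10_000, 10_229))))  # 1115
        rep_b = keyed(sorted(shared | set(range(20_000, 20_222))))  # 1108
        assert (len(rep_a), len(rep_b)) == (1115, 1108)
        inter, union = cns.consensus_calls(rep_a, rep_b)
        assert len(inter) == 886
        assert len(union) == 1337
        assert cns.consensus_fraction(len(inter), len(union)) == 66

    def test_identical_replicates(self):
        calls = keyed([1, 2, 3])
        inter, union = cns.consensus_calls(calls, list(calls))
        assert len(inter) == len(union) == 3

    def test_disjoint_replicates(self):
        inter, union = cns.consensus_calls(keyed([1, 2]), keyed([3, 4, 5]))
        assert inter == []
        assert len(union) == 5

    def test_commutative_in_key_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pool = np.arange(1, 101)
            a = keyed(rng.choice(pool, size=rng.integers(1, 30), replace=False))
            b = keyed(rng.choice(pool, size=rng.integers(1, 30), replace=False))
            i1, u1 = cns.consensus_calls(a, b)
            i2, u2 = cns.consensus_calls(b, a)
            assert {v.key for v in i1} == {v.key for v in i2}
            assert {v.key for v in u1} == {v.key for v in u2}

    def test_duplicate_key_rejected(self):
        with pytest.raises(ValueError, match="duplicate key"):
            cns.consensus_calls(keyed([1, 1]), keyed([2]))

    def test_fraction_examples_and_bounds(self):
        assert cns.consensus_fraction(50, 68) == 74
        assert cns.consensus_fraction(7, 7) == 100
        with pytest.raises(ValueError):
            cns.consensus_fraction(1, 0)


class TestConfirmation:
    @pytest.mark.parametrize(
        "n_ref, n_found, expected_pct",
        [(47, 45, 96), (246, 193, 78)],
    )
    def test_confirmation_rates(self, n_ref, n_found, expected_pct):
        reference = [("chr1", i, "A", "T") for i in range(n_ref)]
        detected = reference[:n_found] + [("chr9", 1, "C", "G")]
        assert cns.confirm_against(reference, detected) == (n_found, expected_pct)

    def test_full_confirmation(self):
        ref = [("chr1", 1, "A", "T")]
        assert cns.confirm_against(ref, ref + [("chr1", 2, "A", "C")]) == (1, 100)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            cns.confirm_against([], [("chr1", 1, "A", "T")])


class TestAnnotation:
    # toy plus-strand CDS at 11-40: ATG GCT TGG AAA CCC GGG TTT ACG TCA TAA
    def test_synonymous_third_position(self, toy_locus):
        genome, plus, _ = toy_locus
        # codon 2 GCT (Ala) at 14-16; T>C at 16 gives GCC (Ala)
        v = snv("chrT", 16, "T", "C")
        assert cns.annotate_consequence(v, plus, genome) == "synonymous"

    def test_stop_gain_in_trp_codon(self, toy_locus):
        genome, plus, _ = toy_locus
        # codon 3 TGG (Trp) at 17-19; G>A at 18 gives TAG (stop)
        v = snv("chrT", 18, "G", "A")
        assert cns.annotate_consequence(v, plus, genome) == "stop_gain"

    def test_missense(self, toy_locus):
        genome, plus, _ = toy_locus
        # codon 4 AAA (Lys) at 20-22; A>C at 20 gives CAA (Gln)
        v = snv("chrT", 20, "A", "C")
        assert cns.annotate_consequence(v, plus, genome) == "missense"

    def test_stop_loss(self, toy_locus):
        genome, plus, _ = toy_locus
        # stop codon TAA at 38-40; T>C at 38 gives CAA (Gln)
        v = snv("chrT", 38, "T", "C")
        assert cns.annotate_consequence(v, plus, genome) == "stop_loss"

    def test_single_base_insertion_is_frameshift(self, toy_locus):
        genome, plus, _ = toy_locus
        v = VariantCall("chrT", 20, "A", "AG")
        assert cns.annotate_consequence(v, plus, genome) == "frameshift"

    def test_three_base_insertion_is_inframe(self, toy_locus):
        genome, plus, _ = toy_locus
        v = VariantCall("chrT", 20, "A", "AGGG")
        assert cns.annotate_consequence(v, plus, genome) == "inframe_indel"

    def test_exonic_outside_cds_is_utr(self, toy_locus):
        genome, plus, _ = toy_locus
        v = snv("chrT", 8, "T", "C")  # exon 6-45, CDS starts at 11
        assert cns.annotate_consequence(v, plus, genome) == "UTR"

    def test_outside_exons_is_intergenic(self, toy_locus):
        genome, plus, _ = toy_locus
        v = snv("chrT", 50, genome["chrT"][49], "A")
        assert cns.annotate_consequence(v, plus, genome) == "intergenic"

    def test_minus_strand_uses_complemented_codon(self, toy_locus):
        genome, _, minus = toy_locus
        # minus-strand codon 3 is TGG (Trp) at genomic 82-84 (revcomp CCA);
        # genomic C>T at 83 complements to coding G>A: TAG stop
        v = snv("chrT", 83, genome["chrT"][82], "T")
        assert cns.annotate_consequence(v, minus, genome) == "stop_gain"

    def test_ref_mismatch_raises(self, toy_locus):
        genome, plus, _ = toy_locus
        wrong = "C" if genome["chrT"][15] != "C" else "G"
        with pytest.raises(ValueError, match="mismatch"):
            cns.annotate_consequence(snv("chrT", 16, wrong, "A"), plus, genome)

    def test_agrees_with_brute_force_translation_oracle(self, default_bundle):
        """Codon-level classification must match translating the whole WT
        and mutant CDS with an independent codon table and diffing."""
        bundle = default_bundle
        by_tid = {t.transcript_id: t for t in bundle.transcripts}
        rng = np.random.default_rng(7)
        snvs = [v for v in bundle.variants if v.is_snv]
        for v in (snvs[i] for i in rng.choice(len(snvs), 200, replace=False)):
            model = by_tid[v.transcript_id]
            gpos = model.cds_genomic_positions()
            if model.strand == "-":
                genomic_order = list(reversed(gpos))
            else:
                genomic_order = gpos
            wt_genomic = "".join(
                bundle.genome[model.chrom][p - 1] for p in genomic_order
            )
            mut_genomic = "".join(
                v.alt if p == v.pos else bundle.genome[model.chrom][p - 1]
                for p in genomic_order
            )
            if model.strand == "-":
                wt_cds, mut_cds = rc(wt_genomic), rc(mut_genomic)
            else:
                wt_cds, mut_cds = wt_genomic, mut_genomic
            wt_protein = oracle_translate(wt_cds)
            mut_protein = oracle_translate(mut_cds)
            diffs = [
                (a, b) for a, b in zip(wt_protein, mut_protein) if a != b
            ]
            if v.pos not in gpos:
                expected = "UTR"
            elif not diffs:
                expected = "synonymous"
            elif diffs[0][1] == "*":
                expected = "stop_gain"
            elif diffs[0][0] == "*":
                expected = "stop_loss"
            else:
                expected = "missense"
            assert cns.annotate_consequence(v, model, bundle.genome) == expected


class TestSummaries:
    def test_paper_scale_breakdown(self):
        variants = []
        specs = (
            [("missense", 248), ("stop_gain", 15), ("stop_loss", 1),
             ("synonymous", 141), ("UTR", 100)]
        )
        pos = 1
        for consequence, n in specs:
            for _ in range(n):
                v = snv("chr1", pos, "A", "T")
                v.consequence = consequence
                variants.append(v)
                pos += 1
        summary = cns.nonsynonymous_summary(variants)
        assert summary == {
            "n_total": 505,
            "n_nonsyn": 264,
            "pct_nonsyn": 52,
            "n_missense": 248,
            "n_stop_gain": 15,
            "n_stop_loss": 1,
        }

    def test_hand_built_tally(self):
        consequences = ["missense", "missense", "stop_gain", "synonymous",
                        "UTR", "UTR", "stop_loss", "synonymous", "missense",
                        "synonymous"]
        variants = []
        for i, c in enumerate(consequences, start=1):
            v = snv("chr1", i, "A", "T")
            v.consequence = c
            variants.append(v)
        s = cns.nonsynonymous_summary(variants)
        assert (s["n_nonsyn"], s["n_missense"], s["pct_nonsyn"]) == (5, 3, 50)

    def test_unannotated_variant_rejected(self):
        with pytest.raises(ValueError, match="unannotated"):
            cns.nonsynonymous_summary([snv("chr1", 1, "A", "T")])

    def test_expressed_fraction_strictness(self):
        expressed = snv("chr1", 1, "A", "T", rna_alt=5, rna_depth=50)
        zero = snv("chr1", 2, "A", "T", rna_alt=0, rna_depth=50)
        undefined = snv("chr1", 3, "A", "T")
        n, pct = cns.expressed_fraction([expressed, zero, undefined])
        assert (n, pct) == (1, 33)
        assert cns.expressed_fraction([zero]) == (0, 0)
        with pytest.raises(ValueError):
            cns.expressed_fraction([])


class TestVafConcordance:
    def test_identical_vafs_give_one(self):
        variants = [
            snv("chr1", i, "A", "T",
                dna_alt=i, dna_depth=100, rna_alt=i, rna_depth=100)
            for i in (10, 30, 70, 90)
        ]
        assert cns.vaf_concordance(variants) == pytest.approx(1.0)

    def test_independent_noise_gives_near_zero(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            variants = [
                snv("chr1", i + 1, "A", "T",
                    dna_alt=int(a), dna_depth=100,
                    rna_alt=int(b), rna_depth=100)
                for i, (a, b) in enumerate(
                    zip(rng.integers(1, 100, 1000), rng.integers(1, 100, 1000))
                )
            ]
            assert cns.vaf_concordance(variants) < 0.05

    def test_default_bundle_reaches_high_concordance(self, default_bundle):
        assert cns.vaf_concordance(default_bundle.variants) >= 0.95

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            cns.vaf_concordance(
                [snv("chr1", 1, "A", "T", dna_alt=1, dna_depth=2,
                     rna_alt=1, rna_depth=2)]
            )


def test_mutation_rate_is_a_raw_ratio():
    assert cns.mutation_rate_per_mb(505, 32e6) == pytest.approx(15.78, abs=0.01)
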