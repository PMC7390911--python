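"""Replicate-consensus variant sets and summary statistics.

Somatic calls made independently on two technical replicates are combined
by exact-key intersection/union; consequence annotation is codon-level and
strand-aware; expressed-mutation and DNA-RNA VAF concordance summaries
mirror the usual tumor-characterization report.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from ._utils import pct_half_up
from .io_core import TranscriptModel, VariantCall

#: most-severe-first convention used when a variant hits several transcripts
SEVERITY_ORDER = [
    "stop_gain",
    "frameshift",
    "stop_loss",
    "missense",
    "inframe_indel",
    "synonymous",
    "UTR",
    "intergenic",
]

NONSYNONYMOUS = {"missense", "stop_gain", "stop_loss"}


def _check_unique(calls: Sequence[VariantCall], label: str) -> dict:
    by_key = {}
    for call in calls:
        if call.key in by_key:
            raise ValueError(f"duplicate key {call.key} in replicate {label}")
        by_key[call.key] = call
    return by_key


def consensus_calls(
    rep_a: Sequence[VariantCall], rep_b: Sequence[VariantCall]
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Intersect and union two replicate call sets by exact (chrom, pos,
    ref, alt) key.

    Records from replicate A are kept as the representatives of shared
    keys. Outputs are sorted by key, so the operation is order-insensitive
    and commutative at the key level.
    """
    a = _check_unique(rep_a, "A")
    b = _check_unique(rep_b, "B")
    inter = [a[k] for k in sorted(a.keys() & b.keys())]
    union = [a.get(k) or b[k] for k in sorted(a.keys() | b.keys())]
    return inter, union


def consensus_fraction(intersection_size: int, union_size: int) -> int:
    """Percentage of the union shared by both replicates, half-up rounded."""
    if union_size == 0:
        raise ValueError("union is empty; consensus fraction undefined")
    if not 0 <= intersection_size <= union_size:
        raise ValueError("need 0 <= intersection <= union")
    return int(pct_half_up(intersection_size, union_size))


def confirm_against(
    reference_keys: Iterable, detected_keys: Iterable
) -> tuple[int, int]:
    """How many previously reported variants are re-detected here.

    Returns (n_confirmed, percentage of the reference set).
    """
    reference = set(reference_keys)
    if not reference:
        raise ValueError("reference key set is empty")
    n = len(reference & set(detected_keys))
    return n, int(pct_half_up(n, len(reference)))


# ---------------------------------------------------------------------------
# consequence annotation


def _codon_start_positions(cds_positions: list[int]) -> dict[int, int]:
    """Map genomic position -> index within the CDS (0-based)."""
    return {pos: i for i, pos in enumerate(cds_positions)}


def _genome_base(genome: Mapping[str, str], chrom: str, pos: int) -> str:
    return genome[chrom][pos - 1]


def annotate_consequence(
    variant: VariantCall,
    transcript: TranscriptModel,
    genome: Mapping[str, str],
) -> str:
    """Classify one variant against one transcript.

    SNVs inside the CDS are classified at codon level via the standard
    genetic code (reverse-complemented on minus-strand transcripts);
    indels inside the CDS are frameshift unless the length change is a
    multiple of 3; exonic variants outside the CDS are UTR; everything
    else is intergenic (introns and flanks included).
    """
    if variant.chrom != transcript.chrom:
        return "intergenic"
    in_exon = any(e.start <= variant.pos <= e.end for e in transcript.exons)
    if not in_exon:
        return "intergenic"
    if not transcript.coding:
        return "UTR"

    ref_genomic = _genome_base(genome, variant.chrom, variant.pos)
    if ref_genomic != variant.ref[0]:
        raise ValueError(
            f"ref allele mismatch at {variant.chrom}:{variant.pos}: "
            f"variant says {variant.ref[0]!r}, genome has {ref_genomic!r}"
        )

    cds_positions = transcript.cds_genomic_positions()
    cds_index = _codon_start_positions(cds_positions)

    if not variant.is_snv:
        # anchor-base convention: the inserted/deleted bases follow the anchor
        length_change = abs(len(variant.alt) - len(variant.ref))
        touches_cds = variant.pos in cds_index or any(
            p in cds_index
            for p in range(variant.pos + 1, variant.pos + len(variant.ref))
        )
        if not touches_cds:
            return "UTR"
        return "inframe_indel" if length_change % 3 == 0 else "frameshift"

    if variant.pos not in cds_index:
        return "UTR"
    idx = cds_index[variant.pos]
    codon_number = idx // 3
    codon_pos = [cds_positions[codon_number * 3 + i] for i in range(3)]
    # codon_pos is in coding order; on the minus strand each genome base
    # must be complemented to give the coding base.
    offset = idx % 3
    base = variant.alt
    if transcript.strand == "-":
        codon = "".join(
            str(Seq(_genome_base(genome, variant.chrom, p)).complement())
            for p in codon_pos
        )
        base = str(Seq(variant.alt).complement())
    else:
        codon = "".join(_genome_base(genome, variant.chrom, p) for p in codon_pos)
    mutated = codon[:offset] + base + codon[offset + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "stop_gain"
    if aa_ref == "*":
        return "stop_loss"
    return "missense"


def annotate_variants(
    variants: Sequence[VariantCall],
    transcripts: Sequence[TranscriptModel],
    genome: Mapping[str, str],
) -> list[VariantCall]:
    """Annotate each variant with its most severe consequence over all
    overlapping transcripts; sets consequence, gene_symbol, transcript_id
    in place and returns the list."""
    rank = {c: i for i, c in enumerate(SEVERITY_ORDER)}
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chrom, []).append(t)
    for v in variants:
        best = ("intergenic", None)
        for t in by_chrom.get(v.chrom, []):
            if not (t.span.start <= v.pos <= t.span.end):
                continue
            cons = annotate_consequence(v, t, genome)
            if rank[cons] < rank[best[0]]:
                best = (cons, t)
        v.consequence = best[0]
        if best[1] is not None:
            v.gene_symbol = best[1].gene_symbol
            v.transcript_id = best[1].transcript_id
    return list(variants)


# ---------------------------------------------------------------------------
# summaries


def nonsynonymous_summary(variants: Sequence[VariantCall]) -> dict[str, int]:
    """Breakdown of SNV consequences: non-synonymous = missense +
    stop_gain + stop_loss, percentage relative to all SNVs."""
    snvs = [v for v in variants if v.is_snv]
    for v in snvs:
        if v.consequence is None:
            raise ValueError(f"unannotated variant {v.key}")
    n_missense = sum(v.consequence == "missense" for v in snvs)
    n_stop_gain = sum(v.consequence == "stop_gain" for v in snvs)
    n_stop_loss = sum(v.consequence == "stop_loss" for v in snvs)
    n_nonsyn = n_missense + n_stop_gain + n_stop_loss
    return {
        "n_total": len(snvs),
        "n_nonsyn": n_nonsyn,
        "pct_nonsyn": int(pct_half_up(n_nonsyn, len(snvs))) if snvs else 0,
        "n_missense": n_missense,
        "n_stop_gain": n_stop_gain,
        "n_stop_loss": n_stop_loss,
    }


def expressed_fraction(nonsyn_variants: Sequence[VariantCall]) -> tuple[int, int]:
    """Count variants with RNA VAF strictly > 0; undefined RNA VAF counts
    as not expressed. Returns (n_expressed, percentage of input)."""
    if not nonsyn_variants:
        raise ValueError("empty variant list")
    n = sum(
        1
        for v in nonsyn_variants
        if v.rna_vaf is not None and v.rna_vaf > 0
    )
    return n, int(pct_half_up(n, len(nonsyn_variants)))


def vaf_concordance(variants: Sequence[VariantCall]) -> float:
    """Squared Pearson correlation of RNA on DNA VAF over records where
    both are defined (records with undefined VAF are excluded)."""
    pairs = [
        (v.dna_vaf, v.rna_vaf)
        for v in variants
        if v.dna_vaf is not None and v.rna_vaf is not None
    ]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 records with both VAFs, got {len(pairs)}")
    x, y = np.asarray(pairs).T
    if np.std(x) == 0 or np.std(y) == 0:
        return 1.0 if np.allclose(x, y) else 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def mutation_rate_per_mb(n_mutations: int, target_bases: float) -> float:
    """Raw mutations-per-megabase ratio (reported, never asserted)."""
    if target_bases <= 0:
        raise ValueError("target_bases must be positive")
    return n_mutations / (target_bases / 1e6)
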