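"""Seeded synthetic "tumor model bundle" generator.

Produces a desk-scale dataset with the statistical structure the analysis
stages assume: a toy two-chromosome genome with multi-exon protein-coding
transcripts, copy-number segments around a configurable true ploidy, SNVs
whose allele fractions sit at k/c (k mutated copies of c) with binomial
read-sampling noise in DNA and RNA, trinucleotide contexts drawn from a
signature mixture, per-tool fusion call sets with tool-specific
sensitivity and independent decoys, two expression replicates with a
tunable correlation, and ELISpot plates with planted positives. All
randomness flows from one generator seeded by the config, so a fixed seed
reproduces the bundle byte-for-byte.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import consensus as _consensus
from ._utils import derive_rng
from .io_core import (
    CNSegment,
    GenomicInterval,
    TranscriptModel,
    VariantCall,
    write_fasta,
    write_gtf_lite,
    write_segments,
    write_variant_table,
)
from .fusions import FusionCall, FusionKey
from .spectrum import (
    CLASS_LABELS,
    COMPLEMENT,
    PYRIMIDINES,
    toy_signature_matrix,
    write_signature_matrix,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}
NON_STOP_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in STOP_CODONS
]

DEFAULT_EXPOSURES = {"AC1": 0.30, "AC2": 0.0, "AC3": 0.55, "AC6": 0.10, "AC20": 0.05}
DEFAULT_TOOLS = ("soapfuse", "mapsplice2", "infusion", "starfusion")


@dataclass
class SimConfig:
    """Study conditions for one synthetic bundle.

    Defaults mirror the characterized cell line: pentaploid-leaning genome,
    505 SNVs / 20 indels, 66% replicate call overlap, ~34% of mutations
    expressed, DNA-RNA VAF concordance near R^2 = 0.98 (via 150x binomial
    read resampling at the shared allele fraction), replicate expression
    correlation > 0.99, 12 true fusions scattered over four tools at 90%
    sensitivity with ~2 decoys per tool and replicate, and 22 of 49
    ELISpot candidates planted positive.
    """

    seed: int = 0
    true_ploidy: int = 5
    n_genes: int = 200
    n_snvs: int = 505
    n_indels: int = 20
    dna_depth: int = 150
    rna_depth: int = 150
    dna_rna_vaf_r2_target: float = 0.98
    replicate_tpm_corr_target: float = 0.99
    signature_exposures: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXPOSURES)
    )
    replicate_overlap_target: float = 0.66
    frac_expressed: float = 0.34
    frac_control_positive: float = 0.05
    fusion_truth_size: int = 12
    tool_sensitivity: dict[str, float] = field(
        default_factory=lambda: {t: 0.9 for t in DEFAULT_TOOLS}
    )
    tool_fp_rate: dict[str, float] = field(
        default_factory=lambda: {t: 2.0 for t in DEFAULT_TOOLS}
    )
    candidate_ploidies: tuple[int, ...] = (2, 3, 4, 5)
    tpm_log_mean: float = np.log(20.0)
    tpm_log_sigma: float = 1.5
    frac_de_background: float = 0.42
    n_candidate_genes: int = 54
    frac_de_candidates: float = 0.685
    n_elispot_candidates: int = 49
    n_elispot_positives: int = 22
    elispot_background_mean: float = 20.0
    elispot_positive_fold: float = 4.0
    elispot_wells: int = 3
    elispot_background_wells: int = 6

    def __post_init__(self) -> None:
        if self.n_snvs < 1:
            raise ValueError("n_snvs must be >= 1")
        if self.dna_depth <= 0 or self.rna_depth <= 0:
            raise ValueError("sequencing depths must be > 0")
        total = sum(self.signature_exposures.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"signature exposures must sum to 1, got {total}")
        for name, rate in [
            ("replicate_overlap_target", self.replicate_overlap_target),
            ("frac_expressed", self.frac_expressed),
            ("frac_control_positive", self.frac_control_positive),
            ("frac_de_background", self.frac_de_background),
            ("frac_de_candidates", self.frac_de_candidates),
            *((f"sensitivity[{t}]", s) for t, s in self.tool_sensitivity.items()),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.elispot_positive_fold < 3.0:
            raise ValueError("planted positives must sit at >= 3x background")
        if self.true_ploidy < 1:
            raise ValueError("true_ploidy must be >= 1")


@dataclass
class TruthBundle:
    """Everything a downstream stage needs, with ground-truth labels."""

    config: SimConfig
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    segments: list[CNSegment]
    segments_by_ploidy: dict[int, list[CNSegment]]
    variants: list[VariantCall]
    rep_a: list[VariantCall]
    rep_b: list[VariantCall]
    variant_truth: pd.DataFrame
    signature_matrix: pd.DataFrame
    exposures: dict[str, float]
    fusion_truth: list[FusionKey]
    fusion_decoy_pool: list[FusionKey]
    fusion_calls: dict[tuple[int, str], list[FusionCall]]
    expression: pd.DataFrame
    tx2gene: dict[str, str]
    elispot_candidates: dict[str, list[int]]
    elispot_background: list[int]
    elispot_truth_positive: set[str]


# ---------------------------------------------------------------------------
# genome and annotation


def _generate_genome_and_transcripts(
    config: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[TranscriptModel]]:
    chrom_names = ["chr1", "chr2"]
    genes_per_chrom = [
        config.n_genes - config.n_genes // 2,
        config.n_genes // 2,
    ]
    genome: dict[str, np.ndarray] = {}
    transcripts: list[TranscriptModel] = []
    gene_index = 0
    for chrom, n_genes in zip(chrom_names, genes_per_chrom):
        pieces: list[TranscriptModel] = []
        cursor = 1
        plan = []
        for _ in range(n_genes):
            gap = int(rng.integers(60, 200))
            n_codons = int(rng.integers(60, 151))
            cds_len = 3 * n_codons
            part1 = int(rng.integers(30, cds_len - 29))
            intron = int(rng.integers(50, 120))
            strand = "+" if rng.random() < 0.7 else "-"
            plan.append((gap, n_codons, cds_len, part1, intron, strand))
        total = sum(
            gap + 30 + part1 + intron + (cds_len - part1) + 30
            for gap, _nc, cds_len, part1, intron, _s in plan
        )
        chrom_len = total + 500
        seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=chrom_len)
        for gap, n_codons, cds_len, part1, intron, strand in plan:
            start = cursor + gap
            exon1 = GenomicInterval(chrom, start, start + 30 + part1 - 1, strand)
            exon2_start = exon1.end + 1 + intron
            part2 = cds_len - part1
            exon2 = GenomicInterval(
                chrom, exon2_start, exon2_start + part2 + 30 - 1, strand
            )
            cds_start = start + 30
            cds_end = exon2_start + part2 - 1
            gene_index += 1
            model = TranscriptModel(
                transcript_id=f"T{gene_index:04d}",
                gene_symbol=f"G{gene_index:04d}",
                exons=[exon1, exon2],
                strand=strand,
                cds_start=cds_start,
                cds_end=cds_end,
            )
            # write a clean ORF (ATG ... TAA, no internal stops) into place
            codon_idx = rng.integers(0, len(NON_STOP_CODONS), size=n_codons - 2)
            coding = "ATG" + "".join(NON_STOP_CODONS[i] for i in codon_idx) + "TAA"
            gpos: list[int] = []
            for e in model.exons:
                lo, hi = max(e.start, cds_start), min(e.end, cds_end)
                if lo <= hi:
                    gpos.extend(range(lo, hi + 1))
            placed = (
                coding
                if strand == "+"
                else "".join(COMPLEMENT[b] for b in reversed(coding))
            )
            for p, base in zip(gpos, placed):
                seq[p - 1] = base.encode()
            pieces.append(model)
            cursor = exon2.end
        genome[chrom] = seq
        transcripts.extend(pieces)
    return (
        {c: s.tobytes().decode() for c, s in genome.items()},
        transcripts,
    )


def _generate_segments(
    config: SimConfig,
    transcripts: Sequence[TranscriptModel],
    rng: np.random.Generator,
    genome: Mapping[str, str],
) -> tuple[list[CNSegment], dict[int, list[CNSegment]]]:
    p = config.true_ploidy
    cn_choices = np.array([max(1, p - 1), p, p + 1])
    segments: list[CNSegment] = []
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom, models in by_chrom.items():
        models = sorted(models, key=lambda m: m.span.start)
        # breakpoints fall in the gaps between gene groups of ~4-8 genes
        boundaries = [1]
        i = 0
        while i < len(models) - 1:
            i += int(rng.integers(4, 9))
            if i >= len(models):
                break
            gap_lo = models[i - 1].span.end + 1
            gap_hi = models[i].span.start - 1
            boundaries.append(int((gap_lo + gap_hi) // 2))
        boundaries.append(len(genome[chrom]) + 1)
        for lo, hi in zip(boundaries, boundaries[1:]):
            cn = int(rng.choice(cn_choices, p=[0.15, 0.7, 0.15]))
            segments.append(CNSegment(GenomicInterval(chrom, lo, hi - 1), cn))
    segments_by_ploidy: dict[int, list[CNSegment]] = {}
    for cand in config.candidate_ploidies:
        scaled = [
            CNSegment(
                s.interval, max(0, round(s.copy_number * cand / p))
            )
            for s in segments
        ]
        segments_by_ploidy[cand] = scaled
    return segments, segments_by_ploidy


# ---------------------------------------------------------------------------
# variants


def _pyrimidine_context(genome: Mapping[str, str], chrom: str, pos: int) -> tuple[str, str, str]:
    """(five, ref, three) of the pyrimidine-collapsed context at pos."""
    seq = genome[chrom]
    five, ref, three = seq[pos - 2], seq[pos - 1], seq[pos]
    if ref not in PYRIMIDINES:
        five, ref, three = COMPLEMENT[three], COMPLEMENT[ref], COMPLEMENT[five]
    return five, ref, three


def _gene_context_index(
    genome: Mapping[str, str], model: TranscriptModel
) -> dict[tuple[str, str, str], list[int]]:
    """CDS-interior positions grouped by pyrimidine trinucleotide context."""
    gpos = model.cds_genomic_positions()
    if model.strand == "-":
        gpos = list(reversed(gpos))  # genomic order
    interior = gpos[3:-3]
    index: dict[tuple[str, str, str], list[int]] = {}
    for p in interior:
        index.setdefault(_pyrimidine_context(genome, model.chrom, p), []).append(p)
    return index


def _generate_variants(
    config: SimConfig,
    genome: Mapping[str, str],
    transcripts: Sequence[TranscriptModel],
    gene_cn: Mapping[str, int],
    rng: np.random.Generator,
) -> tuple[list[VariantCall], list[VariantCall], list[VariantCall], pd.DataFrame, set[str]]:
    sig_matrix = toy_signature_matrix()
    exposures = config.signature_exposures
    mixture = np.zeros(96)
    for sig, w in exposures.items():
        mixture += w * sig_matrix[sig].to_numpy()
    mixture = mixture / mixture.sum()

    by_gene = {t.gene_symbol: t for t in transcripts}
    gene_symbols = [t.gene_symbol for t in transcripts]
    expressed_genes = {
        g for g in gene_symbols if rng.random() < config.frac_expressed
    }
    context_cache: dict[str, dict] = {}
    used_positions: set[tuple[str, int]] = set()

    variants: list[VariantCall] = []
    truth_rows: list[dict] = []

    overlap = config.replicate_overlap_target
    p_both = overlap
    p_only = (1 - overlap) / 2

    def sample_presence() -> tuple[bool, bool]:
        u = rng.random()
        if u < p_both:
            return True, True
        return (True, False) if u < p_both + p_only else (False, True)

    def make_counts(gene: str, k: int, c: int) -> dict:
        p_alt = k / c
        dna_alt = int(rng.binomial(config.dna_depth, p_alt))
        dna_alt = max(1, dna_alt)
        if gene in expressed_genes:
            rna_depth = config.rna_depth
            rna_alt = int(rng.binomial(rna_depth, p_alt))
        else:
            rna_depth, rna_alt = 0, 0
        control_vaf = (
            float(rng.uniform(0.05, 0.5))
            if rng.random() < config.frac_control_positive
            else 0.0
        )
        return dict(
            dna_alt=dna_alt,
            dna_depth=config.dna_depth,
            rna_alt=rna_alt,
            rna_depth=rna_depth,
            control_vaf=control_vaf,
        )

    # --- SNVs with signature-mixture contexts
    n_placed = 0
    while n_placed < config.n_snvs:
        cls = int(rng.choice(96, p=mixture))
        label = CLASS_LABELS[cls]
        five, ref_pyr, alt_pyr, three = label[0], label[2], label[4], label[6]
        position = None
        gene = None
        for _attempt in range(20):
            gene = gene_symbols[int(rng.integers(len(gene_symbols)))]
            if gene not in context_cache:
                context_cache[gene] = _gene_context_index(genome, by_gene[gene])
            candidates = [
                p
                for p in context_cache[gene].get((five, ref_pyr, three), [])
                if (by_gene[gene].chrom, p) not in used_positions
            ]
            if candidates:
                position = candidates[int(rng.integers(len(candidates)))]
                break
        if position is None:
            # context not available: place anywhere free and let the actual
            # context stand (negligible distortion of the spectrum)
            gene = gene_symbols[int(rng.integers(len(gene_symbols)))]
            if gene not in context_cache:
                context_cache[gene] = _gene_context_index(genome, by_gene[gene])
            free = [
                p
                for plist in context_cache[gene].values()
                for p in plist
                if (by_gene[gene].chrom, p) not in used_positions
            ]
            if not free:
                continue
            position = free[int(rng.integers(len(free)))]
            _f, ref_pyr, _t = _pyrimidine_context(
                genome, by_gene[gene].chrom, position
            )
            alt_pyr = {"C": "T", "T": "C"}[ref_pyr]
        chrom = by_gene[gene].chrom
        used_positions.add((chrom, position))
        genome_ref = genome[chrom][position - 1]
        if genome_ref in PYRIMIDINES:
            ref, alt = genome_ref, alt_pyr
        else:
            ref, alt = genome_ref, COMPLEMENT[alt_pyr]
        c = gene_cn[gene]
        k = int(rng.integers(1, c + 1))
        counts = make_counts(gene, k, c)
        v = VariantCall(
            chrom,
            position,
            ref,
            alt,
            dna_alt=counts["dna_alt"],
            dna_depth=counts["dna_depth"],
            rna_alt=counts["rna_alt"],
            rna_depth=counts["rna_depth"],
            gene_symbol=gene,
            transcript_id=by_gene[gene].transcript_id,
            info={"control_rna_vaf": f"{counts['control_vaf']:.4f}"},
        )
        v.consequence = _consensus.annotate_consequence(v, by_gene[gene], genome)
        in_a, in_b = sample_presence()
        truth_rows.append(
            dict(
                chrom=chrom,
                pos=position,
                ref=ref,
                alt=alt,
                gene=gene,
                variant_type="SNV",
                multiplicity=k,
                copy_number=c,
                expressed=gene in expressed_genes,
                control_rna_vaf=counts["control_vaf"],
                consequence=v.consequence,
                in_rep_a=in_a,
                in_rep_b=in_b,
                spectrum_class=label,
            )
        )
        variants.append(v)
        n_placed += 1

    # --- indels (anchor-base convention)
    for _ in range(config.n_indels):
        for _attempt in range(50):
            gene = gene_symbols[int(rng.integers(len(gene_symbols)))]
            model = by_gene[gene]
            if gene not in context_cache:
                context_cache[gene] = _gene_context_index(genome, by_gene[gene])
            free = [
                p
                for plist in context_cache[gene].values()
                for p in plist
                if (model.chrom, p) not in used_positions
            ]
            if free:
                break
        else:
            break
        position = free[int(rng.integers(len(free)))]
        used_positions.add((model.chrom, position))
        anchor = genome[model.chrom][position - 1]
        indel_len = int(rng.integers(1, 4))
        if rng.random() < 0.5:
            inserted = "".join(
                "ACGT"[int(i)] for i in rng.integers(0, 4, size=indel_len)
            )
            ref, alt = anchor, anchor + inserted
        else:
            following = genome[model.chrom][position : position + indel_len]
            ref, alt = anchor + following, anchor
        c = gene_cn[gene]
        k = int(rng.integers(1, c + 1))
        counts = make_counts(gene, k, c)
        v = VariantCall(
            model.chrom,
            position,
            ref,
            alt,
            dna_alt=counts["dna_alt"],
            dna_depth=counts["dna_depth"],
            rna_alt=counts["rna_alt"],
            rna_depth=counts["rna_depth"],
            gene_symbol=gene,
            transcript_id=model.transcript_id,
            info={"control_rna_vaf": f"{counts['control_vaf']:.4f}"},
        )
        v.consequence = _consensus.annotate_consequence(v, model, genome)
        in_a, in_b = sample_presence()
        truth_rows.append(
            dict(
                chrom=model.chrom,
                pos=position,
                ref=ref,
                alt=alt,
                gene=gene,
                variant_type=v.variant_type,
                multiplicity=k,
                copy_number=c,
                expressed=gene in expressed_genes,
                control_rna_vaf=counts["control_vaf"],
                consequence=v.consequence,
                in_rep_a=in_a,
                in_rep_b=in_b,
                spectrum_class="",
            )
        )
        variants.append(v)

    truth = pd.DataFrame(truth_rows)
    rep_a = [v for v, row in zip(variants, truth_rows) if row["in_rep_a"]]
    rep_b = [v for v, row in zip(variants, truth_rows) if row["in_rep_b"]]
    return variants, rep_a, rep_b, truth, expressed_genes


# ---------------------------------------------------------------------------
# expression


def replicate_noise_sigma(corr_target: float, log_sigma: float) -> float:
    """Log-normal replicate noise sigma hitting a raw-scale Pearson target.

    For X_r = exp(G + E_r) with G ~ N(mu, s^2), E_r ~ N(0, e^2) independent
    across replicates, corr(X_1, X_2) = (e^{s^2}-1) / (e^{s^2+e^2}-1);
    solving for e gives the noise level that realizes the target.
    """
    if not 0 < corr_target < 1:
        raise ValueError("correlation target must be in (0, 1)")
    s2 = log_sigma**2
    e2 = np.log((np.expm1(s2)) / corr_target + 1.0) - s2
    if e2 <= 0:
        raise ValueError("correlation target unattainable at this dispersion")
    return float(np.sqrt(e2))


def _generate_expression(
    config: SimConfig,
    transcripts: Sequence[TranscriptModel],
    expressed_genes: set[str],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, str]]:
    genes = [t.gene_symbol for t in transcripts]
    tx2gene = {t.transcript_id: t.gene_symbol for t in transcripts}
    baseline = np.exp(
        rng.normal(config.tpm_log_mean, config.tpm_log_sigma, size=len(genes))
    )
    sigma_eps = replicate_noise_sigma(
        config.replicate_tpm_corr_target, config.tpm_log_sigma
    )

    candidate_genes = list(
        rng.choice(genes, size=min(config.n_candidate_genes, len(genes)), replace=False)
    )
    candidate_set = set(candidate_genes)
    rows = []
    for g, base in zip(genes, baseline):
        frac_de = (
            config.frac_de_candidates
            if g in candidate_set
            else config.frac_de_background
        )
        is_de = rng.random() < frac_de
        lfc = 0.0
        if is_de:
            lfc = float(rng.uniform(1.5, 5.0)) * (1 if rng.random() < 0.5 else -1)
        if g in expressed_genes:
            tumor_mean = base * 2.0**lfc
            control_mean = base if is_de else tumor_mean
        else:
            # silent in the tumor; if DE it was silenced relative to control
            tumor_mean = 0.0
            control_mean = base if is_de else 0.0
        noise = rng.normal(0.0, sigma_eps, size=4)
        tumor = tumor_mean * np.exp(noise[:2] - sigma_eps**2 / 2)
        control = control_mean * np.exp(noise[2:] - sigma_eps**2 / 2)
        rows.append(
            dict(
                gene_symbol=g,
                tpm_rep1=tumor[0],
                tpm_rep2=tumor[1],
                ctrl_tpm_rep1=control[0],
                ctrl_tpm_rep2=control[1],
                count_rep1=int(rng.poisson(tumor[0] * 20)),
                count_rep2=int(rng.poisson(tumor[1] * 20)),
                true_de=is_de,
                true_log2fc=lfc if g in expressed_genes else (-np.inf if is_de else 0.0),
                is_candidate=g in candidate_set,
            )
        )
    return pd.DataFrame(rows).set_index("gene_symbol"), tx2gene


# ---------------------------------------------------------------------------
# fusions


def _generate_fusions(
    config: SimConfig,
    transcripts: Sequence[TranscriptModel],
    rng: np.random.Generator,
) -> tuple[list[FusionKey], list[FusionKey], dict[tuple[int, str], list[FusionCall]]]:
    genes = [t.gene_symbol for t in transcripts]
    all_pairs = [(a, b) for a in genes for b in genes if a != b]
    idx = rng.choice(len(all_pairs), size=config.fusion_truth_size, replace=False)
    truth = [all_pairs[int(i)] for i in idx]
    truth_set = set(truth)
    decoy_pool = [p for p in all_pairs if p not in truth_set]
    calls: dict[tuple[int, str], list[FusionCall]] = {}
    for replicate in (1, 2):
        for tool in config.tool_sensitivity:
            found = [
                pair
                for pair in truth
                if rng.random() < config.tool_sensitivity[tool]
            ]
            n_decoys = int(rng.poisson(config.tool_fp_rate.get(tool, 0.0)))
            n_decoys = min(n_decoys, len(decoy_pool))
            decoy_idx = rng.choice(len(decoy_pool), size=n_decoys, replace=False)
            decoys = [decoy_pool[int(i)] for i in decoy_idx]
            calls[(replicate, tool)] = [
                FusionCall(
                    g5,
                    g3,
                    tool=tool,
                    replicate=replicate,
                    support_reads=int(rng.integers(3, 60)),
                )
                for g5, g3 in found + decoys
            ]
    return truth, decoy_pool, calls


# ---------------------------------------------------------------------------
# ELISpot


def generate_elispot(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, list[int]], list[int], set[str]]:
    """Simulate spot-count plates for the configured candidates.

    Returns (candidate -> well counts, background well counts, set of
    candidate ids planted as true positives). Planted positives have a
    well mean of ``elispot_positive_fold`` x background (>= 3x enforced by
    the config); negatives sit at 1x. Counts are Poisson per well.
    """
    if config.elispot_background_mean <= 0:
        raise ValueError("background mean must be > 0")
    if rng is None:
        rng = derive_rng(config.seed, "elispot")
    n = config.n_elispot_candidates
    candidates = {f"C{i + 1:02d}": None for i in range(n)}
    if n == 0:
        return {}, [
            int(x)
            for x in rng.poisson(
                config.elispot_background_mean, size=config.elispot_background_wells
            )
        ], set()
    positive_ids = set(
        rng.choice(list(candidates), size=min(config.n_elispot_positives, n), replace=False)
    )
    spots: dict[str, list[int]] = {}
    for cid in candidates:
        mean = config.elispot_background_mean * (
            config.elispot_positive_fold if cid in positive_ids else 1.0
        )
        spots[cid] = [
            int(x) for x in rng.poisson(mean, size=config.elispot_wells)
        ]
    background = [
        int(x)
        for x in rng.poisson(
            config.elispot_background_mean, size=config.elispot_background_wells
        )
    ]
    return spots, background, positive_ids


# ---------------------------------------------------------------------------
# bundle


def generate_bundle(config: SimConfig) -> TruthBundle:
    """Generate the full synthetic bundle for one seed (deterministic)."""
    rng = np.random.default_rng(int(config.seed) % 2**31)
    genome, transcripts = _generate_genome_and_transcripts(config, rng)
    segments, segments_by_ploidy = _generate_segments(
        config, transcripts, rng, genome
    )
    from .ploidy import assign_gene_copy_numbers

    gene_cn, _ = assign_gene_copy_numbers(segments, transcripts)
    variants, rep_a, rep_b, truth, expressed_genes = _generate_variants(
        config, genome, transcripts, gene_cn, rng
    )
    expression, tx2gene = _generate_expression(
        config, transcripts, expressed_genes, rng
    )
    fusion_truth, decoy_pool, fusion_calls = _generate_fusions(
        config, transcripts, rng
    )
    spots, background, positives = generate_elispot(config, rng)
    return TruthBundle(
        config=config,
        genome=genome,
        transcripts=transcripts,
        segments=segments,
        segments_by_ploidy=segments_by_ploidy,
        variants=variants,
        rep_a=rep_a,
        rep_b=rep_b,
        variant_truth=truth,
        signature_matrix=toy_signature_matrix(),
        exposures=dict(config.signature_exposures),
        fusion_truth=fusion_truth,
        fusion_decoy_pool=decoy_pool,
        fusion_calls=fusion_calls,
        expression=expression,
        tx2gene=tx2gene,
        elispot_candidates=spots,
        elispot_background=background,
        elispot_truth_positive=positives,
    )


def write_bundle(bundle: TruthBundle, outdir: str | Path) -> None:
    """Emit the bundle as the directory of plain-text files the CLI stages
    read, plus a truth manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.genome, out / "genome.fa")
    write_gtf_lite(bundle.transcripts, out / "transcripts.gtf")
    write_segments(bundle.segments, out / "segments_true.bed")
    for ploidy, segs in sorted(bundle.segments_by_ploidy.items()):
        write_segments(segs, out / f"segments_ploidy{ploidy}.bed")
    write_variant_table(bundle.variants, out / "variants_all.tsv")
    write_variant_table(bundle.rep_a, out / "variants_rep_a.tsv")
    write_variant_table(bundle.rep_b, out / "variants_rep_b.tsv")
    bundle.variant_truth.to_csv(out / "variant_truth.tsv", sep="\t", index=False)
    write_signature_matrix(bundle.signature_matrix, out / "signatures.tsv")
    for (replicate, tool), calls in sorted(bundle.fusion_calls.items()):
        with open(out / f"fusions_rep{replicate}_{tool}.tsv", "w") as fh:
            fh.write("gene5\tgene3\tsupport\n")
            for c in calls:
                fh.write(f"{c.gene5}\t{c.gene3}\t{c.support_reads}\n")
    bundle.expression.to_csv(out / "expression.tsv", sep="\t")
    with open(out / "tx2gene.tsv", "w") as fh:
        fh.write("transcript_id\tgene_symbol\n")
        for tx, gene in sorted(bundle.tx2gene.items()):
            fh.write(f"{tx}\t{gene}\n")
    with open(out / "elispot.tsv", "w") as fh:
        fh.write("candidate\twell\tspots\n")
        for cid, wells in bundle.elispot_candidates.items():
            for w, s in enumerate(wells, start=1):
                fh.write(f"{cid}\t{w}\t{s}\n")
        for w, s in enumerate(bundle.elispot_background, start=1):
            fh.write(f"background\t{w}\t{s}\n")
    manifest = {
        "seed": bundle.config.seed,
        "true_ploidy": bundle.config.true_ploidy,
        "n_snvs": bundle.config.n_snvs,
        "n_indels": bundle.config.n_indels,
        "exposures": bundle.exposures,
        "fusion_truth": [list(p) for p in bundle.fusion_truth],
        "elispot_truth_positive": sorted(bundle.elispot_truth_positive),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
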