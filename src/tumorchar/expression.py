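"""Gene-level expression summaries, DE classification, gene-set overlap
tests, homolog mapping, and viral gene RPKM via union gene models.

Transcript-level TPM is summed to gene level and averaged over the two
technical replicates; differential expression is classified at
FDR <= 0.05 and |log2 fold-change| > 1 (strict); overlap of DE gene sets
is tested one-sided with Fisher's exact test; viral expression counts any
read overlapping the union of a gene's isoform intervals and reports
reads per kilobase of gene model per million mapped reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import round_half_up
from .io_core import GenomicInterval


@dataclass
class ViralGeneModel:
    """Viral gene with the merged union of all isoform intervals."""

    accession: str
    gene: str
    isoform_intervals: list[GenomicInterval]
    tax_group: str | None = None

    def __post_init__(self) -> None:
        if not self.isoform_intervals:
            raise ValueError(f"no intervals for viral gene {self.gene}")
        self.union_model = merge_intervals(self.isoform_intervals)
        self.union_length = sum(iv.length for iv in self.union_model)
        if self.union_length == 0:
            raise ValueError(f"zero-length union model for {self.gene}")


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals (per chromosome) into a union."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end + 1:
            last = merged.pop()
            merged.append(
                GenomicInterval(last.chrom, last.start, max(last.end, iv.end))
            )
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


# ---------------------------------------------------------------------------
# gene-level expression


def gene_tpm(
    transcript_tpms: pd.DataFrame,
    tx2gene: Mapping[str, str] | pd.DataFrame,
) -> pd.DataFrame:
    """Sum transcript TPM to gene level and average the replicates.

    ``transcript_tpms`` needs columns transcript_id, tpm_rep1, tpm_rep2;
    ``tx2gene`` maps transcript_id -> gene_symbol (each transcript to at
    most one gene; a transcript mapped twice is an error). Returns a
    frame indexed by gene_symbol with tpm_rep1, tpm_rep2, mean_tpm.
    """
    if isinstance(tx2gene, pd.DataFrame):
        if tx2gene.iloc[:, 0].duplicated().any():
            dup = tx2gene.iloc[:, 0][tx2gene.iloc[:, 0].duplicated()].iloc[0]
            raise ValueError(f"transcript {dup!r} mapped to multiple genes")
        mapping = dict(zip(tx2gene.iloc[:, 0], tx2gene.iloc[:, 1]))
    else:
        mapping = dict(tx2gene)
    df = transcript_tpms.copy()
    df["gene_symbol"] = df["transcript_id"].map(mapping)
    df = df.dropna(subset=["gene_symbol"])
    out = df.groupby("gene_symbol")[["tpm_rep1", "tpm_rep2"]].sum().sort_index()
    out["mean_tpm"] = (out["tpm_rep1"] + out["tpm_rep2"]) / 2
    return out


def de_classify(log2fc: float, fdr: float) -> str:
    """DE status at the standard thresholds: |log2FC| strictly > 1 and
    FDR inclusively <= 0.05."""
    if not 0 <= fdr <= 1:
        raise ValueError("fdr must be in [0, 1]")
    if fdr <= 0.05 and log2fc > 1:
        return "up"
    if fdr <= 0.05 and log2fc < -1:
        return "down"
    return "ns"


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test(
    case_tpm: pd.DataFrame,
    control_tpm: pd.DataFrame,
    *,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Simple two-sample DE screen on log2(TPM + 1) with replicate columns.

    This is a light built-in test (Welch t on the log scale, BH-adjusted)
    so the pipeline can classify DE end-to-end on desk-scale data; a
    negative-binomial count model is the right tool on real libraries.
    Returns log2fc, pvalue, fdr, de_status indexed by gene.
    """
    genes = case_tpm.index.intersection(control_tpm.index)
    case = np.log2(case_tpm.loc[genes, ["tpm_rep1", "tpm_rep2"]] + pseudocount)
    ctrl = np.log2(control_tpm.loc[genes, ["tpm_rep1", "tpm_rep2"]] + pseudocount)
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    fdr = bh_adjust(p)
    out = pd.DataFrame(
        {"log2fc": log2fc, "pvalue": p, "fdr": fdr}, index=genes
    )
    out["de_status"] = [
        de_classify(f, q) for f, q in zip(out["log2fc"], out["fdr"])
    ]
    return out


# ---------------------------------------------------------------------------
# gene-set comparisons


def geneset_overlap_test(
    de_set_a: Iterable[str],
    de_set_b: Iterable[str],
    background: Iterable[str],
) -> tuple[int, float]:
    """One-sided (enrichment) Fisher's exact test on set overlap.

    Both sets must lie within the background universe. Returns
    (overlap size, p-value); degenerate tables return p = 1.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    a, b = set(de_set_a), set(de_set_b)
    if not a <= bg or not b <= bg:
        raise ValueError("gene sets must be subsets of the background")
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(bg) - len(a | b)
    _, p = stats.fisher_exact([[n11, n12], [n21, n22]], alternative="greater")
    return n11, float(p)


def map_homologs(
    symbols: Iterable[str],
    mapping_table: pd.DataFrame,
) -> tuple[list[str], int]:
    """Translate gene symbols through a two-column homolog table.

    One-to-many mappings expand; symbols without any mapping are dropped
    and counted. Output preserves input order (expanded matches in table
    order) and is deduplicated.
    """
    src = mapping_table.columns[0]
    dst = mapping_table.columns[1]
    lookup: dict[str, list[str]] = {}
    for _, row in mapping_table.iterrows():
        lookup.setdefault(row[src], []).append(row[dst])
    mapped: list[str] = []
    seen: set[str] = set()
    n_unmapped = 0
    for sym in symbols:
        targets = lookup.get(sym)
        if not targets:
            n_unmapped += 1
            continue
        for t in targets:
            if t not in seen:
                seen.add(t)
                mapped.append(t)
    return mapped, n_unmapped


def candidate_set_de_fraction(
    candidate_genes: Iterable[str],
    de_status: Mapping[str, str] | pd.Series,
) -> float:
    """Percentage of candidate genes that are differentially expressed
    (status up or down), to one decimal."""
    candidates = list(candidate_genes)
    if not candidates:
        raise ValueError("empty candidate gene list")
    status = dict(de_status)
    unknown = [g for g in candidates if g not in status]
    if unknown:
        raise ValueError(f"candidate genes missing from records: {unknown[:3]}")
    n_de = sum(status[g] in ("up", "down") for g in candidates)
    return float(round_half_up(100.0 * n_de / len(candidates), 1))


# ---------------------------------------------------------------------------
# viral expression


def viral_read_counts(
    read_intervals: Sequence[GenomicInterval],
    viral_models: Sequence[ViralGeneModel],
) -> dict[str, int]:
    """Count reads overlapping each gene's union model by >= 1 nt.

    A read overlapping two isoforms of the same gene counts once (the
    union model guarantees it); reads are allowed to count toward several
    distinct genes.
    """
    counts = {m.gene: 0 for m in viral_models}
    for m in viral_models:
        for read in read_intervals:
            if any(read.overlap(iv) > 0 for iv in m.union_model):
                counts[m.gene] += 1
    return counts


def viral_rpkm(
    read_intervals: Sequence[GenomicInterval],
    viral_models: Sequence[ViralGeneModel],
    total_mapped_reads: int,
) -> dict[str, float]:
    """RPKM per viral gene over union gene models.

    RPKM = count / (union_length / 1000) / (total mapped reads / 1e6).
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be > 0")
    counts = viral_read_counts(read_intervals, viral_models)
    return {
        m.gene: counts[m.gene]
        / (m.union_length / 1_000)
        / (total_mapped_reads / 1_000_000)
        for m in viral_models
    }


def filter_taxonomic(
    viral_models: Sequence[ViralGeneModel],
    counts: Mapping[str, int],
) -> list[ViralGeneModel]:
    """Within each taxonomic group keep only the accession with the
    highest total read count (drops spurious signal spread over close
    relatives). ``counts`` is per gene; models with no tax group pass
    through untouched."""
    totals: dict[tuple[str, str], int] = {}
    for m in viral_models:
        key = (m.tax_group or f"__solo__{m.accession}", m.accession)
        totals[key] = totals.get(key, 0) + counts.get(m.gene, 0)
    best_accession: dict[str, str] = {}
    for (group, accession), total in sorted(totals.items()):
        if group not in best_accession or total > totals[(group, best_accession[group])]:
            best_accession[group] = accession
    kept_groups = set(best_accession.items())
    return [
        m
        for m in viral_models
        if (m.tax_group or f"__solo__{m.accession}", m.accession) in
        {(g, a) for g, a in kept_groups}
    ]
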