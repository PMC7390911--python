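"""VAF-based ploidy selection from candidate copy-number profiles.

A tumor genome at copy number c places SNV allele fractions on the grid
{k/c : k = 1..c} (k mutated copies out of c). Running the copy-number
caller once per assumed ploidy yields one segment profile per candidate;
the profile whose implied VAF grid best matches the observed DNA VAFs is
the inferred ploidy. The match statistic is the mean, over usable SNVs,
of the minimum absolute distance between the observed VAF and the
expected cluster set of the gene's copy number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_core import CNSegment, GenomicInterval, TranscriptModel, VariantCall

DEFAULT_CANDIDATE_PLOIDIES = (2, 3, 4, 5)


@dataclass
class PloidyCandidate:
    ploidy: int
    gene_cn: dict[str, int] = field(default_factory=dict)
    concordance_score: float = float("nan")

    def __post_init__(self) -> None:
        if not np.isnan(self.concordance_score) and self.concordance_score < 0:
            raise ValueError("concordance score must be >= 0")


def _check_non_overlapping(segments: Sequence[CNSegment]) -> None:
    by_chrom: dict[str, list[CNSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.interval.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.interval.start)
        for a, b in zip(segs, segs[1:]):
            if b.interval.start <= a.interval.end:
                raise ValueError(
                    f"overlapping segments on {chrom} at {b.interval.start}"
                )


def assign_gene_copy_numbers(
    segments: Sequence[CNSegment], transcripts: Sequence[TranscriptModel]
) -> tuple[dict[str, int], int]:
    """Assign each gene the copy number of the segment with maximal overlap
    with the gene's exon-union span.

    Genes not overlapped by any segment are omitted; the count of omitted
    genes is returned alongside the map. Overlap ties break to the
    leftmost segment for determinism.
    """
    _check_non_overlapping(segments)
    ordered = sorted(
        segments, key=lambda s: (s.interval.chrom, s.interval.start)
    )
    gene_cn: dict[str, int] = {}
    n_omitted = 0
    spans: dict[str, GenomicInterval] = {}
    for t in transcripts:
        span = t.span
        prev = spans.get(t.gene_symbol)
        if prev is None:
            spans[t.gene_symbol] = span
        else:
            # widen to the union span across the gene's transcripts
            spans[t.gene_symbol] = GenomicInterval(
                span.chrom, min(prev.start, span.start), max(prev.end, span.end)
            )
    for gene, span in spans.items():
        best_overlap, best_cn = 0, None
        for seg in ordered:
            ov = seg.interval.overlap(span)
            if ov > best_overlap:
                best_overlap, best_cn = ov, seg.copy_number
        if best_cn is None:
            n_omitted += 1
        else:
            gene_cn[gene] = best_cn
    return gene_cn, n_omitted


def expected_vaf_clusters(c: int) -> set[float]:
    """Expected allele-fraction clusters {k/c : k = 1..c} for copy number c.

    c = 0 yields the empty set (such genes carry no usable VAF signal).
    """
    if c < 0:
        raise ValueError("copy number must be >= 0")
    return {k / c for k in range(1, c + 1)}


def concordance_score(
    variants: Sequence[VariantCall],
    gene_cn: Mapping[str, int],
    *,
    min_cn: int = 1,
    max_cn: int = 10,
    depth_weight: bool = False,
) -> float:
    """Mean over usable SNVs of the distance to the nearest expected cluster.

    Usable: SNV with a defined DNA VAF whose gene has an assigned copy
    number within [min_cn, max_cn] (extreme amplifications blur the
    clusters and are excluded). With ``depth_weight=True`` the statistic
    is instead the mean negative binomial log-likelihood under the
    best-fitting allele multiplicity, which accounts for depth-dependent
    cluster width.
    """
    total, n_used = 0.0, 0
    for v in variants:
        if not v.is_snv or v.dna_vaf is None or v.gene_symbol not in gene_cn:
            continue
        c = gene_cn[v.gene_symbol]
        if not (min_cn <= c <= max_cn):
            continue
        clusters = sorted(expected_vaf_clusters(c))
        if depth_weight:
            ll = max(
                stats.binom.logpmf(v.dna_alt, v.dna_depth, p) for p in clusters
            )
            total += -float(ll)
        else:
            total += min(abs(v.dna_vaf - p) for p in clusters)
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable variants for concordance scoring")
    return total / n_used


def evaluate_candidates(
    variants: Sequence[VariantCall],
    segments_by_ploidy: Mapping[int, Sequence[CNSegment]],
    transcripts: Sequence[TranscriptModel],
    **score_kwargs,
) -> list[PloidyCandidate]:
    """Score each candidate ploidy's segment profile against observed VAFs."""
    candidates = []
    for ploidy in sorted(segments_by_ploidy):
        gene_cn, _ = assign_gene_copy_numbers(
            segments_by_ploidy[ploidy], transcripts
        )
        score = concordance_score(variants, gene_cn, **score_kwargs)
        candidates.append(PloidyCandidate(ploidy, gene_cn, score))
    return candidates


def select_best_ploidy(
    candidates: Sequence[PloidyCandidate], *, tie_tol: float = 0.005
) -> PloidyCandidate:
    """Pick the candidate with the lowest concordance score; near-ties
    (within ``tie_tol`` of the minimum) resolve to the lowest ploidy.

    The approximate tie band implements a parsimony rule: the cluster set
    of copy number 2c contains that of c, so a doubled profile can never
    score worse than the true one by more than sampling noise. Any
    candidate indistinguishable from the best within ``tie_tol`` is
    treated as tied and the smallest ploidy wins.
    """
    finite = [c for c in candidates if np.isfinite(c.concordance_score)]
    if not finite:
        raise ValueError("no candidate with a finite score")
    best = min(c.concordance_score for c in finite)
    tied = [c for c in finite if c.concordance_score <= best + tie_tol]
    return min(tied, key=lambda c: c.ploidy)
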