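"""Neoantigen chain: candidate filtering, vaccine-construct design,
peptide tiling, and ELISpot positivity scoring.

The filter cascade keeps somatic variants that are reproducible, coding,
non-synonymous, expressed, and absent from the control transcriptome.
Selected mutations become vaccine constructs (mutation flanked by
wild-type protein sequence), which are tiled into overlapping 15-mer
peptides for IFN-gamma ELISpot readout; a candidate is immunogenic when
its mean spot count strictly exceeds 2x the medium-control background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from ._utils import pct_half_up
from .io_core import VariantCall

#: SNV flank = 13 aa each side; in-frame indels 15 aa; frameshifts keep
#: 15 upstream aa then run to the first novel stop
SNV_FLANK = 13
INDEL_FLANK = 15

#: default SNV filter thresholds (criterion -> threshold where numeric)
DEFAULT_THRESHOLDS = {
    "min_mean_expression": 0.0,   # strict >
    "min_dna_vaf": 0.0,           # strict >
    "min_rna_vaf": 0.1,           # strict >
    "max_control_rna_vaf": 0.0,   # must equal 0
}

CRITERIA = [
    "i_both_replicates",
    "ii_non_utr",
    "iii_nonsynonymous",
    "iv_expressed",
    "v_dna_vaf",
    "vi_rna_vaf",
    "vii_control_rna_vaf",
]


@dataclass
class CandidateRecord:
    """One variant with the annotations the filter cascade consumes."""

    variant: VariantCall
    present_in_both_replicates: bool
    mean_expression: float | None
    control_rna_vaf: float | None
    sanger_confirmed: bool | None = None

    @property
    def consequence(self) -> str | None:
        return self.variant.consequence

    @property
    def dna_vaf(self) -> float | None:
        return self.variant.dna_vaf

    @property
    def rna_vaf(self) -> float | None:
        return self.variant.rna_vaf


@dataclass
class VaccineConstruct:
    """Mutated amino-acid stretch plus wild-type flanks, ready for tiling."""

    sequence: str
    mutation_class: str  # SNV | inframe_indel | frameshift
    mutant_positions: list[int]  # 1-based indices within sequence
    source_key: tuple
    truncated_no_stop: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty construct")
        if "*" in self.sequence:
            raise ValueError("construct must not contain a stop symbol")
        if self.mutation_class == "SNV" and len(self.sequence) > 2 * SNV_FLANK + 1:
            raise ValueError("SNV construct longer than 27 aa")


@dataclass(frozen=True)
class PeptideTile:
    sequence: str
    start: int  # 1-based offset within the construct


@dataclass
class ElispotResult:
    candidate_id: str
    spots: list[float]
    background_mean: float
    subtype: str = "untested"  # CD4 | CD8 | both | untested
    wt_tested: bool = False
    wt_positive: bool | None = None

    @property
    def fold_over_background(self) -> float:
        return float(np.mean(self.spots)) / self.background_mean

    @property
    def positive(self) -> bool:
        return self.fold_over_background > 2.0

    @property
    def mutation_specific(self) -> bool | None:
        if not self.positive or not self.wt_tested:
            return None
        return not self.wt_positive


# ---------------------------------------------------------------------------
# filter cascade


def _first_failure(
    rec: CandidateRecord, thresholds: Mapping[str, float], indel_mode: bool
) -> str | None:
    if rec.control_rna_vaf is None:
        raise ValueError(
            f"missing control RNA VAF for {rec.variant.key}; "
            "criterion vii undecidable"
        )
    if rec.consequence is None:
        raise ValueError(f"unannotated candidate {rec.variant.key}")
    if not rec.present_in_both_replicates:
        return "i_both_replicates"
    if rec.consequence in ("UTR", "intergenic"):
        return "ii_non_utr"
    if indel_mode:
        # frameshifts and in-frame indels are retained; only non-coding
        # classes fail (already handled above)
        pass
    elif rec.consequence != "missense":
        # "non-synonymous amino acid exchange (no stop gain or loss)"
        return "iii_nonsynonymous"
    if rec.mean_expression is None or not (
        rec.mean_expression > thresholds["min_mean_expression"]
    ):
        return "iv_expressed"
    if rec.dna_vaf is None or not (rec.dna_vaf > thresholds["min_dna_vaf"]):
        return "v_dna_vaf"
    if rec.rna_vaf is None or not (rec.rna_vaf > thresholds["min_rna_vaf"]):
        return "vi_rna_vaf"
    if rec.control_rna_vaf > thresholds["max_control_rna_vaf"]:
        return "vii_control_rna_vaf"
    return None


def filter_snv_candidates(
    records: Sequence[CandidateRecord],
    thresholds: Mapping[str, float] | None = None,
) -> tuple[list[CandidateRecord], dict[str, int]]:
    """Apply the seven-criterion SNV cascade.

    Criteria, applied in order: (i) present in both replicates, (ii)
    coding (outside UTR), (iii) missense (no stop gain/loss), (iv) mean
    replicate expression > 0, (v) DNA VAF > 0, (vi) RNA VAF > 0.1
    (strict), (vii) control-sample RNA VAF exactly 0. Each rejected
    record is attributed to its first failing criterion; the passing set
    is the plain conjunction and therefore order-independent.
    """
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    passing: list[CandidateRecord] = []
    rejections = {c: 0 for c in CRITERIA}
    for rec in records:
        fail = _first_failure(rec, th, indel_mode=False)
        if fail is None:
            passing.append(rec)
        else:
            rejections[fail] += 1
    return passing, rejections


def filter_indel_candidates(
    records: Sequence[CandidateRecord],
    thresholds: Mapping[str, float] | None = None,
    *,
    require_sanger: bool = False,
) -> tuple[list[CandidateRecord], dict[str, int]]:
    """Indel cascade: like the SNV cascade but RNA VAF > 0 (less
    stringent) and frameshifts retained; with ``require_sanger`` records
    lacking orthogonal confirmation are additionally dropped."""
    th = {**DEFAULT_THRESHOLDS, "min_rna_vaf": 0.0, **(thresholds or {})}
    passing: list[CandidateRecord] = []
    rejections = {c: 0 for c in CRITERIA}
    rejections["sanger"] = 0
    for rec in records:
        fail = _first_failure(rec, th, indel_mode=True)
        if fail is None and require_sanger and not rec.sanger_confirmed:
            fail = "sanger"
        if fail is None:
            passing.append(rec)
        else:
            rejections[fail] += 1
    return passing, rejections


# ---------------------------------------------------------------------------
# construct design


def _translate(cds: str) -> str:
    """Translate a CDS; trailing partial codons are dropped (frameshifted
    tails legitimately end mid-codon)."""
    usable = len(cds) - len(cds) % 3
    return str(Seq(cds[:usable]).translate())


def build_construct(
    variant_key: tuple,
    mutation_class: str,
    wt_cds: str,
    mutant_cds: str,
) -> VaccineConstruct:
    """Design the vaccine construct for one mutation.

    SNV: mutated residue flanked by 13 wild-type aa each side (truncated
    at the protein termini). In-frame indel: altered segment flanked by
    15 wild-type aa. Frameshift: 15 wild-type aa upstream of the shift,
    then the novel translated sequence up to (not including) the first
    stop codon; if no stop is reached the construct ends at the transcript
    end and is flagged.
    """
    wt_protein = _translate(wt_cds)
    mut_protein = _translate(mutant_cds)
    wt_core = wt_protein.split("*", 1)[0]
    mut_core = mut_protein.split("*", 1)[0]
    if mutation_class == "SNV":
        diffs = [
            i for i, (a, b) in enumerate(zip(wt_core, mut_core)) if a != b
        ]
        if len(diffs) != 1:
            raise ValueError(
                f"expected exactly one residue change for SNV {variant_key}, "
                f"found {len(diffs)}"
            )
        p = diffs[0]
        if p >= len(mut_core):
            raise ValueError(f"variant beyond protein length for {variant_key}")
        lo = max(0, p - SNV_FLANK)
        hi = min(len(wt_core), p + SNV_FLANK + 1)
        seq = wt_core[lo:p] + mut_core[p] + wt_core[p + 1 : hi]
        return VaccineConstruct(seq, "SNV", [p - lo + 1], variant_key)

    # common prefix / suffix alignment of the two proteins
    prefix = 0
    while (
        prefix < len(wt_core)
        and prefix < len(mut_core)
        and wt_core[prefix] == mut_core[prefix]
    ):
        prefix += 1
    if prefix == 0 and mutation_class != "frameshift":
        raise ValueError(f"variant beyond protein length for {variant_key}")

    if mutation_class == "inframe_indel":
        suffix = 0
        while (
            suffix < len(wt_core) - prefix
            and suffix < len(mut_core) - prefix
            and wt_core[len(wt_core) - 1 - suffix] == mut_core[len(mut_core) - 1 - suffix]
        ):
            suffix += 1
        altered = mut_core[prefix : len(mut_core) - suffix]
        lo = max(0, prefix - INDEL_FLANK)
        left = wt_core[lo:prefix]
        right = wt_core[len(wt_core) - suffix :][:INDEL_FLANK]
        seq = left + altered + right
        mut_positions = list(
            range(len(left) + 1, len(left) + max(len(altered), 1) + 1)
        )
        return VaccineConstruct(seq, "inframe_indel", mut_positions, variant_key)

    if mutation_class == "frameshift":
        # novel tail: everything from the first divergent residue onward
        novel = mut_core[prefix:]
        truncated = "*" not in mut_protein
        lo = max(0, prefix - INDEL_FLANK)
        left = wt_core[lo:prefix]
        seq = left + novel
        if not seq:
            raise ValueError(f"frameshift construct empty for {variant_key}")
        mut_positions = list(range(len(left) + 1, len(seq) + 1))
        return VaccineConstruct(
            seq, "frameshift", mut_positions, variant_key, truncated_no_stop=truncated
        )

    raise ValueError(f"unknown mutation class {mutation_class!r}")


def tile_peptides(
    construct: VaccineConstruct | str, k: int = 15, overlap: int = 11
) -> list[PeptideTile]:
    """Tile a construct into k-mers with the given overlap.

    Start offsets advance by k - overlap; if the final regular tile stops
    short of the C-terminus one extra tile anchored at L - k + 1 is
    appended so every residue is covered. Constructs shorter than k yield
    a single full-length tile. Duplicate tiles are removed preserving
    order.
    """
    if k <= overlap:
        raise ValueError("tile length must exceed overlap")
    seq = construct.sequence if isinstance(construct, VaccineConstruct) else construct
    if not seq:
        raise ValueError("empty construct")
    length = len(seq)
    if length <= k:
        return [PeptideTile(seq, 1)]
    step = k - overlap
    starts = list(range(0, length - k + 1, step))
    if starts[-1] + k < length:
        starts.append(length - k)
    tiles: list[PeptideTile] = []
    seen: set[tuple[str, int]] = set()
    for s in starts:
        tile = PeptideTile(seq[s : s + k], s + 1)
        if (tile.sequence, tile.start) not in seen:
            seen.add((tile.sequence, tile.start))
            tiles.append(tile)
    return tiles


# ---------------------------------------------------------------------------
# ELISpot scoring


def call_positive(
    candidate_spots: Mapping[str, Sequence[float]],
    background_spots: Sequence[float],
    subtypes: Mapping[str, str] | None = None,
) -> list[ElispotResult]:
    """Score each candidate's wells against the medium-control background.

    Positive iff mean(candidate spots) > 2 x mean(background spots),
    strictly: a fold of exactly 2.0 is negative.
    """
    bg = float(np.mean(list(background_spots)))
    if bg <= 0:
        raise ValueError("background mean must be > 0")
    results = []
    for cid in candidate_spots:
        results.append(
            ElispotResult(
                candidate_id=cid,
                spots=list(candidate_spots[cid]),
                background_mean=bg,
                subtype=(subtypes or {}).get(cid, "untested"),
            )
        )
    return results


def immunogenicity_summary(results: Sequence[ElispotResult]) -> dict[str, int]:
    """Aggregate positivity and T-cell subtype counts."""
    if not results:
        raise ValueError("no ELISpot results")
    n_pos = sum(r.positive for r in results)
    return {
        "n_tested": len(results),
        "n_positive": n_pos,
        "pct_positive": int(pct_half_up(n_pos, len(results))),
        "n_cd4": sum(r.positive and r.subtype == "CD4" for r in results),
        "n_cd8": sum(r.positive and r.subtype == "CD8" for r in results),
        "n_both": sum(r.positive and r.subtype == "both" for r in results),
        "n_mutation_specific": sum(bool(r.mutation_specific) for r in results),
    }
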