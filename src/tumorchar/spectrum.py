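"""96-class trinucleotide mutation spectra and signature decomposition.

SNVs are collapsed to the pyrimidine-reference representation (a purine
reference base is reverse-complemented together with both flanks), binned
into the conventional 96 classes (6 substitution types x 16 flank
contexts, alphabetical within each type), and decomposed over a
signature matrix by non-negative least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io_core import FormatError, VariantCall

BASES = "ACGT"
PYRIMIDINES = "CT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
SUBSTITUTION_TYPES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]

#: canonical 96-class order: substitution type major, then 5' flank, then 3'
CLASS_LABELS = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five in BASES
    for three in BASES
]
CLASS_INDEX = {label: i for i, label in enumerate(CLASS_LABELS)}

#: the 16 C>T classes and the 4 with a 3' G (the XCG deamination contexts)
CT_CLASSES = [i for i, lab in enumerate(CLASS_LABELS) if "[C>T]" in lab]
XCG_CT_CLASSES = [
    i for i, lab in enumerate(CLASS_LABELS) if "[C>T]" in lab and lab.endswith("G")
]


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass
class SpectrumVector:
    """Counts over the 96 trinucleotide substitution classes."""

    counts: np.ndarray
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have exactly 96 classes")
        if (self.counts < 0).any():
            raise ValueError("negative class count")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def normalized(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("cannot normalize an empty spectrum")
        return self.counts / self.total


@dataclass
class ExposureVector:
    """Fractional signature exposures plus the NNLS residual norm."""

    exposures: dict[str, float]
    residual_norm: float

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.exposures.values()):
            raise ValueError("negative exposure")
        total = sum(self.exposures.values())
        if total > 0 and abs(total - 1.0) > 1e-6:
            raise ValueError("exposures must sum to 1 after normalization")


def triplet_class(genome: Mapping[str, str], snv: VariantCall) -> int:
    """96-class index of an SNV given its genomic trinucleotide context.

    Raises at chromosome edges (no flank available); returns -1 when the
    context contains N (callers count such records as skipped).
    """
    if not snv.is_snv:
        raise ValueError("triplet classification applies to SNVs only")
    chrom_seq = genome[snv.chrom]
    if snv.pos < 2 or snv.pos > len(chrom_seq) - 1:
        raise ValueError(
            f"no flanking base for {snv.chrom}:{snv.pos} (chromosome edge)"
        )
    ref_genomic = chrom_seq[snv.pos - 1]
    if ref_genomic != snv.ref:
        raise ValueError(
            f"ref allele mismatch at {snv.chrom}:{snv.pos}: "
            f"variant says {snv.ref!r}, genome has {ref_genomic!r}"
        )
    five = chrom_seq[snv.pos - 2]
    three = chrom_seq[snv.pos]
    ref, alt = snv.ref, snv.alt
    if "N" in (five, three, ref, alt):
        return -1
    if ref not in PYRIMIDINES:
        five, three = COMPLEMENT[three], COMPLEMENT[five]
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return CLASS_INDEX[f"{five}[{ref}>{alt}]{three}"]


def build_spectrum(
    genome: Mapping[str, str], snvs: Sequence[VariantCall]
) -> SpectrumVector:
    """Tally classifiable SNVs into a 96-class spectrum; N-context records
    are skipped and counted."""
    counts = np.zeros(96)
    n_skipped = 0
    for snv in snvs:
        idx = triplet_class(genome, snv)
        if idx < 0:
            n_skipped += 1
        else:
            counts[idx] += 1
    if counts.sum() == 0:
        raise ValueError("no classifiable SNVs")
    return SpectrumVector(counts, n_skipped)


def xcg_enrichment(
    spectrum: SpectrumVector,
    *,
    genome: Mapping[str, str] | None = None,
) -> tuple[float, float]:
    """Fraction of C>T mass at NCG contexts and its enrichment ratio.

    The expectation is 4/16 under uniform context usage; when a genome is
    supplied, the expectation is instead the genome-wide frequency of NCG
    among NCN trinucleotides (both strands collapsed).
    """
    ct_total = spectrum.counts[CT_CLASSES].sum()
    if ct_total == 0:
        raise ValueError("no C>T substitutions in spectrum")
    fraction = float(spectrum.counts[XCG_CT_CLASSES].sum() / ct_total)
    if genome is None:
        expectation = 4 / 16
    else:
        ncg = ncn = 0
        for seq in genome.values():
            for i in range(1, len(seq) - 1):
                center = seq[i]
                if center in "CG":
                    ncn += 1
                    three = seq[i + 1] if center == "C" else COMPLEMENT[seq[i - 1]]
                    if three == "G":
                        ncg += 1
        if ncn == 0:
            raise ValueError("genome has no cytosine contexts")
        expectation = ncg / ncn
    return fraction, fraction / expectation


def decompose_signatures(
    spectrum: SpectrumVector,
    signature_matrix: pd.DataFrame,
    *,
    zero_cutoff: float = 1e-6,
) -> ExposureVector:
    """Non-negative least-squares decomposition of a spectrum.

    ``signature_matrix`` rows are the 96 context labels, columns are
    signatures with columns summing to 1. Exposures are renormalized to
    fractions; exposures below ``zero_cutoff`` are reported as exactly 0
    (matching the convention of omitting 0% signatures).
    """
    if list(signature_matrix.index) != CLASS_LABELS:
        if set(signature_matrix.index) != set(CLASS_LABELS):
            raise ValueError("signature matrix must be indexed by the 96 classes")
        signature_matrix = signature_matrix.loc[CLASS_LABELS]
    a = signature_matrix.to_numpy(dtype=float)
    b = spectrum.normalized
    coef, residual = nnls(a, b)
    total = coef.sum()
    if total == 0:
        exposures = {sig: 0.0 for sig in signature_matrix.columns}
        return ExposureVector(exposures, float(residual))
    frac = coef / total
    frac[frac < zero_cutoff] = 0.0
    s = frac.sum()
    if s > 0:
        frac = frac / s
    exposures = dict(zip(signature_matrix.columns, map(float, frac)))
    return ExposureVector(exposures, float(residual))


# ---------------------------------------------------------------------------
# signature matrix I/O and a synthetic toy matrix


def read_signature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a signature TSV: first column context labels ("A[C>A]A"),
    remaining columns one signature each."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if set(df.index) != set(CLASS_LABELS):
        raise FormatError(f"{path}: context labels do not cover the 96 classes")
    return df.loc[CLASS_LABELS]


def write_signature_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="context")


def toy_signature_matrix() -> pd.DataFrame:
    """Synthetic five-signature matrix with the qualitative shapes of the
    classic breast-cancer signatures (labels follow the AC* naming).

    AC1 concentrates C>T at NCG contexts (methyl-cytosine deamination),
    AC2 puts C>T/C>G mass at TCN contexts (APOBEC-like), AC3 is flat
    ("BRCAness"), AC6 is T>C-heavy, AC20 is T>A-heavy. Constructed
    programmatically; not fitted to any real catalogue.
    """
    sigs = {}

    def empty() -> np.ndarray:
        return np.zeros(96)

    ac1 = empty()
    for i in XCG_CT_CLASSES:
        ac1[i] = 0.20
    for i in CT_CLASSES:
        if i not in XCG_CT_CLASSES:
            ac1[i] = 0.20 / 12
    sigs["AC1"] = ac1

    ac2 = empty()
    ac2[CLASS_INDEX["T[C>T]A"]] = 0.25
    ac2[CLASS_INDEX["T[C>T]T"]] = 0.25
    ac2[CLASS_INDEX["T[C>G]A"]] = 0.20
    ac2[CLASS_INDEX["T[C>G]T"]] = 0.20
    ac2[ac2 == 0] = 0.10 / (96 - 4)
    sigs["AC2"] = ac2

    sigs["AC3"] = np.full(96, 1 / 96)

    ac6 = empty()
    for i, lab in enumerate(CLASS_LABELS):
        if "[T>C]" in lab:
            ac6[i] = 1 / 16
    sigs["AC6"] = ac6

    ac20 = empty()
    for i, lab in enumerate(CLASS_LABELS):
        if "[T>A]" in lab:
            ac20[i] = 1 / 16
    sigs["AC20"] = ac20

    df = pd.DataFrame(sigs, index=CLASS_LABELS)
    return df / df.sum(axis=0)
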