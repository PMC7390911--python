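"""Shared fixtures: a hand-built toy locus and a default synthetic bundle."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from tumorchar.io_core import GenomicInterval, TranscriptModel
from tumorchar.synthetic import SimConfig, generate_bundle

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_bundle():
    """One default-condition bundle shared by read-only tests."""
    return generate_bundle(SimConfig(seed=11))


@pytest.fixture()
def toy_locus():
    """A 120-bp chromosome with one plus-strand and one minus-strand
    single-exon gene, each a clean ORF.

    Plus gene: positions 11-40 code ATG GCT TGG AAA CCC GGG TTT ACG TCA TAA
    (protein MAWKPGFTS). Minus gene: positions 61-90 on the minus strand
    code the same ORF (genome holds its reverse complement).
    """
    plus_cds = "ATGGCTTGGAAACCCGGGTTTACGTCATAA"
    minus_cds = plus_cds
    rc = str.maketrans("ACGT", "TGCA")
    minus_genomic = minus_cds.translate(rc)[::-1]
    seq = (
        "AACCGGTTAC"  # 1-10 upstream
        + plus_cds  # 11-40
        + "ACGTACGTACGTACGTACGT"  # 41-60 spacer
        + minus_genomic  # 61-90
        + "TTGGCCAATTGGCCAATTGGCCAATTGGCC"  # 91-120
    )
    genome = {"chrT": seq}
    plus = TranscriptModel(
        transcript_id="Tplus",
        gene_symbol="Gplus",
        exons=[GenomicInterval("chrT", 6, 45, "+")],
        strand="+",
        cds_start=11,
        cds_end=40,
    )
    minus = TranscriptModel(
        transcript_id="Tminus",
        gene_symbol="Gminus",
        exons=[GenomicInterval("chrT", 56, 95, "-")],
        strand="-",
        cds_start=61,
        cds_end=90,
    )
    return genome, plus, minus
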