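"""Ensemble ("wisdom of crowds") fusion-call consensus.

Per-tool fusion calls from two technical replicates are combined as the
union of tools within each replicate followed by the intersection across
replicates; the intersection is the high-confidence set. Calls are
matched by ordered (5' gene, 3' gene) symbol pair — breakpoint
coordinates are ignored because tools report them in incompatible
conventions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io_core import FormatError, GenomicInterval

FusionKey = tuple[str, str]


@dataclass
class FusionCall:
    """Normalized 5'/3' gene-pair record from one tool on one replicate."""

    gene5: str
    gene3: str
    tool: str
    replicate: int
    breakpoint5: GenomicInterval | None = None
    breakpoint3: GenomicInterval | None = None
    support_reads: int | None = None

    def __post_init__(self) -> None:
        if not self.gene5 or not self.gene3:
            raise ValueError("fusion partners must be non-empty symbols")
        if self.replicate not in (1, 2):
            raise ValueError("replicate must be 1 or 2")


def fusion_key(call: FusionCall) -> FusionKey:
    """Ordered, orientation-sensitive (gene5, gene3) matching key.

    Self-fusions are rejected (the caller counts them).
    """
    if call.gene5 == call.gene3:
        raise ValueError(f"self-fusion {call.gene5} rejected")
    return (call.gene5, call.gene3)


def drop_self_fusions(calls: Iterable[FusionCall]) -> tuple[list[FusionCall], int]:
    kept, dropped = [], 0
    for c in calls:
        if c.gene5 == c.gene3:
            dropped += 1
        else:
            kept.append(c)
    return kept, dropped


def replicate_union(
    tool_sets: Mapping[str, Sequence[FusionCall]],
) -> dict[FusionKey, set[str]]:
    """Union of per-tool call sets for one replicate.

    Returns key -> set of tools that reported it (provenance).
    """
    union: dict[FusionKey, set[str]] = {}
    for tool, calls in tool_sets.items():
        for call in calls:
            union.setdefault(fusion_key(call), set()).add(tool)
    return union


def high_confidence_set(
    union_rep1: Mapping[FusionKey, set[str]],
    union_rep2: Mapping[FusionKey, set[str]],
) -> dict[FusionKey, set[str]]:
    """Intersection of the two replicate unions with merged provenance."""
    return {
        k: set(union_rep1[k]) | set(union_rep2[k])
        for k in union_rep1.keys() & union_rep2.keys()
    }


# ---------------------------------------------------------------------------
# I/O

#: column maps for the tool dialects we normalize; unknown tools fall back
#: to a generic two-column (gene5, gene3) table
TOOL_COLUMN_MAPS: dict[str, dict[str, str]] = {
    "soapfuse": {"gene5": "up_gene", "gene3": "dw_gene", "support": "span_reads"},
    "mapsplice2": {"gene5": "doner_gene", "gene3": "acceptor_gene", "support": "coverage"},
    "infusion": {"gene5": "gene_1", "gene3": "gene_2", "support": "num_split"},
    "starfusion": {"gene5": "LeftGene", "gene3": "RightGene", "support": "JunctionReadCount"},
}


def read_fusion_calls(
    path: str | Path,
    tool: str,
    replicate: int,
    column_map: Mapping[str, str] | None = None,
) -> list[FusionCall]:
    """Read one tool's fusion TSV into normalized calls.

    ``column_map`` overrides the built-in dialect for the tool; unknown
    tools default to columns named gene5/gene3 (generic two-column table).
    """
    cmap = dict(
        column_map
        or TOOL_COLUMN_MAPS.get(tool.lower(), {"gene5": "gene5", "gene3": "gene3"})
    )
    calls: list[FusionCall] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return calls
        for lineno, row in enumerate(reader, start=2):
            g5 = row.get(cmap["gene5"], "")
            g3 = row.get(cmap["gene3"], "")
            if not g5 or not g3:
                raise FormatError(f"{path} line {lineno}: missing gene symbol")
            support = None
            if "support" in cmap and row.get(cmap["support"]):
                support = int(row[cmap["support"]])
            calls.append(
                FusionCall(g5, g3, tool=tool, replicate=replicate, support_reads=support)
            )
    return calls


def write_high_confidence(
    hc: Mapping[FusionKey, set[str]], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene5", "gene3", "tools"])
        for (g5, g3) in sorted(hc):
            writer.writerow([g5, g3, ",".join(sorted(hc[(g5, g3)]))])


def expected_high_confidence_size(
    truth_size: int,
    sensitivities: Sequence[float],
    fp_rates: Sequence[float],
    decoy_pool_size: int,
) -> float:
    """Closed-form expected size of the high-confidence set.

    True pairs survive with probability (1 - prod(1-s_t))^2; each decoy
    pool pair appears in one replicate union with probability
    q = 1 - prod(1 - lambda_t / D) (Poisson decoys drawn uniformly from a
    pool of D pairs, independent per tool and replicate) and in the
    intersection with q^2.
    """
    p_union = 1.0
    for s in sensitivities:
        p_union *= 1 - s
    p_true = (1 - p_union) ** 2
    q = 1.0
    for lam in fp_rates:
        q *= 1 - min(1.0, lam / decoy_pool_size)
    q = 1 - q
    return truth_size * p_true + decoy_pool_size * q**2
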