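"""End-to-end orchestration over a synthetic bundle.

Runs the stages in dependency order (simulate -> consensus -> ploidy ->
spectrum -> fusions -> neoantigen -> expression) from a single config
with one global seed, writes every stage's files under the output
directory, and aggregates the summary statistics into a machine-readable
run report whose every number is recomputable from the files on disk.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from . import consensus as cns
from . import expression as expr
from . import fusions as fus
from . import neoantigen as neo
from . import ploidy as pld
from . import spectrum as spc
from .synthetic import SimConfig, TruthBundle, generate_bundle, write_bundle

STAGES = (
    "consensus",
    "ploidy",
    "spectrum",
    "fusions",
    "neoantigen",
    "expression",
)


@dataclass
class RunReport:
    seed: int
    version: str
    config: dict
    stages: dict[str, dict] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _log(stage: str, message: str) -> None:
    print(f"[tumorchar:{stage}] {message}", file=sys.stderr)


def load_config(config: str | Path | Mapping) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(config)
    cfg.setdefault("seed", 0)
    cfg.setdefault("stages", list(STAGES))
    cfg.setdefault("simulate", {})
    return cfg


def extract_cds_pair(transcript, genome, variant) -> tuple[str, str]:
    """Wild-type and mutant coding sequence of a transcript, run through
    the transcript end (so frameshift tails can be translated until a
    novel stop). Handles SNVs and anchor-base indels on either strand."""
    gpos = [p for e in transcript.exons for p in range(e.start, e.end + 1)]
    seq = "".join(genome[transcript.chrom][p - 1] for p in gpos)
    index = {p: i for i, p in enumerate(gpos)}
    if variant.pos not in index:
        raise ValueError(f"variant {variant.key} outside exons")
    marker_pos = transcript.cds_start if transcript.strand == "+" else transcript.cds_end
    marker_wt = index[marker_pos]
    i = index[variant.pos]
    marker_mut = marker_wt
    if variant.is_snv:
        mut = seq[:i] + variant.alt + seq[i + 1 :]
    elif len(variant.alt) > len(variant.ref):
        ins = variant.alt[1:]
        mut = seq[: i + 1] + ins + seq[i + 1 :]
        if i < marker_wt:
            marker_mut += len(ins)
    else:
        ndel = len(variant.ref) - 1
        mut = seq[: i + 1] + seq[i + 1 + ndel :]
        if i < marker_wt:
            marker_mut -= ndel
    if transcript.strand == "+":
        return seq[marker_wt:], mut[marker_mut:]
    wt_cds = spc.reverse_complement(seq)[len(seq) - 1 - marker_wt :]
    mut_cds = spc.reverse_complement(mut)[len(mut) - 1 - marker_mut :]
    return wt_cds, mut_cds


def run_pipeline(config: str | Path | Mapping, out: str | Path | None = None) -> RunReport:
    """Run all configured stages on a freshly simulated bundle."""
    cfg = load_config(config)
    outdir = Path(out or cfg.get("out", "tumorchar_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    report = RunReport(seed=seed, version=__version__, config=cfg)

    t0 = time.perf_counter()
    sim = SimConfig(seed=seed, **cfg.get("simulate", {}))
    bundle = generate_bundle(sim)
    write_bundle(bundle, outdir / "bundle")
    _log("simulate", f"bundle written ({time.perf_counter() - t0:.1f}s, "
         f"{len(bundle.variants)} variants, {len(bundle.transcripts)} genes)")

    runners = {
        "consensus": _run_consensus,
        "ploidy": _run_ploidy,
        "spectrum": _run_spectrum,
        "fusions": _run_fusions,
        "neoantigen": _run_neoantigen,
        "expression": _run_expression,
    }
    for stage in STAGES:
        if stage not in cfg["stages"]:
            report.skipped.append(stage)
            _log(stage, "skipped (not in config)")
            continue
        t0 = time.perf_counter()
        try:
            report.stages[stage] = runners[stage](bundle, outdir)
        except Exception as exc:  # noqa: BLE001 - stage-named diagnostics
            raise StageError(stage, str(exc)) from exc
        _log(stage, f"done ({time.perf_counter() - t0:.1f}s)")

    (outdir / "report.json").write_text(report.to_json() + "\n")
    return report


def _run_consensus(bundle: TruthBundle, outdir: Path) -> dict:
    inter, union = cns.consensus_calls(bundle.rep_a, bundle.rep_b)
    frac = cns.consensus_fraction(len(inter), len(union))
    snvs = [v for v in bundle.variants if v.is_snv]
    summary = cns.nonsynonymous_summary(snvs)
    nonsyn = [v for v in snvs if v.consequence in cns.NONSYNONYMOUS]
    n_expr, pct_expr = cns.expressed_fraction(nonsyn) if nonsyn else (0, 0)
    r2 = cns.vaf_concordance(bundle.variants)
    return {
        "n_rep_a": len(bundle.rep_a),
        "n_rep_b": len(bundle.rep_b),
        "n_intersection": len(inter),
        "n_union": len(union),
        "consensus_pct": frac,
        **summary,
        "n_expressed_nonsyn": n_expr,
        "pct_expressed_nonsyn": pct_expr,
        "dna_rna_vaf_r2": round(r2, 4),
    }


def _run_ploidy(bundle: TruthBundle, outdir: Path) -> dict:
    candidates = pld.evaluate_candidates(
        bundle.variants, bundle.segments_by_ploidy, bundle.transcripts
    )
    best = pld.select_best_ploidy(candidates)
    return {
        "scores": {c.ploidy: round(c.concordance_score, 5) for c in candidates},
        "selected_ploidy": best.ploidy,
        "true_ploidy": bundle.config.true_ploidy,
    }


def _run_spectrum(bundle: TruthBundle, outdir: Path) -> dict:
    snvs = [v for v in bundle.variants if v.is_snv]
    spec_vec = spc.build_spectrum(bundle.genome, snvs)
    fraction, ratio = spc.xcg_enrichment(spec_vec)
    exposure = spc.decompose_signatures(spec_vec, bundle.signature_matrix)
    return {
        "n_classified": int(spec_vec.total),
        "n_skipped": spec_vec.n_skipped,
        "xcg_ct_fraction": round(fraction, 4),
        "xcg_enrichment_ratio": round(ratio, 4),
        "exposures": {k: round(v, 4) for k, v in exposure.exposures.items()},
        "residual_norm": round(exposure.residual_norm, 6),
    }


def _run_fusions(bundle: TruthBundle, outdir: Path) -> dict:
    unions = {}
    for replicate in (1, 2):
        tool_sets = {
            tool: calls
            for (rep, tool), calls in bundle.fusion_calls.items()
            if rep == replicate
        }
        unions[replicate] = fus.replicate_union(tool_sets)
    hc = fus.high_confidence_set(unions[1], unions[2])
    fus.write_high_confidence(hc, outdir / "fusions_high_confidence.tsv")
    truth = set(bundle.fusion_truth)
    return {
        "n_union_rep1": len(unions[1]),
        "n_union_rep2": len(unions[2]),
        "n_high_confidence": len(hc),
        "n_true_recovered": len(set(hc) & truth),
        "n_decoys_surviving": len(set(hc) - truth),
    }


def _run_neoantigen(bundle: TruthBundle, outdir: Path) -> dict:
    truth = bundle.variant_truth.set_index(["chrom", "pos", "ref", "alt"])
    mean_tpm = (
        bundle.expression["tpm_rep1"] + bundle.expression["tpm_rep2"]
    ) / 2
    records_snv, records_indel = [], []
    for v in bundle.variants:
        row = truth.loc[v.key]
        rec = neo.CandidateRecord(
            variant=v,
            present_in_both_replicates=bool(row["in_rep_a"] and row["in_rep_b"]),
            mean_expression=float(mean_tpm.get(v.gene_symbol, 0.0)),
            control_rna_vaf=float(row["control_rna_vaf"]),
        )
        (records_snv if v.is_snv else records_indel).append(rec)
    passing_snv, rej_snv = neo.filter_snv_candidates(records_snv)
    passing_indel, rej_indel = neo.filter_indel_candidates(records_indel)

    by_tid = {t.transcript_id: t for t in bundle.transcripts}
    constructs = []
    for rec in passing_snv + passing_indel:
        v = rec.variant
        model = by_tid[v.transcript_id]
        wt_cds, mut_cds = extract_cds_pair(model, bundle.genome, v)
        mclass = {
            "missense": "SNV",
            "frameshift": "frameshift",
            "inframe_indel": "inframe_indel",
        }.get(v.consequence)
        if mclass is None:
            continue
        constructs.append(neo.build_construct(v.key, mclass, wt_cds, mut_cds))
    tiles = {c.source_key: neo.tile_peptides(c) for c in constructs}
    with open(outdir / "constructs.fa", "w") as fh:
        for c in constructs:
            key = "_".join(map(str, c.source_key))
            fh.write(f">{key} {c.mutation_class}\n{c.sequence}\n")

    results = neo.call_positive(
        bundle.elispot_candidates, bundle.elispot_background
    )
    summary = neo.immunogenicity_summary(results)
    return {
        "n_snv_candidates": len(records_snv),
        "n_snv_passing": len(passing_snv),
        "snv_rejections": rej_snv,
        "n_indel_candidates": len(records_indel),
        "n_indel_passing": len(passing_indel),
        "indel_rejections": rej_indel,
        "n_constructs": len(constructs),
        "n_peptide_tiles": sum(len(t) for t in tiles.values()),
        "elispot": summary,
    }


def _run_expression(bundle: TruthBundle, outdir: Path) -> dict:
    case = bundle.expression[["tpm_rep1", "tpm_rep2"]]
    ctrl = bundle.expression[["ctrl_tpm_rep1", "ctrl_tpm_rep2"]].rename(
        columns={"ctrl_tpm_rep1": "tpm_rep1", "ctrl_tpm_rep2": "tpm_rep2"}
    )
    de = expr.de_test(case, ctrl)
    de.to_csv(outdir / "de_table.tsv", sep="\t")
    rep_corr = case["tpm_rep1"].corr(case["tpm_rep2"])
    candidates = bundle.expression.index[bundle.expression["is_candidate"]]
    de_frac = expr.candidate_set_de_fraction(candidates, de["de_status"])
    n_up = int((de["de_status"] == "up").sum())
    n_down = int((de["de_status"] == "down").sum())
    return {
        "n_genes": len(de),
        "replicate_tpm_pearson": round(float(rep_corr), 5),
        "n_de_up": n_up,
        "n_de_down": n_down,
        "pct_de_all": float(
            expr.candidate_set_de_fraction(de.index, de["de_status"])
        ),
        "pct_de_candidates": de_frac,
    }
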