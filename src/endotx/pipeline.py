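"""Pipeline orchestration: configuration, stage execution, metrics and logs.

``run_all`` ties the stages together in the order qc -> differential
expression (+consensus) -> lncRNA (+cis/trans) -> splicing (+consensus) ->
allele-specific expression -> RNA editing -> summary.  Each stage writes a
TSV report plus a JSON metrics file recording the counts surviving each
filter, and a run manifest captures the thresholds used.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import allele_expression as ae
from . import expression_de as de
from . import lncrna as lnc
from . import rna_editing as ed
from . import splicing as spl
from .genomic_core import read_bed, read_gtf

logger = logging.getLogger("endotx")

EXIT_OK = 0
EXIT_BAD_CONFIG = 2
EXIT_INPUT_ERROR = 3
EXIT_STAGE_FAILURE = 4

__all__ = ["PipelineConfig", "run_all", "PipelineError", "InputError"]


class PipelineError(RuntimeError):
    exit_code = EXIT_STAGE_FAILURE


class InputError(PipelineError):
    exit_code = EXIT_INPUT_ERROR


@dataclass
class PipelineConfig:
    """Input paths and decision thresholds (defaults are the published
    decision rules: DE alpha 0.05; DAS FDR 0.05 with |dPSI| > 0.1; ASE FDR
    0.001 with |dAAF| > 0.1; editing AAF cap 0.7 observed in >= 3 samples;
    lncRNA minimum length 200 bp; cis window 2000 bp; |r| > 0.9 for trans
    links)."""

    input_dir: str = "."
    output_dir: str = "results"
    control_group: str = "CTR"
    de_alpha: float = 0.05
    das_fdr: float = 0.05
    dpsi: float = 0.1
    ase_fdr: float = 0.001
    daaf: float = 0.1
    edit_max_aaf: float = 0.7
    edit_min_samples: int = 3
    edit_fdr: float = 0.05
    lnc_min_len: int = 200
    cis_window: int = 2000
    trans_r: float = 0.9
    min_expressed_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_alpha", "das_fdr", "ase_fdr", "edit_fdr"):
            if not (0 < getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        for name in ("dpsi", "daaf", "edit_max_aaf"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.lnc_min_len < 0 or self.cis_window < 0:
            raise ValueError("lengths must be non-negative")
        if not (0 < self.trans_r < 1):
            raise ValueError("trans_r must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise InputError(f"stage {stage}: missing input file {path}")
    return path


def _write_metrics(outdir: Path, stage: str, metrics: dict) -> None:
    with open(outdir / f"{stage}_metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=1, sort_keys=True, default=str)


def _log_stage(stage: str, n_in, n_out, t0: float) -> None:
    logger.info("stage=%s n_in=%s n_out=%s elapsed=%.2fs",
                stage, n_in, n_out, time.time() - t0)


def run_all(config: PipelineConfig) -> dict:
    """Execute the full downstream pipeline on a directory of inputs.

    Expects the file layout written by ``synthetic.simulate_to_dir`` (or
    equivalently named real inputs).  Returns a summary dict; raises
    :class:`InputError` (missing files) or :class:`PipelineError` (stage
    failure).
    """
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": []}

    # --- load shared inputs -------------------------------------------------
    genes = read_gtf(_need(indir / "annotation.gtf", "annotation"))
    sine = read_bed(_need(indir / "sine.bed", "annotation"))
    paralog_path = indir / "paralog.bed"
    paralog = read_bed(paralog_path) if paralog_path.exists() else []

    # --- qc (optional) ------------------------------------------------------
    qc_path = indir / "qc.tsv"
    if qc_path.exists():
        t0 = time.time()
        qc = de.QcSummary.from_tsv(qc_path)
        totals = de.qc_totals(qc)
        _write_metrics(outdir, "qc", totals)
        _log_stage("qc", len(qc.sample_ids), len(totals), t0)
        summary["qc_totals"] = totals
        summary["stages"].append("qc")

    # --- differential expression -------------------------------------------
    t0 = time.time()
    cm = de.CountMatrix.from_tsv(_need(indir / "counts.tsv", "de"),
                                 _need(indir / "design.tsv", "de"))
    expressed = de.filter_expressed(cm, config.min_expressed_fraction)
    results = de.nb_de_test(expressed)
    frame = de.de_results_to_frame(results)
    frame.to_csv(outdir / "de_report.tsv", sep="\t", index=False)
    n_sig = int((frame["padj"] < config.de_alpha).sum())
    _write_metrics(outdir, "de", {
        "n_features": cm.n_features, "n_expressed": expressed.n_features,
        "n_significant": n_sig, "alpha": config.de_alpha,
    })
    _log_stage("de", cm.n_features, n_sig, t0)
    summary["de_significant"] = n_sig
    summary["stages"].append("de")

    # --- lncRNA -------------------------------------------------------------
    t0 = time.time()
    scores_path = indir / "lncrna_scores.tsv"
    if scores_path.exists():
        scores = pd.read_csv(scores_path, sep="\t")
        tx_by_id = {tx.transcript_id: tx
                    for g in genes for tx in g.transcripts}
        candidates = []
        for _, row in scores.iterrows():
            tx = tx_by_id.get(row["transcript_id"])
            if tx is None:
                continue
            pf = row.get("pfam_evalue")
            candidates.append(lnc.LncrnaCandidate(
                transcript=tx, cpat_score=float(row["cpat"]),
                cpc2_score=float(row["cpc2"]), feelnc_score=float(row["feelnc"]),
                pfam_evalue=None if pd.isna(pf) else float(pf),
                rfam_hit=bool(row["rfam_hit"]),
            ))
        thresholds = lnc.CascadeThresholds(min_length_bp=config.lnc_min_len)
        candidates, funnel = lnc.classify_candidates(candidates, thresholds)
        lnc_ids = {c.transcript.transcript_id for c in candidates
                   if c.verdict == "lncRNA"}
        pd.DataFrame({
            "transcript_id": [c.transcript.transcript_id for c in candidates],
            "verdict": [c.verdict for c in candidates],
        }).to_csv(outdir / "lncrna_report.tsv", sep="\t", index=False)

        # cis links between accepted lncRNA loci and protein-coding genes
        lnc_gene_ids = {tx_by_id[t].gene_id for t in lnc_ids}
        loci = {g.gene_id: g.span for g in genes if g.gene_id in lnc_gene_ids}
        coding = [g for g in genes if g.biotype == "protein_coding"]
        cis = lnc.cis_targets(loci, coding, config.cis_window)

        # trans links on normalised expression of accepted lncRNA genes
        norm = de.normalized_counts(expressed)
        expr = dict(zip(expressed.feature_ids, norm))
        lnc_expr = {g: v for g, v in expr.items() if g in lnc_gene_ids}
        gene_expr = {g.gene_id: expr[g.gene_id] for g in coding
                     if g.gene_id in expr}
        trans = lnc.trans_targets(lnc_expr, gene_expr, config.trans_r)
        links = pd.DataFrame({
            "lncrna_id": [x.lncrna_id for x in cis + trans],
            "gene_id": [x.gene_id for x in cis + trans],
            "mode": [x.mode for x in cis + trans],
            "r": [("" if x.pearson_r is None else x.pearson_r)
                  for x in cis + trans],
            "distance": [("" if x.distance_bp is None else x.distance_bp)
                         for x in cis + trans],
        })
        links.to_csv(outdir / "lncrna_links.tsv", sep="\t", index=False)
        funnel["cis_links"] = len(cis)
        funnel["trans_links"] = len(trans)
        _write_metrics(outdir, "lncrna", funnel)
        _log_stage("lncrna", funnel["input"], funnel["lncRNA"], t0)
        summary["lncrna_funnel"] = funnel
        summary["stages"].append("lncrna")

    # --- splicing -----------------------------------------------------------
    t0 = time.time()
    events_a, sample_ids = spl.read_events_tsv(_need(indir / "events_a.tsv",
                                                     "splice"))
    events_b, _ = spl.read_events_tsv(_need(indir / "events_b.tsv", "splice"))
    design = pd.read_csv(indir / "design.tsv", sep="\t")
    labels = np.asarray(design.set_index("sample_id").loc[sample_ids, "group"])
    masks = {g: labels == g for g in dict.fromkeys(labels)}

    das_a = spl.das_test(events_a, masks, config.control_group,
                         config.das_fdr, config.dpsi)
    das_b = spl.das_test(events_b, masks, config.control_group,
                         config.das_fdr, config.dpsi)
    sig_a = {r.event_id for r in das_a if r.significant}
    sig_b = {r.event_id for r in das_b if r.significant}
    pairs, cons = spl.consensus_by_location(
        [e for e in events_a if e.event_id in sig_a],
        [e for e in events_b if e.event_id in sig_b])
    rows = []
    for r in das_a + das_b:
        rows.append({"event_id": r.event_id, "gene_id": r.gene_id,
                     "type": r.event_type, "delta_psi": r.delta_psi,
                     "p": r.p_value, "padj": r.p_adjusted,
                     "significant": r.significant})
    pd.DataFrame(rows).to_csv(outdir / "das_report.tsv", sep="\t", index=False)
    metrics = {
        "n_events_a": len(events_a), "n_events_b": len(events_b),
        "n_das_a": len(sig_a), "n_das_b": len(sig_b),
        "n_consensus": cons["n_pairs"],
        "types_a": spl.summarize_das_types(pairs, "a"),
        "types_b": spl.summarize_das_types(pairs, "b"),
    }
    _write_metrics(outdir, "splice", metrics)
    _log_stage("splice", len(events_a) + len(events_b), cons["n_pairs"], t0)
    summary["das_consensus"] = cons["n_pairs"]
    summary["stages"].append("splice")

    # --- allele-specific expression ----------------------------------------
    t0 = time.time()
    sites, var_samples = ae.read_variants_tsv(_need(indir / "variants.tsv",
                                                    "ase"))
    vlabels = np.asarray(design.set_index("sample_id")
                         .loc[var_samples, "group"])
    vmasks = {g: vlabels == g for g in dict.fromkeys(vlabels)}

    hard_ok, hard_drops = ae.hard_filter(sites)
    ssrs = [iv for chrom, seq in _sequences(indir).items()
            for iv in ae.find_ssrs(seq, chrom)]
    pos_ok, pos_drops = ae.positional_filter(hard_ok, genes, paralog, ssrs)
    calls = ae.ase_cascade(pos_ok, vmasks, config.control_group, genes,
                           fdr_threshold=config.ase_fdr,
                           min_delta_aaf=config.daaf)
    ase_calls = [c for c in calls if c.is_ase]
    ae.calls_to_frame(calls, var_samples).to_csv(
        outdir / "ase_report.tsv", sep="\t", index=False)
    metrics = {
        "n_input": len(sites), "n_hard_pass": len(hard_ok),
        "hard_drops": hard_drops, "n_positional_pass": len(pos_ok),
        "positional_drops": pos_drops, "n_tested": len(calls),
        "n_ase": len(ase_calls),
        "het_classes": {k: sum(c.het_class == k for c in ase_calls)
                        for k in ae.HET_CLASSES},
        "regions": {k: sum(c.region_class == k for c in ase_calls)
                    for k in ae.REGION_CLASSES},
    }
    _write_metrics(outdir, "ase", metrics)
    _log_stage("ase", len(sites), len(ase_calls), t0)
    summary["n_ase"] = len(ase_calls)
    summary["stages"].append("ase")

    # --- RNA editing --------------------------------------------------------
    t0 = time.time()
    known_snps = _read_key_list(indir / "known_snps.tsv")
    editome = _read_key_list(indir / "editome.tsv")
    strands = {}
    for g in genes:
        if g.strand in "+-":
            span = g.span
            for s in pos_ok:
                if s.chrom == g.chrom and span.contains(s.pos0):
                    strands.setdefault(s.key, g.strand)
    cands, funnel = ed.editing_cascade(
        pos_ok, sine, known_snps, editome, vmasks, config.control_group,
        site_strands=strands, min_observed_samples=config.edit_min_samples,
        max_aaf=config.edit_max_aaf, imbalance_fdr=config.edit_fdr)
    for cand in cands:
        region, gene_id = ae.classify_region(cand.site, genes)
        cand.region_annotation = region
        cand.gene_name = gene_id
    report = ed.editing_report(cands, vmasks, config.control_group)
    report.to_csv(outdir / "editing_report.tsv", sep="\t", index=False)
    funnel["n_candidates"] = len(cands)
    funnel["n_known_editome"] = sum(c.known_editome for c in cands)
    _write_metrics(outdir, "edit", funnel)
    _log_stage("edit", funnel["input"], len(cands), t0)
    summary["n_editing"] = len(cands)
    summary["stages"].append("edit")

    # --- manifest -----------------------------------------------------------
    manifest = {"config": asdict(config), "summary": {
        k: v for k, v in summary.items() if k != "stages"}}
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return summary


def _sequences(indir: Path) -> dict[str, str]:
    """Plain FASTA reader for the synthetic genome file (if present)."""
    fa = indir / "genome.fa"
    if not fa.exists():
        return {}
    seqs: dict[str, list[str]] = {}
    name: Optional[str] = None
    with open(fa) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def _read_key_list(path: Path) -> set[str]:
    if not path.exists():
        return set()
    out: set[str] = set()
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            line = line.strip()
            if line:
                out.add(line)
    return out
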