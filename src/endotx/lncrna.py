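"""lncRNA classification cascade and cis/trans regulatory-link inference.

A transcript is accepted as a long noncoding RNA only if it survives an
ordered cascade: it is not annotated protein-coding, is >= 200 bp, is
multi-exonic, is called noncoding by all four coding-potential sources
(CPC2 score < 0, FEELnc coding potential < 0.558, CPAT < 0.43, no Pfam
domain hit below e-value 1e-5), and carries no small-RNA family (Rfam)
annotation.  Candidate counts surviving each step are reported so the
filtering funnel can be inspected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genomic_core import GeneModel, GenomicInterval, TranscriptModel, interval_distance

__all__ = [
    "LncrnaCandidate",
    "RegulatoryLink",
    "CascadeThresholds",
    "classify_lncrna",
    "classify_candidates",
    "trans_targets",
    "cis_targets",
]

VERDICTS = ("lncRNA", "coding", "filtered_short", "filtered_monoexonic",
            "filtered_rfam")


@dataclass
class CascadeThresholds:
    min_length_bp: int = 200
    min_exons: int = 2
    cpc2_max: float = 0.0       # noncoding iff score < 0
    feelnc_max: float = 0.558   # noncoding iff coding potential < cutoff
    cpat_max: float = 0.43      # noncoding iff score < cutoff
    pfam_evalue_max: float = 1e-5  # a hit below this e-value marks coding


@dataclass
class LncrnaCandidate:
    transcript: TranscriptModel
    cpat_score: float
    cpc2_score: float
    feelnc_score: float
    pfam_evalue: Optional[float] = None
    rfam_hit: bool = False
    verdict: Optional[str] = None

    @property
    def length_bp(self) -> int:
        return self.transcript.length

    @property
    def exon_count(self) -> int:
        return self.transcript.exon_count


@dataclass
class RegulatoryLink:
    lncrna_id: str
    gene_id: str
    mode: str  # "cis" or "trans"
    pearson_r: Optional[float] = None  # trans only
    distance_bp: Optional[int] = None  # cis only


def classify_lncrna(candidate: LncrnaCandidate,
                    thresholds: CascadeThresholds = CascadeThresholds()) -> str:
    """Run one candidate through the ordered cascade and return the verdict.

    Order: annotated-coding -> short -> monoexonic -> four-way coding
    potential consensus -> Rfam small-RNA removal.  Thresholds are strict
    inequalities (a CPAT score of exactly 0.43 is coding).
    """
    for tool, score in (("cpat", candidate.cpat_score),
                        ("cpc2", candidate.cpc2_score),
                        ("feelnc", candidate.feelnc_score)):
        if score is None or (isinstance(score, float) and np.isnan(score)):
            raise ValueError(f"missing {tool} score for "
                             f"{candidate.transcript.transcript_id}")
    t = thresholds
    if candidate.transcript.biotype == "protein_coding":
        return "coding"
    if candidate.length_bp < t.min_length_bp:
        return "filtered_short"
    if candidate.exon_count < t.min_exons:
        return "filtered_monoexonic"
    pfam_coding = (candidate.pfam_evalue is not None
                   and candidate.pfam_evalue < t.pfam_evalue_max)
    noncoding = (candidate.cpc2_score < t.cpc2_max
                 and candidate.feelnc_score < t.feelnc_max
                 and candidate.cpat_score < t.cpat_max
                 and not pfam_coding)
    if not noncoding:
        return "coding"
    if candidate.rfam_hit:
        return "filtered_rfam"
    return "lncRNA"


def classify_candidates(candidates: list[LncrnaCandidate],
                        thresholds: CascadeThresholds = CascadeThresholds()):
    """Classify all candidates; returns ``(candidates, funnel_counts)``.

    ``funnel_counts`` records how many candidates reach/survive each step,
    mirroring the stepwise identification funnel.
    """
    funnel = {
        "input": len(candidates),
        "non_coding_annotation": 0,
        "length_ok": 0,
        "multi_exonic": 0,
        "coding_potential_ok": 0,
        "lncRNA": 0,
    }
    for cand in candidates:
        cand.verdict = classify_lncrna(cand, thresholds)
        if cand.verdict == "coding" and cand.transcript.biotype == "protein_coding":
            continue
        funnel["non_coding_annotation"] += 1
        if cand.verdict == "filtered_short":
            continue
        funnel["length_ok"] += 1
        if cand.verdict == "filtered_monoexonic":
            continue
        funnel["multi_exonic"] += 1
        if cand.verdict == "coding":
            continue
        funnel["coding_potential_ok"] += 1
        if cand.verdict == "filtered_rfam":
            continue
        funnel["lncRNA"] += 1
    return candidates, funnel


def trans_targets(lnc_expr: dict[str, np.ndarray],
                  gene_expr: dict[str, np.ndarray],
                  r_threshold: float = 0.9) -> list[RegulatoryLink]:
    """Trans links: lncRNA-gene pairs with |Pearson r| above threshold.

    Expression vectors must share sample order and be normalised; constant
    vectors yield no link.  Fewer than three samples raises (the correlation
    is unstable).
    """
    links: list[RegulatoryLink] = []
    for lnc_id, lvec in lnc_expr.items():
        lvec = np.asarray(lvec, dtype=float)
        if lvec.size < 3:
            raise ValueError("need >= 3 samples for correlation")
        for gene_id, gvec in gene_expr.items():
            gvec = np.asarray(gvec, dtype=float)
            if gvec.size != lvec.size:
                raise ValueError("expression vectors must share samples")
            if np.std(lvec) == 0 or np.std(gvec) == 0:
                continue
            r = float(np.corrcoef(lvec, gvec)[0, 1])
            if abs(r) > r_threshold:
                links.append(RegulatoryLink(lnc_id, gene_id, "trans", pearson_r=r))
    return links


def cis_targets(lncrna_loci: dict[str, GenomicInterval],
                genes: list[GeneModel],
                window_bp: int = 2000) -> list[RegulatoryLink]:
    """Cis links: genes whose span lies strictly closer than ``window_bp``
    to the lncRNA locus boundary (overlap counts as distance 0);
    strand-agnostic."""
    links: list[RegulatoryLink] = []
    for lnc_id, locus in lncrna_loci.items():
        for gene in genes:
            d = interval_distance(locus, gene.span)
            if d < window_bp:
                links.append(
                    RegulatoryLink(lnc_id, gene.gene_id, "cis", distance_bp=int(d))
                )
    return links
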