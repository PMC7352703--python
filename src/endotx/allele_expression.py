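"""Allele-specific expression calling.

The cascade mirrors a standard RNA-seq allelic-imbalance pipeline: variant
quality hard filters (depth, mapping quality, quality-by-depth, rank-sum
statistics), positional exclusions (splice-junction vicinity, bidirectional
gene overlaps, padded paralog regions, simple sequence repeats), alternate
allele fraction (AAF) computation, a pooled 2x2 chi-square imbalance test
with BH FDR, heterozygote classing, and gene-region annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genomic_core import GeneModel, GenomicInterval, IntervalIndex, overlaps
from .expression_de import bh_adjust
from .stats2x2 import chi2_2x2

NUCLEOTIDES = ("A", "C", "G", "T")
HET_CLASSES = ("heteroref", "heteroalt", "true")
REGION_CLASSES = ("CDS", "5'UTR", "3'UTR", "intron", "ncRNA",
                  "upstream", "downstream", "intergenic")

# Hard-filter thresholds: values strictly below any threshold are dropped.
HARD_FILTER_THRESHOLDS = {
    "DP": 10.0,
    "MQ": 40.0,
    "QD": 2.0,
    "MQRankSum": -12.5,
    "ReadPosRankSum": -8.0,
}

# Default SSR minimum full-motif repeat counts by motif length.
SSR_MIN_REPEATS = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

__all__ = [
    "VariantSite",
    "AseCall",
    "hard_filter",
    "positional_filter",
    "find_ssrs",
    "aaf",
    "imbalance_test",
    "ase_cascade",
    "classify_het",
    "classify_region",
    "read_variants_tsv",
    "write_variants_tsv",
]


@dataclass
class VariantSite:
    """A biallelic SNV with per-sample allele counts and caller QC stats."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref_allele: str
    alt_allele: str
    ref_counts: np.ndarray  # per sample
    alt_counts: np.ndarray
    quality_stats: dict[str, float] = field(default_factory=dict)
    known_snp_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref_allele not in NUCLEOTIDES or self.alt_allele not in NUCLEOTIDES:
            raise ValueError(f"invalid alleles {self.ref_allele}>{self.alt_allele}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        self.ref_counts = np.asarray(self.ref_counts, dtype=int)
        self.alt_counts = np.asarray(self.alt_counts, dtype=int)
        if (self.ref_counts < 0).any() or (self.alt_counts < 0).any():
            raise ValueError("allele counts must be non-negative")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}"

    @property
    def pos0(self) -> int:
        """0-based coordinate for interval arithmetic."""
        return self.pos - 1

    @property
    def n_samples(self) -> int:
        return self.ref_counts.size


@dataclass
class AseCall:
    site: VariantSite
    aaf_per_sample: np.ndarray  # NaN at zero depth
    delta_aaf: float
    chi2_stat: float
    p_value: float
    fdr: float = float("nan")
    is_ase: bool = False
    het_class: str = ""
    region_class: str = ""
    gene_id: str = ""


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def passes_hard_filter(site: VariantSite) -> bool:
    """Quality predicate: keep unless any stat falls strictly below its
    threshold.  Missing rank-sum stats pass (homozygous-like sites lack
    them)."""
    for stat, threshold in HARD_FILTER_THRESHOLDS.items():
        value = site.quality_stats.get(stat)
        if value is None or np.isnan(value):
            if stat in ("MQRankSum", "ReadPosRankSum"):
                continue
            return False
        if value < threshold:
            return False
    return True


def hard_filter(sites: list[VariantSite]):
    """Apply the quality predicate; returns ``(survivors, drop_counts)``
    where drop_counts tallies the first failing rule per dropped site."""
    survivors: list[VariantSite] = []
    drops: dict[str, int] = {k: 0 for k in HARD_FILTER_THRESHOLDS}
    drops["missing"] = 0
    for site in sites:
        failed = None
        for stat, threshold in HARD_FILTER_THRESHOLDS.items():
            value = site.quality_stats.get(stat)
            if value is None or np.isnan(value):
                if stat in ("MQRankSum", "ReadPosRankSum"):
                    continue
                failed = "missing"
                break
            if value < threshold:
                failed = stat
                break
        if failed is None:
            survivors.append(site)
        else:
            drops[failed] += 1
    return survivors, drops


def _junction_windows(genes: list[GeneModel], pad: int) -> IntervalIndex:
    """Windows of +-pad bp around internal exon-intron boundaries."""
    idx = IntervalIndex()
    for gene in genes:
        for tx in gene.transcripts:
            if tx.exon_count < 2:
                continue
            # pad bases on each side of the junction point between exon
            # and intron: window [J - pad, J + pad)
            for i, exon in enumerate(tx.exons):
                if i > 0:  # junction at exon start
                    idx.add(GenomicInterval(exon.chrom,
                                            max(0, exon.start - pad),
                                            exon.start + pad))
                if i < tx.exon_count - 1:  # junction at exon end
                    idx.add(GenomicInterval(exon.chrom,
                                            max(0, exon.end - pad),
                                            exon.end + pad))
    return idx


def _bidirectional_regions(genes: list[GeneModel]) -> IntervalIndex:
    """Overlaps of gene pairs on opposite strands."""
    idx = IntervalIndex()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom_genes in by_chrom.values():
        for i, a in enumerate(chrom_genes):
            for b in chrom_genes[i + 1:]:
                if {a.strand, b.strand} == {"+", "-"} and overlaps(a.span, b.span):
                    start = max(a.span.start, b.span.start)
                    end = min(a.span.end, b.span.end)
                    idx.add(GenomicInterval(a.chrom, start, end))
    return idx


def positional_filter(sites: list[VariantSite], gene_models: list[GeneModel],
                      paralog_intervals: list[GenomicInterval],
                      ssr_intervals: list[GenomicInterval],
                      junction_pad: int = 5, paralog_pad: int = 50):
    """Drop sites near splice junctions, inside bidirectional-gene overlaps,
    inside padded paralog regions, or inside SSRs.

    Returns ``(survivors, drop_counts)``; a site failing several rules is
    counted once under the first rule in the order above.
    """
    junctions = _junction_windows(gene_models, junction_pad)
    bidir = _bidirectional_regions(gene_models)
    paralogs = IntervalIndex()
    for iv in paralog_intervals:
        paralogs.add(GenomicInterval(iv.chrom, max(0, iv.start - paralog_pad),
                                     iv.end + paralog_pad, iv.strand))
    ssrs = IntervalIndex.from_intervals(ssr_intervals)

    survivors: list[VariantSite] = []
    drops = {"junction": 0, "bidirectional": 0, "paralog": 0, "ssr": 0}
    for site in sites:
        p = site.pos0
        if junctions.query_point(site.chrom, p):
            drops["junction"] += 1
        elif bidir.query_point(site.chrom, p):
            drops["bidirectional"] += 1
        elif paralogs.query_point(site.chrom, p):
            drops["paralog"] += 1
        elif ssrs.query_point(site.chrom, p):
            drops["ssr"] += 1
        else:
            survivors.append(site)
    return survivors, drops


def find_ssrs(sequence: str, chrom: str,
              min_repeats: dict[int, int] = SSR_MIN_REPEATS
              ) -> list[GenomicInterval]:
    """Locate maximal perfect tandem repeats (microsatellites).

    Motif lengths 1-6 are scanned; a run qualifies when it contains at least
    ``min_repeats[len(motif)]`` full motif copies (defaults: mono 10, di 6,
    tri..hexa 5).  Runs extend through a trailing partial motif.  ``N``
    breaks all repeats.  Overlapping or adjacent reported runs are merged.
    """
    seq = sequence.upper()
    n = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = arr != ord("N")
    raw: list[tuple[int, int]] = []
    for motif_len, need in sorted(min_repeats.items()):
        if n < motif_len * need:
            continue
        # position i continues a period-motif_len run if it matches the base
        # motif_len before it; N never matches
        match = (arr[motif_len:] == arr[:-motif_len]) \
            & valid[motif_len:] & valid[:-motif_len]
        # maximal runs of consecutive matches
        padded = np.concatenate(([False], match, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for run_start, run_end in zip(edges[::2], edges[1::2]):
            start, end = int(run_start), int(run_end) + motif_len
            if (end - start) // motif_len < need:
                continue
            motif = seq[start:start + motif_len]
            # skip motifs that are themselves periodic (e.g. "AA" for di)
            if any(motif == motif[:d] * (motif_len // d)
                   for d in range(1, motif_len) if motif_len % d == 0):
                continue
            raw.append((start, end))
    if not raw:
        return []
    raw.sort()
    merged: list[list[int]] = [list(raw[0])]
    for start, end in raw[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [GenomicInterval(chrom, s, e) for s, e in merged]


# ---------------------------------------------------------------------------
# AAF and imbalance
# ---------------------------------------------------------------------------

def aaf(site: VariantSite, sample_index: int) -> float:
    """Alternate allele fraction in one sample; NaN at zero depth."""
    ref = int(site.ref_counts[sample_index])
    alt = int(site.alt_counts[sample_index])
    depth = ref + alt
    if depth == 0:
        return float("nan")
    return alt / depth


def aaf_vector(site: VariantSite) -> np.ndarray:
    depth = site.ref_counts + site.alt_counts
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(depth > 0, site.alt_counts / np.maximum(depth, 1), np.nan)


def imbalance_test(site: VariantSite, group_masks: dict[str, np.ndarray],
                   control_group: str) -> tuple[float, float, float]:
    """Pooled 2x2 chi-square on [ref, alt] counts per group.

    Returns ``(chi2_stat, p_value, delta_aaf)`` where delta_aaf is the
    pooled AAF of the treated group minus the pooled AAF of the control.
    """
    names = list(group_masks)
    if len(names) != 2 or control_group not in names:
        raise ValueError("exactly two groups including the control required")
    trt = next(n for n in names if n != control_group)
    cmask = np.asarray(group_masks[control_group], dtype=bool)
    tmask = np.asarray(group_masks[trt], dtype=bool)
    ref_c, alt_c = int(site.ref_counts[cmask].sum()), int(site.alt_counts[cmask].sum())
    ref_t, alt_t = int(site.ref_counts[tmask].sum()), int(site.alt_counts[tmask].sum())
    stat, p = chi2_2x2(ref_c, alt_c, ref_t, alt_t)
    aaf_c = alt_c / (ref_c + alt_c) if ref_c + alt_c else float("nan")
    aaf_t = alt_t / (ref_t + alt_t) if ref_t + alt_t else float("nan")
    delta = aaf_t - aaf_c
    return stat, p, float(delta)


def classify_het(aaf_per_sample: np.ndarray,
                 low: float = 0.4, high: float = 0.6) -> str:
    """Expression-skew class from the mean defined AAF.

    mean < ``low`` -> heteroref (reference-dominant); mean > ``high`` ->
    heteroalt (alternate-dominant); otherwise a balanced "true"
    heterozygote.  The 0.4/0.6 binning is a documented stand-in: the class
    boundaries are not standardised.
    """
    arr = np.asarray(aaf_per_sample, dtype=float)
    if np.isnan(arr).all():
        raise ValueError("no defined AAF in any sample")
    mean = float(np.nanmean(arr))
    eps = 1e-9  # boundary means count as balanced
    if mean < low - eps:
        return "heteroref"
    if mean > high + eps:
        return "heteroalt"
    return "true"


# ---------------------------------------------------------------------------
# Region annotation
# ---------------------------------------------------------------------------

def classify_region(site: VariantSite, gene_models: list[GeneModel],
                    flank_bp: int = 5000) -> tuple[str, str]:
    """Annotate a site with its gene region; returns (region_class, gene_id).

    Precedence: CDS > 5'UTR > 3'UTR > intron > ncRNA exon > upstream /
    downstream (within ``flank_bp`` of a gene span, strand-aware) >
    intergenic.  Transcripts are scanned in annotation order and the first
    transcript matching at the winning precedence level is reported.
    """
    p = site.pos0
    best_rank = len(REGION_CLASSES)
    best: tuple[str, str] = ("intergenic", "")
    rank = {c: i for i, c in enumerate(
        ("CDS", "5'UTR", "3'UTR", "intron", "ncRNA", "flank"))}

    def consider(region: str, gene_id: str, level: str) -> None:
        nonlocal best_rank, best
        r = rank[level]
        if r < best_rank:
            best_rank = r
            best = (region, gene_id)

    for gene in gene_models:
        if gene.chrom != site.chrom:
            continue
        span = gene.span
        coding_gene = gene.biotype == "protein_coding"
        if span.contains(p):
            for tx in gene.transcripts:
                if not tx.span.contains(p):
                    continue
                in_exon = any(e.contains(p) for e in tx.exons)
                if tx.cds:
                    if any(c.contains(p) for c in tx.cds):
                        consider("CDS", gene.gene_id, "CDS")
                        continue
                    if in_exon:
                        utr5, utr3 = tx.utrs()
                        if any(u.contains(p) for u in utr5):
                            consider("5'UTR", gene.gene_id, "5'UTR")
                            continue
                        if any(u.contains(p) for u in utr3):
                            consider("3'UTR", gene.gene_id, "3'UTR")
                            continue
                    consider("intron", gene.gene_id, "intron")
                elif in_exon and not coding_gene:
                    consider("ncRNA", gene.gene_id, "ncRNA")
                else:
                    consider("intron", gene.gene_id, "intron")
        else:
            upstream_side = p < span.start
            d = span.start - p if upstream_side else p - span.end + 1
            if d <= flank_bp:
                if gene.strand == "-":
                    region = "downstream" if upstream_side else "upstream"
                else:
                    region = "upstream" if upstream_side else "downstream"
                consider(region, gene.gene_id, "flank")
    return best


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

def ase_cascade(sites: list[VariantSite], group_masks: dict[str, np.ndarray],
                control_group: str, gene_models: Optional[list[GeneModel]] = None,
                min_observed_fraction: float = 0.5, fdr_threshold: float = 0.001,
                min_delta_aaf: float = 0.1, flank_bp: int = 5000
                ) -> list[AseCall]:
    """Test allelic imbalance for sites observed in enough libraries.

    Sites with AAF > 0 in at least ``min_observed_fraction`` of libraries
    are tested; BH is applied across all tested sites in one family.  A call
    is flagged ASE when |delta AAF| > ``min_delta_aaf`` and FDR <
    ``fdr_threshold``.  Heterozygote class and (when annotation is given)
    gene region are attached to every call.
    """
    calls: list[AseCall] = []
    for site in sites:
        vec = aaf_vector(site)
        observed = int(np.nansum(vec > 0))
        if observed < np.ceil(min_observed_fraction * site.n_samples):
            continue
        stat, p, delta = imbalance_test(site, group_masks, control_group)
        call = AseCall(site, vec, delta, stat, p)
        call.het_class = classify_het(vec)
        if gene_models is not None:
            call.region_class, call.gene_id = classify_region(
                site, gene_models, flank_bp)
        calls.append(call)
    if calls:
        fdrs = bh_adjust(np.array([c.p_value for c in calls]))
        for call, fdr in zip(calls, fdrs):
            call.fdr = float(fdr)
            call.is_ase = bool(abs(call.delta_aaf) > min_delta_aaf
                               and fdr < fdr_threshold)
    return calls


def calls_to_frame(calls: list[AseCall], sample_ids: list[str]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "chrom": c.site.chrom, "pos": c.site.pos,
            "ref": c.site.ref_allele, "alt": c.site.alt_allele,
        }
        for s, v in zip(sample_ids, c.aaf_per_sample):
            row[f"aaf:{s}"] = round(float(v), 4) if not np.isnan(v) else ""
        row.update({
            "delta_aaf": c.delta_aaf, "chi2": c.chi2_stat, "p": c.p_value,
            "fdr": c.fdr, "is_ase": c.is_ase, "het_class": c.het_class,
            "region_class": c.region_class, "gene": c.gene_id,
            "rsID": c.site.known_snp_id or "",
        })
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Flat TSV interface for variant tables
# ---------------------------------------------------------------------------

def write_variants_tsv(sites: list[VariantSite], sample_ids: list[str],
                       path) -> None:
    rows = []
    for s in sites:
        row = {"chrom": s.chrom, "pos": s.pos, "ref": s.ref_allele,
               "alt": s.alt_allele, "rsID": s.known_snp_id or ""}
        for stat in HARD_FILTER_THRESHOLDS:
            v = s.quality_stats.get(stat)
            row[stat] = "" if v is None or np.isnan(v) else v
        for name, rc, ac in zip(sample_ids, s.ref_counts, s.alt_counts):
            row[f"ref:{name}"] = int(rc)
            row[f"alt:{name}"] = int(ac)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> tuple[list[VariantSite], list[str]]:
    df = pd.read_csv(path, sep="\t")
    ref_cols = [c for c in df.columns if c.startswith("ref:")]
    alt_cols = [c for c in df.columns if c.startswith("alt:")]
    sample_ids = [c.split(":", 1)[1] for c in ref_cols]
    sites = []
    for _, row in df.iterrows():
        stats = {}
        for stat in HARD_FILTER_THRESHOLDS:
            v = row.get(stat)
            if v is not None and v != "" and not pd.isna(v):
                stats[stat] = float(v)
        rsid = row.get("rsID")
        sites.append(VariantSite(
            chrom=str(row["chrom"]), pos=int(row["pos"]),
            ref_allele=row["ref"], alt_allele=row["alt"],
            ref_counts=row[ref_cols].to_numpy(dtype=int),
            alt_counts=row[alt_cols].to_numpy(dtype=int),
            quality_stats=stats,
            known_snp_id=None if pd.isna(rsid) or rsid == "" else str(rsid),
        ))
    return sites, sample_ids
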