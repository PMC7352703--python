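"""Seeded generators for every input the pipeline consumes.

The generators emulate the study design the package targets: two groups of
three biological replicates; negative-binomial gene counts with a fraction
of genes carrying a spiked log2 fold change; binomial per-site allele
counts with a fraction of sites carrying a group-shifted alternate-allele
fraction; A>G editing sites confined to SINE repeat intervals; splicing
events with binomial inclusion counts and group-shifted PSI reported by two
pseudo-callers with jittered spans.  Every draw flows from a single seed,
so outputs are byte-identical across runs, and the planted ground truth is
returned alongside each table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .genomic_core import (GeneModel, GenomicInterval, TranscriptModel,
                           write_bed, write_gtf)
from .expression_de import CountMatrix
from .splicing import SplicingEvent, write_events_tsv
from .allele_expression import VariantSite, write_variants_tsv
from .lncrna import LncrnaCandidate

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "Annotation",
    "make_annotation",
    "make_counts",
    "make_variants",
    "make_splicing",
    "make_lncrna_candidates",
    "simulate_to_dir",
]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study.

    Defaults reproduce the study conditions the package is tested under:
    3 vs 3 replicates, log2 fold change 2 on differential genes, sequencing
    depth around 60x at variant sites, an AAF shift of 0.35 at allele-
    imbalanced sites and a PSI shift of 0.4 at differentially spliced
    events.
    """

    seed: int = 0
    n_genes: int = 200
    n_samples_per_group: int = 3
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    n_variant_sites: int = 300
    site_depth_mean: int = 60
    ase_fraction: float = 0.1
    ase_delta_aaf: float = 0.35
    n_editing_sites: int = 40
    sine_density: float = 0.15
    n_splicing_events: int = 200
    das_fraction: float = 0.1
    das_delta_psi: float = 0.4
    hard_fail_fraction: float = 0.05
    event_depth_mean: int = 50

    def __post_init__(self) -> None:
        for name in ("de_fraction", "ase_fraction", "das_fraction",
                     "sine_density", "hard_fail_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        n = self.n_samples_per_group
        return [f"CTR{i+1}" for i in range(n)] + [f"LPS{i+1}" for i in range(n)]

    @property
    def group_labels(self) -> list[str]:
        n = self.n_samples_per_group
        return ["CTR"] * n + ["LPS"] * n

    def group_masks(self) -> dict[str, np.ndarray]:
        labels = np.asarray(self.group_labels)
        return {"CTR": labels == "CTR", "LPS": labels == "LPS"}


@dataclass
class GroundTruth:
    de_gene_ids: list[str] = field(default_factory=list)
    ase_site_keys: list[str] = field(default_factory=list)
    editing_site_keys: list[str] = field(default_factory=list)
    das_event_ids: list[str] = field(default_factory=list)
    lncrna_ids: list[str] = field(default_factory=list)
    ssr_intervals: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class Annotation:
    genes: list[GeneModel]
    sine_intervals: list[GenomicInterval]
    paralog_intervals: list[GenomicInterval]
    sequences: dict[str, str]
    truth: GroundTruth


GENE_SPACING = 12_000  # bp between gene starts on a synthetic chromosome
GENES_PER_CHROM = 50


def _build_gene(gene_idx: int, chrom: str, offset: int, rng: np.random.Generator,
                biotype: str, strand: str) -> GeneModel:
    # lncRNA-biotype loci occasionally get mono-exonic or short transcripts
    # so the discovery cascade's early filters are exercised
    n_exons = int(rng.integers(1, 5)) if biotype == "lncRNA" \
        else int(rng.integers(2, 5))
    exons = []
    pos = offset
    for _ in range(n_exons):
        exon_len = (int(rng.integers(80, 400)) if biotype == "lncRNA"
                    else int(rng.integers(120, 400)))
        exons.append((pos, pos + exon_len))
        pos += exon_len + int(rng.integers(200, 800))
    gid = f"G{gene_idx:04d}"
    tid = f"{gid}.t1"
    exon_ivs = [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    cds: list[GenomicInterval] = []
    if biotype == "protein_coding":
        # CDS spans interior of the exon chain, leaving UTRs on both ends
        first_s, first_e = exons[0]
        last_s, last_e = exons[-1]
        cds_start = first_s + min(60, (first_e - first_s) // 2)
        cds_end = last_e - min(60, (last_e - last_s) // 2)
        for s, e in exons:
            cs, ce = max(s, cds_start), min(e, cds_end)
            if cs < ce:
                cds.append(GenomicInterval(chrom, cs, ce, strand))
    tx = TranscriptModel(transcript_id=tid, gene_id=gid, exons=exon_ivs,
                         cds=cds, biotype=biotype)
    return GeneModel(gene_id=gid, name=gid, transcripts=[tx], biotype=biotype)


def _plant_ssr(seq: list, start: int, rng: np.random.Generator) -> tuple[int, int]:
    motifs = ["A", "AC", "AGT", "AAGT", "AATGC", "AACGTC"]
    min_copies = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
    motif = motifs[int(rng.integers(0, len(motifs)))]
    copies = min_copies[len(motif)] + int(rng.integers(0, 4))
    repeat = motif * copies
    seq[start:start + len(repeat)] = list(repeat)
    return start, start + len(repeat)


def make_annotation(config: SimulationConfig,
                    rng: Optional[np.random.Generator] = None) -> Annotation:
    """Gene models, SINE/paralog intervals and sequences with planted SSRs.

    Every 10th gene gets an opposite-strand overlapping partner so the
    bidirectional-gene exclusion has work to do.  SINE intervals are laid in
    intergenic space at roughly ``sine_density`` coverage; sequences carry
    planted perfect tandem repeats recorded in the ground truth.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    truth = GroundTruth()
    genes: list[GeneModel] = []
    sine: list[GenomicInterval] = []
    paralog: list[GenomicInterval] = []
    sequences: dict[str, str] = {}

    n_chroms = max(1, int(np.ceil(config.n_genes / GENES_PER_CHROM)))
    gene_idx = 0
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        n_here = min(GENES_PER_CHROM, config.n_genes - gene_idx)
        chrom_len = GENE_SPACING * (n_here + 1)
        seq = list(rng.choice(list("ACGT"), size=chrom_len))
        for gi in range(n_here):
            offset = GENE_SPACING * gi + 500
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = ("protein_coding" if rng.random() < 0.8 else "lncRNA")
            gene = _build_gene(gene_idx, chrom, offset, rng, biotype, strand)
            genes.append(gene)
            gene_idx += 1
            # opposite-strand overlapping partner -> bidirectional pair
            if gene_idx % 10 == 0 and config.n_genes - gene_idx > 0:
                other = "-" if strand == "+" else "+"
                partner = _build_gene(gene_idx, chrom,
                                      offset + int(rng.integers(100, 600)),
                                      rng, "protein_coding", other)
                genes.append(partner)
                gene_idx += 1
            span = gene.span
            # intergenic gap after the gene hosts SINE / paralog / SSR features
            gap_start = span.end + 200
            gap_end = GENE_SPACING * (gi + 1) + 300
            if gap_end - gap_start > 1200:
                if rng.random() < config.sine_density / 0.15 * 0.5:
                    s = int(rng.integers(gap_start, gap_end - 400))
                    sine.append(GenomicInterval(chrom, s, s + 300))
                if rng.random() < 0.15:
                    s = int(rng.integers(gap_start, gap_end - 300))
                    paralog.append(GenomicInterval(chrom, s, s + 150))
                if rng.random() < 0.2:
                    s = int(rng.integers(gap_start, gap_end - 100))
                    ssr_start, ssr_end = _plant_ssr(seq, s, rng)
                    truth.ssr_intervals.append((chrom, ssr_start, ssr_end))
        sequences[chrom] = "".join(seq)
        if gene_idx >= config.n_genes:
            break
    return Annotation(genes=genes, sine_intervals=sine,
                      paralog_intervals=paralog, sequences=sequences,
                      truth=truth)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB draws parameterised by mean and dispersion alpha (var = mu + a mu^2)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def make_counts(config: SimulationConfig, annotation: Annotation,
                rng: Optional[np.random.Generator] = None
                ) -> tuple[CountMatrix, GroundTruth]:
    """NB count matrix over the annotated genes with spiked fold changes.

    ``de_fraction`` of genes have the treated-group mean multiplied by
    ``2**de_log2fc``; the affected gene ids are recorded in the truth.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    genes = [g.gene_id for g in annotation.genes]
    n_genes = len(genes)
    n = config.n_samples_per_group
    base_mean = np.exp(rng.normal(np.log(100.0), 1.0, size=n_genes))
    n_de = int(round(config.de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], int)
    direction = np.where(rng.random(n_de) < 0.5, 1.0, -1.0)

    mu = np.tile(base_mean[:, None], (1, 2 * n))
    for k, gi in enumerate(de_idx):
        mu[gi, n:] = base_mean[gi] * 2.0 ** (config.de_log2fc * direction[k])
    counts = _nb_draw(rng, mu, config.nb_dispersion)

    cm = CountMatrix(feature_ids=genes, sample_ids=config.sample_ids,
                     counts=counts, group_labels=config.group_labels)
    truth = GroundTruth(de_gene_ids=[genes[i] for i in de_idx])
    return cm, truth


def _passing_quality(rng: np.random.Generator) -> dict[str, float]:
    return {
        "DP": float(rng.integers(20, 200)),
        "MQ": float(rng.uniform(50, 60)),
        "QD": float(rng.uniform(5, 30)),
        "MQRankSum": float(rng.uniform(-3, 3)),
        "ReadPosRankSum": float(rng.uniform(-3, 3)),
    }


def _failing_quality(rng: np.random.Generator) -> dict[str, float]:
    stats = _passing_quality(rng)
    which = rng.choice(["DP", "MQ", "QD", "MQRankSum", "ReadPosRankSum"])
    bad = {"DP": float(rng.integers(1, 10)), "MQ": float(rng.uniform(10, 39.9)),
           "QD": float(rng.uniform(0, 1.9)), "MQRankSum": float(rng.uniform(-20, -12.6)),
           "ReadPosRankSum": float(rng.uniform(-15, -8.1))}
    stats[which] = bad[which]
    return stats


def _exonic_positions(annotation: Annotation, rng: np.random.Generator,
                      count: int, margin: int = 10) -> list[tuple[str, int]]:
    """Sample distinct exon-interior positions clear of junction windows,
    skipping genes involved in opposite-strand (bidirectional) overlaps so
    planted sites survive the positional exclusions."""
    from .genomic_core import overlaps as _ov
    bidirectional: set[str] = set()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in annotation.genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom_genes in by_chrom.values():
        for i, a in enumerate(chrom_genes):
            for b in chrom_genes[i + 1:]:
                if {a.strand, b.strand} == {"+", "-"} and _ov(a.span, b.span):
                    bidirectional.update((a.gene_id, b.gene_id))
    pool: list[tuple[str, int, int]] = []
    for gene in annotation.genes:
        if gene.gene_id in bidirectional:
            continue
        for tx in gene.transcripts:
            for exon in tx.exons:
                if len(exon) > 2 * margin + 2:
                    pool.append((exon.chrom, exon.start + margin,
                                 exon.end - margin))
    out: list[tuple[str, int]] = []
    seen: set[tuple[str, int]] = set()
    while len(out) < count:
        chrom, lo, hi = pool[int(rng.integers(0, len(pool)))]
        pos = int(rng.integers(lo, hi))
        if (chrom, pos) not in seen:
            seen.add((chrom, pos))
            out.append((chrom, pos))
    return out


_TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _binomial_site(rng: np.random.Generator, depth_mean: int,
                   aafs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    depth = rng.poisson(depth_mean, size=aafs.size).astype(int)
    alt = rng.binomial(depth, aafs)
    return depth - alt, alt


def make_variants(config: SimulationConfig, annotation: Annotation,
                  rng: Optional[np.random.Generator] = None):
    """Variant table with planted allele-imbalance and editing signal.

    Returns ``(sites, known_snp_keys, editome_keys, truth)``.  Null sites
    draw both groups at a shared AAF near 0.5; ``ase_fraction`` of sites
    shift the treated group by ``ase_delta_aaf``.  Editing sites are A>G
    substitutions placed inside SINE intervals with moderate AAF.  Decoy
    editing-like sites cover the known-SNP, high-AAF, non-canonical and
    non-SINE failure modes.  A ``hard_fail_fraction`` of null sites carry a
    failing quality statistic.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    n_samples = 2 * config.n_samples_per_group
    n = config.n_samples_per_group
    sites: list[VariantSite] = []
    truth = GroundTruth()
    known_snp_keys: set[str] = set()
    editome_keys: set[str] = set()

    positions = _exonic_positions(annotation, rng, config.n_variant_sites)
    n_ase = int(round(config.ase_fraction * config.n_variant_sites))
    ase_flags = np.zeros(config.n_variant_sites, dtype=bool)
    if n_ase:
        ase_flags[rng.choice(config.n_variant_sites, n_ase, replace=False)] = True

    for (chrom, pos0), is_ase in zip(positions, ase_flags):
        ref = str(rng.choice(list("ACGT")))
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        if is_ase:
            base = 0.2
            aafs = np.array([base] * n + [base + config.ase_delta_aaf] * n)
        else:
            shared = float(rng.uniform(0.35, 0.65))
            aafs = np.full(n_samples, shared)
        ref_counts, alt_counts = _binomial_site(rng, config.site_depth_mean, aafs)
        failing = (not is_ase) and rng.random() < config.hard_fail_fraction
        quality = _failing_quality(rng) if failing else _passing_quality(rng)
        site = VariantSite(chrom, pos0 + 1, ref, alt, ref_counts, alt_counts,
                           quality_stats=quality)
        sites.append(site)
        if is_ase and not failing:
            truth.ase_site_keys.append(site.key)

    # --- editing sites inside SINE intervals --------------------------------
    sine = annotation.sine_intervals
    used: set[tuple[str, int]] = {(c, p) for c, p in positions}

    def sample_sine_pos() -> tuple[str, int]:
        while True:
            iv = sine[int(rng.integers(0, len(sine)))]
            pos0 = int(rng.integers(iv.start, iv.end))
            if (iv.chrom, pos0) not in used:
                used.add((iv.chrom, pos0))
                return iv.chrom, pos0

    def editing_aafs() -> np.ndarray:
        return rng.uniform(0.15, 0.5, size=n_samples)

    def draw_editing_counts(aafs, max_aaf=0.6, min_observed=4):
        # rejection-sample so every planted site is unambiguously observable
        while True:
            ref_c, alt_c = _binomial_site(rng, config.site_depth_mean, aafs)
            depth = ref_c + alt_c
            if (depth == 0).any():
                continue
            frac = alt_c / depth
            if (frac > 0).sum() >= min_observed and frac.max() <= max_aaf:
                return ref_c, alt_c

    if sine:
        for _ in range(config.n_editing_sites):
            chrom, pos0 = sample_sine_pos()
            ref_c, alt_c = draw_editing_counts(editing_aafs())
            site = VariantSite(chrom, pos0 + 1, "A", "G", ref_c, alt_c,
                               quality_stats=_passing_quality(rng))
            sites.append(site)
            truth.editing_site_keys.append(site.key)

        n_decoy = max(4, config.n_editing_sites // 4)
        for _ in range(n_decoy):  # known-SNP decoys
            chrom, pos0 = sample_sine_pos()
            ref_c, alt_c = draw_editing_counts(editing_aafs())
            site = VariantSite(chrom, pos0 + 1, "A", "G", ref_c, alt_c,
                               quality_stats=_passing_quality(rng),
                               known_snp_id=f"rs{900000 + pos0}")
            known_snp_keys.add(site.key)
            sites.append(site)
        for _ in range(n_decoy):  # high-AAF decoys (germline-like, AAF ~0.9)
            chrom, pos0 = sample_sine_pos()
            depth = np.maximum(rng.poisson(config.site_depth_mean,
                                           size=n_samples), 10)
            alt_c = (0.9 * depth).astype(int)
            sites.append(VariantSite(chrom, pos0 + 1, "A", "G",
                                     depth - alt_c, alt_c,
                                     quality_stats=_passing_quality(rng)))
        for _ in range(n_decoy):  # non-canonical substitution decoys
            chrom, pos0 = sample_sine_pos()
            ref_c, alt_c = draw_editing_counts(editing_aafs())
            sites.append(VariantSite(chrom, pos0 + 1, "A", "C", ref_c, alt_c,
                                     quality_stats=_passing_quality(rng)))

    # non-SINE decoys: canonical A>G in intergenic space outside any SINE
    sine_set = {(iv.chrom, p) for iv in sine for p in range(iv.start, iv.end)}
    chrom0 = next(iter(annotation.sequences)) if annotation.sequences else "chr1"
    chrom_len = len(annotation.sequences.get(chrom0, "")) or 100_000
    n_decoy = max(4, config.n_editing_sites // 4)
    placed = 0
    while placed < n_decoy:
        pos0 = int(rng.integers(0, chrom_len))
        if (chrom0, pos0) in sine_set or (chrom0, pos0) in used:
            continue
        used.add((chrom0, pos0))
        ref_c, alt_c = draw_editing_counts(editing_aafs())
        sites.append(VariantSite(chrom0, pos0 + 1, "A", "G", ref_c, alt_c,
                                 quality_stats=_passing_quality(rng)))
        placed += 1

    # the known-editome catalogue covers a seeded half of the planted sites
    for key in truth.editing_site_keys:
        if rng.random() < 0.5:
            editome_keys.add(key)
    return sites, known_snp_keys, editome_keys, truth


def make_splicing(config: SimulationConfig,
                  rng: Optional[np.random.Generator] = None):
    """Two pseudo-caller event tables with overlapping, jittered event sets.

    Returns ``(events_a, events_b, truth)``.  Shared events carry the same
    inclusion/exclusion evidence in both callers but spans jittered by a few
    bp; each caller additionally reports a handful of private events.
    ``das_fraction`` of shared events have the treated-group PSI shifted by
    ``das_delta_psi``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    n_samples = 2 * config.n_samples_per_group
    n = config.n_samples_per_group
    types_a = ["SE", "A5SS", "A3SS", "MXE", "RI"]
    types_b = list(types_a) + ["AF", "AL"]
    truth = GroundTruth()
    events_a: list[SplicingEvent] = []
    events_b: list[SplicingEvent] = []

    n_events = config.n_splicing_events
    n_das = int(round(config.das_fraction * n_events))
    das_flags = np.zeros(n_events, dtype=bool)
    if n_das:
        das_flags[rng.choice(n_events, n_das, replace=False)] = True

    for i in range(n_events):
        gene_id = f"G{i % max(config.n_genes, 1):04d}"
        chrom = f"chr{(i % 4) + 1}"
        start = 1000 + 2000 * i
        end = start + int(rng.integers(150, 600))
        base_psi = float(rng.uniform(0.2, 0.6))
        if das_flags[i]:
            psi = np.array([base_psi] * n
                           + [min(base_psi + config.das_delta_psi, 0.98)] * n)
        else:
            psi = np.full(n_samples, base_psi)
        depth = rng.poisson(config.event_depth_mean, size=n_samples).astype(int)
        inc = rng.binomial(np.maximum(depth, 1), psi)
        exc = np.maximum(depth, 1) - inc
        etype = types_a[int(rng.integers(0, len(types_a)))]
        jitter = int(rng.integers(-10, 11))
        ev_a = SplicingEvent(f"A:{i:04d}", gene_id, etype,
                             GenomicInterval(chrom, start, end, "+"),
                             inc, exc, source="callerA")
        ev_b = SplicingEvent(f"B:{i:04d}", gene_id, etype,
                             GenomicInterval(chrom, max(0, start + jitter),
                                             end + jitter, "+"),
                             inc, exc, source="callerB")
        events_a.append(ev_a)
        events_b.append(ev_b)
        if das_flags[i]:
            truth.das_event_ids.append(ev_a.event_id)

    # private events per caller, in genes/locations the other caller misses
    n_private = max(3, n_events // 20)
    for j in range(n_private):
        chrom = "chr1"
        start = 10_000_000 + 5000 * j
        end = start + 200
        depth = rng.poisson(config.event_depth_mean, size=n_samples).astype(int)
        inc = rng.binomial(np.maximum(depth, 1), 0.5)
        exc = np.maximum(depth, 1) - inc
        events_a.append(SplicingEvent(f"A:prv{j:03d}", f"PRIVA{j:03d}", "SE",
                                      GenomicInterval(chrom, start, end, "+"),
                                      inc, exc, source="callerA"))
        events_b.append(SplicingEvent(f"B:prv{j:03d}", f"PRIVB{j:03d}",
                                      types_b[j % len(types_b)],
                                      GenomicInterval(chrom, start + 2500,
                                                      end + 2500, "+"),
                                      inc, exc, source="callerB"))
    return events_a, events_b, truth


def make_lncrna_candidates(config: SimulationConfig, annotation: Annotation,
                           rng: Optional[np.random.Generator] = None
                           ) -> tuple[list[LncrnaCandidate], GroundTruth]:
    """Coding-potential score table for the annotated transcripts.

    Transcripts of lncRNA-biotype genes that are long and multi-exonic get
    concordant noncoding scores (the planted truth); other noncoding
    transcripts get at least one coding-side score.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 4)
    candidates: list[LncrnaCandidate] = []
    truth = GroundTruth()
    for gene in annotation.genes:
        for tx in gene.transcripts:
            if gene.biotype == "lncRNA":
                cand = LncrnaCandidate(
                    transcript=tx,
                    cpat_score=float(rng.uniform(0.0, 0.4)),
                    cpc2_score=float(rng.uniform(-2.0, -0.1)),
                    feelnc_score=float(rng.uniform(0.0, 0.5)),
                    pfam_evalue=None,
                    rfam_hit=False,
                )
                if tx.length >= 200 and tx.exon_count >= 2:
                    truth.lncrna_ids.append(tx.transcript_id)
            else:
                cand = LncrnaCandidate(
                    transcript=tx,
                    cpat_score=float(rng.uniform(0.5, 1.0)),
                    cpc2_score=float(rng.uniform(0.1, 3.0)),
                    feelnc_score=float(rng.uniform(0.6, 1.0)),
                    pfam_evalue=float(10.0 ** rng.uniform(-30, -6)),
                    rfam_hit=False,
                )
            candidates.append(cand)
    return candidates, truth


def _merge_truth(*parts: GroundTruth) -> GroundTruth:
    merged = GroundTruth()
    for part in parts:
        for field_name in ("de_gene_ids", "ase_site_keys", "editing_site_keys",
                           "das_event_ids", "lncrna_ids", "ssr_intervals"):
            getattr(merged, field_name).extend(getattr(part, field_name))
    return merged


def simulate_to_dir(config: SimulationConfig, outdir) -> GroundTruth:
    """Emit every pipeline input into a directory, plus a truth JSON.

    Files: annotation.gtf, sine.bed, paralog.bed, genome.fa, counts.tsv,
    design.tsv, variants.tsv, known_snps.tsv, editome.tsv, events_a.tsv,
    events_b.tsv, lncrna_scores.tsv, truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = make_annotation(config)
    cm, t_counts = make_counts(config, annotation)
    sites, known_snps, editome, t_var = make_variants(config, annotation)
    events_a, events_b, t_spl = make_splicing(config)
    lnc_cands, t_lnc = make_lncrna_candidates(config, annotation)

    write_gtf(annotation.genes, outdir / "annotation.gtf")
    write_bed(annotation.sine_intervals, outdir / "sine.bed")
    write_bed(annotation.paralog_intervals, outdir / "paralog.bed")
    with open(outdir / "genome.fa", "w") as fh:
        for chrom, seq in annotation.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    cm.to_tsv(outdir / "counts.tsv")
    with open(outdir / "design.tsv", "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s, g in zip(config.sample_ids, config.group_labels):
            fh.write(f"{s}\t{g}\n")
    write_variants_tsv(sites, config.sample_ids, outdir / "variants.tsv")
    with open(outdir / "known_snps.tsv", "w") as fh:
        fh.write("site_key\n")
        for key in sorted(known_snps):
            fh.write(key + "\n")
    with open(outdir / "editome.tsv", "w") as fh:
        fh.write("site_key\n")
        for key in sorted(editome):
            fh.write(key + "\n")
    write_events_tsv(events_a, config.sample_ids, outdir / "events_a.tsv")
    write_events_tsv(events_b, config.sample_ids, outdir / "events_b.tsv")
    with open(outdir / "lncrna_scores.tsv", "w") as fh:
        fh.write("transcript_id\tcpat\tcpc2\tfeelnc\tpfam_evalue\trfam_hit\n")
        for c in lnc_cands:
            pf = "" if c.pfam_evalue is None else f"{c.pfam_evalue:.3e}"
            fh.write(f"{c.transcript.transcript_id}\t{c.cpat_score:.4f}\t"
                     f"{c.cpc2_score:.4f}\t{c.feelnc_score:.4f}\t{pf}\t"
                     f"{int(c.rfam_hit)}\n")

    truth = _merge_truth(annotation.truth, t_counts, t_var, t_spl, t_lnc)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(asdict(truth), fh, indent=1, sort_keys=True)
    return truth
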