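"""Coordinate data model, GTF/BED readers and writers, and interval services.

All coordinates are held internally as 0-based half-open ``[start, end)``.
GTF input/output converts from/to the 1-based inclusive GTF convention;
user-facing site reports (``chrom:pos``) are 1-based.  Chromosome names are
compared as exact strings — no "chr" prefix normalisation is applied unless
an alias map is supplied by the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "GeneModel",
    "IntervalIndex",
    "read_gtf",
    "write_gtf",
    "read_bed",
    "write_bed",
    "overlaps",
    "interval_distance",
]


class GtfError(ValueError):
    """Raised for malformed GTF input; message carries the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """True if the 0-based position lies inside the interval."""
        return self.start <= pos < self.end


@dataclass
class TranscriptModel:
    """A transcript: ordered non-overlapping exons plus optional CDS."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)
    biotype: str = ""
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(f"transcript {self.transcript_id} spans chromosomes")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id} has overlapping exons"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    def utrs(self) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
        """Exonic regions outside the CDS span, split into (5'UTR, 3'UTR).

        Orientation follows the transcript strand; for unstranded
        transcripts the left side is reported as 5'.
        """
        if not self.cds:
            return [], []
        cds_start = min(c.start for c in self.cds)
        cds_end = max(c.end for c in self.cds)
        left, right = [], []
        for e in self.exons:
            if e.start < cds_start:
                left.append(
                    GenomicInterval(e.chrom, e.start, min(e.end, cds_start), e.strand)
                )
            if e.end > cds_end:
                right.append(
                    GenomicInterval(e.chrom, max(e.start, cds_end), e.end, e.strand)
                )
        if self.strand == "-":
            return right, left
        return left, right


@dataclass
class GeneModel:
    """A gene locus grouping one or more transcripts."""

    gene_id: str
    name: str = ""
    transcripts: list[TranscriptModel] = field(default_factory=list)
    biotype: str = ""
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)


class IntervalIndex:
    """Per-chromosome interval index answering overlap queries.

    Backed by an interval tree; ``query(chrom, start, end)`` returns exactly
    the stored payloads whose intervals overlap ``[start, end)``.
    """

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "IntervalIndex":
        idx = cls()
        for iv in intervals:
            idx.add(iv, iv)
        return idx

    def add(self, interval: GenomicInterval, payload=None) -> None:
        tree = self._trees.setdefault(interval.chrom, IntervalTree())
        tree.addi(interval.start, interval.end, payload)

    def query(self, chrom: str, start: int, end: int) -> list:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(start, end)]

    def query_point(self, chrom: str, pos: int) -> list:
        return self.query(chrom, pos, pos + 1)

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1,
             stranded: bool = False) -> bool:
    """True iff the intervals share ``>= min_bp`` bases on the same chromosome.

    Strand is ignored unless ``stranded`` is set, in which case both strands
    must be identical (``.`` matches only ``.``).
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    if a.chrom != b.chrom:
        return False
    if stranded and a.strand != b.strand:
        return False
    return min(a.end, b.end) - max(a.start, b.start) >= min_bp


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Gap in bp between the nearest boundaries; 0 if overlapping.

    Returns ``math.inf`` for intervals on different chromosomes.
    """
    if a.chrom != b.chrom:
        return math.inf
    gap = max(a.start, b.start) - min(a.end, b.end)
    return max(gap, 0)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(raw: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise GtfError(f"line {lineno}: malformed attribute {chunk!r}")
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path) -> list[GeneModel]:
    """Read an ENSEMBL-dialect GTF into gene models.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    Exon records are grouped under transcripts under genes; unknown
    attributes are preserved verbatim in the ``attributes`` bag.  A malformed
    line or an exon without a transcript_id raises :class:`GtfError` naming
    the line number.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    tx_meta: dict[str, dict] = {}
    gene_meta: dict[str, dict] = {}
    tx_order: list[str] = []
    gene_order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, raw = fields
            try:
                start = int(start_s) - 1  # GTF is 1-based inclusive
                end = int(end_s)
            except ValueError:
                raise GtfError(f"line {lineno}: non-integer coordinates") from None
            if strand not in STRANDS:
                raise GtfError(f"line {lineno}: invalid strand {strand!r}")
            attrs = _parse_gtf_attributes(raw, lineno)
            gid = attrs.get("gene_id")
            tid = attrs.get("transcript_id")
            if feature in ("exon", "CDS"):
                if tid is None:
                    raise GtfError(f"line {lineno}: {feature} without transcript_id")
                if gid is None:
                    raise GtfError(f"line {lineno}: {feature} without gene_id")
                iv = GenomicInterval(chrom, start, end, strand)
                if feature == "exon":
                    exons.setdefault(tid, []).append(iv)
                else:
                    cds.setdefault(tid, []).append(iv)
                if tid not in tx_meta:
                    tx_meta[tid] = {"gene_id": gid, "attrs": attrs}
                    tx_order.append(tid)
            elif feature == "transcript":
                if tid is None:
                    raise GtfError(f"line {lineno}: transcript without transcript_id")
                tx_meta.setdefault(tid, {"gene_id": gid, "attrs": attrs})
                if tid not in tx_order:
                    tx_order.append(tid)
                tx_meta[tid]["attrs"] = attrs
            elif feature == "gene":
                if gid is None:
                    raise GtfError(f"line {lineno}: gene without gene_id")
                gene_meta[gid] = attrs
                if gid not in gene_order:
                    gene_order.append(gid)

    genes: dict[str, GeneModel] = {}
    for tid in tx_order:
        meta = tx_meta[tid]
        if tid not in exons:
            continue
        attrs = meta["attrs"]
        tx = TranscriptModel(
            transcript_id=tid,
            gene_id=meta["gene_id"],
            exons=exons[tid],
            cds=sorted(cds.get(tid, []), key=lambda c: c.start),
            biotype=attrs.get("transcript_biotype", ""),
            attributes=attrs,
        )
        gid = meta["gene_id"]
        if gid not in genes:
            gattrs = gene_meta.get(gid, {})
            genes[gid] = GeneModel(
                gene_id=gid,
                name=gattrs.get("gene_name", attrs.get("gene_name", "")),
                transcripts=[tx],
                biotype=gattrs.get("gene_biotype", attrs.get("gene_biotype", "")),
                attributes=gattrs,
            )
        else:
            genes[gid].transcripts.append(tx)
    ordered = [g for g in gene_order if g in genes]
    ordered += [g for g in genes if g not in gene_meta]
    return [genes[g] for g in ordered]


def _fmt_attrs(attrs: dict[str, str]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in attrs.items())


def write_gtf(genes: Iterable[GeneModel], path) -> None:
    """Write gene models as ENSEMBL-dialect GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for gene in genes:
            span = gene.span
            gattrs = {"gene_id": gene.gene_id}
            if gene.name:
                gattrs["gene_name"] = gene.name
            if gene.biotype:
                gattrs["gene_biotype"] = gene.biotype
            for k, v in gene.attributes.items():
                gattrs.setdefault(k, v)
            fh.write(
                f"{gene.chrom}\tendotx\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{gene.strand}\t.\t{_fmt_attrs(gattrs)}\n"
            )
            for tx in gene.transcripts:
                tattrs = {"gene_id": gene.gene_id, "transcript_id": tx.transcript_id}
                if tx.biotype:
                    tattrs["transcript_biotype"] = tx.biotype
                for k, v in tx.attributes.items():
                    tattrs.setdefault(k, v)
                tspan = tx.span
                fh.write(
                    f"{tx.chrom}\tendotx\ttranscript\t{tspan.start + 1}\t{tspan.end}"
                    f"\t.\t{tx.strand}\t.\t{_fmt_attrs(tattrs)}\n"
                )
                for exon in tx.exons:
                    fh.write(
                        f"{exon.chrom}\tendotx\texon\t{exon.start + 1}\t{exon.end}"
                        f"\t.\t{exon.strand}\t.\t{_fmt_attrs(tattrs)}\n"
                    )
                for c in tx.cds:
                    fh.write(
                        f"{c.chrom}\tendotx\tCDS\t{c.start + 1}\t{c.end}"
                        f"\t.\t{c.strand}\t.\t{_fmt_attrs(tattrs)}\n"
                    )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """Read BED3+ (0-based half-open); the strand column, if present, is honored."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: BED needs >= 3 columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer coordinates") from None
            if start >= end:
                raise ValueError(f"line {lineno}: start >= end ({start} >= {end})")
            strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
            out.append(GenomicInterval(chrom, start, end, strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path,
              names: Optional[Iterable[str]] = None) -> None:
    """Write BED6 (name/score filled with placeholders when absent)."""
    names_it: Iterator[str] = iter(names) if names is not None else iter(())
    with open(path, "w") as fh:
        for iv in intervals:
            name = next(names_it, ".")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
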