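"""Percent-spliced-in computation, differential-splicing calls, and
consensus-by-location between two event callers.

PSI is the raw junction-count ratio inclusion / (inclusion + exclusion);
no effective-length normalisation is applied.  An event is differentially
spliced when the BH-adjusted two-proportion chi-square p-value is below the
FDR cutoff AND |dPSI| exceeds the dPSI cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genomic_core import GenomicInterval, overlaps
from .expression_de import bh_adjust
from .stats2x2 import chi2_2x2

EVENT_TYPES = ("SE", "A5SS", "A3SS", "MXE", "RI", "AF", "AL")

__all__ = [
    "SplicingEvent",
    "DasResult",
    "compute_psi",
    "das_test",
    "consensus_by_location",
    "summarize_das_types",
    "read_events_tsv",
    "write_events_tsv",
]


@dataclass
class SplicingEvent:
    event_id: str
    gene_id: str
    event_type: str
    span: GenomicInterval
    inclusion_counts: np.ndarray  # per sample
    exclusion_counts: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        self.inclusion_counts = np.asarray(self.inclusion_counts, dtype=int)
        self.exclusion_counts = np.asarray(self.exclusion_counts, dtype=int)
        if (self.inclusion_counts < 0).any() or (self.exclusion_counts < 0).any():
            raise ValueError(f"negative counts in event {self.event_id}")
        if self.inclusion_counts.shape != self.exclusion_counts.shape:
            raise ValueError("inclusion/exclusion count shapes differ")


@dataclass
class DasResult:
    event_id: str
    psi_per_sample: np.ndarray  # NaN where inc+exc == 0
    delta_psi: float
    p_value: float
    p_adjusted: float = float("nan")
    significant: bool = False
    event_type: str = ""
    gene_id: str = ""


def compute_psi(event: SplicingEvent) -> np.ndarray:
    """Per-sample PSI = inc / (inc + exc); NaN where total evidence is zero."""
    inc = event.inclusion_counts.astype(float)
    tot = inc + event.exclusion_counts
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(tot > 0, inc / np.maximum(tot, 1), np.nan)
    return psi


def das_test(events: list[SplicingEvent], group_masks: dict[str, np.ndarray],
             control_group: str, fdr: float = 0.05,
             min_dpsi: float = 0.1) -> list[DasResult]:
    """Differential splicing between two groups.

    dPSI is the difference of group-mean PSI (treated minus control); the
    p-value comes from a chi-square two-proportion test on the
    inclusion/exclusion counts pooled within each group.  BH is applied
    across events and significance requires both p_adjusted < ``fdr`` and
    |dPSI| > ``min_dpsi``.  Events with zero defined PSI in an entire group
    are excluded from testing.
    """
    names = list(group_masks)
    if len(names) != 2 or control_group not in names:
        raise ValueError("exactly two groups including the control required")
    trt = next(n for n in names if n != control_group)
    cmask = np.asarray(group_masks[control_group], dtype=bool)
    tmask = np.asarray(group_masks[trt], dtype=bool)

    kept: list[DasResult] = []
    for ev in events:
        psi = compute_psi(ev)
        psi_c, psi_t = psi[cmask], psi[tmask]
        if np.isnan(psi_c).all() or np.isnan(psi_t).all():
            continue
        dpsi = float(np.nanmean(psi_t) - np.nanmean(psi_c))
        inc_c = int(ev.inclusion_counts[cmask].sum())
        exc_c = int(ev.exclusion_counts[cmask].sum())
        inc_t = int(ev.inclusion_counts[tmask].sum())
        exc_t = int(ev.exclusion_counts[tmask].sum())
        stat, p = chi2_2x2(inc_c, exc_c, inc_t, exc_t)
        kept.append(DasResult(ev.event_id, psi, dpsi, p,
                              event_type=ev.event_type, gene_id=ev.gene_id))
    if kept:
        padj = bh_adjust(np.array([r.p_value for r in kept]))
        for r, pa in zip(kept, padj):
            r.p_adjusted = float(pa)
            r.significant = bool(pa < fdr and abs(r.delta_psi) > min_dpsi)
    return kept


def consensus_by_location(events_a: list[SplicingEvent],
                          events_b: list[SplicingEvent]):
    """Match events from two callers by genomic location.

    A pair is eligible when both events share a gene_id and their spans
    overlap by >= 1 bp; each event is used at most once.  Pairs are chosen
    greedily by largest overlap, ties broken by the leftmost start of the
    first-list event, then by event ids for determinism.  Event types are
    not required to match.  Returns ``(pairs, summary)`` where pairs is a
    list of (event_a, event_b) and summary carries per-source totals.
    """
    candidates = []
    for a in events_a:
        for b in events_b:
            if a.gene_id != b.gene_id:
                continue
            if not overlaps(a.span, b.span):
                continue
            ov = min(a.span.end, b.span.end) - max(a.span.start, b.span.start)
            candidates.append((ov, a, b))
    candidates.sort(key=lambda t: (-t[0], t[1].span.start, t[1].event_id,
                                   t[2].event_id))
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs: list[tuple[SplicingEvent, SplicingEvent]] = []
    for _, a, b in candidates:
        if a.event_id in used_a or b.event_id in used_b:
            continue
        used_a.add(a.event_id)
        used_b.add(b.event_id)
        pairs.append((a, b))
    summary = {
        "n_a": len(events_a),
        "n_b": len(events_b),
        "n_pairs": len(pairs),
    }
    return pairs, summary


def summarize_das_types(pairs, side: str = "a") -> dict[str, int]:
    """Tally consensus pairs by event type on one caller's side.

    The tallies always sum to the number of pairs.
    """
    idx = {"a": 0, "b": 1}[side]
    tally: dict[str, int] = {}
    for pair in pairs:
        et = pair[idx].event_type
        tally[et] = tally.get(et, 0) + 1
    return tally


# ---------------------------------------------------------------------------
# TSV interface
# ---------------------------------------------------------------------------

def write_events_tsv(events: list[SplicingEvent], sample_ids: list[str],
                     path) -> None:
    rows = []
    for ev in events:
        row = {
            "event_id": ev.event_id, "gene_id": ev.gene_id, "type": ev.event_type,
            "chrom": ev.span.chrom, "start": ev.span.start, "end": ev.span.end,
            "strand": ev.span.strand, "source": ev.source,
        }
        for s, inc, exc in zip(sample_ids, ev.inclusion_counts,
                               ev.exclusion_counts):
            row[f"inc:{s}"] = int(inc)
            row[f"exc:{s}"] = int(exc)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> tuple[list[SplicingEvent], list[str]]:
    df = pd.read_csv(path, sep="\t")
    inc_cols = [c for c in df.columns if c.startswith("inc:")]
    exc_cols = [c for c in df.columns if c.startswith("exc:")]
    sample_ids = [c.split(":", 1)[1] for c in inc_cols]
    events = []
    for _, row in df.iterrows():
        events.append(SplicingEvent(
            event_id=row["event_id"], gene_id=row["gene_id"],
            event_type=row["type"],
            span=GenomicInterval(str(row["chrom"]), int(row["start"]),
                                 int(row["end"]), str(row["strand"])),
            inclusion_counts=row[inc_cols].to_numpy(dtype=int),
            exclusion_counts=row[exc_cols].to_numpy(dtype=int),
            source=row.get("source", ""),
        ))
    return events, sample_ids
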