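"""Canonical RNA-editing candidate detection.

Downstream of the allele-expression quality and positional filters, a site
is an editing candidate when it is observed (AAF > 0) in at least three
samples, shows a canonical substitution class (A>G on + / T>C on - for
A-to-I; C>T on + / G>A on - for C-to-U), carries no known SNP identifier,
keeps AAF <= 0.7 in every sample (near-complete "editing" is more likely a
genomic variant), and lies inside a SINE repeat interval.  Candidates are
cross-referenced against a known-editome catalogue by exact coordinate and
flagged for significant allelic imbalance at FDR < 0.05 (BH within the
candidate family, separate from the ASE family).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genomic_core import GenomicInterval, IntervalIndex
from .expression_de import bh_adjust
from .allele_expression import VariantSite, aaf_vector, imbalance_test

__all__ = [
    "EditingCandidate",
    "canonical_class",
    "editing_cascade",
    "editing_report",
    "read_editing_report",
    "summarize_editing_report",
    "ANNOTATION_TO_REGION",
]

# SnpEff/VEP-style annotation strings mapped onto the module's region vocabulary.
ANNOTATION_TO_REGION = {
    "3_prime_UTR_variant": "UTR",
    "5_prime_UTR_variant": "UTR",
    "intron_variant": "intron",
    "splice_region_variant&intron_variant": "intron",
    "downstream_gene_variant": "downstream",
    "upstream_gene_variant": "upstream",
    "missense_variant": "CDS",
    "synonymous_variant": "CDS",
    "intergenic_variant": "intergenic",
}


@dataclass
class EditingCandidate:
    site: VariantSite
    editing_class: str  # "A-to-I" or "C-to-U"
    strand_resolved: bool
    in_sine: bool
    known_editome: bool
    aaf_per_sample: np.ndarray
    region_annotation: str = ""
    gene_name: str = ""
    p_value: float = float("nan")
    fdr: float = float("nan")
    significant_imbalance: bool = False
    delta_aaf: float = float("nan")


def canonical_class(ref: str, alt: str, strand: str = ".") -> tuple[Optional[str], bool]:
    """Canonical editing class for a substitution, or None.

    Returns ``(editing_class, strand_resolved)``.  On an unknown strand the
    A>G / T>C pair is still reported as A-to-I (and C>T / G>A as C-to-U)
    but flagged as not strand-resolved.
    """
    pair = (ref, alt)
    if strand == "+":
        if pair == ("A", "G"):
            return "A-to-I", True
        if pair == ("C", "T"):
            return "C-to-U", True
        return None, True
    if strand == "-":
        if pair == ("T", "C"):
            return "A-to-I", True
        if pair == ("G", "A"):
            return "C-to-U", True
        return None, True
    if pair in (("A", "G"), ("T", "C")):
        return "A-to-I", False
    if pair in (("C", "T"), ("G", "A")):
        return "C-to-U", False
    return None, False


def editing_cascade(sites: list[VariantSite],
                    sine_intervals: list[GenomicInterval],
                    known_snp_ids: set[str],
                    editome_sites: set[str],
                    group_masks: Optional[dict[str, np.ndarray]] = None,
                    control_group: Optional[str] = None,
                    site_strands: Optional[dict[str, str]] = None,
                    min_observed_samples: int = 3,
                    max_aaf: float = 0.7,
                    imbalance_fdr: float = 0.05):
    """Apply the editing filters; returns ``(candidates, funnel_counts)``.

    ``known_snp_ids`` may hold rs identifiers or ``chrom:pos`` keys; a site
    is excluded if either its own ``known_snp_id`` or its coordinate key is
    known.  ``editome_sites`` holds ``chrom:pos`` keys (1-based).
    ``site_strands`` optionally maps coordinate keys to the host-gene strand
    used for canonical classing; unmapped sites are classed unstranded.
    """
    sine_idx = IntervalIndex.from_intervals(sine_intervals)
    funnel = {
        "input": len(sites), "observed": 0, "canonical": 0,
        "not_known_snp": 0, "aaf_capped": 0, "in_sine": 0,
    }
    candidates: list[EditingCandidate] = []
    for site in sites:
        vec = aaf_vector(site)
        if int(np.nansum(vec > 0)) < min_observed_samples:
            continue
        funnel["observed"] += 1
        strand = (site_strands or {}).get(site.key, ".")
        cls, resolved = canonical_class(site.ref_allele, site.alt_allele, strand)
        if cls is None:
            continue
        funnel["canonical"] += 1
        if site.known_snp_id or site.key in known_snp_ids:
            continue
        funnel["not_known_snp"] += 1
        if np.nanmax(vec) > max_aaf:
            continue
        funnel["aaf_capped"] += 1
        if not sine_idx.query_point(site.chrom, site.pos0):
            continue
        funnel["in_sine"] += 1
        candidates.append(EditingCandidate(
            site=site, editing_class=cls, strand_resolved=resolved,
            in_sine=True, known_editome=site.key in editome_sites,
            aaf_per_sample=vec,
        ))
    if group_masks is not None and candidates:
        for cand in candidates:
            _, p, delta = imbalance_test(cand.site, group_masks, control_group)
            cand.p_value = p
            cand.delta_aaf = delta
        fdrs = bh_adjust(np.array([c.p_value for c in candidates]))
        for cand, fdr in zip(candidates, fdrs):
            cand.fdr = float(fdr)
            cand.significant_imbalance = bool(fdr < imbalance_fdr)
    return candidates, funnel


def editing_report(candidates: list[EditingCandidate],
                   group_masks: dict[str, np.ndarray],
                   control_group: str) -> pd.DataFrame:
    """Site-per-row report: gene, 1-based ``chrom:site`` (starred when the
    site is known-editome), per-group AAFs, annotation, editing class."""
    trt = next(g for g in group_masks if g != control_group)
    cmask = np.asarray(group_masks[control_group], dtype=bool)
    tmask = np.asarray(group_masks[trt], dtype=bool)
    rows = []
    for c in candidates:

        def fmt(mask):
            return ", ".join(
                "NA" if np.isnan(v) else f"{v:.3g}"
                for v in c.aaf_per_sample[mask]
            )

        rows.append({
            "gene_name": c.gene_name,
            "site": f"{c.site.chrom}:{c.site.pos}" + (" *" if c.known_editome else ""),
            f"aaf_{control_group.lower()}": fmt(cmask),
            f"aaf_{trt.lower()}": fmt(tmask),
            "annotation": c.region_annotation,
            "editing_class": c.editing_class,
            "significant_imbalance": c.significant_imbalance,
        })
    return pd.DataFrame(rows)


def read_editing_report(path) -> pd.DataFrame:
    """Read a site-per-row editing report TSV.

    Expected columns: gene_name, chrom, pos (1-based), known_editome (0/1),
    aaf_ctr / aaf_lps (comma-separated per-replicate fractions), annotation.
    A ``region`` column is derived from the annotation string.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if (df["pos"] <= 0).any():
        raise ValueError("site positions must be 1-based positive integers")
    df["region"] = df["annotation"].map(ANNOTATION_TO_REGION)
    if df["region"].isna().any():
        bad = df.loc[df["region"].isna(), "annotation"].unique()
        raise ValueError(f"unmapped annotation strings: {list(bad)}")
    df["known_editome"] = df["known_editome"].astype(bool)
    return df


def summarize_editing_report(report: pd.DataFrame) -> dict:
    """Totals for an editing-site report: site count, per-region counts,
    and the number of known-editome-confirmed sites."""
    return {
        "n_sites": int(len(report)),
        "by_region": {k: int(v) for k, v in
                      report["region"].value_counts().items()},
        "n_editome_confirmed": int(report["known_editome"].sum()),
    }
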