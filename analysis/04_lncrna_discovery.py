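"""lncRNA discovery cascade and cis/trans regulator inference.

Classifies every scored transcript through the ordered cascade
(annotation, length >= 200 bp, multi-exonic, four-way coding-potential
consensus, small-RNA removal), then links accepted lncRNA loci to
protein-coding genes by proximity (< 2 kb) and expression correlation
(|r| > 0.9).
"""

import json
from pathlib import Path

import pandas as pd

from endotx.expression_de import CountMatrix, filter_expressed, normalized_counts
from endotx.genomic_core import read_gtf
from endotx.lncrna import (LncrnaCandidate, cis_targets, classify_candidates,
                           trans_targets)

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sim = BASE / "sim"
    genes = read_gtf(sim / "annotation.gtf")
    tx_by_id = {tx.transcript_id: tx for g in genes for tx in g.transcripts}
    scores = pd.read_csv(sim / "lncrna_scores.tsv", sep="\t")
    candidates = [
        LncrnaCandidate(
            transcript=tx_by_id[row.transcript_id],
            cpat_score=row.cpat, cpc2_score=row.cpc2, feelnc_score=row.feelnc,
            pfam_evalue=None if pd.isna(row.pfam_evalue) else row.pfam_evalue,
            rfam_hit=bool(row.rfam_hit))
        for row in scores.itertuples()
    ]
    candidates, funnel = classify_candidates(candidates)
    print("identification funnel:", funnel)

    accepted = {c.transcript.transcript_id for c in candidates
                if c.verdict == "lncRNA"}
    truth = json.load(open(sim / "truth.json"))
    print(f"cascade accepts {len(accepted)} lncRNAs; "
          f"{len(accepted & set(truth['lncrna_ids']))} of "
          f"{len(truth['lncrna_ids'])} planted")

    lnc_gene_ids = {tx_by_id[t].gene_id for t in accepted}
    coding = [g for g in genes if g.biotype == "protein_coding"]
    loci = {g.gene_id: g.span for g in genes if g.gene_id in lnc_gene_ids}
    cis = cis_targets(loci, coding)

    cm = filter_expressed(CountMatrix.from_tsv(sim / "counts.tsv",
                                               sim / "design.tsv"))
    expr = dict(zip(cm.feature_ids, normalized_counts(cm)))
    trans = trans_targets({g: expr[g] for g in lnc_gene_ids if g in expr},
                          {g.gene_id: expr[g.gene_id] for g in coding
                           if g.gene_id in expr})
    print(f"{len(cis)} cis links (<2 kb) and {len(trans)} trans links "
          "(|r| > 0.9)")
    pd.DataFrame({
        "lncrna_id": [x.lncrna_id for x in cis + trans],
        "gene_id": [x.gene_id for x in cis + trans],
        "mode": [x.mode for x in cis + trans],
    }).to_csv(BASE / "lncrna_links.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
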