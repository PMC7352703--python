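"""Generate the synthetic study inputs.

Emulates the study design: two groups of three biological replicates,
NB-distributed gene counts with spiked log2 fold changes, binomial allele
counts with group-shifted alternate-allele fractions, A>G editing sites
confined to SINE intervals, and splicing events reported by two
pseudo-callers.  Writes every downstream input plus the planted ground
truth to results/sim/.
"""

import json
from pathlib import Path

from endotx.synthetic import SimulationConfig, simulate_to_dir

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    config = SimulationConfig(seed=1)
    truth = simulate_to_dir(config, OUT)
    print(f"wrote synthetic inputs to {OUT}")
    print(f"planted truth: {len(truth.de_gene_ids)} DE genes, "
          f"{len(truth.ase_site_keys)} ASE sites, "
          f"{len(truth.editing_site_keys)} editing sites, "
          f"{len(truth.das_event_ids)} DAS events, "
          f"{len(truth.lncrna_ids)} lncRNA transcripts")


if __name__ == "__main__":
    main()
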