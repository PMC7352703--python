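"""endotx: downstream transcriptome inference for bulk RNA-seq.

Consensus differential expression, lncRNA discovery with cis/trans
regulator inference, differential alternative splicing, allele-specific
expression calling and canonical A-to-I RNA-editing detection, plus a
seeded synthetic-data generator with known ground truth.
"""

from importlib import resources

__version__ = "0.1.0"


def data_path(name: str):
    """Path to a bundled worked-example data table (study tables transcribed
    from the deposited six-library porcine endometrium LPS experiment,
    ENA PRJEB37538)."""
    return resources.files("endotx").joinpath("data", name)
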