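"""Bundled reference tables.

The package ships the published per-sample sequencing summary of the
*M. xanthus* DK1622 starvation time course (NCBI BioProject PRJNA493545):
14 samples — 7 time points × 2 biological replicates — with mapped and
rRNA read counts.  The raw reads live at the SRA; this table is the input
for the run-level arithmetic (rRNA rates, clean reads, genome coverage).
"""

from importlib import resources

from .io import read_sample_sheet

#: M. xanthus DK1622 genome length in bp (NC_008095.1).
DK1622_GENOME_BP = 9_139_763

#: Read length of the sequencing runs summarized in the bundled sheet.
DK1622_READ_LEN_BP = 100


def load_dk1622_sample_sheet():
    """Sample sheet of the DK1622 developmental time course (14 samples)."""
    path = resources.files("tempomod").joinpath("data/dk1622_timecourse_samples.tsv")
    with resources.as_file(path) as p:
        return read_sample_sheet(p)
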