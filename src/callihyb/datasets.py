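"""Packaged study dataset: the per-sample genotype table of the source cohort.

The study's 33 samples (18 putative hybrids Csp1-18 plus 6 C. aurita, 5
C. jacchus and 4 C. penicillata controls) are shipped as three small text
tables — metadata, per-sample marker states (SRY electropherogram allele +
COX2 haplotype label), and the corresponding fragment peak sizes. The raw
sequence reads themselves were never deposited, so the fixture carries the
published marker states, and marker *calls* are recomputed from them (SRY
from fragment size via :func:`~callihyb.sry_genotyping.call_indel_from_size`)
rather than stored pre-classified.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cox2_haplotyping import HaplotypeAssignment
from .io_formats import read_fragment_csv, read_sample_table
from .sry_genotyping import call_indel_from_size

SPECIES_OF_HAPLOTYPE = {
    "HCa": "aurita",
    "HCj": "jacchus",
    "HCp": "penicillata",
    "HCp2": "penicillata",
    "HCp1": "penicillata",
}


def _data_path(name: str):
    return resources.files("callihyb").joinpath("data", name)


def load_samples() -> list:
    """The 33 SampleRecord rows of the packaged cohort table."""
    with resources.as_file(_data_path("table1_samples.tsv")) as p:
        return read_sample_table(p)


def load_markers() -> pd.DataFrame:
    """Per-sample marker states: columns sample_id, sry_allele (del/ins), cox2_haplotype."""
    with resources.as_file(_data_path("table1_markers.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def load_fragments() -> list:
    """Electropherogram peak sizes (196/205 bp) for every sample."""
    with resources.as_file(_data_path("table1_fragments.csv")) as p:
        return read_fragment_csv(p)


def marker_calls() -> tuple:
    """Recompute per-sample marker calls from the packaged evidence.

    Returns (sry_calls, haplotype_assignments): the SRY call is derived from
    the fragment peak size through the size-binning caller; the haplotype
    assignment wraps the published label (distance 0; margin 1, the minimum
    separation any distinct panel haplotype can have).
    """
    sry_calls = [call_indel_from_size(f) for f in load_fragments()]
    markers = load_markers()
    assignments = [
        HaplotypeAssignment(
            sample_id=row.sample_id,
            haplotype_label=row.cox2_haplotype,
            matriline_species=SPECIES_OF_HAPLOTYPE[row.cox2_haplotype],
            distance=0,
            margin=1,
        )
        for row in markers.itertuples()
    ]
    return sry_calls, assignments
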