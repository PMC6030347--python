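"""Bundled example data: a published 21-locus non-CODIS STR panel.

The package ships the allele-frequency spectrum and forensic parameter
table of a published survey of 307 individuals from a Kyrgyz population
typed at 21 autosomal non-CODIS STR loci (168 alleles in total).  The
original table was published with per-locus columns; the machine-readable
copy here stores frequencies at 4 decimals, and counts reconstruct exactly
as round(freq * 614).

The column-to-locus assignment of rare alleles (frequency below ~0.01) was
recovered from the published per-locus summary statistics (each column
must sum to one and reproduce the printed expected heterozygosity and
polymorphism information content); placements of a handful of
single-observation alleles are determined up to that evidence.  All
frequencies themselves are the published values.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_allele_frequency_table
from .model import AlleleFrequencySpectrum

__all__ = [
    "load_kyrgyz_frequencies",
    "load_kyrgyz_parameters",
    "KYRGYZ_N",
]

#: individuals typed in the bundled survey
KYRGYZ_N = 307


def _data_path(name: str):
    return resources.files("strpopkit.data").joinpath(name)


def load_kyrgyz_frequencies() -> list[AlleleFrequencySpectrum]:
    """Allele-frequency spectra of the 21-locus panel (n = 307)."""
    with _data_path("kyrgyz21_allele_freqs.csv").open() as fh:
        return read_allele_frequency_table(fh, n=KYRGYZ_N)


def load_kyrgyz_parameters() -> pd.DataFrame:
    """Published per-locus forensic parameters (MP, PD, PIC, PE, TPI, HO,
    HE and the Hardy-Weinberg exact-test p-value), indexed by locus."""
    with _data_path("kyrgyz21_forensic_params.csv").open() as fh:
        return pd.read_csv(fh, index_col=0)
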