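"""Published reference tables bundled with the package.

Two small tabular datasets ship with the package: a 36-row genome
feature table (genome size in Mb, Helitron count, Helitron density and
species group for seven multiply-sequenced plant species plus two de
novo *A. thaliana* assemblies) and an 18-row *A. thaliana* ecotype table
(origin, Helitron count/density and flowering-time class).  They are the
inputs of the classification and association analyses and serve as
worked-example data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Measured base composition of the A. thaliana TAIR10 assembly
#: (fractions of A, T, G, C; they sum to slightly under 1 because the
#: assembly contains N bases).
TAIR10_COMPOSITION = (0.319414, 0.319033, 0.179905, 0.180095)

#: Non-gap length of the TAIR10 assembly in bases.
TAIR10_LENGTH = 119_667_750

#: Helitron 3'-termini count in TAIR10 at default scan settings; the
#: reference denominator of the false-positive-rate estimate.
TAIR10_HELITRON_COUNT = 665


def _read(name: str) -> pd.DataFrame:
    with resources.files("heliscan.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_genome_features() -> pd.DataFrame:
    """36-row genome feature table.

    Columns: ``group`` (species group label), ``genome``, ``size_mb``,
    ``helitron_count``, ``density`` (Helitrons per Mb), ``dataset``
    (``train`` for the 34 labelled genomes, ``denovo`` for the two
    NGS-assembled test genomes whose true group is *Ath*).
    """
    return _read("genome_features.tsv")


def load_ecotypes() -> pd.DataFrame:
    """18 *A. thaliana* ecotypes with Helitron counts and flowering time.

    Columns include ``accession``, ``size_mb``, ``helitron_count``,
    ``density`` and ``flowering_time`` (5 ``late``, 13 ``intermediate``).
    """
    return _read("ecotypes.tsv")
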