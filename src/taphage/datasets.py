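"""Bundled reference data.

The package ships the published per-genome ACA statistics for the 12 NCBI
reference (+)ssRNA phage genomes (accession, host, length, observed and
expected site counts, relative frequency, shuffle-null exceedance).  The
genome *sequences* themselves are not bundled; ``scripts/fetch_reference_genomes.py``
can download them for users with network access, after which the full
per-genome analysis can be rerun from sequence.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

ESCHERICHIA_PREFIX = "Escherichia"


def load_reference_site_stats() -> pd.DataFrame:
    """Published ACA-site statistics for the 12 reference phage genomes."""
    path = resources.files("taphage.data") / "reference_phage_stats.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def reference_metadata() -> pd.DataFrame:
    """Reference genome metadata in the standard join_metadata schema."""
    stats = load_reference_site_stats()
    return pd.DataFrame(
        {
            "id": stats["accession"],
            "moltype": stats["moltype"],
            "host": stats["host"],
            "complete": "true",
            "evolved": "false",
        }
    )


def escherichia_reference_relative_frequencies() -> pd.Series:
    """Published relative ACA frequencies of the Escherichia-infecting references.

    Includes the broad-host-range phage PRR1, which infects *Escherichia*
    among other genera (nine genomes in total).
    """
    stats = load_reference_site_stats()
    mask = stats["host"].str.startswith(ESCHERICHIA_PREFIX)
    return stats.loc[mask, "aca_relative_frequency"].reset_index(drop=True)
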