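#!/usr/bin/env python
"""Download the 12 NCBI reference (+)ssRNA phage genomes (needs network access).

Fetches the accessions listed in the bundled reference statistics table from
NCBI E-utilities and writes them to data/reference_genomes.fasta, enabling the
sequence-level reproduction checks in the test suite.
"""

from __future__ import annotations

import sys
import time
import urllib.request
from pathlib import Path

from taphage.datasets import load_reference_site_stats

EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={acc}&rettype=fasta&retmode=text"
)


def main() -> None:
    out = Path(__file__).resolve().parent.parent / "data" / "reference_genomes.fasta"
    out.parent.mkdir(parents=True, exist_ok=True)
    accessions = load_reference_site_stats()["accession"].tolist()
    chunks = []
    for acc in accessions:
        url = EFETCH.format(acc=acc)
        print(f"fetching {acc} ...", file=sys.stderr)
        with urllib.request.urlopen(url, timeout=60) as fh:
            chunks.append(fh.read().decode().strip() + "\n")
        time.sleep(0.4)  # NCBI rate limit
    out.write_text("".join(chunks))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
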