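#!/usr/bin/env python
"""One-time fetch of the deposited SaveOBP/SaveCSP GenBank records.

Downloads the nucleotide records KU140605–KU140622 from NCBI efetch into a
FASTA directory so the pipeline can be run on the real deposited sequences::

    python scripts/fetch_accessions.py --out data/accessions

Requires network access; the rest of the package (including the test suite
and scripts/acceptance.py) does not depend on this download and runs on
synthetic stand-ins instead.
"""

from __future__ import annotations

import argparse
import time
import urllib.parse
import urllib.request
from pathlib import Path

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
ACCESSIONS = [f"KU1406{i:02d}" for i in range(5, 23)]  # KU140605..KU140622


def fetch(accession: str) -> str:
    query = urllib.parse.urlencode(
        {"db": "nuccore", "id": accession, "rettype": "fasta", "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EFETCH}?{query}", timeout=60) as resp:
        text = resp.read().decode()
    if not text.startswith(">"):
        raise RuntimeError(f"unexpected response for {accession}")
    return text


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("data/accessions"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        target = args.out / f"{acc}.fasta"
        if target.exists():
            print(f"{acc}: already present")
            continue
        target.write_text(fetch(acc))
        print(f"{acc}: fetched")
        time.sleep(0.4)  # stay under NCBI rate limits


if __name__ == "__main__":
    main()
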