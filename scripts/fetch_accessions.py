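#!/usr/bin/env python
"""One-time download of the small public GenBank records the deposited-
record checks use, into data/accessions/.

The library itself never requires network access; this helper exists so
that `tests/test_acceptance.py::test_deposited_accession_cohorts` can run
against the real deposited sequences.  Run it once from the repository
root on a machine with internet access:

    python scripts/fetch_accessions.py
"""

from __future__ import annotations

import sys
import time
import urllib.request
from pathlib import Path

EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nucleotide&id={acc}&rettype=gbwithparts&retmode=text"
)

ACCESSIONS = (
    ["KY964299.1", "KY964300.1"]  # complete mt genomes
    + [f"KY9642{i}.1" for i in range(90, 99)]  # ND6 gene sample, species 1
    + [f"AB8630{i}.1" for i in range(97, 100)]  # ND6 gene sample, species 2
    + [f"AB8631{i:02d}.1" for i in range(0, 13)]
)

OUTDIR = Path(__file__).resolve().parent.parent / "data" / "accessions"


def main() -> int:
    OUTDIR.mkdir(parents=True, exist_ok=True)
    failures = []
    for acc in ACCESSIONS:
        dest = OUTDIR / f"{acc.split('.')[0]}.gb"
        if dest.exists():
            print(f"{acc}: already present")
            continue
        try:
            with urllib.request.urlopen(EFETCH.format(acc=acc), timeout=60) as resp:
                text = resp.read().decode()
            if "LOCUS" not in text:
                raise ValueError("response does not look like a GenBank record")
            dest.write_text(text)
            print(f"{acc}: fetched ({len(text)} bytes)")
            time.sleep(0.4)  # stay under NCBI's unauthenticated rate limit
        except Exception as exc:
            failures.append((acc, str(exc)))
            print(f"{acc}: FAILED ({exc})", file=sys.stderr)
    if failures:
        print(f"{len(failures)} downloads failed; rerun when network allows", file=sys.stderr)
        return 1
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
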