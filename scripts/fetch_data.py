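#!/usr/bin/env python
"""Download the worked-example sequences from UniProt into data/.

Requires network access.  The two FASTA files are plain text and small;
once present, the worked-example acceptance checks and scripts/acceptance.py
targets t1-t4 run fully offline.
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

ACCESSIONS = ("P78536", "P16471")
DATA = Path(__file__).resolve().parents[1] / "data"


def main() -> int:
    DATA.mkdir(exist_ok=True)
    for acc in ACCESSIONS:
        dest = DATA / f"{acc}.fasta"
        if dest.exists():
            print(f"{dest} already present", file=sys.stderr)
            continue
        url = f"https://rest.uniprot.org/uniprotkb/{acc}.fasta"
        print(f"fetching {url}", file=sys.stderr)
        with urllib.request.urlopen(url, timeout=30) as resp:
            dest.write_bytes(resp.read())
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
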