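#!/usr/bin/env python
"""Optional real-data benchmark (network required).

Downloads the Mnemiopsis leidyi v2.2 filtered protein models from the
NHGRI Mnemiopsis Genome Portal, then:

* screens all predicted proteins for the FYY motif (mode=any) and reports
  the number of gene models scanned and the number carrying the motif;
* globally aligns ML35201a against ML199826a and reports percent identity
  under both gap conventions (the truncated paralog is expected to be
  identical to the full-length protein once gaps are ignored).

This script is the only part of the package that touches the network; the
test suite and scripts/acceptance.py never do.

Usage:  python scripts/benchmark_real_data.py [--fasta local_copy.fasta]
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

PORTAL_URL = (
    "https://research.nhgri.nih.gov/mnemiopsis/download/proteome/"
    "ML2.2.aa.gz"
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument(
        "--fasta",
        type=Path,
        help="Local copy of the filtered protein models (skips the download).",
    )
    args = ap.parse_args()

    if args.fasta:
        path = args.fasta
    else:
        import gzip
        import tempfile

        print(f"downloading {PORTAL_URL} ...", file=sys.stderr)
        raw = urllib.request.urlopen(PORTAL_URL).read()
        tmp = Path(tempfile.mkstemp(suffix=".fasta")[1])
        tmp.write_bytes(gzip.decompress(raw))
        path = tmp

    from luciscreen.align import global_align, percent_identity
    from luciscreen.motif_screen import MotifSpec, scan_proteome
    from luciscreen.seqio import Proteome, read_fasta

    records = read_fasta(path, moltype="protein")
    proteome = Proteome(species="Mlei", records=records)
    summary = scan_proteome(proteome, MotifSpec("FYY", "any"))
    print(f"gene models scanned: {summary.n_records}")
    print(f"models containing FYY: {summary.n_records_with_hit}")

    by_id = {r.id: r for r in records}
    a, b = by_id.get("ML35201a"), by_id.get("ML199826a")
    if a and b:
        pw = global_align(a, b)
        print(
            f"ML35201a vs ML199826a: ignore-gaps "
            f"{percent_identity(pw, 'ignore_gaps'):.1f}%, include-gaps "
            f"{percent_identity(pw, 'include_gaps'):.1f}%"
        )
    else:
        print("ML35201a / ML199826a not found in this FASTA", file=sys.stderr)


if __name__ == "__main__":
    main()
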