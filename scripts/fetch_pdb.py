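#!/usr/bin/env python
"""Download PDB entries from RCSB (network-requiring helper; the core tool
never needs network access).

Usage::

    python scripts/fetch_pdb.py 6drx 3nya 5tvn 3d4s 3uon 3ny8 --out data/pdb/
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("pdb_ids", nargs="+", help="PDB entry ids (e.g. 6drx)")
    parser.add_argument("--out", type=Path, default=Path("data/pdb"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    failures = 0
    for pdb_id in args.pdb_ids:
        target = args.out / f"{pdb_id.lower()}.pdb"
        url = RCSB_URL.format(pdb_id=pdb_id.upper())
        try:
            with urllib.request.urlopen(url, timeout=60) as response:
                target.write_bytes(response.read())
            print(f"{pdb_id} -> {target}")
        except OSError as exc:
            print(f"failed to fetch {pdb_id}: {exc}", file=sys.stderr)
            failures += 1
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main())
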