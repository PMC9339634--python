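"""Fetch the two real study cohorts from the UCI Machine Learning
Repository into ``data/`` (network required; the library itself never
touches the network).

Usage:  python scripts/fetch_uci.py [--dest data/]

Downloads:
* ``sick.data`` — thyroid "sick" database (2800 records, 30 columns,
  comma-separated, ``?`` missing, class field suffixed ``|record-id``).
* ``z_alizadeh_sani.xlsx`` — Z-Alizadeh Sani cardiology registry
  (303 records, 56 attributes), extracted from the UCI zip archive.
"""

from __future__ import annotations

import argparse
import io
import sys
import urllib.request
import zipfile
from pathlib import Path

SICK_URL = ("https://archive.ics.uci.edu/ml/machine-learning-databases/"
            "thyroid-disease/sick.data")
ZAS_ZIP_URL = "https://archive.ics.uci.edu/static/public/412/z+alizadeh+sani.zip"


def fetch(url: str) -> bytes:
    print(f"fetching {url} ...", flush=True)
    with urllib.request.urlopen(url, timeout=60) as resp:
        return resp.read()


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dest", default="data", type=Path)
    args = parser.parse_args()
    args.dest.mkdir(parents=True, exist_ok=True)

    sick = args.dest / "sick.data"
    if sick.exists():
        print(f"{sick} already present, skipping")
    else:
        sick.write_bytes(fetch(SICK_URL))
        print(f"wrote {sick}")

    xlsx = args.dest / "z_alizadeh_sani.xlsx"
    if xlsx.exists():
        print(f"{xlsx} already present, skipping")
    else:
        blob = fetch(ZAS_ZIP_URL)
        with zipfile.ZipFile(io.BytesIO(blob)) as zf:
            names = [n for n in zf.namelist() if n.lower().endswith(".xlsx")]
            if not names:
                print("no .xlsx member found in archive", file=sys.stderr)
                return 1
            xlsx.write_bytes(zf.read(names[0]))
        print(f"wrote {xlsx}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
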