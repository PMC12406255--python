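"""Download the deposited structures used by the integration checks.

Requires network access.  Places 1qjb.pdb (14-3-3zeta) and 2cmy.pdb
(VhTI trypsin inhibitor) under scratch/pdb/ where the integration test
expects them.

Usage: python scripts/fetch_pdb.py
"""

from pathlib import Path
from urllib.request import urlopen

ENTRIES = ("1qjb", "2cmy", "2plx")
OUT = Path(__file__).resolve().parents[1] / "scratch" / "pdb"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for entry in ENTRIES:
        dest = OUT / f"{entry}.pdb"
        if dest.exists():
            print(f"{dest} already present")
            continue
        url = f"https://files.rcsb.org/download/{entry.upper()}.pdb"
        print(f"fetching {url}")
        with urlopen(url, timeout=60) as resp:
            dest.write_bytes(resp.read())
        print(f"wrote {dest}")


if __name__ == "__main__":
    main()
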