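#!/usr/bin/env python
"""Re-derive the published summary counts from the supplementary tables.

Given a local copy of the released supplementary tables (see
lncscreen.supplementary for the expected filenames and columns), re-runs
the filter cascade, hit rule, stringent-non-hit rule, expression threshold,
and cluster join on the raw columns and prints each derived count next to
the published one. The tables are multi-megabyte downloads and are not
bundled with this repository.
"""

import argparse
import sys
from pathlib import Path

from lncscreen.supplementary import PRINTED_COUNTS, reproduce_printed_counts


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("data/supplementary"))
    args = ap.parse_args()

    try:
        derived = reproduce_printed_counts(args.data)
    except FileNotFoundError as exc:
        print(exc)
        print("Download the supplementary tables and place them under "
              f"{args.data} to run this reproduction.")
        sys.exit(1)

    width = max(len(k) for k in PRINTED_COUNTS)
    ok = True
    for key, published in PRINTED_COUNTS.items():
        got = derived.get(key)
        match = "OK" if got == published else "MISMATCH"
        ok &= got == published
        print(f"{key:<{width}}  derived {got:>8}  published {published:>8}  {match}")
    sys.exit(0 if ok else 2)


if __name__ == "__main__":
    main()
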