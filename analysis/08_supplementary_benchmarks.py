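#!/usr/bin/env python
"""Recompute published network statistics from the study's supplementary
datasheets, if present.

The four reconstructed networks and the ortholog table are distributed as
supplementary downloads of the original article and are not shipped here.
Export them as TSV under data/supplementary/ (see antnet.benchmarks for the
recognised file names) and this driver recomputes the printed topology,
conservation and confidence-band statistics for comparison.
"""

import json
from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from antnet.benchmarks import run_supplementary_benchmarks

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "data" / "supplementary"


def main() -> None:
    try:
        results = run_supplementary_benchmarks(DATA)
    except FileNotFoundError as exc:
        print(f"skipping: {exc}")
        print("place the exported supplementary tables under data/supplementary/ to run")
        return
    print(json.dumps(results, indent=2))
    out = ROOT / "results" / "supplementary_benchmarks.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(results, indent=2))
    print(f"written to {out}")


if __name__ == "__main__":
    main()
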