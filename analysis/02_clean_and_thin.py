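#!/usr/bin/env python
"""Clean, filter, period-bin and spatially thin the raw occurrence tables.

Applies the archive-hygiene rules (zero/equal coordinates, listed centroid
points, ocean records), the 1990-2019 window, 5-year period binning and the
one-record-per-species-per-5-km-cell-per-period thinning.  Writes cleaned
CSVs and a JSON removal report per taxon.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import TAXA, cli, taxon_config

from climdebt import generate_world
from climdebt.pipeline import prepare_records


def main() -> None:
    args = cli(__doc__)
    report = {}
    for name in TAXA:
        cfg = taxon_config(name, args.seed)
        landscape, _, raw_path = None, None, args.out / f"occurrences_raw_{name}.csv"
        landscape, pool, raw = generate_world(cfg)
        if raw_path.exists():  # prefer the tables written by script 01
            raw = pd.read_csv(raw_path)
        records, removed = prepare_records(landscape, raw,
                                           thin_seed=cfg.seed + 13)
        records.to_csv(args.out / f"occurrences_clean_{name}.csv", index=False)
        report[name] = {"input": len(raw), "thinned": len(records),
                        "removed": removed}
        print(f"{name}: {len(raw)} raw -> {len(records)} thinned "
              f"({removed})")
    (args.out / "cleaning_report.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
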