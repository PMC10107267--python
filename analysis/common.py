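"""Shared setup for the analysis scripts.

The study system is a synthetic two-continent world observed 1990-2019.
Three "taxa" are simulated as independent worlds that differ in their
tracking fraction lambda (how completely ranges follow warming isotherms),
so the cross-taxon stages (meta-analysis, sensitivity) have real
heterogeneity to work with.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from climdebt import WorldConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"

#: the three simulated taxa: name -> (tracking fraction, seed offset)
TAXA = {"trackers": (1.0, 0), "laggards": (0.5, 1), "sessile": (0.2, 2)}


def taxon_config(name: str, seed: int) -> WorldConfig:
    lam, offset = TAXA[name]
    return WorldConfig(lam=lam, warming_rate=(0.0, 0.04), seed=seed + offset)


def cli(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=RESULTS)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    return args
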