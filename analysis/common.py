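"""Shared plumbing for the numbered analysis drivers.

Every driver re-derives the seeded study simulation in memory (about ten
seconds) instead of parsing bulky read intermediates from disk; the
derivation is deterministic, so all drivers see byte-identical data for
the same seed.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from delscan.pipeline import RunConfig, simulate_study

RESULTS = Path(__file__).resolve().parent.parent / "results"


def parse_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1, help="master seed")
    return ap.parse_args()


def load_study(seed: int = 1, keep_pairs: bool = False):
    cfg = RunConfig(seed=seed, out_dir=str(RESULTS / "pipeline"))
    return simulate_study(cfg, keep_pairs=keep_pairs)


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
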