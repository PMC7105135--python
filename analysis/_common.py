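"""Shared paths and loaders for the numbered analysis scripts."""

import argparse
import warnings
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results" / "analysis"
INPUTS = RESULTS / "inputs"

warnings.filterwarnings("ignore", message="bisulfite conversion efficiency")


def parse_seed(description: str) -> int:
    p = argparse.ArgumentParser(description=description)
    p.add_argument("--seed", type=int, default=1)
    return p.parse_args().seed


def stage_dir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
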