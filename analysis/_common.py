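"""Shared plumbing for the analysis drivers: paths, panel loading."""

from __future__ import annotations

import argparse
from pathlib import Path

from vaxineq.io import build_cells, read_disaggregated

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
PANEL = RESULTS / "panel.csv"


def parse_seed(description: str, default: int = 20260) -> int:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=default)
    return parser.parse_args().seed


def load_cells():
    if not PANEL.exists():
        raise SystemExit(
            f"{PANEL} not found - run `python analysis/01_simulate_panel.py` first"
        )
    records = read_disaggregated(PANEL, strict=True)
    cells, exclusions = build_cells(records)
    return records, cells, exclusions
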