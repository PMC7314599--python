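"""Shared run setup for the numbered analysis scripts.

Every script operates on the same run directory (default scratch/desk_run) so
each stage picks up the previous one's saved outputs; key tables are copied to
results/ at the end of the stages that produce them.
"""

from __future__ import annotations

import argparse
import shutil
from pathlib import Path

from diarmap.pipeline import PipelineConfig, _Run, desk_config

REPO = Path(__file__).resolve().parents[1]
RESULTS = REPO / "results"


def make_run(description: str, n_draws: int = 100) -> _Run:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=REPO / "scratch" / "desk_run")
    ap.add_argument("--draws", type=int, default=n_draws)
    args = ap.parse_args()
    cfg = desk_config(seed=args.seed, n_draws=args.draws)
    return _Run(cfg, args.out)


def publish(run: _Run, *names: str) -> None:
    """Copy a stage's CSV outputs into results/."""
    RESULTS.mkdir(exist_ok=True)
    for name in names:
        src = run.path(name)
        if src.exists():
            shutil.copy(src, RESULTS / name)
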