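"""Shared argument handling for the numbered analysis drivers."""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from gliscan.pipeline import RunConfig


def load_config() -> RunConfig:
    parser = argparse.ArgumentParser()
    parser.add_argument("--config", type=Path, default=None,
                        help="YAML file of RunConfig overrides")
    parser.add_argument("--outdir", default="results/run")
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()
    if args.config is not None:
        cfg = RunConfig.from_yaml(args.config)
    else:
        cfg = RunConfig(outdir=args.outdir, seed=args.seed)
    return cfg
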