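"""Evaluate predictions against a synthetic open-chromatin track.

Generates a feature track enriched over the true enhancers (cover
probability 0.8 over truth vs 0.3 over background) and tests whether
predicted-positive windows overlap it more often than predicted
negatives (pooled two-proportion Z-test, one-sided).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))
from common import load_config  # noqa: E402

from gliscan import pipeline  # noqa: E402

config = load_config()
summary = pipeline.run_stage("evaluate", config)
print(f"Z-test report written to {config.outdir}/ztest_report.tsv")
print(f"  predicted positive windows: {summary['n_pos']}")
print(f"  predicted negative windows: {summary['n_neg']}")
print(f"  Z = {summary['z']:.4f}  (one-sided p = {summary['p_value']:.3g})")
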