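"""Generate the synthetic enhancer study the rest of the analysis runs on.

Writes a 4 Mb synthetic chromosome carrying 1000 implanted enhancer
peaks (GLI 12-mer near the midpoint, cofactor word ~200 bp out) plus
1000 bare decoy GBM sites, together with the truth tables, under the
run directory.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))
from common import load_config  # noqa: E402

from gliscan import pipeline  # noqa: E402

config = load_config()
summary = pipeline.run_stage("synth", config)
print(f"wrote study to {config.outdir}")
print(f"  peaks implanted : {summary['n_peaks']}")
print(f"  genome length   : {summary['genome_length']:,} bp")
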