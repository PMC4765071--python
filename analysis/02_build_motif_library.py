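"""Build the GBM 12-mer library from the synthetic peak set.

Runs the iterative match-remove-rediscover loop (Fisher-exact word
enrichment against shuffled negatives, GLI structural filter) and
writes library.tsv. On the synthetic study this should recover the
implanted grammar words.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))
from common import load_config  # noqa: E402

from gliscan import pipeline  # noqa: E402

config = load_config()
summary = pipeline.run_stage("library", config)
print(f"library written to {config.outdir}/library.tsv")
print(f"  motifs recovered: {summary['n_motifs']}")
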