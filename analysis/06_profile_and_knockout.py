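"""Profile k-mer weights along the top window and knock out its GLI sites.

Writes the per-position weight profile of the highest-scoring window
as bedGraph, then applies the GLI-site knockout (the invariant core C
mutated to G) and rescores, showing how much of the window's score the
GLI sites carry.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))
from common import load_config  # noqa: E402

from gliscan import pipeline  # noqa: E402

config = load_config()
prof = pipeline.run_stage("profile", config)
gko = pipeline.run_stage("gko", config)
print(f"profile written to {config.outdir}/profile_top_window.bedgraph")
print(f"  top window : {prof['top_window']} (score {prof['top_score']:.3f})")
print(f"GLI knockout of {gko['n_sites']} site(s):")
print(f"  wild-type score {gko['wt_score']:.3f} -> knockout "
      f"{gko['gko_score']:.3f}")
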