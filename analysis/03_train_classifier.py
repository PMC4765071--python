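"""Train the k-mer spectrum SVM on motif-containing peaks.

Restricts peaks to those containing a library GBM (the wGBM subset),
samples GC-matched genomic background, evaluates by five repeated
80/20 holdout splits (ROC + PRC), then fits the final model on all
sequences and writes its canonical 8-mer weight table.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))
from common import load_config  # noqa: E402

from gliscan import pipeline  # noqa: E402

config = load_config()
summary = pipeline.run_stage("train", config)
print(f"model written to {config.outdir}/model_SYN.tsv")
print(f"  training set    : {summary['n_pos']} positives, "
      f"{summary['n_neg']} GC-matched negatives")
print(f"  mean ROC AUC    : {summary['mean_roc_auc']:.3f}")
print(f"  mean PRC AUC    : {summary['mean_prc_auc']:.3f}")
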