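# Analysis drivers

Run in order from the repository root; every script accepts
`--outdir` (default `results/run`) and `--seed` (default 0), or
`--config run.yaml` with `gliscan.pipeline.RunConfig` keys.

| script | stage | writes |
| --- | --- | --- |
| `01_simulate_study.py` | synthetic study (genome, peaks, truth, decoy GBM sites) | `genome.fa`, `peaks_SYN.bed`, `truth_*.tsv/bed` |
| `02_build_motif_library.py` | iterative GBM 12-mer library construction | `library.tsv` |
| `03_train_classifier.py` | wGBM restriction, GC-matched background, k-mer SVM + repeated holdout | `model_SYN.tsv`, `curves_SYN.csv` |
| `04_scan_genome.py` | 600 bp windows around every genomic GBM, scored and called | `scored_windows.tsv` |
| `05_evaluate_predictions.py` | overlap Z-test against an enhancer-enriched track | `ztest_report.tsv` |
| `06_profile_and_knockout.py` | per-base weight profile + GLI-site knockout of the top window | `profile_top_window.bedgraph`, `gko_report.tsv` |

Each stage writes a `manifest_<stage>.json` recording parameters, the
seed, and SHA-256 hashes of its inputs.
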