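# gliscan

Sequence-based prediction of Hedgehog-responsive enhancers.

GLI transcription factors (GLI1-3) transduce Hedgehog (Hh) signaling by
binding a well-conserved 12 bp motif (the GLI binding motif, GBM), yet
only a small fraction of genomic GBM occurrences sit in functional
enhancers. `gliscan` implements the computational strategy for telling
them apart:

1. **Motif library construction** — an iterative loop over ChIP peak
   sequence sets: remove sequences matching the current library,
   rediscover enriched 12-mers in the remainder (one-sided Fisher exact
   test, Bonferroni-corrected), keep those passing a structural
   GLI-likeness filter (the invariant `CCxC` block at positions 4-7),
   and repeat until nothing new is accepted. Words are
   reverse-complement canonicalized and tiered **HC/MC/LC** by how many
   datasets contain them.
2. **k-mer spectrum SVM** — a linear soft-margin SVM over canonical
   8-mer counts (32,896 features; a k-mer and its reverse complement
   share one feature), trained on motif-containing peaks vs GC-matched
   genomic background. The score of a window decomposes exactly as

   `s(x) = b + Σ_i w(kmer_i)`

   over its positions, so per-base weight profiles are faithful
   decompositions of the classifier output. Platt scaling
   `P(enhancer | s) = 1 / (1 + exp(A s + B))` turns scores into
   posteriors.
3. **Genome scan** — every exact GBM occurrence (both strands) anchors
   a 600 bp window centered on the site; each window is scored, called
   by sign, and graded by posterior.
4. **Evaluation** — predicted-positive vs predicted-negative windows
   are compared for overlap with epigenomic feature tracks by a pooled
   two-proportion Z-test, `Z = (p̂₁ − p̂₂) / √(p̄(1−p̄)(1/n₁ + 1/n₂))`;
   peak-set sharing is summarized by Venn overlap; regions are
   annotated to their two nearest TSSs.
5. **In silico knockout (GKO)** — the invariant core cytosine of each
   GLI site (position 7 of the 12-mer) is mutated C→G, abolishing the
   match, to quantify how much of a window's score its GLI sites carry.

Because the original ChIP datasets and mouse genome are external, the
package ships a seeded synthetic-study generator
(`gliscan.simulate`) that reproduces the statistical structure the
analysis assumes — peaks with mostly single GBMs (~88%), cofactor words
offset ~200 bp from the peak midpoint, GC-matched-able background, and
feature tracks enriched over true enhancers — so the entire pipeline is
testable end to end on a desk machine.

## Worked example

The numbered drivers under `analysis/` run the whole study
(`--outdir results/run --seed 0`):

```text
$ python analysis/01_simulate_study.py
wrote study to results/run
  peaks implanted : 1000
  genome length   : 4,000,000 bp

$ python analysis/02_build_motif_library.py
library written to results/run/library.tsv
  motifs recovered: 4

$ python analysis/03_train_classifier.py
model written to results/run/model_SYN.tsv
  training set    : 1000 positives, 1000 GC-matched negatives
  mean ROC AUC    : 0.995
  mean PRC AUC    : 0.994

$ python analysis/04_scan_genome.py
scored windows written to results/run/scored_windows.tsv
  GBM windows scored : 2117
  called positive    : 1641 (77.5%)

$ python analysis/05_evaluate_predictions.py
Z-test report written to results/run/ztest_report.tsv
  predicted positive windows: 1641
  predicted negative windows: 476
  Z = 15.7301  (one-sided p = 4.7e-56)

$ python analysis/06_profile_and_knockout.py
profile written to results/run/profile_top_window.bedgraph
  top window : chrS:3000457-3001057 (score 2.047)
GLI knockout of 2 site(s):
  wild-type score 2.047 -> knockout 0.199
```

Reading the numbers: the library loop recovers exactly the four
implanted GLI 12-mers; repeated 80/20 holdout shows the classifier
separates enhancer peaks from GC-matched background nearly perfectly
on this synthetic grammar; the genome scan finds 2,117 GBM windows
(1,000 enhancers, 1,000 bare decoy sites, plus chance occurrences) and
calls 77.5% positive; the positive calls are strongly enriched for the
synthetic open-chromatin track (Z = 15.7); and knocking out the two
GLI sites of the top window removes ~90% of its score — the sequence
signal the classifier uses is concentrated on the GLI sites and their
grammar.

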