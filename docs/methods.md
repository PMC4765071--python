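# Methods

## Problem setting

GLI transcription factors bind a 12 bp motif (GBM) whose genomic
occurrences vastly outnumber functional Hedgehog enhancers. The
pipeline treats enhancer prediction as a supervised sequence
classification problem: ChIP peaks that contain a GBM (the *wGBM*
subset) are positives, GC-matched random genomic regions are
negatives, and the trained classifier is applied to a fixed-width
window around every genomic GBM occurrence.

## Motif library

The library loop per dataset: (i) remove sequences matching any word
of the current library (a word matches if it or its reverse complement
occurs exactly); (ii) run exact-word enrichment on the remainder —
every canonical 12-mer present in the positives is tested by a
one-sided Fisher exact test (hypergeometric tail) of per-sequence
presence against a negative set, Bonferroni-corrected over the tested
words; (iii) accept enriched words that pass the structural filter;
(iv) repeat until no acceptance, capped at 25 iterations. The union
over datasets is tiered by presence: HC in all datasets, MC in two or
more, LC in one.

*Structural filter.* A 12-mer is GLI-like if either orientation
carries C at positions 4, 5 and 7 (the `CCxC` block). The 9 bp GLI
core `GACCACCCA` sits at positions 2-10 of the 12-mer frame; the
invariant core cytosine used by the knockout (below) is the core's 6th
base, i.e. position 7 of the 12-mer.

*Negative sequences for discovery.* When the caller supplies none, the
builder uses per-sequence letter shuffles (seeded), which preserve
each sequence's length and base composition while destroying word
structure — the standard null for word-enrichment testing.

*Word-level replacement of profile-based discovery.* External motif
discoverers and motif-comparison tools are interchangeable engines
inside this loop; the loop logic itself (match → remove → re-enrich)
is the method. The built-in discoverer is exact-word based, so the
library it produces on real data would differ in detail from one built
with profile-based tools, and tests therefore exercise the loop on
synthetic fixtures with known ground truth.

*Matrix similarity.* For PWM site calling the package implements the
information-weighted matrix similarity score
`MSS = (Current − Min) / (Max − Min)` with
`I(i) = Σ_b f(i,b) ln(4 f(i,b))`, `Current = Σ_i I(i) f(i, b_i)`, and
Max/Min the per-column best and worst *realizable* (nonzero-frequency)
base. PWMs are built with pseudocount 0.01 (all frequencies positive,
so the realizable-base qualification is then vacuous); natural log; a
cutoff of 0.81 reproduces the conventional "81% matrix similarity"
calling threshold. Degenerate PWMs with Max = Min score 1.0.

## k-mer spectrum SVM

Features are raw occurrence counts of canonical 8-mers
((4⁸ − 4⁴)/2 + 4⁴ = 32,896 features); windows containing N contribute
nothing. Raw counts (not unit-normalized vectors) keep the score
exactly equal to bias plus the positional sum of weights, which is
what makes per-base weight profiles a faithful decomposition of the
score; this may diverge in detail from implementations that normalize.
The classifier is a linear soft-margin SVM (C = 1.0 by default, exact
kernel solver), fitted with a fixed random seed. Posteriors use
Platt's sigmoid `1/(1 + exp(A s + B))` fitted on the training scores
by regularized maximum likelihood with the usual smoothed targets
`(N₊+1)/(N₊+2)` and `1/(N₋+2)`; A is negative when higher scores mean
more positive.

Evaluation is by stratified repeated holdout: five independent random
80/20 splits, ROC (trapezoidal AUC; tied pairs get half credit, so the
AUC equals the Mann-Whitney concordance probability) and
precision-recall (right-step interpolation, i.e. average precision).
Curve computation is delegated to scikit-learn; the test suite checks
the ROC AUC against an independent brute-force all-pairs oracle.

## Genome scan

Every exact occurrence of a library word or its reverse complement is
reported (overlaps allowed; a site matching a word and its reverse
complement is reported once, forward orientation preferred). The
600 bp scoring window is centered on the site midpoint (start + 6);
windows that would run off a contig are discarded rather than clipped
so that all scored windows have identical length. Calls are
sign-based; "high confidence" is operationalized as raw score ≥ 1, the
computable form of posterior-probability-one. Background regions for
training are rejection-sampled per positive: same length, |ΔGC| ≤ 0.02,
no N, no overlap with any positive, at most 10,000 draws per region
(the failing positive is named on error).

## Evaluation statistics

Overlap of two region groups with a feature track (≥ 1 bp, strand
blind) is compared by the pooled two-proportion Z-test with a
one-sided p-value (direction: predicted positives overlap more); a
pooled proportion of 0 or 1 yields a flagged NaN result rather than a
number. Venn overlap merges all regions across datasets by
single-linkage on ≥ 1 bp and assigns each merged region the subset of
datasets contributing to it. The GBM-per-peak spectrum counts distinct
match start positions per peak and normalizes over peaks with at least
one site. Gene annotation takes the two nearest TSSs by absolute
distance to the region midpoint (ties by gene name), a deliberate
simplification of regulatory-domain annotators, adequate for labeling
predictions.

## Synthetic data generator

The generator emulates the features of GLI ChIP data the analysis
depends on, with defaults drawn from the statistical structure of
those datasets where it is quantified:

| parameter | default | rationale |
| --- | --- | --- |
| `p_single_gbm` | 0.88 | ~85-90% of motif-containing peaks carry a single site |
| `cofactor_offset_mean/sd` | 200 / 50 bp | cofactor (e.g. Sox) enrichment peaks ~200 bp from the peak midpoint |
| `gbm_offset_sd` | 75 bp | GBM enrichment is broad around the midpoint; jitter clipped to the peak |
| `peak_width` | 600 bp | the scoring-window width |
| `gc` | 0.42 | mouse-like genomic GC |
| GBM words | 4 variants of `xGACCACCCAxx` | GLI core with varying flanks, all passing the structural filter |
| cofactor words | `CACCTGTT`, `AACAATGG` | E-box-like and Sox-like words |

Genomes are i.i.d. with the given GC; implants overwrite bases in
place so coordinates stay stable; every implant is recorded in a truth
table verifiable by substring inspection. `n_decoy_gbm` optionally
scatters bare GBM words (no cofactor, with a clear margin around their
scoring window) outside the peaks, emulating the genomic excess of
non-enhancer motif occurrences; the full pipeline enables this so its
scan produces predicted negatives for the Z-test stage. Feature tracks
cover each true-enhancer region with probability `p_enh`, each
supplied background region with probability `p_bg`, plus optional
random decoy intervals.

What the generator does *not* model: Markov or repeat structure of
real genomes, ChIP fragment-level noise, motif degeneracy beyond the
fixed word list, or chromatin context. Passing tests therefore
demonstrate the pipeline's internal correctness and its behavior under
the assumed data structure, not performance on real ChIP data — on
real data the classifier AUCs are expected to be substantially lower
(the synthetic grammar is close to separable by construction).

## Problem sizes and numerical choices

The default study is 1,000 peaks on a 4 Mb chromosome with 1,000
GC-matched negatives; repeated holdout uses five 80/20 splits. The
parameter-recovery experiment uses the GBM-only grammar (no cofactor
words) at n = 400: recovery is defined as motif-substring membership
of the top-weighted 8-mers, and an 8-mer overlapping an 8 bp cofactor
word plus flanking base is not a substring of it, so cofactors are
excluded from that experiment by design. The end-to-end
discrimination check (enhancer windows vs bare-GBM windows) uses
250 + 250 windows on a fresh 2 Mb genome, large enough that the AUC
estimate's sampling noise (≈ 0.02) is small relative to the margin.
Coordinates are 0-based half-open throughout; non-ACGT bases are
masked to N, and N never matches a motif or contributes a k-mer
window. All stochastic operations take explicit seeds and are
bit-reproducible; pipeline stages write manifests with parameter
values, seeds and input hashes.

## Known limitations

- The exact-word discoverer cannot represent degenerate motif
  families compactly; a real-data library built with it would be
  larger and noisier than one from profile-based tools.
- Platt calibration is fitted on training scores (no held-out
  calibration split), matching common practice but slightly
  optimistic.
- The two-nearest-TSS annotation ignores regulatory-domain rules and
  will mis-assign enhancers that skip adjacent genes.
- Whole-genome scanning is pure Python; it is comfortable at tens of
  megabases but not meant for a full mammalian genome in one process.
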