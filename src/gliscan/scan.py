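"""Genome-wide scoring of candidate enhancer windows around GBM sites.

Every exact genomic GBM occurrence anchors a fixed-width window (600 bp
by default, centered on the site midpoint) that is scored by one or
more trained k-mer SVM classifiers; the sign of the score calls the
window positive or negative and Platt posteriors grade confidence.
Also provides GC-matched background sampling for training negatives,
inter-classifier score correlation, and per-position weight profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import pearsonr

from .core import FeatureTrack, Genome, Region, gc_content, overlaps_any, write_bedgraph
from .motifs import GBMMatch, MotifLibrary, scan_genome_for_gbm
from .svm import KmerModel, canonical, posterior, score

GBM_MIDPOINT_OFFSET = 6  # midpoint of a 12-bp site, relative to its start


@dataclass
class BackgroundSet:
    """GC-matched random regions paired 1:n with the positive set."""

    regions: list[Region]
    sequences: list[str]
    provenance: dict = field(default_factory=dict)


def sample_gc_matched_background(
    genome: Genome,
    positives: list[Region],
    n_per_positive: int = 1,
    gc_tol: float = 0.02,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> BackgroundSet:
    """Rejection-sample same-length background regions matched on GC.

    For each positive region, draws `n_per_positive` random regions of
    identical length whose GC content is within `gc_tol` of that
    positive's, that contain no N, and that do not overlap any positive
    region. Deterministic given the seed; raises, naming the positive,
    if matching fails within `max_attempts` draws.
    """
    rng = np.random.default_rng(seed)
    pos_track = FeatureTrack("positives", positives)
    contigs = sorted(genome.contigs)
    lengths = np.array([genome.length(c) for c in contigs], dtype=float)
    weights = lengths / lengths.sum()

    regions: list[Region] = []
    sequences: list[str] = []
    for p_i, pos in enumerate(positives):
        target_gc = gc_content(genome.fetch(pos.contig, pos.start, pos.end))
        width = pos.width
        for _ in range(n_per_positive):
            for _attempt in range(max_attempts):
                c = contigs[rng.choice(len(contigs), p=weights)]
                limit = genome.length(c) - width
                if limit < 0:
                    continue
                start = int(rng.integers(0, limit + 1))
                cand = Region(c, start, start + width, label=f"bg_{p_i}")
                if overlaps_any(cand, pos_track):
                    continue
                seq = genome.fetch(c, start, start + width)
                if "N" in seq:
                    continue
                if abs(gc_content(seq) - target_gc) <= gc_tol:
                    regions.append(cand)
                    sequences.append(seq)
                    break
            else:
                raise RuntimeError(
                    f"could not GC-match positive #{p_i} "
                    f"({pos.contig}:{pos.start}-{pos.end}, GC={target_gc:.3f}) "
                    f"within {max_attempts} attempts"
                )
    return BackgroundSet(
        regions,
        sequences,
        provenance={"seed": seed, "gc_tol": gc_tol,
                    "n_per_positive": n_per_positive},
    )


def extract_window(
    match: GBMMatch, genome: Genome, width: int = 600
) -> Region | None:
    """Fixed-width window centered on the GBM midpoint.

    Windows that would run off a contig end are discarded (None), not
    clipped, so that every scored window has identical length.
    """
    m = match.region.start + GBM_MIDPOINT_OFFSET
    start = m - width // 2
    end = start + width
    if start < 0 or end > genome.length(match.region.contig):
        return None
    return Region(match.region.contig, start, end, strand=".", label=match.word)


@dataclass
class ScoredWindow:
    """A 600 bp window around a genomic GBM with per-classifier scores."""

    region: Region
    gbm: GBMMatch
    scores: dict[str, float]
    posteriors: dict[str, float]
    calls: dict[str, bool]  # sign-based: score > 0


def scan_and_score(
    genome: Genome,
    library: MotifLibrary,
    models: dict[str, KmerModel],
    width: int = 600,
) -> list[ScoredWindow]:
    """Score the window around every genomic GBM with every classifier."""
    if not models:
        raise ValueError("at least one model required")
    out: list[ScoredWindow] = []
    for match in scan_genome_for_gbm(genome, library):
        window = extract_window(match, genome, width)
        if window is None:
            continue
        seq = genome.fetch(window.contig, window.start, window.end)
        scores = {name: score(m, seq) for name, m in models.items()}
        posts = {name: posterior(m, scores[name]) for name, m in models.items()}
        calls = {name: s > 0 for name, s in scores.items()}
        out.append(ScoredWindow(window, match, scores, posts, calls))
    out.sort(key=lambda w: (w.region.contig, w.region.start))
    return out


def classifier_correlation(
    scored: list[ScoredWindow],
    model_a: str,
    model_b: str,
    subset: str = "all",
) -> float:
    """Pearson correlation between two classifiers' window scores.

    subset: "all" uses every window; "positive_only" keeps windows
    where both scores exceed 0; "high_confidence" where both reach 1
    (the score-scale proxy for posterior probability 1.0).
    """
    if subset not in ("all", "positive_only", "high_confidence"):
        raise ValueError(f"unknown subset {subset!r}")
    a = np.array([w.scores[model_a] for w in scored])
    b = np.array([w.scores[model_b] for w in scored])
    if subset == "positive_only":
        keep = (a > 0) & (b > 0)
    elif subset == "high_confidence":
        keep = (a >= 1) & (b >= 1)
    else:
        keep = np.ones(len(a), dtype=bool)
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError(f"subset {subset!r} has fewer than 3 windows")
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise ValueError("zero variance in scores")
    return float(pearsonr(a, b)[0])


def weight_profile(model: KmerModel, seq: str) -> np.ndarray:
    """Per-start-position k-mer weight along a sequence.

    value[i] = weight of the canonical k-mer starting at i (0 for
    N-containing windows); the profile sums to score(seq) - bias, which
    is what makes it a faithful decomposition of the classifier score.
    """
    k = model.index.k
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k = {k}")
    vals = np.zeros(len(seq) - k + 1)
    for i in range(len(vals)):
        w = canonical(seq[i : i + k])
        if w is not None:
            vals[i] = model.weights[model.index.kmer_to_col[w]]
    return vals


def profile_to_bedgraph(
    profile: np.ndarray, contig: str, start: int, path: str | Path
) -> None:
    """Export a weight profile as single-base bedGraph intervals."""
    intervals = [
        (contig, start + i, start + i + 1, float(v))
        for i, v in enumerate(profile)
    ]
    write_bedgraph(intervals, path)
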