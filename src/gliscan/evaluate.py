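"""Downstream assessment of enhancer predictions.

Overlap enrichment of predicted-positive vs predicted-negative windows
against epigenomic feature tracks (pooled two-proportion Z-test),
multi-dataset Venn overlap of peak sets, the GBM-per-peak frequency
spectrum, motif positional profiles around peak midpoints, and a
two-nearest-gene annotation of predicted regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .core import FeatureTrack, Region, overlaps_any, revcomp
from .motifs import MotifLibrary


@dataclass
class OverlapStats:
    """Two-proportion comparison of track overlap between region groups."""

    n_pos: int
    k_pos: int
    n_neg: int
    k_neg: int
    z: float  # NaN when the pooled proportion is degenerate (0 or 1)
    p_value: float

    @property
    def p_pos(self) -> float:
        return self.k_pos / self.n_pos

    @property
    def p_neg(self) -> float:
        return self.k_neg / self.n_neg

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.z)


def overlap_ztest(
    pos_regions: Sequence[Region],
    neg_regions: Sequence[Region],
    track: FeatureTrack,
) -> OverlapStats:
    """Pooled two-proportion Z-test on track overlap fractions.

    Z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with the pooled overlap
    proportion p; the one-sided p-value tests whether predicted
    positives overlap the track more often than predicted negatives.
    When every region overlaps (or none does) the statistic is
    undefined and the result is flagged with Z = NaN.
    """
    if not pos_regions or not neg_regions:
        raise ValueError("both region groups must be non-empty")
    k_pos = sum(overlaps_any(r, track) for r in pos_regions)
    k_neg = sum(overlaps_any(r, track) for r in neg_regions)
    n_pos, n_neg = len(pos_regions), len(neg_regions)
    pooled = (k_pos + k_neg) / (n_pos + n_neg)
    if pooled in (0.0, 1.0):
        return OverlapStats(n_pos, k_pos, n_neg, k_neg, float("nan"), float("nan"))
    se = np.sqrt(pooled * (1 - pooled) * (1 / n_pos + 1 / n_neg))
    z = (k_pos / n_pos - k_neg / n_neg) / se
    return OverlapStats(n_pos, k_pos, n_neg, k_neg, float(z), float(norm.sf(z)))


@dataclass
class VennCounts:
    """Counts of merged regions per dataset subset (<= 4 datasets)."""

    counts: dict[frozenset[str], int]

    def count(self, *names: str) -> int:
        return self.counts.get(frozenset(names), 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def venn_overlap(datasets: Mapping[str, Sequence[Region]]) -> VennCounts:
    """Subset membership of merged regions across 2-4 peak sets.

    All regions are pooled and merged (single-linkage on >= 1 bp
    overlap); each merged region is assigned the subset of datasets
    contributing at least one base to it. Counts are invariant to
    dataset input order.
    """
    if not (2 <= len(datasets) <= 4):
        raise ValueError("venn_overlap supports 2-4 datasets")
    tagged = [
        (r.contig, r.start, r.end, name)
        for name, regions in datasets.items()
        for r in regions
    ]
    tagged.sort()
    counts: dict[frozenset[str], int] = {}
    i = 0
    while i < len(tagged):
        contig, start, end, name = tagged[i]
        members = {name}
        j = i + 1
        while j < len(tagged) and tagged[j][0] == contig and tagged[j][1] < end:
            end = max(end, tagged[j][2])
            members.add(tagged[j][3])
            j += 1
        key = frozenset(members)
        counts[key] = counts.get(key, 0) + 1
        i = j
    return VennCounts(counts)


def _match_positions(seq: str, words: Iterable[str]) -> set[int]:
    """Start offsets of exact occurrences of words or their reverse
    complements within a sequence (distinct positions)."""
    positions: set[int] = set()
    for w in words:
        for probe in {w, revcomp(w)}:
            start = seq.find(probe)
            while start != -1:
                positions.add(start)
                start = seq.find(probe, start + 1)
    return positions


def gbm_count_spectrum(
    peaks: Sequence[str], library: MotifLibrary
) -> dict[int, float]:
    """Relative frequency of peaks containing 1, 2, ... GBM sites.

    Counts distinct match start positions per peak sequence and
    normalizes the histogram over peaks with at least one site (peaks
    with none are excluded, matching how per-peak site counts are
    reported for wGBM subsets).
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    counts = [len(_match_positions(seq, library.words)) for seq in peaks]
    with_site = [c for c in counts if c > 0]
    if not with_site:
        return {}
    total = len(with_site)
    spectrum: dict[int, float] = {}
    for c in with_site:
        spectrum[c] = spectrum.get(c, 0) + 1
    return {c: n / total for c, n in sorted(spectrum.items())}


def motif_positional_profile(
    peaks: Sequence[str],
    motif_words: Sequence[str],
    bin_width: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Density of motif-center offsets from the peak midpoint.

    Requires fixed-width peaks. Returns (bin_edges, density) from
    numpy's histogram; offsets are motif center minus peak midpoint.
    """
    widths = {len(p) for p in peaks}
    if len(widths) != 1:
        raise ValueError("peaks must have a single fixed width")
    (peak_width,) = widths
    mid = peak_width // 2
    offsets: list[int] = []
    for seq in peaks:
        for w in motif_words:
            wlen = len(w)
            for start in _match_positions(seq, [w]):
                offsets.append(start + wlen // 2 - mid)
    if not offsets:
        raise ValueError("no motif occurrences found in peaks")
    lo = -((mid // bin_width) + 1) * bin_width
    hi = ((peak_width - mid) // bin_width + 1) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    density, edges = np.histogram(offsets, bins=edges, density=True)
    return edges, density


@dataclass
class GeneAnnotation:
    """Per-region nearest-gene labels with signed TSS distances."""

    annotations: dict[Region, list[tuple[str, int]]]

    def genes(self, region: Region) -> list[str]:
        return [g for g, _ in self.annotations.get(region, [])]


def annotate_two_nearest_genes(
    regions: Sequence[Region],
    gene_tss: Sequence[tuple[str, str, int]],
) -> GeneAnnotation:
    """Annotate each region to the (up to) two nearest gene TSSs.

    `gene_tss` rows are (gene name, contig, TSS position). Distances
    are signed (TSS minus region midpoint) and ranked by absolute
    value, ties broken by gene name. Regions on contigs without genes
    receive an empty annotation.
    """
    by_contig: dict[str, list[tuple[str, int]]] = {}
    for gene, contig, tss in gene_tss:
        by_contig.setdefault(contig, []).append((gene, tss))
    out: dict[Region, list[tuple[str, int]]] = {}
    for region in regions:
        genes = by_contig.get(region.contig, [])
        mid = region.midpoint
        ranked = sorted(genes, key=lambda g: (abs(g[1] - mid), g[0]))[:2]
        out[region] = [(g, tss - mid) for g, tss in ranked]
    return GeneAnnotation(out)


def ztest_report_rows(
    named_stats: Mapping[str, OverlapStats],
) -> list[dict]:
    """Flatten OverlapStats into TSV-ready rows (one per track)."""
    rows = []
    for name, s in named_stats.items():
        rows.append(
            {
                "track": name,
                "k_pos": s.k_pos,
                "n_pos": s.n_pos,
                "k_neg": s.k_neg,
                "n_neg": s.n_neg,
                "p_pos": round(s.p_pos, 6),
                "p_neg": round(s.p_neg, 6),
                "z": round(s.z, 4) if np.isfinite(s.z) else "NA",
                "p_value": f"{s.p_value:.4g}" if np.isfinite(s.p_value) else "NA",
            }
        )
    return rows
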