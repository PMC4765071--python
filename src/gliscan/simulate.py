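"""Seeded generators for synthetic enhancer-prediction studies.

Everything the pipeline consumes can be generated here: an i.i.d.
genome with controlled GC, positive peak sets whose sequences carry an
implanted GLI binding motif (one site in most peaks, two in the rest)
plus a cofactor word offset from the peak midpoint, multi-dataset
studies with an exact prescribed sharing structure, and feature tracks
enriched over the true enhancers. All generators are bit-reproducible
under a fixed seed, and every implant is recorded in a truth table
that can be verified by direct genome substring inspection.

The grammar defaults mirror the statistical structure of GLI ChIP
peak sets: ~88% of motif-containing peaks carry a single site, and the
cofactor enrichment peaks around 200 bp from the peak midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import FeatureTrack, Genome, Region, write_bed, write_fasta
from .motifs import GBM_WIDTH, is_gli_like

_BASES = np.array(list("ACGT"))

#: Default GLI-like 12-mers: the 9-bp core GACCACCCA at positions 2-10
#: with varying flanks (all pass the CCxC structural filter).
DEFAULT_GBM_WORDS = (
    "AGACCACCCAAG",
    "TGACCACCCACT",
    "CGACCACCCAGA",
    "GGACCACCCATC",
)

#: Cofactor words: an E-box and a Sox-like consensus.
DEFAULT_COFACTOR_WORDS = ("CACCTGTT", "AACAATGG")


@dataclass(frozen=True)
class GrammarConfig:
    """Parameters of the synthetic enhancer grammar.

    p_single_gbm is the probability a positive peak carries exactly one
    GLI site (two otherwise); cofactor offsets are drawn from
    N(offset_mean, offset_sd) bp on a random side of the midpoint.
    """

    gbm_words: tuple[str, ...] = DEFAULT_GBM_WORDS
    cofactor_words: tuple[str, ...] = DEFAULT_COFACTOR_WORDS
    p_single_gbm: float = 0.88
    cofactor_offset_mean: float = 200.0
    cofactor_offset_sd: float = 50.0
    gbm_offset_sd: float = 75.0
    peak_width: int = 600
    gc: float = 0.42

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_single_gbm <= 1.0:
            raise ValueError("p_single_gbm must be in [0, 1]")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")
        for w in self.gbm_words:
            if len(w) != GBM_WIDTH:
                raise ValueError(f"GBM word {w!r} is not a 12-mer")
            if not is_gli_like(w):
                raise ValueError(f"GBM word {w!r} fails the GLI structural filter")


@dataclass(frozen=True)
class Implant:
    """One motif implanted into the genome, recorded for truth-keeping."""

    contig: str
    start: int
    word: str  # as written on the forward strand after implanting
    source_word: str  # the grammar word, pre-orientation
    strand: str
    kind: str  # "gbm" or "cofactor"
    peak_index: int


@dataclass
class SyntheticStudy:
    """A complete synthetic input set with ground truth."""

    genome: Genome
    peaks: dict[str, list[Region]]  # per-dataset positive peak regions
    truth_regions: list[Region]  # distinct true-enhancer regions
    implants: list[Implant]
    grammar: GrammarConfig
    tracks: dict[str, FeatureTrack] = field(default_factory=dict)

    def peak_sequences(self, dataset: str) -> list[str]:
        return [
            self.genome.fetch(r.contig, r.start, r.end)
            for r in self.peaks[dataset]
        ]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        for name, regions in self.peaks.items():
            write_bed(regions, outdir / f"peaks_{name}.bed")
        write_bed(self.truth_regions, outdir / "truth_regions.bed")
        with open(outdir / "truth_implants.tsv", "w") as fh:
            fh.write("contig\tstart\tword\tsource_word\tstrand\tkind\tpeak_index\n")
            for im in self.implants:
                fh.write(
                    f"{im.contig}\t{im.start}\t{im.word}\t{im.source_word}\t"
                    f"{im.strand}\t{im.kind}\t{im.peak_index}\n"
                )
        for name, track in self.tracks.items():
            write_bed(track.regions, outdir / f"track_{name}.bed")


def generate_genome(
    length: int, gc: float = 0.42, seed: int = 0, name: str = "chrS"
) -> Genome:
    """An i.i.d. genome: P(G) = P(C) = gc/2, P(A) = P(T) = (1-gc)/2."""
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(_BASES[rng.choice(4, size=length, p=p)])
    return Genome({name: seq})


def _revcomp_str(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _implant(
    contig_seq: list[str],
    contig: str,
    start: int,
    word: str,
    strand: str,
    kind: str,
    peak_index: int,
) -> Implant:
    written = word if strand == "+" else _revcomp_str(word)
    contig_seq[start : start + len(word)] = list(written)
    return Implant(contig, start, written, word, strand, kind, peak_index)


def _place_nonoverlapping(
    rng: np.random.Generator,
    contig_len: int,
    width: int,
    n: int,
    occupied: list[tuple[int, int]],
    max_attempts: int = 100_000,
) -> list[int]:
    starts: list[int] = []
    taken = sorted(occupied)
    for _ in range(n):
        for _attempt in range(max_attempts):
            s = int(rng.integers(0, contig_len - width + 1))
            if all(s + width <= a or s >= b for a, b in taken):
                starts.append(s)
                taken.append((s, s + width))
                taken.sort()
                break
        else:
            raise RuntimeError(
                f"could not place {n} non-overlapping peaks of width {width}"
            )
    return starts


def generate_positive_peaks(
    genome: Genome,
    grammar: GrammarConfig,
    n: int,
    seed: int = 0,
    contig: str | None = None,
    peak_index_offset: int = 0,
    _occupied: list[tuple[int, int]] | None = None,
) -> tuple[list[Region], list[Implant]]:
    """Implant n non-overlapping enhancer peaks into the genome.

    Each peak carries one GBM (with probability p_single_gbm) or two,
    placed near the peak midpoint with N(0, gbm_offset_sd) jitter, and
    one cofactor word at N(offset_mean, offset_sd) bp from the midpoint
    on a random side. All implants are on a random strand and
    overwrite genome bases in place (coordinates stay stable). Returns
    the peak regions and the implant truth records.
    """
    rng = np.random.default_rng(seed)
    if contig is None:
        contig = max(genome.contigs, key=lambda c: genome.length(c))
    seq = list(genome.contigs[contig])
    clen = len(seq)
    W = grammar.peak_width
    if clen < W * (2 * n):
        raise RuntimeError("genome too short for requested peak count")
    starts = _place_nonoverlapping(rng, clen, W, n, _occupied or [])

    regions: list[Region] = []
    implants: list[Implant] = []
    half = W // 2
    for j, s in enumerate(starts):
        idx = peak_index_offset + j
        regions.append(Region(contig, s, s + W, label=f"peak_{idx}"))
        n_gbm = 1 if rng.random() < grammar.p_single_gbm else 2
        placed: list[tuple[int, int]] = []
        # GBM(s) near the midpoint
        for _g in range(n_gbm):
            for _attempt in range(1000):
                off = int(np.clip(rng.normal(0, grammar.gbm_offset_sd),
                                  -half + GBM_WIDTH, half - 2 * GBM_WIDTH))
                g_start = s + half + off
                if all(g_start + GBM_WIDTH <= a or g_start >= b for a, b in placed):
                    break
            else:
                raise RuntimeError("could not place second GBM without overlap")
            word = grammar.gbm_words[rng.integers(len(grammar.gbm_words))]
            strand = "+" if rng.random() < 0.5 else "-"
            implants.append(
                _implant(seq, contig, g_start, word, strand, "gbm", idx)
            )
            placed.append((g_start, g_start + GBM_WIDTH))
        # one cofactor word offset from the midpoint
        if grammar.cofactor_words:
            word = grammar.cofactor_words[rng.integers(len(grammar.cofactor_words))]
            side = 1 if rng.random() < 0.5 else -1
            for _attempt in range(1000):
                off = side * int(
                    np.clip(rng.normal(grammar.cofactor_offset_mean,
                                       grammar.cofactor_offset_sd),
                            0, half - len(word) - 1)
                )
                c_start = s + half + off
                if all(c_start + len(word) <= a or c_start >= b for a, b in placed):
                    break
            else:
                c_start = None
            if c_start is not None:
                strand = "+" if rng.random() < 0.5 else "-"
                implants.append(
                    _implant(seq, contig, c_start, word, strand, "cofactor", idx)
                )
    genome.contigs[contig] = "".join(seq)
    return regions, implants


def generate_multidataset_study(
    grammar: GrammarConfig,
    sharing_design: dict[frozenset[str] | tuple[str, ...], int],
    seed: int = 0,
    genome: Genome | None = None,
    genome_length: int | None = None,
) -> SyntheticStudy:
    """Build a multi-dataset study with an exact sharing structure.

    `sharing_design` maps dataset subsets to region counts: a region
    "shared" by a subset is implanted once and listed in each of those
    datasets' peak lists, so a Venn overlap of the output reproduces
    the design exactly (regions are mutually non-overlapping by
    construction).
    """
    design = {frozenset(k): v for k, v in sharing_design.items()}
    names = sorted({n for subset in design for n in subset})
    if len(names) > 4:
        raise ValueError("at most 4 dataset names supported")
    total = sum(design.values())
    if genome is None:
        if genome_length is None:
            genome_length = max(200_000, total * grammar.peak_width * 4)
        genome = generate_genome(genome_length, grammar.gc, seed=seed)

    peaks: dict[str, list[Region]] = {n: [] for n in names}
    truth_regions: list[Region] = []
    implants: list[Implant] = []
    occupied: list[tuple[int, int]] = []
    rng_offset = 0
    for subset in sorted(design, key=lambda s: tuple(sorted(s))):
        count = design[subset]
        if count == 0:
            continue
        regions, imps = generate_positive_peaks(
            genome,
            grammar,
            count,
            seed=seed + 7919 * (rng_offset + 1),
            peak_index_offset=len(truth_regions),
            _occupied=occupied,
        )
        rng_offset += 1
        occupied.extend((r.start, r.end) for r in regions)
        truth_regions.extend(regions)
        implants.extend(imps)
        for name in subset:
            peaks[name].extend(regions)
    for name in peaks:
        peaks[name].sort(key=lambda r: (r.contig, r.start))
    truth_regions.sort(key=lambda r: (r.contig, r.start))
    return SyntheticStudy(genome, peaks, truth_regions, implants, grammar)


def generate_feature_track(
    truth_regions: list[Region],
    p_enh: float,
    p_bg: float,
    n_bg: int,
    seed: int = 0,
    genome: Genome | None = None,
    background_regions: list[Region] | None = None,
    name: str = "track",
) -> FeatureTrack:
    """A feature track enriched over true enhancers.

    Each truth region is covered by a track interval with probability
    p_enh; each supplied background region with probability p_bg; and
    n_bg decoy intervals are scattered at random over the genome (when
    one is given). Covering intervals are jittered so they overlap
    their region without coinciding with it.
    """
    if not 0.0 <= p_enh <= 1.0 or not 0.0 <= p_bg <= 1.0:
        raise ValueError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    regions: list[Region] = []

    def _cover(r: Region, tag: str) -> None:
        w = max(100, r.width // 2)
        jitter = int(rng.integers(-w // 2, w // 2 + 1))
        start = max(0, r.midpoint + jitter - w // 2)
        regions.append(Region(r.contig, start, start + w, label=tag))

    for r in truth_regions:
        if rng.random() < p_enh:
            _cover(r, "enh")
    for r in background_regions or []:
        if rng.random() < p_bg:
            _cover(r, "bg")
    if genome is not None and n_bg > 0:
        contig = max(genome.contigs, key=lambda c: genome.length(c))
        clen = genome.length(contig)
        for _ in range(n_bg):
            w = 300
            s = int(rng.integers(0, clen - w))
            regions.append(Region(contig, s, s + w, label="decoy"))
    return FeatureTrack(name, regions)


def implant_decoy_gbm_sites(
    genome: Genome,
    grammar: GrammarConfig,
    occupied: list[tuple[int, int]],
    n: int,
    seed: int = 0,
    contig: str | None = None,
) -> list[Implant]:
    """Drop bare GBM words (no cofactor, no grammar) into free genome
    positions, emulating the excess of genomic motif occurrences that
    are not enhancers. Each decoy keeps a clear margin so its scoring
    window does not touch an enhancer peak."""
    rng = np.random.default_rng(seed)
    if contig is None:
        contig = max(genome.contigs, key=lambda c: genome.length(c))
    seq = list(genome.contigs[contig])
    clen = len(seq)
    margin = grammar.peak_width // 2
    taken = list(occupied)
    implants: list[Implant] = []
    for _ in range(n):
        for _attempt in range(100_000):
            s = int(rng.integers(margin, clen - margin - GBM_WIDTH))
            lo, hi = s - margin, s + GBM_WIDTH + margin
            if all(hi <= a or lo >= b for a, b in taken):
                taken.append((lo, hi))
                break
        else:
            raise RuntimeError("could not place decoy GBM sites")
        word = grammar.gbm_words[rng.integers(len(grammar.gbm_words))]
        strand = "+" if rng.random() < 0.5 else "-"
        implants.append(
            _implant(seq, contig, s, word, strand, "decoy_gbm", -1)
        )
    genome.contigs[contig] = "".join(seq)
    return implants


def default_study(
    n_pos: int = 1000,
    genome_length: int = 4_000_000,
    grammar: GrammarConfig | None = None,
    seed: int = 0,
    n_decoy_gbm: int = 0,
) -> SyntheticStudy:
    """The default single-dataset study used throughout the analysis:
    one synthetic chromosome carrying n_pos implanted enhancer peaks.
    Setting n_decoy_gbm additionally scatters that many bare GBM sites
    outside the peaks, so a genome scan sees non-enhancer motif
    occurrences too (used by the full pipeline's scan/evaluate stages)."""
    grammar = grammar or GrammarConfig()
    genome = generate_genome(genome_length, grammar.gc, seed=seed)
    regions, implants = generate_positive_peaks(
        genome, grammar, n_pos, seed=seed + 1
    )
    decoys = implant_decoy_gbm_sites(
        genome, grammar, [(r.start, r.end) for r in regions],
        n_decoy_gbm, seed=seed + 2,
    )
    regions.sort(key=lambda r: (r.contig, r.start))
    return SyntheticStudy(
        genome, {"SYN": regions}, list(regions), implants + decoys, grammar
    )
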