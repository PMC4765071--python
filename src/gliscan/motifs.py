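"""GLI binding-motif (GBM) 12-mer library construction and use.

The library is built by an iterative match-remove-rediscover loop over
ChIP peak sequence sets: sequences matching the current library are
removed, exact words enriched in the remainder (one-sided Fisher test,
Bonferroni-corrected) are screened by a structural GLI-likeness filter,
and accepted words join the library until no further word is accepted.
Words are stored in canonical orientation (lexicographic minimum of the
word and its reverse complement) and tiered by how many datasets contain
them: HC (all), MC (two or more, not all), LC (one).

The 12-mer frame places the 9-bp GLI core GACCACCCA at positions 2-10,
so the invariant CCxC block sits at positions 4-7 and the core's 6th
position (the C whose mutation abolishes GLI binding) is position 7 of
the 12-mer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom

from .core import Genome, Region, revcomp

GBM_WIDTH = 12
#: 0-based index, within a GLI-oriented 12-mer, of the invariant core C
#: targeted by the GLI-knockout (GKO) point mutation (C -> G).
GKO_POSITION = 6

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


def canonical_word(word: str) -> str:
    """Lexicographic minimum of a word and its reverse complement."""
    rc = revcomp(word)
    return word if word <= rc else rc


def is_gli_like(word: str) -> bool:
    """Structural filter for GLI binding motifs.

    True iff, in either orientation, the word carries the invariant
    CCxC block at positions 4-7 (1-based): C at positions 4, 5 and 7.
    This stands in for a motif-comparison step ("does the discovered
    word resemble a GBM?") in the library loop.
    """
    if len(word) != GBM_WIDTH:
        raise ValueError(f"GBM words are {GBM_WIDTH}-mers, got {len(word)}")

    def _ok(w: str) -> bool:
        return w[3] == "C" and w[4] == "C" and w[6] == "C"

    return _ok(word) or _ok(revcomp(word))


def gli_orientation(word: str) -> str:
    """Return the orientation of `word` carrying the CCxC block.

    Falls back to the word as given when neither orientation matches
    the filter (possible for user-supplied libraries).
    """

    def _ok(w: str) -> bool:
        return len(w) == GBM_WIDTH and w[3] == "C" and w[4] == "C" and w[6] == "C"

    if _ok(word):
        return word
    rc = revcomp(word)
    if _ok(rc):
        return rc
    return word


def classify_confidence(presence: set[str] | frozenset[str], n_datasets: int = 4) -> str:
    """Tier a motif by dataset support: HC = all, MC = 2+, LC = 1."""
    k = len(presence)
    if k == 0:
        raise ValueError("empty presence set")
    if k > n_datasets:
        raise ValueError(f"presence {k} exceeds n_datasets {n_datasets}")
    if k == n_datasets:
        return "HC"
    if k >= 2:
        return "MC"
    return "LC"


@dataclass(frozen=True)
class GBM:
    word: str  # canonical orientation
    presence: frozenset[str]
    tier: str

    def __post_init__(self) -> None:
        if len(self.word) != GBM_WIDTH:
            raise ValueError("GBM word must be a 12-mer")
        if self.word != canonical_word(self.word):
            raise ValueError("GBM word must be stored in canonical orientation")


_TIER_RANK = {"HC": 3, "MC": 2, "LC": 1}


@dataclass
class MotifLibrary:
    """A set of canonical GBM 12-mers with dataset presence and tier."""

    gbms: dict[str, GBM] = field(default_factory=dict)
    source_datasets: list[str] = field(default_factory=list)

    def add(self, word: str, presence: set[str], n_datasets: int | None = None) -> None:
        n = n_datasets if n_datasets is not None else max(len(self.source_datasets), 1)
        cw = canonical_word(word)
        if cw in self.gbms:
            presence = set(self.gbms[cw].presence) | set(presence)
        tier = classify_confidence(presence, n)
        self.gbms[cw] = GBM(cw, frozenset(presence), tier)

    @property
    def words(self) -> list[str]:
        return sorted(self.gbms)

    def __len__(self) -> int:
        return len(self.gbms)

    def __contains__(self, word: str) -> bool:
        return canonical_word(word) in self.gbms

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("word\ttier\tdatasets\n")
            for w in self.words:
                g = self.gbms[w]
                fh.write(f"{g.word}\t{g.tier}\t{','.join(sorted(g.presence))}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MotifLibrary":
        lib = cls()
        datasets: set[str] = set()
        rows = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("word"):
                raise ValueError("library TSV must start with a 'word' header line")
            for line in fh:
                word, tier, ds = line.rstrip("\n").split("\t")
                pres = set(ds.split(",")) if ds else set()
                datasets |= pres
                rows.append((word, pres))
        lib.source_datasets = sorted(datasets)
        for word, pres in rows:
            lib.add(word, pres, n_datasets=len(lib.source_datasets))
        return lib


def _sequence_contains(seq: str, word: str) -> bool:
    """Strand-pooled presence: the word or its reverse complement occurs."""
    return word in seq or revcomp(word) in seq


def discover_enriched_words(
    positives: list[str],
    negatives: list[str],
    word_length: int = GBM_WIDTH,
    alpha: float = 0.05,
) -> list[tuple[str, float]]:
    """Exact-word enrichment discovery.

    Counts, once per sequence and pooling reverse-complement
    occurrences, how many positive and negative sequences contain each
    canonical word of the given length present in the positives. Words
    passing a one-sided Fisher exact test (hypergeometric tail) at
    level `alpha` after Bonferroni correction over the tested words are
    returned ranked by p-value (ties broken alphabetically).
    """
    if word_length < 3:
        raise ValueError("word_length must be >= 3")
    if not positives or not negatives:
        raise ValueError("both sequence sets must be non-empty")
    if word_length > min(len(s) for s in positives):
        raise ValueError("word_length exceeds shortest positive sequence")

    # presence sets, per canonical word, counted once per sequence
    def _presence_counts(seqs: list[str]) -> dict[str, int]:
        counts: dict[str, int] = {}
        for seq in seqs:
            seen: set[str] = set()
            for i in range(len(seq) - word_length + 1):
                w = seq[i : i + word_length]
                if "N" in w:
                    continue
                seen.add(canonical_word(w))
            for w in seen:
                counts[w] = counts.get(w, 0) + 1
        return counts

    pos_counts = _presence_counts(positives)
    neg_counts = _presence_counts(negatives)
    n_pos, n_neg = len(positives), len(negatives)
    n_tested = len(pos_counts)
    if n_tested == 0:
        return []

    results: list[tuple[str, float]] = []
    for w, a in pos_counts.items():
        b = neg_counts.get(w, 0)
        # one-sided Fisher: P(X >= a) with X ~ Hypergeom(N, K=a+b, n=n_pos)
        p = float(hypergeom.sf(a - 1, n_pos + n_neg, a + b, n_pos))
        if p * n_tested <= alpha:
            results.append((w, p))
    results.sort(key=lambda t: (t[1], t[0]))
    return results


def iterative_library_build(
    datasets: dict[str, list[str]],
    matcher_seed: list[str] | None = None,
    *,
    negatives: dict[str, list[str]] | None = None,
    word_length: int = GBM_WIDTH,
    alpha: float = 0.05,
    max_iterations: int = 25,
    rng_seed: int = 0,
) -> MotifLibrary:
    """Build a GBM library by the iterative match-remove-rediscover loop.

    Per dataset: sequences containing any word of the current library
    are removed; exact-word enrichment is run on the remainder against
    the dataset's negative set (letter-shuffled copies of the dataset
    sequences when none is supplied); GLI-like words are accepted; the
    loop repeats until no word is accepted or the iteration cap is hit.
    Presence bookkeeping and tiers are then computed over the union.
    """
    if not datasets:
        raise ValueError("at least one dataset required")
    seed_words = {canonical_word(w) for w in (matcher_seed or [])}

    if negatives is None:
        rng = np.random.default_rng(rng_seed)
        negatives = {}
        for name, seqs in datasets.items():
            shuffled = []
            for s in seqs:
                arr = np.array(list(s))
                rng.shuffle(arr)
                shuffled.append("".join(arr))
            negatives[name] = shuffled

    accepted: set[str] = set()
    for name, seqs in datasets.items():
        current = set(seed_words)
        remaining = list(seqs)
        for _ in range(max_iterations):
            remaining = [
                s
                for s in remaining
                if not any(_sequence_contains(s, w) for w in current)
            ]
            if not remaining:
                break
            found = discover_enriched_words(
                remaining, negatives[name], word_length, alpha
            )
            new = {
                w for w, _ in found if is_gli_like(w) and w not in current
            }
            if not new:
                break
            current |= new
        else:
            raise RuntimeError(
                f"library loop for dataset {name!r} did not converge "
                f"within {max_iterations} iterations"
            )
        accepted |= current

    lib = MotifLibrary(source_datasets=sorted(datasets))
    n = len(datasets)
    for w in sorted(accepted):
        presence = {
            name
            for name, seqs in datasets.items()
            if any(_sequence_contains(s, w) for s in seqs)
        }
        if presence:
            lib.add(w, presence, n_datasets=n)
    return lib


@dataclass
class PWM:
    """Position weight matrix: per-position base frequencies.

    freqs has shape (width, 4) with columns in A, C, G, T order; each
    row sums to 1.
    """

    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 4 or self.freqs.shape[0] < 1:
            raise ValueError("freqs must have shape (width, 4), width >= 1")
        if not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")

    @property
    def width(self) -> int:
        return self.freqs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.freqs.argmax(axis=1))


def build_pwm(words: list[str], pseudocount: float = 0.01) -> PWM:
    """Frequency matrix from equal-length words with additive smoothing.

    f(i, b) = (count(i, b) + pseudocount) / (n + 4 * pseudocount)
    """
    if not words:
        raise ValueError("at least one word required")
    width = len(words[0])
    if any(len(w) != width for w in words):
        raise ValueError("words must have equal length")
    counts = np.zeros((width, 4))
    for w in words:
        for i, b in enumerate(w):
            counts[i, _BASE_IDX[b]] += 1
    freqs = (counts + pseudocount) / (len(words) + 4 * pseudocount)
    return PWM(freqs)


def information_weights(pwm: PWM) -> np.ndarray:
    """Per-position information content I(i) = sum_b f(i,b) ln(4 f(i,b))."""
    f = pwm.freqs
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(f > 0, f * np.log(4.0 * f), 0.0)
    return term.sum(axis=1)


def matrix_similarity(pwm: PWM, seq: str) -> float:
    """Information-weighted matrix similarity score, scaled to [0, 1].

    MSS = (Current - Min) / (Max - Min), where Current sums the
    information-weighted frequency of the observed base at each
    position and Max/Min use the per-position maximum/minimum
    frequency. The consensus scores 1, the per-position worst sequence
    scores 0. A cutoff around 0.81 reproduces the conventional
    "81% overall matrix similarity" site-calling threshold.
    """
    if len(seq) != pwm.width:
        raise ValueError("sequence length must equal PWM width")
    if "N" in seq:
        raise ValueError("sequence must not contain N")
    info = information_weights(pwm)
    f = pwm.freqs
    current = sum(info[i] * f[i, _BASE_IDX[b]] for i, b in enumerate(seq))
    max_s = float((info * f.max(axis=1)).sum())
    # the floor of the scale is the worst *realizable* base per column:
    # zero-frequency bases are excluded (irrelevant once pseudocounts
    # are applied, which is the intended use)
    min_pos = np.where(f > 0, f, np.inf).min(axis=1)
    min_s = float((info * min_pos).sum())
    if math.isclose(max_s, min_s):
        return 1.0
    return (current - min_s) / (max_s - min_s)


@dataclass(frozen=True)
class GBMMatch:
    """An exact genomic occurrence of a library word (12 bp)."""

    region: Region
    strand: str
    word: str  # canonical library word
    tier: str


def scan_genome_for_gbm(genome: Genome, library: MotifLibrary) -> list[GBMMatch]:
    """All exact occurrences of library words on both strands.

    Each 12-bp site is reported once: a window matching a canonical
    word in forward orientation is '+'; a window whose reverse
    complement matches is '-'. Overlapping occurrences of different
    words are all reported. Output is sorted by (contig, start).
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    fwd = set(library.words)
    rev = {revcomp(w): w for w in library.words}
    matches: list[GBMMatch] = []
    w = GBM_WIDTH
    for contig in sorted(genome.contigs):
        seq = genome.contigs[contig]
        for i in range(len(seq) - w + 1):
            window = seq[i : i + w]
            if window in fwd:
                word, strand = window, "+"
            elif window in rev:
                word, strand = rev[window], "-"
            else:
                continue
            matches.append(
                GBMMatch(
                    region=Region(contig, i, i + w, strand=strand, label=word),
                    strand=strand,
                    word=word,
                    tier=library.gbms[word].tier,
                )
            )
    return matches


def matches_to_regions(matches: list[GBMMatch]) -> list[Region]:
    """BED6-ready regions: name = word, score = tier rank (HC=3..LC=1)."""
    return [
        Region(
            m.region.contig,
            m.region.start,
            m.region.end,
            strand=m.strand,
            label=m.word,
            score=_TIER_RANK[m.tier],
        )
        for m in matches
    ]


def merged_match_count(matches: list[GBMMatch]) -> int:
    """Number of distinct sites after merging overlapping occurrences."""
    count = 0
    prev_contig, prev_end = None, -1
    for m in sorted(matches, key=lambda m: (m.region.contig, m.region.start)):
        if m.region.contig != prev_contig or m.region.start >= prev_end:
            count += 1
            prev_contig, prev_end = m.region.contig, m.region.end
        else:
            prev_end = max(prev_end, m.region.end)
    return count


def gko_mutate(seq: str, matches: list[GBMMatch]) -> str:
    """In silico GLI-site knockout: mutate the invariant core C to G.

    `matches` carry coordinates relative to `seq` (region.start is an
    offset into the sequence). For each match, the C at position 7 of
    the GLI-oriented 12-mer is replaced by G; when the site lies on the
    opposite strand the complementary substitution (G -> C) is applied
    at the mirrored coordinate. Raises if the targeted base is not the
    expected one, which signals a frame inconsistency.
    """
    out = list(seq)
    for m in matches:
        s = m.region.start
        if s < 0 or m.region.end > len(seq):
            raise ValueError("match outside sequence")
        oriented = gli_orientation(m.word)
        site = seq[s : s + GBM_WIDTH]
        if site == oriented:
            pos, want, repl = s + GKO_POSITION, "C", "G"
        elif site == revcomp(oriented):
            pos = s + (GBM_WIDTH - 1 - GKO_POSITION)
            want, repl = "G", "C"
        else:
            raise ValueError(
                f"sequence at offset {s} ({site}) does not match word {m.word}"
            )
        if out[pos] != want:
            raise ValueError(
                f"GKO frame inconsistency: expected {want} at offset {pos}, "
                f"found {out[pos]}"
            )
        out[pos] = repl
    return "".join(out)
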