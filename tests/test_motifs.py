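import numpy as np
import pytest
from scipy.stats import hypergeom

from gliscan import motifs
from gliscan.core import Genome, revcomp
from gliscan.motifs import GBMMatch
from gliscan.core import Region

from conftest import random_seq

GLI_WORD = "AGACCACCCAAA"


class TestLibraryCanonicalization:
    def test_word_and_revcomp_collapse_to_one_entry(self):
        lib = motifs.MotifLibrary(source_datasets=["A"])
        lib.add(GLI_WORD, {"A"}, n_datasets=1)
        lib.add(revcomp(GLI_WORD), {"A"}, n_datasets=1)
        assert len(lib) == 1
        assert GLI_WORD in lib and revcomp(GLI_WORD) in lib

    def test_presence_union_on_re_add(self):
        lib = motifs.MotifLibrary(source_datasets=["A", "B"])
        lib.add(GLI_WORD, {"A"}, n_datasets=2)
        lib.add(revcomp(GLI_WORD), {"B"}, n_datasets=2)
        (gbm,) = lib.gbms.values()
        assert gbm.presence == {"A", "B"} and gbm.tier == "HC"

    def test_tsv_round_trip(self, tmp_path):
        lib = motifs.MotifLibrary(source_datasets=["A", "B", "C", "D"])
        lib.add(GLI_WORD, {"A", "B", "C", "D"}, n_datasets=4)
        lib.add("TGACCACCCACT", {"A", "C"}, n_datasets=4)
        lib.add("CGACCACCCAGA", {"D"}, n_datasets=4)
        lib.to_tsv(tmp_path / "lib.tsv")
        back = motifs.MotifLibrary.from_tsv(tmp_path / "lib.tsv")
        assert {w: (g.tier, g.presence) for w, g in back.gbms.items()} == {
            w: (g.tier, g.presence) for w, g in lib.gbms.items()
        }


class TestIsGliLike:
    @pytest.mark.parametrize(
        "word,expected",
        [
            ("AGACCACCCAAA", True),
            ("TTTGGGTGGTCT", True),  # reverse complement of a GLI-like word
            ("AAAAAAAAAAAA", False),
        ],
    )
    def test_examples(self, word, expected):
        assert motifs.is_gli_like(word) is expected

    def test_wrong_length_is_error(self):
        with pytest.raises(ValueError):
            motifs.is_gli_like("ACGT")


class TestClassifyConfidence:
    @pytest.mark.parametrize(
        "presence,tier",
        [
            ({"LD", "CD", "MB", "NP"}, "HC"),
            ({"LD", "CD", "MB"}, "MC"),
            ({"LD", "NP"}, "MC"),
            ({"NP"}, "LC"),
        ],
    )
    def test_tiers(self, presence, tier):
        assert motifs.classify_confidence(presence, 4) == tier

    def test_empty_presence_is_error(self):
        with pytest.raises(ValueError):
            motifs.classify_confidence(set())


class TestBuildPwm:
    def test_hand_counted_frequencies(self):
        pwm = motifs.build_pwm(["AG", "TG"], pseudocount=0)
        np.testing.assert_allclose(pwm.freqs[0], [0.5, 0, 0, 0.5])
        np.testing.assert_allclose(pwm.freqs[1], [0, 0, 1.0, 0])

    def test_single_word_indicator_columns(self):
        pwm = motifs.build_pwm(["ACGT"], pseudocount=0)
        assert pwm.consensus == "ACGT"
        assert (pwm.freqs.max(axis=1) == 1.0).all()

    def test_pseudocount_smoothing(self):
        pwm = motifs.build_pwm(["A"], pseudocount=1)
        np.testing.assert_allclose(pwm.freqs[0], [0.4, 0.2, 0.2, 0.2])

    def test_mixed_lengths_is_error(self):
        with pytest.raises(ValueError):
            motifs.build_pwm(["AG", "AGG"])


class TestMatrixSimilarity:
    def test_consensus_scores_one(self):
        pwm = motifs.build_pwm([GLI_WORD, "TGACCACCCACT", "AGACCACCCAAG"])
        assert motifs.matrix_similarity(pwm, pwm.consensus) == pytest.approx(1.0)

    def test_worst_sequence_scores_zero(self):
        pwm = motifs.build_pwm([GLI_WORD, "TGACCACCCACT", "AGACCACCCAAG"])
        worst = "".join("ACGT"[i] for i in pwm.freqs.argmin(axis=1))
        assert motifs.matrix_similarity(pwm, worst) == pytest.approx(0.0)

    def test_hand_evaluated_minimum_column(self):
        # column 2 is uninformative for Max vs Min; column 1's C is the
        # minimum-frequency base, so "CG" sits at the bottom of the scale
        pwm = motifs.PWM(np.array([[0.7, 0.1, 0.1, 0.1], [0, 0, 1.0, 0]]))
        assert motifs.matrix_similarity(pwm, "CG") == pytest.approx(0.0)

    def test_errors(self):
        pwm = motifs.build_pwm(["ACGT"])
        with pytest.raises(ValueError):
            motifs.matrix_similarity(pwm, "ACG")
        with pytest.raises(ValueError):
            motifs.matrix_similarity(pwm, "ACGN")


def _implant(rng, length, words, gc=0.42):
    seq = random_seq(rng, length, gc)
    for w in words:
        pos = int(rng.integers(0, length - len(w)))
        seq = seq[:pos] + w + seq[pos + len(w):]
    return seq


class TestDiscoverEnrichedWords:
    def test_implanted_word_ranked_first(self):
        rng = np.random.default_rng(3)
        word = "GACCACCCAAGT"
        pos = [_implant(rng, 60, [word]) for _ in range(50)]
        neg = [random_seq(rng, 60) for _ in range(50)]
        found = motifs.discover_enriched_words(pos, neg, 12, alpha=0.05)
        assert found and found[0][0] == motifs.canonical_word(word)
        # p-value matches an independent hypergeometric computation
        expected_p = float(hypergeom.sf(50 - 1, 100, 50, 50))
        assert found[0][1] == pytest.approx(expected_p)

    def test_identical_sets_find_nothing(self):
        rng = np.random.default_rng(4)
        seqs = [random_seq(rng, 60) for _ in range(30)]
        assert motifs.discover_enriched_words(seqs, list(seqs), 12) == []

    def test_single_occurrence_fails_threshold(self):
        # present in 1 of 50 positives, 0 of 50 negatives: one-sided
        # Fisher p = 0.5, far above alpha even before correction
        rng = np.random.default_rng(5)
        word = "GACCACCCAAGT"
        pos = [random_seq(rng, 60) for _ in range(49)] + [_implant(rng, 60, [word])]
        neg = [random_seq(rng, 60) for _ in range(50)]
        found = motifs.discover_enriched_words(pos, neg, 12, alpha=0.05)
        assert motifs.canonical_word(word) not in {w for w, _ in found}

    def test_short_word_length_is_error(self):
        with pytest.raises(ValueError):
            motifs.discover_enriched_words(["ACGT"], ["ACGT"], 2)


class TestIterativeLibraryBuild:
    def test_seed_fixed_point(self):
        rng = np.random.default_rng(6)
        seqs = [_implant(rng, 80, [GLI_WORD]) for _ in range(30)]
        lib = motifs.iterative_library_build({"D1": seqs}, [GLI_WORD])
        assert lib.words == [motifs.canonical_word(GLI_WORD)]
        assert lib.gbms[lib.words[0]].presence == {"D1"}

    def test_two_disjoint_words_recovered(self):
        rng = np.random.default_rng(7)
        w1, w2 = "AGACCACCCAAG", "TGACCTCCCACT"
        seqs = [_implant(rng, 80, [w1]) for _ in range(40)]
        seqs += [_implant(rng, 80, [w2]) for _ in range(40)]
        lib = motifs.iterative_library_build({"D1": seqs})
        assert motifs.canonical_word(w1) in lib.gbms
        assert motifs.canonical_word(w2) in lib.gbms

    def test_no_gli_like_word_returns_present_seeds_only(self):
        rng = np.random.default_rng(8)
        seqs = [random_seq(rng, 80) for _ in range(30)]
        lib = motifs.iterative_library_build({"D1": seqs}, [GLI_WORD])
        assert len(lib) == 0  # seed not present in any sequence

    def test_presence_across_datasets_sets_tier(self):
        rng = np.random.default_rng(9)
        datasets = {
            name: [_implant(rng, 80, [GLI_WORD]) for _ in range(30)]
            for name in ("LD", "CD", "MB", "NP")
        }
        lib = motifs.iterative_library_build(datasets, [GLI_WORD])
        gbm = lib.gbms[motifs.canonical_word(GLI_WORD)]
        assert gbm.tier == "HC" and gbm.presence == {"LD", "CD", "MB", "NP"}


def _brute_force_scan(genome: Genome, library: motifs.MotifLibrary):
    """Naive O(n*m) substring search; forward orientation wins when a
    site matches a word and its reverse complement."""
    found = {}
    for contig, seq in genome.contigs.items():
        for word in library.words:
            for probe, strand in ((word, "+"), (revcomp(word), "-")):
                start = seq.find(probe)
                while start != -1:
                    key = (contig, start)
                    if key not in found or strand == "+":
                        found[key] = (contig, start, word, strand)
                    start = seq.find(probe, start + 1)
    return sorted(found.values())


class TestScanGenome:
    def _library(self):
        lib = motifs.MotifLibrary(source_datasets=["A"])
        lib.add(GLI_WORD, {"A"}, n_datasets=1)
        return lib

    def test_forward_implant(self):
        rng = np.random.default_rng(10)
        seq = random_seq(rng, 1000)
        seq = seq[:500] + GLI_WORD + seq[512:]
        matches = [
            m
            for m in motifs.scan_genome_for_gbm(Genome({"c": seq}), self._library())
            if m.region.start == 500
        ]
        assert len(matches) == 1 and matches[0].strand == "+"
        assert (matches[0].region.start, matches[0].region.end) == (500, 512)

    def test_reverse_implant(self):
        rng = np.random.default_rng(11)
        seq = random_seq(rng, 1000)
        seq = seq[:500] + revcomp(GLI_WORD) + seq[512:]
        matches = [
            m
            for m in motifs.scan_genome_for_gbm(Genome({"c": seq}), self._library())
            if m.region.start == 500
        ]
        assert len(matches) == 1 and matches[0].strand == "-"

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        genome = Genome({"c1": random_seq(rng, 20_000, gc=0.6),
                         "c2": random_seq(rng, 20_000, gc=0.6)})
        lib = motifs.MotifLibrary(source_datasets=["A"])
        for _ in range(20):
            w = random_seq(rng, 12, gc=0.7)
            lib.add(w, {"A"}, n_datasets=1)
        got = [
            (m.region.contig, m.region.start, m.word, m.strand)
            for m in motifs.scan_genome_for_gbm(genome, lib)
        ]
        assert sorted(got) == _brute_force_scan(genome, lib)

    def test_empty_library_is_error(self):
        with pytest.raises(ValueError):
            motifs.scan_genome_for_gbm(Genome({"c": "ACGT" * 10}), motifs.MotifLibrary())


class TestGkoMutate:
    def _match(self, word, start, strand, seq):
        return GBMMatch(
            region=Region("w", start, start + 12, strand=strand, label=word),
            strand=strand,
            word=motifs.canonical_word(word),
            tier="LC",
        )

    def test_core_c_to_g(self):
        seq = GLI_WORD
        out = motifs.gko_mutate(seq, [self._match(GLI_WORD, 0, "+", seq)])
        assert out == "AGACCAGCCAAA"

    def test_minus_strand_mirrored_substitution(self):
        seq = revcomp(GLI_WORD)
        out = motifs.gko_mutate(seq, [self._match(GLI_WORD, 0, "-", seq)])
        assert out == revcomp("AGACCAGCCAAA")

    def test_two_disjoint_matches_both_mutated(self):
        seq = GLI_WORD + "TTTT" + GLI_WORD
        matches = [
            self._match(GLI_WORD, 0, "+", seq),
            self._match(GLI_WORD, 16, "+", seq),
        ]
        assert motifs.gko_mutate(seq, matches) == "AGACCAGCCAAATTTTAGACCAGCCAAA"

    def test_rescan_after_gko_removes_matches(self, default_library):
        rng = np.random.default_rng(13)
        from gliscan import simulate

        for _ in range(20):
            seq = random_seq(rng, 300)
            w = simulate.DEFAULT_GBM_WORDS[rng.integers(4)]
            pos = int(rng.integers(0, 288))
            seq = seq[:pos] + w + seq[pos + 12:]
            g = Genome({"w": seq})
            matches = motifs.scan_genome_for_gbm(g, default_library)
            mutated = motifs.gko_mutate(seq, matches)
            assert motifs.scan_genome_for_gbm(Genome({"w": mutated}), default_library) == []

    def test_frame_inconsistency_is_error(self):
        seq = "AGACCAACCAAA"  # core C already absent
        with pytest.raises(ValueError):
            motifs.gko_mutate(seq, [self._match(GLI_WORD, 0, "+", seq)])


def test_merged_match_count_collapses_overlaps():
    r = lambda s: GBMMatch(Region("c", s, s + 12), "+", GLI_WORD, "LC")
    assert motifs.merged_match_count([r(0), r(5), r(30)]) == 2
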