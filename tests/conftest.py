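import numpy as np
import pytest

from gliscan import motifs, scan, simulate

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.42) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])


@pytest.fixture(scope="session")
def default_library() -> motifs.MotifLibrary:
    """Library holding the default synthetic grammar's GBM words."""
    lib = motifs.MotifLibrary(source_datasets=["SYN"])
    for w in simulate.DEFAULT_GBM_WORDS:
        lib.add(w, {"SYN"}, n_datasets=1)
    return lib


@pytest.fixture(scope="session")
def small_study() -> simulate.SyntheticStudy:
    """200 implanted enhancer peaks on a 600 kb synthetic chromosome."""
    return simulate.default_study(n_pos=200, genome_length=600_000, seed=11)


@pytest.fixture(scope="session")
def small_background(small_study):
    return scan.sample_gc_matched_background(
        small_study.genome, small_study.truth_regions, seed=12
    )


@pytest.fixture(scope="session")
def full_study() -> simulate.SyntheticStudy:
    """The default-scale study: 1000 peaks on a 4 Mb chromosome."""
    return simulate.default_study(n_pos=1000, genome_length=4_000_000, seed=11)


@pytest.fixture(scope="session")
def full_background(full_study):
    return scan.sample_gc_matched_background(
        full_study.genome, full_study.truth_regions, seed=12
    )


@pytest.fixture(scope="session")
def full_model(full_study, full_background):
    from gliscan import svm

    return svm.train(
        full_study.peak_sequences("SYN"), full_background.sequences, seed=13
    )


@pytest.fixture(scope="session")
def small_model(small_study, small_background):
    """Classifier trained on the 200-peak study vs GC-matched background."""
    from gliscan import svm

    return svm.train(
        small_study.peak_sequences("SYN"), small_background.sequences, seed=13
    )
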