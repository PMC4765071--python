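"""k-mer spectrum SVM sequence classifier.

Features are raw occurrence counts of canonical k-mers (default k = 8;
a k-mer and its reverse complement share one feature, so feature
vectors and scores are strand-invariant). A linear soft-margin SVM is
fitted on positive vs negative sequence sets; the learned per-k-mer
weights decompose a sequence's score into positional contributions,
which is what makes weight profiles along a sequence meaningful.
Posterior probabilities come from Platt scaling fitted on the training
scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.optimize import minimize
from scipy.special import expit
from sklearn import metrics
from sklearn.svm import SVC

from .core import revcomp

_BASES = "ACGT"


def canonical(kmer: str) -> str | None:
    """Canonical form of a k-mer; None ("skip") if it contains N."""
    if "N" in kmer:
        return None
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def count_canonical_kmers(k: int) -> int:
    """Number of reverse-complement-collapsed k-mers for even k.

    (4^k - 4^(k/2)) / 2 + 4^(k/2): non-palindromic pairs collapse,
    reverse-complement palindromes (4^(k/2) of them) do not.
    """
    if k < 2 or k % 2 != 0:
        raise ValueError("only even k >= 2 supported")
    half = 4 ** (k // 2)
    return (4**k - half) // 2 + half


class KmerIndex:
    """Bijective map from canonical k-mer to feature column."""

    def __init__(self, k: int = 8):
        if k < 2 or k % 2 != 0:
            raise ValueError("only even k >= 2 supported")
        self.k = k
        kmers = sorted(
            {canonical("".join(p)) for p in product(_BASES, repeat=k)}
        )
        self.kmer_to_col: dict[str, int] = {w: i for i, w in enumerate(kmers)}
        self.col_to_kmer: list[str] = kmers

    def __len__(self) -> int:
        return len(self.col_to_kmer)


def feature_vector(seq: str, index: KmerIndex) -> dict[int, int]:
    """Sparse canonical k-mer counts {column: count}; N windows skipped."""
    k = index.k
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k = {k}")
    counts: dict[int, int] = {}
    lookup = index.kmer_to_col
    for i in range(len(seq) - k + 1):
        w = canonical(seq[i : i + k])
        if w is None:
            continue
        col = lookup[w]
        counts[col] = counts.get(col, 0) + 1
    return counts


def feature_matrix(seqs: list[str], index: KmerIndex) -> sparse.csr_matrix:
    """Stack feature vectors into a CSR matrix (n_seqs x n_features)."""
    data, indices, indptr = [], [], [0]
    for seq in seqs:
        fv = feature_vector(seq, index)
        for col in sorted(fv):
            indices.append(col)
            data.append(fv[col])
        indptr.append(len(indices))
    return sparse.csr_matrix(
        (np.array(data, dtype=float), indices, indptr),
        shape=(len(seqs), len(index)),
    )


def _platt_fit(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Platt's sigmoid fit: P(y=1|s) = 1 / (1 + exp(A s + B)).

    Targets are smoothed to (N+ + 1)/(N+ + 2) and 1/(N- + 2); the
    negative log-likelihood is minimized over (A, B). A comes out
    negative when higher scores mean more positive.
    """
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    t = np.where(pos, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(ab: np.ndarray) -> float:
        a, b = ab
        p = expit(-(a * scores + b))
        eps = 1e-12
        return -float(np.sum(t * np.log(p + eps) + (1 - t) * np.log(1 - p + eps)))

    res = minimize(nll, x0=np.array([-1.0, 0.0]), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    return float(res.x[0]), float(res.x[1])


@dataclass
class KmerModel:
    """Trained k-mer spectrum classifier.

    score(seq) = bias + sum over positions of weight(canonical k-mer);
    the sign of the score is the predicted class, and the posterior is
    1 / (1 + exp(A s + B)) from Platt calibration.
    """

    index: KmerIndex
    weights: np.ndarray
    bias: float
    platt_a: float | None = None
    platt_b: float | None = None
    metadata: dict = field(default_factory=dict)

    def weight_of(self, kmer: str) -> float:
        c = canonical(kmer)
        if c is None:
            return 0.0
        return float(self.weights[self.index.kmer_to_col[c]])

    def top_kmers(self, n: int = 10) -> list[tuple[str, float]]:
        order = np.argsort(self.weights)[::-1][:n]
        return [(self.index.col_to_kmer[i], float(self.weights[i])) for i in order]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#k={self.index.k}\tbias={self.bias!r}\t"
                     f"A={self.platt_a!r}\tB={self.platt_b!r}\t"
                     f"seed={self.metadata.get('seed')}\n")
            fh.write("kmer\tweight\n")
            for i, w in enumerate(self.index.col_to_kmer):
                fh.write(f"{w}\t{float(self.weights[i])!r}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KmerModel":
        with open(path) as fh:
            header = fh.readline().lstrip("#").rstrip("\n").split("\t")
            kv = dict(item.split("=", 1) for item in header)
            fh.readline()  # column names
            weights_by_kmer = {}
            for line in fh:
                w, val = line.rstrip("\n").split("\t")
                weights_by_kmer[w] = float(val)
        index = KmerIndex(int(kv["k"]))
        weights = np.array([weights_by_kmer[w] for w in index.col_to_kmer])
        a = None if kv["A"] == "None" else float(kv["A"])
        b = None if kv["B"] == "None" else float(kv["B"])
        return cls(index, weights, float(kv["bias"]), a, b,
                   metadata={"seed": kv.get("seed")})


def train(
    positives: list[str],
    negatives: list[str],
    k: int = 8,
    C: float = 1.0,
    seed: int = 0,
    index: KmerIndex | None = None,
) -> KmerModel:
    """Fit a linear soft-margin SVM on canonical k-mer count features.

    Requires at least 20 sequences per class. Platt calibration (A, B)
    is fitted on the training scores. Deterministic given the seed.
    """
    if len(positives) < 20 or len(negatives) < 20:
        raise ValueError("need >= 20 sequences per class")
    if index is None:
        index = KmerIndex(k)
    X = feature_matrix(list(positives) + list(negatives), index)
    y = np.array([1] * len(positives) + [-1] * len(negatives))
    clf = SVC(kernel="linear", C=C, random_state=seed)
    clf.fit(X, y)
    weights = np.asarray(clf.coef_.todense()).ravel()
    bias = float(clf.intercept_[0])
    scores = X @ weights + bias
    a, b = _platt_fit(scores, y)
    return KmerModel(
        index, weights, bias, a, b,
        metadata={"C": C, "seed": seed, "n_pos": len(positives),
                  "n_neg": len(negatives)},
    )


def score(model: KmerModel, seq: str) -> float:
    """Sequence score: bias plus the positional sum of k-mer weights."""
    k = model.index.k
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k = {k}")
    fv = feature_vector(seq, model.index)
    s = model.bias
    for col, count in fv.items():
        s += model.weights[col] * count
    return float(s)


def posterior(model: KmerModel, s: float) -> float:
    """Platt posterior probability of the positive class at score s."""
    if model.platt_a is None or model.platt_b is None:
        raise ValueError("model is not calibrated")
    return float(expit(-(model.platt_a * s + model.platt_b)))


@dataclass
class EvalCurves:
    """ROC and precision-recall curves over repeated holdout splits."""

    roc_points: list[np.ndarray]  # per repeat: array of (FPR, TPR) rows
    prc_points: list[np.ndarray]  # per repeat: array of (TPR, PPV) rows
    roc_aucs: list[float]
    prc_aucs: list[float]

    @property
    def mean_roc_auc(self) -> float:
        return float(np.mean(self.roc_aucs))

    @property
    def mean_prc_auc(self) -> float:
        return float(np.mean(self.prc_aucs))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("repeat\tcurve\tx\ty\n")
            for rep, pts in enumerate(self.roc_points):
                for x, y in pts:
                    fh.write(f"{rep}\tROC\t{x:.6g}\t{y:.6g}\n")
            for rep, pts in enumerate(self.prc_points):
                for x, y in pts:
                    fh.write(f"{rep}\tPRC\t{x:.6g}\t{y:.6g}\n")


def roc_auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Trapezoidal ROC AUC; tied score pairs receive half credit."""
    y = np.concatenate([np.ones(len(scores_pos)), np.zeros(len(scores_neg))])
    s = np.concatenate([scores_pos, scores_neg])
    return float(metrics.roc_auc_score(y, s))


def prc_auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Precision-recall AUC by right-step interpolation (average precision)."""
    y = np.concatenate([np.ones(len(scores_pos)), np.zeros(len(scores_neg))])
    s = np.concatenate([scores_pos, scores_neg])
    return float(metrics.average_precision_score(y, s))


def evaluate_repeated_holdout(
    positives: list[str],
    negatives: list[str],
    n_repeats: int = 5,
    train_frac: float = 0.8,
    seed: int = 0,
    k: int = 8,
    C: float = 1.0,
    index: KmerIndex | None = None,
) -> EvalCurves:
    """Stratified repeated 80/20 train/test evaluation.

    Per repeat: random stratified split, train on the training
    fraction, score the held-out fraction, accumulate ROC and PRC
    curves and their AUCs. Deterministic given the seed.
    """
    if len(positives) < 10 or len(negatives) < 10:
        raise ValueError("need >= 10 sequences per class")
    if index is None:
        index = KmerIndex(k)
    rng = np.random.default_rng(seed)
    roc_pts, prc_pts, roc_as, prc_as = [], [], [], []
    for rep in range(n_repeats):
        tr_p, te_p = _split(positives, train_frac, rng)
        tr_n, te_n = _split(negatives, train_frac, rng)
        model = train(tr_p, tr_n, k=k, C=C, seed=int(rng.integers(2**31)),
                      index=index)
        sp = np.array([score(model, s) for s in te_p])
        sn = np.array([score(model, s) for s in te_n])
        y = np.concatenate([np.ones(len(sp)), np.zeros(len(sn))])
        s = np.concatenate([sp, sn])
        fpr, tpr, _ = metrics.roc_curve(y, s)
        prec, rec, _ = metrics.precision_recall_curve(y, s)
        roc_pts.append(np.column_stack([fpr, tpr]))
        prc_pts.append(np.column_stack([rec, prec]))
        roc_as.append(roc_auc(sp, sn))
        prc_as.append(prc_auc(sp, sn))
    return EvalCurves(roc_pts, prc_pts, roc_as, prc_as)


def _split(seqs: list[str], frac: float, rng: np.random.Generator):
    idx = rng.permutation(len(seqs))
    n_train = int(round(frac * len(seqs)))
    return [seqs[i] for i in idx[:n_train]], [seqs[i] for i in idx[n_train:]]
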