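"""Solenoid vs globular discrimination from codeword histograms.

A linear-kernel SVM on L1-normalized histograms separates tandem-repeat
(solenoid) from globular domains.  Evaluation follows a 2-fold
cross-validation protocol in which the codebook itself is rebuilt from
each training fold so no information about held-out images leaks into the
vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.svm import SVC

from .bovw import (
    Codebook,
    CodewordHistogram,
    Feature,
    build_codebook,
    build_dictionary,
    encode,
)

__all__ = [
    "ConfusionCounts",
    "BenchmarkMetrics",
    "SvmModel",
    "train_linear_svm",
    "evaluate",
    "metrics",
    "twofold_cv",
]

POSITIVE = "solenoid"
NEGATIVE = "globular"


@dataclass
class ConfusionCounts:
    """Binary confusion counts with solenoid as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class BenchmarkMetrics:
    """Per-class and overall accuracies in percent, one decimal."""

    solenoid_acc: float
    globular_acc: float
    overall_acc: float


@dataclass
class SvmModel:
    """Trained linear SVM plus the histogram length it expects."""

    clf: SVC
    k: int
    codebook_digest: str = ""


def _l1_normalize(H: np.ndarray) -> np.ndarray:
    sums = H.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        raise ValueError("cannot normalize an all-zero histogram")
    return H / sums


def _matrix(histograms: Sequence[CodewordHistogram]) -> np.ndarray:
    return np.array([h.counts for h in histograms], dtype=float)


def train_linear_svm(
    histograms: Sequence[CodewordHistogram],
    labels: Sequence[str],
    c_param: float = 1.0,
    seed: int = 0,
    codebook_digest: str = "",
) -> SvmModel:
    """Fit a linear-kernel SVM on L1-normalized count histograms.

    L1 normalization removes the domain-size confound (larger images have
    more features); C defaults to 1 with no class weighting.
    """
    labels = list(labels)
    if set(labels) - {POSITIVE, NEGATIVE}:
        raise ValueError(f"labels must be {POSITIVE!r} or {NEGATIVE!r}")
    if len(set(labels)) < 2:
        raise ValueError("training data must contain both classes")
    X = _l1_normalize(_matrix(histograms))
    y = np.array([1 if l == POSITIVE else 0 for l in labels])
    clf = SVC(kernel="linear", C=c_param, random_state=seed)
    clf.fit(X, y)
    return SvmModel(clf=clf, k=X.shape[1], codebook_digest=codebook_digest)


def evaluate(
    model: SvmModel,
    histograms: Sequence[CodewordHistogram],
    labels: Sequence[str],
) -> ConfusionCounts:
    """Confusion counts of the model on labeled histograms."""
    X = _matrix(histograms)
    if X.shape[1] != model.k:
        raise ValueError(
            f"histogram length {X.shape[1]} does not match model ({model.k})"
        )
    pred = model.clf.predict(_l1_normalize(X))
    y = np.array([1 if l == POSITIVE else 0 for l in labels])
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (y == 1))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
    )


def metrics(c: ConfusionCounts) -> BenchmarkMetrics:
    """Per-class and overall accuracy in percent, rounded to one decimal.

    Computed in exact rational arithmetic before the final rounding.
    """
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("both classes must be present")
    sol = Fraction(100 * c.tp, c.tp + c.fn)
    glob = Fraction(100 * c.tn, c.tn + c.fp)
    overall = Fraction(100 * (c.tp + c.tn), c.total)
    return BenchmarkMetrics(
        solenoid_acc=round(float(sol), 1),
        globular_acc=round(float(glob), 1),
        overall_acc=round(float(overall), 1),
    )


def _stratified_halves(
    labels: Sequence[str], rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Random 50/50 split preserving class balance as far as parity allows."""
    labels = np.asarray(labels)
    g1: List[int] = []
    g2: List[int] = []
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        half = len(idx) // 2
        # odd class sizes: the extra item goes to fold 1
        g1.extend(idx[: half + (len(idx) % 2)])
        g2.extend(idx[half + (len(idx) % 2):])
    return np.sort(np.array(g1)), np.sort(np.array(g2))


def twofold_cv(
    feature_sets: Sequence[Sequence[Feature]],
    labels: Sequence[str],
    vocab_size: int,
    seed: int = 0,
    c_param: float = 1.0,
) -> ConfusionCounts:
    """2-fold cross-validation with fold-specific codebooks.

    The corpus is split stratified 50/50; for each fold a fresh codebook is
    clustered from the training images' features only, both halves are
    encoded against it, the SVM is trained on the training half and scored
    on the held-out half.  Counts are summed over the two folds, so every
    image is tested exactly once.
    """
    labels = list(labels)
    for cls in (POSITIVE, NEGATIVE):
        if labels.count(cls) < 2:
            raise ValueError(f"need at least 2 items of class {cls!r}")
    rng = np.random.default_rng(seed)
    g1, g2 = _stratified_halves(labels, rng)

    total = ConfusionCounts(0, 0, 0, 0)
    for train_idx, test_idx in ((g1, g2), (g2, g1)):
        dictionary = build_dictionary([feature_sets[i] for i in train_idx])
        k = min(vocab_size, dictionary.m)
        cb = build_codebook(dictionary, k=k, seed=seed)
        train_h = [encode(feature_sets[i], cb) for i in train_idx]
        test_h = [encode(feature_sets[i], cb) for i in test_idx]
        model = train_linear_svm(
            train_h,
            [labels[i] for i in train_idx],
            c_param=c_param,
            seed=seed,
            codebook_digest=cb.digest,
        )
        total = total + evaluate(model, test_h, [labels[i] for i in test_idx])
    return total
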