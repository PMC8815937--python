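"""Quantitative statistics over codeword histograms.

Covers the descriptive side of the pipeline: cosine nearest-neighbor
retrieval scored against the four-level structural hierarchy, per-codeword
relative frequency (how many images contain a codeword), the spatial
relation between codeword frequency and distance from the matrix diagonal,
the unique-word ratio that flags tandem-repeat texture, Pearson
correlations, and a 2-D PCA embedding of the histogram matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .bovw import CodewordHistogram, Feature
from .structure_io import SCOP_LEVELS, ScopLabel, match_level

__all__ = [
    "CodewordStats",
    "UwrRecord",
    "cosine_distance",
    "nearest_neighbor_accuracy",
    "relative_frequency",
    "diagonal_distance",
    "codeword_diagonal_profile",
    "unique_word_ratio",
    "pearson_r",
    "pca_embed",
]

SQRT2 = sqrt(2.0)
MAX_DIAG_DIST = SQRT2 / 2.0  # farthest corner of the unit square from y = x


@dataclass
class CodewordStats:
    """Per-codeword corpus statistics.

    rel_freq
        Fraction of images in which the codeword occurs (presence-based).
    mean_diag_dist / sd_diag_dist
        Mean and SD of the normalized diagonal distance of all features
        assigned to the codeword, NaN where the codeword is never used.
    rank_by_freq
        Permutation ordering codewords from most to least frequent
        (rank 1 = most frequent; ties broken by codeword index).
    """

    rel_freq: np.ndarray
    mean_diag_dist: np.ndarray
    sd_diag_dist: np.ndarray
    rank_by_freq: np.ndarray
    n_assigned: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "codeword": np.arange(len(self.rel_freq)),
                "rel_freq": self.rel_freq,
                "mean_diag_dist": self.mean_diag_dist,
                "sd_diag_dist": self.sd_diag_dist,
                "rank": self.rank_by_freq,
                "n_assigned": self.n_assigned,
            }
        )


@dataclass
class UwrRecord:
    """Unique-word ratio of one image: distinct codewords / total features."""

    image_id: str
    n_features: int
    n_unique: int
    ratio: float


def cosine_distance(h1: CodewordHistogram, h2: CodewordHistogram) -> float:
    """1 - cos(angle) between two count histograms; in [0, 1] for counts.

    Scale-invariant: proportional histograms are at distance 0.
    """
    a = np.asarray(h1.counts, dtype=float)
    b = np.asarray(h2.counts, dtype=float)
    if a.shape != b.shape:
        raise ValueError("histograms must share a codebook (equal length)")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine distance undefined for a zero histogram")
    return float(np.clip(1.0 - (a @ b) / (na * nb), 0.0, 1.0))


def nearest_neighbor_accuracy(
    histograms: Sequence[CodewordHistogram],
    labels: Sequence[ScopLabel],
    level: str,
) -> float:
    """Leave-one-out nearest-neighbor accuracy at one hierarchy level.

    Each image's nearest other image under cosine distance is its
    prediction; the prediction is correct iff the two labels agree at
    ``level``.  Distance ties are broken toward the smaller image id.
    """
    if level not in SCOP_LEVELS:
        raise ValueError(f"unknown hierarchy level: {level!r}")
    if len(histograms) < 2:
        raise ValueError("need at least 2 items")
    if len(labels) != len(histograms) or any(l is None for l in labels):
        raise ValueError("every item must be labeled")

    H = np.array([h.counts for h in histograms], dtype=float)
    norms = np.linalg.norm(H, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero histogram in corpus")
    Hn = H / norms[:, None]
    D = np.clip(1.0 - Hn @ Hn.T, 0.0, None)
    ids = [h.image_id for h in histograms]

    n_correct = 0
    for i in range(len(ids)):
        best_j = None
        for j in range(len(ids)):
            if j == i:
                continue
            if (
                best_j is None
                or D[i, j] < D[i, best_j]
                or (D[i, j] == D[i, best_j] and ids[j] < ids[best_j])
            ):
                best_j = j
        if match_level(labels[i], labels[best_j], level):
            n_correct += 1
    return n_correct / len(ids)


def relative_frequency(histograms: Sequence[CodewordHistogram]) -> np.ndarray:
    """Per-codeword fraction of images that contain the codeword."""
    if not histograms:
        raise ValueError("empty corpus")
    H = np.array([h.counts for h in histograms])
    return (H > 0).mean(axis=0)


def diagonal_distance(x: float, y: float, n: int) -> float:
    """Normalized distance from pixel (x, y) to the matrix main diagonal.

    Coordinates are scaled by (n - 1) so the image corners map to the unit
    square's corners; the distance from (x̂, ŷ) to the line ŷ = x̂ is
    |x̂ - ŷ| / √2, bounded by √2/2 ≈ 0.7 at the far corners.
    """
    if n < 2:
        raise ValueError("image side must be at least 2")
    if not (0 <= x <= n - 1 and 0 <= y <= n - 1):
        raise ValueError("pixel coordinates out of range")
    xn = x / (n - 1)
    yn = y / (n - 1)
    return abs(xn - yn) / SQRT2


def codeword_diagonal_profile(
    feature_sets: Sequence[Sequence[Feature]],
    histograms: Sequence[CodewordHistogram],
    image_sizes: Sequence[int],
) -> CodewordStats:
    """Relate codeword frequency to feature position in the matrix.

    For every feature (across the corpus) the normalized distance of its
    keypoint to the main diagonal is computed; per codeword, the mean and
    SD over its assigned features summarize where in the matrix that
    codeword lives.  Codewords never assigned are flagged NaN.
    """
    if len(feature_sets) != len(histograms) or len(histograms) != len(image_sizes):
        raise ValueError("feature sets, histograms and sizes must align")
    k = histograms[0].k
    sums = np.zeros(k)
    sqsums = np.zeros(k)
    counts = np.zeros(k, dtype=int)
    for feats, hist, n in zip(feature_sets, histograms, image_sizes):
        if hist.assignments is None:
            raise ValueError(
                f"histogram {hist.image_id!r} lacks retained assignments"
            )
        if len(hist.assignments) != len(feats):
            raise ValueError("assignments do not match features")
        for f, a in zip(feats, hist.assignments):
            d = diagonal_distance(f.x, f.y, n)
            sums[a] += d
            sqsums[a] += d * d
            counts[a] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = np.where(
            counts > 0, sqsums / np.maximum(counts, 1) - mean**2, np.nan
        )
    sd = np.sqrt(np.clip(var, 0.0, None))

    freq = relative_frequency(histograms)
    # rank 1 = most frequent; stable tie-break on codeword index
    order = np.lexsort((np.arange(k), -freq))
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(1, k + 1)
    return CodewordStats(
        rel_freq=freq,
        mean_diag_dist=mean,
        sd_diag_dist=sd,
        rank_by_freq=rank,
        n_assigned=counts,
    )


def unique_word_ratio(h: CodewordHistogram) -> UwrRecord:
    """Distinct codewords divided by total features of one image.

    500 features spread over 400 distinct codewords give 0.8; a ratio near
    1 means nearly every feature is unique, a low ratio means many
    features repeat the same few codewords -- the signature of tandem
    structural repeats in the distance matrix.
    """
    if h.n_features <= 0:
        raise ValueError("unique-word ratio undefined for an empty histogram")
    n_unique = h.n_unique
    return UwrRecord(
        image_id=h.image_id,
        n_features=h.n_features,
        n_unique=n_unique,
        ratio=n_unique / h.n_features,
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def pca_embed(
    histograms: Sequence[CodewordHistogram], n_components: int = 2
) -> Tuple[np.ndarray, np.ndarray]:
    """Mean-centered PCA scores of the image-by-codeword count matrix.

    Returns (scores, explained_variance); variances are non-increasing.
    """
    H = np.array([h.counts for h in histograms], dtype=float)
    if len(H) < n_components:
        raise ValueError("fewer images than requested components")
    if H.shape[1] < n_components:
        raise ValueError("fewer codewords than requested components")
    p = PCA(n_components=n_components, svd_solver="full")
    scores = p.fit_transform(H)
    return scores, p.explained_variance_
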