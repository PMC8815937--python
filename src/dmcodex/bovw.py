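"""Bag-of-Visual-Words over distance-matrix images.

Four stages: extract local features from each image, pool every raw
descriptor into a visual dictionary, cluster the dictionary with k-means
into a codebook of K centroids ("codewords"), and encode each image as a
length-K histogram by assigning every feature to its nearest codeword
(hard assignment).  The histogram is the protein's fixed-length feature
vector regardless of domain size.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus

from .distmat import GrayImage
from .kaze import DESCRIPTOR_SIZE, DetectorParams, detect_and_describe

__all__ = [
    "Feature",
    "VisualDictionary",
    "Codebook",
    "CodewordHistogram",
    "extract_features",
    "build_dictionary",
    "build_codebook",
    "encode",
    "write_codebook",
    "read_codebook",
    "write_histograms",
    "read_histograms",
    "write_features",
    "read_features",
]


@dataclass
class Feature:
    """One detected keypoint: image position, scale and 64-d descriptor."""

    x: float
    y: float
    scale: float
    descriptor: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        self.descriptor = np.asarray(self.descriptor, dtype=float)
        if self.descriptor.shape != (DESCRIPTOR_SIZE,):
            raise ValueError(
                f"descriptor must have length {DESCRIPTOR_SIZE}"
            )
        if not np.all(np.isfinite(self.descriptor)):
            raise ValueError("descriptor must be finite")


@dataclass
class VisualDictionary:
    """All raw descriptors of a corpus, row-stacked, with provenance."""

    descriptors: np.ndarray  # (M, 64)
    provenance: List[Tuple[str, int]]  # (image_id, keypoint index)

    def __post_init__(self) -> None:
        if len(self.provenance) != len(self.descriptors):
            raise ValueError("provenance must have one entry per descriptor")

    @property
    def m(self) -> int:
        return len(self.descriptors)


@dataclass
class Codebook:
    """K cluster centroids in descriptor space; each row is a codeword."""

    centroids: np.ndarray  # (K, 64)
    k: int
    train_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape != (self.k, DESCRIPTOR_SIZE):
            raise ValueError("centroids must be (k, 64)")

    @property
    def digest(self) -> str:
        return hashlib.sha256(
            np.ascontiguousarray(self.centroids).tobytes()
        ).hexdigest()[:16]


@dataclass
class CodewordHistogram:
    """Per-image codeword counts; sums to the image's feature count.

    ``assignments`` retains the codeword index of each feature (in input
    order) so spatial statistics can be computed downstream.
    """

    counts: np.ndarray  # (K,) nonnegative ints
    image_id: str
    n_features: int
    assignments: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if int(self.counts.sum()) != self.n_features:
            raise ValueError("histogram mass must equal the feature count")

    @property
    def k(self) -> int:
        return len(self.counts)

    @property
    def n_unique(self) -> int:
        return int(np.count_nonzero(self.counts))


def extract_features(
    img: GrayImage, params: DetectorParams = DetectorParams()
) -> List[Feature]:
    """Detect keypoints on a grayscale image; may legitimately be empty.

    Images smaller than the detector minimum, or with no intensity
    variation, yield an empty list rather than an error.
    """
    kps, descs = detect_and_describe(img.pixels, params)
    return [
        Feature(
            x=float(kp[0]),
            y=float(kp[1]),
            scale=float(kp[2]),
            descriptor=desc,
            image_id=img.id,
        )
        for kp, desc in zip(kps, descs)
    ]


def build_dictionary(
    feature_sets: Iterable[Sequence[Feature]],
) -> VisualDictionary:
    """Pool per-image features into one descriptor matrix with provenance."""
    rows = []
    provenance = []
    for feats in feature_sets:
        for idx, f in enumerate(feats):
            rows.append(f.descriptor)
            provenance.append((f.image_id, idx))
    if not rows:
        raise ValueError("no features in the corpus: cannot build a dictionary")
    return VisualDictionary(
        descriptors=np.array(rows, dtype=float), provenance=provenance
    )


def _lloyd(
    X: np.ndarray,
    centroids: np.ndarray,
    max_iter: int,
    rtol: float,
) -> Tuple[np.ndarray, np.ndarray, List[float]]:
    """Lloyd iterations with farthest-point reseeding of empty clusters.

    Returns final centroids, assignments and the inertia trace (one entry
    per iteration, non-increasing).
    """
    trace: List[float] = []
    labels = np.zeros(len(X), dtype=int)
    for _ in range(max_iter):
        d2 = cdist(X, centroids, metric="sqeuclidean")
        labels = np.argmin(d2, axis=1)
        inertia = float(d2[np.arange(len(X)), labels].sum())
        new = centroids.copy()
        for j in range(len(centroids)):
            members = X[labels == j]
            if len(members):
                new[j] = members.mean(axis=0)
            else:
                # re-seed an empty cluster at the point farthest from its centroid
                far = int(np.argmax(d2[np.arange(len(X)), labels]))
                new[j] = X[far]
        trace.append(inertia)
        if len(trace) >= 2 and trace[-2] - trace[-1] <= rtol * max(trace[-2], 1e-300):
            centroids = new
            break
        centroids = new
    d2 = cdist(X, centroids, metric="sqeuclidean")
    labels = np.argmin(d2, axis=1)
    return centroids, labels, trace


def build_codebook(
    dictionary: VisualDictionary,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
    rtol: float = 1e-4,
    detector_params: Optional[DetectorParams] = None,
) -> Codebook:
    """Cluster the dictionary with seeded k-means (k-means++ init).

    A single restart with a fixed seed keeps the codebook bit-reproducible;
    the inertia trace is recorded in ``train_meta`` and is non-increasing
    by construction of the Lloyd iteration.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > dictionary.m:
        raise ValueError(
            f"k={k} exceeds the number of dictionary features M={dictionary.m}"
        )
    X = dictionary.descriptors
    init, _ = kmeans_plusplus(X, n_clusters=k, random_state=seed)
    centroids, _, trace = _lloyd(X, init, max_iter=max_iter, rtol=rtol)
    meta = {
        "seed": seed,
        "n_iter": len(trace),
        "inertia": trace[-1] if trace else 0.0,
        "inertia_trace": trace,
        "m_features": dictionary.m,
    }
    if detector_params is not None:
        meta["detector_params"] = detector_params.to_dict()
    return Codebook(centroids=centroids, k=k, train_meta=meta)


def encode(
    features: Sequence[Feature], codebook: Codebook, image_id: Optional[str] = None
) -> CodewordHistogram:
    """Hard-assign each feature to its nearest codeword and count.

    Ties in the nearest-centroid search go to the lower codeword index.
    An empty feature list encodes to the all-zero histogram.
    """
    if codebook.k < 1:
        raise ValueError("codebook is empty")
    if image_id is None:
        image_id = features[0].image_id if features else ""
    if not features:
        return CodewordHistogram(
            counts=np.zeros(codebook.k, dtype=int),
            image_id=image_id,
            n_features=0,
            assignments=np.empty(0, dtype=int),
        )
    X = np.array([f.descriptor for f in features])
    d2 = cdist(X, codebook.centroids, metric="sqeuclidean")
    assignments = np.argmin(d2, axis=1)  # argmin takes the lowest index on ties
    counts = np.bincount(assignments, minlength=codebook.k)
    return CodewordHistogram(
        counts=counts,
        image_id=image_id,
        n_features=len(features),
        assignments=assignments,
    )


# ---------------------------------------------------------------------------
# On-disk formats: TSV tables with JSON sidecars
# ---------------------------------------------------------------------------


def write_codebook(cb: Codebook, path) -> None:
    path = Path(path)
    np.savetxt(path, cb.centroids, delimiter="\t", fmt="%.10g")
    meta = {"k": cb.k, "digest": cb.digest, **cb.train_meta}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=1, sort_keys=True)
    )


def read_codebook(path) -> Codebook:
    path = Path(path)
    centroids = np.loadtxt(path, delimiter="\t", ndmin=2)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        meta.pop("k", None)
        meta.pop("digest", None)
    return Codebook(centroids=centroids, k=len(centroids), train_meta=meta)


def write_histograms(hists: Sequence[CodewordHistogram], path, codebook_digest: str) -> None:
    path = Path(path)
    k = hists[0].k if hists else 0
    df = pd.DataFrame(
        [
            {"image_id": h.image_id, "n_features": h.n_features,
             **{f"w{i}": c for i, c in enumerate(h.counts)}}
            for h in hists
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"k": k, "codebook_digest": codebook_digest}, indent=1)
    )


def read_histograms(path, expected_digest: Optional[str] = None) -> List[CodewordHistogram]:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists() and expected_digest is not None:
        meta = json.loads(sidecar.read_text())
        if meta.get("codebook_digest") != expected_digest:
            raise ValueError(
                f"{path}: histograms were computed against codebook "
                f"{meta.get('codebook_digest')}, expected {expected_digest}"
            )
    df = pd.read_csv(path, sep="\t")
    wcols = [c for c in df.columns if c.startswith("w")]
    return [
        CodewordHistogram(
            counts=row[wcols].to_numpy(dtype=int),
            image_id=str(row["image_id"]),
            n_features=int(row["n_features"]),
        )
        for _, row in df.iterrows()
    ]


def write_features(feature_sets: Sequence[Sequence[Feature]], path) -> None:
    path = Path(path)
    rows = []
    for feats in feature_sets:
        for f in feats:
            rows.append(
                {"image_id": f.image_id, "x": f.x, "y": f.y, "scale": f.scale,
                 **{f"d{i}": v for i, v in enumerate(f.descriptor)}}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_features(path) -> List[List[Feature]]:
    df = pd.read_csv(Path(path), sep="\t")
    dcols = [f"d{i}" for i in range(DESCRIPTOR_SIZE)]
    out: List[List[Feature]] = []
    for image_id, grp in df.groupby("image_id", sort=False):
        out.append(
            [
                Feature(
                    x=float(r["x"]), y=float(r["y"]), scale=float(r["scale"]),
                    descriptor=r[dcols].to_numpy(dtype=float),
                    image_id=str(image_id),
                )
                for _, r in grp.iterrows()
            ]
        )
    return out
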