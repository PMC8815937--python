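"""Cα distance matrices and their grayscale-image rendering.

The pairwise Cα distance matrix is a rotation/translation-invariant
encoding of a 3-D fold.  Rendered as an image, short-range contacts are
bright (the diagonal is pure white) and the longest contact in the domain
is black; local structure, repeats and long-range contacts become texture
that an image feature detector can pick up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DistanceMatrix",
    "GrayImage",
    "distance_matrix",
    "to_gray_image",
    "write_gray_png",
    "read_gray_png",
]


@dataclass
class DistanceMatrix:
    """Symmetric N×N matrix of pairwise Cα distances in Å."""

    values: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(v < 0) or np.any(np.diag(v) != 0):
            raise ValueError("distances must be nonnegative with zero diagonal")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class GrayImage:
    """Square grayscale image with pixel values in [0, 1].

    Row index = residue i (y), column index = residue j (x), origin at the
    top-left, 0-based.  White (1.0) marks short-range contacts, black (0.0)
    the longest contact of the matrix it came from.
    """

    pixels: np.ndarray
    id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        p = self.pixels
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("image must be square")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("pixel values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.pixels.shape[0]


def distance_matrix(trace) -> DistanceMatrix:
    """Pairwise Euclidean distances between all Cα atoms of a trace."""
    coords = np.asarray(trace.coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("need at least 2 residues")
    return DistanceMatrix(values=squareform(pdist(coords)), id=trace.id)


def to_gray_image(
    dm: DistanceMatrix, max_distance: Optional[float] = None
) -> GrayImage:
    """Map a distance matrix to a [0, 1] grayscale image.

    ``pixel = 1 - D/maxD`` so that the zero-distance diagonal is white and
    the maximal distance maps to black.  By default the matrix's own
    maximum is used (per-matrix normalization, full dynamic range); pass
    ``max_distance`` to use a fixed cap instead (distances beyond the cap
    are clamped to black).
    """
    d = dm.values
    if max_distance is None:
        mode = "per_matrix"
        dmax = float(d.max())
        if dmax <= 0:
            raise ValueError("all points identical: maximum distance is 0")
    else:
        mode = "fixed_cap"
        dmax = float(max_distance)
        if dmax <= 0:
            raise ValueError("max_distance must be positive")
    pixels = np.clip(1.0 - d / dmax, 0.0, 1.0)
    np.fill_diagonal(pixels, 1.0)
    return GrayImage(
        pixels=pixels,
        id=dm.id,
        meta={
            "n_residues": dm.n,
            "normalization": {"mode": mode, "max_distance_A": dmax},
        },
    )


def write_gray_png(img: GrayImage, path) -> None:
    """Write an 8-bit single-channel PNG plus a JSON metadata sidecar."""
    path = Path(path)
    data = np.round(img.pixels * 255.0).astype(np.uint8)
    Image.fromarray(data, mode="L").save(path, format="PNG")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {"id": img.id, **img.meta}
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_gray_png(path) -> GrayImage:
    """Read an 8-bit grayscale PNG (and its sidecar, if present)."""
    path = Path(path)
    with Image.open(path) as im:
        if im.mode != "L":
            im = im.convert("L")
        data = np.asarray(im, dtype=float)
    if data.ndim != 2 or data.shape[0] != data.shape[1]:
        raise ValueError(f"{path}: expected a square grayscale image")
    meta: dict = {}
    img_id = path.stem
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        img_id = meta.pop("id", img_id)
    return GrayImage(pixels=data / 255.0, id=img_id, meta=meta)
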