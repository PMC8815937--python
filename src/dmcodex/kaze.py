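"""KAZE-style multiscale feature detection in nonlinear scale space.

The detector builds a scale space by Perona-Malik nonlinear diffusion,
which smooths noise while preserving edges -- the property that makes
KAZE-family features well suited to the sharp band/block texture of
distance-matrix images.  Keypoints are scale-normalized determinant-of-
Hessian extrema over space and scale; each keypoint is described by an
upright M-SURF vector of 64 first-order gradient statistics sampled from
the diffused level nearest its scale.

Distance-matrix images have a canonical orientation (residue index along
both axes), so descriptors are not rotation-normalized.

Everything is plain deterministic numpy/scipy: the same image and
parameters always yield the same keypoints and descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Tuple

import numpy as np
from scipy import ndimage

__all__ = ["DetectorParams", "detect_and_describe"]

DESCRIPTOR_SIZE = 64

# Explicit-scheme diffusion step; 2-D stability bound is 0.25.
_DT = 0.2


@dataclass(frozen=True)
class DetectorParams:
    """Tunable settings of the nonlinear-diffusion detector.

    threshold
        Minimum scale-normalized determinant-of-Hessian response.
    n_octaves, n_sublevels
        Geometry of the scale ladder: sigmas base_sigma * 2**(o + s/S).
    base_sigma
        Presmoothing / first-level scale in pixels.
    contrast_percentile
        Percentile of the gradient-magnitude histogram that sets the
        Perona-Malik contrast factor k (edges stronger than k survive
        diffusion).
    min_image_size
        Images smaller than this yield no features (too few pixels for a
        scale ladder).
    """

    threshold: float = 1e-3
    n_octaves: int = 4
    n_sublevels: int = 4
    base_sigma: float = 1.6
    contrast_percentile: float = 70.0
    min_image_size: int = 16

    def sigmas(self) -> np.ndarray:
        exps = [
            o + s / self.n_sublevels
            for o in range(self.n_octaves)
            for s in range(self.n_sublevels)
        ]
        return self.base_sigma * np.power(2.0, np.array(exps))

    def to_dict(self) -> dict:
        return asdict(self)


def _contrast_factor(image: np.ndarray, percentile: float) -> float:
    """Perona-Malik contrast factor from the smoothed gradient histogram."""
    sm = ndimage.gaussian_filter(image, 1.0, mode="nearest")
    gx = ndimage.sobel(sm, axis=1, mode="nearest") / 8.0
    gy = ndimage.sobel(sm, axis=0, mode="nearest") / 8.0
    mag = np.hypot(gx, gy)
    nz = mag[mag > 0]
    if nz.size == 0:
        return 0.0
    return float(np.percentile(nz, percentile))


def _diffusion_step(L: np.ndarray, k2: float, dt: float) -> np.ndarray:
    """One explicit step of Perona-Malik diffusion (g2 conductivity)."""
    gx = ndimage.sobel(L, axis=1, mode="nearest") / 8.0
    gy = ndimage.sobel(L, axis=0, mode="nearest") / 8.0
    g = 1.0 / (1.0 + (gx * gx + gy * gy) / k2)

    # flux differences with conductivity at cell midpoints, Neumann borders
    dN = np.zeros_like(L)
    dS = np.zeros_like(L)
    dE = np.zeros_like(L)
    dW = np.zeros_like(L)
    dN[1:, :] = L[:-1, :] - L[1:, :]
    dS[:-1, :] = L[1:, :] - L[:-1, :]
    dW[:, 1:] = L[:, :-1] - L[:, 1:]
    dE[:, :-1] = L[:, 1:] - L[:, :-1]

    gN = np.zeros_like(L)
    gS = np.zeros_like(L)
    gE = np.zeros_like(L)
    gW = np.zeros_like(L)
    gN[1:, :] = 0.5 * (g[:-1, :] + g[1:, :])
    gS[:-1, :] = 0.5 * (g[1:, :] + g[:-1, :])
    gW[:, 1:] = 0.5 * (g[:, :-1] + g[:, 1:])
    gE[:, :-1] = 0.5 * (g[:, 1:] + g[:, :-1])

    return L + dt * (gN * dN + gS * dS + gE * dE + gW * dW)


def _build_scale_space(
    image: np.ndarray, params: DetectorParams
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Diffused levels at evolution times t_i = sigma_i^2 / 2.

    Returns (levels stacked [n_levels, H, W], sigmas, contrast k); if the
    image has no gradient at all, k is 0 and a single flat level is
    returned.
    """
    sigmas = params.sigmas()
    k = _contrast_factor(image, params.contrast_percentile)
    if k <= 0.0:
        return image[None, :, :].copy(), sigmas[:1], 0.0
    k2 = k * k
    times = 0.5 * sigmas**2
    L = ndimage.gaussian_filter(image, params.base_sigma, mode="nearest")
    levels = []
    t = 0.5 * params.base_sigma**2
    for t_target in times:
        while t < t_target:
            dt = min(_DT, t_target - t)
            L = _diffusion_step(L, k2, dt)
            t += dt
        levels.append(L.copy())
    return np.stack(levels), sigmas, k


def _derivatives(level: np.ndarray):
    """First and second central-difference derivatives of one level."""
    Ly, Lx = np.gradient(level)
    Lxy, Lxx = np.gradient(Lx)
    Lyy, _ = np.gradient(Ly)
    return Lx, Ly, Lxx, Lyy, Lxy


# ---------------------------------------------------------------------------
# M-SURF descriptor sampling pattern (upright, 4x4 subregions, 64 values)
# ---------------------------------------------------------------------------


def _msurf_pattern():
    """Precompute sample offsets and weights of the upright M-SURF grid.

    16 subregions centered at (-7.5, -2.5, 2.5, 7.5)^2 (in units of the
    keypoint scale), each sampling a 9x9 patch of first derivatives with a
    sigma=2.5 Gaussian; subregion sums are weighted by a sigma=1.5 Gaussian
    over the 4x4 subregion grid.
    """
    centers = np.array([-7.5, -2.5, 2.5, 7.5])
    offs = np.arange(-4, 5, dtype=float)
    ou, ov = np.meshgrid(offs, offs, indexing="ij")
    w1 = np.exp(-(ou**2 + ov**2) / (2 * 2.5**2)).ravel()

    sub_xy = []
    for cy in centers:
        for cx in centers:
            sx = (cx + ou).ravel()
            sy = (cy + ov).ravel()
            sub_xy.append(np.stack([sx, sy], axis=0))
    sample_xy = np.concatenate(sub_xy, axis=1)  # (2, 16*81)

    grid = np.array([-1.5, -0.5, 0.5, 1.5])
    gy, gx = np.meshgrid(grid, grid, indexing="ij")
    w2 = np.exp(-(gx**2 + gy**2) / (2 * 1.5**2)).ravel()  # (16,)
    return sample_xy, w1, w2


_SAMPLE_XY, _W1, _W2 = _msurf_pattern()


def _describe(
    kp_xy: np.ndarray, scale: float, Lx: np.ndarray, Ly: np.ndarray
) -> np.ndarray:
    """Upright M-SURF descriptors for all keypoints of one level."""
    n_kp = kp_xy.shape[0]
    # sample coordinates: (n_kp, 2, 1296)
    sx = kp_xy[:, 0, None] + scale * _SAMPLE_XY[0]
    sy = kp_xy[:, 1, None] + scale * _SAMPLE_XY[1]
    coords = np.stack([sy.ravel(), sx.ravel()])  # row=y, col=x
    dx = ndimage.map_coordinates(Lx, coords, order=1, mode="nearest")
    dy = ndimage.map_coordinates(Ly, coords, order=1, mode="nearest")
    dx = dx.reshape(n_kp, 16, 81)
    dy = dy.reshape(n_kp, 16, 81)

    w1 = _W1[None, None, :]
    parts = np.stack(
        [
            (w1 * dx).sum(axis=2),
            (w1 * dy).sum(axis=2),
            (w1 * np.abs(dx)).sum(axis=2),
            (w1 * np.abs(dy)).sum(axis=2),
        ],
        axis=2,
    )  # (n_kp, 16, 4)
    parts *= _W2[None, :, None]
    desc = parts.reshape(n_kp, DESCRIPTOR_SIZE)
    norms = np.linalg.norm(desc, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return desc / norms


def detect_and_describe(
    pixels: np.ndarray, params: DetectorParams = DetectorParams()
) -> Tuple[np.ndarray, np.ndarray]:
    """Detect keypoints and compute their 64-d descriptors.

    Parameters
    ----------
    pixels : (H, W) float array in [0, 1]
    params : DetectorParams

    Returns
    -------
    keypoints : (n, 3) array of (x, y, scale), x = column, y = row
    descriptors : (n, 64) array, rows L2-normalized
    """
    img = np.asarray(pixels, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale array")
    if min(img.shape) < params.min_image_size:
        return np.empty((0, 3)), np.empty((0, DESCRIPTOR_SIZE))

    levels, sigmas, k = _build_scale_space(img, params)
    if k <= 0.0 or len(levels) < 3:
        return np.empty((0, 3)), np.empty((0, DESCRIPTOR_SIZE))

    derivs = [_derivatives(lv) for lv in levels]
    responses = np.stack(
        [
            (s**4) * (d[2] * d[3] - d[4] ** 2)
            for s, d in zip(sigmas, derivs)
        ]
    )

    # 3x3x3 extrema over (scale, y, x), interior scale levels only
    local_max = ndimage.maximum_filter(responses, size=(3, 3, 3), mode="nearest")
    is_peak = (responses >= local_max) & (responses > params.threshold)
    is_peak[0] = False
    is_peak[-1] = False
    margin = 2
    is_peak[:, :margin, :] = False
    is_peak[:, -margin:, :] = False
    is_peak[:, :, :margin] = False
    is_peak[:, :, -margin:] = False

    kps = []
    descs = []
    for li in range(1, len(levels) - 1):
        yy, xx = np.nonzero(is_peak[li])
        if yy.size == 0:
            continue
        kp_xy = np.stack([xx.astype(float), yy.astype(float)], axis=1)
        Lx, Ly = derivs[li][0], derivs[li][1]
        d = _describe(kp_xy, float(sigmas[li]), Lx, Ly)
        kps.append(
            np.column_stack([kp_xy, np.full(len(kp_xy), sigmas[li])])
        )
        descs.append(d)

    if not kps:
        return np.empty((0, 3)), np.empty((0, DESCRIPTOR_SIZE))
    return np.concatenate(kps), np.concatenate(descs)
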