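"""SURF keypoints and descriptors on PSSM "images".

A PSSM is treated as a single-channel intensity image: positions along
rows, the 20 amino-acid columns along columns.  Blob-like regions of the
matrix — local patches of unusually high or low substitution scores —
are found with the Speeded-Up Robust Features detector: box-filter
approximations of the scale-normalised Hessian evaluated on an integral
image, with keypoints at local maxima of the Hessian determinant across
space and scale.  Each keypoint yields a 64-dimensional Haar-wavelet
descriptor; the variable-size descriptor set of a protein is pooled into
one fixed-length feature vector (mean pooling by default, bag of visual
words as the alternative).

The grid is only 20 columns wide, far narrower than natural images, so
everything operates on a reflection-padded copy large enough to support
the biggest box filter and the descriptor window; keypoints are reported
in the original (unpadded) 0-based coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .dataio import PSSM

logger = logging.getLogger(__name__)

#: Side of the smallest box filter; approximates a Gaussian of sigma 1.2.
BASE_FILTER_SIZE = 9
BASE_FILTER_SCALE = 1.2
#: Filter size increment within the first octave (9, 15, 21, 27, ...).
FILTER_STEP = 6
#: Correction weight on the mixed derivative in the Hessian determinant.
DXY_WEIGHT = 0.9
#: Descriptor length: 4x4 sub-regions x 4 Haar statistics.
DESCRIPTOR_SIZE = 64


@dataclass(frozen=True)
class SurfConfig:
    """Tunable knobs of the PSSM feature extractor.

    threshold=None uses ``rel_threshold`` times the largest determinant
    response of the grid, so detection adapts to per-protein contrast.
    """

    n_levels: int = 4
    threshold: float | None = None
    rel_threshold: float = 1e-2
    pooling: str = "mean"  # "mean" or "bovw"
    K: int = 32
    upsample: int = 1
    upright: bool = False
    seed: int = 0


@dataclass
class IntensityGrid:
    """PSSM rescaled to [0, 1] for consumption by the detector."""

    values: np.ndarray
    protein_id: str = ""


@dataclass
class Keypoint:
    row: int
    col: int
    filter_size: int
    sigma: float
    response: float
    laplacian_sign: int
    orientation: float = 0.0


@dataclass
class Descriptor:
    vector: np.ndarray
    keypoint: Keypoint


@dataclass
class ProteinFeature:
    protein_id: str
    vector: np.ndarray
    n_keypoints: int


@dataclass
class ScaleLevel:
    filter_size: int
    sigma: float
    det: np.ndarray
    laplacian: np.ndarray


# ---------------------------------------------------------------------------
# grid preparation
# ---------------------------------------------------------------------------


def normalize_pssm(pssm: PSSM) -> IntensityGrid:
    """Linear min-max rescale of the score matrix to [0, 1].

    A constant matrix carries no contrast and maps to all 0.5.
    """
    scores = pssm.scores
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        values = np.full_like(scores, 0.5, dtype=float)
    else:
        values = (scores - lo) / (hi - lo)
    return IntensityGrid(values=values, protein_id=pssm.protein_id)


def integral_image(grid) -> np.ndarray:
    """Summed-area table with a zero guard row/column.

    Entry (i, j) is the sum of all grid entries with row < i and
    col < j, so any axis-aligned rectangle sum costs four lookups.
    """
    values = grid.values if isinstance(grid, IntensityGrid) else np.asarray(grid)
    ii = np.zeros((values.shape[0] + 1, values.shape[1] + 1), dtype=float)
    ii[1:, 1:] = values.cumsum(axis=0).cumsum(axis=1)
    return ii


def rect_sum(ii: np.ndarray, r0: int, c0: int, r1: int, c1: int) -> float:
    """Sum of grid rows r0..r1-1, cols c0..c1-1 via four lookups."""
    return ii[r1, c1] - ii[r0, c1] - ii[r1, c0] + ii[r0, c0]


def _box(ii: np.ndarray, row: int, col: int, rows: int, cols: int) -> float:
    """Inclusive box sum starting at (row, col), clamped to the grid."""
    R, C = ii.shape[0] - 1, ii.shape[1] - 1
    r0 = min(max(row, 0), R)
    c0 = min(max(col, 0), C)
    r1 = min(max(row + rows, 0), R)
    c1 = min(max(col + cols, 0), C)
    if r1 <= r0 or c1 <= c0:
        return 0.0
    return rect_sum(ii, r0, c0, r1, c1)


# ---------------------------------------------------------------------------
# Hessian responses and scale space
# ---------------------------------------------------------------------------


def filter_scale(filter_size: int) -> float:
    """Gaussian scale approximated by a box filter of the given side.

    sigma = filter_size * (base scale / base size) = filter_size * 1.2/9.
    """
    if filter_size <= 0:
        raise ValueError(f"filter size must be positive, got {filter_size}")
    return filter_size * BASE_FILTER_SCALE / BASE_FILTER_SIZE


def _box_grid(ii, rb, re, cb, ce, dr, dc, nr, nc):
    """Vectorised box sums over all centers rows rb..re-1, cols cb..ce-1.

    Each box spans grid rows center+dr .. center+dr+nr-1 and similarly
    in columns.
    """
    return (
        ii[rb + dr + nr : re + dr + nr, cb + dc + nc : ce + dc + nc]
        - ii[rb + dr + nr : re + dr + nr, cb + dc : ce + dc]
        - ii[rb + dr : re + dr, cb + dc + nc : ce + dc + nc]
        + ii[rb + dr : re + dr, cb + dc : ce + dc]
    )


def hessian_response(ii: np.ndarray, filter_size: int):
    """Box-filter Hessian determinant and Laplacian sign per pixel.

    Second-order Gaussian derivatives are approximated by box filters
    (outer lobes +1, middle lobe -2 for Dxx/Dyy; four diagonal lobes for
    Dxy), each normalised by the filter area.  The determinant is
    ``Dxx*Dyy - (0.9*Dxy)**2`` and the Laplacian sign distinguishes
    bright blobs (negative trace) from dark ones.  Pixels closer than
    (filter_size-1)/2 to the border are left at zero: callers pad the
    grid by reflection so that every pixel of interest is interior.
    """
    if filter_size < BASE_FILTER_SIZE or filter_size % 2 == 0:
        raise ValueError(f"filter size must be odd and >= 9, got {filter_size}")
    R, C = ii.shape[0] - 1, ii.shape[1] - 1
    det = np.zeros((R, C))
    lap = np.ones((R, C))
    b = (filter_size - 1) // 2
    lobe = filter_size // 3
    if R < filter_size or C < filter_size:
        logger.warning(
            "filter %d larger than %dx%d grid: empty response", filter_size, R, C
        )
        return det, lap
    rb, re, cb, ce = b, R - b, b, C - b
    inv_area = 1.0 / (filter_size * filter_size)
    half = lobe // 2
    dxx = (
        _box_grid(ii, rb, re, cb, ce, -lobe + 1, -b, 2 * lobe - 1, filter_size)
        - 3.0 * _box_grid(ii, rb, re, cb, ce, -lobe + 1, -half, 2 * lobe - 1, lobe)
    ) * inv_area
    dyy = (
        _box_grid(ii, rb, re, cb, ce, -b, -lobe + 1, filter_size, 2 * lobe - 1)
        - 3.0 * _box_grid(ii, rb, re, cb, ce, -half, -lobe + 1, lobe, 2 * lobe - 1)
    ) * inv_area
    dxy = (
        _box_grid(ii, rb, re, cb, ce, -lobe, 1, lobe, lobe)
        + _box_grid(ii, rb, re, cb, ce, 1, -lobe, lobe, lobe)
        - _box_grid(ii, rb, re, cb, ce, -lobe, -lobe, lobe, lobe)
        - _box_grid(ii, rb, re, cb, ce, 1, 1, lobe, lobe)
    ) * inv_area
    det[rb:re, cb:ce] = dxx * dyy - (DXY_WEIGHT * dxy) ** 2
    lap[rb:re, cb:ce] = np.where(dxx + dyy >= 0, 1.0, -1.0)
    return det, lap


def build_scale_space(ii: np.ndarray, n_levels: int = 4):
    """Hessian response stack for filter sizes 9, 15, 21, 27, ...

    A single octave: the filter side grows by 6 per level so the first
    sizes match the canonical sequence, each level carrying the sigma
    given by :func:`filter_scale`.
    """
    if n_levels < 3:
        raise ValueError("scale space needs at least 3 levels")
    levels = []
    for i in range(n_levels):
        size = BASE_FILTER_SIZE + FILTER_STEP * i
        det, lap = hessian_response(ii, size)
        levels.append(ScaleLevel(size, filter_scale(size), det, lap))
    return levels


def detect_keypoints(
    stack: Sequence[ScaleLevel],
    threshold: float | None = None,
    rel_threshold: float = 1e-2,
):
    """Scale-space extrema of the Hessian determinant.

    A pixel at an interior level survives iff its response exceeds the
    threshold and strictly dominates all 26 neighbours of its 3x3x3
    scale-space neighbourhood; ties are suppressed.  With
    ``threshold=None`` the threshold adapts to ``rel_threshold`` times
    the stack's maximum response.
    """
    if len(stack) < 3:
        raise ValueError("keypoint detection needs at least 3 levels")
    dets = np.stack([lv.det for lv in stack])
    if threshold is None:
        threshold = rel_threshold * dets.max()
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    neigh_max = ndimage.maximum_filter(
        dets, footprint=footprint, mode="constant", cval=-np.inf
    )
    keypoints = []
    for li in range(1, len(stack) - 1):
        mask = (dets[li] > threshold) & (dets[li] > neigh_max[li])
        for r, c in np.argwhere(mask):
            lv = stack[li]
            keypoints.append(
                Keypoint(
                    row=int(r),
                    col=int(c),
                    filter_size=lv.filter_size,
                    sigma=lv.sigma,
                    response=float(dets[li, r, c]),
                    laplacian_sign=int(lv.laplacian[r, c]),
                )
            )
    keypoints.sort(key=lambda kp: (-kp.response, kp.sigma, kp.row, kp.col))
    return keypoints


# ---------------------------------------------------------------------------
# orientation and descriptor
# ---------------------------------------------------------------------------


def _haar_x(ii: np.ndarray, r: int, c: int, side: int) -> float:
    """Horizontal Haar wavelet: right half minus left half of a side x side box."""
    half = side // 2
    return _box(ii, r - half, c, side, half) - _box(ii, r - half, c - half, side, half)


def _haar_y(ii: np.ndarray, r: int, c: int, side: int) -> float:
    half = side // 2
    return _box(ii, r, c - half, half, side) - _box(ii, r - half, c - half, half, side)


_SECTOR_WIDTH = math.pi / 3
_SECTOR_STEP = 0.15


def assign_orientation(ii: np.ndarray, kp: Keypoint) -> float:
    """Dominant gradient direction of the keypoint's neighbourhood.

    Haar wavelet responses (side ~4 sigma) are sampled on a sigma-spaced
    grid within radius 6 sigma of the keypoint and Gaussian-weighted
    (std 2 sigma).  A pi/3-wide sector slides around the circle; the
    orientation is the angle of the longest summed (sum dx, sum dy)
    vector.  Out-of-reach keypoints get orientation 0 with a warning.
    """
    R, C = ii.shape[0] - 1, ii.shape[1] - 1
    s = kp.sigma
    side = max(2, int(round(4 * s)))
    reach = int(round(6 * s)) + side
    if kp.row - reach < 0 or kp.row + reach > R or kp.col - reach < 0 or kp.col + reach > C:
        logger.warning(
            "orientation window of keypoint (%d, %d, sigma=%.2f) exceeds grid; "
            "returning 0",
            kp.row,
            kp.col,
            s,
        )
        return 0.0
    dxs, dys, angles = [], [], []
    for j in range(-6, 7):
        for i in range(-6, 7):
            if i * i + j * j >= 36:
                continue
            rr = kp.row + int(round(j * s))
            cc = kp.col + int(round(i * s))
            g = math.exp(-(i * i + j * j) / (2.0 * 2.0**2))
            dx = g * _haar_x(ii, rr, cc, side)
            dy = g * _haar_y(ii, rr, cc, side)
            dxs.append(dx)
            dys.append(dy)
            angles.append(math.atan2(dy, dx) % (2 * math.pi))
    dxs, dys, angles = map(np.asarray, (dxs, dys, angles))
    best_norm, best_vec = -1.0, (1.0, 0.0)
    ang = 0.0
    while ang < 2 * math.pi:
        in_sector = ((angles - ang) % (2 * math.pi)) < _SECTOR_WIDTH
        sx, sy = dxs[in_sector].sum(), dys[in_sector].sum()
        norm = sx * sx + sy * sy
        if norm > best_norm:
            best_norm, best_vec = norm, (sx, sy)
        ang += _SECTOR_STEP
    if best_norm <= 0:
        return 0.0
    return math.atan2(best_vec[1], best_vec[0]) % (2 * math.pi)


def compute_descriptor(ii: np.ndarray, kp: Keypoint, orientation: float) -> Descriptor:
    """64-d Haar descriptor of the oriented 20 sigma window.

    The window is split into 4x4 sub-regions of 5x5 sigma-spaced samples
    each; per sub-region the four statistics (sum dx, sum dy, sum |dx|,
    sum |dy|) of the rotated, Gaussian-weighted (std 3.3 sigma) wavelet
    responses are collected, giving 16 x 4 = 64 entries, then normalised
    to unit Euclidean length (a flat window stays the zero vector).
    """
    s = kp.sigma
    co, si = math.cos(orientation), math.sin(orientation)
    side = max(2, int(round(2 * s)))
    acc = np.zeros((4, 4, 4))
    for vi in range(-10, 10):  # v: keypoint-frame row axis
        for ui in range(-10, 10):  # u: keypoint-frame column axis
            u = ui + 0.5
            v = vi + 0.5
            col_off = s * (u * co - v * si)
            row_off = s * (u * si + v * co)
            rr = int(round(kp.row + row_off))
            cc = int(round(kp.col + col_off))
            dx = _haar_x(ii, rr, cc, side)
            dy = _haar_y(ii, rr, cc, side)
            g = math.exp(-(u * u + v * v) / (2.0 * 3.3**2))
            dxr = g * (co * dx + si * dy)
            dyr = g * (-si * dx + co * dy)
            bi = (ui + 10) // 5
            bj = (vi + 10) // 5
            acc[bj, bi] += (dxr, dyr, abs(dxr), abs(dyr))
    vec = acc.reshape(DESCRIPTOR_SIZE)
    norm = np.linalg.norm(vec)
    # integral-image cancellation leaves ~1e-13 dust on flat windows;
    # normalising that would fabricate structure, so treat it as zero
    if norm > 1e-9:
        vec = vec / norm
    else:
        vec = np.zeros(DESCRIPTOR_SIZE)
    return Descriptor(vector=vec, keypoint=kp)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------


def fit_codebook(descriptors: Sequence[Descriptor], K: int, seed: int = 0) -> np.ndarray:
    """k-means codebook of K visual words over pooled training descriptors."""
    from sklearn.cluster import KMeans

    vectors = np.vstack([d.vector for d in descriptors])
    if vectors.shape[0] < K:
        raise ValueError(f"need at least K={K} descriptors, got {vectors.shape[0]}")
    km = KMeans(n_clusters=K, random_state=seed, n_init=10)
    km.fit(vectors)
    return km.cluster_centers_


def pool_descriptors(
    descriptors: Sequence[Descriptor],
    method: str = "mean",
    K: int | None = None,
    codebook: np.ndarray | None = None,
    protein_id: str = "",
) -> ProteinFeature:
    """Collapse a protein's descriptor set into one fixed-length vector.

    ``mean``: arithmetic mean of the 64-d descriptors.  ``bovw``:
    L1-normalised histogram of nearest-codeword assignments (length K).
    Zero keypoints yield the zero vector.
    """
    if method == "mean":
        dim = DESCRIPTOR_SIZE
    elif method == "bovw":
        if codebook is None:
            raise ValueError("bovw pooling requires a fitted codebook")
        dim = codebook.shape[0]
        if K is not None and K != dim:
            raise ValueError(f"codebook has {dim} words but K={K} requested")
    else:
        raise ValueError(f"unknown pooling method {method!r}")
    if not descriptors:
        return ProteinFeature(protein_id, np.zeros(dim), 0)
    vectors = np.vstack([d.vector for d in descriptors])
    if method == "mean":
        pooled = vectors.mean(axis=0)
    else:
        d2 = ((vectors[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
        hist = np.bincount(d2.argmin(axis=1), minlength=dim).astype(float)
        pooled = hist / hist.sum()
    return ProteinFeature(protein_id, pooled, len(descriptors))


# ---------------------------------------------------------------------------
# end-to-end extraction
# ---------------------------------------------------------------------------


def _support_pad(config: SurfConfig) -> int:
    sigma_max = filter_scale(BASE_FILTER_SIZE + FILTER_STEP * (config.n_levels - 1))
    descriptor_reach = math.ceil(sigma_max * (10 * math.sqrt(2) + 2)) + 2
    orientation_reach = math.ceil(sigma_max * 6 + 4 * sigma_max) + 2
    hessian_border = (BASE_FILTER_SIZE + FILTER_STEP * (config.n_levels - 1)) // 2 + 1
    return max(descriptor_reach, orientation_reach, hessian_border)


def compute_descriptors(pssm: PSSM, config: SurfConfig = SurfConfig()):
    """Detect keypoints on one PSSM and return their descriptors.

    Runs normalise -> reflection pad -> integral image -> scale space ->
    detect -> orient -> describe.  Keypoint coordinates are mapped back
    to the unpadded grid; keypoints whose extremum lies in the padding
    (mirror artefacts) are dropped.
    """
    grid = normalize_pssm(pssm)
    values = grid.values
    if config.upsample > 1:
        values = np.kron(values, np.ones((config.upsample, config.upsample)))
    pad = _support_pad(config)
    padded = np.pad(values, pad, mode="reflect")
    ii = integral_image(padded)
    stack = build_scale_space(ii, config.n_levels)
    keypoints = detect_keypoints(stack, config.threshold, config.rel_threshold)
    R, C = values.shape
    descriptors = []
    for kp in keypoints:
        if not (pad <= kp.row < pad + R and pad <= kp.col < pad + C):
            continue
        orientation = 0.0 if config.upright else assign_orientation(ii, kp)
        kp.orientation = orientation
        desc = compute_descriptor(ii, kp, orientation)
        kp.row -= pad
        kp.col -= pad
        descriptors.append(desc)
    return descriptors


def extract_protein_features(
    pssm: PSSM,
    config: SurfConfig = SurfConfig(),
    codebook: np.ndarray | None = None,
) -> ProteinFeature:
    """Full per-protein pipeline: PSSM in, pooled feature vector out."""
    descriptors = compute_descriptors(pssm, config)
    return pool_descriptors(
        descriptors,
        method=config.pooling,
        K=config.K if config.pooling == "bovw" else None,
        codebook=codebook,
        protein_id=pssm.protein_id,
    )


def extract_features_batch(pssms, config: SurfConfig = SurfConfig()) -> dict:
    """Extract features for a whole PSSM collection.

    For bag-of-visual-words pooling the codebook is fitted once on the
    pooled descriptors of all proteins (an unsupervised step), then every
    protein is encoded against it; mean pooling needs no shared state.
    """
    all_descs = {pid: compute_descriptors(p, config) for pid, p in pssms.items()}
    codebook = None
    if config.pooling == "bovw":
        flat = [d for descs in all_descs.values() for d in descs]
        codebook = fit_codebook(flat, config.K, config.seed)
    return {
        pid: pool_descriptors(
            descs,
            method=config.pooling,
            K=config.K if config.pooling == "bovw" else None,
            codebook=codebook,
            protein_id=pid,
        )
        for pid, descs in all_descs.items()
    }
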