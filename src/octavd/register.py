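"""Longitudinal alignment of en face angiograms of the same eye.

Baseline and follow-up scans are aligned with an aspect-ratio-preserving
**similarity transform** (uniform scale + rotation + translation, no
reflection) estimated in closed form from matched landmark points placed
at vessel junctions.  Metric comparison is then restricted to the maximal
axis-aligned rectangle contained in both fields of view, so that both
visits are quantified over the same retinal area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import EnFaceImage

__all__ = [
    "SimilarityTransform",
    "LandmarkSet",
    "EstimationError",
    "OverlapError",
    "estimate_similarity",
    "warp",
    "overlap_region",
    "intervisit_compare",
]


class EstimationError(ValueError):
    """Raised when landmark geometry cannot determine the transform."""


class OverlapError(ValueError):
    """Raised when two fields of view share no common area."""


@dataclass(frozen=True)
class SimilarityTransform:
    """Map  p ↦ s·R(θ)·p + t  with uniform scale s > 0 (no reflection)."""

    scale: float
    rotation: float  # radians, counter-clockwise in (x right, y down) axes
    translation: tuple[float, float]

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(1.0, 0.0, (0.0, 0.0))

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on column vectors (x, y, 1)."""
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        tx, ty = self.translation
        return np.array([[self.scale * c, -self.scale * s, tx],
                         [self.scale * s, self.scale * c, ty],
                         [0.0, 0.0, 1.0]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        m = self.matrix
        return pts @ m[:2, :2].T + m[:2, 2]

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        c, s = np.cos(-self.rotation), np.sin(-self.rotation)
        tx, ty = self.translation
        return SimilarityTransform(
            inv_scale, -self.rotation,
            (-inv_scale * (c * tx - s * ty), -inv_scale * (s * tx + c * ty)))


@dataclass(frozen=True)
class LandmarkSet:
    """Matched (source, target) landmark pairs, e.g. vessel junctions."""

    source: np.ndarray  # (n, 2) (x, y) in the moving image
    target: np.ndarray  # (n, 2) (x, y) in the fixed image

    def __post_init__(self) -> None:
        src = np.asarray(self.source, dtype=float)
        dst = np.asarray(self.target, dtype=float)
        if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
            raise EstimationError("source/target must both be (n, 2)")
        if src.shape[0] < 3:
            raise EstimationError("need at least 3 landmark pairs")
        object.__setattr__(self, "source", src)
        object.__setattr__(self, "target", dst)

    @property
    def n(self) -> int:
        return self.source.shape[0]


def _collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    d = pts - pts.mean(axis=0)
    # Smallest singular value ~ 0 when all points lie on one line.
    s = np.linalg.svd(d, compute_uv=False)
    return s[-1] <= tol * max(s[0], 1.0)


class SimilarityFit(NamedTuple):
    transform: SimilarityTransform
    rmse: float


def estimate_similarity(landmarks: LandmarkSet) -> SimilarityFit:
    """Least-squares similarity transform from matched landmarks.

    Minimizes Σ‖T(srcᵢ) − dstᵢ‖² over uniform scale, rotation and
    translation.  Writing points as complex numbers z (source) and
    w (target), the model is w = a·z + b with a = s·e^{iθ}, and the
    least-squares solution is the complex regression coefficient

        a = Σ (wᵢ − w̄)(z̄ᵢ − z̄)* / Σ |zᵢ − z̄|²,   b = w̄ − a·z̄.

    This parameterization cannot produce a reflection, matching
    registration that preserves the image aspect ratio.  Collinear source
    landmarks are rejected: although the algebra still yields a solution,
    the configuration gives no leverage against annotation error
    orthogonal to the line and is treated as degenerate.

    Returns the transform and the residual RMSE in pixels.
    """
    src, dst = landmarks.source, landmarks.target
    if _collinear(src):
        raise EstimationError("source landmarks are collinear")
    z = src[:, 0] + 1j * src[:, 1]
    w = dst[:, 0] + 1j * dst[:, 1]
    zc, wc = z - z.mean(), w - w.mean()
    denom = np.vdot(zc, zc).real
    a = np.vdot(zc, wc) / denom  # vdot conjugates the first argument
    if abs(a) == 0:
        raise EstimationError("degenerate landmark configuration (zero scale)")
    b = w.mean() - a * z.mean()
    tf = SimilarityTransform(abs(a), float(np.angle(a)),
                             (b.real, b.imag))
    resid = tf.apply(src) - dst
    rmse = float(np.sqrt((resid ** 2).sum(axis=1).mean()))
    return SimilarityFit(tf, rmse)


def warp(image: EnFaceImage, transform: SimilarityTransform,
         output_shape: tuple[int, int] | None = None,
         order: int = 1) -> tuple[EnFaceImage, np.ndarray]:
    """Resample ``image`` under ``transform`` into the target frame.

    Inverse mapping with bilinear interpolation (``order=1``; use 0 for
    nearest-neighbour, appropriate for masks).  Samples falling outside
    the source frame are filled with 0 and marked False in the returned
    validity mask.
    """
    h, w = output_shape or image.shape
    inv = transform.inverse()
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    src_pts = inv.apply(pts)
    sx = src_pts[:, 0].reshape(h, w)
    sy = src_pts[:, 1].reshape(h, w)
    sh, sw = image.shape
    # Small tolerance absorbs floating-point residue of the inverse map
    # (e.g. exact 90-degree rotations landing at -1e-15).
    eps = 1e-9
    valid = ((sx >= -eps) & (sx <= sw - 1 + eps)
             & (sy >= -eps) & (sy <= sh - 1 + eps))
    sx = np.clip(sx, 0, sw - 1)
    sy = np.clip(sy, 0, sh - 1)
    out = ndimage.map_coordinates(image.astype_float(), [sy, sx],
                                  order=order, mode="constant", cval=0.0)
    out[~valid] = 0.0
    return image.with_pixels(np.clip(np.rint(out), 0, 255).astype(np.uint8)), valid


def _largest_rectangle(valid: np.ndarray) -> tuple[int, int, int, int]:
    """Maximal-area axis-aligned all-True rectangle (y0, x0, h, w).

    Histogram-stack scan, O(rows * cols).  Area ties resolve to the
    earliest (topmost, then leftmost) rectangle encountered.
    """
    h, w = valid.shape
    heights = np.zeros(w, dtype=int)
    best = (0, 0, 0, 0)
    best_area = 0
    for y in range(h):
        heights = np.where(valid[y], heights + 1, 0)
        stack: list[tuple[int, int]] = []  # (left index, bar height)
        for x in range(w + 1):
            cur = int(heights[x]) if x < w else 0
            start = x
            while stack and stack[-1][1] >= cur:
                left, bar = stack.pop()
                area = bar * (x - left)
                if area > best_area:
                    best_area = area
                    best = (y - bar + 1, left, bar, x - left)
                start = left
            if cur > 0:
                stack.append((start, cur))
    return best


def overlap_region(shape_target: tuple[int, int],
                   shape_source: tuple[int, int],
                   transform: SimilarityTransform) -> tuple[int, int, int, int]:
    """Common analysis rectangle of two visits, in the target frame.

    Returns ``(y0, x0, height, width)`` of the maximal axis-aligned
    rectangle contained in both the target image and the valid (in-frame)
    region of the similarity-transformed source — a deterministic stand-in
    for cropping the overlapping area by hand.

    Raises
    ------
    OverlapError
        If the transformed source misses the target frame entirely.
    """
    if min(shape_target) <= 0 or min(shape_source) <= 0:
        raise ValueError("image shapes must be positive")
    h, w = shape_target
    sh, sw = shape_source
    inv = transform.inverse()
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    src_pts = inv.apply(pts)
    sx = src_pts[:, 0].reshape(h, w)
    sy = src_pts[:, 1].reshape(h, w)
    eps = 1e-9
    valid = ((sx >= -eps) & (sx <= sw - 1 + eps)
             & (sy >= -eps) & (sy <= sh - 1 + eps))
    y0, x0, rh, rw = _largest_rectangle(valid)
    if rh == 0 or rw == 0:
        raise OverlapError("transformed source does not overlap the target")
    return y0, x0, rh, rw


def intervisit_compare(baseline: pd.DataFrame,
                       followup: pd.DataFrame) -> pd.DataFrame:
    """Per-eye metric changes (follow-up − baseline) for the paired test.

    Both tables must carry one row per (eye_id, plexus) with the metric
    columns ``whole_vd``, ``extrafaz_vd``, ``faz_area_pct`` computed on
    the common overlap crop, plus ``patient_id`` for clustering.

    Raises
    ------
    KeyError
        If the two visits do not cover the same (eye_id, plexus) pairs.
    """
    keys = ["eye_id", "plexus"]
    metrics = ["whole_vd", "extrafaz_vd", "faz_area_pct"]
    b = baseline.set_index(keys)
    f = followup.set_index(keys)
    if set(b.index) != set(f.index):
        missing = set(b.index) ^ set(f.index)
        raise KeyError(f"visits cover different eyes/plexi: {sorted(missing)}")
    f = f.loc[b.index]
    out = pd.DataFrame(index=b.index)
    out["patient_id"] = b["patient_id"]
    for m in metrics:
        out[f"delta_{m}"] = f[m] - b[m]
    return out.reset_index()
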