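"""Fluorescence-pattern geometry: projection, thresholding, ellipse fitting.

The expression pattern of a wing disc (e.g. a vgQE reporter) is reduced to a
binary footprint by maximum z-projection, optional background subtraction
(mean of a user-annotated square region outside the pattern), thresholding at
a fixed fraction of the maximum intensity (default 20%), and morphological
cleanup.  The footprint's elongation is summarized by fitting an ellipse, by
algebraic least squares, to the vertices of its convex hull; eccentricity
e = sqrt(1 - b^2/a^2) is 0 for a circle and approaches 1 for an elongated
pattern.  The same ellipse fit applies to manually clicked hinge-pouch fold
points, which give a reporter-independent pouch boundary.

All images are (rows, cols) arrays; points are (x, y) = (col, row).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import EllipseModel, label

__all__ = [
    "FittedEllipse",
    "project_stack",
    "subtract_background",
    "binarize_pattern",
    "preprocess_mask",
    "hull_points",
    "fit_ellipse",
    "pattern_eccentricity",
    "fit_hp_ellipse",
    "overlap_nuclei_estimate",
]

BACKGROUND_ROI_SIZE = 30  # side of the square background region, pixels
BINARIZE_FRACTION = 0.20  # threshold as a fraction of the pattern maximum
MIN_COMPONENT_PX = 64  # components smaller than this are treated as noise
BLUR_KERNEL = 5  # mean-filter kernel for edge smoothing
NUCLEUS_PX = 200  # pixel area of one nucleus, for overlap-to-nuclei conversion


class EllipseFitError(ValueError):
    """Points do not determine an ellipse."""


@dataclass(frozen=True)
class FittedEllipse:
    """Least-squares ellipse: center, semi-axes a >= b, orientation, eccentricity."""

    center: tuple[float, float]
    a: float
    b: float
    theta: float
    e: float

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise EllipseFitError(f"semi-axes must satisfy a >= b > 0, got {self.a}, {self.b}")

    @property
    def area(self) -> float:
        return float(np.pi * self.a * self.b)


def project_stack(stack, group_size: int | None = None):
    """Maximum-intensity projection of a z-stack.

    ``group_size`` None collapses the whole stack to one image; ``group_size``
    g yields one projection per consecutive block of g planes (last block may
    be shorter).  A 2-D input is returned unchanged (single-plane stack).
    """
    arr = np.asarray(stack, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[0] == 0:
        raise ValueError("stack must be a non-empty (planes, rows, cols) array")
    if group_size is None:
        return arr.max(axis=0)
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    return [
        arr[i : i + group_size].max(axis=0) for i in range(0, arr.shape[0], group_size)
    ]


def subtract_background(image, roi_corner, roi_size: int = BACKGROUND_ROI_SIZE):
    """Subtract the mean of a square background region; clamp negatives to 0.

    ``roi_corner`` is the (x, y) top-left corner of the square, which must lie
    entirely inside the image.
    """
    img = np.asarray(image, dtype=float)
    x0, y0 = int(roi_corner[0]), int(roi_corner[1])
    if x0 < 0 or y0 < 0 or y0 + roi_size > img.shape[0] or x0 + roi_size > img.shape[1]:
        raise ValueError(
            f"background ROI corner=({x0},{y0}) size={roi_size} exceeds image "
            f"shape {img.shape}"
        )
    mean = img[y0 : y0 + roi_size, x0 : x0 + roi_size].mean()
    return np.clip(img - mean, 0.0, None)


def binarize_pattern(image, fraction: float = BINARIZE_FRACTION) -> np.ndarray:
    """Binary mask: pixels strictly above ``fraction`` x max intensity.

    The threshold is relative, so the mask is invariant to rescaling the
    intensities by any positive factor.
    """
    img = np.asarray(image, dtype=float)
    vmax = img.max()
    if vmax <= 0:
        raise ValueError("image has no positive intensities: no pattern to binarize")
    return (img > fraction * vmax).astype(np.uint8)


def preprocess_mask(
    mask,
    min_component_px: int = MIN_COMPONENT_PX,
    blur_kernel: int = BLUR_KERNEL,
    keep_largest: bool = False,
) -> np.ndarray:
    """Morphological cleanup: drop small components, optionally keep only the
    largest (ties broken by first label in scan order), then smooth edges with
    a mean filter re-thresholded at 0.5."""
    m = np.asarray(mask).astype(bool)
    if min_component_px > 0 or keep_largest:
        lab, n = label(m, return_num=True, connectivity=2)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            keep = sizes >= min_component_px
            if keep_largest and keep.any():
                largest = np.argmax(sizes * keep)  # first max in scan order
                keep = np.zeros_like(keep)
                keep[largest] = True
            m = keep[lab - 1] & (lab > 0)
    if blur_kernel > 1:
        sm = ndimage.uniform_filter(m.astype(float), size=blur_kernel, mode="constant")
        m = sm > 0.5
    if not m.any():
        raise ValueError("mask is empty after cleanup")
    return m.astype(np.uint8)


def hull_points(mask) -> np.ndarray:
    """Counterclockwise convex-hull vertices of the foreground pixels, (x, y)."""
    m = np.asarray(mask).astype(bool)
    rows, cols = np.nonzero(m)
    if len(rows) < 3:
        raise ValueError("need at least 3 foreground pixels for a hull")
    pts = np.column_stack([cols, rows]).astype(float)
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError(f"foreground pixels are degenerate (collinear?): {exc}") from exc
    return pts[hull.vertices]  # Qhull returns 2-D vertices counterclockwise


def fit_ellipse(points) -> FittedEllipse:
    """Direct algebraic least-squares ellipse fit.

    Deterministic, non-iterative conic fit; the returned parameters are
    normalized so a >= b, rotating theta by pi/2 when the axes are swapped.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) < 5:
        raise EllipseFitError(f"need >= 5 points to determine an ellipse, got {len(pts)}")
    model = EllipseModel.from_estimate(pts)
    if not model:  # FailedEstimation is falsy
        raise EllipseFitError("least-squares conic fit did not yield an ellipse")
    xc, yc = (float(v) for v in model.center)
    a, b = (float(v) for v in model.axis_lengths)
    theta = float(model.theta)
    if not all(np.isfinite([xc, yc, a, b, theta])):
        raise EllipseFitError("least-squares conic fit did not yield an ellipse")
    if a <= 0 or b <= 0:
        raise EllipseFitError("degenerate ellipse (non-positive semi-axis)")
    if b > a:
        a, b = b, a
        theta += np.pi / 2.0
    theta = float(np.mod(theta, np.pi))
    e = float(np.sqrt(1.0 - (b / a) ** 2))
    return FittedEllipse(center=(xc, yc), a=a, b=b, theta=theta, e=e)


def pattern_eccentricity(
    mask,
    min_component_px: int = MIN_COMPONENT_PX,
    blur_kernel: int = BLUR_KERNEL,
    keep_largest: bool = True,
) -> FittedEllipse:
    """Convex-envelope eccentricity of a binary pattern.

    Composition of :func:`preprocess_mask`, :func:`hull_points` and
    :func:`fit_ellipse`.
    """
    clean = preprocess_mask(
        mask,
        min_component_px=min_component_px,
        blur_kernel=blur_kernel,
        keep_largest=keep_largest,
    )
    return fit_ellipse(hull_points(clean))


def fit_hp_ellipse(fold_points) -> FittedEllipse:
    """Ellipse through manually clicked hinge-pouch fold points (>= 5 clicks)."""
    return fit_ellipse(fold_points)


def overlap_nuclei_estimate(mask_a, mask_b, nucleus_px: int = NUCLEUS_PX) -> float:
    """Estimated number of nuclei positive in both channels.

    Counts pixels set in both masks and divides by the pixel area of one
    nucleus; reported fractionally (it is an estimate, not a count).
    """
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if nucleus_px <= 0:
        raise ValueError("nucleus_px must be positive")
    return float(np.logical_and(a, b).sum()) / float(nucleus_px)
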