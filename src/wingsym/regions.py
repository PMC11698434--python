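"""Intervein region partition and area quantification.

A disc pattern (binary mask) is split into intervein regions by the vein
polylines clicked between the intervein marker domains, ordered anterior to
posterior.  Each vein polyline, with its terminal segments extended, divides
the plane into an anterior and a posterior side; a pixel's region index is
the number of veins it lies posterior to.  This assigns every foreground
pixel to exactly one region — the partition is exact by construction, so
relative areas always sum to 1.  Region names follow the field convention:
M-L2 (anterior of the first vein), L2-L3, ..., L5-M (posterior of the last).

The same partition applied to a rasterized fitted ellipse gives the
reporter-independent variant, with areas relative to the true ellipse area
pi*a*b.  A shoelace polygon-area utility covers manually outlined adult-wing
regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from skimage.draw import ellipse as draw_ellipse

from .pattern import FittedEllipse

__all__ = [
    "VeinPath",
    "RegionAreaTable",
    "segment_mask_by_veins",
    "relative_region_areas",
    "ellipse_region_areas",
    "polygon_area",
]

DISC_VEINS = ("L2", "L3", "L4", "L5")
ADULT_VEINS = ("L1", "L2", "L3", "L4", "L5")


class VeinOrderError(ValueError):
    """Vein polylines are inconsistent with their anterior->posterior order."""


@dataclass
class VeinPath:
    """An ordered polyline of clicked points along one (pro-)vein."""

    name: str
    points: np.ndarray  # (k, 2) float, (x, y)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise ValueError(f"vein {self.name!r}: need >= 2 (x, y) points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"vein {self.name!r}: non-finite points")


@dataclass
class RegionAreaTable:
    """Absolute and relative areas for named intervein regions."""

    regions: tuple[str, ...]
    absolute_area: np.ndarray
    relative_area: np.ndarray
    reference: str  # "pattern" | "ellipse" | "polygon"
    reference_area: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.regions,
                "absolute_area": self.absolute_area,
                "relative_area": self.relative_area,
                "reference": self.reference,
            }
        )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.regions, self.relative_area))


def _extend_polyline(points: np.ndarray, reach: float) -> np.ndarray:
    """Extend both terminal segments outward by ``reach`` along their directions."""
    p = np.asarray(points, dtype=float)
    d0 = p[0] - p[1]
    d1 = p[-1] - p[-2]
    n0, n1 = np.hypot(*d0), np.hypot(*d1)
    if n0 < 1e-12 or n1 < 1e-12:
        raise ValueError("vein polyline has a zero-length terminal segment")
    head = p[0] + d0 / n0 * reach
    tail = p[-1] + d1 / n1 * reach
    return np.vstack([head, p, tail])


def _side_of_polyline(pts: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Signed side of each query point relative to a polyline.

    For each point the nearest location on the polyline is found; the sign of
    the 2-D cross product between the local segment direction and the vector
    to the point gives the side.  Adding collinear vertices to the polyline
    does not change the result.
    """
    seg_a = poly[:-1]  # (m, 2)
    seg_d = poly[1:] - poly[:-1]  # (m, 2)
    seg_len2 = (seg_d**2).sum(axis=1)
    # project every point on every segment: t in [0, 1]
    diff = pts[:, None, :] - seg_a[None, :, :]  # (n, m, 2)
    t = np.clip((diff * seg_d[None]).sum(axis=2) / seg_len2[None], 0.0, 1.0)
    foot = seg_a[None] + t[..., None] * seg_d[None]
    dist2 = ((pts[:, None, :] - foot) ** 2).sum(axis=2)
    nearest = np.argmin(dist2, axis=1)
    rows = np.arange(len(pts))
    d = seg_d[nearest]
    rel = pts - foot[rows, nearest]
    return d[:, 0] * rel[:, 1] - d[:, 1] * rel[:, 0]


def segment_mask_by_veins(
    mask, veins: Sequence[VeinPath], block_size: int = 65536
) -> np.ndarray:
    """Partition a binary mask into intervein regions.

    Returns an int label map of the mask's shape: 0 = background, k = region
    k (1-based, anterior to posterior; with v veins there are v+1 regions).
    Pixels exactly on a vein line count as anterior of it.  Vein polylines are
    extended beyond their clicked endpoints so they cut the whole mask.

    Raises :class:`VeinOrderError`, naming the vein, when a vein's own points
    do not lie posterior of the preceding vein — the anterior->posterior
    ordering precondition is then violated.
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("mask has no foreground pixels")
    if len(veins) == 0:
        raise ValueError("need at least one vein polyline")
    h, w = m.shape
    reach = float(np.hypot(h, w)) + 1.0
    extended = [_extend_polyline(v.points, reach) for v in veins]

    # Orientation: posterior side of vein i is the side holding the later
    # veins (the earlier veins for the last one); single vein: the right-hand
    # side of the polyline as digitized (deterministic convention; with y
    # increasing downward this is screen-right of a top-to-bottom vein).
    signs = -np.ones(len(veins))
    if len(veins) > 1:
        centroids = np.array([v.points.mean(axis=0) for v in veins])
        for i, poly in enumerate(extended):
            ref = centroids[i + 1 :] if i < len(veins) - 1 else centroids[:i]
            s = _side_of_polyline(np.atleast_2d(ref.mean(axis=0)), poly)[0]
            if s == 0.0:
                raise VeinOrderError(
                    f"vein {veins[i].name!r}: reference veins lie on the vein line; "
                    "cannot orient anterior/posterior sides"
                )
            # for the last vein the reference is anterior, so flip
            signs[i] = np.sign(s) if i < len(veins) - 1 else -np.sign(s)
        # consistency: every later vein must sit posterior of every earlier
        # one, and every earlier vein anterior of every later one
        for i in range(len(veins) - 1):
            for j in range(i + 1, len(veins)):
                s_ij = _side_of_polyline(np.atleast_2d(centroids[j]), extended[i])[0] * signs[i]
                s_ji = _side_of_polyline(np.atleast_2d(centroids[i]), extended[j])[0] * signs[j]
                if s_ij < 0 or s_ji > 0:
                    raise VeinOrderError(
                        f"vein {veins[j].name!r} is not posterior of vein "
                        f"{veins[i].name!r}: veins are not ordered anterior->posterior"
                    )

    rows, cols = np.nonzero(m)
    pts = np.column_stack([cols, rows]).astype(float)
    region = np.zeros(len(pts), dtype=np.int32)
    for poly, sign in zip(extended, signs):
        for start in range(0, len(pts), block_size):
            sl = slice(start, start + block_size)
            s = _side_of_polyline(pts[sl], poly) * sign
            region[sl] += s > 0  # strictly posterior; on-line pixels stay anterior
    labelmap = np.zeros(m.shape, dtype=np.int32)
    labelmap[rows, cols] = region + 1
    return labelmap


def _region_names(veins: Sequence[VeinPath]) -> tuple[str, ...]:
    names = [v.name for v in veins]
    return tuple(
        ["M-" + names[0]]
        + [f"{a}-{b}" for a, b in zip(names[:-1], names[1:])]
        + [names[-1] + "-M"]
    )


def relative_region_areas(
    labelmap, veins: Sequence[VeinPath] | None = None
) -> RegionAreaTable:
    """Pixel counts per region and their fractions of the total foreground.

    The partition is exact, so the relative areas sum to 1.
    """
    lm = np.asarray(labelmap)
    total = int((lm > 0).sum())
    if total == 0:
        raise ValueError("label map has no foreground pixels")
    n_regions = int(lm.max())
    counts = np.bincount(lm.ravel(), minlength=n_regions + 1)[1:].astype(float)
    if veins is not None and len(veins) + 1 >= n_regions:
        names = _region_names(veins)
        counts = np.concatenate([counts, np.zeros(len(names) - len(counts))])
    else:
        names = tuple(f"region_{k}" for k in range(1, len(counts) + 1))
    return RegionAreaTable(
        regions=names,
        absolute_area=counts,
        relative_area=counts / total,
        reference="pattern",
        reference_area=float(total),
    )


def ellipse_region_areas(
    ellipse: FittedEllipse, veins: Sequence[VeinPath], margin: int = 4
) -> RegionAreaTable:
    """Intervein areas inside a fitted ellipse, relative to pi*a*b.

    The ellipse is rasterized onto a canvas translated to fit it, the vein
    partition is applied, and pixel counts are normalized by the true ellipse
    area (so the relative areas sum to the rasterization/true-area ratio,
    within about 1% for pouch-sized ellipses).
    """
    xc, yc = ellipse.center
    half = ellipse.a + margin
    x0, y0 = int(np.floor(xc - half)), int(np.floor(yc - half))
    size = int(np.ceil(2 * half)) + 2
    canvas = np.zeros((size, size), dtype=np.uint8)
    rr, cc = draw_ellipse(
        yc - y0, xc - x0, ellipse.b, ellipse.a,
        shape=canvas.shape, rotation=-ellipse.theta,
    )
    canvas[rr, cc] = 1
    if not canvas.any():
        raise ValueError("rasterized ellipse is empty")
    shifted = [VeinPath(v.name, v.points - np.array([x0, y0])) for v in veins]
    labelmap = segment_mask_by_veins(canvas, shifted)
    counts = np.bincount(labelmap.ravel(), minlength=len(veins) + 2)[1:].astype(float)
    if counts.sum() < np.pi * ellipse.a * ellipse.b * 0.5:
        raise ValueError("veins/ellipse geometry inconsistent: most pixels unassigned")
    names = _region_names(veins)
    counts = counts[: len(names)]
    present = np.bincount(labelmap.ravel(), minlength=len(names) + 1)[1:]
    for k, name in enumerate(names):
        if present[k] == 0 and 0 < k < len(names) - 1:
            raise ValueError(f"vein {veins[k - 1].name!r} does not cross the ellipse")
    return RegionAreaTable(
        regions=names,
        absolute_area=counts,
        relative_area=counts / ellipse.area,
        reference="ellipse",
        reference_area=ellipse.area,
    )


def polygon_area(vertices) -> float:
    """Absolute shoelace area of a simple polygon, orientation-independent."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
        raise ValueError("polygon needs >= 3 (x, y) vertices")
    poly = Polygon(v)
    if not poly.is_valid:
        raise ValueError("polygon is self-intersecting or otherwise invalid")
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
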