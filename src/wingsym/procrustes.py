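"""Pairwise Procrustes superimposition and cohort-level disparity analysis.

Two configurations are compared by centering each at its centroid, scaling
each to unit root-sum-of-squares size, and rotating (orthogonal map,
reflections permitted) and rescaling the second onto the first so the sum of
squared inter-landmark distances is minimal.  That minimum is the *disparity*:
a dimensionless, symmetric measure of shape difference that is zero exactly
when the two configurations are similar figures.

Cohorts are compared exhaustively: every wing of one group against every
wing of the other (n1 x n2 ordered pairs), or all unordered pairs within one
group.  Averaging the aligned coordinate matrices over all pairs gives the
mean aligned shape per group, from which per-landmark displacements are
measured; a landmark is flagged when it moves more than twice the average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _scipy_procrustes

from .landmarks import LandmarkConfiguration, WingCohort

__all__ = [
    "ProcrustesResult",
    "DisparitySet",
    "DisplacementReport",
    "superimpose",
    "pairwise_disparities",
    "mean_aligned_shape",
    "landmark_displacements",
]


class DegenerateConfigurationError(ValueError):
    """All landmarks coincide: shape is undefined."""


@dataclass
class ProcrustesResult:
    """Aligned, standardized coordinates of both configurations plus disparity.

    ``aligned_ref`` is the first configuration centered and scaled to unit
    size; ``aligned_other`` is the second after the optimal similarity
    transform onto the first.
    """

    aligned_ref: np.ndarray
    aligned_other: np.ndarray
    disparity: float
    ref_id: str = ""
    other_id: str = ""


@dataclass
class DisparitySet:
    """All pairwise disparities for one comparison scheme."""

    values: np.ndarray
    pairing: str  # "within_cohort" | "cross_cohort"
    group_names: tuple[str, str]
    pair_ids: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ref_id": [a for a, _ in self.pair_ids],
                "other_id": [b for _, b in self.pair_ids],
                "disparity": self.values,
            }
        )


@dataclass
class DisplacementReport:
    """Per-landmark displacement between two mean aligned shapes."""

    labels: tuple[str, ...]
    per_landmark_distance: np.ndarray
    mean_distance: float
    flagged: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "distance": self.per_landmark_distance,
                "flagged": [lab in self.flagged for lab in self.labels],
            }
        )


def superimpose(
    ref: LandmarkConfiguration, other: LandmarkConfiguration
) -> ProcrustesResult:
    """Optimal similarity superimposition of ``other`` onto ``ref``.

    Both inputs must share the landmark set and label order.  Reflections are
    allowed in the orthogonal part, so the disparity is invariant to
    unrecorded wing side.
    """
    if ref.labels != other.labels:
        raise ValueError(
            f"label order mismatch between {ref.wing_id!r} and {other.wing_id!r}"
        )
    if len(ref) < 3:
        raise ValueError("need at least 3 landmarks")
    for cfg in (ref, other):
        if cfg.centroid_size() < 1e-12:
            raise DegenerateConfigurationError(
                f"wing {cfg.wing_id!r}: all landmarks coincide"
            )
    mtx1, mtx2, disparity = _scipy_procrustes(ref.coords, other.coords)
    return ProcrustesResult(
        aligned_ref=mtx1,
        aligned_other=mtx2,
        disparity=float(disparity),
        ref_id=ref.wing_id,
        other_id=other.wing_id,
    )


def pairwise_disparities(a: WingCohort, b: WingCohort | None = None) -> DisparitySet:
    """Exhaustive disparities: all n1*n2 cross pairs, or all within-a pairs."""
    if len(a) == 0:
        raise ValueError(f"cohort {a.name!r} is empty")
    if b is not None:
        if len(b) == 0:
            raise ValueError(f"cohort {b.name!r} is empty")
        pairs = list(product(a.configurations, b.configurations))
        pairing = "cross_cohort"
        names = (a.name, b.name)
    else:
        pairs = list(combinations(a.configurations, 2))
        pairing = "within_cohort"
        names = (a.name, a.name)
    values = np.empty(len(pairs))
    ids = []
    for k, (x, y) in enumerate(pairs):
        values[k] = superimpose(x, y).disparity
        ids.append((x.wing_id, y.wing_id))
    return DisparitySet(values=values, pairing=pairing, group_names=names, pair_ids=ids)


def mean_aligned_shape(
    results: Sequence[ProcrustesResult],
) -> tuple[np.ndarray, np.ndarray]:
    """Element-wise mean of aligned reference and aligned other matrices."""
    if not results:
        raise ValueError("no Procrustes results to average")
    n = results[0].aligned_ref.shape
    for r in results:
        if r.aligned_ref.shape != n:
            raise ValueError("results have differing landmark counts")
    avg_ref = np.mean([r.aligned_ref for r in results], axis=0)
    avg_other = np.mean([r.aligned_other for r in results], axis=0)
    return avg_ref, avg_other


def landmark_displacements(
    avg_ref: np.ndarray, avg_other: np.ndarray, labels: Sequence[str]
) -> DisplacementReport:
    """Per-landmark Euclidean displacement between two mean aligned shapes.

    Landmarks displaced strictly more than twice the mean displacement are
    flagged.
    """
    avg_ref = np.asarray(avg_ref, dtype=float)
    avg_other = np.asarray(avg_other, dtype=float)
    if avg_ref.shape != avg_other.shape or len(labels) != len(avg_ref):
        raise ValueError("mean shapes and labels must have equal lengths")
    dist = np.linalg.norm(avg_other - avg_ref, axis=1)
    mean = float(dist.mean())
    flagged = tuple(lab for lab, d in zip(labels, dist) if d > 2.0 * mean)
    return DisplacementReport(
        labels=tuple(labels),
        per_landmark_distance=dist,
        mean_distance=mean,
        flagged=flagged,
    )
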