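"""Anterior-posterior symmetry scoring of landmark configurations.

The AP axis of a wing is the line through the midpoints of two designated
landmark pairs (by default the pairs on veins L2 and L5).  Reflecting all
anterior landmarks across this axis and substituting them for their posterior
counterparts yields the *anteriorized* wing — a hypothetical perfectly
mirror-symmetric wing built from the anterior half; the *posteriorized* wing
is the converse.  The Procrustes disparity between a wing and its own
symmetrized images measures how far the wing departs from AP mirror symmetry:
a perfectly symmetric wing scores (0, 0), and the score grows with asymmetry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landmarks import (
    LandmarkConfiguration,
    PairedScheme,
    WingCohort,
    validate_paired_scheme,
)
from .procrustes import superimpose
from .stats import TestReport, gated_two_sample_test

__all__ = [
    "AxisLine",
    "ap_axis",
    "reflect_across_axis",
    "symmetrize",
    "symmetry_scores",
    "cohort_symmetry_comparison",
    "SymmetryComparison",
]


class DegenerateAxisError(ValueError):
    """The two axis-pair midpoints coincide: the AP axis is undefined."""


@dataclass(frozen=True)
class AxisLine:
    """A line given by a point on it and a unit direction vector."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        d = np.asarray(self.direction, dtype=float)
        norm = float(np.hypot(*d))
        if norm < 1e-12:
            raise DegenerateAxisError("axis direction is a zero vector")
        object.__setattr__(self, "direction", d / norm)


def ap_axis(config: LandmarkConfiguration, scheme: PairedScheme) -> AxisLine:
    """AP axis: the line through the two axis-pair midpoints."""
    report = validate_paired_scheme(config, scheme)
    if not report.ok:
        raise DegenerateAxisError("; ".join(report.messages))
    (a1, p1), (a2, p2) = scheme.axis_pairs
    m1 = (config.point(a1) + config.point(p1)) / 2.0
    m2 = (config.point(a2) + config.point(p2)) / 2.0
    return AxisLine(origin=m1, direction=m2 - m1)


def reflect_across_axis(p, axis: AxisLine) -> np.ndarray:
    """Mirror image of point(s) ``p`` across the axis line.

    Accepts a single (2,) point or an (n, 2) array.  The reflection drops a
    perpendicular from each point to the line and places the image at equal
    distance on the far side; it is an isometric involution.
    """
    pts = np.atleast_2d(np.asarray(p, dtype=float))
    rel = pts - axis.origin
    d = axis.direction
    proj = rel @ d
    foot = axis.origin + proj[:, None] * d
    out = 2.0 * foot - pts
    return out[0] if np.ndim(p) == 1 else out


def symmetrize(
    config: LandmarkConfiguration, scheme: PairedScheme, side: str
) -> LandmarkConfiguration:
    """Build the anteriorized or posteriorized image of a wing.

    ``side="anteriorized"``: each posterior landmark iP is replaced by the
    reflection of iA across the wing's own AP axis; ``"posteriorized"`` is the
    converse.  Unpaired landmarks, label order and labels are unchanged, so
    Procrustes correspondence with the original remains label-wise.  The axis
    is always computed from the original configuration.
    """
    if side not in ("anteriorized", "posteriorized"):
        raise ValueError(f"side must be 'anteriorized' or 'posteriorized', got {side!r}")
    axis = ap_axis(config, scheme)
    coords = config.coords.copy()
    idx = {lab: i for i, lab in enumerate(config.labels)}
    for ant, post in scheme.pairs:
        if side == "anteriorized":
            coords[idx[post]] = reflect_across_axis(config.coords[idx[ant]], axis)
        else:
            coords[idx[ant]] = reflect_across_axis(config.coords[idx[post]], axis)
    out = config.with_coords(coords)
    out.wing_id = f"{config.wing_id}:{side}"
    return out


def symmetry_scores(
    config: LandmarkConfiguration, scheme: PairedScheme
) -> tuple[float, float]:
    """(d_anteriorized, d_posteriorized): disparities of a wing to its own
    symmetrized images.  Both are zero iff the wing is AP mirror-symmetric."""
    d_ant = superimpose(config, symmetrize(config, scheme, "anteriorized")).disparity
    d_post = superimpose(config, symmetrize(config, scheme, "posteriorized")).disparity
    return d_ant, d_post


@dataclass
class SymmetryComparison:
    """Per-wing symmetry scores for two cohorts plus the gated test on each score."""

    scores: pd.DataFrame  # wing_id, cohort, d_anteriorized, d_posteriorized
    anteriorized_test: TestReport
    posteriorized_test: TestReport


def cohort_symmetry_comparison(
    controls: WingCohort,
    impaired: WingCohort,
    scheme: PairedScheme,
    alpha: float = 0.05,
) -> SymmetryComparison:
    """Score every wing in both cohorts and compare the score distributions.

    Each score type (anteriorized, posteriorized) is compared across cohorts
    with the gated normality/variance/test procedure.
    """
    if len(controls) == 0 or len(impaired) == 0:
        raise ValueError("both cohorts must be non-empty")
    rows = []
    for group_name, cohort in ((controls.name or "control", controls),
                               (impaired.name or "impaired", impaired)):
        for cfg in cohort:
            d_ant, d_post = symmetry_scores(cfg, scheme)
            rows.append(
                {
                    "wing_id": cfg.wing_id,
                    "cohort": group_name,
                    "d_anteriorized": d_ant,
                    "d_posteriorized": d_post,
                }
            )
    scores = pd.DataFrame(rows)
    groups = [controls.name or "control", impaired.name or "impaired"]
    a_mask = scores["cohort"] == groups[0]
    tests = {}
    for col in ("d_anteriorized", "d_posteriorized"):
        tests[col] = gated_two_sample_test(
            scores.loc[a_mask, col].to_numpy(),
            scores.loc[~a_mask, col].to_numpy(),
            alpha=alpha,
        )
    return SymmetryComparison(
        scores=scores,
        anteriorized_test=tests["d_anteriorized"],
        posteriorized_test=tests["d_posteriorized"],
    )
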