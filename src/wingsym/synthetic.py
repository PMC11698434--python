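"""Synthetic wings and disc phantoms with known ground truth.

Because landmark morphometrics and pattern quantification are validated here
without real micrographs, this module generates inputs whose true geometry is
known exactly:

* **Wing cohorts** — a fixed, exactly mirror-symmetric 10-point template wing
  (AP axis on the x-axis) perturbed by (i) a controllable asymmetry factor
  that pushes posterior landmarks outward from their mirror positions, most
  strongly at the posterior-margin pair (pair 5), emulating a localized
  posterior-compartment growth effect, and (ii) isotropic Gaussian landmark
  noise expressed as a fraction of the template's centroid size.
* **Disc phantoms** — a two-channel image: channel 1 is a filled ellipse of
  known semi-axes (hence known eccentricity) plus Gaussian intensity noise
  (the expression pattern); channel 2 is a bright field crossed by dark
  stripes at stated fractions of the ellipse's anterior-posterior extent (an
  intervein-marker lookalike whose inverse binarization localizes the veins).
  The ground-truth record carries the exact eccentricity and per-region pixel
  counts computed by the generator's own labeling code, independent of the
  analysis modules.

Everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landmarks import (
    LandmarkConfiguration,
    PairedScheme,
    SYM10_LABELS,
    SYM10_SCHEME,
    WingCohort,
    signed_loop_area,
)
from .regions import VeinPath, _region_names

__all__ = [
    "WingGenParams",
    "DiscPhantomParams",
    "DiscPhantom",
    "template_wing",
    "generate_wing_cohort",
    "generate_disc_phantom",
    "TEMPLATE_COORDS",
]

# Template wing: exactly mirror-symmetric about the x-axis (anterior y < 0 in
# image coordinates, posterior y > 0); ordered 1A..5A, 1P..5P.  Chosen to give
# the stored loop order positive signed area (canonical chirality).
_HALF = np.array(
    [
        [0.0, -0.6],  # 1A proximal anterior
        [2.0, -1.5],  # 2A (vein L2 pair)
        [4.5, -1.9],  # 3A (vein L3 pair)
        [7.0, -1.5],  # 4A (vein L4 pair)
        [9.0, -0.7],  # 5A distal anterior
    ]
)
TEMPLATE_COORDS: np.ndarray = np.vstack([_HALF, _HALF * np.array([1.0, -1.0])])
if signed_loop_area(TEMPLATE_COORDS, SYM10_LABELS) < 0:  # canonical handedness:
    TEMPLATE_COORDS = TEMPLATE_COORDS * np.array([1.0, -1.0])  # reflect about axis

#: Outward-displacement weight per pair; the effect peaks at pair 5
#: (posterior margin), echoing a posterior-compartment-specific growth defect.
ASYM_WEIGHTS = np.array([0.2, 0.3, 0.5, 0.75, 1.0])

DEFAULT_NOISE_SD = 0.002  # landmark noise, fraction of template centroid size


@dataclass
class WingGenParams:
    """Parameters of the synthetic wing-cohort generator."""

    n: int = 50
    asym: float = 0.2
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    cohort: str = "control"
    sex: str = "unknown"
    name: str = ""

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.asym < 0 or self.noise_sd < 0:
            raise ValueError("asym and noise_sd must be >= 0")


def template_wing(scheme: PairedScheme = SYM10_SCHEME) -> LandmarkConfiguration:
    """The fixed mirror-symmetric 10-point template wing (AP axis = x-axis)."""
    if len(scheme.pairs) != 5:
        raise ValueError("template wing is defined for a 5-pair (10-point) scheme")
    return LandmarkConfiguration(
        wing_id="template",
        coords=TEMPLATE_COORDS.copy(),
        labels=SYM10_LABELS,
        cohort="control",
        landmark_set="SYM10",
    )


def _asym_displacement(asym: float) -> np.ndarray:
    """Deterministic posterior outward displacement for the template layout."""
    disp = np.zeros_like(TEMPLATE_COORDS)
    posterior = TEMPLATE_COORDS[5:]
    # outward = away from the AP axis (the x-axis): along +/- sign of y
    disp[5:, 1] = asym * ASYM_WEIGHTS * np.abs(posterior[:, 1]) * np.sign(posterior[:, 1])
    return disp


def generate_wing_cohort(params: WingGenParams) -> WingCohort:
    """Template + asymmetry displacement + seeded isotropic Gaussian noise."""
    template = template_wing()
    disp = _asym_displacement(params.asym)
    sd = params.noise_sd * template.centroid_size()
    rng = np.random.default_rng(params.seed)
    configs = []
    for k in range(params.n):
        noise = rng.normal(0.0, sd, size=TEMPLATE_COORDS.shape) if sd > 0 else 0.0
        configs.append(
            LandmarkConfiguration(
                wing_id=f"{params.cohort}_{k}",
                coords=TEMPLATE_COORDS + disp + noise,
                labels=SYM10_LABELS,
                cohort=params.cohort,
                sex=params.sex,
                landmark_set="SYM10",
            )
        )
    return WingCohort(configurations=configs, name=params.name or params.cohort)


# ---------------------------------------------------------------------------
# Disc phantoms
# ---------------------------------------------------------------------------


@dataclass
class DiscPhantomParams:
    """Parameters of the two-channel disc phantom generator."""

    image_shape: tuple[int, int] = (512, 512)
    a: float = 200.0  # semi-major axis, pixels
    b: float = 120.0  # semi-minor axis, pixels
    theta: float = 0.0  # major-axis orientation, radians CCW from +x
    center: tuple[float, float] | None = None  # (x, y); image center if None
    vein_fractions: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    pattern_intensity: float = 200.0
    intervein_intensity: float = 180.0
    noise_sd: float = 5.0
    vein_halfwidth: float = 4.0  # half-width of dark vein stripes, pixels
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError("require a >= b > 0")
        fr = np.asarray(self.vein_fractions, dtype=float)
        if fr.ndim != 1 or np.any(fr <= 0) or np.any(fr >= 1) or np.any(np.diff(fr) <= 0):
            raise ValueError("vein_fractions must be strictly increasing within (0, 1)")

    @property
    def eccentricity(self) -> float:
        return float(np.sqrt(1.0 - (self.b / self.a) ** 2))


@dataclass
class DiscPhantom:
    """Generated phantom plus its exact ground truth."""

    pattern: np.ndarray  # channel 1, float intensities
    intervein: np.ndarray  # channel 2, float intensities
    pattern_mask: np.ndarray  # exact binary footprint of the ellipse
    veins: list[VeinPath]  # polylines at the stated fractions
    eccentricity: float
    region_counts: dict[str, int]  # generator-side exact labeling
    region_fractions: dict[str, float]
    params: DiscPhantomParams = field(repr=False, default=None)


def generate_disc_phantom(params: DiscPhantomParams) -> DiscPhantom:
    """Render the phantom and compute its ground truth by direct labeling.

    Vein stripes run perpendicular to the ellipse's major axis at the stated
    fractions of the major-axis extent (anterior edge = fraction 0).  The
    ground-truth labeling bins each in-ellipse pixel by its exact major-axis
    coordinate — a code path independent of the analysis modules.
    """
    h, w = params.image_shape
    cx, cy = params.center if params.center is not None else ((w - 1) / 2.0, (h - 1) / 2.0)
    a, b, th = params.a, params.b, params.theta

    # ellipse interior via the exact implicit equation on pixel centers
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(th) + dy * np.sin(th)  # coordinate along the major axis
    v = -dx * np.sin(th) + dy * np.cos(th)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if (
        cx - a < 0 or cx + a > w - 1 or cy - a < 0 or cy + a > h - 1
    ):  # conservative bound (rotation-safe)
        raise ValueError("ellipse exceeds image bounds")

    fr = np.asarray(params.vein_fractions, dtype=float)
    vein_u = (2.0 * fr - 1.0) * a  # major-axis coordinate of each stripe

    # ground truth: bin in-ellipse pixels by u against the stripe positions
    region_idx = np.searchsorted(vein_u, u[inside], side="left")
    names = _region_names(
        [VeinPath(f"L{k + 2}", [[0, 0], [0, 1]]) for k in range(len(fr))]
    )
    counts = np.bincount(region_idx, minlength=len(names))
    region_counts = {name: int(c) for name, c in zip(names, counts)}
    total = int(inside.sum())
    region_fractions = {name: c / total for name, c in region_counts.items()}

    rng = np.random.default_rng(params.seed)
    pattern = np.zeros((h, w))
    pattern[inside] = params.pattern_intensity
    if params.noise_sd > 0:
        pattern = np.clip(pattern + rng.normal(0, params.noise_sd, (h, w)), 0, None)

    # intervein channel: bright inside, dark stripes around each vein position
    intervein = np.zeros((h, w))
    intervein[inside] = params.intervein_intensity
    stripe = np.zeros((h, w), dtype=bool)
    for u0 in vein_u:
        stripe |= np.abs(u - u0) <= params.vein_halfwidth
    intervein[stripe & inside] = 0.1 * params.intervein_intensity
    if params.noise_sd > 0:
        intervein = np.clip(intervein + rng.normal(0, params.noise_sd, (h, w)), 0, None)

    # vein polylines: chords of the ellipse at each stripe position
    veins = []
    for k, u0 in enumerate(vein_u):
        half_v = b * np.sqrt(max(0.0, 1.0 - (u0 / a) ** 2))
        ends_uv = np.array([[u0, -half_v], [u0, half_v]])
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        ends = ends_uv @ rot.T + np.array([cx, cy])
        veins.append(VeinPath(f"L{k + 2}", ends))

    return DiscPhantom(
        pattern=pattern,
        intervein=intervein,
        pattern_mask=inside.astype(np.uint8),
        veins=veins,
        eccentricity=params.eccentricity,
        region_counts=region_counts,
        region_fractions=region_fractions,
        params=params,
    )
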