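"""End-to-end orchestration of the two analyses.

``run_adult_wing_analysis`` takes a control and a recruitment-impaired
landmark cohort and produces: the within-control and cross-cohort pairwise
Procrustes disparity sets, the mean aligned shapes with the per-landmark
displacement report, per-wing AP-symmetry scores, and gated statistical
reports comparing the cohorts.  ``run_disc_analysis`` takes disc images with
their JSON annotations (vein click points, optional hinge-pouch fold points
and background ROI) and produces region-area tables, eccentricities, and
gated cross-cohort reports.

Both entry points are deterministic given the same inputs and seed; result
bundles expose pandas DataFrames and can be written to CSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .landmarks import (
    PairedScheme,
    SYM10_SCHEME,
    WingCohort,
    canonicalize_chirality,
    read_landmarks,
)
from .pattern import (
    BACKGROUND_ROI_SIZE,
    BINARIZE_FRACTION,
    BLUR_KERNEL,
    MIN_COMPONENT_PX,
    NUCLEUS_PX,
    binarize_pattern,
    fit_hp_ellipse,
    pattern_eccentricity,
    preprocess_mask,
    project_stack,
    subtract_background,
)
from .procrustes import (
    landmark_displacements,
    mean_aligned_shape,
    pairwise_disparities,
    superimpose,
)
from .regions import (
    VeinPath,
    ellipse_region_areas,
    relative_region_areas,
    segment_mask_by_veins,
)
from .stats import gated_two_sample_test
from .symmetry import cohort_symmetry_comparison

log = logging.getLogger("wingsym")

__all__ = [
    "RunConfig",
    "run_adult_wing_analysis",
    "run_disc_analysis",
    "analyze_disc",
    "load_annotations",
    "PipelineError",
]


class PipelineError(RuntimeError):
    """Stage failure, annotated with the stage / image that failed."""


@dataclass
class RunConfig:
    """Shared knobs of both pipelines; all analysis defaults surfaced here."""

    binarize_fraction: float = BINARIZE_FRACTION
    min_component_px: int = MIN_COMPONENT_PX
    blur_kernel: int = BLUR_KERNEL
    nucleus_px: int = NUCLEUS_PX
    background_roi_size: int = BACKGROUND_ROI_SIZE
    projection_group: int = 5
    alpha: float = 0.05
    power_reps: int = 10000
    seed: int = 0
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.binarize_fraction < 1:
            raise ValueError("binarize_fraction must be in [0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_component_px < 0 or self.blur_kernel < 1:
            raise ValueError("invalid mask-cleanup parameters")
        if self.out_dir is not None:
            self.out_dir = Path(self.out_dir)


# ---------------------------------------------------------------------------
# Adult wings
# ---------------------------------------------------------------------------


@dataclass
class AdultWingResult:
    """Result bundle of the adult-wing shape/symmetry analysis."""

    within_control: pd.DataFrame
    cross_cohort: pd.DataFrame
    displacement: pd.DataFrame
    symmetry_scores: pd.DataFrame
    tests: pd.DataFrame
    sex: str = "pooled"

    def write(self, out_dir: Path, prefix: str = "wings") -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, frame in (
            ("within_control_disparities", self.within_control),
            ("cross_cohort_disparities", self.cross_cohort),
            ("landmark_displacements", self.displacement),
            ("symmetry_scores", self.symmetry_scores),
            ("tests", self.tests),
        ):
            path = out_dir / f"{prefix}_{self.sex}_{name}.csv"
            frame.to_csv(path, index=False)
            written.append(path)
        return written


def _analyze_wing_pair(
    control: WingCohort,
    impaired: WingCohort,
    scheme: PairedScheme | None,
    alpha: float,
    sex: str,
) -> AdultWingResult:
    control = WingCohort([canonicalize_chirality(c) for c in control], control.name)
    impaired = WingCohort([canonicalize_chirality(c) for c in impaired], impaired.name)

    within = pairwise_disparities(control)
    cross = pairwise_disparities(control, impaired)

    results = [
        superimpose(c, i)
        for c in control.configurations
        for i in impaired.configurations
    ]
    avg_ref, avg_other = mean_aligned_shape(results)
    displacement = landmark_displacements(avg_ref, avg_other, control.labels)

    test_rows = []
    disparity_test = gated_two_sample_test(within.values, cross.values, alpha=alpha)
    test_rows.append({"comparison": "within_vs_cross_disparity", "sex": sex,
                      **disparity_test.to_dict()})

    if scheme is not None:
        sym = cohort_symmetry_comparison(control, impaired, scheme, alpha=alpha)
        scores = sym.scores
        test_rows.append({"comparison": "anteriorized_score", "sex": sex,
                          **sym.anteriorized_test.to_dict()})
        test_rows.append({"comparison": "posteriorized_score", "sex": sex,
                          **sym.posteriorized_test.to_dict()})
    else:
        scores = pd.DataFrame(
            columns=["wing_id", "cohort", "d_anteriorized", "d_posteriorized"]
        )

    return AdultWingResult(
        within_control=within.to_frame(),
        cross_cohort=cross.to_frame(),
        displacement=displacement.to_frame(),
        symmetry_scores=scores,
        tests=pd.DataFrame(test_rows),
        sex=sex,
    )


def run_adult_wing_analysis(
    control: WingCohort | str | Path,
    impaired: WingCohort | str | Path,
    scheme: PairedScheme | None = SYM10_SCHEME,
    config: RunConfig | None = None,
    landmark_format: str = "csv",
) -> list[AdultWingResult]:
    """Full adult-wing analysis; one result bundle per sex stratum.

    Cohorts may be given as objects or as landmark-file paths.  When the sex
    field is informative the cohorts are analyzed separately per sex; wings of
    unknown sex are pooled (with a logged warning).  ``scheme`` None skips the
    symmetry scoring (e.g. for ML/VL landmark sets without an A/P pairing).
    """
    config = config or RunConfig()
    if not isinstance(control, WingCohort):
        control = read_landmarks(control, landmark_format, cohort="control", name="control")
    if not isinstance(impaired, WingCohort):
        impaired = read_landmarks(impaired, landmark_format, cohort="impaired", name="impaired")
    if len(control) == 0 or len(impaired) == 0:
        raise PipelineError("adult-wing analysis: empty cohort")

    sexes = sorted({c.sex for c in control} | {c.sex for c in impaired})
    strata: list[tuple[str, WingCohort, WingCohort]] = []
    if sexes == ["unknown"]:
        log.warning("sex not annotated; analyzing pooled cohorts")
        strata.append(("pooled", control, impaired))
    else:
        for sex in sexes:
            sub_c = [c for c in control if c.sex == sex]
            sub_i = [c for c in impaired if c.sex == sex]
            if sub_c and sub_i:
                strata.append(
                    (sex, WingCohort(sub_c, control.name), WingCohort(sub_i, impaired.name))
                )
    log.info(
        "adult-wing analysis: wingsym %s, seed=%d, alpha=%g, strata=%s",
        __version__, config.seed, config.alpha, [s for s, *_ in strata],
    )
    out = []
    for sex, c, i in strata:
        try:
            res = _analyze_wing_pair(c, i, scheme, config.alpha, sex)
        except Exception as exc:  # annotate with stage
            raise PipelineError(f"adult-wing analysis ({sex}): {exc}") from exc
        if config.out_dir is not None:
            res.write(config.out_dir)
        out.append(res)
    return out


# ---------------------------------------------------------------------------
# Wing discs
# ---------------------------------------------------------------------------


def load_annotations(path: str | Path) -> dict:
    """Load the JSON annotation sidecar.

    Schema: ``{"veins": {"L2": [[x, y], ...], ...}, "hp_folds": [[x, y], ...],
    "background_roi": [x, y]}``; ``hp_folds`` and ``background_roi`` optional.
    """
    with open(path) as fh:
        data = json.load(fh)
    if "veins" not in data or not data["veins"]:
        raise PipelineError(f"{path}: annotation file has no vein polylines")
    return data


def _veins_from_annotations(data: dict) -> list[VeinPath]:
    order = {"L1": 1, "L2": 2, "L3": 3, "L4": 4, "L5": 5}
    names = sorted(data["veins"], key=lambda n: order.get(n, 99))
    return [VeinPath(n, np.asarray(data["veins"][n], dtype=float)) for n in names]


def analyze_disc(
    image: np.ndarray,
    annotations: dict,
    config: RunConfig | None = None,
    image_id: str = "",
) -> dict:
    """Quantify one disc: pattern footprint, region areas, eccentricity.

    ``image`` is a 2-D projection or a (planes, rows, cols) stack of the
    pattern channel.  Returns a flat dict: region fractions (pattern-based
    and, when hinge-pouch folds are annotated, ellipse-based), eccentricity
    and ellipse parameters.
    """
    config = config or RunConfig()
    try:
        img = project_stack(image) if np.ndim(image) == 3 else np.asarray(image, float)
        if "background_roi" in annotations and annotations["background_roi"] is not None:
            img = subtract_background(
                img, annotations["background_roi"], config.background_roi_size
            )
        mask = binarize_pattern(img, config.binarize_fraction)
        mask = preprocess_mask(
            mask,
            min_component_px=config.min_component_px,
            blur_kernel=config.blur_kernel,
            keep_largest=True,
        )
        veins = _veins_from_annotations(annotations)
        labelmap = segment_mask_by_veins(mask, veins)
        areas = relative_region_areas(labelmap, veins)
        ell = pattern_eccentricity(
            mask, min_component_px=0, blur_kernel=1, keep_largest=False
        )
        row: dict = {"image_id": image_id}
        for region, frac in areas.as_dict().items():
            row[f"frac_{region}"] = frac
        row.update(
            xc=ell.center[0], yc=ell.center[1], a=ell.a, b=ell.b,
            theta=ell.theta, eccentricity=ell.e,
        )
        if annotations.get("hp_folds"):
            hp = fit_hp_ellipse(np.asarray(annotations["hp_folds"], dtype=float))
            hp_areas = ellipse_region_areas(hp, veins)
            for region, frac in hp_areas.as_dict().items():
                row[f"hp_frac_{region}"] = frac
            row["hp_eccentricity"] = hp.e
        return row
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"disc analysis failed for image {image_id!r}: {exc}") from exc


@dataclass
class DiscResult:
    """Result bundle of the disc-pattern analysis."""

    per_disc: pd.DataFrame
    tests: pd.DataFrame

    def write(self, out_dir: Path, prefix: str = "discs") -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, frame in (("measurements", self.per_disc), ("tests", self.tests)):
            path = out_dir / f"{prefix}_{name}.csv"
            frame.to_csv(path, index=False)
            paths.append(path)
        return paths


def run_disc_analysis(
    entries: list[dict],
    config: RunConfig | None = None,
) -> DiscResult:
    """Analyze a batch of discs and compare cohorts.

    Each entry: ``{"image": 2-D/3-D array or TIFF/PNG path, "annotations":
    dict or JSON path, "cohort": str, "image_id": str}``.  Eccentricity and
    each region fraction are compared across the two cohorts with the gated
    test when exactly two cohorts are present.
    """
    config = config or RunConfig()
    rows = []
    for entry in entries:
        image_id = entry.get("image_id", str(entry.get("image", "?")))
        image = entry["image"]
        if isinstance(image, (str, Path)):
            image = _read_image(image)
        ann = entry.get("annotations")
        if ann is None:
            raise PipelineError(f"disc {image_id!r}: missing vein annotations")
        if isinstance(ann, (str, Path)):
            ann = load_annotations(ann)
        if "veins" not in ann or not ann["veins"]:
            raise PipelineError(f"disc {image_id!r}: missing vein annotations")
        row = analyze_disc(image, ann, config, image_id=image_id)
        row["cohort"] = entry.get("cohort", "control")
        rows.append(row)
    per_disc = pd.DataFrame(rows)
    tests = []
    cohorts = sorted(per_disc["cohort"].unique())
    if len(cohorts) == 2:
        g1 = per_disc[per_disc["cohort"] == cohorts[0]]
        g2 = per_disc[per_disc["cohort"] == cohorts[1]]
        metrics = ["eccentricity"] + [
            c for c in per_disc.columns if c.startswith("frac_")
        ]
        for metric in metrics:
            if len(g1) >= 3 and len(g2) >= 3:
                rep = gated_two_sample_test(
                    g1[metric].to_numpy(), g2[metric].to_numpy(), alpha=config.alpha
                )
                tests.append(
                    {"metric": metric, "group1": cohorts[0], "group2": cohorts[1],
                     **rep.to_dict()}
                )
    result = DiscResult(per_disc=per_disc, tests=pd.DataFrame(tests))
    if config.out_dir is not None:
        result.write(config.out_dir)
    return result


def _read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))
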