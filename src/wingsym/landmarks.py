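"""Landmark domain model and I/O.

Coordinate convention (shared by every module in this package): image
coordinates with the origin at the top-left corner, ``x`` = column index,
``y`` = row index, ``y`` increasing downward.  Landmark files store plain
``(x, y)`` pairs in this frame.

A wing is a :class:`LandmarkConfiguration`: an ordered, labelled set of 2-D
points.  Labels follow the field convention for the symmetric 10-point set
("1A".."5A" anterior, "1P".."5P" posterior); a :class:`PairedScheme` records
which anterior label mirrors which posterior label and which two pairs define
the anterior-posterior (AP) axis (by default the pairs on veins L2 and L5).
"""

from __future__ import annotations

import csv
import io
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LandmarkConfiguration",
    "PairedScheme",
    "WingCohort",
    "ValidationReport",
    "SYM10_LABELS",
    "SYM10_SCHEME",
    "read_landmarks",
    "write_landmarks",
    "validate_paired_scheme",
    "crossvein_margin_points",
    "signed_loop_area",
    "canonicalize_chirality",
]

COHORTS = ("control", "impaired")
SEXES = ("male", "female", "unknown")
LANDMARK_SETS = ("ML", "VL", "SYM10", "EXT26")

#: Labels of the symmetric 10-point landmark set, anterior then posterior.
SYM10_LABELS: tuple[str, ...] = tuple(f"{i}A" for i in range(1, 6)) + tuple(
    f"{i}P" for i in range(1, 6)
)

_PAIRED_LABEL_RE = re.compile(r"^(\d+)([AP])$")


class LandmarkError(ValueError):
    """Structured error for malformed landmark data."""


@dataclass
class LandmarkConfiguration:
    """Ordered labelled 2-D landmarks for a single wing."""

    wing_id: str
    coords: np.ndarray  # (n, 2) float array, columns (x, y)
    labels: tuple[str, ...]
    cohort: str = "control"
    sex: str = "unknown"
    landmark_set: str = "SYM10"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.labels = tuple(self.labels)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise LandmarkError(
                f"wing {self.wing_id!r}: coords must be (n, 2), got {self.coords.shape}"
            )
        if len(self.labels) != len(self.coords):
            raise LandmarkError(
                f"wing {self.wing_id!r}: {len(self.coords)} points but "
                f"{len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise LandmarkError(f"wing {self.wing_id!r}: duplicate labels")
        if not np.all(np.isfinite(self.coords)):
            raise LandmarkError(f"wing {self.wing_id!r}: non-finite coordinates")
        if self.cohort not in COHORTS:
            raise LandmarkError(f"unknown cohort {self.cohort!r}")
        if self.sex not in SEXES:
            raise LandmarkError(f"unknown sex {self.sex!r}")
        if self.landmark_set not in LANDMARK_SETS:
            raise LandmarkError(f"unknown landmark set {self.landmark_set!r}")

    def __len__(self) -> int:
        return len(self.labels)

    def point(self, label: str) -> np.ndarray:
        try:
            return self.coords[self.labels.index(label)]
        except ValueError:
            raise LandmarkError(
                f"wing {self.wing_id!r}: no landmark labelled {label!r}"
            ) from None

    def with_coords(self, coords: np.ndarray) -> "LandmarkConfiguration":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def centroid_size(self) -> float:
        """Root sum of squared deviations from the centroid."""
        c = self.coords - self.coords.mean(axis=0)
        return float(np.sqrt((c**2).sum()))


@dataclass(frozen=True)
class PairedScheme:
    """Anterior/posterior label pairing defining the symmetrization.

    ``axis_pairs`` names the two pairs whose midpoints define the AP axis
    (the pairs on veins L2 and L5 in the default scheme).
    """

    pairs: tuple[tuple[str, str], ...]
    axis_pairs: tuple[tuple[str, str], tuple[str, str]]

    def __post_init__(self) -> None:
        flat = [lab for pair in self.pairs for lab in pair]
        if len(set(flat)) != len(flat):
            raise LandmarkError("paired scheme labels are not disjoint")
        for ap in self.axis_pairs:
            if tuple(ap) not in {tuple(p) for p in self.pairs}:
                raise LandmarkError(f"axis pair {ap} not among scheme pairs")

    @property
    def anterior_labels(self) -> tuple[str, ...]:
        return tuple(a for a, _ in self.pairs)

    @property
    def posterior_labels(self) -> tuple[str, ...]:
        return tuple(p for _, p in self.pairs)


#: Default scheme for the 10-point symmetric set: iA <-> iP, axis from pairs 2 and 5.
SYM10_SCHEME = PairedScheme(
    pairs=tuple((f"{i}A", f"{i}P") for i in range(1, 6)),
    axis_pairs=(("2A", "2P"), ("5A", "5P")),
)


@dataclass
class WingCohort:
    """A named list of configurations sharing one landmark set and label order."""

    configurations: list[LandmarkConfiguration]
    name: str = ""

    def __post_init__(self) -> None:
        if self.configurations:
            ref = self.configurations[0]
            for cfg in self.configurations[1:]:
                if cfg.labels != ref.labels:
                    raise LandmarkError(
                        f"cohort {self.name!r}: wing {cfg.wing_id!r} has labels "
                        f"differing from wing {ref.wing_id!r}"
                    )
                if cfg.landmark_set != ref.landmark_set:
                    raise LandmarkError(
                        f"cohort {self.name!r}: mixed landmark sets"
                    )

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)

    @property
    def labels(self) -> tuple[str, ...]:
        if not self.configurations:
            raise LandmarkError(f"cohort {self.name!r} is empty")
        return self.configurations[0].labels


@dataclass
class ValidationReport:
    """Outcome of checking a paired scheme against a configuration."""

    ok: bool
    missing_labels: list[str] = field(default_factory=list)
    degenerate_axis: bool = False
    messages: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Label / landmark-set inference
# ---------------------------------------------------------------------------


def _infer_landmark_set(labels: Sequence[str]) -> str:
    """SYM10/EXT26 when labels form complete A/P pairs, else ML."""
    pairs: dict[str, set[str]] = {}
    for lab in labels:
        m = _PAIRED_LABEL_RE.match(lab)
        if m is None:
            return "ML"
        pairs.setdefault(m.group(1), set()).add(m.group(2))
    if all(sides == {"A", "P"} for sides in pairs.values()):
        return "SYM10" if len(labels) == 10 else "EXT26" if len(labels) == 26 else "ML"
    return "ML"


def _default_labels(n: int) -> tuple[str, ...]:
    if n == 10:
        return SYM10_LABELS
    return tuple(f"p{i}" for i in range(1, n + 1))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_landmarks(
    path: str | Path,
    format: str = "csv",
    *,
    labels: Sequence[str] | None = None,
    cohort: str = "control",
    sex: str = "unknown",
    landmark_set: str | None = None,
    name: str = "",
) -> WingCohort:
    """Read a cohort of landmark configurations from TPS or CSV.

    TPS carries no labels, cohort or sex: ``labels`` (default: the 10-point
    A/P labels for 10-landmark records, generic ``p1..pn`` otherwise),
    ``cohort`` and ``sex`` apply to every record.  CSV carries everything in
    its columns ``wing_id,label,x,y,cohort,sex``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt == "tps":
        cohorts = _read_tps(path, labels, cohort, sex, landmark_set)
    elif fmt == "csv":
        cohorts = _read_csv(path, landmark_set)
    else:
        raise ValueError(f"unknown landmark format {format!r}")
    return WingCohort(configurations=cohorts, name=name or path.stem)


def _read_tps(
    path: Path,
    labels: Sequence[str] | None,
    cohort: str,
    sex: str,
    landmark_set: str | None,
) -> list[LandmarkConfiguration]:
    text = path.read_text()
    configs: list[LandmarkConfiguration] = []
    lines = [ln.strip() for ln in text.splitlines()]
    i = 0
    n_expected: int | None = None
    record_idx = 0
    while i < len(lines):
        line = lines[i]
        if not line:
            i += 1
            continue
        m = re.match(r"^LM\s*=\s*(\d+)$", line, re.IGNORECASE)
        if m is None:
            raise LandmarkError(f"{path}: expected LM= line, got {line!r} (line {i + 1})")
        n = int(m.group(1))
        i += 1
        pts = []
        while i < len(lines) and len(pts) < n:
            ln = lines[i]
            if not ln or re.match(r"^(LM|ID|IMAGE|SCALE)\s*=", ln, re.IGNORECASE):
                break
            parts = ln.split()
            if len(parts) != 2:
                raise LandmarkError(f"{path}: bad coordinate line {ln!r} (line {i + 1})")
            pts.append((float(parts[0]), float(parts[1])))
            i += 1
        if len(pts) != n:
            raise LandmarkError(
                f"{path}: record {record_idx} declares LM={n} but has "
                f"{len(pts)} coordinate lines"
            )
        wing_id = f"{path.stem}_{record_idx}"
        # optional trailing ID=/IMAGE=/SCALE= lines
        while i < len(lines):
            ln = lines[i]
            if not ln:
                i += 1
                continue
            m_id = re.match(r"^ID\s*=\s*(.*)$", ln, re.IGNORECASE)
            if m_id:
                wing_id = m_id.group(1).strip() or wing_id
                i += 1
                continue
            if re.match(r"^(IMAGE|SCALE)\s*=", ln, re.IGNORECASE):
                i += 1
                continue
            break
        if n_expected is None:
            n_expected = n
        elif n != n_expected:
            raise LandmarkError(
                f"{path}: record {record_idx} ({wing_id!r}) has LM={n}, "
                f"expected {n_expected}"
            )
        labs = tuple(labels) if labels is not None else _default_labels(n)
        if len(labs) != n:
            raise LandmarkError(f"{path}: {len(labs)} labels given for LM={n}")
        configs.append(
            LandmarkConfiguration(
                wing_id=wing_id,
                coords=np.array(pts, dtype=float),
                labels=labs,
                cohort=cohort,
                sex=sex,
                landmark_set=landmark_set or _infer_landmark_set(labs),
            )
        )
        record_idx += 1
    return configs


_CSV_COLUMNS = ("wing_id", "label", "x", "y", "cohort", "sex")


def _read_csv(path: Path, landmark_set: str | None) -> list[LandmarkConfiguration]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        missing = set(_CSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise LandmarkError(f"{path}: missing CSV columns {sorted(missing)}")
        rows = list(reader)
    by_wing: dict[str, list[dict]] = {}
    for row in rows:
        by_wing.setdefault(row["wing_id"], []).append(row)
    configs = []
    n_expected: int | None = None
    for wing_id, wrows in by_wing.items():
        labs = tuple(r["label"] for r in wrows)
        if n_expected is None:
            n_expected = len(wrows)
        elif len(wrows) != n_expected:
            raise LandmarkError(
                f"{path}: wing {wing_id!r} has {len(wrows)} landmarks, "
                f"expected {n_expected}"
            )
        coords = np.array([[float(r["x"]), float(r["y"])] for r in wrows])
        configs.append(
            LandmarkConfiguration(
                wing_id=wing_id,
                coords=coords,
                labels=labs,
                cohort=wrows[0]["cohort"],
                sex=wrows[0]["sex"],
                landmark_set=landmark_set or _infer_landmark_set(labs),
            )
        )
    return configs


def write_landmarks(cohort: WingCohort, path: str | Path, format: str = "csv") -> None:
    """Write a cohort to TPS or CSV; round-trips coordinates at full precision."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "tps":
        buf = io.StringIO()
        for cfg in cohort:
            buf.write(f"LM={len(cfg)}\n")
            for x, y in cfg.coords:
                buf.write(f"{float(x)!r} {float(y)!r}\n")
            buf.write(f"ID={cfg.wing_id}\n")
        path.write_text(buf.getvalue())
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_COLUMNS)
            for cfg in cohort:
                for lab, (x, y) in zip(cfg.labels, cfg.coords):
                    writer.writerow(
                        [cfg.wing_id, lab, repr(float(x)), repr(float(y)), cfg.cohort, cfg.sex]
                    )
    else:
        raise ValueError(f"unknown landmark format {format!r}")


# ---------------------------------------------------------------------------
# Scheme validation
# ---------------------------------------------------------------------------


def validate_paired_scheme(
    config: LandmarkConfiguration, scheme: PairedScheme
) -> ValidationReport:
    """Check that every scheme label exists and the AP axis is non-degenerate."""
    have = set(config.labels)
    missing = [lab for pair in scheme.pairs for lab in pair if lab not in have]
    report = ValidationReport(ok=True, missing_labels=missing)
    if missing:
        report.ok = False
        report.messages.append(f"labels missing from configuration: {missing}")
        return report
    (a1, p1), (a2, p2) = scheme.axis_pairs
    m1 = (config.point(a1) + config.point(p1)) / 2.0
    m2 = (config.point(a2) + config.point(p2)) / 2.0
    if np.allclose(m1, m2, rtol=0.0, atol=1e-12):
        report.ok = False
        report.degenerate_axis = True
        report.messages.append(
            f"axis-pair midpoints coincide at {tuple(m1)}: AP axis undefined"
        )
    return report


# ---------------------------------------------------------------------------
# Crossvein-derived margin landmarks
# ---------------------------------------------------------------------------


def crossvein_margin_points(
    crossvein_segment: Sequence[Sequence[float]],
    margin_polyline: Sequence[Sequence[float]],
) -> np.ndarray:
    """Intersect the infinite line through a crossvein with the wing margin.

    The crossvein is given by its two endpoints; the margin as an ordered
    polyline.  Among all intersections of the extended crossvein line with
    the margin segments, the one closest to the crossvein midpoint is
    returned (a crossvein line generally exits the wing outline twice).
    """
    seg = np.asarray(crossvein_segment, dtype=float)
    margin = np.asarray(margin_polyline, dtype=float)
    if seg.shape != (2, 2):
        raise ValueError("crossvein segment must be two 2-D points")
    if margin.ndim != 2 or margin.shape[0] < 2:
        raise ValueError("margin polyline needs at least 2 points")
    p0, p1 = seg
    d = p1 - p0
    if np.hypot(*d) < 1e-12:
        raise ValueError("crossvein segment endpoints coincide")
    mid = (p0 + p1) / 2.0
    hits: list[np.ndarray] = []
    for q0, q1 in zip(margin[:-1], margin[1:]):
        e = q1 - q0
        denom = d[0] * e[1] - d[1] * e[0]
        if abs(denom) < 1e-14:
            continue  # parallel
        # p0 + t d = q0 + u e ; intersection must lie within the margin segment
        rhs = q0 - p0
        t = (rhs[0] * e[1] - rhs[1] * e[0]) / denom
        u = (rhs[0] * d[1] - rhs[1] * d[0]) / denom
        if -1e-12 <= u <= 1.0 + 1e-12:
            hits.append(p0 + t * d)
    if not hits:
        raise LandmarkError(
            "crossvein line does not intersect the margin polyline: "
            "inconsistent annotation"
        )
    dists = [float(np.hypot(*(h - mid))) for h in hits]
    return hits[int(np.argmin(dists))]


# ---------------------------------------------------------------------------
# Chirality
# ---------------------------------------------------------------------------


def _shoelace(coords: np.ndarray) -> float:
    x, y = coords[:, 0], coords[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _loop_order(labels: Sequence[str]) -> list[int]:
    """Indices tracing the configuration as a boundary loop.

    For A/P-paired labels the loop runs along the anterior landmarks in
    ascending pair number and back along the posterior landmarks in descending
    pair number (the outline order of a paired wing); for unpaired labels the
    stored order is used.
    """
    parsed = [_PAIRED_LABEL_RE.match(lab) for lab in labels]
    if any(m is None for m in parsed):
        return list(range(len(labels)))
    ant = sorted(
        (i for i, m in enumerate(parsed) if m.group(2) == "A"),
        key=lambda i: int(parsed[i].group(1)),
    )
    post = sorted(
        (i for i, m in enumerate(parsed) if m.group(2) == "P"),
        key=lambda i: -int(parsed[i].group(1)),
    )
    return ant + post


def signed_loop_area(coords: np.ndarray, labels: Sequence[str] | None = None) -> float:
    """Shoelace signed area of the landmark loop.

    With A/P-paired ``labels`` the loop traces the wing outline (anterior side
    out, posterior side back); otherwise the points are taken in stored order.
    The sign encodes the configuration's handedness.
    """
    c = np.asarray(coords, dtype=float)
    if labels is not None:
        c = c[_loop_order(labels)]
    return _shoelace(c)


def canonicalize_chirality(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Reflect (negate y) any configuration whose outline loop is negatively
    oriented, so all wings share one handedness regardless of imaged side."""
    if signed_loop_area(config.coords, config.labels) < 0:
        flipped = config.coords.copy()
        flipped[:, 1] = -flipped[:, 1]
        return config.with_coords(flipped)
    return config
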