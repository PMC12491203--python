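"""Hip–knee cyclogram construction and morphological features.

A cyclogram (angle–angle diagram) plots the hip flexion angle (X) against
the knee flexion angle (Y) over one gait cycle; physiological traversal is
clockwise and the curve closes from the last point back to the first.
Morphological features quantify inter-joint coordination:

* perimeter ``P`` — accumulated Euclidean distance between adjacent points
  plus the closing segment, degrees;
* area ``A`` — absolute shoelace area of the closed polygon, degrees²;
* centroid — mean hip and knee angle over the cycle, degrees;
* range of motion — max minus min angle per joint, degrees.

Perimeter and area are additionally decomposed into stance- and
swing-phase contributions as partial sums of the *same* closed-figure
summation (segments assigned to the phase of their starting point, the
closing segment to swing), so stance + swing = total holds identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np

from .segmentation import GaitCycle

logger = logging.getLogger("gaitfusion.cyclogram")


@dataclass
class Cyclogram:
    """Closed hip–knee angle trajectory with per-point phase labels."""

    hip: np.ndarray
    knee: np.ndarray
    stance_mask: np.ndarray  # True = stance, contiguous prefix of the cycle
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.hip = np.asarray(self.hip, float)
        self.knee = np.asarray(self.knee, float)
        self.stance_mask = np.asarray(self.stance_mask, bool)
        if not (len(self.hip) == len(self.knee) == len(self.stance_mask)):
            raise ValueError("hip, knee and phase labels must align")

    @property
    def n(self) -> int:
        return len(self.hip)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.hip, self.knee])


def signed_area(hip: np.ndarray, knee: np.ndarray) -> float:
    """Signed shoelace area of the closed polygon (negative = clockwise)."""
    x, y = np.asarray(hip, float), np.asarray(knee, float)
    return 0.5 * float(np.sum(x * np.roll(y, -1) - y * np.roll(x, -1)))


def build_cyclogram(cycle: GaitCycle) -> Cyclogram:
    """Build the cyclogram of one normalized cycle, labelling phases.

    Point ``i`` of an ``n``-point cycle sits at cycle fraction
    ``i/(n-1)``; points up to and including the toe-off fraction are
    stance, the rest swing (a 101-point cycle with stance fraction 0.60
    yields 61 stance and 40 swing points).
    """
    n = cycle.n_points
    toe_idx = int(round(cycle.stance_fraction * (n - 1)))
    stance_mask = np.arange(n) <= toe_idx
    degenerate = bool(
        np.ptp(cycle.hip) < 1e-12 and np.ptp(cycle.knee) < 1e-12
    )
    cg = Cyclogram(cycle.hip, cycle.knee, stance_mask, degenerate=degenerate)
    if not degenerate and signed_area(cg.hip, cg.knee) > 0:
        logger.warning("counter-clockwise cyclogram: unexpected for physiological gait")
    return cg


def perimeter(points: np.ndarray) -> float:
    """Closed-polygon perimeter: adjacent distances plus the closing edge."""
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) <= 1:
        return 0.0
    d = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    return float(d.sum())


def area(points: np.ndarray) -> float:
    """Absolute shoelace area of the closed polygon (0 for n < 3)."""
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) < 3:
        return 0.0
    return abs(signed_area(pts[:, 0], pts[:, 1]))


@dataclass
class CyclogramFeatures:
    """Morphological feature vector of one cycle (or a cycle average)."""

    hip_rom: float
    knee_rom: float
    hip_com: float
    knee_com: float
    perimeter_stance: float
    perimeter_swing: float
    perimeter_total: float
    area_stance: float
    area_swing: float
    area_total: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def phase_decompose(cg: Cyclogram) -> dict[str, dict[str, float]]:
    """Stance/swing/total perimeter and area of a labelled cyclogram.

    Perimeter: each polygon edge is assigned to the phase of its starting
    point (the closing edge n→1 to swing), so the phase perimeters are
    partial sums of the total and stance + swing = total exactly.

    Area: the loop is split at the toe-off point into the stance and
    swing sub-paths, each closed by the shared chord between the
    heel-strike and toe-off points.  The chord's shoelace term enters the
    two signed sub-areas with opposite signs and cancels, so the signed
    sub-areas add to the signed total exactly; for a simple physiological
    loop both carry the traversal sign and the reported magnitudes are
    positive and additive.  (Raw partial shoelace sums are not used for
    the area: they depend on the coordinate origin and can go negative
    for a phase even on clean gait loops.)
    """
    x, y = cg.hip, cg.knee
    n = cg.n
    edge_start_is_stance = cg.stance_mask.copy()
    if n >= 1:
        edge_start_is_stance[-1] = False  # closing edge → swing

    xn, yn = np.roll(x, -1), np.roll(y, -1)
    edge_len = np.hypot(xn - x, yn - y)
    cross = 0.5 * (x * yn - y * xn)  # cross[i] is the edge i → i+1 term

    per_stance = float(edge_len[edge_start_is_stance].sum())
    per_swing = float(edge_len[~edge_start_is_stance].sum())

    total_signed = float(cross.sum())
    t = int(np.count_nonzero(cg.stance_mask)) - 1  # toe-off point index
    t = max(0, min(t, n - 1))
    chord = 0.5 * (x[t] * y[0] - x[0] * y[t])  # chord t → 0 term
    stance_signed = float(cross[:t].sum()) + chord
    swing_signed = float(cross[t:].sum()) - chord
    sign = -1.0 if total_signed < 0 else 1.0
    return {
        "perimeter": {
            "stance": per_stance,
            "swing": per_swing,
            "total": per_stance + per_swing,
        },
        "area": {
            "stance": sign * stance_signed,
            "swing": sign * swing_signed,
            "total": sign * total_signed,
        },
    }


def centroid(cycle: GaitCycle | Cyclogram) -> tuple[float, float]:
    """Mean hip and knee angle over the cycle (the cyclogram centroid)."""
    hip, knee = cycle.hip, cycle.knee
    if len(hip) == 0:
        raise ValueError("empty cycle")
    return float(np.mean(hip)), float(np.mean(knee))


def range_of_motion(cycle: GaitCycle | Cyclogram) -> tuple[float, float]:
    """Hip and knee range of motion: max angle minus min angle."""
    hip, knee = cycle.hip, cycle.knee
    if len(hip) == 0:
        raise ValueError("empty cycle")
    return float(np.ptp(hip)), float(np.ptp(knee))


def cycle_features(cycle: GaitCycle) -> CyclogramFeatures:
    """All morphological features of a single gait cycle."""
    cg = build_cyclogram(cycle)
    hip_rom, knee_rom = range_of_motion(cycle)
    hip_com, knee_com = centroid(cycle)
    parts = phase_decompose(cg)
    return CyclogramFeatures(
        hip_rom=hip_rom,
        knee_rom=knee_rom,
        hip_com=hip_com,
        knee_com=knee_com,
        perimeter_stance=parts["perimeter"]["stance"],
        perimeter_swing=parts["perimeter"]["swing"],
        perimeter_total=parts["perimeter"]["total"],
        area_stance=parts["area"]["stance"],
        area_swing=parts["area"]["swing"],
        area_total=parts["area"]["total"],
    )


def aggregate_features(
    cycles: list[GaitCycle], how: str = "mean"
) -> CyclogramFeatures:
    """Per-subject features: mean (or median) over the selected cycles."""
    if not cycles:
        raise ValueError("need at least one cycle to aggregate")
    if how not in ("mean", "median"):
        raise ValueError(f"unknown aggregation {how!r}")
    per_cycle = [cycle_features(c).as_dict() for c in cycles]
    agg = np.mean if how == "mean" else np.median
    names = per_cycle[0].keys()
    return CyclogramFeatures(
        **{k: float(agg([d[k] for d in per_cycle])) for k in names}
    )
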