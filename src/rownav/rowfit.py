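"""Crop-row line fitting and central navigation-line construction.

Plant detections (axis-aligned boxes) are reduced to their centre points,
assigned to the left or right crop row, screened for missing-plant gaps, and
fitted with a weighted least-squares line per row.  The navigation line a
weeding implement should follow is the angle bisector of the two row lines
through their intersection (vanishing) point:

    m_c = tan((arctan m1 + arctan m2) / 2),    b_c = y_i - m_c * x_i.

Weighting: a preliminary unweighted fit defines the row axis; each point then
receives a Gaussian weight w_i = exp(-d_i^2 / (2 sigma^2)) in its
perpendicular distance d_i, with sigma the MAD-scaled residual spread.  Off-
row detections (weeds, straw) are thereby down-weighted without a hard
inlier threshold.

Rows in forward-facing field images are near-vertical, so y = mx + b is
ill-conditioned; fits are performed as x = m'y + b' whenever the x-variance
of a row is small relative to its y-variance, and the parameters are mapped
back to slope/intercept form for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Detection",
    "PlantPoint",
    "RowAssignment",
    "GapReport",
    "FittedLine",
    "NavigationLine",
    "RowFitConfig",
    "RowFitResult",
    "centers_from_detections",
    "assign_rows",
    "detect_gaps",
    "compute_weights",
    "weighted_least_squares",
    "navigation_line",
    "fit_rows_pipeline",
]

PARALLEL_SLOPE_TOL = 1e-9


@dataclass(frozen=True)
class Detection:
    """Axis-aligned box in pixel corner coordinates (origin top-left, y down)."""

    x1: float
    y1: float
    x2: float
    y2: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.x1, self.y1, self.x2, self.y2))):
            raise ValueError("box coordinates must be finite")
        if self.x2 <= self.x1 or self.y2 <= self.y1:
            raise ValueError(f"box must have positive area: {self}")

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x1 + self.x2) / 2.0, (self.y1 + self.y2) / 2.0)

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1


@dataclass
class PlantPoint:
    x: float
    y: float
    weight: float = 1.0
    gap_flag: bool = False


@dataclass
class RowAssignment:
    left: list[PlantPoint]
    right: list[PlantPoint]
    discarded: list[PlantPoint] = field(default_factory=list)


@dataclass
class GapReport:
    """Inter-plant spacing audit for one row.

    ``points`` are sorted by y ascending (ties by x); ``distances[i]`` is the
    vertical separation |y_{i+1} - y_i|; ``flagged`` holds the indices (into
    the sorted list) of points that start a suspected missing-plant gap.
    """

    d_thresh: float
    points: list[PlantPoint] = field(default_factory=list)
    distances: list[float] = field(default_factory=list)
    flagged: list[int] = field(default_factory=list)


@dataclass
class FittedLine:
    m: float
    b: float
    form: str = "y_of_x"          # fitting form actually used internally
    n_points: int = 0
    residual_sum: float = 0.0

    def y_at(self, x: float) -> float:
        return self.m * x + self.b


@dataclass
class NavigationLine:
    m1: float
    b1: float
    m2: float
    b2: float
    mc: float
    bc: float
    xi: float | None = None
    yi: float | None = None
    parallel: bool = False


@dataclass(frozen=True)
class RowFitConfig:
    image_width: float = 640.0
    image_height: float = 640.0
    d_thresh: float = 50.0        # px; vertical spacing above this flags a gap
    drop_gap_points: bool = False
    margin_frac: float = 0.05     # outer image margin discarded before row split
    sigma_min: float = 1.0        # px; floor for the robust residual scale
    use_weights: bool = True


@dataclass
class RowFitResult:
    nav: NavigationLine
    left_line: FittedLine
    right_line: FittedLine
    left_gaps: GapReport
    right_gaps: GapReport
    assignment: RowAssignment


def centers_from_detections(dets: list[Detection]) -> list[PlantPoint]:
    """Box midpoints as fitting primitives, order preserved, unit weights."""
    return [PlantPoint(*d.center) for d in dets]


def assign_rows(
    points: list[PlantPoint],
    image_width: float,
    image_height: float,
    margin_frac: float = 0.05,
) -> RowAssignment:
    """Partition centre points into left/right rows.

    Points in the outer ``margin_frac`` band of the image are discarded
    (peripheral plants outside the working corridor); the rest split at the
    vertical midline.
    """
    mx = margin_frac * image_width
    my = margin_frac * image_height
    mid = image_width / 2.0
    out = RowAssignment(left=[], right=[])
    for p in points:
        if not (mx <= p.x <= image_width - mx and my <= p.y <= image_height - my):
            out.discarded.append(p)
        elif p.x < mid:
            out.left.append(p)
        else:
            out.right.append(p)
    return out


def detect_gaps(points: list[PlantPoint], d_thresh: float) -> GapReport:
    """Flag suspected missing plants from within-row vertical spacing.

    After sorting by y (ties by x), point i+1 is flagged whenever the
    vertical distance D_{i,i+1} = |y_{i+1} - y_i| exceeds ``d_thresh``: it is
    the starting point downstream of a gap.  The flag is advisory — a gap
    start is a real plant — and fitting retains flagged points unless
    configured otherwise.
    """
    if d_thresh <= 0:
        raise ValueError("d_thresh must be positive")
    ordered = sorted(points, key=lambda p: (p.y, p.x))
    report = GapReport(d_thresh=d_thresh, points=ordered)
    if len(ordered) < 2:
        return report
    for i in range(len(ordered) - 1):
        d = abs(ordered[i + 1].y - ordered[i].y)
        report.distances.append(d)
        if d > d_thresh:
            report.flagged.append(i + 1)
            ordered[i + 1].gap_flag = True
    return report


def _perpendicular_distances(points: list[PlantPoint], line: FittedLine) -> np.ndarray:
    xs = np.array([p.x for p in points])
    ys = np.array([p.y for p in points])
    # distance to y = mx + b: |mx - y + b| / sqrt(m^2 + 1)
    return np.abs(line.m * xs - ys + line.b) / math.hypot(line.m, 1.0)


def compute_weights(
    points: list[PlantPoint],
    reference: FittedLine,
    sigma_min: float = 1.0,
) -> list[PlantPoint]:
    """Gaussian down-weighting of points far from the row axis (in place).

    w_i = exp(-d_i^2 / (2 sigma^2)) with d_i the perpendicular distance to the
    preliminary fit and sigma = max(1.4826 * median|d_i|, sigma_min) — the
    usual MAD-to-standard-deviation scaling with a floor so collinear rows do
    not collapse sigma to zero.
    """
    if not points:
        return points
    d = _perpendicular_distances(points, reference)
    sigma = max(1.4826 * float(np.median(d)), sigma_min)
    w = np.exp(-(d**2) / (2.0 * sigma**2))
    for p, wi in zip(points, w):
        p.weight = float(wi)
    return points


def _solve_wls(u: np.ndarray, v: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Weighted normal equations for v = m*u + b; returns (m, b, S)."""
    A = np.array([[np.sum(w * u * u), np.sum(w * u)],
                  [np.sum(w * u), np.sum(w)]])
    rhs = np.array([np.sum(w * u * v), np.sum(w * v)])
    # rank check: weighted variance of u must be positive
    wsum = float(np.sum(w))
    ubar = float(np.sum(w * u)) / wsum
    if np.sum(w * (u - ubar) ** 2) <= 1e-12 * max(1.0, float(np.sum(w * u * u))):
        raise ValueError("degenerate geometry: no spread along the fitting axis")
    m, b = np.linalg.solve(A, rhs)
    S = float(np.sum(w * (v - (m * u + b)) ** 2))
    return float(m), float(b), S


def weighted_least_squares(points: list[PlantPoint], form: str = "auto") -> FittedLine:
    """Fit a line to weighted points by solving the 2x2 normal equations.

    With ``form="y_of_x"`` this minimises S = sum_i w_i (y_i - (m x_i + b))^2.
    Rows in forward-facing images are near-vertical, making that form
    ill-conditioned, so ``form="auto"`` (the default) fits x = m'y + b'
    instead whenever the x-spread is below 10% of the y-spread, then converts
    back; the reported (m, b) is always in y-of-x form.  An exactly vertical
    row has no such form and raises.
    """
    if form not in ("auto", "y_of_x", "x_of_y"):
        raise ValueError(f"unknown fitting form {form!r}")
    active = [p for p in points if p.weight > 0]
    if len(active) < 2:
        raise ValueError("need at least 2 points with positive weight")
    x = np.array([p.x for p in active])
    y = np.array([p.y for p in active])
    w = np.array([p.weight for p in active])
    if form == "auto":
        # Spread compared via MAD so a single off-row outlier cannot flip a
        # near-vertical row into the ill-conditioned y-of-x form.
        def _mad(v: np.ndarray) -> float:
            return float(np.median(np.abs(v - np.median(v))))
        sx, sy = _mad(x), _mad(y)
        if sx == 0.0 and sy == 0.0:
            sx, sy = float(np.var(x)), float(np.var(y))
        swap = sx**2 < 0.1 * sy**2
    else:
        swap = form == "x_of_y"
    if not swap:
        m, b, S = _solve_wls(x, y, w)
        return FittedLine(m=m, b=b, form="y_of_x", n_points=len(active), residual_sum=S)
    mp, bp, S = _solve_wls(y, x, w)
    if mp == 0.0:
        raise ValueError("degenerate geometry: exactly vertical row has no y=mx+b form")
    # x = m'y + b'  <=>  y = x/m' - b'/m'
    return FittedLine(m=1.0 / mp, b=-bp / mp, form="x_of_y",
                      n_points=len(active), residual_sum=S)


def navigation_line(line_l: FittedLine, line_r: FittedLine) -> NavigationLine:
    """Central navigation line between two fitted row lines.

    The centre slope is the tangent of the mean of the two line angles (the
    angle bisector), anchored at the rows' intersection point.  Parallel rows
    (slope difference below 1e-9) take the midline between the intercepts.
    """
    m1, b1, m2, b2 = line_l.m, line_l.b, line_r.m, line_r.b
    mc = math.tan((math.atan(m1) + math.atan(m2)) / 2.0)
    if abs(m1 - m2) < PARALLEL_SLOPE_TOL:
        return NavigationLine(m1=m1, b1=b1, m2=m2, b2=b2,
                              mc=m1, bc=(b1 + b2) / 2.0, parallel=True)
    xi = (b2 - b1) / (m1 - m2)
    yi = m1 * xi + b1
    bc = yi - mc * xi
    return NavigationLine(m1=m1, b1=b1, m2=m2, b2=b2, mc=mc, bc=bc, xi=xi, yi=yi)


def _fit_one_row(points: list[PlantPoint], name: str, cfg: RowFitConfig) -> tuple[FittedLine, GapReport]:
    gaps = detect_gaps(points, cfg.d_thresh)
    usable = [p for p in gaps.points if not (cfg.drop_gap_points and p.gap_flag)]
    if len(usable) < 2:
        raise ValueError(f"{name} row has fewer than 2 usable points")
    for p in usable:
        p.weight = 1.0
    preliminary = weighted_least_squares(usable)
    if cfg.use_weights:
        compute_weights(usable, preliminary, sigma_min=cfg.sigma_min)
        line = weighted_least_squares(usable)
    else:
        line = preliminary
    return line, gaps


def fit_rows_pipeline(dets: list[Detection], cfg: RowFitConfig | None = None) -> RowFitResult:
    """Detections -> centres -> row split -> gap audit -> weighted fits -> navigation line."""
    cfg = cfg or RowFitConfig()
    points = centers_from_detections(dets)
    assignment = assign_rows(points, cfg.image_width, cfg.image_height, cfg.margin_frac)
    left_line, left_gaps = _fit_one_row(assignment.left, "left", cfg)
    right_line, right_gaps = _fit_one_row(assignment.right, "right", cfg)
    nav = navigation_line(left_line, right_line)
    return RowFitResult(nav=nav, left_line=left_line, right_line=right_line,
                        left_gaps=left_gaps, right_gaps=right_gaps,
                        assignment=assignment)
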