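"""Neuronal morphometry from soma outlines.

Each manually (or synthetically) delineated soma outline is reduced to an
equivalent ellipse via its polygon moments: the ellipse shares the
polygon's area (shoelace formula, exact) and central second moments, and
its axes come from the moment eigenvalues.  Shape is summarized as
roundness = 4*area / (pi * major_axis^2), which equals minor/major for an
exact ellipse.  Soma position is expressed as normalized cortical depth
(0 = white-matter interface, 1 = pial surface) by projecting the centroid
onto the axis between the two annotated boundary polylines.  Group
comparisons pool all cells of all specimens and t-test area and roundness
within two depth zones (Zone I: 0.7-0.9, Zone II: 0.2-0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import LineString, Point

from .core import CalnetError
from .metrics import cohens_d
from .synthetic import ZONES

__all__ = [
    "EllipseFit",
    "fit_ellipse",
    "roundness",
    "circularity",
    "normalized_depth",
    "compute_morphometry",
    "density_profile",
    "zone_comparison",
]

logger = logging.getLogger(__name__)


@dataclass
class EllipseFit:
    area: float            # polygon area (um^2), shoelace, exact
    major: float           # full major axis length (um)
    minor: float           # full minor axis length (um)
    centroid: np.ndarray   # (2,)
    orientation: float     # radians, major-axis angle in (-pi/2, pi/2]
    perimeter: float


def _polygon_moments(pts: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Signed area, centroid and central second-moment matrix of a polygon.

    Standard Green's-theorem formulas over the closed vertex loop; the
    second-moment matrix is the covariance of the uniform density over the
    polygon interior.
    """
    x, y = pts[:, 0], pts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * cross.sum()
    if a == 0:
        raise CalnetError("degenerate polygon (zero area)")
    cx = ((x + x1) * cross).sum() / (6 * a)
    cy = ((y + y1) * cross).sum() / (6 * a)
    # second moments about the origin
    sxx = ((x * x + x * x1 + x1 * x1) * cross).sum() / 12
    syy = ((y * y + y * y1 + y1 * y1) * cross).sum() / 12
    sxy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24
    # central covariance of the interior (divide by area, shift to centroid)
    cov = np.array(
        [
            [sxx / a - cx * cx, sxy / a - cx * cy],
            [sxy / a - cx * cy, syy / a - cy * cy],
        ]
    )
    return a, np.array([cx, cy]), cov


def fit_ellipse(outline: np.ndarray, cell_id: str = "?") -> EllipseFit:
    """Moment-equivalent ellipse of a soma outline polygon.

    The fitted area is the polygon's shoelace area exactly; the axes are
    derived from the eigenvalues of the central second-moment matrix (for a
    solid ellipse the eigenvalues are (semi-axis)^2 / 4, so the full axes
    are 4*sqrt(eigenvalue)).
    """
    pts = np.asarray(outline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise CalnetError(f"cell {cell_id}: outline must be >= 3 (x, y) vertices")
    try:
        a, centroid, cov = _polygon_moments(pts)
    except CalnetError as err:
        raise CalnetError(f"cell {cell_id}: {err}") from None
    area = abs(a)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0:
        raise CalnetError(f"cell {cell_id}: degenerate (collinear) outline")
    major = 4.0 * np.sqrt(evals[1])
    minor = 4.0 * np.sqrt(evals[0])
    vx, vy = evecs[:, 1]
    orientation = float(np.arctan2(vy, vx))
    if orientation <= -np.pi / 2:
        orientation += np.pi
    elif orientation > np.pi / 2:
        orientation -= np.pi
    closed = np.vstack([pts, pts[:1]])
    perimeter = float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())
    return EllipseFit(
        area=float(area),
        major=float(major),
        minor=float(minor),
        centroid=centroid,
        orientation=orientation,
        perimeter=perimeter,
    )


def roundness(fit: EllipseFit) -> float:
    """Roundness = 4*area / (pi * major^2); equals minor/major for ellipses."""
    if fit.major <= 0:
        raise CalnetError("major axis must be positive")
    return float(4.0 * fit.area / (np.pi * fit.major**2))


def circularity(fit: EllipseFit) -> float:
    """Alternative shape index 4*pi*area / perimeter^2 (not the default)."""
    if fit.perimeter <= 0:
        raise CalnetError("perimeter must be positive")
    return float(4.0 * np.pi * fit.area / fit.perimeter**2)


def normalized_depth(
    centroid: np.ndarray,
    wm_line: np.ndarray,
    pial_line: np.ndarray,
) -> tuple[float, bool]:
    """Normalized cortical depth of a centroid between two boundary polylines.

    Depth is the centroid's distance to the white-matter polyline divided by
    the local cortical thickness (distance to white matter + distance to
    pia), so a point on the white-matter line maps to 0, a point on the pial
    line to 1 and the midpoint to 0.5.  Values are clamped to [0, 1]; the
    second return value flags centroids that were out of range before
    clamping (both distances cannot place the point between the lines).
    """
    wm = LineString(np.asarray(wm_line, dtype=float))
    pial = LineString(np.asarray(pial_line, dtype=float))
    if wm.equals(pial) or wm.distance(pial) == 0 and wm.intersects(pial):
        raise CalnetError("white-matter and pial boundaries coincide or cross")
    p = Point(np.asarray(centroid, dtype=float))
    d_wm = p.distance(wm)
    d_pial = p.distance(pial)
    total = d_wm + d_pial
    if total == 0:
        raise CalnetError("boundaries coincide at the centroid")
    thickness = wm.distance(pial)
    # a point between the lines satisfies d_wm + d_pial ~= local thickness;
    # outside, one distance exceeds the thickness and the point clamps to
    # the boundary it lies beyond
    out_of_range = thickness > 0 and total > thickness * 1.05
    if out_of_range:
        depth = 1.0 if d_wm > d_pial else 0.0
    else:
        depth = d_wm / total
    return float(np.clip(depth, 0.0, 1.0)), bool(out_of_range)


def _zone_of(depth: float) -> str:
    for name, (lo, hi) in ZONES.items():
        if lo <= depth <= hi:
            return name
    return "none"


def compute_morphometry(
    outlines: dict[str, np.ndarray],
    wm_line: np.ndarray,
    pial_line: np.ndarray,
    subject: str = "s0",
) -> pd.DataFrame:
    """Per-cell morphometry table from outlines plus boundary annotations."""
    rows = []
    for cell_id, outline in outlines.items():
        fit = fit_ellipse(outline, cell_id=cell_id)
        depth, flagged = normalized_depth(fit.centroid, wm_line, pial_line)
        rows.append(
            {
                "cell_id": cell_id,
                "subject": subject,
                "area": fit.area,
                "roundness": roundness(fit),
                "major_axis": fit.major,
                "minor_axis": fit.minor,
                "depth": depth,
                "depth_out_of_range": flagged,
                "zone": _zone_of(depth),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["roundness_convention"] = "4*area/(pi*major^2)"
    return df


def density_profile(
    depths_by_subject: dict[str, np.ndarray], n_bins: int = 10
) -> pd.DataFrame:
    """Cell counts per depth bin: per-subject histogram, then mean +/- SE.

    With a single subject the standard error is reported as NaN.
    """
    if not depths_by_subject:
        raise CalnetError("need at least one subject")
    edges = np.linspace(0, 1, n_bins + 1)
    hists = np.stack(
        [
            np.histogram(np.asarray(d, dtype=float), bins=edges)[0]
            for d in depths_by_subject.values()
        ]
    )
    n_subjects = hists.shape[0]
    mean = hists.mean(axis=0)
    se = (
        hists.std(axis=0, ddof=1) / np.sqrt(n_subjects)
        if n_subjects > 1
        else np.full(n_bins, np.nan)
    )
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "mean_count": mean,
            "se_count": se,
            "n_subjects": n_subjects,
        }
    )


def zone_comparison(
    group_a: pd.DataFrame, group_b: pd.DataFrame
) -> pd.DataFrame:
    """Pooled-cell zone-wise group comparison of area and roundness.

    For each zone (I: depth 0.7-0.9, II: 0.2-0.5) and each descriptor, a
    two-sample Student's t-test over the pooled cells of each group plus
    Cohen's d.  Zones empty in either group are skipped with a log entry;
    fewer than two cells per group in a populated zone is an error.
    """
    rows = []
    for zone, (lo, hi) in ZONES.items():
        sub_a = group_a[(group_a["depth"] >= lo) & (group_a["depth"] <= hi)]
        sub_b = group_b[(group_b["depth"] >= lo) & (group_b["depth"] <= hi)]
        if sub_a.empty or sub_b.empty:
            logger.warning("zone %s empty in one group; test skipped", zone)
            continue
        if len(sub_a) < 2 or len(sub_b) < 2:
            raise CalnetError(
                f"zone {zone}: need at least 2 cells per group "
                f"(got {len(sub_a)} and {len(sub_b)})"
            )
        for descriptor in ("area", "roundness"):
            xa = sub_a[descriptor].to_numpy()
            xb = sub_b[descriptor].to_numpy()
            t, p = stats.ttest_ind(xa, xb)
            rows.append(
                {
                    "zone": zone,
                    "descriptor": descriptor,
                    "n_a": len(xa),
                    "n_b": len(xb),
                    "mean_a": float(xa.mean()),
                    "mean_b": float(xb.mean()),
                    "t": float(t),
                    "p": float(p),
                    "cohens_d": cohens_d(xa, xb),
                }
            )
    return pd.DataFrame(rows)
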