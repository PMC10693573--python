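"""Per-element morphometric features and global tissue attributes.

Pore features: area (shoelace), equivalent-disc radius, length (maximum
Feret diameter, a deviation-from-circularity proxy), mean absolute rim
curvature on an arc-length-resampled and lightly smoothed boundary, and rim
tortuosity (boundary perimeter over convex-hull perimeter, >= 1 by
construction).  Vessel features: arc-length-weighted mean diameter and
segment length between splits.  Global attributes: vessel centerline length
per area, pore count per area and pore filling factor.

All outputs are physical (um-based) so 2X and 4X ensembles share axes.
Alternative definitions of "length" (ellipse major axis, skeleton length)
exist in the literature; the max-Feret choice is isolated in
:func:`max_feret_diameter` for easy substitution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

__all__ = [
    "PoreFeatures",
    "VesselFeatures",
    "GlobalAttributes",
    "pore_features",
    "vessel_features",
    "global_attributes",
    "polygon_area",
    "max_feret_diameter",
    "resample_closed_boundary",
]

N_BOUNDARY_POINTS = 128          # resampled points before curvature
SMOOTH_FRACTION = 0.05           # smoothing window as fraction of perimeter


@dataclass
class PoreFeatures:
    area: float                  # um^2
    equivalent_radius: float     # um
    length: float                # um, max Feret diameter
    curvature: float             # 1/um, mean |kappa| along the rim
    tortuosity: float            # dimensionless, >= 1


@dataclass
class VesselFeatures:
    diameter: float              # um, arc-weighted mean
    segment_length: float        # um


@dataclass
class GlobalAttributes:
    vessel_density: float        # mm / mm^2 (centerline length per area)
    pore_number_density: float   # 1 / mm^2
    pore_filling_factor: float   # dimensionless fraction


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _close(poly: np.ndarray) -> np.ndarray:
    poly = np.asarray(poly, dtype=float)
    if np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    return poly


def polygon_area(poly: np.ndarray) -> float:
    """Shoelace area of a closed polygon (vertices in order, any orientation)."""
    p = _close(poly)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_perimeter(poly: np.ndarray) -> float:
    p = _close(poly)
    return float(np.sum(np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1)))


def polygon_centroid(poly: np.ndarray) -> np.ndarray:
    """Area-weighted centroid of a closed polygon (shoelace moments)."""
    p = _close(poly)
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-12:
        return p.mean(axis=0)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def _segments_intersect(p, q, r, s) -> bool:
    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])
    d1, d2 = cross(p, q, r), cross(p, q, s)
    d3, d4 = cross(r, s, p), cross(r, s, q)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def is_simple_polygon(poly: np.ndarray) -> bool:
    """True if no two non-adjacent edges cross (O(n^2); boundaries are short)."""
    p = _close(poly)
    n = len(p)
    for i in range(n):
        a, b = p[i], p[(i + 1) % n]
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            c, d = p[j], p[(j + 1) % n]
            if _segments_intersect(a, b, c, d):
                return False
    return True


def max_feret_diameter(poly: np.ndarray) -> float:
    """Maximum caliper diameter: largest pairwise distance of hull vertices."""
    p = _close(poly)
    if len(p) >= 4:
        try:
            p = p[ConvexHull(p).vertices]
        except Exception:
            pass
    d2 = np.sum((p[:, None, :] - p[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def min_feret_diameter(poly: np.ndarray) -> float:
    """Minimum caliper width via rotating the hull through its edge normals."""
    p = _close(poly)
    try:
        hull = p[ConvexHull(p).vertices]
    except Exception:
        hull = p
    edges = np.roll(hull, -1, axis=0) - hull
    ang = np.arctan2(edges[:, 1], edges[:, 0])
    widths = []
    for a in ang:
        rot = np.array([[np.cos(-a), -np.sin(-a)], [np.sin(-a), np.cos(-a)]])
        r = hull @ rot.T
        widths.append(np.ptp(r[:, 1]))
    return float(min(widths)) if widths else 0.0


def resample_closed_boundary(poly: np.ndarray, n: int = N_BOUNDARY_POINTS) -> np.ndarray:
    """Resample a closed boundary to ``n`` points equidistant in arc length."""
    p = _close(poly)
    p = np.vstack([p, p[:1]])
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate boundary: zero perimeter")
    si = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(si, s, p[:, 0])
    y = np.interp(si, s, p[:, 1])
    return np.column_stack([x, y])


def _smooth_closed(points: np.ndarray, window: int) -> np.ndarray:
    """Circular moving-average smoothing of a closed point sequence."""
    if window < 3:
        return points
    if window % 2 == 0:
        window += 1
    kernel = np.ones(window) / window
    out = np.empty_like(points)
    for k in (0, 1):
        padded = np.concatenate([points[-(window // 2):, k], points[:, k],
                                 points[: window // 2, k]])
        out[:, k] = np.convolve(padded, kernel, mode="valid")
    return out


def _mean_abs_curvature(points: np.ndarray) -> float:
    """Mean |kappa| of a closed curve sampled uniformly in arc length."""
    x, y = points[:, 0], points[:, 1]
    dx = (np.roll(x, -1) - np.roll(x, 1)) / 2.0
    dy = (np.roll(y, -1) - np.roll(y, 1)) / 2.0
    ddx = np.roll(x, -1) - 2 * x + np.roll(x, 1)
    ddy = np.roll(y, -1) - 2 * y + np.roll(y, 1)
    denom = (dx * dx + dy * dy) ** 1.5
    denom = np.where(denom <= 0, np.inf, denom)
    kappa = np.abs(dx * ddy - dy * ddx) / denom
    ds = np.sqrt(dx * dx + dy * dy)
    return float(np.sum(np.abs(kappa) * ds) / np.sum(ds))


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def pore_features(boundary_polygon: np.ndarray, pixel_size: float = 1.0,
                  check_simple: bool = True) -> PoreFeatures:
    """Morphometric features of one pore from its closed boundary polygon.

    ``boundary_polygon`` is (N, 2) in pixel coordinates (or um when
    ``pixel_size`` is 1); N >= 8.  Raises on self-intersecting or degenerate
    polygons.
    """
    poly = _close(np.asarray(boundary_polygon, float)) * float(pixel_size)
    if len(poly) < 8:
        raise ValueError(f"polygon needs >= 8 vertices, got {len(poly)}")
    area = polygon_area(poly)
    if area <= 0:
        raise ValueError("degenerate polygon: zero area")
    if check_simple and len(poly) <= 512 and not is_simple_polygon(poly):
        raise ValueError("self-intersecting polygon")

    res = resample_closed_boundary(poly)
    window = max(3, int(round(SMOOTH_FRACTION * len(res))))
    smooth = _smooth_closed(res, window)

    perim = polygon_perimeter(smooth)
    try:
        hull_perim = polygon_perimeter(smooth[ConvexHull(smooth).vertices])
    except Exception:
        hull_perim = perim
    return PoreFeatures(
        area=float(area),
        equivalent_radius=float(np.sqrt(area / np.pi)),
        length=max_feret_diameter(poly),
        curvature=_mean_abs_curvature(smooth),
        tortuosity=max(1.0, perim / hull_perim),
    )


def vessel_features(centerline: np.ndarray, widths: np.ndarray,
                    pixel_size: float = 1.0) -> VesselFeatures:
    """Mean diameter (arc-length weighted) and length of one vessel segment."""
    line = np.asarray(centerline, float) * float(pixel_size)
    w = np.asarray(widths, float) * float(pixel_size)
    if len(line) < 2:
        raise ValueError("centerline needs at least 2 points")
    if np.any(w <= 0):
        raise ValueError("vessel widths must be positive")
    seg = np.linalg.norm(np.diff(line, axis=0), axis=1)
    length = float(np.sum(seg))
    if length <= 0:
        raise ValueError("degenerate centerline: zero length")
    mid_w = 0.5 * (w[:-1] + w[1:])
    return VesselFeatures(diameter=float(np.sum(mid_w * seg) / length),
                          segment_length=length)


def global_attributes(n_pores: int, total_pore_area_um2: float,
                      total_vessel_length_um: float,
                      analyzed_area_um2: float) -> GlobalAttributes:
    """Specimen-level attributes over the total analyzed (in-focus) area.

    Totals over all images of the specimen divided by the total analyzed
    area, i.e. the area-weighted average of per-image attributes.
    """
    if analyzed_area_um2 <= 0:
        raise ValueError("analyzed area must be positive")
    area_mm2 = analyzed_area_um2 / 1e6
    return GlobalAttributes(
        vessel_density=(total_vessel_length_um / 1e3) / area_mm2,
        pore_number_density=n_pores / area_mm2,
        pore_filling_factor=total_pore_area_um2 / analyzed_area_um2,
    )
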