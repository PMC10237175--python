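"""Local thickness between paired closed contours with curvature-based
gyrus/sulcus classification — the 2D readout applied to digitised
organoid outlines.

At each station of the (arclength-resampled, smoothed) outer contour the
local thickness is the length of the inward-normal ray segment to its
first intersection with the inner contour; stations where the ray misses
(sharp folds) fall back to the nearest-point distance and are flagged.
Stations are classified by the signed curvature of the smoothed outer
contour: convex-outward beyond a dead band is gyral, concave sulcal, and
the dead band is neutral (excluded from class means).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely.geometry as geom

from .synthetic import ContourPair

__all__ = ["ThicknessProfile", "local_thickness", "classify_stations",
           "resample_closed", "signed_curvature"]

GYRAL, SULCAL, NEUTRAL = 1, 0, -1


@dataclass
class ThicknessProfile:
    """Per-station thickness/curvature/class along the outer contour."""

    stations: np.ndarray          # (n, 2) resampled outer points
    arclength: np.ndarray
    thickness: np.ndarray
    curvature: np.ndarray
    labels: np.ndarray            # 1 gyral / 0 sulcal / -1 neutral
    ray_missed: np.ndarray
    summary: dict = field(default_factory=dict)


def resample_closed(poly: np.ndarray, n: int) -> np.ndarray:
    """Arclength-uniform resampling of a closed polyline."""
    p = np.asarray(poly, float)
    if np.allclose(p[0], p[-1]):
        p = p[:-1]
    d = np.linalg.norm(np.diff(np.vstack([p, p[:1]]), axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(d)])
    total = s[-1]
    si = np.linspace(0.0, total, n, endpoint=False)
    closed = np.vstack([p, p[:1]])
    x = np.interp(si, s, closed[:, 0])
    y = np.interp(si, s, closed[:, 1])
    return np.column_stack([x, y])


def _smooth_periodic(v: np.ndarray, frac: float) -> np.ndarray:
    """Periodic moving-average smoothing over a fraction of the samples."""
    n = len(v)
    w = max(int(round(frac * n)), 1)
    if w % 2 == 0:
        w += 1
    kernel = np.ones(w) / w
    ext = np.concatenate([v[-(w // 2):], v, v[:w // 2]])
    return np.convolve(ext, kernel, mode="valid")


def signed_curvature(points: np.ndarray) -> np.ndarray:
    """Signed curvature of a closed polyline (positive = convex outward
    for a counterclockwise contour)."""
    x, y = points[:, 0], points[:, 1]
    dx = np.gradient(np.concatenate([x[-2:], x, x[:2]]))[2:-2]
    dy = np.gradient(np.concatenate([y[-2:], y, y[:2]]))[2:-2]
    ddx = np.gradient(np.concatenate([dx[-2:], dx, dx[:2]]))[2:-2]
    ddy = np.gradient(np.concatenate([dy[-2:], dy, dy[:2]]))[2:-2]
    denom = (dx**2 + dy**2) ** 1.5
    denom[denom == 0] = np.inf
    return (dx * ddy - dy * ddx) / denom


def _ensure_ccw(p: np.ndarray) -> np.ndarray:
    area2 = np.sum(p[:, 0] * np.roll(p[:, 1], -1)
                   - np.roll(p[:, 0], -1) * p[:, 1])
    return p if area2 > 0 else p[::-1]


def local_thickness(pair: ContourPair, n_stations: int = 512,
                    smooth_frac: float = 0.05) -> ThicknessProfile:
    """Thickness profile of an outer/inner contour pair.

    Raises a geometry error when the inner contour is not strictly
    inside the outer one.
    """
    outer = _ensure_ccw(np.asarray(pair.outer, float))
    inner = np.asarray(pair.inner, float)
    poly_o = geom.Polygon(outer)
    poly_i = geom.Polygon(inner)
    if not poly_o.is_valid or not poly_i.is_valid:
        raise ValueError("contours must be simple closed curves")
    if not poly_o.contains(poly_i):
        raise ValueError("inner contour must lie strictly inside the outer")
    pts = resample_closed(outer, n_stations)
    xs = _smooth_periodic(pts[:, 0], smooth_frac)
    ys = _smooth_periodic(pts[:, 1], smooth_frac)
    smoothed = np.column_stack([xs, ys])
    kappa = signed_curvature(smoothed)
    # inward normal of the CCW smoothed contour
    dx = np.gradient(np.concatenate([xs[-2:], xs, xs[:2]]))[2:-2]
    dy = np.gradient(np.concatenate([ys[-2:], ys, ys[:2]]))[2:-2]
    tang = np.column_stack([dx, dy])
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    n_in = np.column_stack([-tang[:, 1], tang[:, 0]]) * -1.0  # CCW: inward
    centroid = np.array(poly_o.centroid.coords[0])
    if np.mean(np.einsum("ij,ij->i", n_in, centroid - pts)) < 0:
        n_in = -n_in
    ring_i = geom.LinearRing(inner)
    diam = np.sqrt(poly_o.area) * 4 + 1.0
    thick = np.empty(n_stations)
    missed = np.zeros(n_stations, dtype=bool)
    for idx in range(n_stations):
        p0 = pts[idx]
        ray = geom.LineString([p0, p0 + diam * n_in[idx]])
        hit = ray.intersection(ring_i)
        if hit.is_empty:
            missed[idx] = True
            thick[idx] = geom.Point(p0).distance(ring_i)
        else:
            p = geom.Point(p0)
            if hit.geom_type == "Point":
                thick[idx] = p.distance(hit)
            else:
                thick[idx] = min(p.distance(g)
                                 for g in getattr(hit, "geoms", [hit]))
    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    arclength = np.concatenate([[0.0], np.cumsum(seg)])[:-1]
    prof = ThicknessProfile(stations=pts, arclength=arclength,
                            thickness=thick, curvature=kappa,
                            labels=np.full(n_stations, NEUTRAL),
                            ray_missed=missed)
    return prof


def classify_stations(profile: ThicknessProfile,
                      dead_band: float | None = None) -> ThicknessProfile:
    """Label stations gyral/sulcal by signed curvature with a dead band.

    The default dead band is 10% of the curvature interquartile range;
    stations within it are neutral and excluded from class means.  The
    profile's summary dict gains mean gyral/sulcal thickness and their
    ratio (nan-flagged when a class is empty).
    """
    kappa = profile.curvature
    if dead_band is None:
        q1, q3 = np.quantile(kappa, [0.25, 0.75])
        dead_band = 0.1 * (q3 - q1)
    labels = np.full(len(kappa), NEUTRAL)
    labels[kappa > dead_band] = GYRAL
    labels[kappa < -dead_band] = SULCAL
    profile.labels = labels
    ok = ~profile.ray_missed
    tg = profile.thickness[(labels == GYRAL) & ok]
    ts = profile.thickness[(labels == SULCAL) & ok]
    t_g = float(np.mean(tg)) if len(tg) else np.nan
    t_s = float(np.mean(ts)) if len(ts) else np.nan
    profile.summary = {
        "t_g": t_g,
        "t_s": t_s,
        "ratio": t_g / t_s if len(tg) and len(ts) else np.nan,
        "dead_band": float(dead_band),
        "undefined": not (len(tg) and len(ts)),
    }
    return profile
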