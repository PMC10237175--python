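"""Gyral/sulcal thickness, wavelength and bifurcation metrics of a
simulated folding trajectory.

Thickness is measured along deformed material columns: the Euclidean
distance between the top-surface node and the layer-substrate interface
node that share a reference station.  Crests (gyri) and fundi (sulci)
are local extrema of the top-surface height with a prominence filter;
half-folds touching the lateral boundaries are excluded from averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "SurfacePair", "ThicknessReading", "BifurcationReport",
    "extract_surfaces", "measure_thickness", "measure_wavelength",
    "detect_bifurcations", "trajectory_metrics",
]


@dataclass(frozen=True)
class SurfacePair:
    """Deformed top surface and layer-substrate interface, column-matched."""

    ref_x: np.ndarray
    top: np.ndarray        # (n, 2) deformed pial surface
    interface: np.ndarray  # (n, 2) deformed gray-white interface

    def __post_init__(self):
        if not (len(self.ref_x) == len(self.top) == len(self.interface)):
            raise ValueError("column counts must match")
        if np.any(np.diff(self.ref_x) <= 0):
            raise ValueError("columns must be ordered by reference x")

    @property
    def column_thickness(self) -> np.ndarray:
        d = self.top - self.interface
        return np.hypot(d[:, 0], d[:, 1])


@dataclass(frozen=True)
class ThicknessReading:
    """Per-snapshot gyral/sulcal thickness measurement."""

    theta: float
    gyral: np.ndarray
    sulcal: np.ndarray
    crest_idx: np.ndarray = field(repr=False, default=None)
    fundus_idx: np.ndarray = field(repr=False, default=None)
    flat: bool = False

    @property
    def t_g(self) -> float:
        return float(np.mean(self.gyral)) if len(self.gyral) else np.nan

    @property
    def t_s(self) -> float:
        return float(np.mean(self.sulcal)) if len(self.sulcal) else np.nan

    @property
    def ratio(self) -> float:
        return self.t_g / self.t_s

    @property
    def kappa(self) -> float:
        return (self.t_g - self.t_s) / (self.t_g + self.t_s)


@dataclass
class BifurcationReport:
    theta_first: float | None
    theta_second: float | None
    complete: bool


def extract_surfaces(u: np.ndarray, mesh, nodes: np.ndarray | None = None
                     ) -> SurfacePair:
    """Deformed top and interface polylines from a displacement field."""
    if nodes is None:
        nodes = mesh.nodes
    d = u.reshape(-1, 2)
    top = mesh.top_nodes
    ifc = mesh.interface_nodes
    if len(top) != len(ifc):
        raise ValueError("mesh boundary sets are not column-matched")
    return SurfacePair(
        ref_x=mesh.nodes[top, 0],
        top=nodes[top] + d[top],
        interface=nodes[ifc] + d[ifc],
    )


def _extrema(y, prominence_rel=0.05):
    """Interior crest/fundus indices with a relative prominence filter."""
    amp = y.max() - y.min()
    prom = prominence_rel * amp if amp > 0 else 0.0
    crests, _ = find_peaks(y, prominence=prom)
    fundi, _ = find_peaks(-y, prominence=prom)
    return crests, fundi, amp


def measure_thickness(pair: SurfacePair, theta: float = np.nan,
                      prominence_rel=0.05, flat_tol=1e-9,
                      edge_margin=None) -> ThicknessReading:
    """Thickness at gyral crests and sulcal fundi of one snapshot.

    Crests and fundi are prominence-filtered local extrema of the
    top-surface height; the thickness at each is the deformed material-
    column length at that reference station.  Extrema closer to a
    lateral boundary than half the mean crest spacing (boundary-touching
    half-folds) are excluded.  A flat surface yields a symmetric reading
    with ``t_g = t_s`` set to the mean column thickness.
    """
    y = pair.top[:, 1]
    t = pair.column_thickness
    crests, fundi, amp = _extrema(y, prominence_rel)
    if amp < flat_tol or (len(crests) == 0 and len(fundi) == 0):
        m = float(np.mean(t))
        return ThicknessReading(theta=theta, gyral=np.array([m]),
                                sulcal=np.array([m]),
                                crest_idx=np.array([], int),
                                fundus_idx=np.array([], int), flat=True)
    x = pair.ref_x
    if edge_margin is None:
        ext = np.sort(x[np.concatenate([crests, fundi])])
        spacing = np.median(np.diff(ext)) * 2 if len(ext) > 1 else 0.0
        edge_margin = 0.5 * spacing
    keep = lambda idx: idx[(x[idx] > x[0] + edge_margin)
                           & (x[idx] < x[-1] - edge_margin)]
    crests_k, fundi_k = keep(crests), keep(fundi)
    if len(crests_k) == 0:
        crests_k = crests
    if len(fundi_k) == 0:
        fundi_k = fundi
    return ThicknessReading(theta=theta, gyral=t[crests_k],
                            sulcal=t[fundi_k], crest_idx=crests_k,
                            fundus_idx=fundi_k)


def measure_wavelength(pair: SurfacePair, domain_width=None,
                       prominence_rel=0.05):
    """Dominant fold wavelength of the top surface.

    Peak of the magnitude spectrum of the height profile over the
    (uniform) reference stations, refined by parabolic interpolation,
    cross-checked against the mean crest spacing.  Returns
    ``(wavelength, crest_spacing)``; both are nan for a flat surface.
    """
    x = pair.ref_x
    y = pair.top[:, 1]
    if domain_width is None:
        domain_width = x[-1] - x[0]
    crests, fundi, amp = _extrema(y, prominence_rel)
    if amp <= 0 or (len(crests) < 2 and len(fundi) < 2):
        return np.nan, np.nan
    yu = np.interp(np.linspace(x[0], x[-1], len(x)), x, y)
    h = yu - yu.mean()
    spec = np.abs(np.fft.rfft(h))
    spec[0] = 0.0
    j = int(np.argmax(spec))
    if 0 < j < len(spec) - 1:  # parabolic peak interpolation
        s0, s1, s2 = spec[j - 1], spec[j], spec[j + 1]
        denom = s0 - 2 * s1 + s2
        dj = 0.5 * (s0 - s2) / denom if denom != 0 else 0.0
    else:
        dj = 0.0
    freq = (j + dj) / domain_width
    wavelength = 1.0 / freq if freq > 0 else np.nan
    spacing = np.nan
    if len(crests) >= 2:
        spacing = float(np.mean(np.diff(x[crests])))
    elif len(fundi) >= 2:
        spacing = float(np.mean(np.diff(x[fundi])))
    return float(wavelength), spacing


def period_doubling_parameter(pair: SurfacePair, prominence_rel=0.05,
                              min_amplitude=0.0):
    """Alternate-fundus depth asymmetry (period-doubling order parameter).

    Fundus depths are measured from the mean top-surface height; the
    parameter is the absolute difference between the mean depths of
    even- and odd-indexed fundi divided by the mean depth of all fundi
    (zero for a single-period sinusoid, order one once alternating sulci
    deepen and flatten).
    """
    y = pair.top[:, 1]
    _, fundi, amp = _extrema(y, prominence_rel)
    if amp <= max(min_amplitude, 0.0) or len(fundi) < 4:
        return 0.0
    d = y.mean() - y[fundi]
    d = np.clip(d, 0, None)
    if d.mean() <= 0:
        return 0.0
    return float(abs(d[::2].mean() - d[1::2].mean()) / d.mean())


def detect_bifurcations(thetas, readings, pd_params, kappa_tol=0.005,
                        pd_tol=0.05, sustain=3) -> BifurcationReport:
    """First (thickness divergence) and second (period doubling)
    bifurcation growth factors of a trajectory.

    Each is the earliest growth factor at which its indicator exceeds
    the tolerance and stays above it for ``sustain`` consecutive
    snapshots.
    """
    thetas = np.asarray(thetas, float)
    kappa = np.array([r.kappa for r in readings])
    pdp = np.asarray(pd_params, float)

    def first_sustained(flag):
        run = 0
        for i, f in enumerate(flag):
            run = run + 1 if f else 0
            if run >= sustain:
                return thetas[i - sustain + 1]
        return None

    th1 = first_sustained(kappa > kappa_tol)
    th2 = first_sustained(pdp > pd_tol)
    return BifurcationReport(theta_first=th1, theta_second=th2,
                             complete=th1 is not None and th2 is not None)


def trajectory_metrics(traj, kappa_tol=0.005, pd_tol=0.05) -> dict:
    """Per-snapshot metrics table and summary for a growth trajectory.

    Returns a dict with a pandas DataFrame (theta, t_g, t_s, ratio,
    kappa, wavelength, pd) and the detected bifurcation/contact growth
    factors.
    """
    rows, readings, pdp = [], [], []
    for st in traj.states:
        pair = extract_surfaces(st.u, traj.mesh, traj.nodes)
        r = measure_thickness(pair, theta=st.theta)
        wl, spacing = measure_wavelength(pair, traj.config.width)
        p = period_doubling_parameter(
            pair, min_amplitude=0.05 * traj.config.layer_thickness)
        readings.append(r)
        pdp.append(p)
        rows.append({"theta": st.theta, "t_g": r.t_g, "t_s": r.t_s,
                     "ratio": r.ratio, "kappa": r.kappa,
                     "wavelength": wl, "crest_spacing": spacing, "pd": p})
    table = pd.DataFrame(rows)
    rep = detect_bifurcations(traj.thetas, readings, pdp,
                              kappa_tol=kappa_tol, pd_tol=pd_tol)
    return {
        "table": table,
        "theta_first": rep.theta_first,
        "theta_second": rep.theta_second,
        "theta_contact": traj.theta_contact,
        "termination": traj.termination,
    }
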