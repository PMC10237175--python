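"""Seeded generators for every synthetic input the pipeline consumes.

Three generator families, all driven by one explicit seed so identical
specs produce bit-identical outputs:

* folded-sheet labeled surfaces with per-vertex thickness, curvature,
  gyral/sulcal truth labels, lobe patches and an optional
  anterior-posterior thickness gradient (emulating MRI-derived cortical
  surfaces);
* paired outer/inner closed contours with a prescribed crest/trough
  thickness profile (emulating digitised organoid outlines);
* multi-mode nodal perturbation fields for the finite-element simulator's
  symmetry breaking.

Every generator embeds its ground truth in the returned metadata so that
downstream measurements can be scored without re-deriving it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .surfaces import LabeledSurface, vertex_areas

__all__ = [
    "SurfaceSpec", "ContourSpec", "PerturbationSpec", "ContourPair",
    "gen_labeled_surface", "gen_contour_pair", "gen_perturbation",
    "write_labeled_surface", "read_labeled_surface",
    "write_contour_pair", "read_contour_pair",
]

LOBE_NAMES = ("temporal", "frontal", "parietal", "occipital")


@dataclass(frozen=True)
class SurfaceSpec:
    """Folded-sheet surface generator parameters (lengths in mm).

    Default class thickness targets are the adult-cortex means of
    2.74 mm (gyral) and 2.37 mm (sulcal) with 0.1 mm within-class spread.
    """

    seed: int = 0
    nx: int = 100
    ny: int = 100
    extent: float = 80.0
    fold_count: int = 6
    amplitude: float = 3.0
    gyral_thickness: float = 2.74
    sulcal_thickness: float = 2.37
    thickness_sd: float = 0.1
    curvature_mean: float = 0.25
    curvature_sd: float = 0.05
    ap_gradient: float = 0.0      # mm thickness change per mm along x
    n_lobes: int = 4

    def __post_init__(self):
        if min(self.gyral_thickness, self.sulcal_thickness) <= 0:
            raise ValueError("thickness targets must be positive")
        if self.thickness_sd < 0 or self.curvature_sd < 0:
            raise ValueError("spreads must be non-negative")


@dataclass(frozen=True)
class ContourSpec:
    """Organoid-like contour-pair generator parameters (arbitrary units)."""

    seed: int = 0
    folds: int = 8
    radius: float = 10.0
    amplitude: float = 1.0
    gyral_thickness: float = 1.2
    sulcal_thickness: float = 0.8
    n_points: int = 720

    def __post_init__(self):
        if self.folds < 0:
            raise ValueError("folds must be >= 0")
        if min(self.gyral_thickness, self.sulcal_thickness) <= 0:
            raise ValueError("thickness targets must be positive")


@dataclass(frozen=True)
class PerturbationSpec:
    """Symmetry-breaking field: first ``n_modes`` lateral cosine modes."""

    seed: int = 0
    amplitude: float = 1.25e-3
    n_modes: int = 30


@dataclass
class ContourPair:
    """Closed outer and inner polylines, counterclockwise, inner inside."""

    outer: np.ndarray
    inner: np.ndarray

    def __post_init__(self):
        for name in ("outer", "inner"):
            arr = np.asarray(getattr(self, name), float)
            if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
                raise ValueError(f"{name} must be an (n, 2) polyline")
            setattr(self, name, arr)


def _truncated_normal(rng, mean, sd, size):
    """Gaussian truncated at three standard deviations (keeps thickness
    positive for the default targets without heavy tails)."""
    x = rng.standard_normal(size)
    x = np.clip(x, -3.0, 3.0)
    return mean + sd * x


def gen_labeled_surface(spec: SurfaceSpec):
    """Folded-sheet triangulation with thickness/curvature/label truth.

    Returns ``(surface, truth)``; truth holds the generator labels,
    class means, per-lobe targets and the spec itself.
    """
    rng = np.random.default_rng(spec.seed)
    xs = np.linspace(0.0, spec.extent, spec.nx)
    ys = np.linspace(0.0, spec.extent, spec.ny)
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    phase = 2 * np.pi * spec.fold_count * X / spec.extent
    Z = spec.amplitude * np.cos(phase)
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    # grid triangulation
    ix, iy = np.meshgrid(np.arange(spec.nx - 1), np.arange(spec.ny - 1),
                         indexing="xy")
    n0 = (iy * spec.nx + ix).ravel()
    f1 = np.column_stack([n0, n0 + 1, n0 + spec.nx])
    f2 = np.column_stack([n0 + 1, n0 + 1 + spec.nx, n0 + spec.nx])
    faces = np.vstack([f1, f2])
    n = len(verts)
    if spec.amplitude == 0:
        labels = np.ones(n, dtype=int)
        curvature = np.zeros(n)
    else:
        labels = (np.cos(phase).ravel() >= 0).astype(int)  # crest = gyral
        mean = np.where(labels == 1, spec.curvature_mean, -spec.curvature_mean)
        curvature = _truncated_normal(rng, mean, spec.curvature_sd, n)
    target = np.where(labels == 1, spec.gyral_thickness, spec.sulcal_thickness)
    thickness = _truncated_normal(rng, target, spec.thickness_sd, n)
    if spec.ap_gradient:
        thickness = thickness + spec.ap_gradient * (X.ravel()
                                                    - spec.extent / 2)
    region = np.minimum((X.ravel() / spec.extent * spec.n_lobes).astype(int),
                        spec.n_lobes - 1)
    surface = LabeledSurface(vertices=verts, faces=faces,
                             thickness=thickness, curvature=curvature,
                             labels=labels, region=region,
                             area=vertex_areas(verts, faces))
    truth = {
        "spec": asdict(spec),
        "labels": labels.copy(),
        "gyral_mean": float(spec.gyral_thickness),
        "sulcal_mean": float(spec.sulcal_thickness),
        "ratio": float(spec.gyral_thickness / spec.sulcal_thickness),
        "class_curvature_means": (-spec.curvature_mean, spec.curvature_mean),
        "lobe_names": LOBE_NAMES[:spec.n_lobes],
    }
    return surface, truth


def contour_amplitude_bound(spec: ContourSpec) -> float:
    """Admissible fold amplitude: keeps the inner offset curve simple.

    The inner curve's radius at troughs is
    ``R - A - t_g``-ish; a conservative bound keeps the offset distance
    below the local radius of curvature of the outer contour,
    ``A < (R - t_g) / (1 + n^2)`` for ``n`` folds.
    """
    n = max(spec.folds, 1)
    return max((spec.radius - spec.gyral_thickness) / (1 + n**2) * (1 + n),
               0.0)


def gen_contour_pair(spec: ContourSpec):
    """Outer folded circle and inner offset contour with thickness truth.

    The outer contour is a circle with sinusoidal radial folds; the inner
    contour is offset inward along the outer normal by a thickness field
    that takes the gyral target at crests and the sulcal target at
    troughs with smooth (cosine) interpolation.
    """
    phi = np.linspace(0.0, 2 * np.pi, spec.n_points, endpoint=False)
    n = spec.folds
    r = spec.radius + (spec.amplitude * np.cos(n * phi) if n else 0.0)
    outer = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    if n:
        blend = 0.5 * (1 + np.cos(n * phi))
    else:
        blend = np.ones_like(phi)
        thickness = np.full_like(phi, 0.5 * (spec.gyral_thickness
                                             + spec.sulcal_thickness))
    thickness = spec.sulcal_thickness + (spec.gyral_thickness
                                         - spec.sulcal_thickness) * blend
    if n == 0:
        thickness = np.full_like(phi, spec.gyral_thickness)
    # inward normal of the parametric (counterclockwise) outer curve
    dx = np.gradient(outer[:, 0], phi, edge_order=2)
    dy = np.gradient(outer[:, 1], phi, edge_order=2)
    norm = np.hypot(dx, dy)
    n_in = np.column_stack([-dy / norm, dx / norm])
    centroid = outer.mean(axis=0)
    if np.mean(np.einsum("ij,ij->i", n_in, centroid - outer)) < 0:
        n_in = -n_in
    inner = outer + thickness[:, None] * n_in
    import shapely.geometry as geom

    ring_o = geom.LinearRing(outer)
    ring_i = geom.LinearRing(inner)
    if not (ring_o.is_simple and ring_i.is_simple):
        raise ValueError(
            "self-intersecting contour: fold amplitude exceeds the "
            f"admissible bound (~{contour_amplitude_bound(spec):.3g})")
    if not geom.Polygon(outer).contains(geom.Polygon(inner)):
        raise ValueError("inner contour not strictly inside outer")
    pair = ContourPair(outer=outer, inner=inner)
    truth = {
        "spec": asdict(spec),
        "thickness": thickness.copy(),
        "phase": phi.copy(),
        "labels": (np.cos(n * phi) >= 0).astype(int) if n
                  else np.ones_like(phi, dtype=int),
        "ratio": float(spec.gyral_thickness / spec.sulcal_thickness),
    }
    return pair, truth


def gen_perturbation(spec: PerturbationSpec, mesh) -> np.ndarray:
    """Deterministic vertical node perturbation for the FE bilayer.

    Sum of the first ``n_modes`` lateral cosine modes with seeded random
    coefficients, ramped quadratically from zero at the (constrained)
    bottom boundary to full strength at the top surface, and normalised
    so the largest nodal offset equals ``amplitude`` exactly.
    """
    if spec.amplitude == 0:
        return np.zeros(len(mesh.nodes))
    rng = np.random.default_rng(spec.seed)
    coeff = rng.standard_normal(spec.n_modes)
    X = mesh.nodes[:, 0]
    Y = mesh.nodes[:, 1]
    modes = np.cos(np.pi * np.outer(np.arange(1, spec.n_modes + 1), X)
                   / mesh.width)
    prof = coeff @ modes
    d = prof * (Y / mesh.height) ** 2
    return d * (spec.amplitude / np.abs(d).max())


# ---------------------------------------------------------------------------
# writers / readers (plain-text formats; lossless round-trip)

def _fmt_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def write_labeled_surface(surface: LabeledSurface, truth, outdir):
    """PLY mesh + per-vertex CSV scalars + truth JSON sidecar."""
    import trimesh

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mesh = trimesh.Trimesh(vertices=surface.vertices, faces=surface.faces,
                           process=False)
    (outdir / "surface.ply").write_bytes(
        trimesh.exchange.ply.export_ply(mesh, encoding="ascii"))
    df = pd.DataFrame({
        "vertex": np.arange(len(surface.vertices)),
        "thickness": surface.thickness,
        "curvature": surface.curvature,
        "label": surface.labels,
        "region": surface.region,
        "area": surface.area,
    })
    _fmt_csv(df, outdir / "scalars.csv")
    t = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
         for k, v in truth.items()}
    (outdir / "truth.json").write_text(json.dumps(t, indent=1))


def read_labeled_surface(outdir):
    import trimesh

    outdir = Path(outdir)
    mesh = trimesh.load(outdir / "surface.ply", process=False)
    df = pd.read_csv(outdir / "scalars.csv", float_precision="round_trip")
    truth = json.loads((outdir / "truth.json").read_text())
    if "labels" in truth:
        truth["labels"] = np.asarray(truth["labels"], int)
    surface = LabeledSurface(
        vertices=np.asarray(mesh.vertices, float),
        faces=np.asarray(mesh.faces, int),
        thickness=df["thickness"].to_numpy(),
        curvature=df["curvature"].to_numpy(),
        labels=df["label"].to_numpy(int),
        region=df["region"].to_numpy(int),
        area=df["area"].to_numpy(),
    )
    return surface, truth


def write_contour_pair(pair: ContourPair, truth, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _fmt_csv(pd.DataFrame(pair.outer, columns=["x", "y"]),
             outdir / "outer.csv")
    _fmt_csv(pd.DataFrame(pair.inner, columns=["x", "y"]),
             outdir / "inner.csv")
    t = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
         for k, v in truth.items()}
    (outdir / "truth.json").write_text(json.dumps(t, indent=1))


def read_contour_pair(outdir):
    outdir = Path(outdir)
    outer = pd.read_csv(outdir / "outer.csv",
                        float_precision="round_trip").to_numpy()
    inner = pd.read_csv(outdir / "inner.csv",
                        float_precision="round_trip").to_numpy()
    truth = json.loads((outdir / "truth.json").read_text())
    for key in ("thickness", "phase", "labels"):
        if key in truth:
            truth[key] = np.asarray(truth[key])
    return ContourPair(outer=outer, inner=inner), truth
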