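"""Structured quadrilateral mesh of the bilayer rectangle.

The reference domain is a ``width x height`` rectangle whose top
``layer_thickness`` band is the growing stiff layer and whose remainder is
the soft substrate.  The default geometry is a 110 x 25 mm slice with a
1.25 mm layer, discretised by 240 x (20 + 4) bilinear quadrilaterals:
5760 elements and 12 050 displacement unknowns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..mechanics import MaterialParams

__all__ = ["SimConfig", "QuadMesh", "build_mesh"]


@dataclass(frozen=True)
class SimConfig:
    """Geometry, discretisation, materials and stepping of a growth run.

    Default material constants: layer mu = 0.30, lam = 2.79 kPa; substrate
    mu = 0.10, lam = 0.93 kPa (stiffness ratio three, Poisson ratio 0.45).
    """

    width: float = 110.0
    height: float = 25.0
    layer_thickness: float = 1.25
    nx: int = 240
    ny_substrate: int = 20
    ny_layer: int = 4
    layer: MaterialParams = field(
        default_factory=lambda: MaterialParams(mu=0.30, lam=2.79, growing=True,
                                               G=1.0))
    substrate: MaterialParams = field(
        default_factory=lambda: MaterialParams(mu=0.10, lam=0.93))
    dtheta: float = 2e-3
    theta_max: float = 2.0
    newton_tol: float = 1e-9
    max_newton_iter: int = 25
    min_dtheta: float = 1e-5
    perturb_amplitude_rel: float = 1e-3
    perturb_modes: int = 30
    perturb_seed: int = 0
    contact_gap: float = 0.1
    frame_correct: bool = False
    theta_watch: float = 1.15
    eig_every: int = 2
    max_rescues: int = 20
    snapshot_every: int = 1

    def __post_init__(self) -> None:
        if min(self.width, self.height, self.layer_thickness) <= 0:
            raise ValueError("all dimensions must be positive")
        if self.layer_thickness >= self.height:
            raise ValueError("layer thicker than the whole domain")
        if min(self.nx, self.ny_substrate, self.ny_layer) < 1:
            raise ValueError("element counts must be >= 1")
        if self.dtheta <= 0:
            raise ValueError("growth step must be positive")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class QuadMesh:
    """Structured Q4 mesh with region labels and boundary node sets."""

    nodes: np.ndarray          # (n_nodes, 2) reference coordinates, mm
    conn: np.ndarray           # (n_elem, 4) counterclockwise connectivity
    layer_elem: np.ndarray     # (n_elem,) bool, True in the layer
    nx: int
    ny: int
    width: float
    height: float
    layer_thickness: float

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.conn)

    @property
    def n_dofs(self) -> int:
        return 2 * self.n_nodes

    @property
    def left_nodes(self) -> np.ndarray:
        return np.arange(0, self.n_nodes, self.nx + 1)

    @property
    def right_nodes(self) -> np.ndarray:
        return np.arange(self.nx, self.n_nodes, self.nx + 1)

    @property
    def bottom_nodes(self) -> np.ndarray:
        return np.arange(0, self.nx + 1)

    @property
    def top_nodes(self) -> np.ndarray:
        return np.arange(self.ny * (self.nx + 1), self.n_nodes)

    @property
    def interface_nodes(self) -> np.ndarray:
        iy = self.ny - _layer_rows(self)
        return np.arange(iy * (self.nx + 1), (iy + 1) * (self.nx + 1))

    def jacobians_positive(self) -> bool:
        xe = self.nodes[self.conn]
        v1 = xe[:, 1] - xe[:, 0]
        v2 = xe[:, 3] - xe[:, 0]
        return bool((v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0] > 0).all())


def _layer_rows(mesh: QuadMesh) -> int:
    # rows of layer elements recovered from region labels
    per_row = mesh.nx
    return int(mesh.layer_elem.sum() // per_row)


def build_mesh(config: SimConfig) -> QuadMesh:
    """Structured grid: substrate rows below, layer rows on top."""
    W, H, t = config.width, config.height, config.layer_thickness
    nx, nys, nyl = config.nx, config.ny_substrate, config.ny_layer
    ys = np.concatenate([
        np.linspace(0.0, H - t, nys + 1),
        np.linspace(H - t, H, nyl + 1)[1:],
    ])
    xs = np.linspace(0.0, W, nx + 1)
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    nodes = np.column_stack([X.ravel(), Y.ravel()])
    ny = nys + nyl
    nnx = nx + 1
    iy, ix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    n0 = iy * nnx + ix
    conn = np.column_stack([
        n0.ravel(), (n0 + 1).ravel(), (n0 + 1 + nnx).ravel(), (n0 + nnx).ravel()
    ])
    layer_elem = (iy >= nys).ravel()
    return QuadMesh(nodes=nodes, conn=conn, layer_elem=layer_elem,
                    nx=nx, ny=ny, width=W, height=H, layer_thickness=t)
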