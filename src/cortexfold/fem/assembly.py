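"""Vectorised residual/tangent assembly for the growing hyperelastic bilayer.

Plane-strain bilinear quadrilaterals with selective reduced integration:
the deviatoric (mu) stress contribution is integrated with 2 x 2 Gauss
points, the volumetric (lam ln Je) contribution with the single centre
point, which mitigates volumetric locking at the Poisson ratio ~0.45
implied by the default Lame constants.

Two constitutive variants share the kinematics ``Fe = F / theta``:

* ``printed`` (default): the expression ``mu (b_e - I) + lam ln(Je) I`` is
  treated directly as the Cauchy stress, giving the first Piola stress
  ``P = Jg Je tau Fe^{-T} / theta``.
* ``frame_correct``: the same expression divided by ``Je`` (the Cauchy
  stress of an explicit strain energy), giving the energy-consistent
  ``P = Jg tau F^{-T}`` with a symmetric tangent.

The consistent tangent ``A = dP/dF`` is assembled in closed form and is
verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .mesh import QuadMesh, SimConfig

__all__ = ["Assembler"]

_GP_FULL = [(-1, -1), (1, -1), (1, 1), (-1, 1)]


def _shape_grads(xe, points, weight):
    """dN/dX and detJ*w at the given Gauss points for all elements."""
    gs, ws = [], []
    for xi, eta in points:
        dN = 0.25 * np.array([
            [-(1 - eta), -(1 - xi)],
            [(1 - eta), -(1 + xi)],
            [(1 + eta), (1 + xi)],
            [-(1 + eta), (1 - xi)],
        ])
        J = np.einsum("ak,eai->eki", dN, xe, optimize=True)
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        Jinv = np.empty_like(J)
        Jinv[:, 0, 0] = J[:, 1, 1]
        Jinv[:, 1, 1] = J[:, 0, 0]
        Jinv[:, 0, 1] = -J[:, 0, 1]
        Jinv[:, 1, 0] = -J[:, 1, 0]
        Jinv /= detJ[:, None, None]
        gs.append(np.einsum("ak,eki->eai", dN, Jinv, optimize=True))
        ws.append(detJ * weight)
    return np.stack(gs, axis=1), np.stack(ws, axis=1)


class Assembler:
    """Residual, tangent and strain energy of the discretised bilayer."""

    def __init__(self, mesh: QuadMesh, config: SimConfig,
                 nodes: np.ndarray | None = None):
        self.mesh = mesh
        self.config = config
        nodes = mesh.nodes if nodes is None else nodes
        self.nodes = nodes
        xe = nodes[mesh.conn]
        s3 = 1.0 / np.sqrt(3.0)
        self.g_full, self.w_full = _shape_grads(
            xe, [(s * s3, t * s3) for s, t in _GP_FULL], 1.0)
        self.g_red, self.w_red = _shape_grads(xe, [(0.0, 0.0)], 4.0)
        self.mu = np.where(mesh.layer_elem, config.layer.mu, config.substrate.mu)
        self.lam = np.where(mesh.layer_elem, config.layer.lam,
                            config.substrate.lam)
        dof = mesh.conn[:, :, None] * 2 + np.arange(2)[None, None, :]
        self.edof = dof.reshape(-1, 8)
        self.Ki = np.repeat(self.edof, 8, axis=1).ravel()
        self.Kj = np.tile(self.edof, (1, 8)).ravel()
        fixed = np.concatenate([
            mesh.left_nodes * 2, mesh.right_nodes * 2, mesh.bottom_nodes * 2 + 1
        ])
        self.fixed = np.unique(fixed)
        self.free = np.setdiff1d(np.arange(mesh.n_dofs), self.fixed)

    def _theta_elem(self, theta: float) -> np.ndarray:
        return np.where(self.mesh.layer_elem, theta, 1.0)

    def assemble(self, u: np.ndarray, theta: float, want_K: bool = True):
        """Internal-force residual and consistent tangent.

        Returns ``(R, K)``; ``(None, None)`` signals element inversion
        (det F <= 0 at a quadrature point) so the caller can reject the
        step.
        """
        mesh, cfg = self.mesh, self.config
        ue = u.reshape(-1, 2)[mesh.conn]
        th = self._theta_elem(theta)
        R = np.zeros(mesh.n_dofs)
        Kdata = 0.0
        for g, w, part in ((self.g_full, self.w_full, "mu"),
                           (self.g_red, self.w_red, "lam")):
            E, Q = w.shape
            F = np.einsum("eai,eqaJ->eqiJ", ue, g, optimize=True)
            F[..., 0, 0] += 1.0
            F[..., 1, 1] += 1.0
            detF = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
            if np.any(detF <= 1e-12):
                return None, None
            thq = th[:, None]
            Je = detF / thq**2
            G = np.empty_like(F)  # F^{-T}
            G[..., 0, 0] = F[..., 1, 1]
            G[..., 1, 1] = F[..., 0, 0]
            G[..., 0, 1] = -F[..., 1, 0]
            G[..., 1, 0] = -F[..., 0, 1]
            G /= detF[..., None, None]
            mu = self.mu[:, None]
            lam = self.lam[:, None]
            if part == "mu":
                b = np.einsum("eqiM,eqjM->eqij", F, F, optimize=True) / thq[..., None, None]**2
                tau = mu[..., None, None] * b
                tau[..., 0, 0] -= mu
                tau[..., 1, 1] -= mu
            else:
                tau = np.zeros_like(F)
                ln = lam * np.log(Je)
                tau[..., 0, 0] = ln
                tau[..., 1, 1] = ln
            c = thq**2 * (1.0 if cfg.frame_correct else Je)
            P = c[..., None, None] * np.einsum("eqim,eqmJ->eqiJ", tau, G, optimize=True)
            Re = np.einsum("eq,eqiJ,eqaJ->eai", w, P, g, optimize=True)
            np.add.at(R, self.edof, Re.reshape(E, 8))
            if not want_K:
                continue
            A = np.zeros(F.shape[:2] + (2, 2, 2, 2))
            if part == "mu":
                FG = np.einsum("eqmL,eqmJ->eqJL", F, G, optimize=True)
                t1 = np.einsum("eq,eqJL->eqJL", c * mu / thq**2, FG, optimize=True)
                for i in range(2):
                    A[..., i, :, i, :] += t1
                A += np.einsum("eq,eqiL,eqkJ->eqiJkL", c * mu / thq**2, F, G, optimize=True)
            else:
                A += np.einsum("eq,eqkL,eqiJ->eqiJkL", c * lam, G, G, optimize=True)
            A -= np.einsum("eq,eqim,eqmL,eqkJ->eqiJkL", c, tau, G, G, optimize=True)
            if not cfg.frame_correct:
                A += np.einsum("eq,eqkL,eqim,eqmJ->eqiJkL", c, G, tau, G, optimize=True)
            Ke = np.einsum("eq,eqaJ,eqiJkL,eqbL->eaibk", w, g, A, g, optimize=True)
            Kdata = Kdata + Ke.reshape(-1, 8, 8)
        K = None
        if want_K:
            K = sp.csr_matrix(
                (np.asarray(Kdata).ravel(), (self.Ki, self.Kj)),
                shape=(mesh.n_dofs, mesh.n_dofs))
        return R, K

    def strain_energy_density(self, u: np.ndarray, theta: float):
        """Per-quadrature-point strain energy of the frame-correct law.

        ``W = mu/2 (tr Ce - 2) - mu ln Je + lam/2 (ln Je)^2`` weighted by
        the grown reference volume ``Jg``; the mu part is evaluated at the
        full quadrature, the lam part at the reduced point, matching the
        selective integration of the residual.
        """
        mesh = self.mesh
        ue = u.reshape(-1, 2)[mesh.conn]
        th = self._theta_elem(theta)
        total = 0.0
        for g, w, part in ((self.g_full, self.w_full, "mu"),
                           (self.g_red, self.w_red, "lam")):
            F = np.einsum("eai,eqaJ->eqiJ", ue, g, optimize=True)
            F[..., 0, 0] += 1.0
            F[..., 1, 1] += 1.0
            detF = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
            thq = th[:, None]
            Je = detF / thq**2
            if part == "mu":
                trC = np.einsum("eqiJ,eqiJ->eq", F, F, optimize=True) / thq**2
                Wq = 0.5 * self.mu[:, None] * (trC - 2.0) \
                    - self.mu[:, None] * np.log(Je)
            else:
                Wq = 0.5 * self.lam[:, None] * np.log(Je) ** 2
            total += float((w * thq**2 * Wq).sum())
        return total

    def internal_energy(self, u: np.ndarray, theta: float) -> float:
        """Total internal energy (quadrature of the strain-energy density)."""
        return self.strain_energy_density(u, theta)
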