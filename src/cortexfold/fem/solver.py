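"""Quasi-static growth continuation of the bilayer with branch switching.

The layer growth factor is stepped from 1 by ``dtheta`` (with adaptive
halving on Newton failure) and mechanical equilibrium is re-solved at
every step by a line-searched Newton iteration.  A deterministic
multi-mode imperfection of the reference node heights breaks the lateral
symmetry once at the start.  Because the folding bifurcation of this
bilayer is weakly subcritical, the solver additionally monitors the
lowest tangent eigenvalue once growth passes ``theta_watch`` and, when
the current equilibrium is unstable, kicks the state along the unstable
eigenvector (escalating amplitude, deterministic sign) until a stable
equilibrium is reached.  The same mechanism carries the solution through
the secondary (period-doubling) bifurcation.  The run stops at the first
self-contact of the top surface, at ``theta_max``, or on repeated
non-convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from ..synthetic import PerturbationSpec, gen_perturbation
from .assembly import Assembler
from .mesh import QuadMesh, SimConfig, build_mesh

__all__ = ["SimState", "SimTrajectory", "run_growth", "detect_self_contact",
           "newton_solve", "lowest_eigenmode"]


@dataclass
class SimState:
    """One converged equilibrium of the growth continuation."""

    u: np.ndarray
    theta: float
    converged: bool
    residual_history: list[float] = field(default_factory=list)


@dataclass
class SimTrajectory:
    """Ordered snapshots of a growth run with its termination reason."""

    config: SimConfig
    mesh: QuadMesh
    nodes: np.ndarray                  # perturbed reference coordinates
    thetas: list[float] = field(default_factory=list)
    states: list[SimState] = field(default_factory=list)
    termination: str = "incomplete"
    theta_contact: float | None = None
    n_kicks: int = 0

    def append(self, state: SimState) -> None:
        if self.thetas and state.theta <= self.thetas[-1]:
            raise ValueError("snapshot growth factors must strictly increase")
        self.thetas.append(state.theta)
        self.states.append(state)

    def __len__(self) -> int:
        return len(self.states)


def newton_solve(asm: Assembler, u0: np.ndarray, theta: float,
                 tol: float = 1e-9, maxit: int = 25):
    """Line-searched Newton iteration at fixed growth.

    Convergence: free-dof residual norm below ``tol`` relative to the
    first iterate's norm (or absolutely tiny).  Returns
    ``(u, converged, residual_history)``.
    """
    u = u0.copy()
    R, K = asm.assemble(u, theta)
    if R is None:
        return None, False, []
    r0 = max(np.linalg.norm(R[asm.free]), 1e-14)
    hist = []
    for _ in range(maxit):
        r = np.linalg.norm(R[asm.free])
        hist.append(float(r))
        if r < tol * r0 or r < 1e-13:
            return u, True, hist
        du = np.zeros(asm.mesh.n_dofs)
        try:
            du[asm.free] = spla.spsolve(
                K[asm.free][:, asm.free].tocsc(), -R[asm.free])
        except Exception:
            return None, False, hist
        # backtracking on the residual norm; trials assemble R only
        alpha, accepted = 1.0, False
        for _ in range(8):
            R2, _ = asm.assemble(u + alpha * du, theta, want_K=False)
            if R2 is not None and \
                    np.linalg.norm(R2[asm.free]) < (1 - 0.1 * alpha) * r + 1e-16:
                u = u + alpha * du
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            R2, _ = asm.assemble(u + du, theta, want_K=False)
            if R2 is None:
                return None, False, hist
            u = u + du
        R, K = asm.assemble(u, theta)
        if R is None:
            return None, False, hist
    return u, False, hist


def lowest_eigenmode(asm: Assembler, u: np.ndarray, theta: float):
    """Smallest eigenvalue and eigenvector of the free-dof tangent."""
    _, K = asm.assemble(u, theta)
    if K is None:
        return np.inf, None
    Kf = K[asm.free][:, asm.free].tocsc()
    v0 = np.ones(Kf.shape[0]) / np.sqrt(Kf.shape[0])  # deterministic start
    try:
        w, v = spla.eigsh(Kf, k=1, sigma=0, which="LM", v0=v0)
    except Exception:
        return np.inf, None
    phi = np.zeros(asm.mesh.n_dofs)
    phi[asm.free] = v[:, 0]
    return float(w[0]), phi


def detect_self_contact(x, y, gap, min_separation=3.0, ref_x=None):
    """First-contact test on the deformed top-surface polyline.

    Samples segment midpoints in addition to the nodes and reports pairs
    of samples closer than ``gap`` whose reference stations are more than
    ``min_separation`` (mm) apart, i.e. contact between non-adjacent
    portions of the surface rather than within one smooth fold.

    Returns ``(contact, locations)`` where locations is an array of
    contact-point coordinates (possibly empty).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if ref_x is None:
        ref_x = np.linspace(0.0, 1.0, len(x)) * max(
            1.0, abs(x[-1] - x[0]))
    ref_x = np.asarray(ref_x, float)
    xm = 0.5 * (x[:-1] + x[1:])
    ym = 0.5 * (y[:-1] + y[1:])
    rm = 0.5 * (ref_x[:-1] + ref_x[1:])
    X = np.concatenate([x, xm])
    Y = np.concatenate([y, ym])
    Rx = np.concatenate([ref_x, rm])
    tree = cKDTree(np.column_stack([X, Y]))
    pairs = tree.query_pairs(gap, output_type="ndarray")
    if len(pairs) == 0:
        return False, np.empty((0, 2))
    sep = np.abs(Rx[pairs[:, 0]] - Rx[pairs[:, 1]])
    hits = pairs[sep > min_separation]
    if len(hits) == 0:
        return False, np.empty((0, 2))
    pts = 0.5 * (np.column_stack([X[hits[:, 0]], Y[hits[:, 0]]])
                 + np.column_stack([X[hits[:, 1]], Y[hits[:, 1]]]))
    return True, pts


def _top_surface(traj_nodes, mesh, u):
    d = u.reshape(-1, 2)
    top = mesh.top_nodes
    return (traj_nodes[top, 0] + d[top, 0], traj_nodes[top, 1] + d[top, 1])


def flow_relax(asm, u0, theta, t_layer, tol=1e-9, nmax=2000, dtau=0.5,
               check_every=50):
    """Explicit pseudo-time relaxation ``u' = -D^{-1} R`` through a snap.

    Marches the diagonally preconditioned residual flow (displacement
    increments capped at 2% of the layer thickness) so the state can
    leave the neighbourhood of a vanished equilibrium, polishing with
    Newton every ``check_every`` steps.  Returns ``(u, converged)``.
    """
    free = asm.free
    R, K = asm.assemble(u0, theta)
    if R is None:
        return None, False
    D = np.abs(K.diagonal()[free])
    D[D < 1e-8 * D.mean()] = D.mean()
    u = u0.copy()
    cap = 0.02 * t_layer
    for i in range(nmax):
        R, _ = asm.assemble(u, theta, want_K=False)
        if R is None:
            return None, False
        du = -dtau * R[free] / D
        m = np.abs(du).max()
        if m > cap:
            du *= cap / m
        u_try = u.copy()
        u_try[free] += du
        R2, _ = asm.assemble(u_try, theta, want_K=False)
        if R2 is None:
            dtau *= 0.5
            continue
        u = u_try
        if (i + 1) % check_every == 0:
            un, ok, _ = newton_solve(asm, u, theta, tol=tol, maxit=20)
            if ok:
                return un, True
    return u, False


def _try_kick(asm, u, theta, t_layer, phi, amp_of,
              amplitudes=(0.05, 0.1, 0.2, 0.5, 1.0), maxit=None):
    """Escalating eigenvector kick; returns (u_new, kicked)."""
    phi = phi / np.abs(phi).max()
    top_dofs = asm.mesh.top_nodes * 2 + 1
    s = np.sign(phi[top_dofs].sum()) or 1.0
    a0 = amp_of(u)
    if maxit is None:
        maxit = asm.config.max_newton_iter
    for ka in amplitudes:
        for sgn in (s, -s):
            u2, ok, _ = newton_solve(asm, u + ka * t_layer * sgn * phi, theta,
                                     tol=asm.config.newton_tol, maxit=maxit)
            if ok and amp_of(u2) > a0 + 0.04 * t_layer:
                return u2, True
    return u, False


def run_growth(config: SimConfig, progress=None) -> SimTrajectory:
    """Run the full growth continuation and record the trajectory."""
    mesh = build_mesh(config)
    pert = gen_perturbation(
        PerturbationSpec(seed=config.perturb_seed,
                         amplitude=config.perturb_amplitude_rel
                         * config.layer_thickness,
                         n_modes=config.perturb_modes),
        mesh)
    nodes = mesh.nodes.copy()
    nodes[:, 1] += pert
    asm = Assembler(mesh, config, nodes=nodes)
    traj = SimTrajectory(config=config, mesh=mesh, nodes=nodes)

    def amp_of(u):
        _, ys = _top_surface(nodes, mesh, u)
        return ys.max() - ys.min()

    # the surface polyline cannot resolve separations below the element
    # scale, so the detection gap is floored at a quarter element width
    gap_eff = max(config.contact_gap, 0.25 * config.width / config.nx)
    min_sep = 3.0 * config.width / config.nx

    def contact_state(u, gap):
        xs, ys = _top_surface(nodes, mesh, u)
        return detect_self_contact(xs, ys, gap, min_separation=min_sep,
                                   ref_x=mesh.nodes[mesh.top_nodes, 0])

    u = np.zeros(mesh.n_dofs)
    theta = 1.0
    step = config.dtheta
    i_accept = 0
    next_eig_check = 0
    n_rescues = 0
    last_stable = None
    while theta < config.theta_max - 1e-12:
        theta_try = min(theta + step, config.theta_max)
        u_new, ok, hist = newton_solve(asm, u, theta_try,
                                       tol=config.newton_tol,
                                       maxit=config.max_newton_iter)
        if not ok:
            step /= 2
            if step < config.min_dtheta:
                # stalled continuation (limit point of a secondary
                # bifurcation / snap-through): first try a finite
                # eigenvector jump onto the nearby stable branch, then a
                # pseudo-time relaxation a quarter growth step ahead
                rescued = False
                if n_rescues < config.max_rescues:
                    lam, phi = lowest_eigenmode(asm, u, theta)
                    if phi is not None:
                        u2, rescued = _try_kick(
                            asm, u, theta, config.layer_thickness, phi,
                            amp_of, amplitudes=(0.3, 0.5, 1.0, 2.0),
                            maxit=150)
                        if rescued:
                            u = u2
                    if not rescued:
                        th_res = theta + config.dtheta / 4
                        u2, ok2 = flow_relax(asm, u, th_res,
                                             config.layer_thickness,
                                             tol=config.newton_tol)
                        if ok2:
                            theta, u = th_res, u2
                            traj.append(SimState(u=u.copy(), theta=theta,
                                                 converged=True))
                            rescued = True
                if rescued:
                    traj.n_kicks += 1
                    n_rescues += 1
                    step = config.dtheta / 4
                    i_accept += 1
                    continue
                # equilibrium lost with fold walls within the resolvable
                # separation: this is first self-contact at this mesh scale
                near, _ = contact_state(u, 1.5 * gap_eff)
                if near:
                    traj.theta_contact = theta
                    traj.termination = "self-contact"
                else:
                    traj.termination = "non-convergence"
                return traj
            continue
        theta, u = theta_try, u_new
        i_accept += 1
        if step < config.dtheta:
            step = min(config.dtheta, step * 2)
        # eigen watch: only needed until the folded branch is reached;
        # afterwards kicks act as a stall rescue (above)
        pre_folded = amp_of(u) < 0.8 * config.layer_thickness
        if pre_folded and theta > config.theta_watch \
                and i_accept >= next_eig_check:
            next_eig_check = i_accept + config.eig_every
            lam, phi = lowest_eigenmode(asm, u, theta)
            if lam < -1e-10 and phi is not None:
                if last_stable is not None and last_stable[0] < theta:
                    # localise the first crossing by bisection and take the
                    # eigenvector there, so the kick follows the
                    # first-destabilised (critical) mode rather than
                    # whichever mode is lowest a few steps later; the kick
                    # itself is applied at the current, more unstable state
                    th_a, u_a = last_stable
                    th_b, phi_b = theta, phi
                    for _ in range(4):
                        th_m = 0.5 * (th_a + th_b)
                        u_m, ok_m, _ = newton_solve(
                            asm, u_a, th_m, tol=config.newton_tol,
                            maxit=config.max_newton_iter)
                        if not ok_m:
                            break
                        lam_m, phi_m = lowest_eigenmode(asm, u_m, th_m)
                        if phi_m is None:
                            break
                        if lam_m < -1e-10:
                            th_b, phi_b = th_m, phi_m
                        else:
                            th_a, u_a = th_m, u_m
                    phi = phi_b
                    last_stable = None
                u2, kicked = _try_kick(asm, u, theta,
                                       config.layer_thickness, phi, amp_of)
                if kicked:
                    u = u2
                    traj.n_kicks += 1
                else:
                    # unstable but no reachable stable branch: back off so
                    # the continuation is not stalled by kick attempts
                    next_eig_check = i_accept + 10 * config.eig_every
            else:
                last_stable = (theta, u.copy())
        if i_accept % config.snapshot_every == 0 and \
                (not traj.thetas or theta > traj.thetas[-1] + 1e-12):
            traj.append(SimState(u=u.copy(), theta=theta, converged=True,
                                 residual_history=hist))
        contact, _ = contact_state(u, gap_eff)
        if progress is not None:
            progress(theta, amp_of(u), contact)
        if contact:
            traj.theta_contact = theta
            traj.termination = "self-contact"
            return traj
    traj.termination = "theta_max"
    return traj
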