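import numpy as np
import pytest

import cortexfold as cf
from cortexfold.fem.assembly import Assembler
from cortexfold.fem.mesh import SimConfig, build_mesh
from cortexfold.fem.solver import (detect_self_contact, lowest_eigenmode,
                                   newton_solve, run_growth)


def small_config(**kw):
    base = dict(nx=8, ny_substrate=3, ny_layer=2, width=20.0, height=6.0,
                layer_thickness=1.25)
    base.update(kw)
    return SimConfig(**base)


class TestMesh:
    def test_printed_discretisation(self):
        mesh = build_mesh(SimConfig())
        assert mesh.n_elements == 5760
        assert mesh.n_dofs == 12050

    def test_tiny_mesh_counts(self):
        mesh = build_mesh(SimConfig(nx=2, ny_substrate=1, ny_layer=1,
                                    width=2.0, height=2.0,
                                    layer_thickness=1.0))
        assert mesh.n_elements == 4
        assert mesh.n_nodes == 9

    def test_positive_jacobians_and_regions(self):
        mesh = build_mesh(small_config())
        assert mesh.jacobians_positive()
        assert mesh.layer_elem.sum() == 8 * 2
        assert len(mesh.top_nodes) == len(mesh.interface_nodes) == 9

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(layer_thickness=30.0)


class TestAssembly:
    def test_stress_free_reference(self):
        cfg = small_config(perturb_amplitude_rel=0.0)
        mesh = build_mesh(cfg)
        asm = Assembler(mesh, cfg)
        R, K = asm.assemble(np.zeros(mesh.n_dofs), 1.0)
        assert np.abs(R).max() < 1e-12
        assert K.shape == (mesh.n_dofs, mesh.n_dofs)

    @pytest.mark.parametrize("frame_correct", [False, True])
    def test_tangent_matches_finite_differences(self, frame_correct, rng):
        cfg = small_config(frame_correct=frame_correct)
        mesh = build_mesh(cfg)
        asm = Assembler(mesh, cfg)
        u = 0.01 * rng.standard_normal(mesh.n_dofs)
        theta = 1.3
        R, K = asm.assemble(u, theta)
        eps = 1e-6
        cols = rng.choice(mesh.n_dofs, 8, replace=False)
        for c in cols:
            up, um = u.copy(), u.copy()
            up[c] += eps
            um[c] -= eps
            Rp, _ = asm.assemble(up, theta, want_K=False)
            Rm, _ = asm.assemble(um, theta, want_K=False)
            fd = (Rp - Rm) / (2 * eps)
            col = np.asarray(K[:, c].todense()).ravel()
            denom = max(np.abs(col).max(), 1e-10)
            assert np.abs(fd - col).max() / denom < 1e-6

    def test_energy_law_tangent_symmetric(self, rng):
        cfg = small_config(frame_correct=True)
        mesh = build_mesh(cfg)
        asm = Assembler(mesh, cfg)
        u = 0.01 * rng.standard_normal(mesh.n_dofs)
        _, K = asm.assemble(u, 1.25)
        K = K.toarray()
        assert np.abs(K - K.T).max() < 1e-9 * np.abs(K).max()

    def test_residual_is_energy_gradient(self, rng):
        # energy consistency of the frame-correct (hyperelastic) law
        cfg = small_config(frame_correct=True)
        mesh = build_mesh(cfg)
        asm = Assembler(mesh, cfg)
        u = 0.02 * rng.standard_normal(mesh.n_dofs)
        v = rng.standard_normal(mesh.n_dofs)
        theta = 1.2
        R, _ = asm.assemble(u, theta, want_K=False)
        eps = 1e-6
        dE = (asm.internal_energy(u + eps * v, theta)
              - asm.internal_energy(u - eps * v, theta)) / (2 * eps)
        assert dE == pytest.approx(float(R @ v), rel=1e-5, abs=1e-8)

    def test_element_inversion_signalled(self):
        cfg = small_config()
        mesh = build_mesh(cfg)
        asm = Assembler(mesh, cfg)
        u = np.zeros(mesh.n_dofs)
        u[1::2] = -10.0 * mesh.nodes[:, 1]  # crushes elements
        R, K = asm.assemble(u, 1.0)
        assert R is None and K is None


class TestSolver:
    def test_newton_converges_superlinearly(self):
        cfg = small_config(perturb_amplitude_rel=0.0)
        mesh = build_mesh(cfg)
        asm = Assembler(mesh, cfg)
        u, ok, hist = newton_solve(asm, np.zeros(mesh.n_dofs), 1.25)
        assert ok
        tail = [h for h in hist if h > 1e-12]
        ratios = [tail[i + 1] / tail[i] for i in range(len(tail) - 1)]
        assert ratios[-1] < 0.1 * ratios[0] or ratios[-1] < 1e-3

    def test_flat_branch_homogeneous_before_instability(self):
        cfg = small_config(nx=20, perturb_amplitude_rel=0.0,
                           theta_max=1.2, dtheta=0.05, theta_watch=2.0)
        traj = run_growth(cfg)
        assert traj.termination == "theta_max"
        st = traj.states[-1]
        pair = cf.extract_surfaces(st.u, traj.mesh, traj.nodes)
        var = np.var(pair.top[:, 1])
        assert var < 1e-6 * cfg.layer_thickness**2

    def test_no_contrast_no_fold(self):
        # identical materials, no perturbation: homogeneous thickening only
        mat = cf.MaterialParams(mu=0.30, lam=2.79, growing=True, G=1.0)
        sub = cf.MaterialParams(mu=0.30, lam=2.79)
        cfg = small_config(nx=20, layer=mat, substrate=sub,
                           perturb_amplitude_rel=0.0, theta_max=1.25,
                           dtheta=0.05, theta_watch=2.0)
        traj = run_growth(cfg)
        pair = cf.extract_surfaces(traj.states[-1].u, traj.mesh, traj.nodes)
        amp = pair.top[:, 1].max() - pair.top[:, 1].min()
        assert amp < 1e-6

    def test_flat_branch_stable_at_low_growth(self):
        cfg = small_config(perturb_amplitude_rel=0.0)
        mesh = build_mesh(cfg)
        asm = Assembler(mesh, cfg)
        u, ok, _ = newton_solve(asm, np.zeros(mesh.n_dofs), 1.1)
        lam, phi = lowest_eigenmode(asm, u, 1.1)
        assert lam > 0


class TestContactDetection:
    def test_flat_no_contact(self):
        x = np.linspace(0, 10, 50)
        y = np.zeros(50)
        contact, _ = detect_self_contact(x, y, gap=0.1, min_separation=1.0,
                                         ref_x=x)
        assert not contact

    def test_constructed_near_touch(self):
        # a hairpin: two legs brought within gap/2 of each other
        gap = 0.2
        x = np.concatenate([np.zeros(10), np.full(10, gap / 2)])
        y = np.concatenate([np.linspace(0, 5, 10), np.linspace(5, 0, 10)])
        ref = np.linspace(0, 10, 20)
        contact, pts = detect_self_contact(x, y, gap=gap, min_separation=2.0,
                                           ref_x=ref)
        assert contact and len(pts) > 0


class TestCascadeSmoke:
    """Quarter-resolution qualitative cascade (shared session fixture)."""

    def test_reaches_folding_and_termination(self, smoke_trajectory):
        assert smoke_trajectory.termination in ("self-contact", "theta_max")
        assert smoke_trajectory.n_kicks >= 1  # instability was crossed

    def test_thickness_asymmetry_emerges(self, smoke_metrics):
        tab = smoke_metrics["table"]
        assert smoke_metrics["theta_first"] is not None
        assert tab.kappa.iloc[-1] > 0.01  # gyri thicker than sulci

    def test_wavelength_scale(self, smoke_metrics):
        tab = smoke_metrics["table"]
        folded = tab[(tab.kappa > 0.005) & np.isfinite(tab.wavelength)]
        wl = folded.wavelength.iloc[0]
        # folding wavelength ~ 10x layer thickness at this resolution
        assert 6.0 < wl < 25.0

    def test_gyral_nondecreasing_sulcal_nonincreasing(self, smoke_metrics):
        tab = smoke_metrics["table"]
        post = tab[tab.kappa > 0.005]
        tg, ts = post.t_g.to_numpy(), post.t_s.to_numpy()
        step = np.diff(tg)
        # one-step tolerance for numerics around branch switches
        assert (np.diff(tg) > -0.05).mean() > 0.9
        assert (np.diff(ts) < 0.05).mean() > 0.9
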