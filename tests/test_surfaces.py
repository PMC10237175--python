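import numpy as np
import pandas as pd
import pytest

import cortexfold as cf
from cortexfold.surfaces import (GYRAL, SULCAL, HMRFSegmenter, LabeledSurface,
                                 ScalingInput, area_weighted_stats,
                                 compare_classes, edge_adjacency,
                                 hmrf_em_label, scaling_k, vertex_areas)
from cortexfold.synthetic import SurfaceSpec, gen_labeled_surface


@pytest.fixture(scope="module")
def separated_surface():
    """Well-separated class-conditional curvature (5 sd between means)."""
    spec = SurfaceSpec(seed=7, nx=60, ny=60, curvature_mean=0.25,
                       curvature_sd=0.05)
    return gen_labeled_surface(spec)


class TestHMRF:
    def test_high_accuracy_on_separated_classes(self, separated_surface):
        surf, truth = separated_surface
        labels = hmrf_em_label(surf.curvature, faces=surf.faces)
        acc = (labels == truth["labels"]).mean()
        assert acc >= 0.99

    def test_matches_bayes_oracle(self, separated_surface):
        # oracle: Bayes rule with the true generator parameters
        surf, truth = separated_surface
        mu0, mu1 = truth["class_curvature_means"]
        bayes = (surf.curvature > 0.5 * (mu0 + mu1)).astype(int)
        labels = hmrf_em_label(surf.curvature, faces=surf.faces)
        assert (labels == bayes).mean() >= 0.99

    def test_zero_smoothness_is_pointwise_ml(self, separated_surface):
        surf, _ = separated_surface
        seg = HMRFSegmenter(smoothness=0.0).fit(surf.curvature,
                                                faces=surf.faces)
        c = surf.curvature
        logp = (-0.5 * ((c[:, None] - seg.means_) / seg.sds_) ** 2
                - np.log(seg.sds_) + np.log(seg.weights_))
        pointwise = (logp[:, 1] > logp[:, 0]).astype(int)
        assert np.array_equal(seg.labels_, pointwise)

    def test_permutation_consistency(self, separated_surface, rng):
        surf, _ = separated_surface
        n = len(surf.curvature)
        perm = rng.permutation(n)
        inv = np.empty(n, int)
        inv[perm] = np.arange(n)
        A = edge_adjacency(n, surf.faces)
        lab = hmrf_em_label(surf.curvature, adjacency=A)
        A_p = A[perm][:, perm]
        lab_p = hmrf_em_label(surf.curvature[perm], adjacency=A_p)
        assert np.array_equal(lab_p, lab[perm])

    def test_constant_field_degenerate(self):
        faces = np.array([[0, 1, 2], [1, 3, 2]])
        with pytest.warns(UserWarning, match="constant curvature"):
            hmrf_em_label(np.zeros(4), faces=faces)

    def test_smoothness_repairs_noisy_vertices(self, rng):
        # overlapping classes: the Potts prior must beat pointwise ML
        spec = SurfaceSpec(seed=3, nx=50, ny=50, curvature_mean=0.08,
                           curvature_sd=0.08)
        surf, truth = gen_labeled_surface(spec)
        a0 = (hmrf_em_label(surf.curvature, faces=surf.faces,
                            smoothness=0.0) == truth["labels"]).mean()
        a1 = (hmrf_em_label(surf.curvature, faces=surf.faces,
                            smoothness=1.5) == truth["labels"]).mean()
        assert a1 > a0


class TestAreaWeightedStats:
    def _flat_surface(self, thickness, labels, region=None):
        nx = ny = 11
        xs, ys = np.meshgrid(np.linspace(0, 10, nx), np.linspace(0, 10, ny))
        verts = np.column_stack([xs.ravel(), ys.ravel(),
                                 np.zeros(nx * ny)])
        ix, iy = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1))
        n0 = (iy * nx + ix).ravel()
        faces = np.vstack([
            np.column_stack([n0, n0 + 1, n0 + nx]),
            np.column_stack([n0 + 1, n0 + 1 + nx, n0 + nx])])
        n = nx * ny
        if region is None:
            region = np.zeros(n, int)
        return LabeledSurface(vertices=verts, faces=faces,
                              thickness=np.asarray(thickness, float),
                              curvature=np.zeros(n),
                              labels=np.asarray(labels), region=region)

    def test_uniform_thickness_ratio_one(self):
        n = 121
        labels = np.tile([GYRAL, SULCAL], 61)[:n]
        s = self._flat_surface(np.full(n, 3.3), labels)
        summ = area_weighted_stats(s)
        assert summ.by_class["mean"].tolist() == pytest.approx([3.3, 3.3])
        assert summ.ratio == pytest.approx(1.0)

    def test_area_weighted_pooling(self):
        # two thickness populations with 1:3 area split pool to 3.5
        w = np.array([1.0, 3.0])
        t = np.array([2.0, 4.0])
        pooled = np.sum(w * t) / w.sum()
        assert pooled == pytest.approx(3.5)
        n = 121
        x = np.linspace(0, 10, 11)
        xs = np.meshgrid(x, x)[0].ravel()
        thickness = np.where(xs < 2.5, 2.0, 4.0)  # quarter/three-quarter
        s = self._flat_surface(thickness, np.full(n, GYRAL))
        summ = area_weighted_stats(s)
        assert summ.by_class.loc["gyral", "mean"] == pytest.approx(3.5,
                                                                   abs=0.2)

    def test_generator_recovery_and_ratio(self):
        spec = SurfaceSpec(seed=11, nx=100, ny=100)
        surf, truth = gen_labeled_surface(spec)
        summ = area_weighted_stats(surf)
        for cls, target in (("gyral", truth["gyral_mean"]),
                            ("sulcal", truth["sulcal_mean"])):
            m = summ.by_class.loc[cls, "mean"]
            n = summ.by_class.loc[cls, "n_vertices"]
            se = spec.thickness_sd / np.sqrt(n)
            assert abs(m - target) < 3 * se
        assert summ.ratio == pytest.approx(2.74 / 2.37, abs=0.01)

    def test_mean_bounded_by_extremes(self):
        spec = SurfaceSpec(seed=2, nx=40, ny=40)
        surf, _ = gen_labeled_surface(spec)
        summ = area_weighted_stats(surf)
        inc = surf.included_mask()
        for cls in ("gyral", "sulcal"):
            m = summ.by_class.loc[cls, "mean"]
            assert surf.thickness[inc].min() <= m <= surf.thickness[inc].max()

    def test_histogram_masses_sum_to_area_fraction(self):
        spec = SurfaceSpec(seed=5, nx=30, ny=30)
        surf, _ = gen_labeled_surface(spec)
        summ = area_weighted_stats(surf)
        assert summ.hist_gyral.sum() + summ.hist_sulcal.sum() == \
            pytest.approx(1.0, abs=1e-6)

    def test_excluded_region_dropped_and_empty_class_flagged(self):
        n = 121
        labels = np.full(n, GYRAL)
        region = np.zeros(n, int)
        region[:40] = 1
        s = self._flat_surface(np.full(n, 2.0), labels, region)
        s.excluded_regions = (1,)
        summ = area_weighted_stats(s)
        assert np.isnan(summ.by_class.loc["sulcal", "mean"])
        reg_ids = summ.by_region.region.unique().tolist()
        assert summ.by_region[summ.by_region.region == 1]["n_vertices"].sum() == 0 \
            or 1 not in reg_ids

    def test_vertex_areas_sum_to_mesh_area(self):
        spec = SurfaceSpec(seed=1, nx=20, ny=20)
        surf, _ = gen_labeled_surface(spec)
        import trimesh

        m = trimesh.Trimesh(vertices=surf.vertices, faces=surf.faces,
                            process=False)
        assert vertex_areas(surf.vertices, surf.faces).sum() == \
            pytest.approx(m.area, rel=1e-10)


class TestCompareClasses:
    def test_identical_samples(self):
        x = np.array([2.0, 2.0, 2.0])
        stat, dof, p = compare_classes(x, x)
        assert stat == 0.0 and p == 1.0

    def test_swapped_inputs_negate_statistic(self, rng):
        g = 2.7 + 0.1 * rng.standard_normal(30)
        s = 2.3 + 0.1 * rng.standard_normal(30)
        st1 = compare_classes(g, s)
        st2 = compare_classes(s, g)
        assert st1[0] == pytest.approx(-st2[0])
        assert st1[2] == pytest.approx(st2[2])

    def test_large_gap_tiny_p(self, rng):
        # 0.4 mm gap, n = 73 regions, 0.1 mm spread: noncentrality ~ 24,
        # so p is far below 1e-10 (closed-form power oracle)
        g = 2.9 + 0.1 * rng.standard_normal(73)
        s = 2.5 + 0.1 * rng.standard_normal(73)
        stat, dof, p = compare_classes(g, s)
        assert p < 1e-10
        assert stat > 10

    def test_agrees_with_scipy_welch(self, rng):
        from scipy import stats as ss

        g = 2.7 + 0.2 * rng.standard_normal(25)
        s = 2.5 + 0.05 * rng.standard_normal(40)
        stat, dof, p = compare_classes(g, s)
        ref = ss.ttest_ind(g, s, equal_var=False)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestScalingLaw:
    def test_human_brain_value(self):
        k = scaling_k(ScalingInput(A_e=594.0, A_t=1791.0, t_c=0.258))
        assert k == pytest.approx(1791 * np.sqrt(0.258) / 594**1.25)
        assert round(k, 3) == 0.310

    def test_unfolded_limit(self):
        # A_t = A_e, t_c = 1 cm: k = A_e^{-1/4}
        k = scaling_k(ScalingInput(A_e=16.0, A_t=16.0, t_c=1.0))
        assert k == pytest.approx(16.0 ** -0.25)

    def test_linear_in_total_area(self):
        k1 = scaling_k(ScalingInput(A_e=100.0, A_t=300.0, t_c=0.25))
        k2 = scaling_k(ScalingInput(A_e=100.0, A_t=600.0, t_c=0.25))
        assert k2 == pytest.approx(2 * k1)

    def test_unit_guard(self):
        with pytest.raises(ValueError):
            ScalingInput(A_e=594.0, A_t=100.0, t_c=0.258)  # A_t < A_e
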