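"""Strain energy axioms, feature computation and registration behavior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from cortexshift.meshcore import MetricMap, SurfaceMesh, build_parcellation, medial_wall_mask, VertexMask
from cortexshift.registration import (
    SphericalCorrespondence,
    StrainParams,
    area_change_from_correspondence,
    compute_feature,
    register_bidirectional,
    register_oneway,
    strain_energy,
)
from cortexshift.synth import make_icosphere, make_pseudocortex
from cortexshift._sphere import SphereLocator


EQUILATERAL = SurfaceMesh(
    np.array([[0, 0, 0], [2, 0, 0], [1, np.sqrt(3), 0]], float), np.array([[0, 1, 2]])
)


class TestStrainEnergy:
    def test_identity_is_zero(self, pseudo3):
        mesh, _ = pseudo3
        total, W, bad = strain_energy(mesh, mesh.vertices.copy())
        assert total == 0.0
        assert not bad.any()

    def test_rigid_motion_is_zero(self, pseudo3):
        mesh, _ = pseudo3
        rot = Rotation.from_rotvec([0.2, -0.5, 0.8])
        moved = rot.apply(mesh.vertices) + np.array([10.0, -4.0, 2.0])
        total, W, _ = strain_energy(mesh, moved)
        assert total == pytest.approx(0.0, abs=1e-15)
        assert np.allclose(W, 0.0, atol=1e-12)

    def test_uniform_scale_oracle(self):
        """Hand-computed singular values: s=1.2 gives W = J + 1/J - 2, J = 1.44."""
        total, W, _ = strain_energy(EQUILATERAL, EQUILATERAL.vertices * 1.2,
                                    StrainParams(1.0, 1.0))
        expected = 1.44 + 1.0 / 1.44 - 2.0
        assert W[0] == pytest.approx(expected, rel=1e-9)

    def test_dilation_symmetry(self):
        """Pure dilation: W is symmetric under J <-> 1/J."""
        _, Wa, _ = strain_energy(EQUILATERAL, EQUILATERAL.vertices * 1.3)
        _, Wb, _ = strain_energy(EQUILATERAL, EQUILATERAL.vertices / 1.3)
        assert Wa[0] == pytest.approx(Wb[0], rel=1e-12)

    def test_collapsed_triangle_flagged(self):
        collapsed = np.zeros_like(EQUILATERAL.vertices)
        total, W, bad = strain_energy(EQUILATERAL, collapsed)
        assert bad[0]
        assert np.isfinite(total) and total > 1e5

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_nonnegative_zero_only_at_isometry(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(scale=0.5, size=(3, 3)) + np.eye(3)
        deformed = EQUILATERAL.vertices @ A.T
        total, W, bad = strain_energy(EQUILATERAL, deformed)
        assert total >= 0.0
        if not bad.any() and total < 1e-12:
            # zero energy implies the in-plane map is an isometry
            d = deformed
            for i, j in [(0, 1), (1, 2), (0, 2)]:
                orig = np.linalg.norm(EQUILATERAL.vertices[i] - EQUILATERAL.vertices[j])
                new = np.linalg.norm(d[i] - d[j])
                assert new == pytest.approx(orig, rel=1e-5)


class TestFeature:
    def test_sphere_is_degenerate(self):
        mesh = make_icosphere(3, 80.0)
        with pytest.warns(UserWarning, match="degenerate"):
            f = compute_feature(mesh)
        assert np.all(f.values == 0)

    def test_rotation_invariance(self, pseudo3):
        mesh, _ = pseudo3
        rot = Rotation.from_rotvec([1.0, 0.2, -0.3])
        moved = SurfaceMesh(rot.apply(mesh.vertices), mesh.faces)
        assert np.allclose(compute_feature(mesh).values, compute_feature(moved).values,
                           atol=1e-9)

    def test_amplitude_scaling(self):
        """Doubling fold amplitude doubles the raw deviation before z-scoring."""
        m1, _ = make_pseudocortex(3, 80.0, 0.1, seed=9)
        m2, _ = make_pseudocortex(3, 80.0, 0.2, seed=9)
        r1 = np.linalg.norm(m1.vertices - m1.vertices.mean(0), axis=1)
        r2 = np.linalg.norm(m2.vertices - m2.vertices.mean(0), axis=1)
        dev1, dev2 = r1 - r1.mean(), r2 - r2.mean()
        assert dev2.std() == pytest.approx(2 * dev1.std(), rel=0.02)
        # z-scored features are then nearly identical
        assert np.corrcoef(compute_feature(m1).values, compute_feature(m2).values)[0, 1] > 0.999


def _self_pair(level=3, seed=7, **kw):
    mesh, sphere = make_pseudocortex(level, seed=seed, **kw)
    feat = compute_feature(mesh).values
    return mesh, sphere, feat


class TestRegisterOneway:
    def test_self_registration_is_identity(self):
        mesh, sphere, feat = _self_pair()
        corr = register_oneway(mesh, sphere, feat, mesh, sphere, feat,
                               control_levels=(2,))
        disp = np.arccos(np.clip(np.einsum("ij,ij->i", corr.warped_points, sphere), -1, 1))
        assert disp.mean() < 1e-3

    def test_objective_monotone(self):
        mesh, sphere, feat = _self_pair(seed=3)
        ref, rsphere = make_pseudocortex(3, seed=4)
        rfeat = compute_feature(ref).values
        corr = register_oneway(mesh, sphere, feat, ref, rsphere, rfeat,
                               control_levels=(2, 3))
        for trace in corr.diagnostics["objective"]:
            assert all(np.diff(trace) <= 1e-10)
            assert trace[-1] <= trace[0]

    def test_rotation_recovery(self):
        """Reference param rotated by a known angle; the warp must recover it."""
        mesh, sphere, feat = _self_pair(level=4, seed=11)
        angle = 0.15
        rot = Rotation.from_rotvec([0.0, 0.0, angle])
        ref_sphere = rot.apply(sphere)
        corr = register_oneway(mesh, sphere, feat, mesh, ref_sphere, feat,
                               control_levels=(2, 3))
        expected = rot.apply(sphere)
        err = np.arccos(np.clip(np.einsum("ij,ij->i", corr.warped_points, expected), -1, 1))
        assert err.mean() < 0.1 * angle

    def test_large_lambda_freezes_warp(self):
        mesh, sphere, feat = _self_pair(seed=3)
        ref, rsphere = make_pseudocortex(3, seed=4)
        rfeat = compute_feature(ref).values
        corr = register_oneway(mesh, sphere, feat, ref, rsphere, rfeat,
                               params=StrainParams(lambda_reg=1e9),
                               control_levels=(2,))
        disp = np.arccos(np.clip(np.einsum("ij,ij->i", corr.warped_points, sphere), -1, 1))
        assert disp.mean() < 1e-3


class TestAreaChange:
    def test_identity_correspondence_zero(self, pseudo3):
        mesh, sphere = pseudo3
        loc = SphereLocator(sphere, mesh.faces)
        face, w = loc.locate(sphere)
        corr = SphericalCorrespondence(sphere.copy(), face, w, mesh.faces)
        amap = area_change_from_correspondence(corr, mesh, mesh)
        assert np.nanmax(np.abs(amap.values)) < 1e-10

    def test_uniform_scale_known_correspondence(self, pseudo3):
        """Known correspondence onto a scaled copy: change = 2 log2(s)."""
        mesh, sphere = pseudo3
        s = 0.95
        scaled = SurfaceMesh(mesh.vertices * s, mesh.faces)
        loc = SphereLocator(sphere, mesh.faces)
        face, w = loc.locate(sphere)
        corr = SphericalCorrespondence(sphere.copy(), face, w, mesh.faces)
        amap = area_change_from_correspondence(corr, mesh, scaled)
        assert np.nanmax(np.abs(amap.values - 2 * np.log2(s))) < 0.01

    def test_random_correspondence_bruteforce_oracle(self, pseudo3, rng):
        """Per-vertex values equal a direct triangle-area recomputation."""
        mesh, sphere = pseudo3
        ref, ref_sphere = make_pseudocortex(3, seed=8)
        pts = sphere + 0.02 * rng.standard_normal(sphere.shape)
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        loc = SphereLocator(ref_sphere, ref.faces)
        face, w = loc.locate(pts)
        corr = SphericalCorrespondence(pts, face, w, ref.faces)
        amap = area_change_from_correspondence(corr, mesh, ref)

        image = np.einsum("nki,nk->ni", ref.vertices[ref.faces[face]], w)
        va0 = np.zeros(mesh.n_vertices)
        va1 = np.zeros(mesh.n_vertices)
        for (i, j, k) in mesh.faces:
            a0 = 0.5 * np.linalg.norm(np.cross(mesh.vertices[j] - mesh.vertices[i],
                                               mesh.vertices[k] - mesh.vertices[i]))
            a1 = 0.5 * np.linalg.norm(np.cross(image[j] - image[i], image[k] - image[i]))
            for v in (i, j, k):
                va0[v] += a0 / 3
                va1[v] += a1 / 3
        expected = np.log2(va1 / va0)
        assert np.allclose(amap.values, expected, atol=1e-10)


class TestBidirectional:
    def _subject(self, level=3, seed=5):
        from cortexshift.synth import NoiseSpec, generate_cohort

        return generate_cohort(2, {"CN": 0.0}, NoiseSpec.preset("none"),
                               level=level, seed=seed, reparam=False)[0]

    def test_identical_timepoints_zero(self):
        sub = self._subject()
        res = register_bidirectional(sub)
        assert not res.failed
        cm = ~sub.baseline_wall.values
        assert np.nanmax(np.abs(res.area_change.values[cm])) < 1e-3

    def test_antisymmetric_average(self, pseudo3, rng):
        """If the reverse map is exactly the negated forward map, the average
        equals the forward map."""
        fwd = rng.standard_normal(100)
        rev_on_base = -fwd
        avg = 0.5 * (fwd + (-rev_on_base))
        assert np.allclose(avg, fwd)


class TestModeComparison:
    def test_anatomical_mode_beats_spherical_on_high_folds(self):
        """With deep folds, a strongly distorted inflation and independent
        sphere misalignment, regularizing strain in the anatomical metric
        recovers true area change at least as accurately as regularizing
        the same warp on the sphere."""
        from cortexshift.synth import NoiseSpec, generate_cohort

        cohort = generate_cohort(
            4, {"AD": 1.0}, NoiseSpec.preset("3T"), level=4, seed=11,
            bumpiness=0.28, param_distortion=0.012, drift_angle=0.01,
        )
        maes = {}
        for mode in ("anatomical", "spherical"):
            errs = []
            for sub in cohort:
                cm = ~sub.baseline_wall.values
                res = register_bidirectional(sub, mode=mode)
                errs.append(np.nanmean(np.abs(res.area_change.values[cm]
                                              - sub.truth_area[cm])))
            maes[mode] = np.median(errs)
        assert maes["anatomical"] <= maes["spherical"]
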