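"""Vertex-wise tests, TFCE, permutation FWE, and the global/ROI inference."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from cortexshift.meshcore import vertex_areas
from cortexshift.stats import (
    PermutationScheme,
    TfceParams,
    anova_f_map,
    cohens_d,
    global_anova_tukey,
    one_sample_t_map,
    permutation_fwe,
    roi_group_tests,
    tfce_enhance,
)


class TestVertexwiseStats:
    def test_t_formula(self):
        X = np.array([[-0.2], [-0.1], [-0.3]])
        t = one_sample_t_map(X)
        assert t.values[0] == pytest.approx(-3.4641, abs=1e-4)

    def test_t_antisymmetry(self, rng):
        X = rng.standard_normal((8, 30))
        assert np.allclose(one_sample_t_map(-X).values, -one_sample_t_map(X).values)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            t = one_sample_t_map(np.ones((4, 3)))
        assert np.all(t.values == 0)

    def test_f_identical_groups_zero(self, rng):
        X = rng.standard_normal((3, 20))
        F = anova_f_map({"a": X, "b": X.copy()})
        assert np.allclose(F.values, 0.0)

    def test_f_degenerate_within_variance(self):
        F = anova_f_map({"a": np.zeros((2, 4)), "b": np.ones((2, 4))})
        assert np.all(F.values == 0)  # flagged, not inf

    def test_f_matches_scipy_oracle(self, rng):
        groups = {g: rng.standard_normal((3, 25)) for g in "abc"}
        F = anova_f_map(groups)
        for v in range(25):
            expected = sps.f_oneway(*[groups[g][:, v] for g in "abc"]).statistic
            assert F.values[v] == pytest.approx(expected, rel=1e-10)


def _dense_tfce_oracle(values, mesh, E, H, n_steps):
    """Per-threshold connected components, integrated explicitly."""
    va = vertex_areas(mesh).values
    e = mesh.edges()
    out = np.zeros(len(values))
    for sign in (1, -1):
        v = values * sign
        vmax = v.max()
        if vmax <= 0:
            continue
        dh = vmax / n_steps
        for k in range(1, n_steps + 1):
            h = vmax * k / n_steps
            sup = v >= h
            idx = np.flatnonzero(sup)
            keep = sup[e[:, 0]] & sup[e[:, 1]]
            remap = -np.ones(len(v), int)
            remap[idx] = np.arange(len(idx))
            g = coo_matrix(
                (np.ones(keep.sum()), (remap[e[keep, 0]], remap[e[keep, 1]])),
                shape=(len(idx),) * 2,
            )
            _, lab = connected_components(g, directed=False)
            areas = np.bincount(lab, weights=va[idx])
            out[idx] += sign * areas[lab] ** E * h**H * dh
    return out


class TestTfce:
    def test_zero_map(self, ico3):
        out = tfce_enhance(np.zeros(ico3.n_vertices), ico3)
        assert np.all(out.values == 0)

    def test_blob_beats_lone_vertex(self, ico3):
        """Same height, larger extent: every blob vertex gets more enhancement."""
        vals = np.zeros(ico3.n_vertices)
        vals[0] = 1.0
        blob = [100] + [int(v) for v in ico3.edges()[ico3.edges()[:, 0] == 100][:, 1]]
        vals[blob] = 1.0
        out = tfce_enhance(vals, ico3, params=TfceParams(E=1.0, H=2.0))
        assert out.values[blob].min() > out.values[0]

    def test_scaling_monotonicity(self, ico3, rng):
        vals = np.abs(rng.standard_normal(ico3.n_vertices))
        a = tfce_enhance(vals, ico3).values
        b = tfce_enhance(1.5 * vals, ico3).values
        nz = a > 0
        assert np.all(b[nz] > a[nz])

    def test_matches_dense_integration_oracle(self, ico3, rng):
        vals = np.zeros(ico3.n_vertices)
        sel = rng.choice(ico3.n_vertices, 100, replace=False)
        vals[sel] = rng.standard_normal(100)
        out = tfce_enhance(vals, ico3, params=TfceParams(n_steps=2000)).values
        oracle = _dense_tfce_oracle(vals, ico3, 1.0, 2.0, 2000)
        scale = np.abs(oracle).max()
        assert np.max(np.abs(out - oracle)) / scale < 0.01


class TestPermutationFwe:
    def test_determinism(self, ico3, rng):
        X = rng.standard_normal((8, ico3.n_vertices))
        kw = dict(scheme=PermutationScheme("sign_flip", 200, seed=9, exhaustive=False))
        a = permutation_fwe(X, "one_sample", ico3, **kw)
        b = permutation_fwe(X, "one_sample", ico3, **kw)
        assert np.array_equal(a.fwe_p_map.values, b.fwe_p_map.values)

    def test_strong_signal_hits_floor(self, ico3, rng):
        X = rng.normal(-0.5, 0.05, (12, ico3.n_vertices))
        rep = permutation_fwe(
            X, "one_sample", ico3,
            scheme=PermutationScheme("sign_flip", 400, seed=1, exhaustive=False),
        )
        assert rep.fwe_p_map.values.min() == pytest.approx(1 / rep.n_permutations)

    def test_exhaustive_vs_sampled_agree(self, ico3, rng):
        """n=10 sign-flips: all 1024 flips vs 511 sampled, p within 0.05."""
        X = rng.normal(-0.08, 0.1, (10, ico3.n_vertices))
        full = permutation_fwe(
            X, "one_sample", ico3, scheme=PermutationScheme("sign_flip", 1023, 0, True)
        )
        sampled = permutation_fwe(
            X, "one_sample", ico3,
            scheme=PermutationScheme("sign_flip", 511, seed=4, exhaustive=False),
        )
        assert np.max(np.abs(full.fwe_p_map.values - sampled.fwe_p_map.values)) < 0.05

    def test_identity_floor(self, ico3, rng):
        rep = permutation_fwe(
            rng.standard_normal((8, ico3.n_vertices)), "one_sample", ico3,
            scheme=PermutationScheme("sign_flip", 150, seed=2, exhaustive=False),
        )
        assert rep.fwe_p_map.values.min() >= 1 / rep.n_permutations

    def test_too_few_subjects_refused(self, ico3, rng):
        with pytest.raises(ValueError, match="distinct permutations"):
            permutation_fwe(
                rng.standard_normal((3, ico3.n_vertices)), "one_sample", ico3,
                scheme=PermutationScheme("sign_flip", 100, 0, True),
            )


class TestGlobalInference:
    def test_identical_groups(self):
        res = global_anova_tukey({"a": np.array([1.0, 1.0, 1.0]),
                                  "b": np.array([1.0, 1.0, 1.0])})
        assert res["F"] == 0.0
        assert np.all(res["pairwise"]["cohens_d"] == 0.0)

    def test_translation_invariance_of_d(self, rng):
        x, y = rng.standard_normal(6), rng.standard_normal(6)
        assert cohens_d(x, y) == pytest.approx(cohens_d(x + 5, y + 5))

    def test_d_formula(self):
        """Means 1 and 2 with pooled SD 0.5 give d = -2."""
        x = np.array([0.5, 1.5])  # mean 1, sd ~0.707... construct exact pooled 0.5
        x = np.array([1 - 0.5 / np.sqrt(2), 1 + 0.5 / np.sqrt(2)])
        y = x + 1.0
        assert np.std(x, ddof=1) == pytest.approx(0.5)
        assert cohens_d(x, y) == pytest.approx(-2.0)

    def test_tukey_matches_scipy(self, rng):
        groups = {g: rng.standard_normal(7) + i for i, g in enumerate("abc")}
        res = global_anova_tukey(groups)
        ref = sps.tukey_hsd(*groups.values())
        for row, (i, j) in zip(res["pairwise"].itertuples(),
                               itertools.combinations(range(3), 2)):
            assert row.tukey_p == pytest.approx(ref.pvalue[i, j], rel=1e-9)


def _toy_roi_table(rng, n_per_group=8, n_roi=3, shift=0.0):
    rows = []
    for g, delta in [("A", 0.0), ("B", shift)]:
        for s in range(n_per_group):
            for roi in range(1, n_roi + 1):
                val = rng.normal(delta * roi, 0.1)
                rows.append(
                    {"subject_id": f"{g}{s}", "group": g, "roi": roi,
                     "d_thick_log2": val, "d_area_log2": val / 2,
                     "d_vol_log2": 1.5 * val}
                )
    return pd.DataFrame(rows)


class TestRoiGroupTests:
    def test_pillai_matches_eigen_oracle(self, rng):
        table = _toy_roi_table(rng, shift=0.3)
        res = roi_group_tests(table, metrics=("d_thick_log2",))
        wide = table.pivot_table(index=["subject_id", "group"], columns="roi",
                                 values="d_thick_log2")
        labels = np.array([g for (_, g) in wide.index])
        Y = wide.to_numpy()
        grand = Y.mean(axis=0)
        H = np.zeros((Y.shape[1],) * 2)
        E = np.zeros_like(H)
        for g in np.unique(labels):
            Yg = Y[labels == g]
            d = (Yg.mean(axis=0) - grand)[:, None]
            H += len(Yg) * d @ d.T
            R = Yg - Yg.mean(axis=0)
            E += R.T @ R
        eig = np.linalg.eigvals(np.linalg.solve(E, H)).real
        pillai_oracle = float(np.sum(eig / (1 + eig)))
        assert res["manova"]["d_thick_log2"]["pillai"] == pytest.approx(
            pillai_oracle, abs=1e-10
        )

    def test_identical_groups_null(self, rng):
        table = _toy_roi_table(rng, shift=0.0)
        res = roi_group_tests(table, metrics=("d_thick_log2",))
        assert res["manova"]["d_thick_log2"]["p"] > 0.01
        assert (res["pairwise"]["p_bonferroni"] <= 1.0).all()

    def test_bonferroni_arithmetic(self):
        assert min(1.0, 0.01 * 20) == pytest.approx(0.2)

    def test_small_n_reduces_rois(self, rng):
        rows = []
        for g in ("A", "B"):
            for s in range(3):
                for roi in range(1, 9):
                    rows.append({"subject_id": f"{g}{s}", "group": g, "roi": roi,
                                 "d_thick_log2": rng.normal(), "d_area_log2": 0.0,
                                 "d_vol_log2": 0.0})
        with pytest.warns(UserWarning, match="reducing ROI set"):
            roi_group_tests(pd.DataFrame(rows), metrics=("d_thick_log2",))
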