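"""Thresholding, %PAAS and cross-timepoint threshold matching."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

from atriascar import (
    SurfaceMesh,
    match_threshold,
    paas,
    threshold_iir,
    threshold_zscore,
)
from atriascar.shell_projection import ShellScalarMap

from oracles import exhaustive_match


def _square_mesh(n=2, side=1.0):
    """A flat n x n grid of right triangles (2 n^2 equal-area faces)."""
    xs = np.linspace(0, side * n, n + 1)
    verts = np.array([[x, y, 0.0] for x in xs for y in xs])
    faces = []
    for i in range(n):
        for j in range(n):
            a = i * (n + 1) + j
            b = a + 1
            c = a + (n + 1)
            d = c + 1
            faces += [[a, b, c], [b, d, c]]
    return SurfaceMesh(verts, np.array(faces))


def _map_from_values(values, mesh=None):
    values = np.asarray(values, dtype=float)
    if mesh is None:
        ico = trimesh.creation.icosphere(subdivisions=0, radius=10.0)
        mesh = SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
        values = np.resize(values, mesh.n_faces)
    return ShellScalarMap(mesh, values)


def _random_map(rng, n_faces=200):
    """A map on a 320-face icosphere trimmed to n_faces valid values."""
    ico = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
    mesh = SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
    values = rng.normal(100, 20, mesh.n_faces)
    values[n_faces:] = np.nan  # exercise missing-face exclusion too
    return ShellScalarMap(mesh, values)


class TestThresholds:
    def test_zscore_worked_case_strict_boundary(self):
        m = _map_from_values([133.0, 133.01, 50.0, 140.0] * 5)
        lab = threshold_zscore(m, bp_mean=100.0, bp_sd=10.0, k=3.3)
        assert lab.absolute_cutoff == pytest.approx(133.0)
        assert not lab.scar[0]  # exactly at cutoff is NOT scar
        assert lab.scar[1] and lab.scar[3] and not lab.scar[2]

    def test_zscore_limits(self):
        m = _map_from_values(np.linspace(10, 20, 20))
        assert not threshold_zscore(m, 100, 10, k=1e9).scar.any()
        all_scar = threshold_zscore(m, 0, 1, k=5.0)  # cutoff 5 < min value 10
        assert all_scar.scar.all()
        assert paas(all_scar).paas_fraction == 1.0

    def test_iir_worked_cases(self):
        m = _map_from_values([131.0, 133.0, 96.0, 98.0] * 5)
        lab = threshold_iir(m, bp_mean=100.0, r=1.32)
        assert lab.absolute_cutoff == pytest.approx(132.0)
        assert list(lab.scar[:4]) == [False, True, False, False]
        baseline = threshold_iir(m, bp_mean=100.0, r=0.97)  # native-fibrosis ratio
        assert baseline.absolute_cutoff == pytest.approx(97.0)
        assert list(baseline.scar[:4]) == [True, True, False, True]

    def test_iir_zero_ratio_marks_positive_values(self):
        m = _map_from_values([-1.0, 0.0, 0.5, 2.0] * 5)
        lab = threshold_iir(m, bp_mean=100.0, r=0.0)
        assert list(lab.scar[:4]) == [False, False, True, True]

    def test_invalid_reference_stats(self):
        m = _map_from_values(np.ones(20))
        with pytest.raises(ValueError):
            threshold_zscore(m, 100, 0.0, 3.3)
        with pytest.raises(ValueError):
            threshold_iir(m, -5.0, 1.32)

    @given(
        k1=st.floats(-2, 8),
        k2=st.floats(-2, 8),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=50, deadline=None)
    def test_paas_monotone_in_threshold(self, k1, k2, seed):
        rng = np.random.default_rng(seed)
        m = _random_map(rng)
        lo, hi = sorted((k1, k2))
        p_lo = paas(threshold_zscore(m, 100, 10, lo), m).paas_fraction
        p_hi = paas(threshold_zscore(m, 100, 10, hi), m).paas_fraction
        assert p_hi <= p_lo

    @given(k=st.floats(-2, 8), seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_zscore_iir_mode_consistency(self, k, seed):
        # iir with r = (mean + k sd) / mean must reproduce the zscore labeling
        rng = np.random.default_rng(seed)
        m = _random_map(rng)
        mean, sd = 100.0, 10.0
        a = threshold_zscore(m, mean, sd, k)
        b = threshold_iir(m, mean, (mean + k * sd) / mean)
        assert np.array_equal(a.scar, b.scar)


class TestPaas:
    def test_equal_area_quarters(self):
        mesh = _square_mesh(n=2)  # 8 equal faces
        values = np.array([10, 10, 1, 1, 1, 1, 1, 1], dtype=float)
        lab = threshold_zscore(ShellScalarMap(mesh, values), 0, 1, 5.0)
        assert paas(lab).paas_fraction == pytest.approx(0.25)

    def test_limits(self):
        m = _map_from_values(np.linspace(10, 20, 20))
        assert paas(threshold_zscore(m, 100, 10, 10)).paas_fraction == 0.0
        assert paas(threshold_zscore(m, 0, 1, 1)).paas_fraction == 1.0

    def test_unequal_areas_match_direct_summation(self, rng):
        ico = trimesh.creation.icosphere(subdivisions=1, radius=10.0)
        verts = np.asarray(ico.vertices) * np.array([1.0, 1.7, 0.6])  # skew areas
        mesh = SurfaceMesh(verts, np.asarray(ico.faces))
        values = rng.normal(100, 15, mesh.n_faces)
        lab = threshold_zscore(ShellScalarMap(mesh, values), 100, 15, 0.5)
        expected = mesh.face_areas[lab.scar].sum() / mesh.face_areas.sum()
        assert paas(lab).paas_fraction == pytest.approx(expected, rel=1e-12)

    def test_count_weighting(self, rng):
        m = _random_map(rng, n_faces=320)
        lab = threshold_zscore(m, 100, 20, 0.0)
        assert paas(lab, weighting="count").paas_fraction == pytest.approx(
            lab.scar.mean()
        )

    def test_missing_faces_excluded(self, rng):
        m = _random_map(rng, n_faces=200)
        lab = threshold_zscore(m, 100, 20, -100.0)  # everything valid is scar
        res = paas(lab, m)
        assert res.excluded_faces == 120
        assert res.paas_fraction == pytest.approx(1.0)


class TestMatchThreshold:
    def test_order_statistics_on_distinct_equal_area_values(self):
        mesh = _square_mesh(n=4)  # 32 equal-area faces
        rng = np.random.default_rng(5)
        values = rng.permutation(np.linspace(10, 40, 32))
        m = ShellScalarMap(mesh, values)
        target = 8 / 32
        res = match_threshold(m, 100, 10, "zscore", target)
        v_sorted = np.sort(values)[::-1]
        assert res.achieved_paas == pytest.approx(target)
        # the cutoff is the 9th-largest value: exactly 8 values exceed it
        assert res.absolute_cutoff == pytest.approx(v_sorted[8])

    def test_self_consistency_with_fixed_threshold(self, rng):
        m = _random_map(rng)
        mean, sd = 100.0, 10.0
        target = paas(threshold_zscore(m, mean, sd, 3.3), m).paas_fraction
        res = match_threshold(m, mean, sd, "zscore", target)
        # same plateau: re-thresholding at the matched cutoff reproduces the burden
        relabel = threshold_zscore(m, mean, sd, res.threshold_value)
        assert paas(relabel, m).paas_fraction == pytest.approx(target)

    def test_matches_exhaustive_sweep(self, rng):
        for _ in range(3):
            m = _random_map(rng)
            valid = m.valid
            w = m.mesh.face_areas[valid]
            v = m.values[valid]
            for target in rng.uniform(0.02, 0.95, 50):
                expected = exhaustive_match(v, w, target)
                res = match_threshold(m, 100, 10, "zscore", float(target))
                assert res.absolute_cutoff == pytest.approx(expected[0], abs=0)
                assert res.achieved_paas == pytest.approx(expected[1], rel=1e-12)

    def test_iir_mode_units(self, rng):
        m = _random_map(rng)
        res = match_threshold(m, 80.0, 10.0, "iir", 0.3)
        assert res.threshold_value == pytest.approx(res.absolute_cutoff / 80.0)

    def test_unattainable_target_errors(self, rng):
        m = _random_map(rng, n_faces=320)
        with pytest.raises(ValueError, match="unattainable"):
            match_threshold(m, 100, 10, "zscore", 0.9999)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_target_domain(self, rng, bad):
        m = _random_map(rng)
        with pytest.raises(ValueError, match="target_paas"):
            match_threshold(m, 100, 10, "zscore", bad)
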