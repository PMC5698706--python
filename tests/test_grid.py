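"""Grid geometry, dielectric/screening maps, B-spline charge discretization."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cupredox as cx
from cupredox.grid import (
    GridError,
    GridSpec,
    ScalarField,
    build_dielectric_map,
    build_screening_map,
    interpolate,
    solvent_excluded_mask,
    spread_charges,
)


class TestGridSpec:
    def test_default_matches_published_setup(self):
        g = GridSpec()
        assert g.length == 57.8
        assert g.n_points == 290  # 289 intervals of 0.2 A
        assert g.spacing == pytest.approx(57.8 / 289)

    def test_spacing_recomputed_from_node_count(self):
        g = GridSpec((0, 0, 0), 16.0, 0.3)  # 53.3 intervals -> 53
        assert g.n_points == 54
        assert g.spacing == pytest.approx(16.0 / 53)

    def test_too_coarse_rejected(self):
        with pytest.raises(GridError, match="33"):
            GridSpec((0, 0, 0), 10.0, 1.0)


class TestDielectricMap:
    def test_empty_structure_uniform_solvent(self):
        empty = cx.as_parameterized(cx.Structure([]))
        g = GridSpec((0, 0, 0), 16.0, 0.4)
        eps = build_dielectric_map(empty, g)
        np.testing.assert_allclose(eps.values, 78.0)

    def test_born_ion_limiting_regions(self, born_ion_ps):
        ps = born_ion_ps(q=1.0, radius=2.0)
        g = GridSpec((0, 0, 0), 24.0, 0.4)
        eps = build_dielectric_map(ps, g)
        c = g.n_points // 2
        assert eps.values[c, c, c] == pytest.approx(4.0)
        i10 = c + int(round(10.0 / g.spacing))
        assert eps.values[i10, c, c] == pytest.approx(78.0)

    def test_values_bounded_by_endpoints(self, born_ion_ps):
        ps = born_ion_ps()
        g = GridSpec((0, 0, 0), 16.0, 0.4)
        eps = build_dielectric_map(ps, g)
        assert eps.values.min() >= 4.0 - 1e-9
        assert eps.values.max() <= 78.0 + 1e-9

    def test_reentrant_region_is_interior(self):
        """Nodes between two atoms closer than a probe diameter are inside the
        solvent-excluded surface; verified against a brute-force rolling-probe
        membership test."""
        probe, r = 1.4, 1.6
        sep = 4.4  # gap of 1.2 A < 2*probe: probe cannot pass between
        pair = cx.as_parameterized(cx.make_fixture(
            "charge_pair", {"q1": 0.0, "q2": 0.0, "separation": sep, "radius": r}))
        g = GridSpec((0, 0, 0), 16.0, 0.2)
        inside = solvent_excluded_mask(pair, g, probe)
        c = g.n_points // 2
        assert inside[c, c, c]  # midpoint: excluded volume despite no atom overlap

        # brute-force SES: a point is solvent iff within `probe` of some probe
        # center that itself clears both inflated spheres
        centers = np.array([[-sep / 2, 0, 0], [sep / 2, 0, 0]])
        rng = np.random.default_rng(0)
        pts = rng.uniform(-4, 4, size=(300, 3))
        # candidate probe centers on a fine lattice
        axes = np.linspace(-8, 8, 81)
        px, py, pz = np.meshgrid(axes, axes, axes, indexing="ij")
        probes = np.stack([px.ravel(), py.ravel(), pz.ravel()], axis=1)
        ok = np.all(
            np.linalg.norm(probes[:, None, :] - centers[None], axis=2) >= r + probe,
            axis=1,
        )
        probes = probes[ok]
        for p in pts:
            idx = np.round((p - g.origin) / g.spacing).astype(int)
            node = g.origin + idx * g.spacing
            probe_dist = np.min(np.linalg.norm(probes - node, axis=1))
            # skip nodes within a lattice tolerance of the SES boundary (the
            # locus where the nearest valid probe center is exactly `probe` away)
            if abs(probe_dist - probe) < 0.3:
                continue
            in_vdw_n = np.any(np.linalg.norm(centers - node, axis=1) <= r)
            expected_at_node = in_vdw_n or probe_dist > probe
            assert inside[tuple(idx)] == expected_at_node, node

    def test_structure_beyond_grid_rejected(self, born_ion_ps):
        ps = born_ion_ps(center=(10.0, 0.0, 0.0))
        with pytest.raises(GridError, match="beyond"):
            build_dielectric_map(ps, GridSpec((0, 0, 0), 16.0, 0.4))


class TestScreeningMap:
    def test_zero_ionic_strength_zero_field(self, born_ion_ps):
        g = GridSpec((0, 0, 0), 16.0, 0.4)
        kap = build_screening_map(born_ion_ps(), g, ionic_strength=0.0)
        assert not np.any(kap.values)

    def test_uniform_for_empty_structure(self):
        empty = cx.as_parameterized(cx.Structure([]))
        g = GridSpec((0, 0, 0), 16.0, 0.4)
        kap = build_screening_map(empty, g, ionic_strength=0.15)
        assert np.all(kap.values > 0)
        assert np.ptp(kap.values) == 0.0
        lam = cx.debye_length(0.15)
        assert kap.values[0, 0, 0] == pytest.approx(78.0 / lam**2)

    def test_kappa2_proportional_to_ionic_strength(self):
        empty = cx.as_parameterized(cx.Structure([]))
        g = GridSpec((0, 0, 0), 16.0, 0.4)
        k1 = build_screening_map(empty, g, ionic_strength=0.1).values[0, 0, 0]
        k2 = build_screening_map(empty, g, ionic_strength=0.2).values[0, 0, 0]
        assert k2 == pytest.approx(2.0 * k1)

    def test_stern_layer_exclusion(self, born_ion_ps):
        ps = born_ion_ps(radius=2.0)
        g = GridSpec((0, 0, 0), 16.0, 0.4)
        kap = build_screening_map(ps, g, ionic_strength=0.15, stern=2.0)
        c = g.n_points // 2
        i3 = c + int(round(3.5 / g.spacing))   # inside radius+stern = 4.0
        i5 = c + int(round(4.5 / g.spacing))   # outside
        assert kap.values[i3, c, c] == 0.0
        assert kap.values[i5, c, c] > 0.0


class TestChargeSpreading:
    def test_charge_on_node_reproduces_stencil(self):
        g = GridSpec((0, 0, 0), 16.0, 0.4)
        ps = cx.as_parameterized(cx.make_fixture("born_ion", {"q": 1.0, "radius": 1.0}))
        rho = spread_charges(ps, g)
        assert rho.values.sum() * g.voxel_volume() == pytest.approx(1.0, abs=1e-12)
        c = g.n_points // 2
        # on-node cubic B-spline weights: 2/3 at the node, 1/6 at neighbours
        assert rho.values[c, c, c] * g.voxel_volume() == pytest.approx((2 / 3) ** 3)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.tuples(*[st.floats(-3, 3) for _ in range(3)]),
           st.floats(-2, 2).filter(lambda q: abs(q) > 1e-3))
    def test_partition_of_unity_random_positions(self, center, q):
        g = GridSpec((0, 0, 0), 16.0, 0.4)
        ps = cx.as_parameterized(cx.make_fixture(
            "born_ion", {"q": q, "radius": 1.0, "center": center}))
        rho = spread_charges(ps, g)
        assert rho.values.sum() * g.voxel_volume() == pytest.approx(q, abs=1e-9)

    def test_dipole_total_charge_cancels(self):
        g = GridSpec((0, 0, 0), 16.0, 0.4)
        pair = cx.as_parameterized(cx.make_fixture(
            "charge_pair", {"q1": 1.0, "q2": -1.0, "separation": 3.3}))
        rho = spread_charges(pair, g)
        assert abs(rho.values.sum() * g.voxel_volume()) < 1e-12

    def test_atom_near_boundary_rejected(self):
        g = GridSpec((0, 0, 0), 16.0, 0.4)
        ps = cx.as_parameterized(cx.make_fixture(
            "born_ion", {"q": 1.0, "radius": 0.5, "center": (7.9, 0, 0)}))
        with pytest.raises(GridError, match="boundary"):
            spread_charges(ps, g)

    def test_interpolation_of_linear_field_is_exact(self):
        # cubic B-splines reproduce affine functions exactly
        g = GridSpec((0, 0, 0), 16.0, 0.4)
        x, _, _ = np.meshgrid(*g.axes(), indexing="ij")
        field = ScalarField(g, 2.0 * x + 1.0)
        pts = np.array([[0.13, -1.7, 2.21], [3.03, 0.5, -0.77]])
        np.testing.assert_allclose(interpolate(field, pts), 2.0 * pts[:, 0] + 1.0,
                                   atol=1e-10)


def test_dx_export_roundtrip_values(tmp_path):
    g = GridSpec((0, 0, 0), 16.0, 0.5)
    values = np.arange(g.n_points**3, dtype=float).reshape(g.shape)
    ScalarField(g, values).write_dx(tmp_path / "f.dx")
    text = (tmp_path / "f.dx").read_text()
    assert f"counts {g.n_points} {g.n_points} {g.n_points}" in text
    data = [float(tok) for line in text.splitlines()
            if line and line[0] in "-0123456789"
            for tok in line.split()][: g.n_points ** 3]
    # header lines with digits excluded by the filter above picking only data
    assert data[:4] == [0.0, 1.0, 2.0, 3.0]
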