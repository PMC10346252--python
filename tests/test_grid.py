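"""Spatial discretization: geometry, interface closure, operator structure."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from capnoflow.grid import (
    CompartmentSpec,
    InvalidGeometryError,
    PecletWarning,
    build_grid,
    grid_from_params,
    interface_concentrations,
)


def _uniform(n_comp=1, n_interior=3, D=0.01, u=0.0, H=1.0, height=1.0):
    return tuple(
        CompartmentSpec(f"c{i}", height, D, u, H, n_interior)
        for i in range(n_comp)
    )


class TestGeometry:
    def test_device_grid_has_13_states(self, device_grid):
        assert device_grid.n_states == 13
        assert len(device_grid.z_positions) == 13
        assert np.all(np.diff(device_grid.z_positions) > 0)

    def test_single_compartment_single_point(self):
        g = build_grid(_uniform(n_interior=1), include_outer_point=False)
        assert g.n_states == 1
        assert g.z_positions[0] == pytest.approx(0.5)

    def test_positions_follow_equidistant_spacing(self, device_grid, params):
        """Interior points sit at k·δz inside each compartment, δz = Δz/(N+1)."""
        z = device_grid.z_positions
        heights = [params.blood.dz, params.skin.dz, params.air.dz_meas,
                   params.air.dz_coll]
        expected = []
        z0 = 0.0
        for h in heights:
            dz = h / 4.0
            expected.extend([z0 + dz, z0 + 2 * dz, z0 + 3 * dz])
            z0 += h
        expected.append(z0)  # outer collection boundary point
        assert z == pytest.approx(expected)

    def test_observation_selects_last_measurement_point(self, device_grid):
        assert device_grid.h_index == device_grid.slices["meas"].stop - 1 == 8
        assert device_grid.h.sum() == 1.0

    def test_invalid_geometry_raises(self):
        with pytest.raises(InvalidGeometryError):
            CompartmentSpec("bad", -1.0, 0.01, 0.0, 1.0, 3)
        with pytest.raises(InvalidGeometryError):
            CompartmentSpec("bad", 1.0, 0.01, 0.0, 1.0, 0)

    def test_high_peclet_warns(self):
        spec = CompartmentSpec("fast", 1.0, 1e-4, 0.5, 1.0, 3)
        with pytest.warns(PecletWarning):
            build_grid((spec,))


class TestInterfaceClosure:
    def test_identical_media_average(self):
        c_minus, c_plus = interface_concentrations(
            1.0, 3.0, (0.01, 0.1, 1.0), (0.01, 0.1, 1.0))
        assert c_minus == pytest.approx(2.0)
        assert c_plus == pytest.approx(2.0)

    def test_henry_jump_hand_solved(self):
        """H+/H- = 2, equal D and spacing: closure gives (2/3, 4/3)."""
        c_minus, c_plus = interface_concentrations(
            1.0, 1.0, (0.01, 0.1, 1.0), (0.01, 0.1, 2.0))
        assert c_minus == pytest.approx(2.0 / 3.0)
        assert c_plus == pytest.approx(4.0 / 3.0)

    @given(
        c_b=st.floats(0, 10), c_a=st.floats(0, 10),
        D_b=st.floats(1e-7, 1.0), D_a=st.floats(1e-7, 1.0),
        dz_b=st.floats(1e-4, 1.0), dz_a=st.floats(1e-4, 1.0),
        H_b=st.floats(0.1, 10.0), H_a=st.floats(0.1, 10.0),
    )
    def test_flux_continuity_identity(self, c_b, c_a, D_b, D_a, dz_b, dz_a,
                                      H_b, H_a):
        """Diffusive flux below the interface equals the flux above it."""
        c_minus, c_plus = interface_concentrations(
            c_b, c_a, (D_b, dz_b, H_b), (D_a, dz_a, H_a))
        flux_below = D_b * (c_minus - c_b) / dz_b
        flux_above = D_a * (c_a - c_plus) / dz_a
        # tolerance scales with the conductances times the concentration
        # magnitude (cancellation floor of the closure arithmetic)
        scale = (D_b / dz_b + D_a / dz_a) * (abs(c_b) + abs(c_a) + 1.0)
        assert abs(flux_below - flux_above) <= 1e-9 * scale
        # Henry partial-pressure continuity
        assert c_plus / H_a == pytest.approx(c_minus / H_b, rel=1e-9, abs=1e-12)


class TestOperator:
    def test_single_compartment_no_convection_is_laplacian(self):
        spec = CompartmentSpec("c", 1.0, 0.02, 0.0, 1.0, 4)
        g = build_grid((spec,), include_outer_point=False)
        d = spec.D / spec.dz**2
        F_expected = d * (
            np.diag(-2.0 * np.ones(4))
            + np.diag(np.ones(3), 1)
            + np.diag(np.ones(3), -1)
        )
        F_expected[3, 2] = 2 * d  # Neumann top closure
        assert g.F == pytest.approx(F_expected)
        assert g.G[0, 0] == pytest.approx(d)

    def test_blood_rows_match_hand_plugged_stencil(self, device_grid, params):
        """Interior blood row carries (d+a, −2d, d−a) with published D, u, δz."""
        b = params.blood
        dz = b.dz / 4.0
        d = b.D / dz**2
        a = b.u_z / (2 * dz)
        F = device_grid.F
        assert F[1, 0] == pytest.approx(d + a)
        assert F[1, 1] == pytest.approx(-2 * d)
        assert F[1, 2] == pytest.approx(d - a)
        # Dirichlet steering on row 0
        assert device_grid.G[0, 0] == pytest.approx(d + a)

    def test_spectrum_is_stable(self, device_grid):
        """All eigenvalues of F have non-positive real part."""
        ev = np.linalg.eigvals(device_grid.F)
        assert ev.real.max() <= 1e-12

    @pytest.mark.parametrize("dt", [0.1, 1.0, 10.0, 100.0])
    def test_implicit_operator_is_contractive(self, device_grid, dt):
        """A = I − δt·F has all eigenvalue magnitudes > 1 for any δt > 0."""
        A = np.eye(13) - dt * device_grid.F
        assert np.abs(np.linalg.eigvals(A)).min() > 1.0

    def test_sealed_convection_free_null_space(self):
        """Sealed uniform-H column: constants are stationary."""
        specs = (CompartmentSpec("a", 1.0, 0.01, 0.0, 1.0, 4),
                 CompartmentSpec("b", 0.5, 0.03, 0.0, 1.0, 3))
        g = build_grid(specs, lower_bc="neumann")
        assert np.abs(g.F @ np.ones(g.n_states)).max() < 1e-12

    def test_steady_state_matches_analytic_henry_profile(self):
        """Two-compartment toy, Dirichlet both ends: piecewise-linear profile
        with flux continuity and a Henry jump at the interface."""
        s1 = CompartmentSpec("a", 1.0, 0.02, 0.0, 1.0, 5)
        s2 = CompartmentSpec("b", 0.5, 0.005, 0.0, 2.5, 4)
        g = build_grid((s1, s2), include_outer_point=False,
                       upper_bc="dirichlet")
        cb, ct = 3.0, 0.4
        ss = g.steady_state(cb, ct)
        r = s2.H / s1.H
        g1, g2 = s1.D / s1.height, s2.D / s2.height
        c_minus = (g1 * cb + g2 * ct) / (g1 + r * g2)
        c_plus = r * c_minus
        z = g.z_positions
        analytic = np.where(
            z <= s1.height,
            cb + (c_minus - cb) * z / s1.height,
            c_plus + (ct - c_plus) * (z - s1.height) / s2.height,
        )
        assert np.abs(ss - analytic).max() < 1e-8

    def test_export_csv_round_trips(self, device_grid, tmp_path):
        path = tmp_path / "grid.csv"
        device_grid.export_csv(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        assert data[:, 1:14] == pytest.approx(device_grid.F)
        assert data[:, 14:16] == pytest.approx(device_grid.G)
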