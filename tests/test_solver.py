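"""Diffusion models, Poisson and Nernst-Planck assembly, Gummel iteration."""

import math

import numpy as np
import pytest
from dataclasses import replace

from nanopnp.solver import (
    NOSKOV_CONSTANTS,
    PNPParameters,
    PNPSystem,
    SpeciesSpec,
    buffered_diffusion,
    diffusion_profile,
    kcl_species,
    xi_upwind,
)
from nanopnp.units import EPS0_E_PER_V_A
from nanopnp.verification import box_mesh, make_fixture


K_SPEC, CL_SPEC = kcl_species(1.0)


class TestDiffusionProfile:
    def test_constants_sum_to_one_so_bulk_limit_holds(self):
        """beta -> 0: denominator -> A + B + D = 1, hence D_p -> D_b."""
        k = NOSKOV_CONSTANTS
        assert k["A"] + k["B"] + k["D"] == pytest.approx(1.0, abs=1e-10)
        wide = diffusion_profile(K_SPEC, 1e9)
        assert wide == pytest.approx(K_SPEC.bulk_diffusion, rel=1e-8)

    def test_potassium_in_1nm_pore_hand_computed(self):
        """Direct evaluation of the correlation for R_p = 10 A."""
        k = NOSKOV_CONSTANTS
        beta = 1.764 / 10.0
        denom = (
            k["A"] + k["B"] * math.exp(beta / k["C"]) + k["D"] * math.exp(beta / k["E"])
        )
        assert diffusion_profile(K_SPEC, 10.0) == pytest.approx(0.196 / denom)
        # the reduction is substantial: ~35 % slower than bulk
        assert 0.6 < diffusion_profile(K_SPEC, 10.0) / 0.196 < 0.7

    def test_chloride_at_beta_one(self):
        k = NOSKOV_CONSTANTS
        denom = k["A"] + k["B"] * math.exp(1.0 / k["C"]) + k["D"] * math.exp(1.0 / k["E"])
        assert diffusion_profile(CL_SPEC, 2.27) == pytest.approx(0.203 / denom)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            diffusion_profile(K_SPEC, 0.0)


class TestBufferedDiffusion:
    def test_channel_end_value(self):
        assert buffered_diffusion(0.1, 0.2, 0.0, z_chan=0.0, z_ion=10.0) == pytest.approx(0.1)

    def test_bulk_end_value(self):
        """f(1) = n - (n+1) = -1 recovers the bulk diffusion constant."""
        assert buffered_diffusion(0.1, 0.2, 10.0, z_chan=0.0, z_ion=10.0) == pytest.approx(0.2)

    def test_c1_matching_at_both_ends(self):
        """df/dz = 0 at z_chan and z_ion (smooth blending)."""
        eps = 1e-6
        d0 = buffered_diffusion(0.1, 0.2, eps, 0.0, 10.0) - buffered_diffusion(
            0.1, 0.2, 0.0, 0.0, 10.0
        )
        d1 = buffered_diffusion(0.1, 0.2, 10.0, 0.0, 10.0) - buffered_diffusion(
            0.1, 0.2, 10.0 - eps, 0.0, 10.0
        )
        assert abs(d0 / eps) < 1e-4
        assert abs(d1 / eps) < 1e-4

    def test_monotone_between_endpoints(self):
        z = np.linspace(0, 10, 200)
        D = buffered_diffusion(0.1, 0.2, z, 0.0, 10.0)
        assert np.all(np.diff(D) >= -1e-12)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            buffered_diffusion(0.1, 0.2, 0.0, 1.0, 1.0)


def test_xi_upwind_piecewise():
    assert xi_upwind(0.5) == pytest.approx(0.5)
    assert xi_upwind(1.0) == pytest.approx(1.0)
    assert xi_upwind(2.0) == pytest.approx(1.0)


class TestParameters:
    def test_relaxation_bounds_enforced(self):
        with pytest.raises(ValueError):
            PNPParameters(species=kcl_species(1.0), relaxation=1.0)
        with pytest.raises(ValueError):
            PNPParameters(species=kcl_species(1.0), relaxation=0.0)

    def test_species_validation(self):
        with pytest.raises(ValueError):
            SpeciesSpec("X", 0, 1.0, 0.2, 1.5)
        with pytest.raises(ValueError):
            SpeciesSpec("X", 1, 1.0, -0.2, 1.5)


class TestPoisson:
    def test_no_charge_zero_bias_gives_zero_potential(self):
        mesh = box_mesh(10.0, -10.0, 10.0, 5.0, 5.0)
        params = PNPParameters(species=kcl_species(1.0), voltage=0.0, use_pore_diffusion=False)
        system = PNPSystem(mesh, params)
        zero_n = {s.name: np.zeros(mesh.n_nodes) for s in params.species}
        u = system.solve_poisson(zero_n)
        np.testing.assert_allclose(u, 0.0, atol=1e-14)

    def test_uniform_dielectric_gives_linear_ramp(self):
        """No charge: u is the parallel-plate solution, slope V / L_z."""
        mesh = box_mesh(10.0, -10.0, 10.0, 5.0, 5.0)
        params = PNPParameters(
            species=kcl_species(1.0), voltage=0.2, use_pore_diffusion=False
        )
        system = PNPSystem(mesh, params)
        zero_n = {s.name: np.zeros(mesh.n_nodes) for s in params.species}
        u = system.solve_poisson(zero_n)
        expected = 0.2 * (mesh.nodes[:, 2] - mesh.nodes[:, 2].min()) / 20.0
        np.testing.assert_allclose(u, expected, atol=1e-12)

    def test_point_charge_matches_coulomb_mid_range(self):
        """A +1e charge in uniform eps=78 water: u ~ e/(4 pi eps0 eps r)."""
        from nanopnp.molecule import ChargedAtom, Molecule

        mesh = box_mesh(30.0, -30.0, 30.0, 3.0, 3.0)
        params = PNPParameters(species=kcl_species(1.0), voltage=0.0, use_pore_diffusion=False)
        mol = Molecule([ChargedAtom((0.0, 0.0, 0.0), +1.0, 1.0)])
        system = PNPSystem(mesh, params, molecule=mol)
        zero_n = {s.name: np.zeros(mesh.n_nodes) for s in params.species}
        u = system.solve_poisson(zero_n)
        r = np.linalg.norm(mesh.nodes, axis=1)
        sel = (r > 6.0) & (r < 12.0)
        # grounded box shifts the potential by ~ -k/R_box; fit u = a/r + b so
        # the image term is absorbed and compare the 1/r strength a with k
        A = np.column_stack([1.0 / r[sel], np.ones(sel.sum())])
        a, b = np.linalg.lstsq(A, u[sel], rcond=None)[0]
        k = 1.0 / (4.0 * math.pi * EPS0_E_PER_V_A * 78.0)
        assert a == pytest.approx(k, rel=0.10)


class TestGummel:
    def test_zero_bias_neutral_converges_immediately(self, tiny_pore_geometry, tiny_pore_mesh):
        params = PNPParameters(species=kcl_species(1.0), voltage=0.0)
        sol = PNPSystem(tiny_pore_mesh, params, geometry=tiny_pore_geometry).solve()
        assert sol.converged
        assert sol.n_iterations <= 2
        for s in params.species:
            n = sol.concentrations[s.name]
            sel = n > 0
            np.testing.assert_allclose(n[sel], s.bulk_density, rtol=1e-8)

    def test_concentration_positivity(self, tiny_pore_geometry, tiny_pore_mesh):
        params = PNPParameters(species=kcl_species(1.0), voltage=0.3, relaxation=0.5)
        sol = PNPSystem(tiny_pore_mesh, params, geometry=tiny_pore_geometry).solve()
        assert sol.converged
        for s in params.species:
            assert sol.concentrations[s.name].min() >= 0.0

    def test_converged_solution_is_a_fixed_point(self, tiny_pore_geometry, tiny_pore_mesh):
        params = PNPParameters(species=kcl_species(1.0), voltage=0.1, relaxation=0.5)
        system = PNPSystem(tiny_pore_mesh, params, geometry=tiny_pore_geometry)
        sol = system.solve()
        resolve = PNPSystem(tiny_pore_mesh, params, geometry=tiny_pore_geometry).solve(
            initial=sol
        )
        assert resolve.n_iterations <= 2
        np.testing.assert_allclose(resolve.u, sol.u, atol=5e-6)

    def test_relaxation_factor_does_not_change_the_fixed_point(
        self, tiny_pore_geometry, tiny_pore_mesh
    ):
        params = PNPParameters(species=kcl_species(1.0), voltage=0.1)
        sol_a = PNPSystem(
            tiny_pore_mesh, replace(params, relaxation=0.8), geometry=tiny_pore_geometry
        ).solve()
        sol_b = PNPSystem(
            tiny_pore_mesh, replace(params, relaxation=0.4), geometry=tiny_pore_geometry
        ).solve()
        np.testing.assert_allclose(sol_a.u, sol_b.u, atol=2e-5)
        for s in params.species:
            np.testing.assert_allclose(
                sol_a.concentrations[s.name],
                sol_b.concentrations[s.name],
                rtol=2e-4,
                atol=1e-9,
            )
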