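"""Currents, conductance, blockade amplitudes and field-map export."""

import io

import numpy as np
import pytest

from nanopnp.observables import (
    CurrentRecord,
    IVCurve,
    NotConvergedError,
    conductance,
    export_field_maps,
    ionic_current,
    load_field_map,
    plane_current,
    plane_currents,
    signal_amplitude,
)
from nanopnp.solver import PNPParameters, PNPSystem, kcl_species
from nanopnp.units import E_PER_PS_TO_AMPERE
from nanopnp.verification import make_fixture


@pytest.fixture(scope="module")
def slab_solution():
    _, mesh, params = make_fixture("slab")
    system = PNPSystem(mesh, params)
    return system.solve()


@pytest.fixture(scope="module")
def pore_solution():
    g, mesh, params = make_fixture("tiny_cylinder_pore")
    from dataclasses import replace

    system = PNPSystem(mesh, replace(params, relaxation=0.5), geometry=g)
    return system.solve()


class TestConductance:
    def test_two_point_slope(self):
        iv = IVCurve(
            [
                CurrentRecord(voltage=0.0, open_current=0.0),
                CurrentRecord(voltage=0.1, open_current=1e-9),
            ]
        )
        assert conductance(iv) == pytest.approx(1e-8)

    def test_linear_curve_recovered_exactly(self):
        v = np.linspace(0, 0.3, 7)
        iv = IVCurve([CurrentRecord(voltage=float(x), open_current=float(5e-9 * x)) for x in v])
        assert conductance(iv) == pytest.approx(5e-9, rel=1e-12)

    def test_single_point_rejected(self):
        iv = IVCurve([CurrentRecord(voltage=0.1, open_current=1e-9)])
        with pytest.raises(ValueError):
            conductance(iv)


class TestSignalAmplitude:
    def test_amplitude_is_difference(self):
        a = CurrentRecord(voltage=0.3, open_current=5e-9)
        b = CurrentRecord(voltage=0.3, open_current=3e-9)
        assert signal_amplitude(a, b) == pytest.approx(2e-9)

    def test_equal_currents_give_zero(self):
        a = CurrentRecord(voltage=0.3, open_current=5e-9)
        assert signal_amplitude(a, a) == 0.0

    def test_mismatched_voltage_rejected(self):
        a = CurrentRecord(voltage=0.3, open_current=5e-9)
        b = CurrentRecord(voltage=0.2, open_current=3e-9)
        with pytest.raises(ValueError):
            signal_amplitude(a, b)

    def test_mismatched_geometry_rejected(self):
        a = CurrentRecord(voltage=0.3, open_current=5e-9, manifest={"geometry": {"d": 4}})
        b = CurrentRecord(voltage=0.3, open_current=3e-9, manifest={"geometry": {"d": 6}})
        with pytest.raises(ValueError):
            signal_amplitude(a, b)

    def test_record_amplitude_identity(self):
        r = CurrentRecord(voltage=0.3, open_current=5e-9, blocked_current=3e-9)
        assert r.amplitude == pytest.approx(r.open_current - r.blocked_current)


class TestPlaneCurrent:
    def test_slab_current_matches_ohmic_closed_form(self, slab_solution):
        params = slab_solution.params
        sigma = sum(
            s.valence**2 * s.bulk_diffusion * s.bulk_density for s in params.species
        ) / params.thermal_voltage
        I_exact = sigma * params.voltage / 40.0 * 40.0**2 * E_PER_PS_TO_AMPERE
        assert plane_current(slab_solution, 0.0) == pytest.approx(I_exact, rel=1e-3)

    def test_plane_position_independence(self, slab_solution):
        Is = [plane_current(slab_solution, z) for z in (-12.0, -4.0, 0.0, 4.0, 12.0)]
        assert (max(Is) - min(Is)) / np.mean(Is) < 1e-4

    def test_pore_plane_spread_small(self, pore_solution):
        Is = plane_currents(pore_solution, n_planes=5)
        assert (Is.max() - Is.min()) / Is.mean() < 0.05

    def test_plane_outside_pore_rejected(self, pore_solution):
        with pytest.raises(ValueError):
            ionic_current(pore_solution, z_plane=100.0)

    def test_zero_bias_zero_current(self):
        g, mesh, params = make_fixture("tiny_cylinder_pore")
        from dataclasses import replace

        sol = PNPSystem(mesh, replace(params, voltage=0.0), geometry=g).solve()
        assert abs(ionic_current(sol)) < 1e-15


class TestFieldMaps:
    def test_uniform_slab_has_constant_field(self, slab_solution):
        buf = io.StringIO()
        df = export_field_maps(slab_solution, buf, n_u=12, n_v=16)
        inside = df.dropna()
        expected = slab_solution.params.voltage / 40.0
        np.testing.assert_allclose(inside["E_V_per_A"], expected, rtol=1e-4)

    def test_export_reload_round_trip(self, slab_solution):
        buf = io.StringIO()
        df = export_field_maps(slab_solution, buf, n_u=8, n_v=10)
        back = load_field_map(io.StringIO(buf.getvalue()))
        np.testing.assert_allclose(back["u_V"], df["u_V"], rtol=1e-6)

    def test_solution_vtk_and_iteration_log_exports(self, slab_solution):
        from nanopnp.observables import export_solution_vtk

        buf = io.StringIO()
        export_solution_vtk(slab_solution, buf)
        text = buf.getvalue()
        assert "POINT_DATA" in text and "potential_V" in text and "n_K_per_A3" in text
        log = io.StringIO()
        slab_solution.iteration_log_csv(log)
        assert "iteration" in log.getvalue().splitlines()[0]

    def test_non_converged_solution_refused(self, slab_solution):
        import copy

        bad = copy.copy(slab_solution)
        bad.converged = False
        with pytest.raises(NotConvergedError):
            export_field_maps(bad, io.StringIO())
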