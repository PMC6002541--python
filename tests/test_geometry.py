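"""Pore geometry construction, point classification, config round trips."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanopnp.geometry import (
    InvalidGeometryError,
    OutOfDomainError,
    PoreGeometry,
    RegionLabel,
    build_conical_pore,
    build_cylinder_pore,
    classify_point,
)
from nanopnp.molecule import ChargedAtom, Molecule


class TestConstruction:
    def test_cylinder_box_scales_with_thickness_and_margin(self):
        g = build_cylinder_pore(40.0, 27.0, 60.0)
        assert g.bottom_radius == g.top_radius == 20.0
        assert g.is_cylinder
        # box z-extent = h + 2 margins: 2.7 + 2*6 = 14.7 nm
        assert g.z_max - g.z_min == pytest.approx(147.0)
        assert g.half_width_x == pytest.approx(20.0 + 60.0)

    def test_equal_top_and_bottom_diameters_degenerate_to_cylinder(self):
        g = build_conical_pore(40.0, 40.0, 40.0)
        assert g.is_cylinder
        assert g.wall_radius(0.0) == pytest.approx(20.0)

    def test_cone_wall_slope_and_endpoints(self):
        g = build_conical_pore(40.0, 80.0, 40.0)
        assert not g.is_cylinder
        assert g.wall_radius(g.z_bottom) == pytest.approx(20.0)
        assert g.wall_radius(g.z_top) == pytest.approx(40.0)
        slope = (g.top_radius - g.bottom_radius) / g.membrane_thickness
        assert slope == pytest.approx(0.5)

    def test_discrimination_cone_dimensions(self):
        g = build_conical_pore(40.0, 30.0, 23.0)
        assert g.bottom_radius == 20.0 and g.top_radius == 15.0
        assert g.membrane_thickness == 23.0

    @pytest.mark.parametrize(
        "args", [(0.0, 50.0, 50.0), (40.0, 0.0, 60.0), (40.0, 27.0, -1.0)]
    )
    def test_nonpositive_dimension_rejected(self, args):
        with pytest.raises(InvalidGeometryError):
            build_cylinder_pore(*args)

    def test_frustum_volume_formula(self):
        g = build_conical_pore(40.0, 80.0, 40.0)
        r, R, h = 20.0, 40.0, 40.0
        assert g.pore_frustum_volume() == pytest.approx(
            math.pi * h * (R**2 + R * r + r**2) / 3.0
        )


class TestClassification:
    def setup_method(self):
        self.g = build_cylinder_pore(40.0, 40.0, 60.0)

    def test_membrane_outside_wall_radius(self):
        assert classify_point(self.g, None, (30.0, 0.0, 0.0)) == RegionLabel.MEMBRANE

    def test_pore_center_is_pore_solvent(self):
        assert classify_point(self.g, None, (0.0, 0.0, 0.0)) == RegionLabel.SOLVENT_PORE

    def test_above_membrane_is_bulk_solvent(self):
        assert classify_point(self.g, None, (0.0, 0.0, 50.0)) == RegionLabel.SOLVENT_BULK

    def test_molecule_sphere_wins_inside_pore(self):
        mol = Molecule([ChargedAtom((0.0, 0.0, 0.0), -1.0, 2.0)])
        assert classify_point(self.g, mol, (1.0, 0.0, 0.0)) == RegionLabel.MOLECULE

    def test_point_outside_box_rejected(self):
        with pytest.raises(OutOfDomainError):
            classify_point(self.g, None, (0.0, 0.0, 1e4))

    @settings(max_examples=200, deadline=None)
    @given(
        x=st.floats(-79, 79),
        y=st.floats(-79, 79),
        z=st.floats(-79, 79),
    )
    def test_classification_is_a_partition(self, x, y, z):
        """Every in-box point maps to exactly one region label."""
        label = classify_point(self.g, None, (x, y, z))
        assert label in set(RegionLabel)

    @settings(max_examples=100, deadline=None)
    @given(
        x=st.floats(-79, 79),
        y=st.floats(-79, 79),
        z=st.floats(-79, 79),
    )
    def test_mirror_symmetry_of_cylinder(self, x, y, z):
        """Without a molecule, a cylinder is symmetric under z -> -z."""
        a = classify_point(self.g, None, (x, y, z))
        b = classify_point(self.g, None, (x, y, -z))
        assert a == b


class TestConfigRoundTrip:
    def test_cylinder_round_trip(self):
        g = build_cylinder_pore(40.0, 27.0, 60.0)
        g2 = PoreGeometry.from_config(g.to_config())
        assert g2 == g
        assert g.to_config()["d"] == pytest.approx(4.0)

    def test_cone_round_trip_via_yaml(self):
        import io

        g = build_conical_pore(40.0, 30.0, 23.0)
        buf = io.StringIO()
        g.save(buf)
        g2 = PoreGeometry.load(buf.getvalue())
        assert g2 == g
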