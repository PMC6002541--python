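"""Mesh generation: validity, conformity, volumes, tags, io round trips."""

import io

import numpy as np
import pytest

from nanopnp.geometry import RegionLabel, build_conical_pore, build_cylinder_pore, classify_point
from nanopnp.mesh import (
    FACET_TAGS,
    Mesh,
    MeshIOError,
    MeshOptions,
    MeshQualityReport,
    export_mesh,
    import_mesh,
    mesh_geometry,
)
from nanopnp.molecule import build_charged_rod


class TestMeshGeometry:
    def test_valid_mesh_with_positive_volumes(self, tiny_pore_mesh):
        tiny_pore_mesh.validate()
        assert (tiny_pore_mesh.tet_volumes() > 0).all()

    def test_interior_faces_shared_by_exactly_two_tets(self, tiny_pore_mesh):
        t = tiny_pore_mesh.tets
        faces = np.sort(
            np.concatenate(
                [t[:, [1, 2, 3]], t[:, [0, 3, 2]], t[:, [0, 1, 3]], t[:, [0, 2, 1]]]
            ),
            axis=1,
        )
        _, counts = np.unique(faces, axis=0, return_counts=True)
        assert set(counts) <= {1, 2}

    def test_coarser_resolution_gives_fewer_elements(self, tiny_pore_geometry):
        fine = mesh_geometry(
            tiny_pore_geometry,
            options=MeshOptions(res_pore=3.0, res_bulk=8.0, res_z_fine=3.0, res_z_bulk=8.0),
        )
        coarse = mesh_geometry(
            tiny_pore_geometry,
            options=MeshOptions(res_pore=6.0, res_bulk=14.0, res_z_fine=6.0, res_z_bulk=14.0),
        )
        assert coarse.n_tets < fine.n_tets

    @pytest.mark.parametrize("two_R", [20.0, 30.0])
    def test_solvent_volume_matches_analytic(self, two_R):
        """Box - membrane slab + pore frustum, within 2 % at this resolution."""
        g = build_conical_pore(20.0, two_R, 20.0, 25.0)
        mesh = mesh_geometry(
            g, options=MeshOptions(res_pore=3.0, res_bulk=8.0, res_z_fine=3.0, res_z_bulk=8.0)
        )
        vols = mesh.tet_volumes()
        solv = vols[np.isin(mesh.region, (0, 1))].sum()
        box = (2 * g.half_width_x) * (2 * g.half_width_y) * (g.z_max - g.z_min)
        analytic = (
            box
            - (2 * g.half_width_x) * (2 * g.half_width_y) * g.membrane_thickness
            + g.pore_frustum_volume()
        )
        assert solv == pytest.approx(analytic, rel=0.02)

    def test_region_tags_match_point_classification(self, tiny_pore_geometry, tiny_pore_mesh, rng):
        """Element tags agree with classify_point at (in-box) centroids."""
        centroids = tiny_pore_mesh.centroids()
        sample = rng.choice(len(centroids), size=400, replace=False)
        agree = 0
        for e in sample:
            label = classify_point(tiny_pore_geometry, None, centroids[e])
            agree += int(label) == int(tiny_pore_mesh.region[e])
        # staircase elements right at the wall may differ; the bulk must agree
        assert agree >= 0.97 * len(sample)

    def test_molecule_surface_facets_present(self):
        g = build_cylinder_pore(30.0, 20.0, 20.0)
        rod = build_charged_rod(radius=10.0, length=58.0)
        mesh = mesh_geometry(
            g, rod, options=MeshOptions(res_pore=3.0, res_bulk=8.0, res_z_fine=3.0, res_z_bulk=8.0)
        )
        tags = set(mesh.facet_tags.tolist())
        assert FACET_TAGS["molecule_surface"] in tags
        assert FACET_TAGS["membrane_wall"] in tags
        assert (mesh.region == int(RegionLabel.MOLECULE)).any()

    def test_nonpositive_resolution_rejected(self, tiny_pore_geometry):
        from nanopnp.mesh import MeshingError

        with pytest.raises(MeshingError):
            mesh_geometry(tiny_pore_geometry, options=MeshOptions(res_pore=-1.0))

    def test_quality_report_counts(self, tiny_pore_mesh):
        q = MeshQualityReport.from_mesh(tiny_pore_mesh)
        assert q.n_tets == tiny_pore_mesh.n_tets
        assert 0 < q.min_dihedral_deg < q.max_dihedral_deg < 180
        assert q.min_edge > 0
        assert q.radius_edge_histogram[0].sum() == q.n_tets


class TestMeshIO:
    @pytest.mark.parametrize("fmt", ["MSH", "VTK"])
    def test_round_trip_preserves_connectivity_and_tags(self, tiny_pore_mesh, fmt):
        buf = io.StringIO()
        export_mesh(tiny_pore_mesh, buf, format=fmt)
        back = import_mesh(io.StringIO(buf.getvalue()), format=fmt)
        np.testing.assert_array_equal(back.tets, tiny_pore_mesh.tets)
        np.testing.assert_array_equal(back.region, tiny_pore_mesh.region)
        np.testing.assert_array_equal(back.boundary_facets, tiny_pore_mesh.boundary_facets)
        np.testing.assert_array_equal(back.facet_tags, tiny_pore_mesh.facet_tags)
        np.testing.assert_allclose(back.nodes, tiny_pore_mesh.nodes, rtol=1e-9)

    def test_unknown_format_rejected(self, tiny_pore_mesh):
        with pytest.raises(MeshIOError, match="unknown mesh format"):
            export_mesh(tiny_pore_mesh, io.StringIO(), format="XDMF")

    def test_msh_without_boundary_tags_lists_required(self):
        text = (
            "$MeshFormat\n2.2 0 8\n$EndMeshFormat\n"
            "$Nodes\n4\n1 0 0 0\n2 1 0 0\n3 0 1 0\n4 0 0 1\n$EndNodes\n"
            "$Elements\n1\n1 4 2 1 1 1 2 3 4\n$EndElements\n"
        )
        with pytest.raises(MeshIOError, match="top"):
            import_mesh(io.StringIO(text), format="MSH")

    def test_single_tet_vtk(self):
        text = (
            "# vtk DataFile Version 3.0\nt\nASCII\nDATASET UNSTRUCTURED_GRID\n"
            "POINTS 4 double\n0 0 0\n1 0 0\n0 1 0\n0 0 1\n"
            "CELLS 1 5\n4 0 1 2 3\nCELL_TYPES 1\n10\n"
        )
        mesh = import_mesh(io.StringIO(text), format="VTK")
        assert mesh.n_tets == 1
        assert mesh.n_nodes == 4
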