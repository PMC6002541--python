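"""Duplex generator, PQR io, cross-sections and effective pore radius."""

import io
import math

import numpy as np
import pytest

from nanopnp.molecule import (
    EFFECTIVE_RADIUS_EPSILON,
    ChargedAtom,
    Molecule,
    MoleculeParseError,
    build_charged_rod,
    cross_section_area,
    cross_section_area_mc,
    effective_pore_radius,
    generate_duplex,
    read_pqr,
    write_pqr,
)


class TestDuplexGenerator:
    def test_20bp_duplex_carries_38_backbone_charges(self):
        """Two strands x 20 nt minus the two 5'-terminal phosphates."""
        mol = generate_duplex("AT" * 10, "B-DNA")
        phosphates = [a for a in mol.atoms if a.name == "P"]
        assert len(phosphates) == 38
        assert mol.total_charge == pytest.approx(-38.0)

    def test_single_bp_rejected(self):
        with pytest.raises(ValueError):
            generate_duplex("A", "B-DNA")

    def test_invalid_base_symbol_rejected(self):
        with pytest.raises(MoleculeParseError):
            generate_duplex("AXT", "B-DNA")
        with pytest.raises(MoleculeParseError):
            generate_duplex("AT", "A-RNA")  # T is not an RNA base

    def test_full_charge_model_differs_only_through_bases(self):
        at = generate_duplex("AT" * 12 + "A", "B-DNA", "full")
        gc = generate_duplex("GC" * 12 + "G", "B-DNA", "full")
        backbone = lambda m: sum(a.charge for a in m.atoms if a.name == "P")
        assert backbone(at) == pytest.approx(backbone(gc))
        assert at.total_charge != pytest.approx(gc.total_charge)

    def test_homopolymer_register_shift_is_a_rigid_rotation(self):
        """Shifting the register of a homopolymer only rotates the helix:
        radial distances and z-levels of the atom cloud are unchanged."""
        a = generate_duplex("A" * 10, "B-DNA")
        b = generate_duplex("A" * 10, "B-DNA")  # deterministic generator
        ra = np.sort(np.hypot(a.positions[:, 0], a.positions[:, 1]))
        rb = np.sort(np.hypot(b.positions[:, 0], b.positions[:, 1]))
        np.testing.assert_allclose(ra, rb)
        np.testing.assert_allclose(np.sort(a.positions[:, 2]), np.sort(b.positions[:, 2]))

    def test_b_dna_cross_section_in_physical_corridor(self):
        """20-bp B-DNA mid-height cross-section ~ a 2 nm-diameter rod."""
        mol = generate_duplex("AT" * 10, "B-DNA")
        S = cross_section_area(mol, 0.0)
        assert 250.0 <= S <= 350.0  # A^2, i.e. 2.5-3.5 nm^2

    def test_a_rna_is_wider_than_b_dna(self):
        dna = generate_duplex("GCAT" * 5, "B-DNA")
        rna = generate_duplex("GCAU" * 5, "A-RNA")
        zs = np.linspace(-5, 5, 7)
        S_d = np.mean([cross_section_area(dna, z) for z in zs])
        S_r = np.mean([cross_section_area(rna, z) for z in zs])
        assert S_r > S_d


class TestPQR:
    def test_toy_pqr_total_charge(self):
        text = (
            "ATOM 1 O MOL 1 0.0 0.0 0.0 -0.5 1.5\n"
            "ATOM 2 H MOL 1 1.0 0.0 0.0 0.2 1.0\n"
            "HETATM 3 O2 MOL 1 0.0 1.0 0.0 -0.7 1.4\n"
        )
        mol = read_pqr(io.StringIO(text))
        assert len(mol.atoms) == 3
        assert mol.total_charge == pytest.approx(-1.0)

    def test_missing_radius_column_reports_line(self):
        text = "ATOM 1 O MOL 1 0.0 0.0 0.0\n"
        with pytest.raises(MoleculeParseError, match="line 1"):
            read_pqr(io.StringIO(text))

    def test_empty_file_rejected(self):
        with pytest.raises(MoleculeParseError):
            read_pqr(io.StringIO(""))

    def test_write_read_round_trip(self, duplex20):
        buf = io.StringIO()
        write_pqr(duplex20, buf)
        back = read_pqr(io.StringIO(buf.getvalue()))
        np.testing.assert_allclose(back.positions, duplex20.positions, atol=1e-4)
        np.testing.assert_allclose(back.charges, duplex20.charges, atol=1e-4)
        np.testing.assert_allclose(back.radii, duplex20.radii, atol=1e-4)


class TestCrossSection:
    def test_single_atom_circle_area(self):
        mol = Molecule([ChargedAtom((0, 0, 0), 0.0, 2.0)])
        assert cross_section_area(mol, 0.0) == pytest.approx(4 * math.pi, rel=1e-3)

    def test_disjoint_atoms_areas_add(self):
        mol = Molecule(
            [ChargedAtom((0, 0, 0), 0.0, 1.0), ChargedAtom((5, 0, 0), 0.0, 1.0)]
        )
        assert cross_section_area(mol, 0.0) == pytest.approx(2 * math.pi, rel=1e-3)

    def test_coincident_atoms_union_idempotent(self):
        mol = Molecule(
            [ChargedAtom((0, 0, 0), 0.0, 1.0), ChargedAtom((0, 0, 0), 0.0, 1.0)]
        )
        assert cross_section_area(mol, 0.0) == pytest.approx(math.pi, rel=1e-3)

    def test_plane_outside_molecule_warns_and_returns_zero(self):
        mol = Molecule([ChargedAtom((0, 0, 0), 0.0, 1.0)])
        with pytest.warns(UserWarning):
            assert cross_section_area(mol, 10.0) == 0.0

    def test_union_bounded_by_sum_of_disks(self, duplex20):
        z = 1.0
        dz = z - duplex20.positions[:, 2]
        m = np.abs(dz) < duplex20.radii
        disk_sum = float(np.sum(np.pi * (duplex20.radii[m] ** 2 - dz[m] ** 2)))
        S = cross_section_area(duplex20, z)
        assert S <= disk_sum

    def test_convex_hull_bounds_disk_union(self, duplex20):
        S = cross_section_area(duplex20, 0.0, method="disk_union")
        H = cross_section_area(duplex20, 0.0, method="convex_hull")
        assert H >= S

    def test_monte_carlo_agrees_with_exact_union(self, duplex20):
        """The two independent area routes agree to 0.5 %."""
        S = cross_section_area(duplex20, 0.0)
        S_mc = cross_section_area_mc(duplex20, 0.0, n_samples=1_000_000)
        assert S_mc == pytest.approx(S, rel=5e-3)


class TestEffectivePoreRadius:
    def test_printed_formula(self):
        assert effective_pore_radius(20.0, math.pi * 100.0) == pytest.approx(10.0)

    def test_open_pore_limit(self):
        assert effective_pore_radius(20.0, 0.0) == pytest.approx(20.0)

    def test_overfilled_pore_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            rp = effective_pore_radius(10.0, math.pi * 12.0**2)
        assert rp == EFFECTIVE_RADIUS_EPSILON


def test_charged_rod_linear_charge_density():
    rod = build_charged_rod(radius=10.0, length=68.0)
    assert rod.total_charge == pytest.approx(-2.0 * 68.0 / 3.4)
    assert np.all(rod.radii == 10.0)
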