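"""Charged-sphere representations of nucleic acids.

Continuum electrodiffusion does not need atomistic detail: a molecule is a
list of charged spheres.  Three sources are supported:

* an ideal-duplex generator (B-DNA / A-RNA) built from standard fiber helix
  parameters, with either a phosphate-only charge model (one -1e per
  non-terminal phosphate) or a coarse per-nucleotide template that also gives
  the bases small partial charges (so AT and GC duplexes differ);
* PQR files as written by PDB2PQR (whitespace-delimited, x y z charge radius);
* PDB files, coordinates only, with element van der Waals radii and zero
  charge (useful for geometry-only blockade estimates).

Cross-section areas S(z) — the quantity the pore-diffusion model consumes via
R_p = R - sqrt(S/pi) — are computed as the exact area of the union of the
circles cut from the atom spheres by the plane (shapely polygonal union; a
Monte-Carlo estimator cross-checks it in the test-suite).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, TextIO, Tuple

import numpy as np
from shapely.geometry import Point
from shapely.ops import unary_union

from .units import NM

__all__ = [
    "ChargedAtom",
    "Molecule",
    "generate_duplex",
    "build_charged_rod",
    "read_pqr",
    "write_pqr",
    "read_pdb",
    "cross_section_area",
    "effective_pore_radius",
    "EFFECTIVE_RADIUS_EPSILON",
]


class MoleculeParseError(ValueError):
    """Malformed PQR/PDB input (carries the offending line number)."""


@dataclass(frozen=True)
class ChargedAtom:
    """A sphere at ``position`` (angstrom) with ``charge`` (e) and ``radius``."""

    position: Tuple[float, float, float]
    charge: float
    radius: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("atom radius must be non-negative")
        if not math.isfinite(self.charge):
            raise ValueError("atom charge must be finite")


@dataclass
class Molecule:
    """A rigid molecule as a union of charged spheres."""

    atoms: List[ChargedAtom]
    descriptor: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("molecule must contain at least one atom")
        self._rebuild_arrays()

    def _rebuild_arrays(self) -> None:
        self._xyz = np.array([a.position for a in self.atoms], dtype=float)
        self._q = np.array([a.charge for a in self.atoms], dtype=float)
        self._r = np.array([a.radius for a in self.atoms], dtype=float)

    # -- bulk views ---------------------------------------------------------

    @property
    def positions(self) -> np.ndarray:
        return self._xyz

    @property
    def charges(self) -> np.ndarray:
        return self._q

    @property
    def radii(self) -> np.ndarray:
        return self._r

    @property
    def total_charge(self) -> float:
        return float(self._q.sum())

    @property
    def z_extent(self) -> Tuple[float, float]:
        return (
            float((self._xyz[:, 2] - self._r).min()),
            float((self._xyz[:, 2] + self._r).max()),
        )

    def contains(self, p: np.ndarray, probe_radius: float = 0.0) -> bool:
        """True if ``p`` lies inside any (inflated) atom sphere."""
        d2 = np.sum((self._xyz - np.asarray(p, dtype=float)) ** 2, axis=1)
        return bool(np.any(d2 <= (self._r + probe_radius) ** 2))

    def recentered(self, align_axis: bool = False) -> "Molecule":
        """Centroid moved to the origin; optionally principal axis -> z."""
        xyz = self._xyz - self._xyz.mean(axis=0)
        if align_axis and len(self.atoms) > 2:
            cov = xyz.T @ xyz
            w, v = np.linalg.eigh(cov)
            axis = v[:, np.argmax(w)]
            if axis[2] < 0:
                axis = -axis
            rot = _rotation_to_z(axis)
            xyz = xyz @ rot.T
        atoms = [
            ChargedAtom(tuple(p), a.charge, a.radius, a.name)
            for p, a in zip(xyz, self.atoms)
        ]
        return Molecule(atoms, self.descriptor, dict(self.metadata))


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    c = float(axis @ z)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


# ---------------------------------------------------------------------------
# Ideal duplex generator
# ---------------------------------------------------------------------------

#: fiber helix parameters: rise per bp (A), twist per bp (deg)
HELIX_PARAMS = {
    "B-DNA": {"rise": 3.4, "twist": 36.0},
    "A-RNA": {"rise": 2.81, "twist": 32.7},
}

#: radial placement (A) of the coarse per-nucleotide spheres; A-form helices
#: are wider, with base pairs displaced from the axis
_RADIAL = {
    "B-DNA": {"P": 8.9, "S": 6.9, "G1": 4.9, "B": 2.6},
    "A-RNA": {"P": 9.4, "S": 8.4, "G1": 6.2, "B": 4.0},
}

#: angular offsets (deg) of sugar/glycosidic/base relative to the phosphate
_ANG_OFFSET = {"S": -25.0, "G1": -42.0, "B": -60.0}

#: angle between the two strands' backbones (minor-groove side)
_STRAND_OFFSET_DEG = 154.0

#: effective group radii (A): whole chemical groups, not single atoms
_SPHERE_RADII = {"P": 4.0, "S": 4.2, "G1": 4.0}
_BASE_RADII = {"A": 4.2, "G": 4.2, "T": 3.8, "C": 3.8, "U": 3.8}

#: synthetic coarse-grained base partial charges (e); chosen so duplexes with
#: different base composition differ electrostatically while backbones match.
_BASE_CHARGES = {"A": 0.06, "T": -0.01, "U": -0.01, "G": -0.10, "C": 0.02}

_COMPLEMENT = {
    "B-DNA": {"A": "T", "T": "A", "G": "C", "C": "G"},
    "A-RNA": {"A": "U", "U": "A", "G": "C", "C": "G"},
}


def generate_duplex(
    sequence: str,
    form: str = "B-DNA",
    charge_model: str = "phosphate_backbone",
) -> Molecule:
    """Build an ideal double helix for ``sequence`` (given strand, 5'->3').

    The helix axis is z and the duplex is centred at the origin.  Each
    nucleotide contributes a phosphate, a sugar and a base sphere; the
    5'-terminal nucleotide of each strand carries no phosphate, so an N-bp
    duplex holds 2N-2 phosphates (total backbone charge -(2N-2) e).

    ``charge_model``:
      * ``"phosphate_backbone"`` - one -1e per phosphate, all else neutral.
      * ``"full"`` (alias ``"full_pqr"``) - additionally places small
        template partial charges on the bases.
    """
    if form not in HELIX_PARAMS:
        raise ValueError(f"unknown helix form {form!r}")
    if charge_model not in ("phosphate_backbone", "full", "full_pqr"):
        raise ValueError(f"unknown charge model {charge_model!r}")
    full = charge_model in ("full", "full_pqr")
    seq = sequence.upper()
    comp = _COMPLEMENT[form]
    if len(seq) < 2:
        raise ValueError("duplex needs at least 2 base pairs")
    bad = set(seq) - set(comp)
    if bad:
        raise MoleculeParseError(
            f"invalid base symbol(s) {sorted(bad)} for form {form}"
        )

    n = len(seq)
    rise = HELIX_PARAMS[form]["rise"]
    twist = math.radians(HELIX_PARAMS[form]["twist"])
    radial = _RADIAL[form]
    z0 = -0.5 * (n - 1) * rise

    atoms: List[ChargedAtom] = []

    def place(kind: str, base: str, theta: float, z: float, with_p: bool) -> None:
        if with_p:
            ang = theta
            atoms.append(
                ChargedAtom(
                    (radial["P"] * math.cos(ang), radial["P"] * math.sin(ang), z),
                    -1.0,
                    _SPHERE_RADII["P"],
                    "P",
                )
            )
        for kind2 in ("S", "G1", "B"):
            ang = theta + math.radians(_ANG_OFFSET[kind2]) * (1 if kind == "w" else -1)
            r_ax = radial[kind2]
            if kind2 != "B":
                q, rad = 0.0, _SPHERE_RADII[kind2]
            else:
                q = _BASE_CHARGES[base] if full else 0.0
                rad = _BASE_RADII[base]
            atoms.append(
                ChargedAtom(
                    (r_ax * math.cos(ang), r_ax * math.sin(ang), z), q, rad, kind2
                )
            )

    for k, base in enumerate(seq):
        theta = k * twist
        z = z0 + k * rise
        # Watson strand runs 5'->3' with increasing z: its 5' terminus is k=0.
        place("w", base, theta, z, with_p=(k > 0))
        # Crick strand is antiparallel: its 5' terminus is the k = n-1 level.
        theta2 = theta + math.radians(_STRAND_OFFSET_DEG)
        place("c", comp[base], theta2, z, with_p=(k < n - 1))

    return Molecule(
        atoms,
        descriptor=f"{form} duplex {seq} ({charge_model})",
        metadata={
            "form": form,
            "sequence": seq,
            "charge_model": charge_model,
            "rise_A": rise,
            "twist_deg": HELIX_PARAMS[form]["twist"],
            "generator": "ideal fiber helix, coarse 3-sphere nucleotides",
        },
    )


def build_charged_rod(
    radius: float = 1.0 * NM,
    length: float = 6.0 * NM,
    charge_per_rise: float = -2.0,
    rise: float = 3.4,
    sphere_spacing: float = 2.0,
) -> Molecule:
    """Uniformly charged rod surrogate for a duplex.

    A stack of overlapping spheres of ``radius`` spaced ``sphere_spacing``
    along z approximates a cylinder carrying ``charge_per_rise`` e per
    ``rise`` angstrom of length (DNA-like default: -2e per 3.4 A).
    """
    n = max(2, int(round(length / sphere_spacing)) + 1)
    zs = np.linspace(-0.5 * length, 0.5 * length, n)
    q = charge_per_rise * length / rise / n
    atoms = [ChargedAtom((0.0, 0.0, float(z)), q, radius, "ROD") for z in zs]
    return Molecule(
        atoms,
        descriptor=f"charged rod r={radius:g}A L={length:g}A",
        metadata={"kind": "charged_rod", "radius_A": radius, "length_A": length},
    )


# ---------------------------------------------------------------------------
# PQR / PDB io
# ---------------------------------------------------------------------------


def read_pqr(stream: TextIO, recenter: bool = False, align_axis: bool = False) -> Molecule:
    """Read a PQR file (whitespace-delimited ATOM/HETATM records).

    The last five fields of each record are x y z charge radius, which is
    robust to the many chain-id/column conventions PDB2PQR emits.
    """
    atoms: List[ChargedAtom] = []
    for lineno, line in enumerate(stream, start=1):
        rec = line.split()
        if not rec or rec[0] not in ("ATOM", "HETATM"):
            continue
        if len(rec) < 8:
            raise MoleculeParseError(
                f"line {lineno}: PQR record needs x y z charge radius fields"
            )
        try:
            x, y, z, q, r = (float(v) for v in rec[-5:])
        except ValueError as exc:
            raise MoleculeParseError(f"line {lineno}: {exc}") from exc
        if r < 0:
            raise MoleculeParseError(f"line {lineno}: negative radius")
        atoms.append(ChargedAtom((x, y, z), q, r, rec[2] if len(rec) > 2 else ""))
    if not atoms:
        raise MoleculeParseError("no ATOM/HETATM records found")
    mol = Molecule(atoms, descriptor="PQR import")
    if recenter or align_axis:
        mol = mol.recentered(align_axis=align_axis)
    return mol


def write_pqr(molecule: Molecule, stream: TextIO) -> None:
    """Write a whitespace-delimited PQR file (round-trips with read_pqr)."""
    for i, a in enumerate(molecule.atoms, start=1):
        name = a.name or "X"
        stream.write(
            f"ATOM  {i:5d} {name:<4s} MOL A {1:4d}    "
            f"{a.position[0]:10.4f} {a.position[1]:10.4f} {a.position[2]:10.4f} "
            f"{a.charge:8.4f} {a.radius:7.4f}\n"
        )


_ELEMENT_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "P": 1.8, "S": 1.8}


def read_pdb(stream: TextIO, recenter: bool = False, align_axis: bool = False) -> Molecule:
    """Read coordinates from a PDB file; element vdW radii, zero charges."""
    atoms: List[ChargedAtom] = []
    for lineno, line in enumerate(stream, start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except (ValueError, IndexError) as exc:
            raise MoleculeParseError(f"line {lineno}: bad coordinates") from exc
        name = line[12:16].strip()
        elem = line[76:78].strip() or (name[:1] if name else "C")
        radius = _ELEMENT_RADII.get(elem.upper(), 1.7)
        atoms.append(ChargedAtom((x, y, z), 0.0, radius, name))
    if not atoms:
        raise MoleculeParseError("no ATOM/HETATM records found")
    mol = Molecule(atoms, descriptor="PDB import (coordinates only)")
    if recenter or align_axis:
        mol = mol.recentered(align_axis=align_axis)
    return mol


# ---------------------------------------------------------------------------
# Cross sections and effective pore radius
# ---------------------------------------------------------------------------

#: polygonal resolution of the circle union (relative area error < 1e-4)
_QUAD_SEGS = 64


def _slice_circles(molecule: Molecule, z: float) -> List[Tuple[float, float, float]]:
    dz = z - molecule.positions[:, 2]
    mask = np.abs(dz) < molecule.radii
    rows = []
    for (x, y, _), d, R in zip(
        molecule.positions[mask], dz[mask], molecule.radii[mask]
    ):
        rows.append((x, y, math.sqrt(R * R - d * d)))
    return rows


def cross_section_area(
    molecule: Molecule, z: float, method: str = "disk_union"
) -> float:
    """Area S(z) of the molecule's cross-section in the XY-plane at ``z``.

    ``disk_union`` is the exact union of the sliced circles; ``convex_hull``
    is the (larger) convex hull of that union, an upper-envelope estimate of
    the blocked area.
    """
    circles = _slice_circles(molecule, z)
    if not circles:
        warnings.warn(f"plane z={z:g} A lies outside the molecule; S = 0")
        return 0.0
    shapes = [Point(x, y).buffer(r, quad_segs=_QUAD_SEGS) for x, y, r in circles]
    union = unary_union(shapes)
    if method == "disk_union":
        return float(union.area)
    if method == "convex_hull":
        return float(union.convex_hull.area)
    raise ValueError(f"unknown cross-section method {method!r}")


def cross_section_area_mc(
    molecule: Molecule, z: float, n_samples: int = 1_000_000, seed: int = 20260927
) -> float:
    """Monte-Carlo estimate of the disk-union area (independent cross-check)."""
    circles = _slice_circles(molecule, z)
    if not circles:
        return 0.0
    c = np.array(circles)
    lo = (c[:, :2] - c[:, 2:3]).min(axis=0)
    hi = (c[:, :2] + c[:, 2:3]).max(axis=0)
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n_samples, 2))
    d2 = ((pts[:, None, :] - c[None, :, :2]) ** 2).sum(axis=2)
    hit = (d2 <= c[None, :, 2] ** 2).any(axis=1)
    box = float(np.prod(hi - lo))
    return box * float(hit.mean())


#: floor for the effective pore radius, keeps the pore-diffusion model finite
EFFECTIVE_RADIUS_EPSILON = 0.1  # angstrom


def effective_pore_radius(R_open: float, S: float) -> float:
    """R_p = R - sqrt(S/pi), floored at a small positive epsilon.

    ``R_open`` is the open-pore wall radius at the plane, ``S`` the molecule
    cross-section area there.
    """
    if R_open <= 0:
        raise ValueError("open-pore radius must be positive")
    if S < 0:
        raise ValueError("cross-section area must be non-negative")
    rp = R_open - math.sqrt(S / math.pi)
    if rp < EFFECTIVE_RADIUS_EPSILON:
        warnings.warn(
            f"molecule cross-section fills the pore (R_p={rp:.3g} A); "
            f"clamped to {EFFECTIVE_RADIUS_EPSILON} A"
        )
        return EFFECTIVE_RADIUS_EPSILON
    return rp
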