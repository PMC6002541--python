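"""Tagged tetrahedral meshes of nanopore geometries.

The built-in mesher produces a layered, boundary-conforming mesh: a single
2D triangulation of the box cross-section is remapped radially per z-layer so
that one ring of nodes lies exactly on the pore wall rho(z) and (when a
molecule is present) one ring lies on the molecule's effective surface
a(z) = sqrt(S(z)/pi).  Each triangular prism between consecutive layers is
split into three tetrahedra with a diagonal rule keyed on global node indices,
which makes neighbouring prisms conform and the construction deterministic.

Region tags (solvent bulk/pore, membrane, molecule) are assigned per element
at its centroid; boundary and interface facets (top, bottom, side,
membrane_wall, molecule_surface) are extracted by face matching.

Meshes round-trip through Gmsh MSH v2.2 ASCII and legacy VTK ASCII.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, TextIO, Tuple

import numpy as np
from scipy.spatial import Delaunay

from .geometry import PoreGeometry, RegionLabel
from .molecule import Molecule, cross_section_area

__all__ = [
    "Mesh",
    "MeshOptions",
    "MeshQualityReport",
    "MeshingError",
    "MeshIOError",
    "mesh_geometry",
    "export_mesh",
    "import_mesh",
]


class MeshingError(RuntimeError):
    pass


class MeshIOError(ValueError):
    pass


FACET_TAGS = {"top": 101, "bottom": 102, "side": 103, "membrane_wall": 104, "molecule_surface": 105}
FACET_NAMES = {v: k for k, v in FACET_TAGS.items()}
REGION_TAG_OFFSET = 1  # MSH physical id = RegionLabel + 1


@dataclass
class Mesh:
    """Tetrahedral volume mesh with region and boundary tags."""

    nodes: np.ndarray           # (N, 3) float
    tets: np.ndarray            # (M, 4) int
    region: np.ndarray          # (M,) int (RegionLabel values)
    boundary_facets: np.ndarray  # (F, 3) int
    facet_tags: np.ndarray      # (F,) int (FACET_TAGS codes)
    metadata: dict = field(default_factory=dict)

    # -- derived ------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        p = self.nodes[self.tets]
        return np.einsum(
            "ij,ij->i",
            p[:, 3] - p[:, 0],
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
        ) / 6.0

    def centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def region_volume(self, label: RegionLabel) -> float:
        return float(self.tet_volumes()[self.region == int(label)].sum())

    def edge_lengths(self) -> np.ndarray:
        t = self.tets
        pairs = np.concatenate(
            [t[:, [0, 1]], t[:, [0, 2]], t[:, [0, 3]], t[:, [1, 2]], t[:, [1, 3]], t[:, [2, 3]]]
        )
        d = self.nodes[pairs[:, 0]] - self.nodes[pairs[:, 1]]
        return np.linalg.norm(d, axis=1)

    def validate(self) -> None:
        if self.tets.min() < 0 or self.tets.max() >= self.n_nodes:
            raise MeshingError("tet indices out of range")
        vols = self.tet_volumes()
        if (vols <= 0).any():
            raise MeshingError(f"{int((vols <= 0).sum())} non-positive tetrahedra")
        if len(self.boundary_facets) and self.boundary_facets.max() >= self.n_nodes:
            raise MeshingError("facet indices out of range")


@dataclass
class MeshQualityReport:
    n_nodes: int
    n_tets: int
    min_edge: float
    min_dihedral_deg: float
    max_dihedral_deg: float
    radius_edge_histogram: Tuple[np.ndarray, np.ndarray]  # (counts, bin edges)

    @classmethod
    def from_mesh(cls, mesh: Mesh) -> "MeshQualityReport":
        p = mesh.nodes[mesh.tets]
        # face normals for the four faces opposite each vertex
        faces = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
        normals = []
        for a, b, c in faces:
            n = np.cross(p[:, b] - p[:, a], p[:, c] - p[:, a])
            normals.append(n / np.linalg.norm(n, axis=1, keepdims=True))
        dihedrals = []
        for i in range(4):
            for j in range(i + 1, 4):
                cosang = np.einsum("ij,ij->i", normals[i], normals[j])
                dihedrals.append(np.degrees(np.pi - np.arccos(np.clip(cosang, -1, 1))))
        dihedrals = np.concatenate(dihedrals)
        edges = mesh.edge_lengths().reshape(6, -1)
        # circumradius via |a|^2 formulation
        a = p[:, 1] - p[:, 0]
        b = p[:, 2] - p[:, 0]
        c = p[:, 3] - p[:, 0]
        vol6 = np.abs(np.einsum("ij,ij->i", a, np.cross(b, c)))
        num = (
            np.sum(a * a, axis=1, keepdims=True) * np.cross(b, c)
            + np.sum(b * b, axis=1, keepdims=True) * np.cross(c, a)
            + np.sum(c * c, axis=1, keepdims=True) * np.cross(a, b)
        )
        circ = np.linalg.norm(num, axis=1) / np.maximum(2 * vol6, 1e-300)
        ratio = circ / edges.min(axis=0)
        hist = np.histogram(ratio, bins=[0, 1, 1.5, 2, 3, 5, 10, np.inf])
        return cls(
            n_nodes=mesh.n_nodes,
            n_tets=mesh.n_tets,
            min_edge=float(edges.min()),
            min_dihedral_deg=float(dihedrals.min()),
            max_dihedral_deg=float(dihedrals.max()),
            radius_edge_histogram=hist,
        )


@dataclass
class MeshOptions:
    """Resolution knobs (all lengths in angstrom)."""

    res_pore: float = 4.0        # in-plane target spacing inside/near the pore
    res_bulk: float = 15.0       # in-plane spacing far from the pore
    res_z_fine: float = 4.0      # layer spacing near the membrane faces
    res_z_bulk: float = 14.0     # layer spacing in the far bulk
    growth: float = 1.35         # geometric grading factor
    buffer_length: float = 10.0  # diffusion-buffer span beyond each face
    min_molecule_radius: float = 1.2   # mapping floor for the molecule ring
    wall_clearance: float = 1.2  # minimum gap kept between molecule and wall
    surface_spacing: Optional[float] = None  # radial boundary-layer spacing
                                 # at the molecule surface (resolves the
                                 # screening layer; defaults to res_pore)

    def scaled(self, factor: float) -> "MeshOptions":
        """Uniformly refined/coarsened copy (factor < 1 refines)."""
        return MeshOptions(
            res_pore=self.res_pore * factor,
            res_bulk=self.res_bulk * factor,
            res_z_fine=self.res_z_fine * factor,
            res_z_bulk=self.res_z_bulk * factor,
            growth=self.growth,
            buffer_length=self.buffer_length,
            min_molecule_radius=self.min_molecule_radius,
            wall_clearance=self.wall_clearance,
            surface_spacing=(
                None if self.surface_spacing is None else self.surface_spacing * factor
            ),
        )


# ---------------------------------------------------------------------------
# layer and ring construction
# ---------------------------------------------------------------------------


def _graded_steps(span: float, d0: float, dmax: float, g: float) -> np.ndarray:
    """Cumulative positions 0..span with spacing d0 growing by g, capped at dmax."""
    if span <= 1e-9:
        return np.array([0.0])
    if span <= d0:
        return np.array([0.0, span])
    pts = [0.0]
    d = d0
    while pts[-1] < span - 0.5 * d:
        pts.append(pts[-1] + d)
        d = min(d * g, dmax)
    pts.append(span)
    pts = np.array(pts)
    # even out the last interval
    if len(pts) > 2 and (pts[-1] - pts[-2]) < 0.4 * (pts[-2] - pts[-3]):
        pts = np.delete(pts, len(pts) - 2)
    return pts


def _symmetric_graded(a: float, b: float, d0: float, dmax: float, g: float) -> np.ndarray:
    """Points in [a, b] graded fine at both ends, coarse in the middle."""
    span = b - a
    half = 0.5 * span
    up = _graded_steps(half, d0, dmax, g)
    pts = np.concatenate([a + up, b - up[::-1]])
    return np.unique(np.round(pts, 9))


def _layer_positions(geometry: PoreGeometry, opts: MeshOptions) -> np.ndarray:
    """Layer planes: anchored at box ends, membrane faces and buffer ends."""
    zb, zt = geometry.z_bottom, geometry.z_top
    h = geometry.membrane_thickness
    buf = min(opts.buffer_length, 0.8 * (zb - geometry.z_min))
    anchors = [geometry.z_min, zb - buf, zb, zt, zt + buf, geometry.z_max]

    segments: List[np.ndarray] = []
    # lower bulk: coarse at the box end, fine at the buffer
    lb = _graded_steps(anchors[1] - anchors[0], 1.5 * opts.res_z_fine, opts.res_z_bulk, opts.growth)
    segments.append(anchors[1] - lb[::-1])
    # buffer below
    nb = max(2, int(round(buf / opts.res_z_fine)))
    segments.append(np.linspace(anchors[1], anchors[2], nb + 1))
    # membrane interior: fine at both faces
    dmax_mem = max(opts.res_z_fine, min(h / 4.0, 3.0 * opts.res_z_fine))
    segments.append(_symmetric_graded(zb, zt, opts.res_z_fine, dmax_mem, opts.growth))
    # buffer above
    segments.append(np.linspace(anchors[3], anchors[4], nb + 1))
    # upper bulk
    ub = _graded_steps(anchors[5] - anchors[4], 1.5 * opts.res_z_fine, opts.res_z_bulk, opts.growth)
    segments.append(anchors[4] + ub)

    zs = np.unique(np.round(np.concatenate(segments), 6))
    # drop non-anchor layers that crowd an anchor or a previous layer
    keep = []
    anchor_set = np.array(anchors)
    last = -np.inf
    min_gap = 0.3 * opts.res_z_fine
    for z in zs:
        is_anchor = np.any(np.abs(anchor_set - z) < 1e-6)
        near_anchor = np.any((np.abs(anchor_set - z) >= 1e-6) & (np.abs(anchor_set - z) < min_gap))
        if is_anchor or (z - last >= min_gap and not near_anchor):
            keep.append(z)
            last = z
    return np.asarray(keep)


def _ring_points(radius: float, spacing: float, phase: float) -> np.ndarray:
    m = max(8, int(math.ceil(2.0 * math.pi * radius / spacing)))
    ang = phase + 2.0 * math.pi * np.arange(m) / m
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang)])


def _square_ring(half: float, spacing: float) -> np.ndarray:
    m = max(2, int(math.ceil(2.0 * half / spacing)))
    s = np.linspace(-half, half, m + 1)
    top = np.column_stack([s, np.full_like(s, half)])
    bot = np.column_stack([s, np.full_like(s, -half)])
    left = np.column_stack([np.full_like(s[1:-1], -half), s[1:-1]])
    right = np.column_stack([np.full_like(s[1:-1], half), s[1:-1]])
    return np.concatenate([top, bot, left, right])


def _reference_plane(
    geometry: PoreGeometry,
    s_mol: Optional[float],
    opts: MeshOptions,
) -> Tuple[np.ndarray, np.ndarray, dict]:
    """Reference 2D points + triangulation + the radial anchor structure."""
    wall_max = geometry.max_radius
    s_wall = geometry.wall_radius(geometry.membrane_z_center)
    half_w = geometry.half_width_x
    r_fix = min(wall_max + max(2.5 * opts.res_pore, 8.0), 0.82 * half_w)
    if r_fix <= s_wall:
        r_fix = 0.5 * (s_wall + half_w)

    pts: List[np.ndarray] = [np.zeros((1, 2))]
    ref_radius: List[float] = [0.0]

    def add_ring(s: float, spacing: float, phase: float) -> None:
        ring = _ring_points(s, spacing, phase)
        pts.append(ring)
        ref_radius.extend([s] * len(ring))

    phase_toggle = 0.0
    if s_mol is not None:
        n0 = max(2, int(round(s_mol / (1.4 * opts.res_pore))) + 1)
        for k in range(1, n0 + 1):
            add_ring(s_mol * k / n0, 1.4 * opts.res_pore, phase_toggle)
            phase_toggle = 0.5 - phase_toggle
        gap = s_wall - s_mol
        d_surf = opts.surface_spacing or opts.res_pore
        if d_surf < opts.res_pore:
            # boundary-layer grading away from the molecule surface
            offs = _graded_steps(gap, d_surf, opts.res_pore, 1.5)[1:]
        else:
            n1 = max(3, int(math.ceil(gap / opts.res_pore)))
            offs = gap * np.arange(1, n1 + 1) / n1
        if len(offs) < 3:
            offs = gap * np.arange(1, 4) / 3.0
        for off in offs:
            add_ring(s_mol + float(off), opts.res_pore, phase_toggle)
            phase_toggle = 0.5 - phase_toggle
    else:
        n1 = max(3, int(math.ceil(s_wall / opts.res_pore)))
        for k in range(1, n1 + 1):
            add_ring(s_wall * k / n1, opts.res_pore, phase_toggle)
            phase_toggle = 0.5 - phase_toggle

    # graded rings out to the fixed radius, then to the square frame
    s = s_wall
    d = opts.res_pore
    while s < r_fix - 0.5 * d:
        s = min(s + d, r_fix)
        add_ring(s, d, phase_toggle)
        phase_toggle = 0.5 - phase_toggle
        d = min(d * opts.growth, opts.res_bulk)
    outer = []
    lvl = r_fix + d
    while lvl < half_w - 0.5 * opts.res_bulk:
        outer.append(_square_ring(lvl, opts.res_bulk))
        lvl += min(d, opts.res_bulk)
        d = min(d * opts.growth, opts.res_bulk)
    outer.append(_square_ring(half_w, opts.res_bulk))
    for ring in outer:
        pts.append(ring)
        ref_radius.extend([-1.0] * len(ring))  # -1 marks fixed (unmapped) nodes

    points = np.vstack(pts)
    ref = np.array(ref_radius)
    tri = Delaunay(points)
    anchors = {"s_mol": s_mol, "s_wall": s_wall, "r_fix": r_fix}
    return points, tri.simplices.copy(), {"ref_radius": ref, **anchors}


def _map_plane(
    points: np.ndarray,
    ref: dict,
    a_z: float,
    rho_z: float,
) -> np.ndarray:
    """Radially remap the reference plane to a layer with wall radius rho(z)."""
    s = ref["ref_radius"]
    s_wall, r_fix, s_mol = ref["s_wall"], ref["r_fix"], ref["s_mol"]
    scale = np.ones(len(points))
    mapped = s >= 0
    sm = s[mapped]
    out = np.empty_like(sm)
    if s_mol is None:
        inner = sm <= s_wall
        out[inner] = sm[inner] * (rho_z / s_wall)
    else:
        inner = sm <= s_mol
        out[inner] = sm[inner] * (a_z / s_mol)
        mid = (sm > s_mol) & (sm <= s_wall)
        out[mid] = a_z + (sm[mid] - s_mol) * (rho_z - a_z) / (s_wall - s_mol)
    outer = sm > s_wall
    out[outer] = rho_z + (sm[outer] - s_wall) * (r_fix - rho_z) / (r_fix - s_wall)
    with np.errstate(divide="ignore", invalid="ignore"):
        sc = np.where(sm > 0, out / np.maximum(sm, 1e-30), 1.0)
    scale[mapped] = sc
    return points * scale[:, None]


# ---------------------------------------------------------------------------
# prism splitting
# ---------------------------------------------------------------------------


def _split_prisms(tri: np.ndarray, n_plane: int, n_layers: int) -> np.ndarray:
    """Split all prisms into tets with neighbour-consistent diagonals.

    For the quad face between columns i and j (bottom A_i A_j, top B_j B_i)
    the diagonal is the one incident to the smallest global node index; this
    choice matches across neighbouring prisms.  At least one prism vertex has
    both adjacent quad diagonals meeting at it; that vertex serves as the
    apex of a valid 3-tet decomposition.
    """
    tets = []
    for l in range(n_layers - 1):
        off_a, off_b = l * n_plane, (l + 1) * n_plane
        for t in tri:
            A = [off_a + t[0], off_a + t[1], off_a + t[2]]
            B = [off_b + t[0], off_b + t[1], off_b + t[2]]
            tets.extend(_split_one_prism(A, B))
    return np.array(tets, dtype=np.int64)


def _diag_low(Ai: int, Aj: int, Bj: int, Bi: int) -> bool:
    """True if the quad's diagonal is (Ai, Bj) (incident to min index)."""
    m = min(Ai, Aj, Bi, Bj)
    return m == Ai or m == Bj


def _split_one_prism(A: List[int], B: List[int]) -> List[Tuple[int, int, int, int]]:
    # diag[c] describes the quad between columns c and c+1
    diag = [_diag_low(A[c], A[(c + 1) % 3], B[(c + 1) % 3], B[c]) for c in range(3)]
    # find a bottom apex: both quads adjacent to column c use diagonal from A_c
    for c in range(3):
        left = (c + 2) % 3  # quad between columns c-1 and c
        if diag[c] and not diag[left]:
            return _apex_tets(A, B, c, diag)
    # otherwise a top apex exists: flip the prism upside town and recurse
    diag_f = [not d for d in diag]
    for c in range(3):
        left = (c + 2) % 3
        if diag_f[c] and not diag_f[left]:
            return _apex_tets(B, A, c, diag_f)
    raise MeshingError("prism splitting failed (inconsistent diagonals)")


def _apex_tets(A, B, c, diag) -> List[Tuple[int, int, int, int]]:
    i0, i1, i2 = c, (c + 1) % 3, (c + 2) % 3
    A0, A1, A2 = A[i0], A[i1], A[i2]
    B0, B1, B2 = B[i0], B[i1], B[i2]
    # quad between columns i1-i2: diagonal (A1,B2) iff diag[i1]
    if diag[i1]:
        return [(A0, A1, A2, B2), (A0, A1, B2, B1), (A0, B0, B1, B2)]
    return [(A0, A1, A2, B1), (A0, A2, B1, B2), (A0, B0, B1, B2)]


# ---------------------------------------------------------------------------
# main entry
# ---------------------------------------------------------------------------


def molecule_radius_profile(
    molecule: Molecule, zs: np.ndarray
) -> np.ndarray:
    """Effective rod radius sqrt(S(z)/pi) per layer (0 outside the molecule)."""
    import warnings

    out = np.zeros(len(zs))
    zlo, zhi = molecule.z_extent
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, z in enumerate(zs):
            if zlo <= z <= zhi:
                out[i] = math.sqrt(cross_section_area(molecule, float(z)) / math.pi)
    return out


def mesh_geometry(
    geometry: PoreGeometry,
    molecule: Optional[Molecule] = None,
    options: Optional[MeshOptions] = None,
) -> Mesh:
    """Mesh the full simulation box, conforming to membrane faces and walls.

    The whole box is meshed (the Poisson equation lives everywhere); region
    tags mark membrane, molecule and solvent so the Nernst-Planck equations
    can be restricted to the solvent.  The molecule region is its effective
    axisymmetric rod of radius sqrt(S(z)/pi).
    """
    opts = options or MeshOptions()
    if opts.res_pore <= 0 or opts.res_z_fine <= 0:
        raise MeshingError("mesh resolutions must be positive")
    if geometry.half_width_x != geometry.half_width_y:
        raise MeshingError("built-in mesher requires a square cross-section box")

    zs = _layer_positions(geometry, opts)
    rho = np.asarray(geometry.wall_radius(zs), dtype=float)

    a_profile = None
    s_mol = None
    if molecule is not None:
        a_profile = molecule_radius_profile(molecule, zs)
        a_profile = np.minimum(a_profile, rho - opts.wall_clearance)
        if (a_profile <= 0).all():
            raise MeshingError("molecule does not intersect the simulation box")
        s_mol = float(a_profile.max())

    points2d, tri, ref = _reference_plane(geometry, s_mol, opts)
    n_plane, n_layers = len(points2d), len(zs)

    layers = []
    for i, z in enumerate(zs):
        a_z = opts.min_molecule_radius
        if a_profile is not None:
            a_z = max(float(a_profile[i]), opts.min_molecule_radius)
        plane = points2d if s_mol is None and math.isclose(
            rho[i], ref["s_wall"]
        ) else _map_plane(points2d, ref, a_z, float(rho[i]))
        layer = np.column_stack([plane, np.full(n_plane, z)])
        layers.append(layer)
    nodes = np.vstack(layers)

    tets = _split_prisms(tri, n_plane, n_layers)

    # orientation fix: make all signed volumes positive
    p = nodes[tets]
    vol = np.einsum(
        "ij,ij->i", p[:, 3] - p[:, 0], np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    )
    flip = vol < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    degenerate = np.abs(vol) < 1e-12
    if degenerate.any():
        raise MeshingError(
            f"{int(degenerate.sum())} degenerate tetrahedra; refine the resolution"
        )

    region = _classify_elements(nodes, tets, geometry, zs, a_profile)
    boundary_facets, facet_tags = _extract_facets(nodes, tets, region, geometry)

    mesh = Mesh(
        nodes=nodes,
        tets=tets,
        region=region,
        boundary_facets=boundary_facets,
        facet_tags=facet_tags,
        metadata={
            "geometry": geometry.to_config(),
            "layers": zs.tolist(),
            "n_plane": n_plane,
            "molecule": molecule.descriptor if molecule is not None else None,
            "options": vars(opts).copy(),
        },
    )
    mesh.validate()
    return mesh


def _classify_elements(
    nodes: np.ndarray,
    tets: np.ndarray,
    geometry: PoreGeometry,
    layer_zs: np.ndarray,
    a_profile: Optional[np.ndarray],
) -> np.ndarray:
    c = nodes[tets].mean(axis=1)
    radial = np.hypot(c[:, 0], c[:, 1])
    z = c[:, 2]
    in_slab = (z >= geometry.z_bottom) & (z <= geometry.z_top)
    rho = np.asarray(geometry.wall_radius(z))
    region = np.where(
        in_slab, int(RegionLabel.SOLVENT_PORE), int(RegionLabel.SOLVENT_BULK)
    )
    region[in_slab & (radial > rho)] = int(RegionLabel.MEMBRANE)
    if a_profile is not None:
        a_c = np.interp(z, layer_zs, a_profile)
        mol = (radial < a_c) & (region != int(RegionLabel.MEMBRANE))
        region[mol] = int(RegionLabel.MOLECULE)
    return region.astype(np.int32)


def _extract_facets(
    nodes: np.ndarray, tets: np.ndarray, region: np.ndarray, geometry: PoreGeometry
) -> Tuple[np.ndarray, np.ndarray]:
    faces = np.concatenate(
        [tets[:, [1, 2, 3]], tets[:, [0, 3, 2]], tets[:, [0, 1, 3]], tets[:, [0, 2, 1]]]
    )
    owner = np.tile(np.arange(len(tets)), 4)
    key = np.sort(faces, axis=1)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    key_s, faces_s, owner_s = key[order], faces[order], owner[order]
    same = np.all(key_s[1:] == key_s[:-1], axis=1)
    is_pair_start = np.concatenate([same, [False]])
    is_pair_end = np.concatenate([[False], same])
    single = ~(is_pair_start | is_pair_end)

    out_faces: List[np.ndarray] = []
    out_tags: List[np.ndarray] = []

    # external boundary: tag by position
    ext = faces_s[single]
    if len(ext):
        fx = nodes[ext]
        zc = fx[:, :, 2]
        tol = 1e-6
        tags = np.full(len(ext), FACET_TAGS["side"])
        tags[np.all(np.abs(zc - geometry.z_max) < tol, axis=1)] = FACET_TAGS["top"]
        tags[np.all(np.abs(zc - geometry.z_min) < tol, axis=1)] = FACET_TAGS["bottom"]
        out_faces.append(ext)
        out_tags.append(tags)

    # interfaces between regions
    starts = np.where(is_pair_start)[0]
    ra = region[owner_s[starts]]
    rb = region[owner_s[starts + 1]]
    solv = lambda r: (r == int(RegionLabel.SOLVENT_BULK)) | (r == int(RegionLabel.SOLVENT_PORE))
    mem_iface = (solv(ra) & (rb == int(RegionLabel.MEMBRANE))) | (
        solv(rb) & (ra == int(RegionLabel.MEMBRANE))
    )
    mol_iface = (solv(ra) & (rb == int(RegionLabel.MOLECULE))) | (
        solv(rb) & (ra == int(RegionLabel.MOLECULE))
    )
    for mask, name in ((mem_iface, "membrane_wall"), (mol_iface, "molecule_surface")):
        if mask.any():
            out_faces.append(faces_s[starts[mask]])
            out_tags.append(np.full(int(mask.sum()), FACET_TAGS[name]))

    if out_faces:
        return np.vstack(out_faces), np.concatenate(out_tags)
    return np.empty((0, 3), dtype=np.int64), np.empty(0, dtype=np.int64)


# ---------------------------------------------------------------------------
# MSH / VTK io
# ---------------------------------------------------------------------------


def export_mesh(mesh: Mesh, stream: TextIO, format: str = "MSH") -> None:
    fmt = format.upper()
    if fmt == "MSH":
        _write_msh2(mesh, stream)
    elif fmt == "VTK":
        _write_vtk(mesh, stream)
    else:
        raise MeshIOError(f"unknown mesh format {format!r} (use MSH or VTK)")


def import_mesh(stream: TextIO, format: str = "MSH") -> Mesh:
    fmt = format.upper()
    if fmt == "MSH":
        return _read_msh2(stream)
    if fmt == "VTK":
        return _read_vtk(stream)
    raise MeshIOError(f"unknown mesh format {format!r} (use MSH or VTK)")


def _write_msh2(mesh: Mesh, f: TextIO) -> None:
    f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n$Nodes\n")
    f.write(f"{mesh.n_nodes}\n")
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        f.write(f"{i} {x:.10g} {y:.10g} {z:.10g}\n")
    f.write("$EndNodes\n$Elements\n")
    n_el = mesh.n_tets + len(mesh.boundary_facets)
    f.write(f"{n_el}\n")
    eid = 1
    for face, tag in zip(mesh.boundary_facets, mesh.facet_tags):
        a, b, c = (int(v) + 1 for v in face)
        f.write(f"{eid} 2 2 {int(tag)} {int(tag)} {a} {b} {c}\n")
        eid += 1
    for tet, reg in zip(mesh.tets, mesh.region):
        a, b, c, d = (int(v) + 1 for v in tet)
        phys = int(reg) + REGION_TAG_OFFSET
        f.write(f"{eid} 4 2 {phys} {phys} {a} {b} {c} {d}\n")
        eid += 1
    f.write("$EndElements\n")


def _read_msh2(f: TextIO) -> Mesh:
    lines = iter(f.read().splitlines())

    def seek(section: str) -> None:
        for ln in lines:
            if ln.strip() == section:
                return
        raise MeshIOError(f"missing {section} section")

    seek("$MeshFormat")
    ver = next(lines).split()[0]
    if not ver.startswith("2"):
        raise MeshIOError(f"unsupported MSH version {ver} (v2.2 ASCII required)")
    seek("$Nodes")
    n = int(next(lines))
    nodes = np.empty((n, 3))
    for i in range(n):
        rec = next(lines).split()
        nodes[i] = [float(v) for v in rec[1:4]]
    seek("$Elements")
    n_el = int(next(lines))
    tets, regions, faces, tags = [], [], [], []
    for _ in range(n_el):
        rec = next(lines).split()
        etype, ntags = int(rec[1]), int(rec[2])
        phys = int(rec[3]) if ntags else 0
        conn = [int(v) - 1 for v in rec[3 + ntags:]]
        if etype == 2:
            faces.append(conn)
            tags.append(phys)
        elif etype == 4:
            tets.append(conn)
            regions.append(phys - REGION_TAG_OFFSET)
    if not tets:
        raise MeshIOError("no tetrahedra found in MSH file")
    valid = set(FACET_TAGS.values())
    if not faces or not any(t in valid for t in tags):
        required = ", ".join(sorted(FACET_TAGS, key=FACET_TAGS.get))
        raise MeshIOError(
            f"mesh carries no tagged boundary facets; required tags: {required} "
            f"(physical ids {sorted(valid)})"
        )
    return Mesh(
        nodes=nodes,
        tets=np.array(tets, dtype=np.int64),
        region=np.array(regions, dtype=np.int32),
        boundary_facets=np.array(faces, dtype=np.int64),
        facet_tags=np.array(tags, dtype=np.int64),
        metadata={"source": "msh2 import"},
    )


def _write_vtk(mesh: Mesh, f: TextIO) -> None:
    f.write("# vtk DataFile Version 3.0\nnanopnp mesh\nASCII\n")
    f.write("DATASET UNSTRUCTURED_GRID\n")
    f.write(f"POINTS {mesh.n_nodes} double\n")
    for x, y, z in mesh.nodes:
        f.write(f"{x:.10g} {y:.10g} {z:.10g}\n")
    n_cells = mesh.n_tets + len(mesh.boundary_facets)
    size = 5 * mesh.n_tets + 4 * len(mesh.boundary_facets)
    f.write(f"CELLS {n_cells} {size}\n")
    for tet in mesh.tets:
        f.write("4 " + " ".join(str(int(v)) for v in tet) + "\n")
    for face in mesh.boundary_facets:
        f.write("3 " + " ".join(str(int(v)) for v in face) + "\n")
    f.write(f"CELL_TYPES {n_cells}\n")
    f.write("\n".join(["10"] * mesh.n_tets + ["5"] * len(mesh.boundary_facets)) + "\n")
    f.write(f"CELL_DATA {n_cells}\nSCALARS tag int 1\nLOOKUP_TABLE default\n")
    vals = [int(r) + REGION_TAG_OFFSET for r in mesh.region] + [
        int(t) for t in mesh.facet_tags
    ]
    f.write("\n".join(str(v) for v in vals) + "\n")


def _read_vtk(f: TextIO) -> Mesh:
    tokens = f.read().split()
    it = iter(range(len(tokens)))

    def find(word: str, start: int = 0) -> int:
        for i in range(start, len(tokens)):
            if tokens[i] == word:
                return i
        raise MeshIOError(f"missing {word} in VTK file")

    ip = find("POINTS")
    n = int(tokens[ip + 1])
    coords = np.array(tokens[ip + 3 : ip + 3 + 3 * n], dtype=float).reshape(n, 3)
    ic = find("CELLS", ip)
    n_cells = int(tokens[ic + 1])
    pos = ic + 3
    cells = []
    for _ in range(n_cells):
        k = int(tokens[pos])
        cells.append([int(v) for v in tokens[pos + 1 : pos + 1 + k]])
        pos += k + 1
    itypes = find("CELL_TYPES", ic)
    ctypes = [int(v) for v in tokens[itypes + 2 : itypes + 2 + n_cells]]
    tags = [0] * n_cells
    try:
        icd = find("CELL_DATA", itypes)
        ilt = find("LOOKUP_TABLE", icd)
        tags = [int(v) for v in tokens[ilt + 2 : ilt + 2 + n_cells]]
    except MeshIOError:
        pass
    tets, regions, faces, ftags = [], [], [], []
    for cell, ct, tg in zip(cells, ctypes, tags):
        if ct == 10:
            tets.append(cell)
            regions.append(tg - REGION_TAG_OFFSET)
        elif ct == 5:
            faces.append(cell)
            ftags.append(tg)
    if not tets:
        raise MeshIOError("no tetrahedra found in VTK file")
    return Mesh(
        nodes=coords,
        tets=np.array(tets, dtype=np.int64),
        region=np.array(regions, dtype=np.int32),
        boundary_facets=(
            np.array(faces, dtype=np.int64) if faces else np.empty((0, 3), dtype=np.int64)
        ),
        facet_tags=np.array(ftags, dtype=np.int64),
        metadata={"source": "vtk import"},
    )
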