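"""Currents, conductances and blockade amplitudes from field solutions.

The ionic current through the pore is the surface integral of the z-component
of the total charge flux over a cut plane inside the channel,

    I = sum_i q_i e  int_S  -D_i ( dn_i/dz + (q_i e / k_B T) n_i du/dz ) dx dy,

evaluated exactly for the piecewise-linear FEM fields by intersecting the
plane with each solvent tetrahedron (the integrand is affine on each
intersection polygon, so area x value-at-centroid is exact).  In steady state
the value is independent of the plane position up to discretization error;
by default the current is averaged over five equally spaced planes inside
the membrane and the spread is reported alongside.

Sign convention: the reported current is the one flowing from the biased
electrode through the pore, so a positive bias drives a positive current
for KCl (both carriers add with the same sign) regardless of which face
carries the bias.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, TextIO, Tuple

import numpy as np
import pandas as pd

from .solver import FemCore, FieldSolution
from .units import E_PER_PS_TO_AMPERE

__all__ = [
    "CurrentRecord",
    "IVCurve",
    "ionic_current",
    "plane_currents",
    "conductance",
    "signal_amplitude",
    "export_field_maps",
    "load_field_map",
]


class NotConvergedError(RuntimeError):
    pass


@dataclass
class CurrentRecord:
    """Open and (optionally) blocked current at one bias point."""

    voltage: float                    # volt
    open_current: float               # ampere
    blocked_current: Optional[float] = None
    manifest: dict = field(default_factory=dict)

    @property
    def amplitude(self) -> Optional[float]:
        """Blockade amplitude dI = I_open - I_blocked."""
        if self.blocked_current is None:
            return None
        return self.open_current - self.blocked_current


@dataclass
class IVCurve:
    """Current-voltage relation; conductance is its least-squares slope."""

    records: List[CurrentRecord]

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: r.voltage)

    @property
    def voltages(self) -> np.ndarray:
        return np.array([r.voltage for r in self.records])

    @property
    def currents(self) -> np.ndarray:
        return np.array([r.open_current for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "voltage_V": r.voltage,
                    "open_current_A": r.open_current,
                    "blocked_current_A": r.blocked_current,
                    "amplitude_A": r.amplitude,
                }
            )
        return pd.DataFrame(rows)


def conductance(iv: IVCurve) -> float:
    """Least-squares slope dI/dV in siemens over the supplied bias range."""
    if len(iv.records) < 2:
        raise ValueError("conductance needs at least two voltage points")
    slope, _ = np.polyfit(iv.voltages, iv.currents, 1)
    return float(slope)


def signal_amplitude(open_rec: CurrentRecord, blocked_rec: CurrentRecord) -> float:
    """dI = I_open - I_blocked for matching bias and geometry manifests."""
    if not math.isclose(open_rec.voltage, blocked_rec.voltage, rel_tol=1e-9, abs_tol=1e-12):
        raise ValueError(
            f"voltage mismatch: {open_rec.voltage} vs {blocked_rec.voltage}"
        )
    g1 = open_rec.manifest.get("geometry")
    g2 = blocked_rec.manifest.get("geometry")
    if g1 is not None and g2 is not None and g1 != g2:
        raise ValueError("geometry manifests differ between open and blocked runs")
    return open_rec.open_current - blocked_rec.open_current


# ---------------------------------------------------------------------------
# plane-integral current
# ---------------------------------------------------------------------------


def _core_of(sol: FieldSolution) -> FemCore:
    core = getattr(sol, "_core", None)
    if core is None:
        core = FemCore(sol.mesh)
        sol._core = core
    return core


def _polygon_area_centroid(pts: np.ndarray) -> Tuple[float, np.ndarray]:
    """Area and centroid of a convex planar polygon given unordered vertices."""
    c0 = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 1] - c0[1], pts[:, 0] - c0[0])
    p = pts[np.argsort(ang)]
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    if abs(area) < 1e-300:
        return 0.0, c0
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return abs(area), np.array([cx, cy])


_TET_EDGES = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


def plane_current(sol: FieldSolution, z_plane: float) -> float:
    """Current (ampere) through the horizontal plane z = z_plane."""
    mesh = sol.mesh
    core = _core_of(sol)
    solvent = np.isin(mesh.region, (0, 1))
    zn = mesh.nodes[mesh.tets][:, :, 2]
    # nudge off any node plane to avoid degenerate intersections
    if np.any(np.abs(mesh.nodes[:, 2] - z_plane) < 1e-9):
        z_plane += 1.37e-4 * max(1.0, abs(z_plane))
    crossed = solvent & (zn.min(axis=1) < z_plane) & (zn.max(axis=1) > z_plane)
    idx = np.where(crossed)[0]
    if len(idx) == 0:
        raise ValueError(f"plane z={z_plane:g} does not intersect the solvent")

    p = sol.params
    VT = p.thermal_voltage
    species = list(p.species)
    grads_n = {s.name: core.elem_gradient(sol.concentrations[s.name]) for s in species}
    grad_u = core.elem_gradient(sol.u)

    total = 0.0
    nodes = mesh.nodes
    for e in idx:
        tet = mesh.tets[e]
        pts = nodes[tet]
        below = pts[:, 2] < z_plane
        poly = []
        for a, b in _TET_EDGES:
            if below[a] != below[b]:
                t = (z_plane - pts[a, 2]) / (pts[b, 2] - pts[a, 2])
                poly.append(pts[a] + t * (pts[b] - pts[a]))
        if len(poly) < 3:
            continue
        poly = np.asarray(poly)
        area, cxy = _polygon_area_centroid(poly[:, :2])
        if area == 0.0:
            continue
        x = np.array([cxy[0], cxy[1], z_plane])
        # affine interpolation of each field at the polygon centroid
        d = x - pts[0]
        jz = 0.0
        for s in species:
            D = sol.coefficients.diffusion[s.name][e]
            gn = grads_n[s.name][e]
            n_c = sol.concentrations[s.name][tet[0]] + gn @ d
            flux_z = -D * (gn[2] + (s.valence / VT) * n_c * grad_u[e][2])
            jz += s.valence * flux_z
        total += jz * area
    # report the current flowing from the biased electrode through the pore,
    # so a positive applied bias yields a positive current either way round
    sign = -1.0 if sol.params.bias_side == "top" else 1.0
    return sign * total * E_PER_PS_TO_AMPERE


def plane_currents(sol: FieldSolution, n_planes: int = 5) -> np.ndarray:
    """Currents on ``n_planes`` equally spaced planes inside the membrane."""
    if sol.geometry is None:
        raise ValueError("solution carries no geometry; use plane_current(z)")
    zb, zt = sol.geometry.z_bottom, sol.geometry.z_top
    h = zt - zb
    zs = zb + h * (np.arange(1, n_planes + 1)) / (n_planes + 1)
    return np.array([plane_current(sol, float(z)) for z in zs])


def ionic_current(
    sol: FieldSolution, z_plane: Optional[float] = None, n_planes: int = 5
) -> float:
    """Ionic current in ampere.

    With an explicit ``z_plane`` the integral is taken on that plane (which
    must intersect the pore); otherwise it is averaged over ``n_planes``
    planes spaced through the membrane.
    """
    if z_plane is not None:
        g = sol.geometry
        if g is not None and not (g.z_bottom <= z_plane <= g.z_top):
            raise ValueError(
                f"plane z={z_plane:g} lies outside the pore "
                f"[{g.z_bottom:g}, {g.z_top:g}]"
            )
        return plane_current(sol, z_plane)
    return float(plane_currents(sol, n_planes).mean())


# ---------------------------------------------------------------------------
# field maps
# ---------------------------------------------------------------------------


def export_field_maps(
    sol: FieldSolution,
    stream: TextIO,
    plane: str = "xz",
    n_u: int = 80,
    n_v: int = 120,
    offset: float = 0.0,
) -> pd.DataFrame:
    """Sample u and |grad u| on a regular grid in the requested plane (CSV).

    ``plane`` is ``"xz"`` or ``"yz"``; ``offset`` fixes the third coordinate.
    Refuses to export a non-converged solution.
    """
    if not sol.converged:
        raise NotConvergedError("refusing to export maps of a non-converged solution")
    if plane not in ("xz", "yz"):
        raise ValueError("plane must be 'xz' or 'yz'")
    mesh = sol.mesh
    core = _core_of(sol)
    grad_u = core.elem_gradient(sol.u)
    lo, hi = mesh.nodes.min(axis=0), mesh.nodes.max(axis=0)
    iu = 0 if plane == "xz" else 1
    us = np.linspace(lo[iu], hi[iu], n_u)
    vs = np.linspace(lo[2], hi[2], n_v)

    from scipy.spatial import cKDTree

    centroids = mesh.nodes[mesh.tets].mean(axis=1)
    tree = cKDTree(centroids)
    pts_tet = mesh.nodes[mesh.tets]

    rows = []
    from .solver import _barycentric

    for vv in vs:
        for uu in us:
            x = np.zeros(3)
            x[iu], x[2] = uu, vv
            x[1 - iu] = offset
            _, cand = tree.query(x, k=min(24, mesh.n_tets))
            val = emag = np.nan
            for e in np.atleast_1d(cand):
                lam = _barycentric(pts_tet[e], x)
                if lam is not None:
                    val = float(lam @ sol.u[mesh.tets[e]])
                    emag = float(np.linalg.norm(grad_u[e]))
                    break
            rows.append({plane[0]: uu, "z": vv, "u_V": val, "E_V_per_A": emag})
    df = pd.DataFrame(rows)
    df.to_csv(stream, index=False)
    return df


def load_field_map(stream) -> pd.DataFrame:
    return pd.read_csv(stream)


def export_solution_vtk(sol: FieldSolution, stream: TextIO) -> None:
    """Write the mesh with u and the ion densities as VTK point data."""
    from .mesh import export_mesh

    export_mesh(sol.mesh, stream, format="VTK")
    n = sol.mesh.n_nodes
    stream.write(f"POINT_DATA {n}\n")
    stream.write("SCALARS potential_V double 1\nLOOKUP_TABLE default\n")
    stream.write("\n".join(f"{v:.8g}" for v in sol.u) + "\n")
    for name, values in sol.concentrations.items():
        stream.write(f"SCALARS n_{name}_per_A3 double 1\nLOOKUP_TABLE default\n")
        stream.write("\n".join(f"{v:.8g}" for v in values) + "\n")
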