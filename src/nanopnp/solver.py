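"""Coupled steady-state Poisson / Nernst-Planck finite-element solver.

The electrostatic potential u obeys the Poisson equation on the whole box,

    -div(eps eps0 grad u) = sum_i q_i e n_i + sum_j Q_j delta(x - x_j),

with the relative permittivity eps = 78 in solvent and 2 in membrane and
molecule, mobile ion densities n_i on the right-hand side, and the molecule's
partial charges Q_j deposited onto the vertices of their containing
tetrahedra by barycentric weights (total charge preserved exactly).

Each ionic species obeys the steady Nernst-Planck equation on the solvent,

    div( D_i ( grad n_i + (q_i e / k_B T) n_i grad u ) ) = 0,

discretized with P1 tetrahedra and streamline-upwind Petrov-Galerkin (SUPG)
stabilization: the test space is enriched by sigma_N p_i . grad v with the
element stability parameter

    sigma_N = h_N / (2 |p_i|) * xi(Pe_N),   Pe_N = |p_i| h_N / (6 D_i),
    xi(Pe) = Pe for Pe <= 1, else 1,

where h_N is the element diameter and p_i the element drift velocity
-D_i q_i e grad(u) / (k_B T).  The two equations are alternated in a Gummel
fixed-point loop; each new iterate is blended with the previous one
(under-relaxation factor t, default 0.8) until the maximum relative nodal
change drops below tolerance.

Boundary conditions: the applied bias is imposed on the top face (the wide
opening of a conical pore) with the bottom face grounded, side faces carry
the linear interpolation between the two; ion concentrations are fixed at
their bulk values on top and bottom, with no normal flux through side
walls, membrane and molecule.

Units: angstrom / picosecond / elementary charge / volt (see units module).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree

from .geometry import PoreGeometry, RegionLabel
from .mesh import Mesh
from .molecule import Molecule, effective_pore_radius, cross_section_area
from .units import EPS0_E_PER_V_A, molar_to_density, thermal_voltage

__all__ = [
    "SpeciesSpec",
    "PNPParameters",
    "CoefficientField",
    "FieldSolution",
    "PNPSystem",
    "SolverDivergenceError",
    "kcl_species",
    "diffusion_profile",
    "buffered_diffusion",
    "xi_upwind",
    "gummel_solve",
    "NOSKOV_CONSTANTS",
]


class SolverDivergenceError(RuntimeError):
    def __init__(self, message: str, log: List[dict]):
        super().__init__(message)
        self.iteration_log = log


@dataclass(frozen=True)
class SpeciesSpec:
    """An ionic species: valence (e), bulk concentration (mol/L), bulk
    diffusion constant (A^2/ps) and van der Waals radius (A)."""

    name: str
    valence: int
    bulk_concentration: float
    bulk_diffusion: float
    ion_radius: float

    def __post_init__(self) -> None:
        if self.bulk_diffusion <= 0:
            raise ValueError("bulk diffusion constant must be positive")
        if self.valence == 0:
            raise ValueError("ionic species needs a non-zero valence")

    @property
    def bulk_density(self) -> float:
        """Bulk number density in A^-3."""
        return molar_to_density(self.bulk_concentration)


def kcl_species(concentration: float) -> Tuple[SpeciesSpec, SpeciesSpec]:
    """KCl at the given molarity with CHARMM27 vdW radii and the
    experimental bulk diffusion constants D_K = 0.196, D_Cl = 0.203 A^2/ps."""
    return (
        SpeciesSpec("K", +1, concentration, 0.196, 1.764),
        SpeciesSpec("Cl", -1, concentration, 0.203, 2.27),
    )


#: empirical constants of the pore-radius diffusion correlation
NOSKOV_CONSTANTS = {"A": 0.64309, "B": 0.00044, "C": 0.06894, "D": 0.35647, "E": 0.19409}


def diffusion_profile(species: SpeciesSpec, R_p: float) -> float:
    """In-pore diffusion constant D_b / (A + B e^(beta/C) + D e^(beta/E)),
    beta = R_ion / R_p.  The denominator tends to A+B+D = 1 as beta -> 0."""
    if R_p <= 0:
        raise ValueError("effective pore radius must be positive")
    k = NOSKOV_CONSTANTS
    beta = species.ion_radius / R_p
    denom = k["A"] + k["B"] * math.exp(beta / k["C"]) + k["D"] * math.exp(beta / k["E"])
    return species.bulk_diffusion / denom


def _buffer_f(s: np.ndarray, n: int) -> np.ndarray:
    """Blending polynomial f(s) = n s^(n+1) - (n+1) s^n on [0, 1]:
    f(0) = 0, f(1) = -1, f'(0) = f'(1) = 0 (C1 matching at both ends)."""
    return n * s ** (n + 1) - (n + 1) * s**n


def buffered_diffusion(
    D_chan: float,
    D_ion: float,
    z,
    z_chan: float,
    z_ion: float,
    n: int = 7,
):
    """Piecewise-continuous diffusion constant along the pore axis.

    Channel side of ``z_chan`` -> D_chan; bulk side of ``z_ion`` -> D_ion;
    in between D_chan + (D_chan - D_ion) f(s) with s the normalized distance
    from the channel boundary.
    """
    if z_chan == z_ion:
        raise ValueError("z_chan and z_ion must differ")
    z = np.asarray(z, dtype=float)
    s = (z - z_chan) / (z_ion - z_chan)
    out = np.where(
        s <= 0.0,
        D_chan,
        np.where(s >= 1.0, D_ion, D_chan + (D_chan - D_ion) * _buffer_f(np.clip(s, 0, 1), n)),
    )
    return float(out) if out.ndim == 0 else out


def xi_upwind(pe) -> np.ndarray:
    """SUPG upwind function: xi(Pe) = Pe for 0 <= Pe <= 1, else 1."""
    return np.minimum(np.asarray(pe, dtype=float), 1.0)


@dataclass
class PNPParameters:
    """Solver configuration.

    ``relaxation`` is the under-relaxation factor t in (0, 1): each Gummel
    update keeps a fraction t of the previous iterate.  ``buffer_length`` is
    the distance from the membrane face (z_chan) to the start of the bulk
    region (z_ion) for the diffusion blending.
    """

    species: Sequence[SpeciesSpec]
    temperature: float = 294.15
    voltage: float = 0.0
    eps_solvent: float = 78.0
    eps_membrane: float = 2.0
    eps_molecule: float = 2.0
    use_pore_diffusion: bool = True
    buffer_exponent: int = 7
    buffer_length: float = 10.0
    relaxation: float = 0.8
    tolerance: float = 1e-6
    max_iterations: int = 400
    supg: bool = True
    supg_drift: str = "physical"  # or "as_printed" (the printed k_B T q factor)
    supg_h: str = "diameter"      # element length: "diameter" (longest edge)
                                  # or "streamline" (directional; weaker
                                  # stabilization on anisotropic meshes)
    bias_side: str = "top"        # electrode carrying V_applied (top = the
                                  # wide opening, radius R, of a conical pore)
    side_potential: str = "interpolated"  # or "insulating"

    def __post_init__(self) -> None:
        if not (0.0 < self.relaxation < 1.0):
            raise ValueError("relaxation factor must satisfy 0 < t < 1")
        if self.eps_solvent <= 0 or self.eps_membrane <= 0 or self.eps_molecule <= 0:
            raise ValueError("dielectric constants must be positive")
        if self.bias_side not in ("bottom", "top"):
            raise ValueError("bias_side must be 'bottom' or 'top'")
        if self.supg_drift not in ("physical", "as_printed"):
            raise ValueError("supg_drift must be 'physical' or 'as_printed'")
        if self.supg_h not in ("streamline", "diameter"):
            raise ValueError("supg_h must be 'streamline' or 'diameter'")

    @property
    def thermal_voltage(self) -> float:
        return thermal_voltage(self.temperature)


@dataclass
class CoefficientField:
    """Per-element relative permittivity and per-species diffusion maps."""

    eps: np.ndarray                  # (M,)
    diffusion: Dict[str, np.ndarray]  # species name -> (M,), 0 off-solvent


@dataclass
class FieldSolution:
    """Converged (or flagged) nodal fields on a mesh."""

    mesh: Mesh
    u: np.ndarray                     # (N,) electrostatic potential, volt
    concentrations: Dict[str, np.ndarray]  # (N,) number densities, A^-3
    params: PNPParameters
    iteration_log: List[dict]
    converged: bool
    coefficients: CoefficientField
    geometry: Optional[PoreGeometry] = None
    clipped_density: float = 0.0      # total negative density removed

    @property
    def n_iterations(self) -> int:
        return len(self.iteration_log)

    def iteration_log_csv(self, stream) -> None:
        """Write the per-iteration residual log as CSV."""
        import pandas as pd

        pd.DataFrame(self.iteration_log).to_csv(stream, index=False)


# ---------------------------------------------------------------------------
# FEM core: P1 gradients and assembly helpers
# ---------------------------------------------------------------------------


class FemCore:
    """Precomputed P1 data for one mesh: element gradients, volumes,
    scatter indices for vectorized stiffness assembly."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        p = mesh.nodes[mesh.tets]          # (M,4,3)
        e1 = p[:, 1] - p[:, 0]
        e2 = p[:, 2] - p[:, 0]
        e3 = p[:, 3] - p[:, 0]
        vol6 = np.einsum("ij,ij->i", e3, np.cross(e1, e2))
        self.volume = vol6 / 6.0
        # gradients of the barycentric basis functions
        J = np.stack([e1, e2, e3], axis=2)  # (M,3,3), columns are edges
        g123 = np.linalg.inv(J)             # row i = grad of lambda_{i+1}
        g0 = -g123.sum(axis=1, keepdims=True)
        self.grads = np.concatenate([g0, g123], axis=1)  # (M,4,3)
        # element diameters (longest edge)
        t = mesh.tets
        edges = np.stack(
            [p[:, a] - p[:, b] for a, b in ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))]
        )
        self.h_elem = np.linalg.norm(edges, axis=2).max(axis=0)
        self.rows = np.repeat(mesh.tets, 4, axis=1).reshape(-1)
        self.cols = np.tile(mesh.tets, (1, 4)).reshape(-1)
        self.GG = np.einsum("eac,ebc->eab", self.grads, self.grads)  # (M,4,4)

    def stiffness(self, coeff: np.ndarray, elem_mask: Optional[np.ndarray] = None) -> sp.csr_matrix:
        """Assemble sum_e c_e vol_e grad(phi_a).grad(phi_b)."""
        vals = (coeff * self.volume)[:, None, None] * self.GG
        return self._scatter(vals, elem_mask)

    def _scatter(self, vals: np.ndarray, elem_mask: Optional[np.ndarray]) -> sp.csr_matrix:
        n = self.mesh.n_nodes
        if elem_mask is not None:
            vals = np.where(elem_mask[:, None, None], vals, 0.0)
        A = sp.coo_matrix(
            (vals.reshape(-1), (self.rows, self.cols)), shape=(n, n)
        )
        return A.tocsr()

    def mass(self, elem_mask: Optional[np.ndarray] = None) -> sp.csr_matrix:
        """Consistent P1 mass matrix (vol/10 diagonal, vol/20 off-diagonal)."""
        base = np.full((4, 4), 1.0 / 20.0)
        np.fill_diagonal(base, 1.0 / 10.0)
        vals = self.volume[:, None, None] * base
        return self._scatter(vals, elem_mask)

    def elem_gradient(self, nodal: np.ndarray) -> np.ndarray:
        """Per-element gradient of a nodal field: (M, 3)."""
        return np.einsum("eac,ea->ec", self.grads, nodal[self.mesh.tets])


# ---------------------------------------------------------------------------
# coefficient construction
# ---------------------------------------------------------------------------


def build_coefficients(
    mesh: Mesh,
    params: PNPParameters,
    geometry: Optional[PoreGeometry] = None,
    molecule: Optional[Molecule] = None,
) -> CoefficientField:
    """Dielectric and diffusion maps from region tags and the pore profile.

    Inside the channel (membrane z-span) the diffusion constant follows the
    pore-radius correlation with R_p = rho(z) - sqrt(S(z)/pi); a buffer of
    ``params.buffer_length`` on each side blends C1-continuously to the bulk
    value; elsewhere ions diffuse at their bulk rate.
    """
    region = mesh.region
    eps = np.full(mesh.n_tets, params.eps_solvent)
    eps[region == int(RegionLabel.MEMBRANE)] = params.eps_membrane
    eps[region == int(RegionLabel.MOLECULE)] = params.eps_molecule

    solvent = (region == int(RegionLabel.SOLVENT_BULK)) | (
        region == int(RegionLabel.SOLVENT_PORE)
    )
    zc = mesh.nodes[mesh.tets].mean(axis=1)[:, 2]

    diffusion: Dict[str, np.ndarray] = {}
    if geometry is None or not params.use_pore_diffusion:
        for spec in params.species:
            diffusion[spec.name] = np.where(solvent, spec.bulk_diffusion, 0.0)
        return CoefficientField(eps=eps, diffusion=diffusion)

    # effective open radius profile R_p(z) within the channel span
    a_sq = None
    if molecule is not None:
        zlo, zhi = molecule.z_extent
        zgrid = np.linspace(zlo, zhi, 81)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            S = np.array([cross_section_area(molecule, float(z)) for z in zgrid])
        a_sq = (zgrid, np.sqrt(S / math.pi))

    def r_p(zv: np.ndarray) -> np.ndarray:
        rho = np.asarray(geometry.wall_radius(zv), dtype=float)
        if a_sq is None:
            return rho
        a = np.interp(zv, a_sq[0], a_sq[1], left=0.0, right=0.0)
        return np.maximum(rho - a, 0.1)

    zb, zt = geometry.z_bottom, geometry.z_top
    Lb = params.buffer_length
    nbuf = params.buffer_exponent

    for spec in params.species:
        D = np.full(mesh.n_tets, spec.bulk_diffusion)
        in_chan = (zc >= zb) & (zc <= zt)
        rp_chan = r_p(zc[in_chan])
        k = NOSKOV_CONSTANTS
        beta = spec.ion_radius / rp_chan
        denom = k["A"] + k["B"] * np.exp(beta / k["C"]) + k["D"] * np.exp(beta / k["E"])
        D[in_chan] = spec.bulk_diffusion / denom
        # buffers: blend from the channel-boundary value to the bulk value
        D_top_face = spec.bulk_diffusion / _noskov_denom(spec.ion_radius / float(r_p(np.array([zt]))[0]))
        D_bot_face = spec.bulk_diffusion / _noskov_denom(spec.ion_radius / float(r_p(np.array([zb]))[0]))
        up = (zc > zt) & (zc < zt + Lb)
        D[up] = buffered_diffusion(D_top_face, spec.bulk_diffusion, zc[up], zt, zt + Lb, nbuf)
        dn = (zc < zb) & (zc > zb - Lb)
        D[dn] = buffered_diffusion(D_bot_face, spec.bulk_diffusion, zc[dn], zb, zb - Lb, nbuf)
        diffusion[spec.name] = np.where(solvent, D, 0.0)

    return CoefficientField(eps=eps, diffusion=diffusion)


def _noskov_denom(beta: float) -> float:
    k = NOSKOV_CONSTANTS
    return k["A"] + k["B"] * math.exp(beta / k["C"]) + k["D"] * math.exp(beta / k["E"])


# ---------------------------------------------------------------------------
# the coupled system
# ---------------------------------------------------------------------------


class PNPSystem:
    """Assembles and solves the coupled system on one mesh.

    Parameters
    ----------
    mesh:
        Tagged tetrahedral mesh (the whole box).
    params:
        Physical and numerical parameters.
    geometry:
        Pore geometry; required for the pore-diffusion model and for the
        side-face potential interpolation.
    molecule:
        Optional molecule supplying fixed point charges and the blockade
        cross-section.
    coefficients:
        Pre-built coefficient field (overrides the builder; used by
        verification fixtures with bespoke diffusion profiles).
    """

    def __init__(
        self,
        mesh: Mesh,
        params: PNPParameters,
        geometry: Optional[PoreGeometry] = None,
        molecule: Optional[Molecule] = None,
        coefficients: Optional[CoefficientField] = None,
    ):
        self.mesh = mesh
        self.params = params
        self.geometry = geometry
        self.molecule = molecule
        self.core = FemCore(mesh)
        self.coefficients = coefficients or build_coefficients(
            mesh, params, geometry, molecule
        )
        self._setup_topology()
        self._setup_poisson()
        self._setup_np_patterns()
        self._setup_charges()

    # -- setup --------------------------------------------------------------

    def _setup_topology(self) -> None:
        mesh, region = self.mesh, self.mesh.region
        solvent_elems = (region == int(RegionLabel.SOLVENT_BULK)) | (
            region == int(RegionLabel.SOLVENT_PORE)
        )
        self.solvent_elems = solvent_elems
        solvent_nodes = np.zeros(mesh.n_nodes, dtype=bool)
        solvent_nodes[np.unique(mesh.tets[solvent_elems])] = True
        self.solvent_nodes = solvent_nodes

        z = mesh.nodes[:, 2]
        tol = 1e-6
        self.z_lo, self.z_hi = float(z.min()), float(z.max())
        self.top_nodes = np.abs(z - self.z_hi) < tol
        self.bottom_nodes = np.abs(z - self.z_lo) < tol
        x, y = mesh.nodes[:, 0], mesh.nodes[:, 1]
        self.side_nodes = (
            (np.abs(np.abs(x) - np.abs(x).max()) < tol)
            | (np.abs(np.abs(y) - np.abs(y).max()) < tol)
        ) & ~(self.top_nodes | self.bottom_nodes)

    def _potential_dirichlet(self) -> Tuple[np.ndarray, np.ndarray]:
        p = self.params
        z = self.mesh.nodes[:, 2]
        frac = (z - self.z_lo) / (self.z_hi - self.z_lo)
        if p.bias_side == "bottom":
            u_lin = p.voltage * (1.0 - frac)
        else:
            u_lin = p.voltage * frac
        mask = self.top_nodes | self.bottom_nodes
        if p.side_potential == "interpolated":
            mask = mask | self.side_nodes
        return mask, u_lin

    def _setup_poisson(self) -> None:
        eps0 = EPS0_E_PER_V_A
        K = self.core.stiffness(self.coefficients.eps * eps0)
        self.mass_solvent = self.core.mass(elem_mask=self.solvent_elems)
        self.lumped_mass = np.asarray(self.mass_solvent.sum(axis=1)).ravel()
        mask, u_lin = self._potential_dirichlet()
        self.u_dirichlet_mask = mask
        self.u_dirichlet_values = u_lin
        free = ~mask
        self.u_free = free
        self._K_ff = K[free][:, free].tocsc()
        self._K_fd = K[free][:, mask].tocsr()
        self._lu_screened = None
        self._screen_c = np.zeros(self.mesh.n_nodes)

    def _setup_charges(self) -> None:
        self.fixed_charge = np.zeros(self.mesh.n_nodes)
        if self.molecule is None:
            return
        mesh = self.mesh
        lo, hi = mesh.nodes.min(axis=0), mesh.nodes.max(axis=0)
        centroids = mesh.nodes[mesh.tets].mean(axis=1)
        tree = cKDTree(centroids)
        node_tree = cKDTree(mesh.nodes)
        p = mesh.nodes[mesh.tets]
        dropped = 0.0
        for pos, q in zip(self.molecule.positions, self.molecule.charges):
            if q == 0.0:
                continue
            if np.any(pos < lo - 1e-9) or np.any(pos > hi + 1e-9):
                dropped += q
                continue
            _, cand = tree.query(pos, k=min(48, mesh.n_tets))
            placed = False
            for e in np.atleast_1d(cand):
                lam = _barycentric(p[e], pos)
                if lam is not None:
                    self.fixed_charge[mesh.tets[e]] += q * lam
                    placed = True
                    break
            if not placed:
                # sliver-robust fallback: all of the charge to the nearest node
                _, j = node_tree.query(pos)
                self.fixed_charge[j] += q
        if dropped:
            warnings.warn(
                f"{dropped:+.2f} e of molecule charge lies outside the box and was dropped"
            )

    # -- single-field solves ------------------------------------------------

    def solve_poisson(
        self,
        concentrations: Dict[str, np.ndarray],
        u_old: Optional[np.ndarray] = None,
        refresh_screening: bool = True,
    ) -> np.ndarray:
        """Potential from the current ion densities and fixed charges.

        The classical Gummel Poisson step: the mobile charge is linearized
        around the current iterate, n_i(u) ~ n_i (1 - q_i (u - u_old) / V_T),
        which adds a (lumped) screening term on the left-hand side.  The
        fixed point is unchanged -- at convergence u = u_old the extra terms
        cancel -- but the step never overshoots the Debye screening, which
        keeps the alternation stable for strongly charged molecules.  The
        screening factorization is refreshed only while densities still move
        appreciably (any frozen value leaves the fixed point intact).
        """
        rho = np.zeros(self.mesh.n_nodes)
        VT = self.params.thermal_voltage
        for spec in self.params.species:
            rho += spec.valence * concentrations[spec.name]
        rhs = self.mass_solvent @ rho + self.fixed_charge
        if refresh_screening or self._lu_screened is None:
            screen = np.zeros(self.mesh.n_nodes)
            for spec in self.params.species:
                screen += spec.valence**2 * concentrations[spec.name] / VT
            self._screen_c = self.lumped_mass * screen
            A = self._K_ff + sp.diags(self._screen_c[self.u_free])
            self._lu_screened = splu(A.tocsc())
        c = self._screen_c
        if u_old is not None:
            rhs = rhs + c * u_old
        mask = self.u_dirichlet_mask
        free = self.u_free
        u = self.u_dirichlet_values.copy()
        b = rhs[free] - self._K_fd @ u[mask]
        u[free] = self._lu_screened.solve(b)
        return u

    def _np_element_values(self, spec: SpeciesSpec, u: np.ndarray) -> np.ndarray:
        """Per-element 4x4 SUPG-stabilized Nernst-Planck blocks."""
        core, p = self.core, self.params
        D = self.coefficients.diffusion[spec.name]
        VT = p.thermal_voltage
        grads = core.grads
        vol = core.volume
        gu = core.elem_gradient(u)                       # (M,3)
        drift = -(spec.valence / VT) * D[:, None] * gu   # w = -D q grad(u)/VT

        vals = (D * vol)[:, None, None] * core.GG
        # drift term: int (q D / VT) n grad(u).grad(v)
        wdotg = np.einsum("ec,eac->ea", gu, grads)       # grad(u).grad(phi_a)
        coef = (spec.valence / VT) * D * vol / 4.0
        vals = vals + coef[:, None, None] * wdotg[:, :, None]
        if p.supg:
            if p.supg_drift == "physical":
                p_vec = drift
            else:
                p_vec = -(spec.valence * VT) * D[:, None] * gu
            pn = np.linalg.norm(p_vec, axis=1)
            wg = np.einsum("ec,eac->ea", drift, grads)   # w.grad(phi_a)
            if p.supg_h == "streamline":
                # element length along the drift direction: 2 / sum_a |w_hat.grad(phi_a)|
                wn = np.linalg.norm(drift, axis=1)
                denom = np.abs(wg).sum(axis=1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    h_N = np.where(denom > 0, 2.0 * wn / np.maximum(denom, 1e-300), 0.0)
            else:
                h_N = core.h_elem
            with np.errstate(divide="ignore", invalid="ignore"):
                pe = pn * h_N / (6.0 * np.maximum(D, 1e-300))
                sigma = np.where(
                    pn > 0, h_N / (2.0 * np.maximum(pn, 1e-300)) * xi_upwind(pe), 0.0
                )
            vals = vals + (sigma * vol)[:, None, None] * wg[:, :, None] * wg[:, None, :]
        return vals

    def np_matrix(self, spec: SpeciesSpec, u: np.ndarray) -> sp.csr_matrix:
        """Full-size SUPG-stabilized Nernst-Planck operator for one species."""
        return self.core._scatter(self._np_element_values(spec, u), self.solvent_elems)

    def _setup_np_patterns(self) -> None:
        """Precompute scatter patterns for the reduced (free-node) NP system."""
        dir_mask = (self.top_nodes | self.bottom_nodes) & self.solvent_nodes
        free = self.solvent_nodes & ~dir_mask
        self.n_dirichlet_mask = dir_mask
        self.n_free_mask = free
        red = np.full(self.mesh.n_nodes, -1, dtype=np.int64)
        self.n_free_idx = np.where(free)[0]
        red[self.n_free_idx] = np.arange(len(self.n_free_idx))
        rows, cols = self.core.rows, self.core.cols
        elem_ok = np.repeat(self.solvent_elems, 16)
        rf, cf = red[rows], red[cols]
        self._np_sel_ff = elem_ok & (rf >= 0) & (cf >= 0)
        self._np_rows_ff = rf[self._np_sel_ff]
        self._np_cols_ff = cf[self._np_sel_ff]
        self._np_sel_fd = elem_ok & (rf >= 0) & (cf < 0) & dir_mask[cols]
        self._np_rows_fd = rf[self._np_sel_fd]
        self._np_cols_fd = cols[self._np_sel_fd]

    def solve_np(self, spec: SpeciesSpec, u: np.ndarray) -> np.ndarray:
        vals = self._np_element_values(spec, u).reshape(-1)
        nf = len(self.n_free_idx)
        A_ff = sp.coo_matrix(
            (vals[self._np_sel_ff], (self._np_rows_ff, self._np_cols_ff)),
            shape=(nf, nf),
        ).tocsc()
        n = np.zeros(self.mesh.n_nodes)
        n[self.n_dirichlet_mask] = spec.bulk_density
        b = -np.bincount(
            self._np_rows_fd,
            weights=vals[self._np_sel_fd] * n[self._np_cols_fd],
            minlength=nf,
        )
        n[self.n_free_idx] = splu(A_ff).solve(b)
        return n

    # -- Gummel loop --------------------------------------------------------

    def solve(self, initial: Optional[FieldSolution] = None) -> FieldSolution:
        p = self.params
        n_cur: Dict[str, np.ndarray] = {}
        for spec in p.species:
            if initial is not None and spec.name in initial.concentrations:
                n_cur[spec.name] = initial.concentrations[spec.name].copy()
            else:
                n = np.where(self.solvent_nodes, spec.bulk_density, 0.0)
                n_cur[spec.name] = n
        u_cur = initial.u.copy() if initial is not None else self.solve_poisson(n_cur)

        t = p.relaxation
        log: List[dict] = []
        clipped = 0.0
        converged = False
        best = np.inf
        worse_streak = 0
        u_scale = max(abs(p.voltage), p.thermal_voltage)

        for it in range(p.max_iterations):
            changes = {}
            for spec in p.species:
                n_new = self.solve_np(spec, u_cur)
                n_mix = t * n_cur[spec.name] + (1.0 - t) * n_new
                neg = n_mix < 0.0
                if neg.any():
                    clipped += float(-n_mix[neg].sum())
                    n_mix[neg] = 0.0
                changes[spec.name] = float(
                    np.max(np.abs(n_mix - n_cur[spec.name])) / spec.bulk_density
                )
                n_cur[spec.name] = n_mix
            u_new = self.solve_poisson(
                n_cur, u_old=u_cur, refresh_screening=(it < 8 or it % 10 == 0)
            )
            u_mix = t * u_cur + (1.0 - t) * u_new
            changes["u"] = float(np.max(np.abs(u_mix - u_cur)) / u_scale)
            u_cur = u_mix
            log.append({"iteration": it, **changes})
            worst = max(changes.values())
            if worst < p.tolerance:
                converged = True
                break
            if worst < best:
                best = worst
                worse_streak = 0
            else:
                worse_streak += 1
                if worse_streak > 25 and worst > 100.0 * best:
                    raise SolverDivergenceError(
                        f"Gummel iteration diverging after {it + 1} steps "
                        f"(residual {worst:.3g}, best {best:.3g})",
                        log,
                    )

        if not converged:
            warnings.warn(
                f"Gummel iteration stopped at max_iterations={p.max_iterations} "
                f"with residual {max(log[-1][k] for k in log[-1] if k != 'iteration'):.3g}"
            )
        sol = FieldSolution(
            mesh=self.mesh,
            u=u_cur,
            concentrations=n_cur,
            params=p,
            iteration_log=log,
            converged=converged,
            coefficients=self.coefficients,
            geometry=self.geometry,
            clipped_density=clipped,
        )
        sol._core = self.core  # cache for observables
        return sol


def _barycentric(tet_pts: np.ndarray, pos: np.ndarray) -> Optional[np.ndarray]:
    T = (tet_pts[1:] - tet_pts[0]).T
    try:
        lam = np.linalg.solve(T, np.asarray(pos) - tet_pts[0])
    except np.linalg.LinAlgError:
        return None
    lam = np.concatenate([[1.0 - lam.sum()], lam])
    if (lam >= -1e-9).all():
        return np.clip(lam, 0.0, None)
    return None


def gummel_solve(
    mesh: Mesh,
    params: PNPParameters,
    geometry: Optional[PoreGeometry] = None,
    molecule: Optional[Molecule] = None,
    initial: Optional[FieldSolution] = None,
) -> FieldSolution:
    """One-call interface: build the system and run the Gummel loop."""
    return PNPSystem(mesh, params, geometry, molecule).solve(initial=initial)
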