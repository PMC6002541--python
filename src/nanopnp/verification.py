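"""Independent oracles and small deterministic fixtures.

Nothing here shares assembly code with the 3D solver: the 1D reference
solver discretizes the same electrodiffusion equations with finite
differences and Scharfetter-Gummel exponential fluxes on a uniform grid, and
the bulk conductivity is the closed-form Nernst-Einstein expression

    sigma = sum_i q_i^2 e^2 D_i n_i / (k_B T).

Fixtures are seed-free, fully determined by their name, and small enough to
run entire pipelines in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .geometry import PoreGeometry, RegionLabel, build_cylinder_pore, build_conical_pore
from .mesh import Mesh, MeshOptions, mesh_geometry, _split_prisms
from .molecule import Molecule, build_charged_rod
from .solver import PNPParameters, SpeciesSpec, kcl_species
from .units import E_PER_PS_TO_AMPERE, EPS0_E_PER_V_A, thermal_voltage

__all__ = [
    "OracleResult",
    "pnp_1d_oracle",
    "bulk_conductivity",
    "make_fixture",
    "box_mesh",
    "run_oracle_suite",
]


@dataclass
class OracleResult:
    quantity: str
    oracle_value: float
    solver_value: float
    tolerance: float

    @property
    def relative_deviation(self) -> float:
        scale = max(abs(self.oracle_value), 1e-300)
        return abs(self.solver_value - self.oracle_value) / scale

    @property
    def passed(self) -> bool:
        return self.relative_deviation <= self.tolerance


def bulk_conductivity(species, temperature: float = 294.15) -> float:
    """Nernst-Einstein electrolyte conductivity in S/m."""
    VT = thermal_voltage(temperature)
    sigma = sum(s.valence**2 * s.bulk_diffusion * s.bulk_density for s in species) / VT
    # e/(V ps A) -> A/(V m) : multiply by e/ps->A and A->m^-1 conversions
    return sigma * E_PER_PS_TO_AMPERE * 1e10


# ---------------------------------------------------------------------------
# 1D Scharfetter-Gummel reference solver
# ---------------------------------------------------------------------------


def _bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x / (e^x - 1), stable near zero."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-10
    out[small] = 1.0 - 0.5 * x[small]
    xs = x[~small]
    out[~small] = xs / np.expm1(xs)
    return out


def pnp_1d_oracle(
    species,
    L: float,
    grid_n: int = 400,
    voltage: float = 0.0,
    temperature: float = 294.15,
    eps_r: float = 78.0,
    diffusion_profile: Optional[Callable[[np.ndarray], Dict[str, np.ndarray]]] = None,
    fixed_charge_density: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    relaxation: float = 0.5,
    tolerance: float = 1e-10,
    max_iterations: int = 2000,
) -> dict:
    """Finite-difference PNP solve on [0, L] (angstrom); bias on z = 0.

    Returns ``{"current_density": J (A/A^2), "u": ..., "n": {...}, "z": ...}``.
    ``diffusion_profile(z_mid)`` may return per-species diffusion constants on
    interval midpoints; ``fixed_charge_density(z)`` a charge density (e/A^3).
    """
    z = np.linspace(0.0, L, grid_n + 1)
    dz = z[1] - z[0]
    zm = 0.5 * (z[:-1] + z[1:])
    VT = thermal_voltage(temperature)
    species = list(species)
    D_mid = {s.name: np.full(grid_n, s.bulk_diffusion) for s in species}
    if diffusion_profile is not None:
        D_mid = {k: np.asarray(v, dtype=float) for k, v in diffusion_profile(zm).items()}
    rho_fix = np.zeros(grid_n + 1)
    if fixed_charge_density is not None:
        rho_fix = np.asarray(fixed_charge_density(z), dtype=float)

    n = {s.name: np.full(grid_n + 1, s.bulk_density) for s in species}
    u = voltage * (1.0 - z / L)

    eps = eps_r * EPS0_E_PER_V_A
    # Poisson: -eps u'' = rho ; tridiagonal with Dirichlet ends.  The mobile
    # charge is linearized around the current iterate (classical Gummel
    # step), adding a screening term on the diagonal.
    main = np.full(grid_n - 1, 2.0 * eps / dz**2)
    off = np.full(grid_n - 2, -eps / dz**2)
    A_lap = np.diag(main) + np.diag(off, 1) + np.diag(off, -1)

    t = relaxation
    for it in range(max_iterations):
        worst = 0.0
        # NP solves with SG fluxes
        for s in species:
            q = s.valence
            delta = q * (u[1:] - u[:-1]) / VT
            Dm = D_mid[s.name]
            w_lo = Dm / dz * _bernoulli(delta)       # multiplies n_j
            w_hi = Dm / dz * _bernoulli(-delta)      # multiplies n_{j+1}
            # flux F_{j+1/2} = w_lo[j] n_j - w_hi[j] n_{j+1}
            A = np.zeros((grid_n - 1, grid_n - 1))
            b = np.zeros(grid_n - 1)
            for j in range(1, grid_n):
                r = j - 1
                A[r, r] = w_lo[j] + w_hi[j - 1]
                if r > 0:
                    A[r, r - 1] = -w_lo[j - 1]
                if r < grid_n - 2:
                    A[r, r + 1] = -w_hi[j]
            b[0] += w_lo[0] * s.bulk_density
            b[-1] += w_hi[-1] * s.bulk_density
            interior = np.linalg.solve(A, b)
            n_new = n[s.name].copy()
            n_new[1:-1] = interior
            n_mix = t * n[s.name] + (1 - t) * n_new
            worst = max(worst, float(np.max(np.abs(n_mix - n[s.name])) / s.bulk_density))
            n[s.name] = np.clip(n_mix, 0.0, None)
        rho = rho_fix.copy()
        screen = np.zeros(grid_n + 1)
        for s in species:
            rho += s.valence * n[s.name]
            screen += s.valence**2 * n[s.name] / VT
        rhs = rho[1:-1] + screen[1:-1] * u[1:-1]
        rhs[0] += eps / dz**2 * voltage  # u(0) = V, u(L) = 0
        u_new = u.copy()
        u_new[1:-1] = np.linalg.solve(A_lap + np.diag(screen[1:-1]), rhs)
        u_new[0], u_new[-1] = voltage, 0.0
        u_mix = t * u + (1 - t) * u_new
        worst = max(worst, float(np.max(np.abs(u_mix - u)) / max(abs(voltage), VT)))
        u = u_mix
        if worst < tolerance:
            break
    else:
        raise RuntimeError("1D oracle did not converge")

    # current density on every interval; report the mean (constant in theory)
    J = np.zeros(grid_n)
    for s in species:
        q = s.valence
        delta = q * (u[1:] - u[:-1]) / VT
        Dm = D_mid[s.name]
        F = Dm / dz * (_bernoulli(delta) * n[s.name][:-1] - _bernoulli(-delta) * n[s.name][1:])
        J += q * F
    return {
        "current_density": float(J.mean()) * E_PER_PS_TO_AMPERE,  # A per A^2
        "current_density_spread": float(J.max() - J.min()) * E_PER_PS_TO_AMPERE,
        "u": u,
        "n": n,
        "z": z,
    }


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def box_mesh(half_w: float, z_min: float, z_max: float, dx: float, dz: float) -> Mesh:
    """Structured all-solvent box mesh (prisms from a 2D Delaunay grid)."""
    k = max(2, int(round(2 * half_w / dx)))
    xs = np.linspace(-half_w, half_w, k + 1)
    X, Y = np.meshgrid(xs, xs)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    # break the grid's cocircular symmetry deterministically (interior only)
    interior = (np.abs(pts[:, 0]) < half_w - 1e-9) & (np.abs(pts[:, 1]) < half_w - 1e-9)
    jitter = 0.05 * dx * np.sin(3.1 * np.arange(len(pts)))
    pts[interior, 0] += jitter[interior]
    tri = Delaunay(pts).simplices
    nz = max(2, int(round((z_max - z_min) / dz)))
    zs = np.linspace(z_min, z_max, nz + 1)
    layers = [np.column_stack([pts, np.full(len(pts), z)]) for z in zs]
    nodes = np.vstack(layers)
    tets = _split_prisms(tri, len(pts), len(zs))
    p = nodes[tets]
    vol = np.einsum(
        "ij,ij->i", p[:, 3] - p[:, 0], np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    )
    tets[vol < 0] = tets[vol < 0][:, [0, 1, 3, 2]]
    region = np.full(len(tets), int(RegionLabel.SOLVENT_BULK), dtype=np.int32)
    mesh = Mesh(
        nodes=nodes,
        tets=tets,
        region=region,
        boundary_facets=np.empty((0, 3), dtype=np.int64),
        facet_tags=np.empty(0, dtype=np.int64),
        metadata={"fixture": "box"},
    )
    mesh.validate()
    return mesh


_FIXTURES = ("slab", "column", "tiny_cylinder_pore", "tiny_cone_pore", "charged_rod_in_pore")


def make_fixture(name: str):
    """Deterministic small instances: (geometry, mesh, params[, molecule]).

    * ``slab`` / ``column`` - pure electrolyte boxes (no membrane) where the
      Ohmic closed form and the 1D oracle apply; insulating side walls.
    * ``tiny_cylinder_pore`` / ``tiny_cone_pore`` - 2 nm pores in a 2 nm
      membrane with reduced box margins.
    * ``charged_rod_in_pore`` - the cylinder fixture threaded by a uniformly
      charged rod (radius 1 nm, -2e per 3.4 A) at 0.1 M KCl, for Boltzmann
      equilibrium tests with a resolved screening layer.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {_FIXTURES}")
    if name == "slab":
        mesh = box_mesh(half_w=20.0, z_min=-20.0, z_max=20.0, dx=5.0, dz=5.0)
        params = PNPParameters(
            species=kcl_species(1.0), voltage=0.1,
            use_pore_diffusion=False, side_potential="insulating",
        )
        return None, mesh, params
    if name == "column":
        mesh = box_mesh(half_w=8.0, z_min=-30.0, z_max=30.0, dx=4.0, dz=3.0)
        params = PNPParameters(
            species=kcl_species(1.0), voltage=0.1,
            use_pore_diffusion=False, side_potential="insulating",
        )
        return None, mesh, params
    opts = MeshOptions(res_pore=3.0, res_bulk=8.0, res_z_fine=3.0, res_z_bulk=8.0)
    if name == "tiny_cylinder_pore":
        g = build_cylinder_pore(20.0, 20.0, 25.0)
        mesh = mesh_geometry(g, options=opts)
        return g, mesh, PNPParameters(species=kcl_species(1.0), voltage=0.1)
    if name == "tiny_cone_pore":
        g = build_conical_pore(20.0, 30.0, 20.0, 25.0)
        mesh = mesh_geometry(g, options=opts)
        return g, mesh, PNPParameters(species=kcl_species(1.0), voltage=0.1)
    # charged_rod_in_pore: the rod pierces the whole box (no end caps), so
    # the continuum equilibrium solution is exactly Boltzmann with u = 0 and
    # n = bulk on the electrode faces.
    g = build_cylinder_pore(30.0, 20.0, 20.0)
    rod = build_charged_rod(radius=10.0, length=58.0)
    opts = MeshOptions(
        res_pore=2.5, res_bulk=6.0, res_z_fine=3.0, res_z_bulk=7.0,
        surface_spacing=0.4,
    )
    mesh = mesh_geometry(g, rod, options=opts)
    params = PNPParameters(species=kcl_species(0.1), voltage=0.0)
    return g, mesh, params, rod


# ---------------------------------------------------------------------------
# oracle suite
# ---------------------------------------------------------------------------


def run_oracle_suite(verbose: bool = False) -> pd.DataFrame:
    """Cross-checks of the 3D solver against its independent oracles."""
    from .observables import plane_current
    from .solver import PNPSystem

    results: List[OracleResult] = []

    # Ohmic slab: closed form sigma V / L
    _, mesh, params = make_fixture("slab")
    sys3d = PNPSystem(mesh, params)
    sol = sys3d.solve()
    area = (2 * 20.0) ** 2
    L = 40.0
    sigma_int = sum(
        s.valence**2 * s.bulk_diffusion * s.bulk_density for s in params.species
    ) / params.thermal_voltage
    I_exact = sigma_int * params.voltage / L * area * E_PER_PS_TO_AMPERE
    I_num = plane_current(sol, 0.0)
    results.append(OracleResult("slab_ohmic_current", I_exact, I_num, 0.02))

    # column vs 1D Scharfetter-Gummel with a varying diffusion profile
    _, mesh, params = make_fixture("column")
    prof = lambda z: {
        s.name: s.bulk_diffusion * (1.0 - 0.5 * np.exp(-((z - 0.0) ** 2) / 100.0))
        for s in params.species
    }
    from .solver import CoefficientField, build_coefficients

    base = build_coefficients(mesh, params)
    zc = mesh.nodes[mesh.tets].mean(axis=1)[:, 2]
    coeff = CoefficientField(
        eps=base.eps,
        diffusion={k: np.where(v > 0, prof(zc)[k], 0.0) for k, v in base.diffusion.items()},
    )
    sys3d = PNPSystem(mesh, params, coefficients=coeff)
    sol = sys3d.solve()
    I3d = plane_current(sol, 1.23)
    ora = pnp_1d_oracle(
        params.species,
        L=60.0,
        grid_n=600,
        voltage=params.voltage,
        temperature=params.temperature,
        diffusion_profile=lambda zm: prof(zm - 30.0),
    )
    I1d = ora["current_density"] * (2 * 8.0) ** 2
    results.append(OracleResult("column_vs_1d_oracle", I1d, I3d, 0.02))

    rows = [
        {
            "quantity": r.quantity,
            "oracle": r.oracle_value,
            "solver": r.solver_value,
            "rel_dev": r.relative_deviation,
            "tolerance": r.tolerance,
            "passed": r.passed,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    if verbose:
        print(df.to_string(index=False))
    return df
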