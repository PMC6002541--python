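"""Parametric nanopore geometries.

A pore is a (possibly conical) channel of circular cross-section drilled
through a dielectric membrane slab that sits in the middle of a rectangular
electrolyte box.  The pore axis is the z axis and the membrane is centred at
z = 0.  The wall radius varies linearly from ``r`` at the bottom face (the
tip) to ``R`` at the top face (the wide opening); ``R == r`` is a cylinder.

All lengths on this API are in angstrom; the YAML config interface speaks
nanometre (the unit the lab bench uses).
"""

from __future__ import annotations

import enum
import io
import math
from dataclasses import dataclass
from typing import Optional, TextIO, Union

import numpy as np
import yaml

from .units import NM


class InvalidGeometryError(ValueError):
    """Raised for non-positive or inconsistent pore dimensions."""


class OutOfDomainError(ValueError):
    """Raised when a query point lies outside the simulation box."""


class RegionLabel(enum.IntEnum):
    """Material classification of a point in the simulation box."""

    SOLVENT_BULK = 0
    SOLVENT_PORE = 1
    MEMBRANE = 2
    MOLECULE = 3


@dataclass(frozen=True)
class PoreGeometry:
    """Membrane slab with a conical/cylindrical pore inside a box.

    Parameters
    ----------
    half_width_x, half_width_y:
        Box half-extents in x and y (angstrom).
    z_min, z_max:
        Box extent in z (angstrom).
    membrane_thickness:
        Slab thickness h (angstrom).
    bottom_radius, top_radius:
        Pore wall radii r (at z = -h/2) and R (at z = +h/2).
    membrane_z_center:
        z coordinate of the slab centre (0 by convention).
    margin:
        Distance from each pore mouth / wall to the box boundary (recorded
        for provenance; the box extents are derived from it).
    """

    half_width_x: float
    half_width_y: float
    z_min: float
    z_max: float
    membrane_thickness: float
    bottom_radius: float
    top_radius: float
    membrane_z_center: float = 0.0
    margin: float = 0.0

    def __post_init__(self) -> None:
        h = self.membrane_thickness
        if h <= 0 or self.bottom_radius <= 0 or self.top_radius <= 0:
            raise InvalidGeometryError(
                "membrane thickness and pore radii must be positive"
            )
        if self.half_width_x <= 0 or self.half_width_y <= 0:
            raise InvalidGeometryError("box half-widths must be positive")
        if not (self.z_min < self.z_bottom and self.z_top < self.z_max):
            raise InvalidGeometryError("membrane slab must lie strictly inside box")

    # -- derived quantities -------------------------------------------------

    @property
    def z_bottom(self) -> float:
        return self.membrane_z_center - 0.5 * self.membrane_thickness

    @property
    def z_top(self) -> float:
        return self.membrane_z_center + 0.5 * self.membrane_thickness

    @property
    def is_cylinder(self) -> bool:
        return math.isclose(self.bottom_radius, self.top_radius, rel_tol=1e-12)

    @property
    def max_radius(self) -> float:
        return max(self.bottom_radius, self.top_radius)

    def wall_radius(self, z: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        """Pore wall radius rho(z), linear in z inside the membrane.

        Outside the slab the value is clamped to the nearest face radius
        (useful for coefficient fields in the buffer region).
        """
        h = self.membrane_thickness
        t = (np.asarray(z) - self.z_bottom) / h
        t = np.clip(t, 0.0, 1.0)
        rho = self.bottom_radius + (self.top_radius - self.bottom_radius) * t
        return float(rho) if np.isscalar(z) else rho

    def pore_frustum_volume(self) -> float:
        """Volume of the pore channel through the slab: pi*h*(R^2+R*r+r^2)/3."""
        r, R, h = self.bottom_radius, self.top_radius, self.membrane_thickness
        return math.pi * h * (R * R + R * r + r * r) / 3.0

    def contains(self, p: np.ndarray) -> bool:
        x, y, z = p
        return (
            abs(x) <= self.half_width_x + 1e-9
            and abs(y) <= self.half_width_y + 1e-9
            and self.z_min - 1e-9 <= z <= self.z_max + 1e-9
        )

    # -- config round trip --------------------------------------------------

    def to_config(self) -> dict:
        """Serializable description; lengths in nm."""
        cfg = {
            "units": "nm",
            "h": self.membrane_thickness / NM,
            "margin": self.margin / NM,
        }
        if self.is_cylinder:
            cfg["d"] = 2.0 * self.bottom_radius / NM
        else:
            cfg["2r"] = 2.0 * self.bottom_radius / NM
            cfg["2R"] = 2.0 * self.top_radius / NM
        return cfg

    @classmethod
    def from_config(cls, cfg: dict) -> "PoreGeometry":
        if cfg.get("units", "nm") != "nm":
            raise InvalidGeometryError(f"unsupported units {cfg.get('units')!r}")
        h, margin = cfg["h"], cfg["margin"]
        if "d" in cfg:
            return build_cylinder_pore(cfg["d"] * NM, h * NM, margin * NM)
        return build_conical_pore(cfg["2r"] * NM, cfg["2R"] * NM, h * NM, margin * NM)

    def save(self, stream: TextIO) -> None:
        yaml.safe_dump(self.to_config(), stream)

    @classmethod
    def load(cls, stream: Union[TextIO, str]) -> "PoreGeometry":
        if isinstance(stream, str):
            stream = io.StringIO(stream)
        return cls.from_config(yaml.safe_load(stream))


def build_conical_pore(
    two_r: float, two_R: float, h: float, box_margin: float = 6.0 * NM
) -> PoreGeometry:
    """Conical pore: bottom (tip) diameter ``two_r``, top diameter ``two_R``.

    The box extends ``box_margin`` beyond the pore mouth on every side, so the
    box scales with the membrane thickness and with the widest mouth; the
    pore-mouth-to-boundary distance stays fixed across sweeps.
    """
    if two_r <= 0 or two_R <= 0 or h <= 0 or box_margin <= 0:
        raise InvalidGeometryError("all pore dimensions must be positive")
    r, R = 0.5 * two_r, 0.5 * two_R
    half_w = max(r, R) + box_margin
    z_half = 0.5 * h + box_margin
    return PoreGeometry(
        half_width_x=half_w,
        half_width_y=half_w,
        z_min=-z_half,
        z_max=z_half,
        membrane_thickness=h,
        bottom_radius=r,
        top_radius=R,
        membrane_z_center=0.0,
        margin=box_margin,
    )


def build_cylinder_pore(
    d: float, h: float, box_margin: float = 6.0 * NM
) -> PoreGeometry:
    """Cylindrical pore of diameter ``d`` through a slab of thickness ``h``."""
    return build_conical_pore(d, d, h, box_margin)


def classify_point(
    geometry: PoreGeometry,
    molecule: Optional["Molecule"],  # noqa: F821 - molecule_model import cycle
    p: np.ndarray,
    probe_radius: float = 0.0,
) -> RegionLabel:
    """Classify a point as membrane, molecule, or solvent (pore vs bulk).

    The classification is a partition: membrane wins outside the wall radius
    inside the slab; the molecule test is against its union of atom spheres
    (optionally inflated by ``probe_radius``); everything else is solvent,
    split into pore (membrane z-span) and bulk.
    """
    p = np.asarray(p, dtype=float)
    if not geometry.contains(p):
        raise OutOfDomainError(f"point {p} lies outside the simulation box")
    x, y, z = p
    in_slab = geometry.z_bottom <= z <= geometry.z_top
    radial = math.hypot(x, y)
    if in_slab and radial > geometry.wall_radius(z):
        return RegionLabel.MEMBRANE
    if molecule is not None and molecule.contains(p, probe_radius=probe_radius):
        return RegionLabel.MOLECULE
    return RegionLabel.SOLVENT_PORE if in_slab else RegionLabel.SOLVENT_BULK
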