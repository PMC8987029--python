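"""Solvent-accessible surface area (Shrake–Rupley).

Each heavy atom is expanded by the probe radius and sampled with a
Fibonacci-lattice point set; a sample point is accessible when it lies outside
every other atom's expanded sphere.  Per-atom accessible area is
``4*pi*(r+probe)^2 * n_accessible/n_points``; residue SASA is the sum over the
residue's atoms.  Relative SASA normalizes by a Gly-X-Gly tripeptide maximum
(Tien et al. theoretical scale), so "solvent exposed" can be thresholded as a
fraction independent of residue size.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree

from .structures import ConformationalState

__all__ = [
    "VDW_RADII",
    "MAX_SASA_GXG",
    "fibonacci_sphere",
    "shrake_rupley_atoms",
    "shrake_rupley_sasa",
    "relative_sasa",
]

# van der Waals radii (A), Bondi-style set for common protein elements
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

# Maximum SASA (A^2) of residue X in an extended Gly-X-Gly tripeptide,
# theoretical values (Tien et al. 2013)
MAX_SASA_GXG: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Near-uniform unit vectors on the sphere (golden-angle spiral)."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    i = np.arange(n_points)
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = i * _GOLDEN_ANGLE
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _radii_for(elements: list[str]) -> np.ndarray:
    radii = np.empty(len(elements))
    for k, elem in enumerate(elements):
        key = elem.upper()
        if key not in VDW_RADII:
            raise ValueError(
                f"unknown element {elem!r} for atom index {k}: no van der Waals radius"
            )
        radii[k] = VDW_RADII[key]
    return radii


def shrake_rupley_atoms(
    coords: np.ndarray,
    elements: list[str],
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom accessible surface area (Å²) for an arbitrary atom set."""
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a usable surface estimate")
    if probe_radius < 0:
        raise ValueError("probe_radius must be non-negative")
    coords = np.asarray(coords, float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be an (n, 3) array")
    radii = _radii_for(elements) + probe_radius
    n = len(radii)
    sphere = fibonacci_sphere(n_points)
    areas = np.empty(n)
    tree = cKDTree(coords)
    rmax = radii.max()
    for i in range(n):
        pts = coords[i] + radii[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax) if j != i]
        if neighbors:
            nb = np.asarray(neighbors, int)
            close = np.linalg.norm(coords[nb] - coords[i], axis=1) < radii[i] + radii[nb]
            nb = nb[close]
        else:
            nb = np.empty(0, int)
        if nb.size:
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (radii[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * math.pi * radii[i] ** 2 * frac
    return areas


def shrake_rupley_sasa(
    state: ConformationalState,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-residue absolute SASA (Å²) for a state carrying its heavy-atom set."""
    if state.atom_coords is None or state.atom_elements is None:
        raise ValueError(
            f"state {state.label!r} carries no atom set; SASA needs full heavy atoms"
        )
    atom_areas = shrake_rupley_atoms(
        state.atom_coords, state.atom_elements, probe_radius, n_points
    )
    out = np.zeros(len(state.sites))
    np.add.at(out, state.atom_site_index, atom_areas)
    return out


def relative_sasa(abs_sasa: float, residue_name: str) -> float:
    """Fractional exposure: absolute SASA over the Gly-X-Gly maximum.

    Values above 1 are possible for distorted geometry and are reported as-is.
    """
    key = residue_name.upper()
    if key not in MAX_SASA_GXG:
        raise ValueError(f"no maximum-SASA reference for residue {residue_name!r}")
    if abs_sasa < 0:
        raise ValueError("absolute SASA must be non-negative")
    return float(abs_sasa) / MAX_SASA_GXG[key]
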