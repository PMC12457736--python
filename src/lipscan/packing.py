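"""Voronoi atomic volumes and the packing-density ratio ρ.

ρ = Σ V°ᵢ / Σ Vᵢ over the atoms of an interface, where V° is the standard
(reference) Voronoi volume of the atom type and V its actual Voronoi cell
volume in the structure.  ρ ≈ 1 for well-packed protein cores; lower values
mean looser packing.  The tessellation is the plain bisector-plane Voronoi
diagram of atom centres (unweighted); cells touching the unbounded region are
flagged and excluded pairwise from both sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError, Voronoi

from .config import StandardVolumeTable, load_standard_volumes
from .structure import Structure

__all__ = ["VoronoiCell", "voronoi_cells", "voronoi_cells_of_coords",
           "packing_density", "standard_volume"]


@dataclass
class VoronoiCell:
    atom_index: int
    volume: float | None   # Å³, None when the cell is unbounded
    bounded: bool


def voronoi_cells_of_coords(coords: np.ndarray) -> list[VoronoiCell]:
    """Voronoi cell volume per point; unbounded (surface) cells get volume None."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 5:
        raise ValueError("need at least 5 points for a 3-D Voronoi tessellation")
    try:
        vor = Voronoi(coords)
    except QhullError as exc:
        raise ValueError(f"degenerate point geometry for Voronoi tessellation: {exc}") from exc

    cells = []
    for i in range(len(coords)):
        region = vor.regions[vor.point_region[i]]
        if not region or -1 in region:
            cells.append(VoronoiCell(atom_index=i, volume=None, bounded=False))
            continue
        vertices = vor.vertices[region]
        try:
            volume = float(ConvexHull(vertices).volume)
        except QhullError:
            cells.append(VoronoiCell(atom_index=i, volume=None, bounded=False))
            continue
        cells.append(VoronoiCell(atom_index=i, volume=volume, bounded=True))
    return cells


def voronoi_cells(structure: Structure) -> dict[int, VoronoiCell]:
    """Cells keyed by atom index in ``structure.atoms()`` order."""
    cells = voronoi_cells_of_coords(structure.coords())
    return {c.atom_index: c for c in cells}


def standard_volume(resname: str, atomname: str, element: str,
                    table: StandardVolumeTable | None = None) -> float:
    table = table or load_standard_volumes()
    vol = table.lookup(resname, atomname, element)
    if vol is None:
        raise KeyError(f"no standard volume for atom {atomname!r} of {resname!r} "
                       f"(element {element!r})")
    if (resname.upper(), atomname.upper()) not in table.by_res_atom:
        warnings.warn(f"standard volume for {resname} {atomname}: "
                      f"element-level fallback used")
    return vol


def packing_density(interface_atoms: list[int] | set[int],
                    cells: dict[int, VoronoiCell],
                    standard_volumes: list[float] | dict[int, float],
                    ) -> float | None:
    """ρ = Σ V° / Σ V over interface atoms with bounded Voronoi cells.

    ``standard_volumes`` maps the same atom indices to V°.  Atoms with
    unbounded cells are dropped from both sums (pairwise exclusion); if no
    atom has a bounded cell, returns None (undefined).
    """
    atoms = sorted(set(interface_atoms))
    if not atoms:
        raise ValueError("interface_atoms must be non-empty")
    if not isinstance(standard_volumes, dict):
        standard_volumes = dict(zip(atoms, standard_volumes))
    num = 0.0
    den = 0.0
    any_bounded = False
    for i in atoms:
        cell = cells[i]
        if not cell.bounded:
            continue
        if i not in standard_volumes:
            raise KeyError(f"no standard volume supplied for atom index {i}")
        any_bounded = True
        num += standard_volumes[i]
        den += cell.volume
    if not any_bounded:
        return None
    return num / den
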