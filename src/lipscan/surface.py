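"""Shrake–Rupley solvent-accessible surface area with a deterministic point set.

Each atom's accessible area is estimated by distributing test points on a
sphere of radius r_vdw + r_probe (probe 1.4 Å by default) and counting the
points not occluded by any neighbouring atom's expanded sphere.  The point set
is a golden-spiral (Fibonacci) lattice, so results are reproducible without a
random seed; 960 points give per-atom areas converged to a few tenths of Å².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .config import MaxSasaTable, load_max_sasa
from .structure import Residue, ResidueKey, Structure

__all__ = [
    "SasaResult",
    "DeltaSasaRecord",
    "ExposureClass",
    "fibonacci_sphere",
    "canonical_frame",
    "apply_frame",
    "atom_sasa",
    "sasa_of_coords",
    "delta_sasa",
    "relative_exposure",
    "classify_exposure",
]

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960

# Relative-exposure class boundaries: buried < 0.10 <= intermediate <= 0.40 < exposed
BURIED_MAX = 0.10
INTERMEDIATE_MAX = 0.40


@dataclass
class SasaResult:
    per_atom: dict[int, float]          # atom index within the structure → Å²
    per_residue: dict[ResidueKey, float]
    probe_radius: float
    n_points: int
    per_atom_list: list[float] = field(default_factory=list, repr=False)


@dataclass
class DeltaSasaRecord:
    residue_key: ResidueKey
    sasa_full: float
    sasa_cropped: float

    @property
    def delta(self) -> float:
        """Exposure gained on cropping: SASA(cropped) − SASA(full), Å²."""
        return self.sasa_cropped - self.sasa_full


@dataclass
class ExposureClass:
    residue_key: ResidueKey
    rel_exposure: float | None   # None for residues without a defined maximum
    label: str | None            # buried / intermediate / exposed / None


def canonical_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic principal-axes frame (rotation, centroid) of a point set.

    Transforming coordinates as ``(coords - centroid) @ rotation`` makes the
    quadrature orientation-independent: rigid copies of the same atom set
    (e.g. the two subunits of a symmetric homodimer) yield the same areas.
    Axis signs are fixed by the largest-magnitude projection; the frame is
    right-handed.
    """
    coords = np.asarray(coords, dtype=float)
    centroid = coords.mean(axis=0)
    x = coords - centroid
    _w, v = np.linalg.eigh(x.T @ x)
    v = v[:, ::-1]  # principal axis first
    for k in range(3):
        proj = x @ v[:, k]
        if proj[np.argmax(np.abs(proj))] < 0:
            v[:, k] = -v[:, k]
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return v, centroid


def apply_frame(coords: np.ndarray, frame: tuple[np.ndarray, np.ndarray] | None,
                ) -> np.ndarray:
    if frame is None:
        return coords
    rotation, centroid = frame
    return (coords - centroid) @ rotation


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    sin_phi = np.sin(phi)
    return np.column_stack((np.cos(theta) * sin_phi,
                            np.sin(theta) * sin_phi,
                            np.cos(phi)))


def sasa_of_coords(coords: np.ndarray, radii: np.ndarray, *,
                   probe: float = DEFAULT_PROBE,
                   n_points: int = DEFAULT_N_POINTS,
                   frame: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """Per-atom SASA (Å²) for raw coordinates and van der Waals radii.

    ``frame`` (from :func:`canonical_frame`) reorients the coordinates before
    quadrature; pass the same frame to related runs (e.g. a structure and its
    cropped version) so their per-atom areas stay strictly comparable.
    """
    coords = apply_frame(np.asarray(coords, dtype=float), frame)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) == 0:
        raise ValueError("coords must be a non-empty (n, 3) array")
    if n_points < 32:
        raise ValueError("n_points must be >= 32")
    if np.any(radii <= 0) or not np.all(np.isfinite(coords)):
        raise ValueError("radii must be positive and coordinates finite")

    expanded = radii + probe
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        r_i = expanded[i]
        neighbours = tree.query_ball_point(coords[i], r_i + expanded.max())
        neighbours = [j for j in neighbours
                      if j != i and
                      np.dot(coords[j] - coords[i], coords[j] - coords[i])
                      < (r_i + expanded[j]) ** 2]
        if not neighbours:
            areas[i] = 4.0 * np.pi * r_i ** 2
            continue
        pts = coords[i] + r_i * sphere          # (n_points, 3)
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 >= expanded[j] ** 2
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * r_i ** 2 * accessible.sum() / n_points
    return areas


def atom_sasa(structure: Structure, probe: float = DEFAULT_PROBE,
              n_points: int = DEFAULT_N_POINTS,
              frame: tuple[np.ndarray, np.ndarray] | None = None) -> SasaResult:
    """SASA of every protein atom in the structure (waters/ligands excluded)."""
    atoms = structure.atoms()
    if not atoms:
        raise ValueError("structure has no atoms")
    coords = np.array([a.coords for a in atoms])
    radii = np.array([a.radius for a in atoms], dtype=float)
    areas = sasa_of_coords(coords, radii, probe=probe, n_points=n_points,
                           frame=frame)

    per_atom = {i: float(areas[i]) for i in range(len(atoms))}
    per_residue: dict[ResidueKey, float] = {}
    i = 0
    for res in structure.residues():
        per_residue[res.key] = float(areas[i:i + len(res.atoms)].sum())
        i += len(res.atoms)
    return SasaResult(per_atom=per_atom, per_residue=per_residue,
                      probe_radius=probe, n_points=n_points,
                      per_atom_list=list(map(float, areas)))


def delta_sasa(full: SasaResult, cropped: SasaResult) -> list[DeltaSasaRecord]:
    """Per-residue exposure gained when a span is cropped out.

    One record per residue of the *cropped* structure; the cropped span itself
    has no record.  Raises if the cropped result covers residues absent from
    the full one.
    """
    records = []
    for key, area_cropped in cropped.per_residue.items():
        if key not in full.per_residue:
            raise KeyError(f"residue {key} in cropped result but not in full result")
        records.append(DeltaSasaRecord(residue_key=key,
                                       sasa_full=full.per_residue[key],
                                       sasa_cropped=area_cropped))
    return records


def relative_exposure(residue: Residue, sasa: float,
                      table: MaxSasaTable | None = None) -> float | None:
    """SASA divided by the residue type's theoretical maximum.

    Returns None for residues without a defined maximum (non-canonical);
    values > 1 are possible for distorted geometry and are not clamped.
    """
    table = table or load_max_sasa()
    if not residue.is_canonical:
        return None
    max_area = table.lookup(residue.name)
    if max_area is None:
        return None
    return float(sasa) / max_area


def classify_exposure(rel: float | None) -> str | None:
    """buried (<10%), intermediate (10–40%, inclusive), exposed (>40%)."""
    if rel is None:
        return None
    if rel < BURIED_MAX:
        return "buried"
    if rel <= INTERMEDIATE_MAX:
        return "intermediate"
    return "exposed"


def exposure_classes(structure: Structure, sasa: SasaResult,
                     table: MaxSasaTable | None = None) -> dict[ResidueKey, ExposureClass]:
    out = {}
    for res in structure.residues():
        rel = relative_exposure(res, sasa.per_residue[res.key], table)
        out[res.key] = ExposureClass(residue_key=res.key, rel_exposure=rel,
                                     label=classify_exposure(rel))
    return out
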