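"""Deterministic synthetic protein structures for testing and demos.

Structures are built from ideal internal coordinates (standard bond lengths
and angles, fixed φ/ψ per secondary-structure mode) with side chains placed up
to the γ position — enough to give each residue type its polar or apolar
character at a contact face.  Asn and Asp additionally get their δ oxygens /
nitrogen, since without them a carboxamide or carboxylate side chain would
present no polar surface at all.  Construction is pure arithmetic: identical
specs give bit-identical coordinates, no seeds involved.

Geometries:

* ``ideal-helix`` — a single α-helix (φ=−57°, ψ=−47°), axis on z.
* ``extended`` — a single β-strand-like extended chain (φ=−139°, ψ=135°).
* ``two-helix-bundle`` — one chain carrying two antiparallel helices side by
  side at a chosen axis separation, with a numbering jump and a structural
  (unbonded) gap between them.
* ``symmetric-dimer`` — chain A plus an exact C2 copy as chain B.

Selected ``face_positions`` can be rotated to point their side chains at the
partner helix/chain, which is how polar or apolar contact faces are designed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import cos, radians, sin, sqrt

import numpy as np

from .structure import Structure, read_pdb, write_pdb

__all__ = ["FixtureSpec", "make_structure", "make_pdb_text",
           "polar_bundle_spec", "leucine_bundle_spec"]

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

# side-chain atoms beyond CB: (name, bond to CB, placement rule)
#   gamma: (name, bond_length, chi1_offset_deg)
GAMMA = {
    "ARG": [("CG", 1.52, 0.0)],
    "ASN": [("CG", 1.52, 0.0)],
    "ASP": [("CG", 1.52, 0.0)],
    "CYS": [("SG", 1.81, 0.0)],
    "GLN": [("CG", 1.52, 0.0)],
    "GLU": [("CG", 1.52, 0.0)],
    "HIS": [("CG", 1.50, 0.0)],
    "ILE": [("CG1", 1.53, 0.0), ("CG2", 1.53, 120.0)],
    "LEU": [("CG", 1.53, 0.0)],
    "LYS": [("CG", 1.52, 0.0)],
    "MET": [("CG", 1.52, 0.0)],
    "PHE": [("CG", 1.50, 0.0)],
    "PRO": [("CG", 1.49, 25.0)],
    "SER": [("OG", 1.42, 0.0)],
    "THR": [("OG1", 1.43, 0.0), ("CG2", 1.53, 120.0)],
    "TRP": [("CG", 1.50, 0.0)],
    "TYR": [("CG", 1.51, 0.0)],
    "VAL": [("CG1", 1.53, 0.0), ("CG2", 1.53, 120.0)],
}

# δ atoms for the carboxamide/carboxylate side chains (sp2 about CG)
DELTA = {
    "ASN": [("OD1", 1.23, -30.0), ("ND2", 1.33, 150.0)],
    "ASP": [("OD1", 1.25, -30.0), ("OD2", 1.25, 150.0)],
}

CHI1_DEFAULT = -65.0

PHI_PSI = {
    "helix": (-57.0, -47.0),
    "extended": (-139.0, 135.0),
}


@dataclass
class FixtureSpec:
    """Recipe for a deterministic synthetic structure."""

    sequences: list[str]
    geometry: str = "ideal-helix"          # ideal-helix | extended | two-helix-bundle | symmetric-dimer
    contact_distance: float = 10.0         # helix-axis / chain separation, Å
    face_positions: list[list[int]] = field(default_factory=list)
    # 0-based residue indices per helix whose CB should face the partner
    chain_ids: list[str] = field(default_factory=lambda: ["A", "B"])
    numbering_start: int = 1
    numbering_jump: int = 5                # extra numbering offset at the inter-helix gap
    site_records: list[tuple[str, list[int]]] = field(default_factory=list)
    # (site_id, 0-based indices into the concatenated residue list of chain A)
    antiparallel: bool = True
    axial_offset: float = 0.0              # z-shift of the second helix/chain


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd|=bond, ∠(b,c,d)=angle, χ(a,b,c,d)=torsion."""
    ang, tor = radians(angle_deg), radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * cos(ang),
                        bond * sin(ang) * cos(tor),
                        bond * sin(ang) * sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _build_segment(sequence: str, phi: float, psi: float) -> list[list[tuple[str, np.ndarray]]]:
    """Backbone + stub side chains for one continuous segment; returns per-residue atom lists."""
    residues: list[list[tuple[str, np.ndarray]]] = []
    # seed atoms of residue 0
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    c = ca + 1.525 * np.array([cos(radians(180 - 111.2)), sin(radians(180 - 111.2)), 0.0])
    prev = None
    for i, letter in enumerate(sequence):
        resname = AA3[letter]
        if i > 0:
            n = _place_atom(prev["N"], prev["CA"], prev["C"], 1.329, 116.2, psi)
            ca = _place_atom(prev["CA"], prev["C"], n, 1.458, 121.7, 180.0)
            c = _place_atom(prev["C"], n, ca, 1.525, 111.2, phi)
        o = _place_atom(n, ca, c, 1.231, 120.8, psi + 180.0)
        atoms = [("N", n), ("CA", ca), ("C", c), ("O", o)]
        if resname != "GLY":
            cb = _place_atom(n, c, ca, 1.53, 110.5, 122.6)
            atoms.append(("CB", cb))
            for (gname, gbond, chi_off) in GAMMA.get(resname, []):
                g = _place_atom(n, ca, cb, gbond, 114.0, CHI1_DEFAULT + chi_off)
                atoms.append((gname, g))
            if resname in DELTA:
                cg = dict(atoms)["CG"]
                for (dname, dbond, chi2) in DELTA[resname]:
                    d = _place_atom(ca, cb, cg, dbond, 120.5, chi2)
                    atoms.append((dname, d))
        residues.append([(name, pos.copy()) for name, pos in atoms])
        prev = {"N": n, "CA": ca, "C": c}
    return residues


def _segment_coords(residues) -> np.ndarray:
    return np.array([pos for res in residues for (_n, pos) in res])


def _transform(residues, rotation: np.ndarray, translation: np.ndarray):
    return [[(name, rotation @ pos + translation) for name, pos in res]
            for res in residues]


def _align_axis_to_z(residues):
    """Centre on the CA centroid and rotate the principal CA axis onto +z."""
    cas = np.array([dict(res)["CA"] for res in residues])
    centroid = cas.mean(axis=0)
    _u, _s, vt = np.linalg.svd(cas - centroid)
    axis = vt[0]
    if np.dot(axis, cas[-1] - cas[0]) < 0:
        axis = -axis
    rot = _rotation_between(axis, np.array([0.0, 0.0, 1.0]))
    return _transform(residues, rot, -rot @ centroid)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    c = float(np.dot(a, b))
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)


def _rot_z(deg: float) -> np.ndarray:
    t = radians(deg)
    return np.array([[cos(t), -sin(t), 0.0], [sin(t), cos(t), 0.0], [0.0, 0.0, 1.0]])


def _face_angle(residues, positions) -> float:
    """Mean xy-direction (degrees) of CB−CA at the given residue indices."""
    vx = vy = 0.0
    for i in positions:
        res = dict(residues[i])
        cb = res.get("CB")
        if cb is None:
            continue
        d = cb - res["CA"]
        norm = sqrt(d[0] ** 2 + d[1] ** 2)
        if norm > 1e-9:
            vx += d[0] / norm
            vy += d[1] / norm
    return float(np.degrees(np.arctan2(vy, vx)))


def _orient_face(residues, positions, target_deg: float):
    """Rotate about z so the mean CB face of ``positions`` points at target_deg."""
    if not positions:
        return residues
    current = _face_angle(residues, positions)
    return _transform(residues, _rot_z(target_deg - current), np.zeros(3))


def make_pdb_text(spec: FixtureSpec) -> str:
    """Build the structure described by ``spec`` and return it as PDB text."""
    for seq in spec.sequences:
        if not seq:
            raise ValueError("empty sequence in fixture spec")
        bad = sorted(set(seq) - set(AA3))
        if bad:
            raise ValueError(f"non-canonical sequence letters: {bad}")

    if spec.geometry in ("ideal-helix", "extended"):
        mode = "helix" if spec.geometry == "ideal-helix" else "extended"
        phi, psi = PHI_PSI[mode]
        residues = _align_axis_to_z(_build_segment(spec.sequences[0], phi, psi))
        chains = {spec.chain_ids[0]: [(spec.sequences[0], residues, spec.numbering_start)]}
    elif spec.geometry == "two-helix-bundle":
        if len(spec.sequences) != 2:
            raise ValueError("two-helix-bundle needs exactly 2 sequences")
        chains = {spec.chain_ids[0]: _bundle_segments(spec)}
    elif spec.geometry == "symmetric-dimer":
        half = _bundle_segments(spec) if len(spec.sequences) == 2 else [
            (spec.sequences[0],
             _align_axis_to_z(_build_segment(spec.sequences[0], *PHI_PSI["helix"])),
             spec.numbering_start)]
        # C2 copy: rotate 180° about z, push apart along x
        shift = np.array([spec.contact_distance, 0.0, spec.axial_offset])
        a_segments = [(seq, _transform(res, np.eye(3), -shift / 2), start)
                      for seq, res, start in half]
        b_segments = [(seq, _transform(res, _rot_z(180.0), shift / 2), start)
                      for seq, res, start in half]
        chains = {spec.chain_ids[0]: a_segments, spec.chain_ids[1]: b_segments}
    else:
        raise ValueError(f"unknown geometry {spec.geometry!r}")

    return _to_pdb(chains, spec)


def _bundle_segments(spec: FixtureSpec):
    phi, psi = PHI_PSI["helix"]
    seq1, seq2 = spec.sequences
    h1 = _align_axis_to_z(_build_segment(seq1, phi, psi))
    h2 = _align_axis_to_z(_build_segment(seq2, phi, psi))
    if spec.antiparallel:
        h2 = _transform(h2, np.diag([1.0, -1.0, -1.0]), np.zeros(3))  # flip about x
    face1 = spec.face_positions[0] if spec.face_positions else []
    face2 = spec.face_positions[1] if len(spec.face_positions) > 1 else []
    h1 = _orient_face(h1, face1, 0.0)       # face +x
    h2 = _orient_face(h2, face2, 180.0)     # face −x
    h2 = _transform(h2, np.eye(3),
                    np.array([spec.contact_distance, 0.0, spec.axial_offset]))
    start1 = spec.numbering_start
    start2 = start1 + len(seq1) + spec.numbering_jump
    return [(seq1, h1, start1), (seq2, h2, start2)]


def _to_pdb(chains: dict, spec: FixtureSpec) -> str:
    lines = []
    serial = 0
    chain_a_keys: list[tuple[str, int, str]] = []
    for chain_id, segments in chains.items():
        last = None
        for seq, residues, start in segments:
            for i, (letter, atoms) in enumerate(zip(seq, residues)):
                resname = AA3[letter]
                num = start + i
                last = (resname, num)
                if chain_id == list(chains)[0]:
                    chain_a_keys.append((resname, num, chain_id))
                for name, pos in atoms:
                    serial += 1
                    pdb_name = name if len(name) >= 4 else f" {name}"
                    lines.append(
                        f"ATOM  {serial:5d} {pdb_name:<4s} {resname:>3s} {chain_id}"
                        f"{num:4d}    {pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
                        f"  1.00  0.00          {name[0]:>2s}"
                    )
        serial += 1
        lines.append(f"TER   {serial:5d}      {last[0]:>3s} {chain_id}{last[1]:4d}")

    site_lines = []
    for site_id, indices in spec.site_records:
        members = [chain_a_keys[i] for i in indices]
        for rec_no, s in enumerate(range(0, len(members), 4), start=1):
            chunk = members[s:s + 4]
            line = f"SITE   {rec_no:3d} {site_id:>3s} {len(members):2d} "
            for resname, num, cid in chunk:
                line += f"{resname:>3s} {cid}{num:4d}  "
            site_lines.append(line.rstrip())
    return "\n".join(site_lines + lines) + "\nEND\n"


def _heptad_face(length: int) -> list[int]:
    # a/d-like positions of a coiled-coil heptad, kept off the termini
    return [i for i in range(1, length - 1) if i % 7 in (1, 4)]


def polar_bundle_spec(length: int = 18, distance: float = 10.5,
                      **kwargs) -> FixtureSpec:
    """Loosely packed two-helix bundle with a serine/asparagine contact face.

    The canonical positive control: its polar, under-packed inter-helix
    interface carries at least one intra-chain mLIP under default thresholds.
    """
    face = _heptad_face(length)
    seq = list("A" * length)
    for j, i in enumerate(face):
        seq[i] = "SN"[j % 2]
    return FixtureSpec(sequences=["".join(seq)] * 2, geometry="two-helix-bundle",
                       contact_distance=distance,
                       face_positions=[face, face], **kwargs)


def leucine_bundle_spec(length: int = 18, distance: float = 9.5,
                        **kwargs) -> FixtureSpec:
    """Tightly packed all-leucine two-helix bundle: the negative control.

    Its interface is apolar (PR well under the 0.8 peak cut-off), so no mLIP
    is detected.
    """
    face = _heptad_face(length)
    return FixtureSpec(sequences=["L" * length] * 2, geometry="two-helix-bundle",
                       contact_distance=distance,
                       face_positions=[face, face], **kwargs)


def make_structure(spec: FixtureSpec) -> tuple[Structure, str]:
    """Build the fixture and return (parsed Structure, PDB text).

    The structure is produced by round-tripping the generated PDB text through
    the package's own reader, so fixtures exercise the same code path as user
    input.
    """
    text = make_pdb_text(spec)
    return read_pdb(text), text
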