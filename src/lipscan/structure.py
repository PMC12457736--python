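"""Typed protein structure model on top of gemmi's PDB reader.

The model keeps only what the interface analysis needs: heavy protein atoms
with polarity class and van der Waals radius, residues under author numbering
(gaps preserved), chains in file order, and SITE annotations.  Waters and
hydrogens are dropped on read; other HETATM groups are kept aside for SITE
bookkeeping but excluded from all surface/volume computation.  Alternate
locations are resolved to the highest-occupancy conformer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .config import PolarityTable, RadiusTable, load_polarity, load_radii

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "SiteAnnotation",
    "ResidueKey",
    "read_pdb",
    "atom_polarity",
    "crop",
    "merge",
    "parse_site_records",
    "write_pdb",
]

ResidueKey = tuple[str, int, str]  # (chain_id, author seq_num, icode)

CANONICAL_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# Modified residues mapped to their canonical parent (flagged non-canonical).
MODIFIED_PARENT = {"MSE": "MET", "SEC": "CYS", "MLY": "LYS", "SEP": "SER",
                   "TPO": "THR", "PTR": "TYR", "CSO": "CYS", "HYP": "PRO"}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

# Peptide-bond C–N distance above which two consecutive residues are treated
# as a structural break (unsolved stretch between them).
PEPTIDE_BOND_CUTOFF = 2.5


class PDBParseError(ValueError):
    pass


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    polarity: str | None
    coords: np.ndarray
    radius: float | None
    occupancy: float = 1.0
    altloc: str = ""


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    name: str
    atoms: list[Atom]
    is_canonical: bool = True
    file_pos: int = 0  # position within chain at parse time; stable merge order

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_num, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SiteAnnotation:
    site_id: str
    # (chain_id, seq_num, icode, resname, is_protein)
    members: list[tuple[str, int, str, str, bool]] = field(default_factory=list)


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    het_residues: list[Residue] = field(default_factory=list)
    site_annotations: list[SiteAnnotation] = field(default_factory=list)
    provenance: str = ""

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def residues(self) -> list[Residue]:
        return [r for c in self.chains for r in c.residues]

    def residue(self, key: ResidueKey) -> Residue:
        for r in self.chain(key[0]).residues:
            if r.key == key:
                return r
        raise KeyError(f"no residue {key} in structure")

    def atoms(self) -> list[Atom]:
        return [a for r in self.residues() for a in r.atoms]

    def residue_keys(self) -> list[ResidueKey]:
        return [r.key for r in self.residues()]

    def sequence_map(self) -> dict[str, list[dict]]:
        """Per-chain consecutive-residue transitions with numbering/structural gaps.

        A *numbering gap* is a jump in author numbering; a *structural gap* is a
        broken peptide bond (C–N distance > 2.5 Å or missing atoms).  Numbering
        jumps without a broken bond are renumbering artifacts and do not split
        profile windows; they are still reported here.
        """
        out: dict[str, list[dict]] = {}
        for chain in self.chains:
            entries = []
            for prev, cur in zip(chain.residues, chain.residues[1:]):
                numbering_gap = cur.seq_num != prev.seq_num + 1 and not (
                    cur.seq_num == prev.seq_num and cur.icode > prev.icode
                )
                entries.append({
                    "from": prev.key, "to": cur.key,
                    "numbering_gap": numbering_gap,
                    "structural_gap": not _bonded(prev, cur),
                })
            out[chain.chain_id] = entries
        return out

    def segments(self, chain_id: str) -> list[list[Residue]]:
        """Maximal runs of consecutively solved (peptide-bonded) residues."""
        segs: list[list[Residue]] = []
        for res in self.chain(chain_id).residues:
            if segs and _bonded(segs[-1][-1], res):
                segs[-1].append(res)
            else:
                segs.append([res])
        return segs

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms()], dtype=float)


def _bonded(prev: Residue, cur: Residue) -> bool:
    c = prev.atom("C")
    n = cur.atom("N")
    if c is None or n is None:
        return False
    return float(np.linalg.norm(c.coords - n.coords)) <= PEPTIDE_BOND_CUTOFF


def atom_polarity(element: str, table: PolarityTable | None = None,
                  atom_name: str = "?") -> str:
    """Classify an atom as polar or apolar from its element (N,O → polar; C,S → apolar)."""
    table = table or load_polarity()
    pol = table.lookup(element)
    if pol is None:
        raise ValueError(f"cannot classify polarity of atom {atom_name!r} (element {element!r})")
    return pol


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    by_name: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for at in residue:
        if at.name not in by_name:
            by_name[at.name] = at
            order.append(at.name)
        else:
            cur = by_name[at.name]
            # highest occupancy wins; ties broken by altloc letter order
            if (at.occ, -ord(at.altloc or "~")) > (cur.occ, -ord(cur.altloc or "~")):
                by_name[at.name] = at
    return [by_name[n] for n in order]


def read_pdb(source: str | Path, *, on_unknown_element: str = "error",
             radii: RadiusTable | None = None,
             polarity: PolarityTable | None = None) -> Structure:
    """Read a PDB file (path or raw text) into a :class:`Structure`.

    Model 1 only; hydrogens and waters discarded; altlocs resolved to the
    highest-occupancy copy; every retained protein atom gets a radius and a
    polarity class.  ``on_unknown_element`` is ``"error"`` or ``"skip"``.
    """
    if on_unknown_element not in ("error", "skip"):
        raise ValueError("on_unknown_element must be 'error' or 'skip'")
    radii = radii or load_radii()
    polarity = polarity or load_polarity()

    text, provenance = _source_text(source)
    if not any(line.startswith("ATOM") for line in text.splitlines()):
        raise PDBParseError(f"{provenance or 'input'}: no ATOM records")

    st = gemmi.read_pdb_string(text)
    st.setup_entities()
    model = st[0]  # single-model policy: first model only

    structure = Structure(provenance=provenance)
    chain_index: dict[str, Chain] = {}
    for gchain in model:
        for pos, gres in enumerate(gchain):
            name = gres.name.strip().upper()
            if name in WATER_NAMES:
                continue
            parent = MODIFIED_PARENT.get(name)
            is_protein = name in CANONICAL_AA or parent is not None
            atoms: list[Atom] = []
            for gat in _resolve_altlocs(gres):
                elem = gat.element.name.upper()
                if elem in ("H", "D"):
                    continue
                atom_name = gat.name
                if parent == "MET" and atom_name == "SE":
                    atom_name, elem = "SD", "S"  # selenomethionine → Met
                resname = parent or name
                rad = radii.lookup(resname, atom_name, elem)
                pol = polarity.lookup(elem)
                if is_protein and (rad is None or pol is None):
                    msg = (f"atom {atom_name!r} (element {elem!r}) in residue "
                           f"{name} {gchain.name}{gres.seqid.num}: no radius/polarity")
                    if on_unknown_element == "error":
                        raise PDBParseError(msg)
                    warnings.warn(msg + "; skipped")
                    continue
                atoms.append(Atom(
                    serial=gat.serial, name=atom_name, element=elem,
                    polarity=pol,
                    coords=np.array([gat.pos.x, gat.pos.y, gat.pos.z], dtype=float),
                    radius=rad, occupancy=gat.occ, altloc=gat.altloc or "",
                ))
            if not atoms:
                continue
            residue = Residue(
                chain_id=gchain.name, seq_num=gres.seqid.num,
                icode=(gres.seqid.icode or "").strip(), name=parent or name,
                atoms=atoms, is_canonical=(name in CANONICAL_AA), file_pos=pos,
            )
            if is_protein:
                if gchain.name not in chain_index:
                    chain_index[gchain.name] = Chain(gchain.name)
                    structure.chains.append(chain_index[gchain.name])
                chain_index[gchain.name].residues.append(residue)
            else:
                structure.het_residues.append(residue)

    structure.site_annotations = parse_site_records(text, structure)
    return structure


def _source_text(source: str | Path) -> tuple[str, str]:
    if isinstance(source, Path):
        return source.read_text(), str(source)
    if "\n" in source or source.lstrip().startswith(("ATOM", "HEADER", "HETATM",
                                                     "MODEL", "REMARK", "TITLE", "SITE")):
        return source, ""
    return Path(source).read_text(), str(source)


def parse_site_records(source: str | Path, structure: Structure | None = None,
                       ) -> list[SiteAnnotation]:
    """Extract SITE annotations from PDB text.

    Records sharing a site identifier are merged (PDB continuation semantics).
    Members that do not resolve to a protein residue of ``structure`` (ligands,
    waters) are flagged non-protein but retained.
    """
    text, _ = _source_text(source)
    protein_keys: set[tuple[str, int, str]] = set()
    if structure is not None:
        protein_keys = set(structure.residue_keys())

    sites: dict[str, SiteAnnotation] = {}
    for line in text.splitlines():
        if not line.startswith("SITE"):
            continue
        line = line.rstrip("\n").ljust(61)
        site_id = line[11:14].strip()
        if not site_id:
            warnings.warn(f"malformed SITE record skipped: {line.rstrip()!r}")
            continue
        ann = sites.setdefault(site_id, SiteAnnotation(site_id=site_id))
        for start in (18, 29, 40, 51):
            block = line[start:start + 10]
            resname = block[0:3].strip()
            if not resname:
                continue
            chain_id = block[4:5].strip()
            try:
                seq_num = int(block[5:9])
            except ValueError:
                warnings.warn(f"malformed SITE member skipped: {block!r}")
                continue
            icode = block[9:10].strip()
            is_protein = (chain_id, seq_num, icode) in protein_keys \
                if structure is not None else resname.upper() in CANONICAL_AA
            ann.members.append((chain_id, seq_num, icode, resname, is_protein))
    return [sites[k] for k in sites]


def crop(structure: Structure, span: set[ResidueKey] | list[ResidueKey],
         ) -> tuple[Structure, Structure]:
    """Partition a structure into (retained, removed) by residue keys.

    ``span`` must be a non-empty subset of the structure's residues.  Atom
    coordinates are shared, not copied.
    """
    span = set(span)
    if not span:
        raise ValueError("empty crop span")
    present = set(structure.residue_keys())
    missing = span - present
    if missing:
        raise KeyError(f"crop span residues not in structure: {sorted(missing)}")

    retained = Structure(provenance=structure.provenance,
                         site_annotations=structure.site_annotations,
                         het_residues=structure.het_residues)
    removed = Structure(provenance=structure.provenance)
    for chain in structure.chains:
        keep = [r for r in chain.residues if r.key not in span]
        drop = [r for r in chain.residues if r.key in span]
        if keep:
            retained.chains.append(Chain(chain.chain_id, keep))
        if drop:
            removed.chains.append(Chain(chain.chain_id, drop))
    return retained, removed


def merge(a: Structure, b: Structure) -> Structure:
    """Inverse of :func:`crop`: re-join two disjoint partitions in file order."""
    out = Structure(provenance=a.provenance or b.provenance,
                    site_annotations=a.site_annotations or b.site_annotations,
                    het_residues=a.het_residues or b.het_residues)
    order: list[str] = []
    pool: dict[str, list[Residue]] = {}
    for st in (a, b):
        for chain in st.chains:
            if chain.chain_id not in pool:
                pool[chain.chain_id] = []
                order.append(chain.chain_id)
            pool[chain.chain_id].extend(chain.residues)
    for cid in order:
        residues = sorted(pool[cid], key=lambda r: r.file_pos)
        out.chains.append(Chain(cid, residues))
    return out


def write_pdb(structure: Structure, path: str | Path | None = None) -> str:
    """Serialize a Structure back to PDB text (ATOM/TER/SITE/END subset)."""
    lines: list[str] = []
    serial = 0
    for chain in structure.chains:
        for res in chain.residues:
            for at in res.atoms:
                serial += 1
                lines.append(
                    f"ATOM  {serial:5d} {_fmt_atom_name(at.name):4s}{'':1s}"
                    f"{res.name:>3s} {chain.chain_id:1s}{res.seq_num:4d}{res.icode or ' ':1s}   "
                    f"{at.coords[0]:8.3f}{at.coords[1]:8.3f}{at.coords[2]:8.3f}"
                    f"{at.occupancy:6.2f}{0.0:6.2f}          {at.element:>2s}"
                )
        serial += 1
        lines.append(f"TER   {serial:5d}      {chain.residues[-1].name:>3s} "
                     f"{chain.chain_id:1s}{chain.residues[-1].seq_num:4d}")
    for ann in structure.site_annotations:
        members = ann.members
        for rec_no, start in enumerate(range(0, len(members), 4), start=1):
            chunk = members[start:start + 4]
            line = f"SITE   {rec_no:3d} {ann.site_id:>3s} {len(members):2d} "
            for (cid, num, icode, resname, _prot) in chunk:
                line += f"{resname:>3s} {cid:1s}{num:4d}{icode or ' ':1s} "
            lines.append(line.rstrip())
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def _fmt_atom_name(name: str) -> str:
    # PDB convention: element symbol right-aligned in columns 13-14 for
    # one-letter elements, so short names get a leading space.
    if len(name) >= 4:
        return name[:4]
    return f" {name}" if len(name) < 4 and not name[0].isdigit() else name
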