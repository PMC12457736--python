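"""Parameter tables: van der Waals radii, atom polarity, maximum SASA, standard volumes.

All tables ship as editable plain-text files under ``lipscan/data`` and can be
overridden by passing a file path to the loader functions.  Lookup conventions:

* radii / standard volumes: exact ``(resname, atomname)`` entry first, then a
  wildcard ``(*, atomname)`` entry, then the element fallback;
* polarity: element-based only (N, O polar; C, S apolar by default).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path

__all__ = [
    "RadiusTable",
    "PolarityTable",
    "MaxSasaTable",
    "StandardVolumeTable",
    "load_radii",
    "load_polarity",
    "load_max_sasa",
    "load_standard_volumes",
]


def _data_path(name: str) -> Path:
    return Path(str(files("lipscan").joinpath("data", name)))


def _read_rows(path: Path) -> list[list[str]]:
    rows = []
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            rows.append(line.split())
    return rows


@dataclass
class RadiusTable:
    """van der Waals radii in Å, NACCESS (Chothia-style) defaults."""

    by_res_atom: dict[tuple[str, str], float] = field(default_factory=dict)
    by_atom: dict[str, float] = field(default_factory=dict)
    by_element: dict[str, float] = field(default_factory=dict)

    def lookup(self, resname: str, atomname: str, element: str) -> float | None:
        key = (resname.upper(), atomname.upper())
        if key in self.by_res_atom:
            return self.by_res_atom[key]
        if atomname.upper() in self.by_atom:
            return self.by_atom[atomname.upper()]
        return self.by_element.get(element.upper())


@dataclass
class PolarityTable:
    """Element → {polar, apolar} assignment (NACCESS convention by default)."""

    by_element: dict[str, str] = field(default_factory=dict)

    def lookup(self, element: str) -> str | None:
        return self.by_element.get(element.upper())


@dataclass
class MaxSasaTable:
    """Residue-type theoretical maximum SASA (Å²), Tien et al. theoretical values."""

    by_resname: dict[str, float] = field(default_factory=dict)

    def lookup(self, resname: str) -> float | None:
        return self.by_resname.get(resname.upper())


@dataclass
class StandardVolumeTable:
    """Standard (reference) Voronoi atomic volumes V° in Å³.

    Exact ``(resname, atomname)`` entries with an element-level median fallback
    for unmatched atom names.
    """

    by_res_atom: dict[tuple[str, str], float] = field(default_factory=dict)
    by_element: dict[str, float] = field(default_factory=dict)

    def lookup(self, resname: str, atomname: str, element: str) -> float | None:
        key = (resname.upper(), atomname.upper())
        if key in self.by_res_atom:
            return self.by_res_atom[key]
        return self.by_element.get(element.upper())


@functools.lru_cache(maxsize=8)
def load_radii(path: str | None = None) -> RadiusTable:
    table = RadiusTable()
    p = Path(path) if path else _data_path("radii.txt")
    for row in _read_rows(p):
        kind = row[0].lower()
        if kind == "element":
            table.by_element[row[1].upper()] = float(row[2])
        elif kind == "atom":
            res, atom, val = row[1].upper(), row[2].upper(), float(row[3])
            if res == "*":
                table.by_atom[atom] = val
            else:
                table.by_res_atom[(res, atom)] = val
        else:
            raise ValueError(f"bad radii row: {row}")
    return table


@functools.lru_cache(maxsize=8)
def load_polarity(path: str | None = None) -> PolarityTable:
    table = PolarityTable()
    p = Path(path) if path else _data_path("polarity.txt")
    for row in _read_rows(p):
        if row[0].lower() != "element" or row[2] not in ("polar", "apolar"):
            raise ValueError(f"bad polarity row: {row}")
        table.by_element[row[1].upper()] = row[2]
    return table


@functools.lru_cache(maxsize=8)
def load_max_sasa(path: str | None = None) -> MaxSasaTable:
    table = MaxSasaTable()
    p = Path(path) if path else _data_path("max_sasa.txt")
    for row in _read_rows(p):
        table.by_resname[row[0].upper()] = float(row[1])
    return table


@functools.lru_cache(maxsize=8)
def load_standard_volumes(path: str | None = None) -> StandardVolumeTable:
    table = StandardVolumeTable()
    p = Path(path) if path else _data_path("standard_volumes.txt")
    for row in _read_rows(p):
        if row[0].lower() == "element":
            table.by_element[row[1].upper()] = float(row[2])
        else:
            table.by_res_atom[(row[0].upper(), row[1].upper())] = float(row[2])
    return table
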