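"""Molecular domain types and readers/writers for SDF (V2000) and the tabular inputs.

Molecules are treated as bare 3D atom clouds: an element symbol, Cartesian
coordinates in Angstrom and a van der Waals radius per atom. Bond information is
ignored on input (shape comparison is united-atom) and written as an empty bond
block on output.
"""
from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, SchemaError, ValidationError

log = logging.getLogger(__name__)

#: Bondi-style van der Waals radii (Angstrom). Elements not listed fall back to
#: the carbon-like default of 1.70 A.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}
DEFAULT_RADIUS = 1.70

_HERB_PREFIX = re.compile(r"^([A-Z]{2})\d")


def vdw_radius(element: str, table: Mapping[str, float] | None = None) -> float:
    """Radius lookup; total (falls back to the carbon default for unknown elements)."""
    table = VDW_RADII if table is None else table
    return float(table.get(element.upper(), DEFAULT_RADIUS))


@dataclass(frozen=True)
class Atom:
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    radius: float  # van der Waals, Angstrom

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValidationError(f"atom position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)
        if not (self.radius > 0 and math.isfinite(self.radius)):
            raise ValidationError(f"atom radius must be positive, got {self.radius!r}")


@dataclass
class Molecule:
    """A named single-conformer molecule (hydrogens usually suppressed)."""

    id: str
    atoms: list[Atom]
    herb_code: str | None = None

    def __post_init__(self):
        if not self.atoms:
            raise ValidationError(f"molecule {self.id!r} has no atoms")
        if self.herb_code is None:
            m = _HERB_PREFIX.match(self.id)
            if m:
                self.herb_code = m.group(1)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def transformed(self, coords: np.ndarray, new_id: str | None = None) -> "Molecule":
        """Copy of this molecule with replaced coordinates (same elements/radii)."""
        atoms = [Atom(a.element, c, a.radius) for a, c in zip(self.atoms, coords)]
        return Molecule(new_id or self.id, atoms, herb_code=self.herb_code)


@dataclass(frozen=True)
class DescriptorRecord:
    """Per-compound ADME/T descriptor values consumed by the rule filter.

    A field may be ``None`` when the source table had no value; the filter
    treats such compounds conservatively (removed with code MISSING).
    """

    compound_id: str
    solubility_level: float | None
    bbb_level: int | None
    cyp2d6: bool | None
    absorption_level: int | None

    def __post_init__(self):
        if not self.compound_id:
            raise ValidationError("compound_id must be non-empty")
        if self.solubility_level is not None and not math.isfinite(self.solubility_level):
            raise ValidationError(f"{self.compound_id}: non-finite solubility_level")

    @property
    def complete(self) -> bool:
        return None not in (
            self.solubility_level, self.bbb_level, self.cyp2d6, self.absorption_level
        )


@dataclass
class FormulaTable:
    """Herb -> member compound mapping; each compound belongs to exactly one herb."""

    herbs: dict[str, list[str]]
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        seen: dict[str, str] = {}
        for herb, compounds in self.herbs.items():
            for cid in compounds:
                if cid in seen:
                    raise IntegrityError(
                        f"compound {cid!r} listed under both {seen[cid]!r} and {herb!r}"
                    )
                seen[cid] = herb
        self._herb_of = seen

    @property
    def herb_codes(self) -> list[str]:
        return list(self.herbs)

    @property
    def compound_ids(self) -> list[str]:
        return [c for members in self.herbs.values() for c in members]

    def herb_of(self, compound_id: str) -> str:
        try:
            return self._herb_of[compound_id]
        except KeyError:
            raise IntegrityError(f"compound {compound_id!r} not present in formula table")

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._herb_of

    def __len__(self) -> int:
        return len(self._herb_of)


# ---------------------------------------------------------------------------
# SDF (V2000)

def read_sdf(
    path: str | Path,
    suppress_hydrogens: bool = True,
    radius_table: Mapping[str, float] | None = None,
) -> list[Molecule]:
    """Read a V2000 SD file into Molecules.

    One Molecule per record; elements get radii from ``radius_table`` (built-in
    Bondi-style table by default, unknown elements fall back to 1.70 A).
    Hydrogens are dropped when ``suppress_hydrogens`` is true; a record left with
    zero heavy atoms is skipped with a warning while the remaining records are
    still returned.
    """
    text = Path(path).read_text()
    if not text.strip():
        return []
    mols: list[Molecule] = []
    line_offset = 0
    for rec_index, record in enumerate(text.split("$$$$")):
        lines = record.split("\n")
        # leading blank lines between records belong to the delimiter
        while lines and not lines[0].strip():
            lines.pop(0)
            line_offset += 1
        if not any(l.strip() for l in lines):
            line_offset += len(lines)
            continue
        mol = _parse_record(lines, rec_index, line_offset, suppress_hydrogens, radius_table)
        if mol is not None:
            mols.append(mol)
        line_offset += len(lines)
    ids = [m.id for m in mols]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise IntegrityError(f"duplicate molecule id {dup!r} in {path}")
    return mols


def _parse_record(
    lines: list[str],
    rec_index: int,
    line_offset: int,
    suppress_hydrogens: bool,
    radius_table: Mapping[str, float] | None,
) -> Molecule | None:
    if len(lines) < 4:
        raise FormatError(f"record {rec_index}: truncated header block")
    counts = lines[3]
    if "V3000" in counts:
        raise FormatError(f"record {rec_index}: V3000 records are not supported")
    try:
        n_atoms = int(counts[0:3])
    except (ValueError, IndexError):
        raise FormatError(f"record {rec_index}: malformed counts line {counts!r}")
    if len(lines) < 4 + n_atoms:
        raise FormatError(f"record {rec_index}: atom block truncated ({n_atoms} atoms declared)")
    atoms: list[Atom] = []
    for i in range(n_atoms):
        line = lines[4 + i]
        lineno = line_offset + 4 + i + 1  # 1-based line number in the file
        try:
            x = float(line[0:10])
            y = float(line[10:20])
            z = float(line[20:30])
        except (ValueError, IndexError):
            raise FormatError(f"line {lineno}: non-numeric coordinate field in {line!r}")
        element = line[31:34].strip()
        if not element:
            raise FormatError(f"line {lineno}: missing element symbol")
        if suppress_hydrogens and element.upper() in ("H", "D", "T"):
            continue
        atoms.append(Atom(element, np.array([x, y, z]), vdw_radius(element, radius_table)))
    mol_id = lines[0].strip() or f"mol{rec_index}"
    if not atoms:
        log.warning("record %d (%s): zero heavy atoms after hydrogen suppression; skipped",
                    rec_index, mol_id)
        return None
    return Molecule(mol_id, atoms)


def write_sdf(molecules: Iterable[Molecule], path: str | Path) -> None:
    """Write molecules as V2000 records with an empty bond block.

    Coordinates are written at fixed %10.4f precision so output is byte-stable.
    """
    out = []
    for mol in molecules:
        out.append(mol.id)
        out.append("  herbnet")
        out.append("")
        out.append(f"{len(mol.atoms):3d}{0:3d}  0  0  0  0  0  0  0  0999 V2000")
        for a in mol.atoms:
            x, y, z = a.position
            out.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {a.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
        out.append("M  END")
        out.append("$$$$")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Tabular inputs

_DESCRIPTOR_COLUMNS = ["compound_id", "solubility_level", "bbb_level", "cyp2d6", "absorption_level"]


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or (
        isinstance(value, str) and not value.strip()
    )


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().upper()
    if s == "TRUE":
        return True
    if s == "FALSE":
        return False
    raise ValueError(f"expected TRUE/FALSE, got {value!r}")


def read_descriptor_table(path: str | Path) -> list[DescriptorRecord]:
    """Read a tab-delimited ADME/T descriptor table into typed records.

    cyp2d6 is parsed from TRUE/FALSE case-insensitively; empty cells become
    ``None`` on the record. Unparseable cells raise a row-level FormatError.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _DESCRIPTOR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"descriptor table {path} missing columns: {', '.join(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowno = i + 2  # header is line 1
        try:
            records.append(
                DescriptorRecord(
                    compound_id=str(row.compound_id).strip(),
                    solubility_level=None if _is_missing(row.solubility_level)
                    else float(row.solubility_level),
                    bbb_level=None if _is_missing(row.bbb_level) else int(row.bbb_level),
                    cyp2d6=None if _is_missing(row.cyp2d6) else _parse_bool(row.cyp2d6),
                    absorption_level=None if _is_missing(row.absorption_level)
                    else int(row.absorption_level),
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"descriptor table row {rowno}: {exc}")
    return records


def read_formula_table(path: str | Path) -> FormulaTable:
    """Read a tab-delimited herb_code/compound_id membership table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("herb_code", "compound_id") if c not in df.columns]
    if missing:
        raise SchemaError(f"formula table {path} missing columns: {', '.join(missing)}")
    herbs: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        herbs.setdefault(str(row.herb_code).strip(), []).append(str(row.compound_id).strip())
    return FormulaTable(herbs)


def write_formula_table(formula: FormulaTable, path: str | Path) -> None:
    lines = ["herb_code\tcompound_id"]
    for herb, members in formula.herbs.items():
        for cid in members:
            lines.append(f"{herb}\t{cid}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_descriptor_table(records: Sequence[DescriptorRecord], path: str | Path) -> None:
    lines = ["\t".join(_DESCRIPTOR_COLUMNS)]
    for r in records:
        sol = "" if r.solubility_level is None else f"{r.solubility_level:.4f}"
        bbb = "" if r.bbb_level is None else str(r.bbb_level)
        cyp = "" if r.cyp2d6 is None else ("TRUE" if r.cyp2d6 else "FALSE")
        absv = "" if r.absorption_level is None else str(r.absorption_level)
        lines.append(f"{r.compound_id}\t{sol}\t{bbb}\t{cyp}\t{absv}")
    Path(path).write_text("\n".join(lines) + "\n")
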