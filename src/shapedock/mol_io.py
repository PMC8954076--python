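"""Molecular coordinate I/O and atom correspondence between conformers.

Supported formats: XYZ, PDB, SDF (V2000) and PDBQT.  Coordinates are
always ångström internally.  PDB/PDBQT records are parsed by fixed
columns, not whitespace.  For PDBQT only the coordinate fields are ever
rewritten; every other column is preserved verbatim so that a
read → write round trip is byte identical.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

__all__ = [
    "Atom",
    "Molecule",
    "AtomMap",
    "MolIOError",
    "ParseError",
    "CorrespondenceError",
    "read_structure",
    "write_structure",
    "match_atoms",
    "read_atom_map",
]

_FORMATS = ("xyz", "pdb", "sdf", "pdbqt")

_PT = Chem.GetPeriodicTable()


class MolIOError(ValueError):
    """Base error for structure I/O problems."""


class ParseError(MolIOError):
    """A record in an input file does not conform to the named standard."""


class CorrespondenceError(MolIOError):
    """Two conformers cannot be atom-matched under the shared-order model."""


def _check_element(symbol: str, context: str) -> str:
    symbol = symbol.strip()
    sym = symbol.capitalize() if len(symbol) <= 2 else symbol
    try:
        if _PT.GetAtomicNumber(sym) <= 0:
            raise MolIOError(f"unknown element {symbol!r} ({context})")
    except Exception as exc:  # RDKit raises RuntimeError on unknown symbols
        raise MolIOError(f"unknown element {symbol!r} ({context})") from exc
    return sym


@dataclass(frozen=True)
class Atom:
    """A single atom: ordinal index, element symbol, site label, coords in Å."""

    index: int
    element: str
    label: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,):
            raise MolIOError(f"atom coords must be a 3-vector, got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise MolIOError(f"non-finite coordinates for atom {self.index}")
        object.__setattr__(self, "coords", coords)


@dataclass
class Molecule:
    """An ordered list of atoms with provenance of the file it came from."""

    name: str
    atoms: list[Atom]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for want, atom in enumerate(self.atoms):
            if atom.index != want:
                raise MolIOError(
                    f"atom indices must be contiguous from 0; got {atom.index} at {want}"
                )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(k, 3) coordinate matrix in Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def labels(self) -> list[str]:
        return [a.label for a in self.atoms]

    def with_coords(self, coords: np.ndarray, name: Optional[str] = None) -> "Molecule":
        """Copy of this molecule with replaced coordinates (same atoms/provenance)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self), 3):
            raise MolIOError(f"expected coords of shape ({len(self)}, 3), got {coords.shape}")
        atoms = [replace(a, coords=c.copy()) for a, c in zip(self.atoms, coords)]
        return Molecule(name or self.name, atoms, dict(self.provenance))

    def subset(self, indices: Sequence[int], name: Optional[str] = None) -> "Molecule":
        """New molecule containing the given atoms, reindexed from 0."""
        atoms = [
            replace(self.atoms[i], index=new)
            for new, i in enumerate(indices)
        ]
        return Molecule(name or self.name, atoms, {"parent": self.name})


@dataclass
class AtomMap:
    """Injective correspondence between atoms of two conformers."""

    pairs: list[tuple[int, int]]
    unmatched_a: list[int] = field(default_factory=list)
    unmatched_b: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        a_side = [i for i, _ in self.pairs]
        b_side = [j for _, j in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise CorrespondenceError("atom map must be injective on both sides")

    @property
    def indices_a(self) -> np.ndarray:
        return np.array([i for i, _ in self.pairs], dtype=int)

    @property
    def indices_b(self) -> np.ndarray:
        return np.array([j for _, j in self.pairs], dtype=int)

    @classmethod
    def identity(cls, k: int) -> "AtomMap":
        return cls(pairs=[(i, i) for i in range(k)])


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_xyz(path: Path) -> Molecule:
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty XYZ file")
    try:
        k = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}: line 1: expected atom count, got {lines[0]!r}") from exc
    if len(lines) < k + 2:
        raise ParseError(f"{path}: expected {k + 2} lines for {k} atoms, got {len(lines)}")
    comment = lines[1].strip()
    atoms = []
    for i in range(k):
        lineno = i + 3
        parts = lines[i + 2].split()
        if len(parts) < 4:
            raise ParseError(f"{path}: line {lineno}: expected 'element x y z'")
        element = _check_element(parts[0], f"{path} line {lineno}")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: bad coordinate field") from exc
        atoms.append(Atom(i, element, f"{element}{i + 1}", np.array(xyz)))
    name = comment or path.stem
    return Molecule(name, atoms, {"path": str(path), "format": "xyz"})


def _parse_pdb_atom_line(line: str, lineno: int, path: Path) -> tuple[str, str, np.ndarray]:
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise ParseError(f"{path}: line {lineno}: bad coordinate columns 31-54") from exc
    label = line[12:16].strip()
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back to the atom-name column, dropping leading digits
        element = re.sub(r"^\d+", "", label)[:2]
        if len(element) == 2 and element[1].islower() is False:
            element = element[0]
    element = _check_element(element, f"{path} line {lineno}")
    return label, element, np.array([x, y, z])


def _read_pdb_like(path: Path, fmt: str) -> Molecule:
    atoms = []
    raw_lines: list[str] = []
    atom_line_nos: list[int] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        raw_lines.append(line)
        if line[:6].strip() in ("ATOM", "HETATM"):
            if len(line) < 54:
                raise ParseError(f"{path}: line {lineno}: truncated {line[:6].strip()} record")
            label, element, xyz = _parse_pdb_atom_line(line, lineno, path)
            atoms.append(Atom(len(atoms), element, label or element, xyz))
            atom_line_nos.append(lineno - 1)
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    prov = {"path": str(path), "format": fmt, "lines": raw_lines, "atom_lines": atom_line_nos}
    return Molecule(path.stem, atoms, prov)


def _read_sdf(path: Path) -> Molecule:
    # RDKit is the reference V2000 parser; sanitize off so geometry-only
    # blocks (no valence model, explicit H) pass through untouched.
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    try:
        rdmol = next(iter(supplier))
    except StopIteration:
        rdmol = None
    if rdmol is None:
        raise ParseError(f"{path}: RDKit could not parse the SDF/MOL block")
    conf = rdmol.GetConformer()
    atoms = []
    for i, rdatom in enumerate(rdmol.GetAtoms()):
        pos = conf.GetAtomPosition(i)
        element = _check_element(rdatom.GetSymbol(), f"{path} atom {i}")
        atoms.append(Atom(i, element, f"{element}{i + 1}", np.array([pos.x, pos.y, pos.z])))
    name = rdmol.GetProp("_Name").strip() if rdmol.HasProp("_Name") else ""
    return Molecule(name or path.stem, atoms, {"path": str(path), "format": "sdf"})


def read_structure(path, format: Optional[str] = None) -> Molecule:
    """Read a molecular structure file into a :class:`Molecule`.

    ``format`` is one of ``xyz``, ``pdb``, ``sdf``, ``pdbqt``; if omitted it
    is taken from the file suffix.  Atoms are returned in file order with
    coordinates in Å.
    """
    path = Path(path)
    if not path.exists():
        raise MolIOError(f"no such file: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "mol":
        fmt = "sdf"
    if fmt not in _FORMATS:
        raise MolIOError(f"unsupported format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt in ("pdb", "pdbqt"):
        return _read_pdb_like(path, fmt)
    return _read_sdf(path)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _write_xyz(mol: Molecule, path: Path) -> None:
    lines = [str(len(mol)), mol.name]
    for a in mol.atoms:
        lines.append(f"{a.element} {a.coords[0]:.8f} {a.coords[1]:.8f} {a.coords[2]:.8f}")
    path.write_text("\n".join(lines) + "\n")


def _write_pdb(mol: Molecule, path: Path) -> None:
    lines = []
    for a in mol.atoms:
        name = a.label[:4]
        # column-conformant atom-name packing: 1/2-char names start in col 14
        name_field = f" {name:<3s}" if len(name) < 4 else name
        lines.append(
            "HETATM{serial:>5d} {name} LIG A   1    "
            "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}".format(
                serial=a.index + 1,
                name=name_field,
                x=a.coords[0],
                y=a.coords[1],
                z=a.coords[2],
                el=a.element,
            )
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _write_pdb_like_rewrite(mol: Molecule, path: Path) -> None:
    lines = mol.provenance.get("lines")
    atom_lines = mol.provenance.get("atom_lines")
    if lines is None or atom_lines is None:
        raise MolIOError(
            "PDBQT output requires the non-coordinate columns of the source "
            "file; read the structure from a PDBQT first"
        )
    out = list(lines)
    for atom, li in zip(mol.atoms, atom_lines):
        line = out[li]
        coords = f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
        out[li] = line[:30] + coords + line[54:]
    path.write_text("\n".join(out) + "\n")


def _write_sdf(mol: Molecule, path: Path) -> None:
    rdmol = Chem.RWMol()
    for a in mol.atoms:
        rdmol.AddAtom(Chem.Atom(a.element))
    conf = Chem.Conformer(len(mol))
    for a in mol.atoms:
        conf.SetAtomPosition(a.index, tuple(float(v) for v in a.coords))
    rdmol.AddConformer(conf)
    rdmol.SetProp("_Name", mol.name)
    block = Chem.MolToMolBlock(rdmol, kekulize=False)
    path.write_text(block + "$$$$\n")


def write_structure(mol: Molecule, path, format: Optional[str] = None) -> None:
    """Write ``mol`` to ``path`` in the requested format.

    PDB coordinates use the standard 8.3f columns; PDBQT output rewrites
    only the coordinate fields of the originally read file.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "mol":
        fmt = "sdf"
    if fmt not in _FORMATS:
        raise MolIOError(f"unsupported format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "xyz":
        _write_xyz(mol, path)
    elif fmt == "pdb":
        if mol.provenance.get("format") == "pdb" and "lines" in mol.provenance:
            _write_pdb_like_rewrite(mol, path)
        else:
            _write_pdb(mol, path)
    elif fmt == "pdbqt":
        _write_pdb_like_rewrite(mol, path)
    else:
        _write_sdf(mol, path)


# ---------------------------------------------------------------------------
# atom correspondence
# ---------------------------------------------------------------------------

def _deletion_matches(parent_el: list[str], variant_el: list[str], removed: int) -> bool:
    return parent_el[:removed] + parent_el[removed + 1:] == variant_el


def match_atoms(
    parent: Molecule,
    variant: Molecule,
    removed_label: Optional[str] = None,
) -> AtomMap:
    """Correspond ``variant`` atoms to ``parent`` atoms under shared ordering.

    The variant must have either the same number of atoms (identity map
    after element check) or exactly one fewer.  In the deletion case the
    unmatched parent atom must be a hydrogen; with ``removed_label`` given,
    the deleted H is the one closest in space to the heavy atom carrying
    that label, otherwise the first order-consistent deletion point is
    used.
    """
    ka, kb = len(parent), len(variant)
    if ka - kb not in (0, 1):
        raise CorrespondenceError(
            f"size difference must be 0 or 1 (parent {ka}, variant {kb})"
        )
    pel, vel = parent.elements, variant.elements

    if ka == kb:
        for i, (ea, eb) in enumerate(zip(pel, vel)):
            if ea != eb:
                raise CorrespondenceError(
                    f"element mismatch at shared index {i}: {ea} vs {eb}"
                )
        return AtomMap.identity(ka)

    if removed_label is not None:
        heavy = [a for a in parent.atoms if a.label == removed_label and a.element != "H"]
        if not heavy:
            raise CorrespondenceError(f"no heavy atom labelled {removed_label!r} in parent")
        site = heavy[0]
        hydrogens = [a for a in parent.atoms if a.element == "H"]
        if not hydrogens:
            raise CorrespondenceError("parent has no hydrogens to delete")
        removed = min(
            hydrogens, key=lambda a: float(np.linalg.norm(a.coords - site.coords))
        ).index
        if not _deletion_matches(pel, vel, removed):
            raise CorrespondenceError(
                f"deleting parent H {removed} (nearest to {removed_label}) does not "
                "reconcile the element orderings"
            )
    else:
        # first index where the shared ordering diverges is the deletion point
        removed = kb  # if variant is a prefix, the last parent atom was deleted
        for i in range(kb):
            if pel[i] != vel[i]:
                removed = i
                break
        if not _deletion_matches(pel, vel, removed):
            raise CorrespondenceError(
                "orderings do not differ by a single deletion; supply an "
                "explicit atom map"
            )
        if pel[removed] != "H":
            raise CorrespondenceError(
                f"single unmatched parent atom {removed} is {pel[removed]}, not H"
            )

    pairs = [(i if i < removed else i + 1, i) for i in range(kb)]
    return AtomMap(pairs=pairs, unmatched_a=[removed])


def read_atom_map(path) -> AtomMap:
    """Read a user-supplied map file of whitespace-delimited 0-based index pairs."""
    pairs = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        parts = stripped.split()
        if len(parts) != 2:
            raise ParseError(f"{path}: line {lineno}: expected two integers")
        try:
            pairs.append((int(parts[0]), int(parts[1])))
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: expected two integers") from exc
    if not pairs:
        raise ParseError(f"{path}: empty atom map")
    return AtomMap(pairs=pairs)
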