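"""Protein structure container, PDB I/O, radius assignment and atom selections.

The docking engine treats a protein as a rigid cloud of spheres: each atom
carries a Cartesian position and a van der Waals radius.  Parsing of PDB
files is delegated to :mod:`gemmi`; writing uses gemmi's PDB serializer so
round trips preserve coordinates to the format precision (0.001 A).
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "RadiiTable",
    "EmptyStructureError",
    "read_pdb",
    "write_pdb",
    "assign_radii",
    "select",
]

#: Atom names forming the peptide backbone.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


class EmptyStructureError(ValueError):
    """Raised when an operation requires a non-empty structure."""


@dataclass(frozen=True)
class Atom:
    """A single atom of a rigid body.

    ``vdw_radius`` is ``nan`` until :func:`assign_radii` has run; the grid
    discretization refuses to work with unassigned radii.
    """

    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray  # shape (3,), Angstrom
    vdw_radius: float = math.nan
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.atom_name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)

    @property
    def is_backbone(self) -> bool:
        return self.atom_name in BACKBONE_NAMES

    @property
    def is_calpha(self) -> bool:
        return self.atom_name == "CA"


@dataclass
class Structure:
    """An ordered, rigid collection of atoms (one docking partner)."""

    atoms: list[Atom] = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) coordinate array in Angstrom."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    @property
    def centroid(self) -> np.ndarray:
        if not self.atoms:
            raise EmptyStructureError("centroid of an empty structure")
        return self.positions.mean(axis=0)

    def has_radii(self) -> bool:
        return len(self.atoms) > 0 and bool(np.all(np.isfinite(self.radii)))

    def with_positions(self, positions: np.ndarray, label: str | None = None) -> "Structure":
        """Copy of this structure with every atom moved to ``positions``."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self.atoms), 3):
            raise ValueError("positions must have shape (n_atoms, 3)")
        atoms = [replace(a, position=p) for a, p in zip(self.atoms, positions)]
        return Structure(atoms=atoms, label=label if label is not None else self.label)

    def translated(self, shift: np.ndarray) -> "Structure":
        return self.with_positions(self.positions + np.asarray(shift, dtype=float))


class RadiiTable:
    """Element -> van der Waals radius lookup with a default fallback."""

    def __init__(self, radii: dict[str, float], default: float = 1.8):
        self.radii = {k.upper(): float(v) for k, v in radii.items()}
        self.default = float(default)
        if any(v <= 0 for v in self.radii.values()) or self.default <= 0:
            raise ValueError("radii must be positive")

    def __getitem__(self, element: str) -> float:
        return self.radii.get(element.upper(), self.default)

    def __contains__(self, element: str) -> bool:
        return element.upper() in self.radii

    @property
    def max_radius(self) -> float:
        return max([self.default, *self.radii.values()])

    @classmethod
    def from_file(cls, path: str | Path) -> "RadiiTable":
        radii: dict[str, float] = {}
        default = 1.8
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, value = line.split()
            if key.lower() == "default":
                default = float(value)
            else:
                radii[key] = float(value)
        return cls(radii, default=default)

    @classmethod
    def default_table(cls) -> "RadiiTable":
        with resources.as_file(resources.files("lscdock.data") / "vdw_radii.dat") as p:
            return cls.from_file(p)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _pick_altloc(candidates: list[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; ties prefer altloc 'A' (then alphabetical)."""
    def key(a: gemmi.Atom):
        return (-a.occ, a.altloc != "A", a.altloc)

    return sorted(candidates, key=key)[0]


def read_pdb(
    source: str | Path | io.TextIOBase,
    *,
    include_hetatm: bool = False,
    label: str | None = None,
) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Only the first MODEL is used.  Alternate locations are collapsed to the
    highest-occupancy conformer (ties resolved toward altloc ``A``).  HETATM
    records (waters, ligands, ions) are skipped unless ``include_hetatm``.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        try:
            st = gemmi.read_pdb(str(path))
        except (RuntimeError, OSError) as exc:
            raise IOError(f"cannot read PDB file {path}: {exc}") from exc
        if label is None:
            label = path.stem
    else:
        st = gemmi.read_pdb_string(source.read())
        if label is None:
            label = "structure"

    if len(st) == 0:
        raise EmptyStructureError(f"{label}: no models in PDB input")
    model = st[0]

    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            if residue.het_flag == "H" and not include_hetatm:
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in residue:
                by_name.setdefault(atom.name, []).append(atom)
            for name, group in by_name.items():
                atom = group[0] if len(group) == 1 else _pick_altloc(group)
                atoms.append(
                    Atom(
                        atom_name=name,
                        element=atom.element.name,
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        chain_id=chain.name,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=atom.occ,
                    )
                )
    if not atoms:
        raise EmptyStructureError(f"{label}: no atoms left after filtering")
    return Structure(atoms=atoms, label=label)


def write_pdb(structure: Structure, sink: str | Path | io.TextIOBase) -> None:
    """Write ``structure`` as PDB ATOM records.

    Raises on empty input and on coordinates that do not fit the fixed-width
    PDB coordinate fields (|x| >= 10000 A), rather than emitting a truncated
    file.
    """
    if len(structure) == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    coords = structure.positions
    # %8.3f accommodates -999.999 .. 9999.999
    if np.any(coords >= 10000) or np.any(coords <= -1000):
        raise ValueError("coordinates exceed the PDB fixed-width field (must lie in (-1000, 10000) A)")

    st = gemmi.Structure()
    st.name = structure.label or "lscdock"
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    for a in structure.atoms:
        chain = chain_map.get(a.chain_id)
        if chain is None:
            chain = gemmi.Chain(a.chain_id or "A")
            chain_map[a.chain_id] = chain
        if len(chain) == 0 or chain[-1].seqid.num != a.residue_number or chain[-1].name != a.residue_name:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, " ")
            res.het_flag = "A"
            chain.add_residue(res)
        res = chain[-1]
        ga = gemmi.Atom()
        ga.name = a.atom_name
        ga.element = gemmi.Element(a.element)
        ga.pos = gemmi.Position(*a.position)
        ga.occ = a.occupancy
        res.add_atom(ga)
    for chain in chain_map.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()

    text = st.make_pdb_string()
    if isinstance(sink, (str, Path)):
        try:
            Path(sink).write_text(text)
        except OSError as exc:
            raise IOError(f"cannot write PDB file {sink}: {exc}") from exc
    else:
        sink.write(text)


# ---------------------------------------------------------------------------
# Radius assignment and selections
# ---------------------------------------------------------------------------

def assign_radii(structure: Structure, table: RadiiTable | None = None) -> Structure:
    """Return a copy of ``structure`` with a VDW radius on every atom.

    Unknown elements receive the table's default radius; one warning is
    emitted listing them.  Re-assignment with another table overwrites.
    """
    if table is None:
        table = RadiiTable.default_table()
    unknown: set[str] = set()
    atoms = []
    for a in structure.atoms:
        if a.element not in table:
            unknown.add(a.element or "?")
        atoms.append(replace(a, vdw_radius=table[a.element]))
    if unknown:
        warnings.warn(
            f"{structure.label or 'structure'}: elements {sorted(unknown)} not in radii "
            f"table, using default {table.default} A",
            stacklevel=2,
        )
    return Structure(atoms=atoms, label=structure.label)


def select(structure: Structure, selector: str) -> Structure:
    """Subset of atoms, order preserved.

    ``selector`` is ``"backbone"`` (N, CA, C, O), ``"calpha"`` or
    ``"chain:X"``.  An empty result is returned as an empty Structure; the
    caller decides whether that is an error.
    """
    if selector == "backbone":
        keep = [a for a in structure.atoms if a.is_backbone]
    elif selector == "calpha":
        keep = [a for a in structure.atoms if a.is_calpha]
    elif selector.startswith("chain:"):
        chain_id = selector.split(":", 1)[1]
        keep = [a for a in structure.atoms if a.chain_id == chain_id]
    else:
        raise ValueError(f"unknown selector {selector!r}")
    return Structure(atoms=list(keep), label=f"{structure.label}[{selector}]")
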