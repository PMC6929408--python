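"""Deterministic synthetic complexes with known bound poses.

The generator builds "knob/socket" pseudo-proteins: the receptor is a
jittered-lattice atom cloud filling a sphere with a hemispherical socket
carved out of its surface, the ligand a matching spherical knob nested in
that socket.  All atoms are carbons with the table radius; each atom is its
own residue with one CA atom, so the C-alpha and backbone selections used
by the evaluation operations apply directly.  Shape is the only signal the
scoring function uses, so a purely geometric interface suffices.

Everything is a pure function of its parameters and seed: identical calls
produce byte-identical PDB output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.spatial.distance import cdist

from .structures import Atom, Structure, write_pdb

__all__ = ["ToyComplex", "make_knob_socket", "perturb_pose", "mini_benchmark"]

_LATTICE = 2.0  # pseudo-atom lattice spacing, Angstrom
_JITTER = 0.15  # uniform coordinate jitter amplitude, Angstrom
_GAP = 3.5  # carve clearance between socket wall and knob surface, Angstrom
_PSEUDO_RADIUS = 1.9  # carbon radius of the shipped table, used for the audit


@dataclass(frozen=True)
class ToyComplex:
    """A synthetic receptor/ligand pair with its ground-truth bound pose."""

    receptor: Structure
    ligand: Structure  # reference frame: centroid at the origin
    true_rotation: np.ndarray  # (3, 3)
    true_translation: np.ndarray  # (3,), Angstrom
    seed: int

    @property
    def ligand_bound(self) -> Structure:
        """Ligand placed in the bound (native) position."""
        pos = self.ligand.positions @ self.true_rotation.T + self.true_translation
        return self.ligand.with_positions(pos, label=f"{self.ligand.label}_bound")

    def native(self) -> tuple[Structure, Structure]:
        return self.receptor, self.ligand_bound

    def interface_distances(self) -> np.ndarray:
        """All receptor-ligand atom-center distances in the bound pose."""
        return cdist(self.receptor.positions, self.ligand_bound.positions)


def _lattice_cloud(max_radius: float) -> np.ndarray:
    """Cubic-lattice points within a ball, sorted by (radius, x, y, z)."""
    m = int(math.ceil(max_radius / _LATTICE))
    ax = np.arange(-m, m + 1) * _LATTICE
    pts = np.array(np.meshgrid(ax, ax, ax, indexing="ij")).reshape(3, -1).T
    r2 = np.sum(pts**2, axis=1)
    keep = r2 <= max_radius**2
    pts, r2 = pts[keep], r2[keep]
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], np.round(r2, 9)))
    return pts[order]


def _make_atoms(positions: np.ndarray, chain_id: str, label: str) -> Structure:
    atoms = [
        Atom(
            atom_name="CA",
            element="C",
            residue_name="ALA",
            residue_number=i + 1,
            chain_id=chain_id,
            position=p,
        )
        for i, p in enumerate(positions)
    ]
    return Structure(atoms=atoms, label=label)


def make_knob_socket(
    seed: int,
    n_receptor: int = 300,
    n_ligand: int = 80,
    knob_radius: float = 6.0,
) -> ToyComplex:
    """Build one deterministic knob/socket complex.

    The receptor ball radius follows from ``n_receptor`` at the fixed
    pseudo-atom lattice density; the socket is carved around a point on the
    +x pole of that ball with a clearance that keeps the bound interface
    clash-free (minimum cross distance >= 0.8 of summed radii) while
    leaving at least ten contact pairs within 1.2 of summed radii.
    """
    if n_receptor < 50:
        raise ValueError("n_receptor must be >= 50")
    if n_ligand < 20:
        raise ValueError("n_ligand must be >= 20")

    rng = np.random.default_rng(seed)

    # ligand knob: n_ligand closest lattice points around the origin
    lig_candidates = _lattice_cloud(knob_radius + 4 * _LATTICE)
    if len(lig_candidates) < n_ligand:
        raise ValueError("n_ligand too large for the requested knob radius")
    lig_local = lig_candidates[:n_ligand].copy()
    knob_extent = float(np.linalg.norm(lig_local, axis=1).max())
    if knob_extent > knob_radius:
        raise ValueError(
            f"knob of {n_ligand} atoms (radius {knob_extent:.1f} A) exceeds "
            f"knob_radius {knob_radius} A"
        )

    # receptor ball radius from the atom budget, with room for the carve
    ball_radius = (3 * n_receptor * _LATTICE**3 / (4 * math.pi)) ** (1 / 3)
    if knob_radius + _GAP >= 2 * ball_radius:
        raise ValueError("knob larger than the receptor ball; reduce knob_radius")
    candidates = _lattice_cloud(ball_radius + knob_radius + 6 * _LATTICE)
    socket_center = np.array([ball_radius, 0.0, 0.0])
    # carve relative to the knob's actual atom-cloud extent so the bound
    # interface sits in the contact band regardless of lattice quantization
    carved = candidates[
        np.linalg.norm(candidates - socket_center, axis=1) >= knob_extent + _GAP
    ]
    if len(carved) < n_receptor:
        raise ValueError("n_receptor too large for the candidate cloud")
    rec_pos = carved[:n_receptor].copy()

    rec_pos += rng.uniform(-_JITTER, _JITTER, size=rec_pos.shape)
    lig_local += rng.uniform(-_JITTER, _JITTER, size=lig_local.shape)
    lig_centroid = lig_local.mean(axis=0)
    lig_local -= lig_centroid  # reference frame: centroid at the origin

    toy = ToyComplex(
        receptor=_make_atoms(rec_pos, "A", f"knobsocket{seed}_receptor"),
        ligand=_make_atoms(lig_local, "B", f"knobsocket{seed}_ligand"),
        true_rotation=np.eye(3),
        true_translation=socket_center + lig_centroid,
        seed=seed,
    )
    _audit_interface(toy)
    return toy


def _audit_interface(toy: ToyComplex) -> None:
    """Construction-time check of the bound-pose interface invariant."""
    d = toy.interface_distances()
    touching = 2 * _PSEUDO_RADIUS
    if d.min() < 0.8 * touching:
        raise AssertionError(
            f"fixture has a deep clash: min interface distance {d.min():.2f} A"
        )
    n_contact = int(np.count_nonzero(d <= 1.2 * touching))
    if n_contact < 10:
        raise AssertionError(f"fixture interface too sparse: {n_contact} contact pairs")


def perturb_pose(
    toy: ToyComplex, angle: float, displacement: float, seed: int
) -> Structure:
    """Bound-pose ligand rotated by ``angle`` (deg) about a random axis
    through its centroid and translated by ``displacement`` (A) along a
    random direction; deterministic per seed."""
    rng = np.random.default_rng(seed)
    bound = toy.ligand_bound
    pos = bound.positions
    if angle != 0:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        mat = Rotation.from_rotvec(np.radians(angle) * axis).as_matrix()
        c = pos.mean(axis=0)
        pos = (pos - c) @ mat.T + c
    if displacement != 0:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = pos + displacement * direction
    return bound.with_positions(pos, label=f"{bound.label}_perturbed")


def mini_benchmark(n_cases: int, seed: int, out_dir: str | Path) -> Path:
    """Write ``n_cases`` knob/socket cases plus a case-list TSV.

    Per case: ``<id>_receptor.pdb`` and ``<id>_ligand.pdb`` (the docking
    inputs, ligand in a perturbed pose) and ``<id>_native.pdb`` (receptor
    chain A + bound ligand chain B).  Returns the case-list path.  Category
    labels cycle through EI/AA/OT purely as metadata.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc

    sizes = [(260, 70, 5.5), (300, 80, 6.0), (340, 90, 6.5)]
    categories = ["EI", "AA", "OT"]
    rows = ["case_id\tcategory\treceptor_pdb\tligand_pdb\tnative_pdb"]
    for i in range(n_cases):
        n_rec, n_lig, knob = sizes[i % len(sizes)]
        toy = make_knob_socket(seed=seed + i, n_receptor=n_rec, n_ligand=n_lig, knob_radius=knob)
        case_id = f"case{i + 1:03d}"
        rec_path = out_dir / f"{case_id}_receptor.pdb"
        lig_path = out_dir / f"{case_id}_ligand.pdb"
        nat_path = out_dir / f"{case_id}_native.pdb"
        write_pdb(toy.receptor, rec_path)
        write_pdb(perturb_pose(toy, angle=60.0, displacement=20.0, seed=seed + i), lig_path)
        native = Structure(
            atoms=list(toy.receptor.atoms) + list(toy.ligand_bound.atoms),
            label=f"{case_id}_native",
        )
        write_pdb(native, nat_path)
        rows.append(
            f"{case_id}\t{categories[i % 3]}\t{rec_path.name}\t{lig_path.name}\t{nat_path.name}"
        )
    case_list = out_dir / "cases.tsv"
    case_list.write_text("\n".join(rows) + "\n")
    return case_list
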