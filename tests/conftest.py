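import numpy as np
import pytest

from lscdock.fixtures import make_knob_socket
from lscdock.gridding import Layer
from lscdock.structures import Atom, RadiiTable, Structure, assign_radii


@pytest.fixture(scope="session")
def radii_table():
    return RadiiTable.default_table()


@pytest.fixture(scope="session")
def toy(radii_table):
    """Default knob/socket complex with radii assigned."""
    toy = make_knob_socket(seed=1)
    receptor = assign_radii(toy.receptor, radii_table)
    ligand = assign_radii(toy.ligand, radii_table)
    return toy, receptor, ligand


def make_structure(positions, radius=1.9, chain_id="A", atom_name="CA", start_residue=1):
    """Small helper: one-atom-per-residue carbon structure at given coordinates."""
    atoms = [
        Atom(
            atom_name=atom_name,
            element="C",
            residue_name="ALA",
            residue_number=start_residue + i,
            chain_id=chain_id,
            position=np.asarray(p, dtype=float),
            vdw_radius=radius,
        )
        for i, p in enumerate(np.atleast_2d(positions))
    ]
    return Structure(atoms=atoms, label="test")


def random_cloud(rng, n_atoms, spread=6.0, radius=1.9):
    return make_structure(rng.uniform(-spread, spread, size=(n_atoms, 3)), radius=radius)


FACE_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def audit_layer_labels(labels):
    """Brute-force check of the layer partition and adjacency definitions.

    outside/surface/near-surface/core partition the lattice; a surface point
    has an outside face-neighbor; a near-surface point touches the surface
    layer but not the outside; a core point touches neither outside nor
    surface.  Off-grid neighbors count as outside.
    """
    n = labels.shape[0]

    def neighbor_labels(i, j, k):
        out = []
        for di, dj, dk in FACE_OFFSETS:
            a, b, c = i + di, j + dj, k + dk
            if 0 <= a < n and 0 <= b < n and 0 <= c < n:
                out.append(int(labels[a, b, c]))
            else:
                out.append(int(Layer.OUTSIDE))
        return out

    assert set(np.unique(labels)).issubset({0, 1, 2, 3})
    for i, j, k in zip(*np.nonzero(labels)):
        lab = int(labels[i, j, k])
        nbrs = neighbor_labels(i, j, k)
        if lab == Layer.SURFACE:
            assert Layer.OUTSIDE in nbrs, f"surface point {(i, j, k)} has no outside neighbor"
        elif lab == Layer.NEAR_SURFACE:
            assert Layer.OUTSIDE not in nbrs, f"near-surface point {(i, j, k)} touches outside"
            assert Layer.SURFACE in nbrs, f"near-surface point {(i, j, k)} has no surface neighbor"
        elif lab == Layer.CORE:
            assert Layer.OUTSIDE not in nbrs and Layer.SURFACE not in nbrs, (
                f"core point {(i, j, k)} touches outside or surface"
            )


def naive_neighbor_sums(labels, include_self=True):
    """Triple-loop oracle for the exponential neighbor sums of the score grids.

    Returns (s1, s3): the +-1 box exp(-r^2) sum and the +-3 box
    exp(-(r-1)^2) sum over near-surface/core points, r in index units.
    """
    n = labels.shape[0]
    occupied = (labels == Layer.NEAR_SURFACE) | (labels == Layer.CORE)
    s1 = np.zeros(labels.shape)
    s3 = np.zeros(labels.shape)
    for i in range(n):
        for j in range(n):
            for k in range(n):
                for reach, out, fn in (
                    (1, s1, lambda r2: np.exp(-r2)),
                    (3, s3, lambda r2: np.exp(-((np.sqrt(r2) - 1.0) ** 2))),
                ):
                    acc = 0.0
                    for di in range(-reach, reach + 1):
                        for dj in range(-reach, reach + 1):
                            for dk in range(-reach, reach + 1):
                                a, b, c = i + di, j + dj, k + dk
                                if not (0 <= a < n and 0 <= b < n and 0 <= c < n):
                                    continue
                                if not occupied[a, b, c]:
                                    continue
                                if reach == 1 and not include_self and (di, dj, dk) == (0, 0, 0):
                                    continue
                                acc += fn(di * di + dj * dj + dk * dk)
                    out[i, j, k] = acc
    return s1, s3
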