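"""Deterministic quasi-uniform sampling of rotation space.

Orientations are parameterized as z-y-z Euler triples (alpha, beta, gamma in
degrees).  For an angular interval D the sampler covers the sphere of ligand
axis directions with K = round(4*pi / D_rad^2) points of a Fibonacci spiral
(one point per D^2 of solid angle) and combines each direction with
M = round(360 / D) spin angles.  At the default 15 degree interval this
yields K = 183 directions x M = 24 spins = 4392 orientations.

The point set is fully deterministic: no seed is involved, and the first
entry is always the identity orientation (north-pole direction, zero spin).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "EulerTriple",
    "RotationSet",
    "generate_rotation_set",
    "rotation_matrix",
    "apply_rotation",
]

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class EulerTriple:
    """z-y-z Euler angles in degrees: alpha, gamma in [0, 360), beta in [0, 180]."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not (0 <= self.alpha < 360 and 0 <= self.beta <= 180 and 0 <= self.gamma < 360):
            raise ValueError(f"Euler triple out of range: {self}")


@dataclass(frozen=True)
class RotationSet:
    """Ordered, duplicate-free list of Euler triples at a fixed interval."""

    interval: float
    entries: tuple[EulerTriple, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[EulerTriple]:
        return iter(self.entries)

    def __getitem__(self, i: int) -> EulerTriple:
        return self.entries[i]

    def directions(self) -> np.ndarray:
        """Unit vectors (K*M, 3): image of +z under each rotation."""
        mats = np.array([rotation_matrix(e) for e in self.entries])
        return mats[:, :, 2]

    def to_tsv(self, path: str | Path) -> None:
        lines = ["index\talpha\tbeta\tgamma"]
        for i, e in enumerate(self.entries):
            lines.append(f"{i}\t{e.alpha:.6f}\t{e.beta:.6f}\t{e.gamma:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")


def sphere_covering(k: int) -> np.ndarray:
    """K quasi-uniform unit vectors (Fibonacci spiral, poles included)."""
    i = np.arange(k, dtype=float)
    if k == 1:
        z = np.array([1.0])
    else:
        z = 1.0 - 2.0 * i / (k - 1)
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.mod(i * _GOLDEN_ANGLE, 2 * math.pi)
    # the azimuth is degenerate at the poles; pin it for reproducibility
    phi[np.isclose(np.abs(z), 1.0)] = 0.0
    return np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )


def generate_rotation_set(interval: float) -> RotationSet:
    """Uniformly distributed Euler-angle triples at the given interval (deg).

    ``interval`` must lie in (0, 90].  The entry count is
    round(4*pi/interval_rad^2) * round(360/interval); 4392 at 15 degrees.
    """
    if not 0 < interval <= 90:
        raise ValueError(f"angular interval must be in (0, 90] degrees, got {interval}")
    d_rad = math.radians(interval)
    k = round(4 * math.pi / d_rad**2)
    m = round(360.0 / interval)
    dirs = sphere_covering(k)
    entries = []
    for d in dirs:
        beta = math.degrees(math.acos(np.clip(d[2], -1.0, 1.0)))
        alpha = math.degrees(math.atan2(d[1], d[0])) % 360.0
        if beta in (0.0, 180.0):
            alpha = 0.0
        for j in range(m):
            gamma = (j * 360.0 / m) % 360.0
            entries.append(EulerTriple(alpha=alpha, beta=beta, gamma=gamma))
    return RotationSet(interval=float(interval), entries=tuple(entries))


def rotation_matrix(euler: EulerTriple) -> np.ndarray:
    """Orthonormal 3x3 matrix R = Rz(alpha) Ry(beta) Rz(gamma)."""
    return Rotation.from_euler(
        "ZYZ", [euler.alpha, euler.beta, euler.gamma], degrees=True
    ).as_matrix()


def apply_rotation(structure, matrix: np.ndarray, pivot: np.ndarray | None = None):
    """Rotate a structure rigidly about ``pivot`` (default: its centroid)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3) or not np.allclose(matrix @ matrix.T, np.eye(3), atol=1e-8):
        raise ValueError("rotation matrix must be 3x3 orthonormal")
    pivot = structure.centroid if pivot is None else np.asarray(pivot, dtype=float)
    pos = structure.positions
    return structure.with_positions((pos - pivot) @ matrix.T + pivot)
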