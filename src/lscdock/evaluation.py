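"""Pose quality: receptor superposition, ligand RMSD, hits and success rates.

A predicted complex is compared with the native one by (i) least-squares
superposing the predicted receptor onto the native receptor over paired
backbone atoms (Kabsch), (ii) applying that rigid transform to the
predicted ligand, and (iii) taking the root-mean-square deviation over
paired ligand C-alpha atoms.  A pose with ligand RMSD strictly below 10 A
counts as a hit; the success rate at K is the percentage of cases with at
least one hit among the top K ranked predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structures import Structure, select

__all__ = [
    "SuperpositionResult",
    "CaseResult",
    "BenchmarkSummary",
    "kabsch_superpose",
    "ligand_rmsd",
    "is_hit",
    "summarize",
    "HIT_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: Ligand-RMSD hit threshold in Angstrom (strict inequality).
HIT_THRESHOLD = 10.0


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform x -> rotation @ x + translation and its residual."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,), Angstrom
    rmsd: float

    def apply(self, positions: np.ndarray) -> np.ndarray:
        return positions @ self.rotation.T + self.translation


def kabsch_superpose(mobile: Structure, reference: Structure) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Atoms are paired by position in the list; counts must match.  Requires
    at least three non-collinear atoms for a well-defined rotation.
    """
    x = mobile.positions
    y = reference.positions
    if x.shape != y.shape:
        raise ValueError(f"atom count mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    if np.linalg.matrix_rank(x0, tol=1e-8) < 2:
        raise ValueError("superposition needs at least 3 non-collinear atoms")
    u, s, vt = np.linalg.svd(x0.T @ y0)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.diag([1.0, 1.0, d])
    rot = (u @ flip @ vt).T
    trans = yc - rot @ xc
    resid = x0 @ rot.T - y0
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def _atom_key(atom) -> tuple:
    return (atom.chain_id, atom.residue_number, atom.atom_name)


def _paired_indices(a: Structure, b: Structure) -> tuple[list[int], list[int]]:
    """Pair atoms by (chain, residue number, atom name); unmatched dropped."""
    index_a = {_atom_key(at): i for i, at in enumerate(a.atoms)}
    ia, ib = [], []
    for i, at in enumerate(b.atoms):
        j = index_a.get(_atom_key(at))
        if j is not None:
            ia.append(j)
            ib.append(i)
    dropped = (len(a) - len(ia)) + (len(b) - len(ib))
    if dropped:
        logger.info("atom pairing dropped %d unmatched atoms", dropped)
    return ia, ib


def _paired_positions(a: Structure, b: Structure) -> tuple[np.ndarray, np.ndarray]:
    ia, ib = _paired_indices(a, b)
    if not ia:
        raise ValueError("no common atoms between structures")
    return a.positions[ia], b.positions[ib]


def ligand_rmsd(
    predicted: tuple[Structure, Structure], native: tuple[Structure, Structure]
) -> float:
    """C-alpha ligand RMSD after receptor backbone superposition (Angstrom)."""
    pred_rec, pred_lig = predicted
    nat_rec, nat_lig = native
    rec_mob, rec_ref = _paired_positions(select(pred_rec, "backbone"), select(nat_rec, "backbone"))
    sup = kabsch_superpose(_as_structure(rec_mob), _as_structure(rec_ref))
    lig_pred, lig_nat = _paired_positions(select(pred_lig, "calpha"), select(nat_lig, "calpha"))
    if lig_pred.shape[0] == 0:
        raise ValueError("no common ligand C-alpha atoms")
    moved = sup.apply(lig_pred)
    return float(np.sqrt(np.mean(np.sum((moved - lig_nat) ** 2, axis=1))))


def _as_structure(positions: np.ndarray) -> Structure:
    """Anonymous structure wrapper so kabsch_superpose can take raw coordinates."""
    from .structures import Atom

    atoms = [
        Atom(atom_name="CA", element="C", residue_name="GLY", residue_number=i + 1,
             chain_id="A", position=p)
        for i, p in enumerate(positions)
    ]
    return Structure(atoms=atoms)


def is_hit(lrmsd: float, threshold: float = HIT_THRESHOLD) -> bool:
    """Strict threshold: a pose at exactly ``threshold`` is not a hit."""
    if lrmsd < 0:
        raise ValueError("ligand RMSD cannot be negative")
    return lrmsd < threshold


@dataclass(frozen=True)
class CaseResult:
    """Ranked ligand-RMSD trace of one docking case."""

    case_id: str
    lrmsd_by_rank: tuple[float, ...]
    category: str = "unlabeled"

    def hits_in_top(self, k: int, threshold: float = HIT_THRESHOLD) -> int:
        return sum(1 for v in self.lrmsd_by_rank[:k] if is_hit(v, threshold))

    def first_hit_rank(self, threshold: float = HIT_THRESHOLD) -> int | None:
        for rank, v in enumerate(self.lrmsd_by_rank):
            if is_hit(v, threshold):
                return rank + 1  # 1-based
        return None


@dataclass(frozen=True)
class BenchmarkSummary:
    """Success rate (%) and mean hits per case at each requested K."""

    k_values: tuple[int, ...]
    success_rate: dict[int, float]
    mean_hits: dict[int, float]
    n_cases: int
    by_category: dict[str, "BenchmarkSummary"] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"# {self.n_cases} cases"]
        header = "group\tmetric\t" + "\t".join(f"top{k}" for k in self.k_values)
        lines.append(header)

        def rows(tag: str, summary: "BenchmarkSummary"):
            sr = "\t".join(f"{summary.success_rate[k]:.2f}" for k in summary.k_values)
            mh = "\t".join(f"{summary.mean_hits[k]:.2f}" for k in summary.k_values)
            return [f"{tag}\tsuccess_rate\t{sr}", f"{tag}\tmean_hits\t{mh}"]

        lines += rows("all", self)
        for cat in sorted(self.by_category):
            lines += rows(cat, self.by_category[cat])
        Path(path).write_text("\n".join(lines) + "\n")


def summarize(
    results: list[CaseResult],
    k_values: list[int],
    threshold: float = HIT_THRESHOLD,
    by_category: bool = True,
) -> BenchmarkSummary:
    """Aggregate per-case RMSD traces into success rates and mean hit counts."""
    if not results:
        raise ValueError("no case results to summarize")
    if any(k < 1 for k in k_values):
        raise ValueError("top-K values must be >= 1")

    def build(cases: list[CaseResult], nested: bool) -> BenchmarkSummary:
        success, mean_hits = {}, {}
        for k in k_values:
            with_hit = sum(1 for c in cases if c.hits_in_top(k, threshold) > 0)
            success[k] = 100.0 * with_hit / len(cases)
            mean_hits[k] = float(np.mean([c.hits_in_top(k, threshold) for c in cases]))
        cats = {}
        if nested:
            for cat in sorted({c.category for c in cases}):
                sub = [c for c in cases if c.category == cat]
                cats[cat] = build(sub, nested=False)
        return BenchmarkSummary(
            k_values=tuple(k_values),
            success_rate=success,
            mean_hits=mean_hits,
            n_cases=len(cases),
            by_category=cats,
        )

    return build(list(results), nested=by_category)
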