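"""Exhaustive translational search of the shape-complementarity score.

For one ligand orientation the score of every circular lattice shift
(o, p, q) is

    E(o, p, q) = Re[ sum_{l,m,n} R(l, m, n) * L(l+o, m+p, n+q) ]

with all indices wrapped modulo N.  The full map is obtained in
O(N^3 log N^3) through the cross-correlation theorem: with hat the discrete
Fourier transform, E = Re[ IDFT( conj(DFT(conj(R))) * DFT(L) ) ].  The FFT
realization is verified against the direct triple sum (``direct_score``) in
the test suite rather than assumed.

Sign conventions
----------------
The grid assignments make the raw correlation behave like an interaction
*energy*: receptor surface points carry a negative real weight (attraction
of the partner's interior) while overlapping imaginary parts of opposite
sign produce large positive (repulsive) contributions, up to +99 for a
core-on-core clash.  Two ranking modes are provided:

``repulsive_core``
    scores with the *negated* receptor field, i.e. ranks by -E descending
    (equivalently: minimizes the printed correlation).  Under this mode a
    clash of the atom-occupied layers scores strongly negative (core-core
    -99) and ligand interior sitting on the receptor surface layer scores
    positive, so maximizing the score favors snug interfaces.  This is the
    default.

``as_printed``
    ranks by the raw correlation E descending.  Because overlapping
    imaginary parts then *reward* interpenetration, this mode tends to bury
    the ligand inside the receptor; it is retained so the arithmetic of the
    published equations can be audited directly (see ``sanity_audit``).

A map index (o, p, q) pairs receptor point l with ligand reference point
l + o, i.e. it realizes the ligand *displaced by -(o, p, q)* lattice steps.
Predictions therefore record the physical displacement (-o mod N, ...), so
that ``translation = unwrap(shift) * spacing`` places the ligand where the
score was measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import fft as sp_fft

from . import __version__
from .gridding import (
    ComplexGrid,
    GridSpec,
    Layer,
    _classify_arrays,
    choose_grid,
    ligand_grid,
    receptor_grid,
)
from .params import DockParams
from .rotations import EulerTriple, generate_rotation_set, rotation_matrix
from .structures import Structure

__all__ = [
    "TranslationScoreMap",
    "Prediction",
    "PredictionList",
    "AuditReport",
    "direct_score",
    "correlate",
    "best_translation",
    "dock",
    "realize_pose",
    "sanity_audit",
    "resolve_sign_mode",
]


@dataclass(frozen=True)
class TranslationScoreMap:
    """Real score for every circular shift (o, p, q) of one orientation."""

    spec: GridSpec
    scores: np.ndarray  # (n, n, n) float64


@dataclass(frozen=True)
class Prediction:
    """One ranked pose: a rotation plus its best lattice displacement."""

    rotation_index: int
    euler: EulerTriple
    shift: tuple[int, int, int]  # ligand displacement in lattice steps, in [0, N)^3
    translation: np.ndarray  # unwrapped physical displacement, Angstrom
    score: float
    spacing: float


@dataclass(frozen=True)
class PredictionList:
    """Score-ranked predictions of a global run (one per orientation)."""

    predictions: tuple[Prediction, ...]
    params: DockParams
    sign_mode_used: str
    spec: GridSpec
    receptor_centroid: np.ndarray
    receptor_label: str = ""
    ligand_label: str = ""

    def __len__(self) -> int:
        return len(self.predictions)

    def __getitem__(self, i: int) -> Prediction:
        return self.predictions[i]

    def __iter__(self):
        return iter(self.predictions)

    def realize(self, ligand: Structure, rank: int) -> Structure:
        """Ligand coordinates of the pose at ``rank``, in the receptor frame."""
        return realize_pose(
            ligand,
            self.predictions[rank],
            self.params,
            receptor_centroid=self.receptor_centroid,
        )

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"# lscdock {__version__} predictions"]
        echo = dict(self.params.echo())
        echo["sign_mode"] = self.sign_mode_used
        echo["grid_n"] = self.spec.n
        for key in sorted(echo):
            lines.append(f"# {key} = {echo[key]}")
        lines.append("rank\trotation_index\talpha\tbeta\tgamma\ttx\tty\ttz\tscore")
        for rank, p in enumerate(self.predictions):
            tx, ty, tz = p.translation
            lines.append(
                f"{rank}\t{p.rotation_index}\t{p.euler.alpha:.6f}\t{p.euler.beta:.6f}"
                f"\t{p.euler.gamma:.6f}\t{tx:.6f}\t{ty:.6f}\t{tz:.6f}\t{p.score:.6f}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def _check_same_spec(a: ComplexGrid, b: ComplexGrid) -> None:
    if a.spec.n != b.spec.n or a.spec.spacing != b.spec.spacing:
        raise ValueError("receptor and ligand grids must share the same GridSpec")


def direct_score(receptor: ComplexGrid, ligand: ComplexGrid, shift) -> float:
    """Direct O(N^3) evaluation of E at one shift (the brute-force oracle)."""
    _check_same_spec(receptor, ligand)
    o, p, q = (int(s) for s in shift)
    rolled = np.roll(ligand.values, shift=(-o, -p, -q), axis=(0, 1, 2))
    return float(np.sum(receptor.values * rolled).real)


def correlate(receptor: ComplexGrid, ligand: ComplexGrid) -> TranslationScoreMap:
    """All-shift score map via 3D FFT (matches ``direct_score`` everywhere)."""
    _check_same_spec(receptor, ligand)
    r_hat_neg = np.conj(sp_fft.fftn(np.conj(receptor.values)))  # \hat{R}(-k)
    scores = sp_fft.ifftn(r_hat_neg * sp_fft.fftn(ligand.values)).real
    return TranslationScoreMap(spec=receptor.spec, scores=np.ascontiguousarray(scores))


def best_translation(score_map: TranslationScoreMap) -> tuple[tuple[int, int, int], float]:
    """Maximal-score shift; ties resolve to the lexicographically smallest."""
    scores = score_map.scores
    flat = int(np.argmax(scores))  # first occurrence in C order == lexicographic min
    shift = tuple(int(i) for i in np.unravel_index(flat, scores.shape))
    return shift, float(scores[shift])


def _unwrap(shift: tuple[int, int, int], n: int) -> np.ndarray:
    return np.array([s if s <= n // 2 else s - n for s in shift], dtype=float)


def realize_pose(
    ligand: Structure,
    prediction: Prediction,
    params: DockParams,
    receptor_centroid=(0.0, 0.0, 0.0),
) -> Structure:
    """Ligand coordinates for a prediction, expressed in the receptor frame.

    The ligand is rotated about its centroid by the prediction's Euler
    triple, then its centroid is placed at ``receptor_centroid`` (the
    gridding reference) plus the unwrapped physical translation.
    """
    if params.spacing != prediction.spacing:
        raise ValueError(
            f"prediction was produced at spacing {prediction.spacing}, "
            f"params specify {params.spacing}"
        )
    mat = rotation_matrix(prediction.euler)
    local = ligand.positions - ligand.centroid
    target = np.asarray(receptor_centroid, dtype=float) + prediction.translation
    return ligand.with_positions(local @ mat.T + target)


def dock(receptor: Structure, ligand: Structure, params: DockParams | None = None) -> PredictionList:
    """Global rigid-body search: every orientation x every lattice shift.

    The receptor is gridded once; for each orientation of the rotation set
    the ligand is rotated about its centroid, re-gridded, correlated with
    the receptor field, and its single best translation retained.  The
    result holds one prediction per orientation, sorted by score descending
    (ties by rotation index).
    """
    params = params or DockParams()
    mode = resolve_sign_mode(params.sign_mode)
    for st, name in ((receptor, "receptor"), (ligand, "ligand")):
        if not st.has_radii():
            raise ValueError(f"{name} has unassigned VDW radii; run assign_radii first")

    spec = choose_grid(receptor, ligand, spacing=params.spacing, cap=params.grid_cap)
    n = spec.n

    rec_pos = receptor.positions - receptor.centroid  # centroid -> grid center (origin frame 0)
    rec_layers = _classify_arrays(rec_pos, receptor.radii, spec, params.connectivity)
    r_field = receptor_grid(rec_layers, include_self=params.include_self).values
    if mode == "repulsive_core":
        r_field = -r_field
    r_hat_neg = np.conj(sp_fft.fftn(np.conj(r_field)))

    lig_local = ligand.positions - ligand.centroid
    lig_radii = ligand.radii
    rotations = generate_rotation_set(params.interval)

    predictions: list[Prediction] = []
    for ridx, euler in enumerate(rotations):
        mat = rotation_matrix(euler)
        rotated = lig_local @ mat.T
        layers = _classify_arrays(rotated, lig_radii, spec, params.connectivity)
        l_field = ligand_grid(layers, include_self=params.include_self).values
        smap = sp_fft.ifftn(r_hat_neg * sp_fft.fftn(l_field)).real
        flat = int(np.argmax(smap))
        map_shift = np.unravel_index(flat, smap.shape)
        score = float(smap[map_shift])
        # map index (o,p,q) realizes the ligand displaced by -(o,p,q) steps
        disp = tuple(int((-s) % n) for s in map_shift)
        predictions.append(
            Prediction(
                rotation_index=ridx,
                euler=euler,
                shift=disp,
                translation=_unwrap(disp, n) * spec.spacing,
                score=score,
                spacing=spec.spacing,
            )
        )

    predictions.sort(key=lambda p: (-p.score, p.rotation_index))
    return PredictionList(
        predictions=tuple(predictions),
        params=params,
        sign_mode_used=mode,
        spec=spec,
        receptor_centroid=receptor.centroid,
        receptor_label=receptor.label,
        ligand_label=ligand.label,
    )


# ---------------------------------------------------------------------------
# Sign-mode audit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AuditReport:
    """Outcome of redocking the deterministic knob/socket fixture."""

    sign_mode: str
    passed: bool
    contact_count: int  # receptor-surface cells overlapped by ligand near-surface/core
    clash_count: int  # receptor-core cells overlapped by ligand core
    ligand_core_count: int
    top_score: float

    CLASH_FRACTION_LIMIT = 0.02


_audit_cache: dict[tuple, AuditReport] = {}
_auto_choice: str | None = None


def sanity_audit(
    sign_mode: str,
    interval: float = 30.0,
    seed: int = 1,
    n_receptor: int = 300,
    n_ligand: int = 80,
    knob_radius: float = 6.0,
) -> AuditReport:
    """Redock the knob/socket fixture and check the global best pose.

    PASS means the top-scoring pose touches the receptor (some receptor
    surface cells overlapped by ligand near-surface/core) without deep
    interpenetration (receptor-core/ligand-core overlaps at most 2% of the
    ligand's core cells).  The verdict is reported, never asserted here.
    """
    if sign_mode not in ("as_printed", "repulsive_core"):
        raise ValueError("sanity_audit requires an explicit sign mode")
    key = (sign_mode, interval, seed, n_receptor, n_ligand, knob_radius)
    if key in _audit_cache:
        return _audit_cache[key]

    from .fixtures import make_knob_socket
    from .structures import RadiiTable, assign_radii

    toy = make_knob_socket(
        seed=seed, n_receptor=n_receptor, n_ligand=n_ligand, knob_radius=knob_radius
    )
    table = RadiiTable.default_table()
    rec = assign_radii(toy.receptor, table)
    lig = assign_radii(toy.ligand, table)
    params = DockParams(interval=interval, sign_mode=sign_mode)
    preds = dock(rec, lig, params)
    pose = preds.realize(lig, 0)

    spec = preds.spec
    rec_centroid = rec.centroid
    rec_lab = _classify_arrays(rec.positions - rec_centroid, rec.radii, spec).labels
    pose_lab = _classify_arrays(pose.positions - rec_centroid, lig.radii, spec).labels

    pose_occ = (pose_lab == Layer.NEAR_SURFACE) | (pose_lab == Layer.CORE)
    contact = int(np.count_nonzero((rec_lab == Layer.SURFACE) & pose_occ))
    clash = int(np.count_nonzero((rec_lab == Layer.CORE) & (pose_lab == Layer.CORE)))
    lig_core = int(np.count_nonzero(pose_lab == Layer.CORE))
    passed = contact > 0 and clash <= AuditReport.CLASH_FRACTION_LIMIT * max(1, lig_core)
    report = AuditReport(
        sign_mode=sign_mode,
        passed=passed,
        contact_count=contact,
        clash_count=clash,
        ligand_core_count=lig_core,
        top_score=preds[0].score,
    )
    _audit_cache[key] = report
    return report


def resolve_sign_mode(sign_mode: str) -> str:
    """Resolve ``"auto"`` to the sign mode that passes the sanity audit."""
    global _auto_choice
    if sign_mode != "auto":
        return sign_mode
    if _auto_choice is None:
        for candidate in ("repulsive_core", "as_printed"):
            if sanity_audit(candidate).passed:
                _auto_choice = candidate
                break
        else:
            import warnings

            warnings.warn("no sign mode passed the sanity audit; defaulting to repulsive_core")
            _auto_choice = "repulsive_core"
    return _auto_choice
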