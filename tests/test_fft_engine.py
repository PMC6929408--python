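import numpy as np
import pytest

from lscdock.fft_engine import (
    best_translation,
    correlate,
    direct_score,
    dock,
    realize_pose,
    sanity_audit,
)
from lscdock.gridding import ComplexGrid, GridSpec, _classify_arrays, ligand_grid
from lscdock.params import DockParams

from conftest import make_structure


def delta_grid(n, index, value, side):
    spec = GridSpec.centered(1.2, n)
    v = np.zeros((n, n, n), dtype=np.complex128)
    v[index] = value
    return ComplexGrid(spec=spec, values=v, side=side)


def random_grid_pair(rng, n):
    spec = GridSpec.centered(1.2, n)
    mk = lambda: rng.normal(size=(n, n, n)) + 1j * rng.normal(size=(n, n, n))
    return (
        ComplexGrid(spec=spec, values=mk(), side="receptor"),
        ComplexGrid(spec=spec, values=mk(), side="ligand"),
    )


class TestDirectScore:
    def test_core_core_pairing_arithmetic(self):
        # Re[(-1+10J)(1-10J)] = 99: the literal equations reward a deep clash
        r = delta_grid(4, (1, 2, 3), -1 + 10j, "receptor")
        l = delta_grid(4, (2, 1, 0), 1 - 10j, "ligand")
        shift = ((2 - 1) % 4, (1 - 2) % 4, (0 - 3) % 4)
        assert direct_score(r, l, shift) == pytest.approx(99.0)

    def test_core_surface_pairing_arithmetic(self):
        r = delta_grid(4, (0, 0, 0), -1 + 10j, "receptor")
        l = delta_grid(4, (0, 0, 0), 1 - 1j, "ligand")
        assert direct_score(r, l, (0, 0, 0)) == pytest.approx(9.0)

    def test_zero_ligand_scores_zero_everywhere(self):
        rng = np.random.default_rng(0)
        r, _ = random_grid_pair(rng, 4)
        l = delta_grid(4, (0, 0, 0), 0.0, "ligand")
        for shift in [(0, 0, 0), (1, 2, 3), (3, 3, 3)]:
            assert direct_score(r, l, shift) == 0.0

    def test_mismatched_specs_rejected(self):
        r = delta_grid(4, (0, 0, 0), 1.0, "receptor")
        l = delta_grid(6, (0, 0, 0), 1.0, "ligand")
        with pytest.raises(ValueError):
            direct_score(r, l, (0, 0, 0))


class TestCorrelate:
    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_matches_direct_sum_oracle(self, n):
        rng = np.random.default_rng(n)
        r, l = random_grid_pair(rng, n)
        m = correlate(r, l)
        scale = 1.0 + np.abs(m.scores).max()
        for o in range(n):
            for p in range(n):
                for q in range(n):
                    assert m.scores[o, p, q] == pytest.approx(
                        direct_score(r, l, (o, p, q)), abs=1e-9 * scale
                    )

    def test_delta_peak_carries_over(self):
        r = delta_grid(4, (1, 2, 3), -1 + 10j, "receptor")
        l = delta_grid(4, (2, 1, 0), 1 - 10j, "ligand")
        shift, score = best_translation(correlate(r, l))
        assert shift == (1, 3, 1)
        assert score == pytest.approx(99.0)

    def test_all_zero_grids(self):
        r = delta_grid(4, (0, 0, 0), 0.0, "receptor")
        l = delta_grid(4, (0, 0, 0), 0.0, "ligand")
        assert np.allclose(correlate(r, l).scores, 0.0)

    def test_circular_shift_equivariance(self):
        rng = np.random.default_rng(42)
        r, l = random_grid_pair(rng, 6)
        base = correlate(r, l).scores
        v = (1, 4, 2)
        rolled = ComplexGrid(l.spec, np.roll(l.values, v, axis=(0, 1, 2)), "ligand")
        shifted = correlate(r, rolled).scores
        np.testing.assert_allclose(shifted, np.roll(base, v, axis=(0, 1, 2)), atol=1e-8)

    def test_conjugation_identity(self):
        # negating ligand imaginary parts is the same as conjugating the ligand:
        # Re[sum R * L~] == Re[sum R * conj(L)] at every shift
        rng = np.random.default_rng(9)
        r, l = random_grid_pair(rng, 4)
        neg = ComplexGrid(l.spec, np.conj(l.values), "ligand")
        for shift in [(0, 0, 0), (1, 0, 3), (2, 3, 1)]:
            o, p, q = shift
            rolled = np.roll(l.values, (-o, -p, -q), axis=(0, 1, 2))
            expect = float(np.sum(r.values * np.conj(rolled)).real)
            assert direct_score(r, neg, shift) == pytest.approx(expect)


class TestBestTranslation:
    def test_unique_maximum(self):
        m = correlate(*random_grid_pair(np.random.default_rng(1), 4))
        shift, score = best_translation(m)
        assert score == m.scores.max()
        assert m.scores[shift] == score

    def test_constant_map_tie_breaks_to_origin(self):
        spec = GridSpec.centered(1.2, 4)
        from lscdock.fft_engine import TranslationScoreMap

        m = TranslationScoreMap(spec=spec, scores=np.ones((4, 4, 4)))
        shift, score = best_translation(m)
        assert shift == (0, 0, 0)
        assert score == 1.0


@pytest.fixture(scope="module")
def small_dock(toy):
    """Coarse (60 degree) global run on the knob/socket fixture."""
    _, receptor, ligand = toy
    params = DockParams(interval=60.0)
    return receptor, ligand, params, dock(receptor, ligand, params)


class TestDock:
    def test_one_prediction_per_orientation_sorted(self, small_dock):
        _, _, params, preds = small_dock
        from lscdock.rotations import generate_rotation_set

        assert len(preds) == len(generate_rotation_set(params.interval))
        scores = [p.score for p in preds]
        assert scores == sorted(scores, reverse=True)
        assert len({p.rotation_index for p in preds}) == len(preds)

    def test_determinism(self, small_dock, toy, tmp_path):
        _, receptor, ligand = toy
        _, _, params, preds = small_dock
        again = dock(receptor, ligand, params)
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        preds.to_tsv(a)
        again.to_tsv(b)
        assert a.read_bytes() == b.read_bytes()

    def test_realized_pose_rescores_to_prediction(self, small_dock, toy):
        """Re-gridding the realized pose and scoring at zero shift must
        reproduce the prediction score (lattice translations only)."""
        _, receptor, ligand = toy
        _, _, params, preds = small_dock
        from lscdock.gridding import receptor_grid, _classify_arrays

        p = preds[0]
        pose = preds.realize(ligand, 0)
        spec = preds.spec
        rec_centroid = receptor.centroid
        rec_layers = _classify_arrays(receptor.positions - rec_centroid, receptor.radii, spec)
        r = receptor_grid(rec_layers)
        rv = ComplexGrid(spec, -r.values, "receptor")  # repulsive_core scoring field
        pose_layers = _classify_arrays(pose.positions - rec_centroid, ligand.radii, spec)
        l = ligand_grid(pose_layers)
        assert direct_score(rv, l, (0, 0, 0)) == pytest.approx(p.score, rel=1e-6)

    def test_unwrap_rule(self, small_dock):
        _, _, _, preds = small_dock
        n, h = preds.spec.n, preds.spec.spacing
        for p in preds:
            for s, t in zip(p.shift, p.translation):
                expect = (s if s <= n // 2 else s - n) * h
                assert t == pytest.approx(expect)

    def test_single_atom_pair_not_superposed(self, radii_table):
        from lscdock.structures import assign_radii

        rec = assign_radii(make_structure([[0.0, 0.0, 0.0]]), radii_table)
        lig = assign_radii(make_structure([[0.0, 0.0, 0.0]]), radii_table)
        preds = dock(rec, lig, DockParams(interval=90.0, sign_mode="repulsive_core"))
        top = preds[0]
        # superposition overlaps the occupied layers and scores negative;
        # the optimum must sit at a non-clashing placement
        assert top.score >= 0
        assert np.linalg.norm(top.translation) > 0

    def test_unassigned_radii_rejected(self):
        rec = make_structure([[0, 0, 0]], radius=np.nan)
        lig = make_structure([[0, 0, 0]])
        with pytest.raises(ValueError, match="radii"):
            dock(rec, lig, DockParams(interval=90.0))


class TestRealizePose:
    def test_zero_shift_identity_rotation(self, small_dock, toy):
        _, receptor, ligand = toy
        _, _, params, preds = small_dock
        from dataclasses import replace

        p = replace(
            preds[0],
            shift=(0, 0, 0),
            translation=np.zeros(3),
            euler=type(preds[0].euler)(0.0, 0.0, 0.0),
        )
        pose = realize_pose(ligand, p, params, receptor_centroid=receptor.centroid)
        np.testing.assert_allclose(pose.centroid, receptor.centroid, atol=1e-9)
        local = pose.positions - pose.centroid
        np.testing.assert_allclose(local, ligand.positions - ligand.centroid, atol=1e-9)

    def test_spacing_mismatch_rejected(self, small_dock, toy):
        _, _, _, preds = small_dock
        _, _, ligand = toy
        with pytest.raises(ValueError, match="spacing"):
            realize_pose(ligand, preds[0], DockParams(spacing=2.0))


class TestSanityAudit:
    def test_repulsive_core_passes(self):
        report = sanity_audit("repulsive_core")
        assert report.passed
        assert report.contact_count > 0
        assert report.clash_count <= 0.02 * max(1, report.ligand_core_count)

    def test_as_printed_verdict_is_recorded_not_asserted(self):
        report = sanity_audit("as_printed")
        assert report.sign_mode == "as_printed"
        assert isinstance(report.passed, bool)

    def test_auto_mode_resolves_to_audited_mode(self):
        from lscdock.fft_engine import resolve_sign_mode

        assert resolve_sign_mode("auto") == "repulsive_core"
        assert resolve_sign_mode("as_printed") == "as_printed"

    def test_requires_explicit_mode(self):
        with pytest.raises(ValueError):
            sanity_audit("auto")
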