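"""Geometric metrics: oracles, rigid-body invariance, planted round-trips."""

import numpy as np
import pytest

from crkscreen import structmodel as sm
from crkscreen import synthetic_data as sd


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


@pytest.fixture
def standard_model():
    spec = sd.DimerFixtureSpec("Standard", 10, 4.8, 6, seed=7)
    return sd.make_dimer_fixture(spec)


class TestIO:
    def test_pdb_round_trip_coordinates_and_plddt(self, tmp_path, standard_model):
        model, _ = standard_model
        path = tmp_path / "m.pdb"
        sm.write_structure(model, path)
        back = sm.read_structure(path)
        assert [c.chain_id for c in back.chains] == ["A", "B"]
        for c0, c1 in zip(model.chains, back.chains):
            for r0, r1 in zip(c0.residues, c1.residues):
                for name, a0 in r0.atoms.items():
                    assert np.allclose(a0.xyz, r1.atoms[name].xyz, atol=1e-3)
                assert r1.bfactor == pytest.approx(r0.bfactor, abs=0.01)

    def test_unparsable_file_rejected(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("not a structure\n")
        with pytest.raises(Exception):
            sm.read_structure(bad)

    def test_pae_json_round_trip(self, tmp_path):
        pae = sd.make_pae_fixture(sd.PaeFixtureSpec(4, 6, 2.0, 5.0, 0.5, seed=3))
        path = tmp_path / "pae.json"
        sm.write_pae_json(pae, path)
        back = sm.read_pae(path, (4, 6))
        assert np.allclose(back.values, pae.values)

    def test_pae_plain_matrix(self, tmp_path):
        pae = sd.make_pae_fixture(sd.PaeFixtureSpec(3, 3, 2.0, 4.0, 0.0, seed=0))
        path = tmp_path / "pae.txt"
        np.savetxt(path, pae.values)
        back = sm.read_pae(path, (3, 3))
        assert np.allclose(back.values, pae.values)


class TestPlddt:
    @pytest.mark.parametrize(
        "value,expected",
        [(95, "very-high"), (90, "high"), (75, "high"), (70, "low"), (50, "low"), (49.9, "very-low")],
    )
    def test_class_boundaries(self, value, expected):
        assert sm.confidence_class(value) == expected

    def test_summary_mean_matches_oracle(self, standard_model):
        model, ann = standard_model
        table = sm.plddt_summary(model, ann)
        for c in model.chains:
            expected = np.mean([r.bfactor for r in c.residues])
            row = table[(table.chain == c.chain_id) & (table.region == "all")]
            assert row.mean_plddt.iloc[0] == pytest.approx(expected, abs=1e-9)
        assert set(table.region) == {"all", "DUF26-A", "DUF26-B"}

    def test_missing_plddt_rejected(self):
        res = sm.Residue(1, "ALA", {"CA": sm.Atom("CA", [0, 0, 0])}, bfactor=None)
        model = sm.StructureModel([sm.Chain("A", [res])])
        with pytest.raises(ValueError):
            sm.plddt_summary(model)


class TestIPae:
    def test_constant_cross_blocks(self):
        pae = sd.make_pae_fixture(sd.PaeFixtureSpec(5, 5, 2.0, 4.0, 0.0, seed=0))
        assert sm.compute_ipae(pae) == 4.0

    def test_unequal_blocks_average(self):
        values = np.full((10, 10), 2.0)
        values[:5, 5:] = 3.0
        values[5:, :5] = 5.0
        assert sm.compute_ipae(sm.PaeMatrix(values, (5, 5))) == 4.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(3, 12)), int(rng.integers(3, 12))
        values = rng.uniform(0, 31.75, size=(n1 + n2, n1 + n2))
        pae = sm.PaeMatrix(values, (n1, n2))
        total, count = 0.0, 0
        for i in range(n1):
            for j in range(n1, n1 + n2):
                total += values[i, j] + values[j, i]
                count += 2
        assert sm.compute_ipae(pae) == pytest.approx(total / count, abs=1e-12)


class TestInterface:
    def test_far_chains_have_empty_interface(self):
        model, _ = sd.make_dimer_fixture(sd.DimerFixtureSpec("Standard", 8, 50.0, 5, seed=1))
        res = sm.interface_residues(model)
        assert all(len(v) == 0 for v in res.values())

    def test_planted_contacts_recovered_exactly(self, fixture_grid):
        for spec in fixture_grid:
            model, _ = sd.make_dimer_fixture(spec)
            a, b, total = sm.interface_counts(model)
            assert a == spec.planted_contacts, spec
            assert b == spec.planted_contacts, spec

    def test_matches_brute_force_all_pairs(self, standard_model):
        model, _ = standard_model
        c1, c2 = model.chains
        expected = {c1.chain_id: set(), c2.chain_id: set()}
        for r1 in c1.residues:
            for r2 in c2.residues:
                for a1 in r1.atoms.values():
                    for a2 in r2.atoms.values():
                        if np.linalg.norm(a1.xyz - a2.xyz) <= 5.0:
                            expected[c1.chain_id].add(r1.index)
                            expected[c2.chain_id].add(r2.index)
        got = sm.interface_residues(model)
        assert {k: set(v) for k, v in got.items()} == expected

    def test_single_chain_rejected(self):
        model = sd.make_disulfide_fixture(2)
        with pytest.raises(ValueError):
            sm.interface_residues(model)


class TestDisulfides:
    def test_planted_pairs_all_bonded(self):
        model = sd.make_disulfide_fixture(6, seed=0)
        bonds = sm.detect_disulfides(model)
        assert len(bonds) == 6
        assert all(b.vicinal for b in bonds)
        assert all(b.distance == pytest.approx(2.05, abs=1e-9) for b in bonds)

    def test_each_cysteine_in_at_most_one_bond(self):
        model = sd.make_disulfide_fixture(4, seed=1)
        bonds = sm.detect_disulfides(model)
        partners = [(b.chain_a, b.res_a) for b in bonds] + [(b.chain_b, b.res_b) for b in bonds]
        assert len(partners) == len(set(partners))

    def test_separated_pair_not_bonded(self):
        residues = []
        for i, x in enumerate([0.0, 3.0], start=1):
            residues.append(
                sm.Residue(i, "CYS", {"CA": sm.Atom("CA", [x, 2, 0]), "SG": sm.Atom("SG", [x, 0, 0])})
            )
        model = sm.StructureModel([sm.Chain("A", residues)])
        assert sm.detect_disulfides(model) == []


class TestBetaLadder:
    def test_planted_ladder_recovered_at_exact_length(self, fixture_grid):
        for spec in fixture_grid:
            model, _ = sd.make_dimer_fixture(spec)
            segments = sm.cross_chain_beta_ladder(model)
            assert len(segments) == 1, spec
            assert segments[0].length == spec.planted_contacts, spec

    def test_far_chains_have_no_ladder(self):
        model, _ = sd.make_dimer_fixture(sd.DimerFixtureSpec("Standard", 8, 50.0, 5, seed=2))
        assert sm.cross_chain_beta_ladder(model) == []

    def test_matches_exhaustive_pairing_oracle(self, standard_model):
        model, _ = standard_model
        c1, c2 = model.chains
        pairs = set()
        for r1 in c1.residues:
            for r2 in c2.residues:
                for x, y in (("N", "O"), ("O", "N")):
                    p1, p2 = r1.atom_xyz(x), r2.atom_xyz(y)
                    if p1 is not None and p2 is not None and np.linalg.norm(p1 - p2) <= 3.5:
                        pairs.add((r1.index, r2.index))
        seg = sm.cross_chain_beta_ladder(model)[0]
        expected = {(i, i) for i in range(seg.range_a[0], seg.range_a[1] + 1)}
        assert pairs == expected


class TestOrientation:
    def test_grid_label_recovery_is_total(self, fixture_grid):
        for spec in fixture_grid:
            model, ann = sd.make_dimer_fixture(spec)
            call = sm.classify_orientation(model, ann)
            assert call.label == spec.orientation_label, spec

    def test_no_contacts_is_unclassified_with_reason(self):
        model, ann = sd.make_dimer_fixture(sd.DimerFixtureSpec("Standard", 8, 50.0, 5, seed=3))
        call = sm.classify_orientation(model, ann)
        assert call.label == "Unclassified"
        assert call.reason == "no cross-chain contacts"

    def test_rigid_transformation_invariance(self, fixture_grid):
        R = rotation_matrix([1, 2, 3], 1.1)
        t = np.array([10.0, -4.0, 2.5])
        for spec in fixture_grid[::4]:
            model, ann = sd.make_dimer_fixture(spec)
            moved = model.transformed(R, t)
            assert (
                sm.classify_orientation(moved, ann).label
                == sm.classify_orientation(model, ann).label
            )
            assert sm.interface_residues(moved) == sm.interface_residues(model)

    def test_axis_equivariance(self, standard_model):
        model, ann = standard_model
        R = rotation_matrix([0, 1, 0], 0.7)
        moved = model.transformed(R, np.zeros(3))
        axis0 = sm.domain_axis(model, "A", ann["A"])
        axis1 = sm.domain_axis(moved, "A", ann["A"])
        assert np.allclose(axis1, R @ axis0, atol=1e-9)


class TestKabsch:
    def test_identical_coordinates_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        assert sm.kabsch_rmsd(X, X) == pytest.approx(0.0, abs=1e-12)

    def test_rigidly_rotated_copy_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 3))
        R = rotation_matrix([1, 0, 1], 2.2)
        Y = X @ R.T + np.array([3.0, -1.0, 7.0])
        assert sm.kabsch_rmsd(X, Y) == pytest.approx(0.0, abs=1e-9)

    def test_displaced_point_matches_numerical_minimum(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3)) * 5
        Y = X.copy()
        Y[0] += np.array([2.0, 0.0, 0.0])
        got = sm.kabsch_rmsd(X, Y)

        # independent numerical minimisation over rotations+translations
        from scipy.optimize import minimize

        def loss(params):
            # rotation parametrized by a rotation vector
            angle = np.linalg.norm(params[:3])
            axis = params[:3] / angle if angle > 0 else np.array([1.0, 0, 0])
            R = rotation_matrix(axis, angle)
            t = params[3:]
            d = (X @ R.T + t) - Y
            return np.sqrt((d**2).sum() / len(X))

        best = min(
            minimize(loss, np.concatenate([v, np.zeros(3)]), method="Nelder-Mead",
                     options={"maxiter": 5000, "xatol": 1e-10, "fatol": 1e-12}).fun
            for v in (np.zeros(3), np.array([0.1, 0.1, 0.1]), np.array([0.0, 0.3, -0.2]))
        )
        assert got == pytest.approx(best, abs=1e-4)

    def test_shape_errors(self):
        with pytest.raises(ValueError):
            sm.kabsch_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))
        with pytest.raises(ValueError):
            sm.kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))
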