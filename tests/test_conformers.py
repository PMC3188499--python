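"""Threading, side-chain construction and rotamer packing."""
import itertools

import numpy as np
import pytest

import caaxbind as cb
from caaxbind._geometry import bond_length, dihedral
from caaxbind.conformers import PeptideSequence, RotamerLibrary, build_sidechain
from caaxbind.energy import ScoringModel
from caaxbind.topology import AA1_TO_3, n_chi


@pytest.fixture(scope="module")
def frame():
    return {
        "N": np.array([0.0, 0.0, 0.0]),
        "CA": np.array([1.458, 0.0, 0.0]),
        "C": np.array([2.0, 1.42, 0.0]),
    }


class TestPeptideSequence:
    def test_valid(self):
        seq = PeptideSequence("CVIM")
        assert seq.letters == "CVIM"
        assert seq.roles == ("C", "a1", "a2", "X")

    @pytest.mark.parametrize("bad", ["AVIM", "CVI", "CVIMM", "CBIM", "CXIM"])
    def test_invalid(self, bad):
        with pytest.raises(ValueError):
            PeptideSequence(bad)


class TestRotamerLibrary:
    def test_every_residue_covered(self):
        lib = RotamerLibrary.default()
        for aa, res3 in AA1_TO_3.items():
            rots = lib.rotamers(res3)
            assert len(rots) >= 1
            assert all(len(r) == n_chi(res3) for r in rots)

    def test_gly_ala_have_empty_tuple(self):
        lib = RotamerLibrary.default()
        assert lib.rotamers("GLY") == [()]
        assert lib.rotamers("ALA") == [()]

    def test_extra_chi_adds_subrotamers(self):
        lib = RotamerLibrary.default()
        base = lib.rotamers("LEU")
        expanded = lib.rotamers("LEU", extra_chi=True)
        assert len(expanded) == 9 * len(base)  # +-10 deg on chi1 and chi2
        chi1_values = {r[0] for r in expanded}
        for r in base:
            assert {r[0] - 10.0, r[0], r[0] + 10.0} <= chi1_values


class TestBuildSidechain:
    def test_ala_single_cb_at_tetrahedral_position(self, frame):
        out = build_sidechain("ALA", frame, ())
        assert list(out) == ["CB"]
        assert bond_length(frame["CA"], out["CB"]) == pytest.approx(1.53, abs=0.01)

    def test_chi_construction_measurement_inverse(self, frame):
        out = build_sidechain("VAL", frame, (180.0,))
        chi1 = dihedral(frame["N"], frame["CA"], out["CB"], out["CG1"])
        assert chi1 == pytest.approx(180.0, abs=1e-6)

    def test_leu_rotamers_differ_geometrically(self, frame):
        a = build_sidechain("LEU", frame, (-60.0, 180.0))
        b = build_sidechain("LEU", frame, (-60.0, -60.0))
        assert bond_length(a["CD1"], b["CD1"]) > 1.0

    def test_wrong_chi_count_rejected(self, frame):
        with pytest.raises(ValueError):
            build_sidechain("VAL", frame, (60.0, 60.0))

    @pytest.mark.parametrize("res3", sorted(AA1_TO_3.values()))
    def test_all_residues_buildable(self, frame, res3):
        lib = RotamerLibrary.default()
        out = build_sidechain(res3, frame, lib.rotamers(res3)[0])
        from caaxbind.topology import sidechain_atom_names

        assert list(out) == sidechain_atom_names(res3)
        for xyz in out.values():
            assert np.all(np.isfinite(xyz))


class TestThreading:
    def test_identity_threading_preserves_backbone_exactly(
        self, toy_template, native_pose
    ):
        for i, res in enumerate(toy_template.peptide):
            names = ["N", "CA", "C", "O"] + (["OXT"] if i == 3 else [])
            for nm in names:
                idx = native_pose.atom_index(("pep", i, nm))
                assert np.array_equal(native_pose.coords[idx], res.atom(nm).xyz)

    def test_threading_replaces_residue_types(self, toy_template):
        pose = cb.thread_sequence(toy_template, "CVIM")
        types = [pose.residues[ri].type3 for ri in pose.peptide_residue_indices]
        assert types == ["CYS", "VAL", "ILE", "MET"]
        # backbone unchanged
        for i, res in enumerate(toy_template.peptide):
            idx = pose.atom_index(("pep", i, "CA"))
            assert np.array_equal(pose.coords[idx], res.atom("CA").xyz)

    def test_non_cys_start_rejected(self, toy_template):
        with pytest.raises(ValueError):
            cb.thread_sequence(toy_template, "AVIM")

    def test_rebuild_with_unchanged_state_is_identity(self, native_pose):
        rebuilt = native_pose.rebuild()
        assert np.abs(rebuilt - native_pose.base_coords).max() < 1e-9


class TestPacking:
    def _brute_force(self, pose, position, efn, lib):
        """Explicit enumeration of full-pose energies over one position."""
        res3 = pose.sequence.type3(position)
        model = ScoringModel(pose, efn)
        best_chi, best_e = None, np.inf
        for chis in lib.rotamers(res3):
            trial = pose.copy()
            trial.set_dofs({("pchi", position, k): c
                            for k, c in enumerate(chis, start=1)})
            e = model.total(trial.coords)
            if e < best_e - 1e-12:
                best_chi, best_e = chis, e
        return best_chi, best_e

    def test_single_position_matches_brute_force(self, toy_template, energy_fn):
        lib = RotamerLibrary.default()
        pose = cb.thread_sequence(toy_template, "CNLQ")
        packed = cb.pack_sidechains(pose, [2], energy_fn=energy_fn, seed=0)
        expected_chi, _ = self._brute_force(pose, 2, energy_fn, lib)
        assert packed.chi_state(2) == pytest.approx(expected_chi)

    def test_two_positions_match_brute_force(self, toy_template, energy_fn):
        lib = RotamerLibrary.default()
        pose = cb.thread_sequence(toy_template, "CNVS")
        packed = cb.pack_sidechains(pose, [2, 3], energy_fn=energy_fn, seed=0)
        model = ScoringModel(pose, energy_fn)
        best, best_e = None, np.inf
        for c2, c3 in itertools.product(
            lib.rotamers("VAL"), lib.rotamers("SER")
        ):
            trial = pose.copy()
            trial.set_dofs({("pchi", 2, 1): c2[0], ("pchi", 3, 1): c3[0]})
            e = model.total(trial.coords)
            if e < best_e - 1e-12:
                best, best_e = (c2, c3), e
        assert packed.chi_state(2) == pytest.approx(best[0])
        assert packed.chi_state(3) == pytest.approx(best[1])

    def test_exhaustive_path_is_seed_free(self, toy_template, energy_fn):
        pose = cb.thread_sequence(toy_template, "CNVS")
        a = cb.pack_sidechains(pose, [2, 3], energy_fn=energy_fn, seed=1)
        b = cb.pack_sidechains(pose, [2, 3], energy_fn=energy_fn, seed=999)
        assert np.array_equal(a.coords, b.coords)

    def test_no_rotatable_chis_independent_of_seed(self, toy_template, energy_fn):
        pose = cb.thread_sequence(toy_template, "CAAA")
        a = cb.pack_sidechains(pose, [1, 2, 3], energy_fn=energy_fn, seed=1)
        b = cb.pack_sidechains(pose, [1, 2, 3], energy_fn=energy_fn, seed=2)
        assert np.array_equal(a.coords, b.coords)

    def test_empty_flexible_set_returns_pose_unchanged(
        self, native_pose, energy_fn
    ):
        out = cb.pack_sidechains(native_pose, [], energy_fn=energy_fn, seed=0)
        assert np.array_equal(out.coords, native_pose.coords)

    def test_packing_never_increases_energy(self, toy_template, energy_fn):
        for seq in ("CVIM", "CRKD", "CNIQ"):
            pose = cb.thread_sequence(toy_template, seq)
            model = ScoringModel(pose, energy_fn)
            before = model.total(pose.coords)
            packed = cb.pack_sidechains(
                pose, [0, 1, 2, 3], energy_fn=energy_fn, seed=3
            )
            after = model.total(packed.coords)
            assert after <= before + 1e-9

    def test_annealing_path_near_exhaustive_optimum(self, toy_template, energy_fn):
        """Forcing the stochastic path on a small instance recovers the
        exhaustive answer (tables are identical; search differs)."""
        pose = cb.thread_sequence(toy_template, "CNLM")
        exh = cb.pack_sidechains(pose, [2, 3], energy_fn=energy_fn, seed=0)
        ann = cb.pack_sidechains(
            pose, [2, 3], energy_fn=energy_fn, seed=5, exhaustive_limit=1
        )
        model = ScoringModel(pose, energy_fn)
        assert model.total(ann.coords) <= model.total(exh.coords) + 1e-6
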