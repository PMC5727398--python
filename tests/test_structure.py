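"""Structure comparison: superposition, RMSD maps, dimer rise, footprints."""

import numpy as np
import pytest
import biotite.structure as struc
from scipy.spatial.transform import Rotation

from mtarch.lattice import LatticeSpec
from mtarch.structure import (
    AtomicModel,
    Selection,
    dimer_rise,
    fit_cylinder_axis,
    footprint,
    pair_residues,
    rmsd_map,
    superpose,
)
from mtarch.synth import build_lattice, write_lattice_pdb

_SEQ = ["ALA", "GLY", "SER", "LEU", "VAL", "THR", "TYR", "TRP", "PHE", "MET"]


def make_model(coords, chain="A", res_names=None, atom_names=None,
               res_ids=None, name="toy"):
    n = len(coords)
    a = struc.AtomArray(n)
    a.coord = np.asarray(coords, dtype=np.float32)
    a.chain_id = np.full(n, chain)
    a.res_id = np.asarray(res_ids) if res_ids is not None else np.arange(1, n + 1)
    a.res_name = np.asarray(res_names) if res_names is not None else np.asarray(
        (_SEQ * (n // len(_SEQ) + 1))[:n]
    )
    a.atom_name = np.asarray(atom_names) if atom_names is not None else np.full(
        n, "CA"
    )
    a.element = np.full(n, "C")
    return AtomicModel(a, name)


@pytest.fixture()
def ten_residue_model(rng):
    return make_model(rng.normal(scale=5.0, size=(10, 3)))


class TestSuperpose:
    def test_model_vs_itself_is_zero(self, ten_residue_model):
        _, rmsd = superpose(ten_residue_model, ten_residue_model)
        assert rmsd == pytest.approx(0.0, abs=1e-5)

    def test_rigid_copy_superposes_to_zero(self, ten_residue_model):
        R = Rotation.from_euler("xyz", [0.4, 1.1, -0.7]).as_matrix()
        moved = make_model(
            ten_residue_model.atoms.coord @ R.T + [10.0, -3.0, 7.0],
            res_names=ten_residue_model.atoms.res_name,
        )
        transform, rmsd = superpose(moved, ten_residue_model)
        assert rmsd == pytest.approx(0.0, abs=1e-5)
        fitted = moved.transformed(transform)
        assert np.allclose(
            fitted.atoms.coord, ten_residue_model.atoms.coord, atol=1e-4
        )

    def test_single_displaced_atom_unfitted_deviation(self):
        """With one of three atoms displaced by 1 A the frame-fixed RMSD is
        exactly 1/sqrt(3); a least-squares refit can only reduce it."""
        ref = make_model(
            [[0.0, 0, 0], [4, 0, 0], [2, 3, 0]], res_names=_SEQ[:3]
        )
        mob = make_model(
            [[0.0, 0, 1], [4, 0, 0], [2, 3, 0]], res_names=_SEQ[:3]
        )
        unfitted = rmsd_map(mob, ref)
        overall = np.sqrt(np.mean(unfitted["rmsd"] ** 2))
        assert overall == pytest.approx(1 / np.sqrt(3), abs=1e-6)
        _, fitted_rmsd = superpose(mob, ref)
        assert fitted_rmsd <= overall + 1e-9

    def test_optimal_fit_matches_kabsch_oracle(self, rng):
        """Independent oracle: scipy's rotation alignment on centred sets."""
        ref = make_model(rng.normal(scale=4.0, size=(10, 3)))
        mob = make_model(
            ref.atoms.coord + rng.normal(scale=0.6, size=(10, 3)),
            res_names=ref.atoms.res_name,
        )
        _, rmsd = superpose(mob, ref)
        a = mob.atoms.coord - mob.atoms.coord.mean(axis=0)
        b = ref.atoms.coord - ref.atoms.coord.mean(axis=0)
        rot, rssd = Rotation.align_vectors(b, a)
        assert rmsd == pytest.approx(rssd / np.sqrt(len(a)), abs=1e-5)

    def test_core_selection_restricts_fit(self, rng):
        ref = make_model(rng.normal(scale=5.0, size=(10, 3)))
        coords = ref.atoms.coord.copy()
        coords[5:] += [3.0, 0, 0]  # displace the non-core half
        mob = make_model(coords, res_names=ref.atoms.res_name)
        _, core_rmsd = superpose(mob, ref, core=Selection(res_range=(1, 5)))
        assert core_rmsd == pytest.approx(0.0, abs=1e-5)

    def test_unpairable_core_reports_residues(self, ten_residue_model):
        with pytest.raises(ValueError, match="fewer than 3"):
            superpose(
                ten_residue_model, ten_residue_model,
                core=Selection(res_range=(100, 120)),
            )


class TestRmsdMap:
    def test_identical_models_all_zero(self, ten_residue_model):
        table = rmsd_map(ten_residue_model, ten_residue_model)
        assert len(table) == 10
        assert table["rmsd"].max() == 0.0

    def test_pairing_survives_renumbering(self, ten_residue_model):
        """Residue pairing is by sequence alignment, not numbering."""
        renumbered = make_model(
            ten_residue_model.atoms.coord,
            res_names=ten_residue_model.atoms.res_name,
            res_ids=np.arange(101, 111),
        )
        pairs = pair_residues(renumbered, ten_residue_model)
        assert [(m, r) for _, m, _, r in pairs] == [
            (101 + k, 1 + k) for k in range(10)
        ]
        table = rmsd_map(renumbered, ten_residue_model)
        assert table["rmsd"].max() == pytest.approx(0.0, abs=1e-6)


class TestDimerRise:
    @pytest.mark.parametrize(
        "dimer_nm, expected_A", [(8.3, 83.0), (8.291, 82.91), (8.144, 81.44)]
    )
    def test_generated_lattice_rise(self, tmp_path, dimer_nm, expected_A):
        spec = LatticeSpec(
            monomer_rise=dimer_nm / 2, lateral_rise=3 * dimer_nm / 2 / 13
        )
        path = tmp_path / "lattice.pdb"
        write_lattice_pdb(build_lattice(spec, 25 * dimer_nm), str(path))
        model = AtomicModel.load(path)
        rise = dimer_rise(model, Selection("A", (1, 2)), Selection("A", (3, 4)))
        assert rise == pytest.approx(expected_A, abs=0.02)

    def test_cylinder_axis_found_for_full_tube(self, tmp_path):
        path = tmp_path / "lattice.pdb"
        write_lattice_pdb(build_lattice(LatticeSpec(), 100.0), str(path))
        model = AtomicModel.load(path)
        axis = fit_cylinder_axis(model.atoms.coord)
        assert abs(axis[2]) == pytest.approx(1.0, abs=1e-4)

    def test_flat_patch_requires_explicit_axis(self, rng):
        flat = rng.normal(size=(40, 3)) * [20.0, 20.0, 1.0]
        with pytest.raises(ValueError, match="axis"):
            fit_cylinder_axis(flat)
        model = make_model(flat, res_ids=np.arange(1, 41))
        rise = dimer_rise(
            model, Selection("A", (1, 20)), Selection("A", (21, 40)),
            axis=[0, 0, 1],
        )
        assert np.isfinite(rise)


class TestFootprint:
    def test_cutoff_boundary(self):
        model = make_model(
            [[0.0, 0, 0], [3.9, 0, 0], [30, 0, 0], [34.1, 0, 0]],
            res_names=["GLY", "LYS", "GLY", "LYS"],
        )
        near = footprint(model, Selection(res_range=(1, 1)),
                         Selection(res_range=(2, 2)))
        assert near == [("A", 2, "LYS")]
        far = footprint(model, Selection(res_range=(3, 3)),
                        Selection(res_range=(4, 4)))
        assert far == []

    def test_planted_contacts_match_brute_force(self, rng):
        """Five residues planted inside the cutoff; brute-force distance
        matrix is the oracle."""
        lig_xyz = rng.normal(scale=3.0, size=(8, 3))
        tgt_xyz = rng.normal(scale=3.0, size=(20, 3)) + [40.0, 0, 0]
        planted = [2, 5, 9, 13, 17]
        for k, idx in enumerate(planted):
            tgt_xyz[idx] = lig_xyz[k % len(lig_xyz)] + [0, 0, 2.5]
        coords = np.vstack([lig_xyz, tgt_xyz])
        model = make_model(coords, res_ids=np.arange(1, 29))
        hits = footprint(model, Selection(res_range=(1, 8)),
                         Selection(res_range=(9, 28)), cutoff=4.0)
        d = np.linalg.norm(tgt_xyz[:, None] - lig_xyz[None], axis=2)
        oracle = {9 + k for k in np.where((d < 4.0).any(axis=1))[0]}
        assert {r[1] for r in hits} == oracle == {idx + 9 for idx in planted}

    def test_symmetric_under_selection_swap(self, rng):
        coords = rng.normal(scale=4.0, size=(16, 3))
        model = make_model(coords, res_ids=np.arange(1, 17))
        a, b = Selection(res_range=(1, 8)), Selection(res_range=(9, 16))
        ab = footprint(model, a, b)
        ba = footprint(model, b, a)
        # contact is mutual: residue r in footprint(a->b) iff some partner
        # of r is in footprint(b->a)'s ligand... check counts both ways on
        # an exhaustive oracle instead
        d = np.linalg.norm(
            coords[8:][:, None] - coords[:8][None], axis=2
        )
        assert {r[1] for r in ab} == {9 + k for k in
                                      np.where((d < 4.0).any(axis=1))[0]}
        assert {r[1] for r in ba} == {1 + k for k in
                                      np.where((d < 4.0).any(axis=0))[0]}

    def test_polar_charged_filter(self):
        model = make_model(
            [[0.0, 0, 0], [2, 0, 0], [0, 2, 0]],
            res_names=["GLY", "LYS", "LEU"],
        )
        hits = footprint(model, Selection(res_range=(1, 1)),
                         Selection(res_range=(2, 3)), polar_charged_only=True)
        assert hits == [("A", 2, "LYS")]

    def test_empty_selection_is_an_error(self, ten_residue_model):
        with pytest.raises(ValueError):
            footprint(ten_residue_model, Selection(chain="Z"),
                      Selection(res_range=(1, 5)))


class TestRmsdInvariants:
    def test_rigid_transform_invariance_and_triangle(self, rng):
        base = rng.normal(scale=5.0, size=(10, 3))
        a = make_model(base)
        b = make_model(base + rng.normal(scale=0.5, size=(10, 3)),
                       res_names=a.atoms.res_name)
        c = make_model(base + rng.normal(scale=0.5, size=(10, 3)),
                       res_names=a.atoms.res_name)

        def frame_rmsd(x, y):
            t = rmsd_map(x, y)
            return float(np.sqrt(np.mean(t["rmsd"] ** 2)))

        _, r_ab = superpose(a, b)
        R = Rotation.from_euler("zyx", [0.2, -0.5, 1.0]).as_matrix()
        a_moved = make_model(a.atoms.coord @ R.T + [4, 5, 6],
                             res_names=a.atoms.res_name)
        _, r_ab_moved = superpose(a_moved, b)
        assert r_ab_moved == pytest.approx(r_ab, abs=1e-4)
        assert r_ab >= 0
        assert frame_rmsd(a, c) <= frame_rmsd(a, b) + frame_rmsd(b, c) + 1e-9
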