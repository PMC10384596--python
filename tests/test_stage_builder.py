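"""Stage-construction rules: boxes, replication, excipients, ions, ice,
water stripping, residual selection, re-solvation and the end-to-end run."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lyotraj as lt
from lyotraj.stage_builder import (
    AVOGADRO,
    StageConfig,
    min_distance_to_faces,
)


class TestDefineBox:
    def test_single_atom_margin(self):
        m = lt.StructureModel([lt.Atom("C", "CA", 1, "GLY", "A", np.zeros(3))])
        box = lt.define_box(m, margin=15.0, cubic=True)
        assert np.allclose(box.lengths, 30.0)
        assert min_distance_to_faces(m, box) == pytest.approx(15.0)

    def test_anisotropic_extent_cubic(self):
        corners = np.array([[0, 0, 0], [40, 0, 0], [0, 30, 0], [0, 0, 20],
                            [40, 30, 20]], dtype=float)
        atoms = [lt.Atom("C", "CA", i + 1, "GLY", "A", c)
                 for i, c in enumerate(corners)]
        box = lt.define_box(lt.StructureModel(atoms), margin=15.0, cubic=True)
        assert np.allclose(box.lengths, 70.0)

    def test_cg_default_margin(self, cg_monomer):
        cfg = StageConfig.for_stage("CG")
        assert cfg.box_margin == 7.5
        box = lt.define_box(cg_monomer, margin=cfg.box_margin, cubic=True)
        assert min_distance_to_faces(cg_monomer, box) == pytest.approx(7.5)

    def test_no_protein_errors(self):
        w = lt.StructureModel([lt.Atom("O", "OW", 1, "HOH", "W", np.zeros(3),
                                       role="water")])
        with pytest.raises(ValueError):
            lt.define_box(w, 15.0)


class TestReplicateMonomers:
    def test_default_octamer_spacing(self, cg_monomer):
        system = lt.replicate_monomers(cg_monomer, (2, 2, 2), 85.0)
        chains = system.chain_ids
        assert len(chains) == 8
        coms = np.array([system.center_of_mass(system.select(chain_id=c))
                         for c in chains])
        d = np.linalg.norm(coms[:, None] - coms[None, :], axis=2)
        nn = np.sort(d, axis=1)[:, 1]
        assert np.allclose(nn, 85.0)

    def test_identity_grid(self, cg_monomer):
        out = lt.replicate_monomers(cg_monomer, (1, 1, 1), 85.0)
        assert len(out.chain_ids) == 1
        assert np.allclose(out.coords, cg_monomer.coords)

    def test_single_axis_displacement(self, cg_monomer):
        out = lt.replicate_monomers(cg_monomer, (2, 1, 1), 10.0)
        ca = out.center_of_mass(out.select(chain_id=out.chain_ids[0]))
        cb = out.center_of_mass(out.select(chain_id=out.chain_ids[1]))
        assert np.allclose(cb - ca, [10.0, 0.0, 0.0])

    def test_zero_grid_errors(self, cg_monomer):
        with pytest.raises(ValueError):
            lt.replicate_monomers(cg_monomer, (0, 2, 2), 85.0)

    def test_internal_distances_preserved(self, hairpin):
        system = lt.replicate_monomers(hairpin, (2, 1, 1), 50.0)
        ref = hairpin.coords
        dref = np.linalg.norm(ref[:, None] - ref[None, :], axis=2)
        for c in system.chain_ids:
            xyz = system.coords[system.select(chain_id=c)]
            d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=2)
            assert np.allclose(d, dref, atol=1e-9)


class TestExcipientCounting:
    def test_zero_concentration(self):
        box = lt.SimulationBox([100.0, 100.0, 100.0])
        assert lt.count_excipients_molar(box, 0.0) == 0

    def test_molar_closed_form(self):
        # V chosen so 10 mM -> exactly 10 molecules
        v_l = 10 / (10e-3 * AVOGADRO)
        side = (v_l * 1e27) ** (1 / 3)
        box = lt.SimulationBox([side] * 3)
        assert lt.count_excipients_molar(box, 10.0) == 10

    def test_formulation_table_ratio(self):
        # box volume recovered by inverting the 100 mM -> 51 molecules row;
        # the same box must then give 5 molecules at 10 mM
        v_l = 51 / (100e-3 * AVOGADRO)
        box = lt.SimulationBox([(v_l * 1e27) ** (1 / 3)] * 3)
        assert lt.count_excipients_molar(box, 100.0) == 51
        assert lt.count_excipients_molar(box, 10.0) == 5

    @given(st.floats(1.0, 500.0), st.integers(1, 5))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_molar_homogeneous_and_monotone(self, conc, k):
        box = lt.SimulationBox([50.0, 50.0, 50.0])
        n1 = lt.count_excipients_molar(box, conc)
        nk = lt.count_excipients_molar(box, k * conc)
        assert nk == round(k * conc * 1e-3 * box.volume_litres * AVOGADRO)
        assert nk >= n1

    def test_ww_zero(self):
        spec = lt.ExcipientSpec.of("ARG", mass_fraction=0.10)
        assert lt.count_excipients_ww(1000, spec, 0.0) == 0

    def test_ww_arginine(self):
        spec = lt.ExcipientSpec.of("ARG", mass_fraction=0.10)
        # 0.1/0.9 * 1000 * 18.015 / 174.2 = 11.49 -> 11
        assert lt.count_excipients_ww(1000, spec, 0.10) == 11

    def test_ww_symmetry_equal_masses(self):
        spec = lt.ExcipientSpec(name="X", molar_mass=18.015, net_charge=0,
                                mass_fraction=0.5)
        assert lt.count_excipients_ww(100, spec, 0.5) == 100

    def test_ww_fraction_one_errors(self):
        spec = lt.ExcipientSpec.of("SUC", mass_fraction=0.10)
        with pytest.raises(ValueError):
            lt.count_excipients_ww(100, spec, 1.0)

    def test_one_concentration_mode(self):
        with pytest.raises(ValueError):
            lt.ExcipientSpec(name="ARG", molar_mass=174.2, net_charge=1)


class TestNeutralize:
    @pytest.mark.parametrize("charge,na,cl", [
        (283, 0, 283),   # protein -1 + 284 arginine(+1)
        (50, 0, 50),     # protein -1 + 51 arginine(+1)
        (-1, 1, 0),      # protein alone, or with neutral excipients
        (0, 0, 0),
    ])
    def test_formulation_rows(self, charge, na, cl):
        inv = lt.neutralize(charge)
        assert (inv.n_na, inv.n_cl) == (na, cl)
        assert charge + inv.net_charge == 0

    def test_non_integer_charge_errors(self):
        with pytest.raises(ValueError):
            lt.neutralize(0.5)

    @given(st.integers(-500, 500))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_always_neutral_never_mixed(self, q):
        inv = lt.neutralize(q)
        assert q + inv.net_charge == 0
        assert inv.n_na == 0 or inv.n_cl == 0


class TestIce:
    def test_unit_cell_occupancy(self):
        ice = lt.build_ice_block(1, 1, 1)
        assert len(ice.atoms) == 12  # 4 molecules x 3 atoms
        assert all(a.role == "ice" for a in ice.atoms)

    def test_nearest_oxygen_distance(self):
        ice = lt.build_ice_block(3, 3, 2)
        oxy = ice.coords[[i for i, a in enumerate(ice.atoms) if a.element == "O"]]
        d = np.linalg.norm(oxy[:, None] - oxy[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() == pytest.approx(2.75, abs=0.02)

    def test_tiling_doubles_molecules(self):
        n1 = len(lt.build_ice_block(1, 1, 1).atoms)
        n2 = len(lt.build_ice_block(2, 1, 1).atoms)
        assert n2 == 2 * n1

    def test_bad_counts_error(self):
        with pytest.raises(ValueError):
            lt.build_ice_block(0, 1, 1)


class TestPlaceIceBlocks:
    def _empty_boxed(self, side=20.0):
        a = lt.Atom("C", "CA", 1, "GLY", "A", np.full(3, side / 2))
        m = lt.StructureModel([a])
        m.box = lt.SimulationBox([side] * 3)
        return m

    def test_three_disjoint_slabs(self):
        m = self._empty_boxed()
        out = lt.place_ice_blocks(m, thickness=8.0, seed=1)
        ice_o = [a for a in out.atoms if a.role == "ice" and a.element == "O"]
        assert ice_o
        box = m.box
        per_axis = [0, 0, 0]
        for a in ice_o:
            outside = [axis for axis in range(3)
                       if a.coords[axis] >= box.origin[axis] + box.lengths[axis]]
            assert len(outside) == 1  # each molecule belongs to exactly one slab
            per_axis[outside[0]] += 1
        assert all(n > 0 for n in per_axis)

    def test_clash_pruning(self):
        m = self._empty_boxed()
        # put solute right at the +x face so some ice would clash
        m.atoms.append(lt.Atom("C", "CA", 2, "GLY", "A",
                               np.array([20.0, 10.0, 10.0])))
        out = lt.place_ice_blocks(m, thickness=8.0, clash_cutoff=2.4, seed=1)
        solute = out.coords[[i for i, a in enumerate(out.atoms) if a.role != "ice"]]
        ice = out.coords[[i for i, a in enumerate(out.atoms) if a.role == "ice"
                          and a.element == "O"]]
        d = np.linalg.norm(ice[:, None] - solute[None, :], axis=2)
        assert d.min() >= 2.4

    def test_pruning_monotone(self):
        free = lt.place_ice_blocks(self._empty_boxed(), thickness=8.0, seed=1)
        crowded = self._empty_boxed()
        for k in range(2, 12):
            crowded.atoms.append(lt.Atom("C", "CA", k, "GLY", "A",
                                         np.array([20.0, 2.0 * k, 10.0])))
        pruned = lt.place_ice_blocks(crowded, thickness=8.0, seed=1)
        n_free = sum(a.role == "ice" for a in free.atoms)
        n_pruned = sum(a.role == "ice" for a in pruned.atoms)
        assert n_pruned <= n_free

    def test_missing_box_errors(self, helix):
        with pytest.raises(ValueError):
            lt.place_ice_blocks(helix)


class TestStripBulkWater:
    def test_retention_by_distance(self, helix):
        solv = lt.make_solvated_fixture(helix, [(2.0, 5), (5.0, 5)], seed=3)
        out = lt.strip_bulk_water(solv, cutoff=3.0)
        assert len(out.select(role="water")) == 5
        prot = out.coords[out.select(role="protein")]
        for i in out.select(role="water"):
            dmin = np.linalg.norm(prot - out.atoms[i].coords, axis=1).min()
            assert dmin <= 3.0

    def test_no_waters_unchanged(self, helix):
        out = lt.strip_bulk_water(helix, cutoff=3.0)
        assert len(out) == len(helix)

    def test_all_beyond_cutoff(self, helix):
        solv = lt.make_solvated_fixture(helix, [(6.0, 8)], seed=5)
        out = lt.strip_bulk_water(solv, cutoff=3.0)
        assert len(out.select(role="water")) == 0

    def test_never_touches_other_roles(self, solvated):
        out = lt.strip_bulk_water(solvated, cutoff=3.0)
        assert len(out.select(role="protein")) == len(solvated.select(role="protein"))
        assert len(out) <= len(solvated)


class TestSelectResidualWaters:
    def test_coincident_retained(self, solvated):
        waters = solvated.coords[solvated.water_oxygen_indices()]
        out = lt.select_residual_waters(solvated, waters[:4], match_cutoff=1.5)
        assert len(out.water_oxygen_indices()) == 4

    def test_displaced_within_cutoff(self, solvated):
        waters = solvated.coords[solvated.water_oxygen_indices()]
        shifted = waters[:4] + np.array([0.5, 0.0, 0.0])
        out = lt.select_residual_waters(solvated, shifted, match_cutoff=1.5)
        assert len(out.water_oxygen_indices()) == 4

    def test_empty_crystal_list(self, solvated, caplog):
        with caplog.at_level("WARNING", logger="lyotraj"):
            out = lt.select_residual_waters(solvated, np.zeros((0, 3)))
        assert len(out.select(role="water")) == 0
        assert any("crystal" in r.message for r in caplog.records)


class TestResolvate:
    def test_empty_solute_grid_count(self):
        m = lt.StructureModel([], box=lt.SimulationBox([12.0, 12.0, 12.0]))
        out = lt.resolvate(m, grid_spacing=3.0, clash_cutoff=2.4)
        assert len(out.select(role="water")) == int(12.0 // 3.0) ** 3

    def test_no_water_within_clash_cutoff(self, helix):
        out = lt.resolvate(helix, margin=15.0, grid_spacing=3.1, clash_cutoff=2.4)
        prot = out.coords[out.select(role="protein")]
        wat = out.coords[out.select(role="water")]
        d = np.linalg.norm(wat[:, None] - prot[None, :], axis=2)
        assert d.min() >= 2.4

    def test_default_margin(self, helix):
        out = lt.resolvate(helix, margin=15.0, grid_spacing=3.1)
        assert min_distance_to_faces(out, out.box) == pytest.approx(15.0)

    def test_bad_spacing_errors(self, helix):
        with pytest.raises(ValueError):
            lt.resolvate(helix, grid_spacing=0.0)


class TestPipeline:
    def test_end_to_end_stage_contract(self, solvated):
        cw = solvated.coords[solvated.water_oxygen_indices()][:3]
        result = lt.run_pipeline(solvated, crystal_waters=cw, seed=2)
        assert result.stages == ["RT", "F", "1D", "2D", "REC"]
        # each stage consumes the previous stage's output
        assert len(result.system("F")) > len(result.system("RT"))  # ice added
        n_rt_w = len(result.system("RT").select(role="water"))
        n_1d_w = len(result.system("1D").select(role="water"))
        n_2d_w = len(result.system("2D").select(role="water"))
        n_rec_w = len(result.system("REC").select(role="water"))
        assert n_1d_w <= n_rt_w          # sublimation removes bulk water
        assert n_2d_w <= n_1d_w          # desorption keeps only residual water
        assert n_rec_w > n_2d_w          # reconstitution re-adds water
        assert len(result.system("2D").select(role="ice")) == 0
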