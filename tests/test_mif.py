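"""Grid construction, pair energies, field computation and OpenDX I/O."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pocketmif as pm
from pocketmif.dx import read_dx, write_dx

from .oracles import oracle_field, oracle_pair_energy


def _single_atom(name="CD1", res="LEU", element="C", pos=(0.0, 0.0, 0.0)):
    return pm.assign_atom_types([pm.AtomRecord(
        serial=1, name=name, element=element, residue_name=res,
        chain_id="A", residue_number=1, coords=pos)])


class TestBuildGrid:
    def test_single_atom_arithmetic(self):
        grid = pm.build_grid(np.zeros((1, 3)), spacing=1.0, padding=2.0)
        assert grid.origin == (-2.0, -2.0, -2.0)
        assert grid.shape == (5, 5, 5)

    def test_zero_spacing_rejected(self):
        with pytest.raises(ValueError):
            pm.build_grid(np.zeros((1, 3)), spacing=0.0)

    def test_bounds_contain_all_atoms_plus_padding(self, toy):
        structure, pocket = toy
        coords = structure.coords[pocket.atom_indices(structure)]
        grid = pm.build_grid(coords, spacing=0.5, padding=3.0)
        lo = np.asarray(grid.origin)
        hi = lo + grid.spacing * (np.asarray(grid.shape) - 1)
        for xyz in coords:  # brute-force containment
            assert np.all(xyz - 3.0 >= lo - 1e-9)
            assert np.all(xyz + 3.0 <= hi + 1e-9)

    def test_identical_inputs_identical_grids(self, toy):
        structure, pocket = toy
        coords = structure.coords[pocket.atom_indices(structure)]
        assert pm.build_grid(coords) == pm.build_grid(coords.copy())


class TestPairEnergy:
    def test_lj_minimum_is_exact(self, params):
        probe = params.probe("CRY")
        rh, eps = params.atom_lj("C")
        rmin = probe.rmin_half + rh
        e = pm.pair_energy(probe, "hydrophobic", rh, eps, 0.0, rmin,
                           params=params)
        assert e == pytest.approx(-np.sqrt(probe.eps * eps), rel=1e-12)

    @pytest.mark.parametrize("probe_name", ["H", "CRY", "N1", "O", "OH2"])
    @pytest.mark.parametrize("cls,q", [("hydrophobic", 0.0),
                                       ("anion", -0.5), ("cation", 0.5)])
    def test_long_range_decay(self, params, probe_name, cls, q):
        probe = params.probe(probe_name)
        e = pm.pair_energy(probe, cls, 1.8, 0.15, q, 50.0, params=params)
        assert abs(e) < 1e-3

    def test_nonpositive_distance_rejected(self, params):
        with pytest.raises(ValueError):
            pm.pair_energy(params.probe("CRY"), "hydrophobic",
                           1.9, 0.12, 0.0, 0.0, params=params)

    def test_donor_probe_vs_acceptor_matches_formula_oracle(self, params):
        # N1 probe against an ASN OD1-like acceptor at 2.9 A, ideal geometry
        probe = params.probe("N1")
        rh, eps = params.atom_lj("O")
        got = pm.pair_energy(probe, "acceptor", rh, eps, 0.0, 2.9,
                             geometry=1.0, params=params)
        want = oracle_pair_energy(probe, "acceptor", rh, eps, 0.0, 2.9, 1.0)
        assert got == pytest.approx(want, rel=1e-12)

    @given(st.sampled_from(["H", "CRY", "N1", "O", "OH2"]),
           st.sampled_from(["hydrophobic", "donor", "acceptor", "anion",
                            "cation", "donor_acceptor", "polar"]),
           st.floats(0.5, 20.0), st.floats(0.0, 1.0))
    def test_matches_oracle_everywhere(self, probe_name, cls, r, geom):
        params = pm.load_params()
        probe = params.probe(probe_name)
        q = {"anion": -0.5, "cation": 0.5}.get(cls, 0.0)
        got = pm.pair_energy(probe, cls, 1.8, 0.15, q, r, geom,
                             params=params)
        want = oracle_pair_energy(probe, cls, 1.8, 0.15, q, r, geom)
        assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_clamped_at_plus_five(self, params):
        probe = params.probe("H")
        e = pm.pair_energy(probe, "hydrophobic", 1.9, 0.12, 0.0, 0.3,
                           params=params)
        assert e == 5.0


class TestComputeMif:
    def test_empty_structure_gives_zero_field(self, params):
        empty = pm.TypedStructure(atoms=[], atom_class=[],
                                  rmin_half=np.empty(0), eps=np.empty(0),
                                  partial_charge=np.empty(0))
        grid = pm.GridSpec(origin=(0, 0, 0), spacing=1.0, shape=(4, 4, 4))
        mif = pm.compute_mif(empty, None, params.probe("CRY"), grid,
                             params=params)
        assert np.all(mif.energy == 0.0)
        assert np.all(mif.max_contributor == -1)

    def test_single_atom_cry_minimum_near_rmin(self, params):
        ts = _single_atom()
        grid = pm.build_grid(np.zeros((1, 3)), spacing=0.25, padding=4.0)
        mif = pm.compute_mif(ts, None, params.probe("CRY"), grid,
                             params=params)
        probe = params.probe("CRY")
        rmin = probe.rmin_half + float(ts.rmin_half[0])
        pts = grid.points()
        r = np.linalg.norm(pts, axis=1)
        # the field minimum sits at a lattice point whose distance from the
        # atom is as close to rmin as the lattice allows
        kmin = int(np.argmin(mif.energy.ravel(order="C")))
        best_possible = np.min(np.abs(r - rmin))
        assert abs(r[kmin] - rmin) <= best_possible + grid.spacing
        # the lone atom is the contributor wherever the field is favourable
        fav = mif.energy < 0
        assert np.all(mif.max_contributor[fav] == 1)

    @pytest.mark.parametrize("probe_name", ["CRY", "N1", "O"])
    def test_two_atom_contributors_match_bruteforce(self, params, probe_name):
        atoms = [
            pm.AtomRecord(serial=10, name="CD1", element="C",
                          residue_name="LEU", chain_id="A",
                          residue_number=1, coords=(0.0, 0.0, 0.0)),
            pm.AtomRecord(serial=20, name="OD1", element="O",
                          residue_name="ASN", chain_id="A",
                          residue_number=2, coords=(5.0, 0.0, 0.0)),
        ]
        ts = pm.assign_atom_types(atoms)
        grid = pm.build_grid(ts.coords, spacing=1.0, padding=3.0)
        mif = pm.compute_mif(ts, None, params.probe(probe_name), grid,
                             params=params)
        energy, best, contributor = oracle_field(ts, params.probe(probe_name),
                                                 grid)
        np.testing.assert_allclose(mif.energy, energy, rtol=1e-9, atol=1e-12)
        np.testing.assert_array_equal(mif.max_contributor, contributor)

    def test_translation_equivariance(self, params, tiny):
        structure, pocket = tiny
        shift = np.array([7.0, -3.0, 2.0])
        moved = pm.transform_structure(
            structure, pm.Superposition(rotation=np.eye(3),
                                        translation=shift, rmsd=0.0,
                                        n_pairs=len(structure)))
        idx = pocket.atom_indices(structure)
        grid = pm.build_grid(structure.coords[idx], spacing=1.0, padding=2.0)
        grid2 = pm.GridSpec(origin=tuple(np.asarray(grid.origin) + shift),
                            spacing=grid.spacing, shape=grid.shape)
        a = pm.compute_mif(structure, pocket, params.probe("OH2"), grid,
                           params=params)
        b = pm.compute_mif(moved, pocket, params.probe("OH2"), grid2,
                           params=params)
        # equal up to float round-off from the shifted absolute coordinates
        np.testing.assert_allclose(a.energy, b.energy, rtol=0, atol=1e-10)
        np.testing.assert_array_equal(a.max_contributor, b.max_contributor)

    def test_removing_atom_only_affects_points_within_cutoff(self, params,
                                                             tiny):
        structure, pocket = tiny
        idx = pocket.atom_indices(structure)
        grid = pm.build_grid(structure.coords[idx], spacing=1.0, padding=2.0)
        full = pm.compute_mif(structure, pocket, params.probe("CRY"), grid,
                              cutoff=6.0, params=params)
        reduced = structure.subset(np.arange(1, len(structure)))
        part = pm.compute_mif(reduced, pocket, params.probe("CRY"), grid,
                              cutoff=6.0, params=params)
        removed_pos = structure.coords[0]
        far = np.linalg.norm(grid.points() - removed_pos,
                             axis=1).reshape(grid.shape) > 6.0
        np.testing.assert_array_equal(full.energy[far], part.energy[far])

    def test_field_never_exceeds_clamp(self, params, toy):
        structure, pocket = toy
        idx = pocket.atom_indices(structure)
        grid = pm.build_grid(structure.coords[idx], spacing=0.8)
        for name in ("H", "CRY", "N1", "O", "OH2"):
            mif = pm.compute_mif(structure, pocket, params.probe(name), grid,
                                 params=params)
            assert mif.energy.max() <= params.clamp + 1e-12
            assert np.isfinite(mif.energy).all()

    def test_nonoverlapping_grid_warns_and_zeroes(self, params, caplog):
        ts = _single_atom(pos=(100.0, 100.0, 100.0))
        grid = pm.GridSpec(origin=(0, 0, 0), spacing=1.0, shape=(4, 4, 4))
        with caplog.at_level("WARNING", logger="pocketmif.mif_engine"):
            mif = pm.compute_mif(ts, None, params.probe("CRY"), grid,
                                 params=params)
        assert np.all(mif.energy == 0.0)
        assert any("overlap" in r.message for r in caplog.records)


class TestOpenDX:
    def test_zero_field_has_eight_zeros(self):
        text = write_dx(np.zeros(3), 1.0, np.zeros((2, 2, 2)))
        data = [tok for line in text.splitlines()
                if line and line[0] in "-0123456789"
                for tok in line.split()]
        assert len(data) == 8 and all(float(t) == 0.0 for t in data)

    def test_header_counts_equal_shape_product(self, params, tiny):
        structure, pocket = tiny
        idx = pocket.atom_indices(structure)
        grid = pm.build_grid(structure.coords[idx], spacing=1.2, padding=2.0)
        mif = pm.compute_mif(structure, pocket, params.probe("CRY"), grid,
                             params=params)
        text = pm.export_field(mif)
        items = int(text.split("items")[1].split()[0])
        assert items == grid.n_points

    def test_roundtrip(self, params, tiny):
        structure, pocket = tiny
        idx = pocket.atom_indices(structure)
        grid = pm.build_grid(structure.coords[idx], spacing=1.2, padding=2.0)
        mif = pm.compute_mif(structure, pocket, params.probe("N1"), grid,
                             params=params)
        grid2, values = pm.import_field(pm.export_field(mif))
        assert grid2.shape == grid.shape
        np.testing.assert_allclose(np.asarray(grid2.origin), grid.origin,
                                   atol=1e-6)
        np.testing.assert_allclose(values, mif.energy, atol=1e-5)

    def test_garbage_rejected(self):
        with pytest.raises(ValueError):
            read_dx("this is not a dx file\n")
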