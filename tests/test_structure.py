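"""Structure parsing, inter-chain distances, and interface-region extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_interface, make_atom, make_residue
from e2face.structure import (
    StructureEnsemble,
    interface_residues,
    load_ensemble,
    merge_regions,
    min_interchain_distance,
    write_ensemble,
)
from e2face.synthetic import Plant, simulate_complex

# A hand-written single-model PDB (no MODEL records) with an altloc pair and
# a hydrogen, to pin the parsing conventions.
SINGLE_MODEL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CB AALA A   1       2.000   1.400   0.000  0.50  0.00           C
ATOM      4  CB BALA A   1       2.000  -1.400   0.000  0.50  0.00           C
ATOM      5  HA  ALA A   1       1.800   0.000   1.000  1.00  0.00           H
ATOM      6  CA  GLY B   2       4.458   3.000   0.000  1.00  0.00           C
END
"""


class TestLoadEnsemble:
    def test_generated_three_model_file_round_trips(self, tmp_path):
        ens, _ = simulate_complex(
            seed=11, n_models=3, query_length=6,
            planted_contacts=[Plant(2, "hydrogen_bond")], out_dir=tmp_path,
        )
        loaded = load_ensemble(tmp_path / "complex.pdb")
        assert loaded.n_models == 3
        assert loaded.chains() == ["A", "B"]

    def test_file_without_model_records_is_single_model(self, tmp_path):
        p = tmp_path / "single.pdb"
        p.write_text(SINGLE_MODEL_PDB)
        ens = load_ensemble(p)
        assert ens.n_models == 1
        assert ens.chains() == ["A", "B"]

    def test_first_altloc_kept_and_hydrogens_flagged(self, tmp_path):
        p = tmp_path / "single.pdb"
        p.write_text(SINGLE_MODEL_PDB)
        res = load_ensemble(p).models[0][0]
        cbs = [a for a in res.atoms if a.name == "CB"]
        assert len(cbs) == 1 and cbs[0].coords[1] == pytest.approx(1.4)
        hydrogens = [a for a in res.atoms if a.is_hydrogen]
        assert len(hydrogens) == 1 and hydrogens[0].name == "HA"
        assert {a.name for a in res.atoms if a.is_sidechain} == {"CB", "HA"}

    def test_mmcif_reads_same_models_as_pdb(self, tmp_path):
        import gemmi

        ens, _ = simulate_complex(
            seed=4, n_models=2, query_length=5,
            planted_contacts=[Plant(3, "generic")], out_dir=tmp_path,
        )
        st_ = gemmi.read_structure(str(tmp_path / "complex.pdb"))
        st_.setup_entities()
        cif = tmp_path / "complex.cif"
        st_.make_mmcif_document().write_file(str(cif))
        from_pdb = load_ensemble(tmp_path / "complex.pdb", format="pdb")
        from_cif = load_ensemble(cif, format="mmcif")
        assert from_cif.n_models == from_pdb.n_models == 2
        for a, b in zip(from_pdb.models[0], from_cif.models[0]):
            assert a.key == b.key and a.name == b.name

    def test_missing_file_and_empty_structure_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_ensemble(tmp_path / "nope.pdb")
        empty = tmp_path / "empty.pdb"
        empty.write_text("END\n")
        with pytest.raises(Exception):
            load_ensemble(empty)

    def test_mismatched_model_residue_sets_rejected(self):
        r1 = make_residue("A", 1, "GLY", [make_atom("CA", "C", (0, 0, 0), False)])
        r2 = make_residue("A", 1, "ALA", [make_atom("CA", "C", (0, 0, 0), False)])
        with pytest.raises(ValueError, match="residue set"):
            StructureEnsemble(models=[[r1], [r2]])

    def test_reserialization_preserves_numbering_and_coords(self, tmp_path, ref_complex):
        ens, _ = ref_complex
        p1 = tmp_path / "a.pdb"
        write_ensemble(ens, p1)
        loaded = load_ensemble(p1)
        assert loaded.n_models == ens.n_models
        for orig, back in zip(ens.models[0], loaded.models[0]):
            assert (orig.chain_id, orig.seq_number, orig.name) == (
                back.chain_id, back.seq_number, back.name)
            np.testing.assert_allclose(
                orig.coord_array(), back.coord_array(), atol=5e-4)


class TestMinInterchainDistance:
    def test_three_four_five_triangle(self):
        qa = make_residue("A", 1, "GLY", [make_atom("CA", "C", (0, 0, 0), False)])
        pb = make_residue("B", 1, "GLY", [make_atom("CA", "C", (3, 4, 0), False)])
        model = [qa, pb]
        assert min_interchain_distance(model, qa, "B") == pytest.approx(5.0)

    def test_minimum_over_residue_atoms(self):
        qa = make_residue("A", 1, "SER", [
            make_atom("CB", "C", (0, 0, 0)),
            make_atom("OG", "O", (0, 1.3, 0)),
        ])
        pb = make_residue("B", 1, "GLY", [make_atom("CA", "C", (0, 7.2, 0), False)])
        model = [qa, pb]
        assert min_interchain_distance(model, qa, "B") == pytest.approx(5.9)

    def test_empty_partner_is_infinite(self):
        qa = make_residue("A", 1, "GLY", [make_atom("CA", "C", (0, 0, 0), False)])
        assert min_interchain_distance([qa], qa, "B") == float("inf")

    def test_unknown_residue_errors(self):
        qa = make_residue("A", 1, "GLY", [make_atom("CA", "C", (0, 0, 0), False)])
        other = make_residue("A", 9, "GLY", [make_atom("CA", "C", (0, 0, 0), False)])
        with pytest.raises(ValueError, match="not found"):
            min_interchain_distance([qa], other, "A")

    def test_matches_brute_force_on_synthetic_model(self):
        ens, _ = simulate_complex(
            seed=5, n_models=1, query_length=20,
            planted_contacts=[Plant(4, "salt_bridge"), Plant(11, "hydrophobic")],
        )
        model = ens.models[0]
        partner_atoms = [
            a for r in model if r.chain_id == "B" for a in r.heavy_atoms()
        ]
        for res in model:
            if res.chain_id != "A":
                continue
            expect = min(
                np.linalg.norm(np.subtract(qa.coords, pa.coords))
                for qa in res.heavy_atoms()
                for pa in partner_atoms
            )
            assert min_interchain_distance(model, res, "B") == pytest.approx(float(expect))


class TestInterfaceResidues:
    def test_planted_contact_included_and_support_counted(self):
        ens, truth = simulate_complex(
            seed=2, n_models=4, query_length=8, planted_contacts=[Plant(5, "salt_bridge")]
        )
        got = interface_residues(ens, "A", "B", 6.0, "any_model")
        assert got == {5: 4}

    def test_boundary_is_inclusive(self):
        qa = make_residue("A", 1, "GLY", [make_atom("CA", "C", (0, 0, 0), False)])
        near = make_residue("B", 1, "GLY", [make_atom("CA", "C", (6.0, 0, 0), False)])
        far = make_residue("A", 2, "GLY", [make_atom("CA", "C", (0, 100, 0), False)])
        ens = StructureEnsemble(models=[[qa, far, near]])
        assert 1 in interface_residues(ens, "A", "B", 6.0)
        shifted = make_residue("B", 1, "GLY", [make_atom("CA", "C", (6.1, 0, 0), False)])
        ens2 = StructureEnsemble(models=[[qa, far, shifted]])
        assert 1 not in interface_residues(ens2, "A", "B", 6.0)

    def test_model_subset_respects_aggregation(self):
        ens, _ = simulate_complex(
            seed=3, n_models=6, query_length=8,
            planted_contacts=[Plant(4, "hydrogen_bond", models=(1, 2, 3))],
        )
        assert interface_residues(ens, "A", "B", 6.0, "any_model") == {4: 3}
        assert interface_residues(ens, "A", "B", 6.0, "all_models") == {}
        assert interface_residues(ens, "A", "B", 6.0, ("min_count", 3)) == {4: 3}
        assert interface_residues(ens, "A", "B", 6.0, ("min_count", 4)) == {}

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        plants = [
            Plant(int(r), cls)
            for r, cls in zip(
                rng.choice(np.arange(1, 15, 3), size=2, replace=False),
                ["salt_bridge", "hydrophobic"],
            )
        ]
        ens, _ = simulate_complex(seed=seed + 100, n_models=3, query_length=15,
                                  planted_contacts=plants)
        for cutoff in (4.0, 6.0, 9.0):
            oracle = brute_force_interface(ens, "A", "B", cutoff)
            got = interface_residues(ens, "A", "B", cutoff, "any_model")
            assert got == {k: v for k, v in oracle.items() if v >= 1}

    def test_cutoff_and_aggregation_monotonicity(self, ref_complex):
        ens, _ = ref_complex
        sets = [
            set(interface_residues(ens, "A", "B", c, "any_model"))
            for c in (4.0, 6.0, 8.0)
        ]
        assert sets[0] <= sets[1] <= sets[2]
        all_m = set(interface_residues(ens, "A", "B", 6.0, "all_models"))
        min5 = set(interface_residues(ens, "A", "B", 6.0, ("min_count", 5)))
        any_m = set(interface_residues(ens, "A", "B", 6.0, "any_model"))
        assert all_m <= min5 <= any_m

    def test_absent_chain_errors(self, ref_complex):
        ens, _ = ref_complex
        with pytest.raises(ValueError, match="chain"):
            interface_residues(ens, "A", "Z")


class TestMergeRegions:
    def test_contiguous_run_is_one_region(self):
        regs = merge_regions(range(1, 10), max_gap=3)
        assert [(r.start, r.end) for r in regs] == [(1, 9)]

    def test_gap_larger_than_max_gap_splits(self):
        regs = merge_regions({1, 2, 3, 8, 9}, max_gap=3)
        assert [(r.start, r.end) for r in regs] == [(1, 3), (8, 9)]

    def test_gap_of_four_closed_at_max_gap_four(self):
        regs = merge_regions({1, 2, 3, 8, 9}, max_gap=4)
        assert [(r.start, r.end) for r in regs] == [(1, 9)]
        assert regs[0].members == [1, 2, 3, 8, 9]

    def test_empty_input(self):
        assert merge_regions([], 3) == []

    @given(
        numbers=st.sets(st.integers(1, 60), max_size=25),
        max_gap=st.integers(0, 5),
    )
    @settings(max_examples=200, deadline=None)
    def test_regions_partition_the_input(self, numbers, max_gap):
        regs = merge_regions(numbers, max_gap=max_gap)
        covered = [m for r in regs for m in r.members]
        assert covered == sorted(numbers)  # exactly the input, in order
        for r in regs:
            assert r.start == r.members[0] and r.end == r.members[-1]
            assert all(b - a - 1 <= max_gap for a, b in zip(r.members, r.members[1:]))
        for r1, r2 in zip(regs, regs[1:]):
            assert r2.start - r1.end - 1 > max_gap  # maximality
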