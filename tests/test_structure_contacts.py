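"""Structure parsing and contact-extraction behaviour."""

from __future__ import annotations

import math

import numpy as np
import pytest

from helpers import brute_force_contact_positions
from conftest import pdb_line

from ligprop import (
    Atom,
    Chain,
    HetGroup,
    Residue,
    StructureModel,
    build_dataset,
    contacts_to_table,
    extract_contacts,
    filter_ligands,
    parse_structure,
    random_toy_spec,
    make_toy_complex,
)
from ligprop.errors import (
    EmptyDatasetError,
    EmptyStructureError,
    LigandNotFoundError,
    PDBParseError,
)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

class TestParseStructure:
    def test_minimal_complex(self, simple_model):
        assert len(simple_model.chains) == 1
        assert [r.name for r in simple_model.chains[0].residues] == ["GLY", "ALA", "SER"]
        assert [h.code for h in simple_model.het_groups] == ["ATP"]

    def test_water_only_het_excluded(self):
        text = pdb_line("HETATM", 1, "O", "HOH", "W", 1, 1.0, 1.0, 1.0, element="O")
        model = parse_structure(text + "\n")
        assert model.het_groups == []

    def test_first_model_only(self):
        lines = [
            "MODEL        1",
            pdb_line("ATOM", 1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0),
            "ENDMDL",
            "MODEL        2",
            pdb_line("ATOM", 2, "CA", "GLY", "A", 1, 9.0, 9.0, 9.0),
            pdb_line("ATOM", 3, "CA", "ALA", "A", 2, 9.0, 9.0, 12.0),
            "ENDMDL",
            "END",
        ]
        model = parse_structure("\n".join(lines) + "\n")
        assert len(model.chains) == 1
        residues = model.chains[0].residues
        assert len(residues) == 1
        assert residues[0].atoms[0].x == pytest.approx(0.0)

    def test_altloc_keeps_highest_occupancy(self):
        lines = [
            pdb_line("ATOM", 1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, occ=0.4, altloc="A"),
            pdb_line("ATOM", 2, "CA", "ALA", "A", 1, 5.0, 0.0, 0.0, occ=0.6, altloc="B"),
        ]
        model = parse_structure("\n".join(lines) + "\n")
        atoms = model.chains[0].residues[0].atoms
        assert len(atoms) == 1
        assert atoms[0].x == pytest.approx(5.0)

    def test_altloc_tie_keeps_first(self):
        lines = [
            pdb_line("ATOM", 1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, occ=0.5, altloc="A"),
            pdb_line("ATOM", 2, "CA", "ALA", "A", 1, 5.0, 0.0, 0.0, occ=0.5, altloc="B"),
        ]
        model = parse_structure("\n".join(lines) + "\n")
        assert model.chains[0].residues[0].atoms[0].x == pytest.approx(0.0)

    def test_hydrogens_discarded(self):
        lines = [
            pdb_line("ATOM", 1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0),
            pdb_line("ATOM", 2, "H", "GLY", "A", 1, 0.5, 0.0, 0.0, element="H"),
        ]
        model = parse_structure("\n".join(lines) + "\n")
        assert [a.element for a in model.chains[0].residues[0].atoms] == ["C"]

    def test_malformed_record_names_line(self):
        good = pdb_line("ATOM", 1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0)
        bad = good[:30] + "xxxxxxxx" + good[38:]
        with pytest.raises(PDBParseError, match="line 2"):
            parse_structure(good + "\n" + bad + "\n")

    def test_no_atoms_raises(self):
        with pytest.raises(EmptyStructureError):
            parse_structure("TITLE  empty\nEND\n")


# ---------------------------------------------------------------------------
# contact extraction
# ---------------------------------------------------------------------------

class TestExtractContacts:
    def test_single_contact_geometry(self, simple_model):
        # GLY CA is 3.5 Å from the ligand atom, others are farther
        het = simple_model.het_groups[0]
        recs = extract_contacts(simple_model, het, cutoff=4.0)
        assert [(r.residue_name, r.residue_number) for r in recs] == [("G", 1)]
        assert recs[0].min_distance == pytest.approx(3.5)

    def test_below_cutoff_empty(self, simple_model):
        recs = extract_contacts(simple_model, simple_model.het_groups[0], cutoff=3.0)
        assert recs == []

    def test_unknown_ligand_raises(self, simple_model):
        stranger = HetGroup("GTP", "Z", 9, "", [Atom("C1", "C", 0, 0, 0)])
        with pytest.raises(LigandNotFoundError):
            extract_contacts(simple_model, stranger, 4.0)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        spec = random_toy_spec(seed)
        model = parse_structure(make_toy_complex(spec), structure_id=spec.structure_id)
        het = model.het_groups[0]
        oracle = brute_force_contact_positions(model, het, spec.cutoff)
        recs = extract_contacts(model, het, spec.cutoff)
        assert {
            (r.residue_chain, r.residue_number, r.insertion_code) for r in recs
        } == set(oracle)
        for r in recs:
            assert r.min_distance == pytest.approx(
                oracle[(r.residue_chain, r.residue_number, r.insertion_code)]
            )

    @pytest.mark.parametrize("seed", range(8))
    def test_cutoff_monotonicity(self, seed):
        spec = random_toy_spec(seed)
        model = parse_structure(make_toy_complex(spec))
        het = model.het_groups[0]
        previous: set = set()
        for cutoff in (2.0, 3.0, 4.0, 6.0, 9.0):
            current = {
                (r.residue_chain, r.residue_number)
                for r in extract_contacts(model, het, cutoff)
            }
            assert previous <= current
            previous = current

    def test_rigid_transform_invariance(self):
        spec = random_toy_spec(7)
        model = parse_structure(make_toy_complex(spec))
        angle = 0.81
        rot = np.array(
            [
                [math.cos(angle), -math.sin(angle), 0],
                [math.sin(angle), math.cos(angle), 0],
                [0, 0, 1],
            ]
        )
        shift = np.array([12.3, -4.5, 8.8])

        def move(atom: Atom) -> Atom:
            xyz = rot @ np.array([atom.x, atom.y, atom.z]) + shift
            return Atom(atom.name, atom.element, *xyz, atom.occupancy, atom.altloc)

        moved = StructureModel(
            structure_id=model.structure_id,
            chains=[
                Chain(c.chain_id, [
                    Residue(r.name, r.number, r.icode, [move(a) for a in r.atoms])
                    for r in c.residues
                ])
                for c in model.chains
            ],
            het_groups=[
                HetGroup(h.code, h.chain_id, h.number, h.icode, [move(a) for a in h.atoms])
                for h in model.het_groups
            ],
        )
        before = extract_contacts(model, model.het_groups[0], 4.0)
        after = extract_contacts(moved, moved.het_groups[0], 4.0)
        assert [(r.residue_number, r.residue_name) for r in before] == [
            (r.residue_number, r.residue_name) for r in after
        ]
        for b, a in zip(before, after):
            assert abs(b.min_distance - a.min_distance) < 1e-6


# ---------------------------------------------------------------------------
# dataset building and filtering
# ---------------------------------------------------------------------------

class TestBuildDataset:
    def test_counts_by_construction(self, toy_model_factory):
        model, spec = toy_model_factory(length=10, contact_positions={3, 7}, seed=11)
        ds = build_dataset([model], spec.ligand_code)
        assert ds.site_count == 1
        assert ds.interacting_counts.sum() == 2
        assert ds.total_counts.sum() == 10
        [chain] = ds.chains
        assert chain.interacting_positions == {3, 7}
        assert len(chain.sequence) == 10

    def test_two_identical_models_double_counts(self, toy_model_factory):
        model, spec = toy_model_factory(length=12, contact_positions={1, 5, 9}, seed=3)
        single = build_dataset([model], spec.ligand_code)
        double = build_dataset([model, model], spec.ligand_code)
        assert double.site_count == 2 * single.site_count
        assert (double.interacting_counts == 2 * single.interacting_counts).all()
        assert (double.total_counts == 2 * single.total_counts).all()

    def test_additivity_over_disjoint_collections(self, toy_model_factory):
        m1, spec1 = toy_model_factory(length=9, contact_positions={2}, seed=21,
                                      structure_id="toyA")
        m2, spec2 = toy_model_factory(length=14, contact_positions={4, 8}, seed=22,
                                      structure_id="toyB")
        union = build_dataset([m1, m2], "ATP")
        d1 = build_dataset([m1], "ATP")
        d2 = build_dataset([m2], "ATP")
        assert union.site_count == d1.site_count + d2.site_count
        assert (union.interacting_counts == d1.interacting_counts + d2.interacting_counts).all()
        assert (union.total_counts == d1.total_counts + d2.total_counts).all()

    def test_counts_match_oracle_recount(self):
        rng = np.random.default_rng(5)
        models, specs = [], []
        for seed in rng.integers(0, 10_000, size=10):
            spec = random_toy_spec(int(seed))
            models.append(parse_structure(make_toy_complex(spec),
                                          structure_id=spec.structure_id))
            specs.append(spec)
        ds = build_dataset(models, "ATP")
        from ligprop.amino_acids import AA_INDEX
        R = np.zeros(20, dtype=int)
        N = np.zeros(20, dtype=int)
        sites = 0
        for model, spec in zip(models, specs):
            het = model.het_groups[0]
            oracle = brute_force_contact_positions(model, het, 4.0)
            if not oracle:
                continue
            sites += 1
            chain = model.chains[0]
            for (_, num, _icode) in oracle:
                res = next(r for r in chain.residues if r.number == num)
                R[AA_INDEX[res.one_letter]] += 1
            for res in chain.residues:
                N[AA_INDEX[res.one_letter]] += 1
        assert ds.site_count == sites
        assert (ds.interacting_counts == R).all()
        assert (ds.total_counts == N).all()

    def test_absent_ligand_raises(self, toy_model_factory):
        model, _ = toy_model_factory(length=6, contact_positions={2}, seed=2)
        with pytest.raises(EmptyDatasetError):
            build_dataset([model], "GTP")

    def test_json_round_trip(self, toy_model_factory):
        from ligprop import LigandDataset

        model, spec = toy_model_factory(length=8, contact_positions={1, 8}, seed=9)
        ds = build_dataset([model], spec.ligand_code)
        again = LigandDataset.from_json(ds.to_json())
        assert again.ligand_code == ds.ligand_code
        assert (again.interacting_counts == ds.interacting_counts).all()
        assert again.chains[0].interacting_positions == ds.chains[0].interacting_positions


class TestFilterLigands:
    @pytest.mark.parametrize("sites,kept", [(29, False), (30, True), (31, True)])
    def test_threshold_is_inclusive(self, sites, kept, toy_model_factory):
        model, spec = toy_model_factory(length=5, contact_positions={1}, seed=1)
        ds = build_dataset([model], spec.ligand_code)
        ds.site_count = sites
        assert (filter_ligands([ds], min_sites=30) == [ds]) is kept

    def test_min_sites_one_is_identity(self, toy_model_factory):
        model, spec = toy_model_factory(length=5, contact_positions={1}, seed=1)
        ds = build_dataset([model], spec.ligand_code)
        assert filter_ligands([ds, ds], min_sites=1) == [ds, ds]


def test_contacts_table_columns(simple_model):
    recs = extract_contacts(simple_model, simple_model.het_groups[0], 4.0)
    frame = contacts_to_table(recs)
    assert list(frame.columns[:3]) == ["ligand_code", "structure_id", "ligand_chain"]
    assert frame.loc[0, "residue_name"] == "G"
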