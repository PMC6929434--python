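"""Stereo- and aromaticity-aware matching, MCS rescue, query library."""
import pytest
from rdkit import Chem

from biounits.chemgraph import parse_structure
from biounits.config import DisassemblerConfig
from biounits.library import UnitLibrary, unit_from_smiles
from biounits.matching import (
    build_query_library,
    find_embeddings,
    has_substructure,
    mcs_with_ambiguity,
)

from .oracles import count_embeddings, subgraph_embeds

ALPHA_GLC = "C([C@@H]1[C@H]([C@@H]([C@H]([C@H](O1)O)O)O)O)O"
BETA_GLC = "C([C@@H]1[C@H]([C@@H]([C@H]([C@@H](O1)O)O)O)O)O"
# D-glucose with the anomeric centre left unspecified
UNSPEC_GLC = "C([C@@H]1[C@H]([C@@H]([C@H](C(O1)O)O)O)O)O"
TERPHENYL = "c1ccc(-c2ccc(-c3ccccc3)cc2)cc1"  # 18 aromatic bonds
DIPHENYL_DIENE = r"C(=C/c1ccccc1)\C=C\c1ccccc1"  # same atoms, localized middle


@pytest.fixture(scope="module")
def glucoside(suite_by_name):
    return suite_by_name["cinnamyl-glucoside"].mol


class TestHasSubstructure:
    def test_alpha_glucose_contained_in_alpha_glucoside(self, glucoside):
        assert has_substructure(glucoside, parse_structure(ALPHA_GLC))

    def test_beta_glucose_not_contained(self, glucoside):
        assert not has_substructure(glucoside, parse_structure(BETA_GLC))

    def test_unspecified_stereocentre_matches_either(self, glucoside):
        assert has_substructure(glucoside, parse_structure(UNSPEC_GLC))

    def test_localized_diene_not_contained_in_aromatic_ring(self):
        assert not has_substructure(
            parse_structure(TERPHENYL), parse_structure(DIPHENYL_DIENE)
        )

    def test_chirality_can_be_disabled(self, glucoside):
        assert has_substructure(
            glucoside, parse_structure(BETA_GLC), use_chirality=False
        )


class TestFindEmbeddings:
    def test_benzene_in_biphenyl_two_disjoint_embeddings(self):
        biphenyl = parse_structure("c1ccc(-c2ccccc2)cc1")
        benzene = parse_structure("c1ccccc1")
        embs = find_embeddings(biphenyl, benzene, max_embeddings=8)
        assert len(embs) == 2
        assert embs[0].atoms.isdisjoint(embs[1].atoms)
        assert count_embeddings(biphenyl, benzene) == 2

    def test_self_embedding_unique(self):
        mol = parse_structure("NCCCCCN")
        embs = find_embeddings(mol, parse_structure("NCCCCCN"), max_embeddings=8)
        assert len(embs) == 1

    def test_first_match_only_by_default(self):
        quinolizidine = parse_structure("C1CCN2CCCCC2C1")
        chain = parse_structure("CCCCC")
        assert len(find_embeddings(quinolizidine, chain, max_embeddings=1)) == 1
        assert len(find_embeddings(quinolizidine, chain, max_embeddings=16)) > 1

    def test_injective_atom_map(self):
        embs = find_embeddings(
            parse_structure("CCOCC"), parse_structure("CCO"), max_embeddings=4
        )
        for emb in embs:
            assert len(set(emb.atom_map)) == len(emb.atom_map)


class TestMcsWithAmbiguity:
    def test_identical_molecules_cover_without_ambiguity(self):
        mol = parse_structure("OC(=O)/C=C/c1ccccc1")
        res = mcs_with_ambiguity(mol, Chem.Mol(mol))
        assert res.covers_unit
        assert res.n_ambiguous_bonds == 0

    def test_benzene_vs_cyclohexadiene_fully_ambiguous(self):
        res = mcs_with_ambiguity(
            parse_structure("c1ccccc1"), parse_structure("C1=CC=CCC1")
        )
        assert res.covers_unit
        assert res.n_ambiguous_bonds == 6
        assert res.ambiguity_ratio > 0.2

    def test_terphenyl_diene_ratio_at_rescue_boundary(self):
        res = mcs_with_ambiguity(
            parse_structure(TERPHENYL), parse_structure(DIPHENYL_DIENE)
        )
        assert res.covers_unit
        assert res.n_ambiguous_bonds == 3
        assert res.ambiguity_ratio == pytest.approx(0.2)

    def test_disjoint_elements_tiny_mcs(self):
        res = mcs_with_ambiguity(parse_structure("ClC(Cl)(Cl)Cl"), parse_structure("O"))
        assert not res.covers_unit
        assert res.n_atoms <= 1


class TestBuildQueryLibrary:
    def _lib(self, *units):
        lib = UnitLibrary()
        for i, (smi, role) in enumerate(units):
            lib.add(unit_from_smiles(f"u{i}-{smi[:8]}", smi, role))
        return lib

    def test_sorted_by_decreasing_atom_count(self, default_lib, suite_by_name):
        target = suite_by_name["cinnamyl-glucoside"].mol
        qlib = build_query_library(target, default_lib)
        sizes = [e.unit.n_atoms for e in qlib]
        assert sizes == sorted(sizes, reverse=True)
        assert qlib.n_bul > 0

    def test_rescue_requires_aromatic_rich_query(self):
        # 6 aromatic bonds only: the localized-diene unit stays excluded
        lib = self._lib(("C1=CC=CCC1", "BBU"))
        qlib = build_query_library(parse_structure("c1ccccc1"), lib)
        assert qlib.n_bul == 0

    def test_rescue_included_above_threshold_and_ratio(self):
        lib = self._lib((DIPHENYL_DIENE, "BBU"))
        qlib = build_query_library(parse_structure(TERPHENYL), lib)
        assert qlib.n_bul == 1
        assert qlib.entries[0].rescued

    def test_aromatic_rich_but_ratio_too_high_still_excluded(self):
        # cyclohexadiene maps entirely onto one aromatic ring: ratio 1.0
        lib = self._lib(("C1=CC=CCC1", "BBU"))
        qlib = build_query_library(parse_structure(TERPHENYL), lib)
        assert qlib.n_bul == 0

    def test_non_rescued_units_verified_by_independent_oracle(
        self, default_lib, suite
    ):
        for f in suite[:6]:
            qlib = build_query_library(f.mol, default_lib)
            for entry in qlib:
                if not entry.rescued:
                    assert subgraph_embeds(f.mol, entry.unit.mol), entry.unit.id

    def test_monotone_under_library_growth(self, suite_by_name):
        target = suite_by_name["c2-ala"].mol
        small = self._lib(("CC(=O)O", "BBU"))
        bigger = self._lib(("CC(=O)O", "BBU"), ("C[C@@H](N)C(=O)O", "BBU"))
        ids_small = {e.unit.key for e in build_query_library(target, small)}
        ids_big = {e.unit.key for e in build_query_library(target, bigger)}
        assert ids_small <= ids_big

    def test_epimer_pair_exactly_one_matches(self, suite_by_name):
        glycoside = suite_by_name["cinnamyl-glucoside"].mol
        lib = self._lib((ALPHA_GLC, "PBU"), (BETA_GLC, "PBU"))
        qlib = build_query_library(glycoside, lib)
        assert qlib.n_bul == 1
        assert qlib.entries[0].unit.key == Chem.CanonSmiles(ALPHA_GLC)
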