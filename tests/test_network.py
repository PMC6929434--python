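"""Fragment digestion and network construction."""
import pytest
from rdkit import Chem

from biounits.chemgraph import attachment_count, parse_structure, plain_key
from biounits.config import DisassemblerConfig
from biounits.errors import ContractViolation, SearchSpaceExceeded
from biounits.matching import Embedding, build_query_library, find_embeddings
from biounits.network import FragmentNetwork, build_network, digest
from biounits.search import unit_budget


def root_of(smiles: str):
    net = FragmentNetwork(parse_structure(smiles))
    return net.root_fragment


class TestDigest:
    def test_unit_spanning_whole_fragment_is_no_op(self):
        root = root_of("c1ccccc1")
        emb = find_embeddings(root.mol, parse_structure("c1ccccc1"))[0]
        assert digest(root, emb) == [root]

    def test_benzene_cut_out_of_ethylbenzene(self):
        root = root_of("CCc1ccccc1")
        emb = find_embeddings(root.mol, parse_structure("c1ccccc1"))[0]
        children = sorted(digest(root, emb), key=lambda f: f.n_atoms)
        assert [c.n_atoms for c in children] == [2, 6]
        assert children[0].plain == "CC"
        assert children[1].plain == "c1ccccc1"
        # exactly one attachment stub on each side of the cut
        assert attachment_count(children[0].mol) == 1
        assert attachment_count(children[1].mol) == 1

    def test_glucoside_digestion_partitions_provenance(self, suite_by_name):
        fx = suite_by_name["cinnamyl-glucoside"]
        root = FragmentNetwork(fx.mol).root_fragment
        glucose = fx.units[0]
        emb = find_embeddings(root.mol, glucose.mol)[0]
        children = digest(root, emb)
        assert len(children) == 2
        atom_union = frozenset().union(*(c.atoms for c in children))
        assert atom_union == root.atoms
        assert sum(c.n_atoms for c in children) == root.n_atoms
        assert sorted(c.plain for c in children) == list(fx.ground_truth_keys)

    def test_embedding_outside_fragment_rejected(self):
        root = root_of("CCO")
        with pytest.raises(ContractViolation):
            digest(root, Embedding("bogus", (0, 99)))

    def test_stereo_descriptor_dropped_at_cut_bond(self):
        # cutting the allylic C-C leaves a terminal alkene with no E/Z partner
        root = root_of(r"C/C=C/CC(=O)O")
        emb = find_embeddings(root.mol, parse_structure("CC(=O)O"))[0]
        children = digest(root, emb)
        for child in children:
            Chem.SanitizeMol(Chem.MolFromSmiles(child.plain))  # must be valid


class TestBuildNetwork:
    def test_target_equal_to_unit_single_node_no_stage_b(self, suite_by_name):
        fx = suite_by_name["phe-identity"]
        qlib = build_query_library(fx.mol, fx.library())
        net = build_network(fx.mol, qlib)
        assert net.root_fragment.resolved
        assert len(net.fragments) == 1 and not net.events

    def test_two_unit_fixture_one_digestion_event(self, suite_by_name):
        fx = suite_by_name["c2-ala"]
        qlib = build_query_library(fx.mol, fx.library())
        net = build_network(fx.mol, qlib)
        assert len(net.events) == 1
        event = net.events[0]
        assert len(event.children) == 2
        leaf_keys = sorted(f.plain for f in net.leaves())
        assert leaf_keys == list(fx.ground_truth_keys)

    def test_planted_units_appear_as_leaves(self, suite_by_name):
        fx = suite_by_name["c2-chain-3"]
        qlib = build_query_library(fx.mol, fx.library())
        net = build_network(fx.mol, qlib)
        leaf_keys = [f.plain for f in net.leaves() if f.resolved]
        for key in set(fx.ground_truth_keys):
            assert key in leaf_keys

    def test_atom_conservation_every_event(self, suite, default_lib):
        for fx in suite:
            qlib = build_query_library(fx.mol, fx.library())
            net = build_network(fx.mol, qlib)
            for ev in net.events:
                child_sets = [net.fragments[c].atoms for c in ev.children]
                union = frozenset().union(*child_sets)
                assert union == ev.parent
                assert sum(len(s) for s in child_sets) == len(ev.parent)

    def test_stage_a_budget_instrumented(self, suite, default_lib):
        for fx in suite:
            qlib = build_query_library(fx.mol, default_lib)
            if qlib.n_bul == 0:
                continue
            net = build_network(fx.mol, qlib)
            assert net.stage_a_non_pbu_used <= unit_budget(qlib.n_bul)

    def test_rebuild_gives_identical_node_keys(self, suite_by_name):
        fx = suite_by_name["cadaverine-diacetate"]
        qlib = build_query_library(fx.mol, fx.library())
        first = build_network(fx.mol, qlib)
        second = build_network(fx.mol, qlib)
        assert first.node_keys() == second.node_keys()
        assert len(first.events) == len(second.events)

    def test_dead_end_marked_not_raised(self):
        # nothing in the library embeds into the leftover two-carbon piece
        target = parse_structure("c1ccccc1CC")
        from biounits.library import UnitLibrary, unit_from_smiles

        lib = UnitLibrary([unit_from_smiles("benzene", "c1ccccc1", "BBU")])
        qlib = build_query_library(target, lib)
        net = build_network(target, qlib)
        dead = [f for f in net.fragments.values() if f.dead_end]
        assert len(dead) == 1 and dead[0].plain == "CC"

    def test_node_cap_raises_search_space_exceeded(self, suite_by_name):
        fx = suite_by_name["dodecanoic-c2"]
        qlib = build_query_library(fx.mol, fx.library())
        cfg = DisassemblerConfig(max_network_nodes=3)
        with pytest.raises(SearchSpaceExceeded):
            build_network(fx.mol, qlib, cfg)

    def test_networkx_export_shares_nodes_for_identical_fragments(
        self, suite_by_name
    ):
        fx = suite_by_name["biphenyl"]
        qlib = build_query_library(fx.mol, fx.library())
        net = build_network(fx.mol, qlib)
        g = net.to_networkx()
        # two benzene occurrences, one key-level node
        benzene_nodes = [
            n for n, d in g.nodes(data=True) if d["smiles"] == "c1ccccc1"
        ]
        assert len(benzene_nodes) == 1
        assert g.number_of_nodes() < len(net.fragments) + 1 or len(net.fragments) == 2
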