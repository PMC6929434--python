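"""Genetic-algorithm baseline: fitness, operators, reproducibility."""
import pytest

from biounits.errors import ConfigurationError, ContractViolation
from biounits.ga import (
    FitnessEvaluator,
    GAConfig,
    digestible_bonds,
    run_ga,
    tanimoto,
)
from biounits.chemgraph import parse_structure
from biounits.matching import build_query_library


def small_cfg(**kw):
    defaults = dict(population=60, generations=10, seed=11)
    defaults.update(kw)
    return GAConfig(**defaults)


def planted_genome(fx, evaluator):
    """Genome whose 1-bits are exactly the planted junction bonds."""
    junction_bond_ids = {
        fx.mol.GetBondBetweenAtoms(i, j).GetIdx() for i, j in fx.junction_bonds
    }
    assert junction_bond_ids <= set(evaluator.bonds)
    return tuple(1 if b in junction_bond_ids else 0 for b in evaluator.bonds)


class TestTanimoto:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((1, 1, 0, 1), (1, 1, 0, 1), 1.0),
            ((1, 1, 0, 0), (0, 0, 1, 1), 0.0),
            ((1, 1, 0, 0), (0, 1, 1, 0), 1 / 3),
            ((0, 0, 0), (0, 0, 0), 0.0),
        ],
    )
    def test_bit_vector_values(self, a, b, expected):
        assert tanimoto(a, b) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractViolation):
            tanimoto((1, 0), (1, 0, 1))

    def test_matches_rdkit_on_fingerprints(self):
        from rdkit.Chem import rdFingerprintGenerator

        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
        fa = gen.GetFingerprint(parse_structure("CC(=O)O"))
        fb = gen.GetFingerprint(parse_structure("CCC(=O)O"))
        assert tanimoto(fa, fb) == pytest.approx(
            tanimoto(tuple(fa), tuple(fb))
        )


class TestFitness:
    def test_default_config_matches_published_baseline(self):
        cfg = GAConfig()
        assert (cfg.population, cfg.crossover_prob, cfg.mutation_prob) == (
            300,
            0.80,
            0.005,
        )
        assert (cfg.generations, cfg.fp_radius, cfg.fp_bits, cfg.top_k) == (
            200,
            2,
            1024,
            5,
        )

    def test_digestible_bonds_default_universe(self):
        mol = parse_structure("CCc1ccccc1")  # 1 C-C + 1 C-aryl acyclic single
        assert len(digestible_bonds(mol)) == 2
        assert len(digestible_bonds(mol, cut_all=True)) == 8

    def test_planted_cut_scores_one(self, suite_by_name):
        fx = suite_by_name["c2-ala"]
        qlib = build_query_library(fx.mol, fx.library())
        ev = FitnessEvaluator(fx.mol, qlib, GAConfig())
        assert ev(planted_genome(fx, ev)) == pytest.approx(1.0)

    def test_all_zero_genome_on_unit_target_scores_one(self, suite_by_name):
        fx = suite_by_name["phe-identity"]
        qlib = build_query_library(fx.mol, fx.library())
        ev = FitnessEvaluator(fx.mol, qlib, GAConfig())
        assert ev(tuple([0] * len(ev.bonds))) == pytest.approx(1.0)

    def test_isolated_single_atom_scores_low(self, suite_by_name):
        fx = suite_by_name["c2-ala"]
        qlib = build_query_library(fx.mol, fx.library())
        ev = FitnessEvaluator(fx.mol, qlib, GAConfig())
        genome = tuple([1] * len(ev.bonds))  # shatter everything
        assert ev(genome) < 0.3

    def test_empty_query_library_rejected(self, suite_by_name):
        from biounits.matching import QueryLibrary

        fx = suite_by_name["c2-ala"]
        with pytest.raises(ConfigurationError):
            FitnessEvaluator(fx.mol, QueryLibrary(), GAConfig())

    def test_genome_length_contract(self, suite_by_name):
        fx = suite_by_name["c2-ala"]
        qlib = build_query_library(fx.mol, fx.library())
        ev = FitnessEvaluator(fx.mol, qlib, GAConfig())
        with pytest.raises(ContractViolation):
            ev((0, 1))


class TestRunGa:
    def test_unit_target_reaches_one(self, suite_by_name):
        fx = suite_by_name["phe-identity"]
        qlib = build_query_library(fx.mol, fx.library())
        results = run_ga(fx.mol, qlib, small_cfg(generations=5))
        assert results[0][0].fitness == pytest.approx(1.0)

    def test_two_unit_fixture_top5_contains_planted_cut(self, suite_by_name):
        fx = suite_by_name["c2-ala"]
        qlib = build_query_library(fx.mol, fx.library())
        results = run_ga(fx.mol, qlib, GAConfig(generations=20, seed=1))
        best_fits = [ind.fitness for ind, _ in results]
        assert any(f == pytest.approx(1.0) for f in best_fits)
        decoded = [combo.key_multiset for _, combo in results]
        assert fx.ground_truth_keys in decoded

    def test_seed_reproducibility(self, suite_by_name):
        fx = suite_by_name["c2-ala"]
        qlib = build_query_library(fx.mol, fx.library())
        a = run_ga(fx.mol, qlib, small_cfg(seed=42))
        b = run_ga(fx.mol, qlib, small_cfg(seed=42))
        assert [i.genome for i, _ in a] == [i.genome for i, _ in b]
        assert [i.fitness for i, _ in a] == [i.fitness for i, _ in b]

    def test_zero_generations_ranks_initial_population(self, suite_by_name):
        fx = suite_by_name["c2-ala"]
        qlib = build_query_library(fx.mol, fx.library())
        a = run_ga(fx.mol, qlib, small_cfg(generations=0, seed=3))
        b = run_ga(fx.mol, qlib, small_cfg(generations=0, seed=3))
        assert [i.genome for i, _ in a] == [i.genome for i, _ in b]

    def test_elitism_makes_best_fitness_monotone(self, suite_by_name):
        fx = suite_by_name["lys-ala"]
        qlib = build_query_library(fx.mol, fx.library())
        log = []
        run_ga(fx.mol, qlib, small_cfg(generations=12, seed=5), log=log)
        best = [b for _, b, _ in log]
        assert all(x <= y for x, y in zip(best, best[1:]))

    def test_workflow_cuts_encode_as_perfect_genome(self, suite, default_lib):
        # wherever the knowledge-based workflow resolves a fixture, the
        # genome encoding its junction cuts must reach fitness 1.0
        for fx in suite:
            if fx.name == "dodecanoic-c2":
                continue  # excluded by the fragment limit in the main workflow
            qlib = build_query_library(fx.mol, fx.library())
            ev = FitnessEvaluator(fx.mol, qlib, GAConfig())
            assert ev(planted_genome(fx, ev)) == pytest.approx(1.0), fx.name
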