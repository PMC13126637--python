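"""Genetic optimizer: fitness, elite selection, convergence, campaigns."""

import numpy as np
import pytest

from molevolve import (
    GAConfig,
    MoleculeRecord,
    PolicyConfig,
    PolicyNetwork,
    check_convergence,
    fitness,
    mock_scorer,
    run_campaign,
    select_elite,
)
from molevolve.ga import (
    Campaign,
    EliteMember,
    TraceRow,
    WORST_FITNESS,
    score_molecule,
)
from molevolve.properties import fingerprint, tanimoto


def make_variants(seed=0):
    return [(m, PolicyNetwork(PolicyConfig(), rng_seed=seed + m))
            for m in (1, 2, 3)]


class TestFitness:
    def test_single_target_is_ligand_efficiency(self):
        rec = MoleculeRecord.from_smiles("C" * 25)
        score = score_molecule(rec, [lambda s: -9.0], "single_target")
        assert score.le[0] == pytest.approx(-1.8)
        assert score.fitness == pytest.approx(-1.8)

    def test_harmonic_mean_identities(self):
        assert fitness([-2.0, -2.0], "dual_target") == pytest.approx(-2.0)
        assert fitness([-3.0, -1.0], "dual_target") == pytest.approx(-1.5)

    def test_mixed_sign_gets_sentinel(self):
        assert fitness([-3.0, 1.0], "dual_target") == WORST_FITNESS
        assert fitness([0.0, -1.0], "dual_target") == WORST_FITNESS

    def test_arity_checked(self):
        with pytest.raises(ValueError):
            fitness([-1.0, -2.0], "single_target")
        with pytest.raises(ValueError):
            fitness([-1.0], "dual_target")


def member(smiles, fit):
    from types import SimpleNamespace

    rec = MoleculeRecord.from_smiles(smiles)
    return EliteMember(record=rec, score=SimpleNamespace(fitness=fit),
                       fp=fingerprint(rec))


class TestSelectElite:
    def test_duplicates_collapse(self):
        cands = [member("c1ccccc1", -2.0), member("c1ccccc1", -1.9)]
        elite = select_elite(cands, 20, 0.4)
        assert len(elite) == 1

    def test_sim_cut_one_is_pure_top_n(self):
        cands = [member("c1ccccc1", -2.0), member("c1ccccc1", -1.9),
                 member("CCO", -1.5)]
        elite = select_elite(cands, 2, 1.0)
        assert len(elite) == 2
        assert elite[0].score.fitness == -2.0

    def test_greedy_matches_bruteforce_oracle(self):
        smiles = ["Clc1ccccc1", "Brc1ccccc1", "CCCCCCO", "CCCCCCN",
                  "O=C1CCCCC1"]
        cands = [member(s, -3.0 + 0.1 * i) for i, s in enumerate(smiles)]
        sim_cut = 0.4
        elite = select_elite(cands, 20, sim_cut)
        # independent brute-force greedy scan
        expected = []
        for c in cands:
            if all(tanimoto(c.fp, e.fp) < sim_cut for e in expected):
                expected.append(c)
        assert [e.record.smiles for e in elite] == \
            [e.record.smiles for e in expected]
        # the global best always survives selection
        assert elite[0].record.smiles == "Clc1ccccc1"


def flat_trace(n, best=-5.0, mean=-3.0, pop=50, new_best=False, start=1):
    return [TraceRow(generation=start + i, best_fitness=best,
                     mean_fitness=mean, population_size=pop,
                     new_global_best=new_best) for i in range(n)]


class TestConvergence:
    def test_all_four_satisfied(self):
        trace = flat_trace(100, pop=150) + flat_trace(30, pop=50, start=101)
        converged, which = check_convergence(trace, GAConfig(),
                                             max_population=150)
        assert which == {1, 2, 3, 4}
        assert converged

    def test_improving_best_never_converges_alone(self):
        trace = []
        for g in range(150):
            trace.append(TraceRow(generation=g + 1, best_fitness=-g,
                                  mean_fitness=-g * 1.0, population_size=200,
                                  new_global_best=True))
        converged, which = check_convergence(trace, GAConfig())
        assert which == {4}
        assert not converged

    def test_three_of_four_suffice(self):
        trace = flat_trace(120, pop=500)
        converged, which = check_convergence(trace, GAConfig())
        assert which == {1, 2, 4}
        assert converged

    def test_short_stagnation_not_enough(self):
        trace = flat_trace(10)
        converged, which = check_convergence(trace, GAConfig())
        assert not converged

    def test_population_floor_requires_prior_peak(self):
        trace = flat_trace(30, pop=50)
        _, which = check_convergence(trace, GAConfig(), max_population=50)
        assert 3 not in which
        _, which = check_convergence(trace, GAConfig(), max_population=150)
        assert 3 in which


class TestCampaign:
    def test_best_fitness_non_increasing_and_elite_diverse(self):
        cfg = GAConfig(elite_size=6, sim_cut=0.4, max_generations=6,
                       min_generations=100, rng_seed=3)
        campaign = Campaign(cfg, [mock_scorer("n_count")], make_variants(3))
        campaign.initialize([MoleculeRecord.from_smiles("C")])
        best_so_far = np.inf
        for _ in range(6):
            row = campaign.generation_step()
            assert row.best_fitness <= best_so_far
            best_so_far = row.best_fitness
            for i, a in enumerate(campaign.elite):
                for b in campaign.elite[i + 1:]:
                    assert tanimoto(a.fp, b.fp) < cfg.sim_cut

    def test_archive_grows_and_is_unique(self):
        cfg = GAConfig(elite_size=4, max_generations=4, rng_seed=5)
        campaign = Campaign(cfg, [mock_scorer("n_count")], make_variants(5))
        campaign.initialize([MoleculeRecord.from_smiles("C")])
        sizes = []
        for _ in range(4):
            campaign.generation_step()
            sizes.append(len(campaign.archive))
        assert sizes == sorted(sizes)
        frame = campaign.archive_frame()
        assert frame["smiles"].is_unique

    def test_scaffold_constraint_enforced(self):
        cfg = GAConfig(elite_size=4, max_generations=3,
                       scaffold_constraint="c1ccccc1", rng_seed=1)
        campaign = Campaign(cfg, [mock_scorer("n_count")], make_variants(1))
        with pytest.raises(ValueError):
            campaign.initialize([MoleculeRecord.from_smiles("C")])
        campaign.initialize([MoleculeRecord.from_smiles("c1ccccc1")])
        from rdkit import Chem

        patt = Chem.MolFromSmiles("c1ccccc1")
        for _ in range(3):
            campaign.generation_step()
        for smi in campaign.archive:
            assert Chem.MolFromSmiles(smi).HasSubstructMatch(patt)

    def test_dual_mode_fitness_consistency(self):
        cfg = GAConfig(elite_size=4, mode="dual_target", max_generations=3,
                       rng_seed=2)
        scorers = [mock_scorer("n_count"), mock_scorer("o_count")]
        campaign = Campaign(cfg, scorers, make_variants(2))
        campaign.initialize([MoleculeRecord.from_smiles("NCCO")])
        for _ in range(3):
            campaign.generation_step()
        frame = campaign.archive_frame()
        for _, row in frame.iterrows():
            if row["LE"] < 0 and row["LE2"] < 0:
                expected = 2 * row["LE"] * row["LE2"] / (row["LE"] + row["LE2"])
                assert row["F"] == pytest.approx(expected)

    def test_run_campaign_writes_outputs(self, tmp_path):
        cfg = GAConfig(elite_size=3, max_generations=3, rng_seed=7)
        campaign = run_campaign([MoleculeRecord.from_smiles("C")], cfg,
                                [mock_scorer("hetero_rings")],
                                make_variants(7), out_dir=str(tmp_path))
        assert (tmp_path / "archive.csv").exists()
        assert (tmp_path / "trace.csv").exists()
        assert len(campaign.trace) == 3

    def test_scorer_count_must_match_mode(self):
        with pytest.raises(ValueError):
            Campaign(GAConfig(), [mock_scorer("n_count"),
                                  mock_scorer("o_count")], make_variants())
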