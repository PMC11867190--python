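import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from pbdrates.params import PBDParams, SimulationConfig, TREE_SIM_DEFAULTS
from pbdrates.rates import PiecewiseConstantRates
from pbdrates.simulate import (
    count_extant_species,
    extract_good_species_tree,
    run_comparison_experiment,
    simulate_bd,
    simulate_bd_batch,
    simulate_pbd,
    simulate_pbd_batch,
)
from pbdrates.trees import FullTree, LineageRecord


class TestPBDGillespie:
    def test_all_rates_zero_is_a_single_quiet_lineage(self):
        p = PBDParams(0.0, 0.0, 0.0, 0.0, 0.0)
        full = simulate_pbd(p, SimulationConfig(T=15.0, seed=1))
        assert len(full.lineages) == 1
        assert full.lineages[0].death is None
        assert count_extant_species(full) == 1

    def test_no_initiation_means_one_species_forever(self):
        p = PBDParams(0.0, 0.4, 0.3, 0.0, 0.1)
        full = simulate_pbd(p, SimulationConfig(T=50.0, seed=2))
        assert count_extant_species(full) == 1
        assert len(full.lineages) == 1

    def test_pure_birth_limit_matches_yule_mean(self):
        """With instantaneous completion and no extinction the species count
        follows a stem pure-birth law with mean e^(lambda1*T)."""
        p = PBDParams(0.3, 1e4, 0.3, 0.0, 0.0)
        cfg = SimulationConfig(T=15.0, seed=3)
        counts = []
        for seed in range(500):
            full = simulate_pbd(p, cfg, rng=np.random.default_rng(seed))
            counts.append(count_extant_species(full))
        mean = np.mean(counts)
        expect = np.exp(0.3 * 15.0)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - expect) < 3 * se

    def test_times_within_bounds_and_ordered(self):
        full = simulate_pbd(TREE_SIM_DEFAULTS, SimulationConfig(T=15.0, seed=4))
        for rec in full.lineages:
            assert 0.0 <= rec.birth <= 15.0
            if rec.completion is not None and rec.id != 0:
                assert rec.completion > rec.birth
            if rec.death is not None:
                assert rec.death > rec.birth


class TestSpeciesTreeExtraction:
    def test_sole_surviving_root_gives_one_tip(self):
        recs = [LineageRecord(id=0, parent=None, birth=0.0, species=1, completion=0.0)]
        tree = extract_good_species_tree(FullTree(T=10.0, lineages=recs))
        assert tree.n_tips == 1
        assert tree.stem_length == 10.0

    def test_single_completed_daughter_crown_age_is_initiation_time(self):
        recs = [
            LineageRecord(id=0, parent=None, birth=0.0, species=1, completion=0.0),
            LineageRecord(id=1, parent=0, birth=4.0, species=2, completion=6.0),
        ]
        tree = extract_good_species_tree(FullTree(T=10.0, lineages=recs))
        assert tree.n_tips == 2
        assert tree.height == pytest.approx(6.0)  # crown age = T - initiation
        assert tree.is_ultrametric()

    def test_incipient_member_keeps_dead_species_extant(self):
        """Oldest-representative convention: a species whose completed lineage
        died but whose conspecific incipient lineage survives is extant."""
        recs = [
            LineageRecord(id=0, parent=None, birth=0.0, species=1, completion=0.0),
            LineageRecord(id=1, parent=0, birth=2.0, species=2, completion=3.0, death=8.0),
            LineageRecord(id=2, parent=1, birth=5.0, species=2),
        ]
        full = FullTree(T=10.0, lineages=recs)
        tree = extract_good_species_tree(full, convention="oldest")
        assert tree.n_tips == 2
        assert sorted(t for t in tree.tip_labels) == ["s1", "s2"]
        # under the strict flag the species dies with its good lineage
        strict = extract_good_species_tree(full, require_good_alive=True)
        assert strict.n_tips == 1

    def test_representative_convention_changes_divergence_time(self):
        """With two conspecific members alive, oldest vs youngest pick
        different divergence times for the sister species."""
        recs = [
            LineageRecord(id=0, parent=None, birth=0.0, species=1, completion=0.0),
            LineageRecord(id=1, parent=0, birth=2.0, species=1),   # incipient member of s1
            LineageRecord(id=2, parent=1, birth=6.0, species=1),   # later incipient member
            LineageRecord(id=3, parent=0, birth=7.0, species=2, completion=8.0),
        ]
        full = FullTree(T=10.0, lineages=recs)
        oldest = extract_good_species_tree(full, convention="oldest")
        youngest = extract_good_species_tree(full, convention="youngest")
        assert oldest.n_tips == youngest.n_tips == 2
        assert oldest.height == pytest.approx(3.0)  # root lineage vs initiation at 7
        # youngest representative of s1 is lineage 2, whose path leaves the
        # root branch at the initiation at time 2 -> divergence age 10 - 2 = 8
        assert youngest.height == pytest.approx(8.0)


class TestBDSimulator:
    def test_no_birth_with_conditioning_always_invalid(self):
        rates = PiecewiseConstantRates.constant(0.0, 0.2, 10.0)
        cfg = SimulationConfig(T=10.0, seed=5, condition_on_survivors=2, max_attempts=10)
        tree, attempts = simulate_bd(rates, cfg)
        assert tree is None
        assert attempts == 10

    def test_yule_mean_tip_count(self):
        rates = PiecewiseConstantRates.constant(0.3, 0.0, 10.0)
        cfg = SimulationConfig(T=10.0, seed=6, condition_on_survivors=1, max_attempts=1)
        tips = []
        for seed in range(800):
            tree, _ = simulate_bd(rates, cfg, rng=np.random.default_rng(seed))
            tips.append(tree.n_tips if tree is not None else 0)
        se = np.std(tips, ddof=1) / np.sqrt(len(tips))
        assert abs(np.mean(tips) - np.exp(3.0)) < 3 * se

    def test_piecewise_constant_equals_constant_given_same_seed(self):
        const = PiecewiseConstantRates.constant(0.4, 0.1, 12.0)
        pieces = PiecewiseConstantRates(
            edges=np.linspace(0, 12.0, 41), lam=np.full(40, 0.4), mu=np.full(40, 0.1)
        )
        cfg = SimulationConfig(T=12.0, seed=7)
        t1, _ = simulate_bd(const, cfg, rng=np.random.default_rng(99))
        t2, _ = simulate_bd(pieces, cfg, rng=np.random.default_rng(99))
        assert t1.to_newick() == t2.to_newick()

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            PiecewiseConstantRates(edges=[0, 1], lam=[0.1], mu=[-0.2])


class TestBatchesAndComparison:
    def test_same_seed_reproduces_batches_bitwise(self):
        cfg = SimulationConfig(T=10.0, seed=11)
        b1 = simulate_pbd_batch(TREE_SIM_DEFAULTS, cfg, 5)
        b2 = simulate_pbd_batch(TREE_SIM_DEFAULTS, cfg, 5)
        nwk1 = [t.to_newick() if t else None for t in b1.trees]
        nwk2 = [t.to_newick() if t else None for t in b2.trees]
        assert nwk1 == nwk2
        assert b1.seeds == b2.seeds

    def test_empty_batch(self):
        cfg = SimulationConfig(T=10.0, seed=11)
        b = simulate_pbd_batch(TREE_SIM_DEFAULTS, cfg, 0)
        assert b.trees == [] and b.n_valid == 0

    def test_batch_conditioning_and_manifest(self, pbd_batch_small):
        m = pbd_batch_small.manifest()
        assert (m.loc[m["valid"], "n_tips"] >= 2).all()
        assert m.shape[0] == 60
        assert (m["attempts"] >= 1).all()

    def test_comparison_experiment_runs_three_models(self):
        cfg = SimulationConfig(T=8.0, seed=21, n_grid=50)
        out = run_comparison_experiment(TREE_SIM_DEFAULTS, cfg, n_reps=8)
        assert set(out) == {"PBD", "varBD", "BD"}
        for batch in out.values():
            assert len(batch.trees) == 8

    def test_instantaneous_completion_pbd_indistinguishable_from_bd(self):
        """PBD with lambda2 = 1e4 and BD(lambda1, mu1) give the same
        species-richness distribution (two-sample test, alpha = 0.01)."""
        p = PBDParams(0.3, 1e4, 0.3, 0.1, 0.1)
        cfg = SimulationConfig(T=10.0, seed=31)
        pbd = simulate_pbd_batch(p, cfg, 300)
        bd = simulate_bd_batch(
            PiecewiseConstantRates.constant(0.3, 0.1, 10.0), cfg, 300
        )
        sr_pbd = [t.n_tips for t in pbd.valid_trees()]
        sr_bd = [t.n_tips for t in bd.valid_trees()]
        assert mannwhitneyu(sr_pbd, sr_bd).pvalue > 0.01
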