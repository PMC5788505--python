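"""Annealing schedule, Metropolis criterion, move set, and run aggregation."""

import math

import numpy as np
import pytest

from pathmapper.model import (
    CandidateSets,
    Metabolite,
    PathwayModel,
    Protein,
    canonical_key,
    enumerate_pathways,
    validate_pathway,
)
from pathmapper.restraints import RestraintSet, Scorer
from pathmapper.sampler import (
    SamplerConfig,
    metropolis_accept,
    propose_move,
    random_pathway,
    random_score_distribution,
    run_ensemble,
    run_mc,
    temperature,
)


class TestTemperature:
    def test_start_value(self):
        assert temperature(0.0) == pytest.approx(0.4)

    def test_end_value(self):
        assert temperature(1.0) == pytest.approx(0.16)

    def test_midpoint(self):
        assert temperature(0.5) == pytest.approx(0.234164, abs=1e-6)

    def test_strictly_decreasing(self):
        xs = np.linspace(0, 1, 101)
        ts = [temperature(x) for x in xs]
        assert all(a > b for a, b in zip(ts, ts[1:]))

    def test_domain_guard(self):
        with pytest.raises(ValueError):
            temperature(1.5)
        with pytest.raises(ValueError):
            temperature(-0.1)


class TestMetropolis:
    def test_improving_move_accepted_without_rng_draw(self):
        rng = np.random.default_rng(0)
        before = rng.bit_generator.state
        assert metropolis_accept(1.0, 2.0, 0.3, rng)
        assert rng.bit_generator.state == before

    def test_zero_difference_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(5.0, 5.0, 0.2, rng) for _ in range(100))

    def test_acceptance_rate_at_d_equals_t(self):
        # p = exp(-D/T) = e^-1 when D = T; binomial 3-sigma band over 1e5
        rng = np.random.default_rng(123)
        n = 10**5
        accepted = sum(metropolis_accept(1.0, 0.7, 0.3, rng) for _ in range(n))
        p = math.exp(-1)
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(accepted - n * p) < 3 * sigma

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            metropolis_accept(1.0, 0.0, 0.0, np.random.default_rng(0))


def _pools(n_prot, n_met, **kwargs):
    proteins = {f"E{i}": Protein(f"E{i}") for i in range(1, n_prot + 1)}
    mets = {f"M{i}": Metabolite(f"M{i}", "C") for i in range(1, n_met + 1)}
    return CandidateSets(proteins, mets, **kwargs)


class TestMoves:
    def test_moves_preserve_validity_and_type(self, tiny_candidates):
        rng = np.random.default_rng(5)
        p = PathwayModel(("M1", "E1", "M2", "E2", "M3"))
        for _ in range(200):
            q = propose_move(p, tiny_candidates, rng)
            ok, v = validate_pathway(q, tiny_candidates)
            assert ok, v
            diff = sum(a != b for a, b in zip(p.nodes, q.nodes))
            assert diff in (1, 2)
            p = q

    def test_only_swaps_when_pools_are_exhausted(self, tiny_candidates):
        # K=2 uses both proteins and all three metabolites: no replacements
        rng = np.random.default_rng(2)
        p = PathwayModel(("M1", "E1", "M2", "E2", "M3"))
        for _ in range(100):
            q = propose_move(p, tiny_candidates, rng)
            assert sorted(q.nodes) == sorted(p.nodes)

    def test_swap_exchanges_two_positions(self, tiny_candidates):
        rng = np.random.default_rng(3)
        p = PathwayModel(("M1", "E1", "M2", "E2", "M3"))
        q = propose_move(p, tiny_candidates, rng)
        assert set(q.nodes) == set(p.nodes)

    def test_constrained_positions_never_violated(self):
        c = _pools(3, 4, n_proteins_in_pathway=2,
                   position_constraints={0: {"M1"}, 1: {"E1"}})
        rng = np.random.default_rng(7)
        p = random_pathway(c, 2, rng)
        for _ in range(300):
            p = propose_move(p, c, rng)
            assert p.nodes[0] == "M1" and p.nodes[1] == "E1"

    def test_fully_constrained_instance_errors(self):
        c = _pools(1, 2, n_proteins_in_pathway=1,
                   position_constraints={0: {"M1"}, 1: {"E1"}, 2: {"M2"}})
        rng = np.random.default_rng(1)
        p = PathwayModel(("M1", "E1", "M2"))
        with pytest.raises(RuntimeError):
            propose_move(p, c, rng)


def _uniform_scorer(c):
    """Scorer over a single docking table so every pathway has a score."""
    rng = np.random.default_rng(99)
    from pathmapper.restraints import DockingTable

    docking = {
        pid: DockingTable(
            pid, {mid: float(rng.normal()) for mid in c.metabolites}
        )
        for pid in c.proteins
    }
    return Scorer(c, RestraintSet(docking=docking))


class TestRuns:
    def test_zero_steps_records_start_only(self, tiny_candidates):
        scorer = _uniform_scorer(tiny_candidates)
        cfg = SamplerConfig(n_steps=0, n_runs=1, n_random_models=10)
        visited = run_mc(tiny_candidates, scorer, cfg, run_seed=4)
        assert len(visited) == 1

    def test_same_seed_reproduces_visited_set_and_order(self, tiny_candidates):
        scorer = _uniform_scorer(tiny_candidates)
        cfg = SamplerConfig(n_steps=500, n_runs=1, n_random_models=10)
        a = run_mc(tiny_candidates, scorer, cfg, run_seed=8)
        b = run_mc(tiny_candidates, scorer, cfg, run_seed=8)
        assert list(a) == list(b)
        assert all(a[k].total == b[k].total for k in a)

    def test_tiny_instance_fully_covered(self, tiny_candidates):
        scorer = _uniform_scorer(tiny_candidates)
        cfg = SamplerConfig(n_steps=10_000, n_runs=1, n_random_models=10)
        visited = run_mc(tiny_candidates, scorer, cfg, run_seed=0)
        all_keys = {canonical_key(p) for p in enumerate_pathways(tiny_candidates, 2)}
        assert set(visited) == all_keys and len(all_keys) == 12

    def test_recorded_models_are_valid_with_fresh_scores(self, small_problem, small_scorer):
        cfg = SamplerConfig(n_steps=300, n_runs=2, n_random_models=50, seed=5)
        good = run_ensemble(small_problem.candidates, small_scorer, cfg)
        for sp in good.models.values():
            ok, v = validate_pathway(sp.pathway, small_problem.candidates)
            assert ok, v
            assert small_scorer.score_pathway(sp.pathway).total == sp.total

    def test_cutoff_arithmetic(self, small_problem, small_scorer):
        cfg = SamplerConfig(n_steps=200, n_runs=2, n_random_models=100,
                            seed=6, cutoff_sd=2.0)
        good = run_ensemble(small_problem.candidates, small_scorer, cfg)
        assert good.cutoff == pytest.approx(
            good.best_score - 2.0 * good.random_sd
        )
        assert all(s.total >= good.cutoff for s in good.models.values())
        cfg15 = SamplerConfig(n_steps=200, n_runs=2, n_random_models=100,
                              seed=6, cutoff_sd=1.5)
        good15 = run_ensemble(small_problem.candidates, small_scorer, cfg15)
        assert good15.cutoff == pytest.approx(
            good15.best_score - 1.5 * good15.random_sd
        )
        assert good15.cutoff >= good.cutoff
        assert len(good15.models) <= len(good.models)

    def test_random_score_distribution_reproducible(self, small_problem, small_scorer):
        a = random_score_distribution(small_problem.candidates, small_scorer, 200, seed=3)
        b = random_score_distribution(small_problem.candidates, small_scorer, 200, seed=3)
        assert a == b

    def test_random_sd_close_to_exhaustive_sd(self, small_problem, small_scorer):
        _, sd = random_score_distribution(
            small_problem.candidates, small_scorer, 4000, seed=9
        )
        totals = np.array(
            [
                small_scorer.score_pathway(p).total
                for p in enumerate_pathways(small_problem.candidates, 3)
            ]
        )
        assert sd == pytest.approx(totals.std(ddof=0), rel=0.05)
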