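"""Restraint terms, normalization statistics, and the composite score."""

import itertools
import logging

import numpy as np
import pytest

from pathmapper.model import (
    CandidateSets,
    Metabolite,
    PathwayModel,
    Protein,
    Transformation,
)
from pathmapper.restraints import (
    DockingTable,
    RestraintSet,
    Scorer,
    SEAMatrix,
    sea_sab,
    zscore,
)
from pathmapper.sampler import random_pathway


class TestZScore:
    def test_center_of_population(self):
        assert zscore(2, 2.0, 0.8164965809) == 0.0

    def test_one_sd_above(self):
        assert zscore(3.5, 2.0, 1.5) == pytest.approx(1.0)

    def test_degenerate_sd_returns_zero(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert zscore(5.0, 2.0, 0.0) == 0.0
        assert any("z-score" in r.message for r in caplog.records)


class TestSeaSab:
    def test_printed_glycolysis_pair_value_caps_at_50(self):
        # -log10(9.5e-63) ~ 62 exceeds the cap, and F = 1 at full confidence
        assert sea_sab(9.5e-63, 50.0, 50.0) == pytest.approx(50.0)

    def test_evalue_one_scores_zero(self):
        assert sea_sab(1.0, 50.0, 50.0) == 0.0

    def test_confidence_factor_arithmetic(self):
        assert sea_sab(1e-25, 50.0, 40.0) == pytest.approx(20.0)

    def test_nonpositive_evalue_rejected(self):
        with pytest.raises(ValueError):
            sea_sab(0.0)

    def test_symmetry_and_cap_on_random_matrices(self):
        rng = np.random.default_rng(0)
        pids = [f"P{i}" for i in range(6)]
        evalues = {(p, p): 10.0 ** -rng.uniform(0, 60) for p in pids}
        for a, b in itertools.combinations(pids, 2):
            evalues[(a, b)] = 10.0 ** -rng.uniform(0, 80)
        sea = SEAMatrix(evalues)
        for a, b in itertools.combinations(pids, 2):
            sab = sea.sab(a, b)
            assert sab == sea.sab(b, a)
            assert 0.0 <= sab <= 50.0
            assert min(-np.log10(sea.evalue(a, b)), 50.0) >= sab / 1.0 - 1e-12

    def test_missing_self_evalue_defaults_to_cap(self, caplog):
        sea = SEAMatrix({("A", "B"): 1e-10})
        with caplog.at_level(logging.WARNING):
            assert sea.sab("A", "B") == pytest.approx(10.0)


class TestDockingNormalization:
    def test_table_zscores_standardized(self):
        rng = np.random.default_rng(1)
        scores = {f"M{i}": float(rng.normal(-40, 6)) for i in range(500)}
        table = DockingTable("E1", scores)
        zs = np.array([table.z(m) for m in scores])
        assert abs(zs.mean()) < 1e-9
        assert abs(zs.std(ddof=0) - 1.0) < 1e-9

    def test_score_docking_is_negative_mean_of_pair_z(self, small_problem, small_scorer):
        truth = small_problem.truth
        expected = -np.mean(
            [
                small_problem.restraints.docking[prot].z(lig)
                for prot, lig in truth.protein_ligand_pairs()
            ]
        )
        assert small_scorer.score_docking(truth) == pytest.approx(expected)

    def test_missing_pairs_excluded_not_penalized(self):
        mets = {m: Metabolite(m, s) for m, s in
                [("M1", "CCO"), ("M2", "CC=O"), ("M3", "CC(=O)O")]}
        prots = {"E1": Protein("E1"), "E2": Protein("E2")}
        c = CandidateSets(prots, mets, 2)
        # Only E1 has a table, and it lacks M3: exactly two scored pairs.
        table = DockingTable("E1", {"M1": -2.0, "M2": 0.0, "M3b": 2.0, "M4b": 0.0})
        scorer = Scorer(c, RestraintSet(docking={"E1": table}))
        p = PathwayModel(("M1", "E1", "M2", "E2", "M3"))
        z1, z2 = table.z("M1"), table.z("M2")
        assert scorer.score_docking(p) == pytest.approx(-(z1 + z2) / 2)

    def test_no_scored_pairs_makes_term_absent(self):
        mets = {m: Metabolite(m, "CCO") for m in ["M1", "M2"]}
        c = CandidateSets({"E1": Protein("E1")}, mets, 1)
        table = DockingTable("E9", {"Mx": 1.0, "My": 2.0})
        scorer = Scorer(c, RestraintSet(docking={"E9": table}))
        assert scorer.score_docking(PathwayModel(("M1", "E1", "M2"))) is None


class TestSeaTerm:
    def _scorer(self, evalues, n=3):
        pids = [f"E{i + 1}" for i in range(n)]
        mets = {f"M{i}": Metabolite(f"M{i}", "CCO") for i in range(n + 1)}
        c = CandidateSets({p: Protein(p) for p in pids}, mets, n)
        return Scorer(c, RestraintSet(sea=SEAMatrix(evalues)))

    def test_population_normalization_arithmetic(self):
        # S_AB population {0, 10, 20}: mean 10, population sd 8.16497
        evalues = {
            ("E1", "E2"): 1.0,      # S = 0
            ("E1", "E3"): 1e-10,    # S = 10
            ("E2", "E3"): 1e-20,    # S = 20
        }
        evalues.update({(f"E{i}", f"E{i}"): 1e-50 for i in (1, 2, 3)})
        scorer = self._scorer(evalues)
        p = PathwayModel(("M0", "E2", "M1", "E3", "M2"))
        assert scorer.score_sea(p) == pytest.approx((20 - 10) / 8.1649658, abs=1e-6)

    def test_equal_pairs_score_zero_via_sd_guard(self):
        evalues = {(a, b): 1e-10 for a, b in itertools.combinations(["E1", "E2", "E3"], 2)}
        scorer = self._scorer(evalues)
        p = PathwayModel(("M0", "E1", "M1", "E2", "M2"))
        assert scorer.score_sea(p) == 0.0

    def test_single_protein_pathway_term_absent(self):
        scorer = self._scorer({("E1", "E2"): 1e-10}, n=2)
        assert scorer.score_sea(PathwayModel(("M0", "E1", "M1"))) is None


class TestCompositeScore:
    def test_total_equals_sum_of_terms_on_random_pathways(self, small_problem, small_scorer):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            p = random_pathway(small_problem.candidates, 3, rng)
            sp = small_scorer.score_pathway(p)
            assert sp.total == sum(sp.terms.values())

    def test_scoring_is_pure(self, small_problem, small_scorer):
        sp1 = small_scorer.score_pathway(small_problem.truth)
        sp2 = small_scorer.score_pathway(small_problem.truth)
        assert sp1.total == sp2.total and sp1.terms == sp2.terms

    def test_endpoint_term_rewards_central_metabolite(self, small_problem, small_scorer):
        truth = small_problem.truth
        z_true = small_scorer.score_endpoint(truth)
        others = [
            small_scorer._cm_z[mid]
            for mid in small_problem.candidates.metabolites
        ]
        assert z_true == pytest.approx(max(others))

    def test_transform_consistent_product_scores_best(self, small_problem, small_scorer):
        # Within the first triad, the true product maximizes the CT vector.
        sub, prot, prod = next(small_problem.truth.triads())
        cache = small_scorer._transform_cache(prot, sub)
        assert cache is not None
        assert cache.vector[prod] == pytest.approx(max(cache.vector.values()))
        assert cache.vector[prod] == pytest.approx(1.0)


class TestGeneCluster:
    def _scorer(self, members, pids):
        mets = {f"M{i}": Metabolite(f"M{i}", "CCO") for i in range(len(pids) + 1)}
        c = CandidateSets({p: Protein(p) for p in pids}, mets, len(pids) - 1)
        r = RestraintSet(gene_cluster=frozenset(members), enable_gc=True)
        return Scorer(c, r)

    def test_exact_cluster_match_overlap_one(self):
        scorer = self._scorer({"A", "B", "C"}, ["A", "B", "C", "D"])
        assert scorer.gene_cluster_overlap({"A", "B", "C"}) == 1.0

    def test_disjoint_overlap_zero(self):
        scorer = self._scorer({"A", "B", "C"}, ["A", "B", "C", "D", "E", "F"])
        assert scorer.gene_cluster_overlap({"D", "E", "F"}) == 0.0

    def test_partial_overlap_pair_counting(self):
        # cluster {A,B,C} has 3 pairs; pathway {A,B,D} has 3; shared {AB}
        scorer = self._scorer({"A", "B", "C"}, ["A", "B", "C", "D"])
        assert scorer.gene_cluster_overlap({"A", "B", "D"}) == pytest.approx(1 / 3)


@pytest.fixture(scope="module")
def swapped():
    """A planted problem scored before/after replacing E2 with the dummy."""
    from pathmapper import synthetic

    prob = synthetic.generate(
        synthetic.SyntheticConfig(
            k=3, n_decoy_proteins=1, n_decoy_metabolites=2,
            include_dummy=True, seed=3,
        )
    )
    scorer = prob.scorer()
    truth = prob.truth
    nodes = list(truth.nodes)
    nodes[3] = "DUMMY"  # replace the middle enzyme E2
    return prob, scorer, scorer.score_pathway(truth), scorer.score_pathway(
        PathwayModel(tuple(nodes))
    )


class TestDummyContract:
    """Replacing an enzyme with a dummy changes exactly the scoped terms."""

    def test_endpoint_term_unchanged(self, swapped):
        _, _, before, after = swapped
        assert after.terms["cm"] == before.terms["cm"]

    def test_docking_drops_only_dummy_pairs(self, swapped):
        prob, scorer, before, after = swapped
        kept = [
            scorer._dock_z[prot][lig]
            for prot, lig in after.pathway.protein_ligand_pairs()
            if prot != "DUMMY"
        ]
        assert after.terms["vs"] == pytest.approx(-np.mean(kept))

    def test_sea_excludes_dummy_pairs(self, swapped):
        prob, scorer, before, after = swapped
        # E1-DUMMY and DUMMY-E3 are skipped: no consecutive pair remains
        assert "sea" not in after.terms

    def test_dummy_triads_use_direct_substrate_product_similarity(self, swapped):
        prob, scorer, before, after = swapped
        sub, prot, prod = list(after.pathway.triads())[1]
        assert prot == "DUMMY"
        cache = scorer._dummy_triad_cache(sub)
        expected_triads = []
        for s, e, pr in after.pathway.triads():
            if e == "DUMMY":
                expected_triads.append(cache.z_of(pr))
            else:
                expected_triads.append(scorer._transform_cache(e, s).z_of(pr))
        assert after.terms["ct"] == pytest.approx(np.mean(expected_triads))

    def test_screened_and_annotated_terms_follow_their_protein(self, swapped):
        prob, scorer, before, after = swapped
        # E1 (screened) and E3 (annotated) are still present: terms remain
        assert "hts" in after.terms and "hs" in after.terms


class TestAblation:
    def test_drop_removes_exactly_one_term(self, small_problem):
        from pathmapper import synthetic

        reduced = synthetic.ablate(small_problem, "endpoint")
        scorer = reduced.scorer()
        sp = scorer.score_pathway(small_problem.truth)
        assert "cm" not in sp.terms

    def test_drop_then_score_subtracts_term(self, small_problem, small_scorer):
        from pathmapper import synthetic

        before = small_scorer.score_pathway(small_problem.truth)
        reduced = synthetic.ablate(small_problem, "sea")
        after = reduced.scorer().score_pathway(small_problem.truth)
        assert after.total == pytest.approx(before.total - before.terms["sea"])

    def test_docking_only_scoring(self, small_problem):
        scorer = Scorer(
            small_problem.candidates, small_problem.restraints, enabled={"vs"}
        )
        sp = scorer.score_pathway(small_problem.truth)
        assert set(sp.terms) == {"vs"}

    def test_unknown_restraint_rejected(self, small_problem):
        from pathmapper import synthetic

        with pytest.raises(KeyError):
            synthetic.ablate(small_problem, "voodoo")
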