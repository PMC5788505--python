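"""Shared fixtures: hand-built tiny instances and session-scoped planted problems."""

import pytest

from pathmapper.model import CandidateSets, Metabolite, Protein
from pathmapper import synthetic


@pytest.fixture
def tiny_candidates():
    """2 enzymes, 3 metabolites, no constraints: 12 pathways at K=2."""
    proteins = {pid: Protein(pid) for pid in ("E1", "E2")}
    metabolites = {
        "M1": Metabolite("M1", "CCO"),
        "M2": Metabolite("M2", "CC=O"),
        "M3": Metabolite("M3", "CC(=O)O"),
    }
    return CandidateSets(proteins, metabolites, n_proteins_in_pathway=2)


@pytest.fixture(scope="session")
def small_problem():
    """Planted K=3 problem small enough for exhaustive enumeration."""
    return synthetic.generate(
        synthetic.SyntheticConfig(
            k=3, n_decoy_proteins=1, n_decoy_metabolites=2, seed=1
        )
    )


@pytest.fixture(scope="session")
def small_scorer(small_problem):
    return small_problem.scorer()


@pytest.fixture(scope="session")
def default_problem():
    """Planted problem at the default study conditions (K=4, 3+8 decoys)."""
    return synthetic.generate(synthetic.SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def default_scorer(default_problem):
    return default_problem.scorer()
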