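"""Self-contained planted-pathway problem generator.

Generates a chemically coherent linear chain (successive oxidations of an
alpha,omega-diol: alcohol -> aldehyde -> carboxylic acid on each terminus)
together with every restraint input the mapper consumes: docking tables in
which the true enzyme-ligand pairs score better by a configurable Z
advantage, a symmetric ligand-set E-value matrix favoring adjacent true
enzymes, reaction transforms, anchor constraints, a central-metabolism
endpoint consistent with the planted final product, screening hits, a
homology reference, and a gene cluster.  The planted pathway is the ground
truth against which sampling and scoring are assessed.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import chem
from .model import (
    CandidateSets,
    Metabolite,
    PathwayModel,
    Protein,
    Transformation,
    canonical_key,
    count_pathways,
    enumerate_pathways,
    validate_pathway,
)
from .restraints import DockingTable, RestraintSet, Scorer, SEAMatrix

logger = logging.getLogger(__name__)

__all__ = ["SyntheticConfig", "PlantedProblem", "generate", "ablate"]

# Planted chain: pentane-1,5-diol oxidized stepwise to glutaric acid.
CHAIN_SMILES = (
    "OCCCCCO",          # pentane-1,5-diol
    "O=CCCCCO",         # 5-hydroxypentanal
    "O=C(O)CCCCO",      # 5-hydroxypentanoic acid
    "O=CCCCC(=O)O",     # 5-oxopentanoic acid
    "O=C(O)CCCC(=O)O",  # pentanedioic (glutaric) acid
)

OX_ALCOHOL = Transformation("[CH2:1][OX2H1:2]>>[CH1:1]=[O:2]", "alcohol->aldehyde")
OX_ALDEHYDE = Transformation("[CX3H1:1]=[OX1:2]>>[C:1](=[O:2])O", "aldehyde->acid")
TRUE_TRANSFORMS = (OX_ALCOHOL, OX_ALDEHYDE, OX_ALCOHOL, OX_ALDEHYDE)

DECOY_TRANSFORMS = (
    Transformation("[CX3:1](=[OX1:2])([#6:3])[#6:4]>>[CH1:1]([OX2H1:2])([#6:3])[#6:4]", "ketone->alcohol"),
    Transformation("[NX3;H2:1]>>[N:1]C", "amine N-methylation"),
    Transformation("[C:1]#[N:2]>>[C:1](=O)[NH2:2]", "nitrile->amide"),
)

# First eight decoys are chosen so none is a one-step transform product of
# another decoy in that prefix (no accidental competing chains at defaults).
DECOY_SMILES = (
    "CCO", "CC(C)O", "OCC(O)CO", "CC(=O)CC", "C1CCOC1", "NCCO",
    "Oc1ccccc1", "OC1CCCCC1",
    "CCCO", "CCC=O", "CCC(=O)O", "CCCCO", "CC(C)CO", "CC(O)C(=O)O",
    "CC(=O)O", "OCCCO", "CCOC(C)=O", "CC(N)C(=O)O", "OCCOCCO", "CCCCCCO",
)

CENTRAL_EXTRAS = (
    ("CEN_pyruvate", "CC(=O)C(=O)O"),
    ("CEN_oxaloacetate", "O=C(O)CC(=O)C(=O)O"),
    ("CEN_acetate", "CC(=O)O"),
)


@dataclass
class SyntheticConfig:
    """Study conditions for a planted problem.

    ``docking_signal`` is the mean Z advantage of true enzyme-ligand pairs
    over decoys; ``sea_signal`` the E-value exponent of adjacent true
    enzyme pairs (random pairs sit near E = 1); ``transform_fidelity`` the
    probability that a true enzyme keeps its correct transform rather than
    a scrambled decoy transform.
    """

    k: int = 4
    n_decoy_proteins: int = 3
    n_decoy_metabolites: int = 8
    docking_signal: float = 1.5
    docking_noise: float = 1.0
    sea_signal: float = 30.0
    transform_fidelity: float = 1.0
    include_anchor: bool = True
    include_dummy: bool = False
    include_decoys: bool = True
    include_hts: bool = True
    include_homology: bool = True
    include_endpoint: bool = True
    seed: int = 0
    verify_ceiling: int = 20_000

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("pathway length K must be >= 2")
        if not self.include_decoys:
            self.n_decoy_proteins = 0
            self.n_decoy_metabolites = 0

    @classmethod
    def null(cls, **overrides) -> "SyntheticConfig":
        """All signals zeroed: the planted pathway carries no information.

        Docking has no true-pair advantage, adjacent-pair E-values are drawn
        from the random-pair distribution, transforms are scrambled, and the
        intrinsically informative components (anchor, endpoint, screening
        hits, homology) are omitted.
        """
        base = dict(
            docking_signal=0.0,
            sea_signal=0.0,
            transform_fidelity=0.0,
            include_anchor=False,
            include_hts=False,
            include_homology=False,
            include_endpoint=False,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class PlantedProblem:
    """A complete problem instance with its planted true pathway."""

    candidates: CandidateSets
    restraints: RestraintSet
    truth: PathwayModel
    config: SyntheticConfig
    verified_optimal: bool | None = None  # None: instance too large to check

    def scorer(self, **kwargs) -> Scorer:
        return Scorer(self.candidates, self.restraints, **kwargs)


def _infeasible(step: str, detail: str) -> ValueError:
    return ValueError(f"infeasible synthetic config at step {step!r}: {detail}")


def generate(config: SyntheticConfig) -> PlantedProblem:
    """Build a planted problem; deterministic for a fixed config and seed."""
    k = config.k
    if k > len(TRUE_TRANSFORMS):
        raise _infeasible(
            "transform-chain",
            f"the oxidation chain supports K <= {len(TRUE_TRANSFORMS)}, got K={k}",
        )
    if config.n_decoy_metabolites > len(DECOY_SMILES):
        raise _infeasible(
            "decoy-metabolites",
            f"at most {len(DECOY_SMILES)} decoy metabolites available",
        )
    rng = np.random.default_rng(config.seed)

    chain_ids = [f"M{i}" for i in range(k + 1)]
    metabolites = {
        mid: Metabolite(mid, chem.canonical_smiles(CHAIN_SMILES[i]))
        for i, mid in enumerate(chain_ids)
    }
    for j in range(config.n_decoy_metabolites):
        mid = f"D{j + 1:02d}"
        metabolites[mid] = Metabolite(mid, chem.canonical_smiles(DECOY_SMILES[j]))

    true_pids = [f"E{i + 1}" for i in range(k)]
    transforms: dict[str, tuple[Transformation, ...]] = {}
    proteins: dict[str, Protein] = {}
    for i, pid in enumerate(true_pids):
        if rng.random() < config.transform_fidelity:
            t = TRUE_TRANSFORMS[i]
        else:
            t = DECOY_TRANSFORMS[int(rng.integers(len(DECOY_TRANSFORMS)))]
        transforms[pid] = (t,)
        proteins[pid] = Protein(pid, "enzyme", (t,), f"oxidoreductase-step-{i + 1}")
    for j in range(config.n_decoy_proteins):
        pid = f"X{j + 1}"
        t = DECOY_TRANSFORMS[j % len(DECOY_TRANSFORMS)]
        transforms[pid] = (t,)
        proteins[pid] = Protein(pid, "enzyme", (t,), "decoy-family")
    if config.include_dummy:
        proteins["DUMMY"] = Protein("DUMMY", "dummy", (), "unknown")

    truth_nodes = [""] * (2 * k + 1)
    truth_nodes[0::2] = chain_ids
    truth_nodes[1::2] = true_pids
    truth = PathwayModel(tuple(truth_nodes))

    # Docking: noise for every pair, a Z advantage for true adjacent pairs.
    true_pairs = set(truth.protein_ligand_pairs())
    docking: dict[str, DockingTable] = {}
    for pid in sorted(p for p in proteins if not proteins[p].is_dummy):
        scores = {}
        for mid in sorted(metabolites):
            x = float(rng.normal(0.0, config.docking_noise))
            if (pid, mid) in true_pairs:
                x -= config.docking_signal * config.docking_noise
            scores[mid] = x
        docking[pid] = DockingTable(pid, scores)

    # SEA E-value matrix: significant for adjacent true enzymes.
    adjacent = {frozenset(p) for p in zip(true_pids, true_pids[1:])}
    evalues: dict[tuple[str, str], float] = {}
    pids = sorted(p for p in proteins if not proteins[p].is_dummy)
    for pid in pids:
        evalues[(pid, pid)] = 1e-50
    for i, a in enumerate(pids):
        for b in pids[i + 1 :]:
            if config.sea_signal > 0 and frozenset((a, b)) in adjacent:
                e = 10.0 ** (-config.sea_signal)
            else:
                e = 10.0 ** (-float(rng.uniform(0.0, 1.0)))
            evalues[(a, b)] = e

    central_ids = None
    library = dict(metabolites)
    if config.include_endpoint:
        central_ids = [f"CEN_end"]
        library["CEN_end"] = Metabolite(
            "CEN_end", metabolites[chain_ids[-1]].smiles
        )
        for cid, smi in CENTRAL_EXTRAS:
            library[cid] = Metabolite(cid, chem.canonical_smiles(smi))
            central_ids.append(cid)

    hts_hits = {true_pids[0]: [chain_ids[0]]} if config.include_hts else None
    homology = (
        {true_pids[-1]: metabolites[chain_ids[-2]].smiles}
        if config.include_homology
        else None
    )
    gene_cluster = frozenset(true_pids)

    constraints: dict[int, frozenset[str]] = {}
    if config.include_anchor:
        constraints[0] = frozenset({chain_ids[0]})
        constraints[1] = frozenset({true_pids[0]})

    candidates = CandidateSets(
        proteins=proteins,
        metabolites=metabolites,
        n_proteins_in_pathway=k,
        position_constraints=constraints,
    )
    restraints = RestraintSet(
        docking=docking,
        sea=SEAMatrix(evalues),
        transforms=transforms,
        central_ids=central_ids,
        hts_hits=hts_hits,
        homology=homology,
        gene_cluster=gene_cluster,
        library=library,
    )
    problem = PlantedProblem(candidates, restraints, truth, config)

    ok, violations = validate_pathway(truth, candidates)
    if not ok:
        raise _infeasible("planted-pathway", f"planted model invalid: {violations}")

    total = count_pathways(len(proteins), len(metabolites), k)
    if config.docking_signal > 0 and total <= config.verify_ceiling:
        scorer = problem.scorer()
        best = max(
            (scorer.score_pathway(p) for p in enumerate_pathways(candidates, k)),
            key=lambda s: (s.total, s.key),
        )
        problem.verified_optimal = best.key == canonical_key(truth)
        if not problem.verified_optimal:
            logger.warning(
                "planted pathway is not the global optimum for seed %s "
                "(best %s at %.3f)",
                config.seed, best.key, best.total,
            )
    return problem


def ablate(problem: PlantedProblem, drop: str) -> PlantedProblem:
    """Copy of the problem with one named restraint removed.

    Accepted names follow :meth:`RestraintSet.drop` (e.g. "docking", "sea",
    "transforms", "endpoint", "hts", "homology", "gene_cluster").
    """
    restraints = problem.restraints.drop(drop)
    return PlantedProblem(
        candidates=copy.deepcopy(problem.candidates),
        restraints=restraints,
        truth=problem.truth,
        config=replace(problem.config),
        verified_optimal=None,
    )
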