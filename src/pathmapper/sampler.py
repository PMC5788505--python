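"""Monte Carlo simulated-annealing search for good-scoring pathways.

The sampler proposes (i) swaps of two same-type nodes within the pathway and
(ii) replacement of a node by an unused candidate of the same type, accepts
with the Metropolis criterion under an annealed temperature
T = 0.3 * 0.2^N + 0.1 (N = step fraction), and records every accepted model.
Independent runs are merged; good-scoring models are the unique models whose
score lies within ``cutoff_sd`` random-model standard deviations of the best
sampled score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import CandidateSets, PathwayModel, validate_pathway
from .restraints import Scorer, ScoredPathway

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerConfig",
    "GoodScoringSet",
    "temperature",
    "metropolis_accept",
    "propose_move",
    "random_pathway",
    "random_score_distribution",
    "run_mc",
    "run_ensemble",
]


@dataclass
class SamplerConfig:
    """Sampling parameters.

    Defaults follow the published protocol (5,000,000 steps, 1000 runs,
    2 SD cutoff, 10,000 random models); tests and desk-scale problems scale
    ``n_steps``/``n_runs`` down.
    """

    n_steps: int = 5_000_000
    n_runs: int = 1000
    cutoff_sd: float = 2.0
    n_random_models: int = 10_000
    seed: int = 1
    t_coeffs: tuple[float, float, float] = (0.3, 0.2, 0.1)

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.cutoff_sd <= 0:
            raise ValueError("cutoff_sd must be positive")


@dataclass
class GoodScoringSet:
    """Unique good-scoring models plus the statistics defining the cutoff."""

    models: dict[str, ScoredPathway]          # score >= cutoff
    all_models: dict[str, ScoredPathway]      # every unique sampled model
    per_run_keys: list[list[str]]             # good-scoring keys per run
    cutoff: float
    best_score: float
    random_mean: float
    random_sd: float
    cutoff_sd: float

    @property
    def best(self) -> ScoredPathway:
        return max(self.models.values(), key=lambda s: (s.total, s.key))

    def score_rank(self, total: float) -> int:
        """1 + number of unique sampled models scoring strictly better."""
        return 1 + sum(1 for s in self.all_models.values() if s.total > total)

    def ranked(self) -> list[ScoredPathway]:
        return sorted(self.models.values(), key=lambda s: (-s.total, s.key))


def temperature(step_fraction: float, coeffs: tuple[float, float, float] = (0.3, 0.2, 0.1)) -> float:
    """Annealing temperature T = a * b^N + c for N in [0, 1]."""
    if not 0.0 <= step_fraction <= 1.0:
        raise ValueError(f"step fraction {step_fraction} outside [0, 1]")
    a, b, c = coeffs
    return a * b**step_fraction + c


def metropolis_accept(
    old_score: float, new_score: float, t: float, rng: np.random.Generator
) -> bool:
    """Accept improving moves always; otherwise with p = exp(-D/T), D = old - new.

    No random draw is consumed when the move improves (or ties) the score.
    """
    if t <= 0:
        raise ValueError("temperature must be positive")
    if new_score >= old_score:
        return True
    p = math.exp(-(old_score - new_score) / t)
    return bool(rng.random() < p)


def _swap_positions(p: PathwayModel, c: CandidateSets, i: int, j: int) -> PathwayModel | None:
    nodes = list(p.nodes)
    if nodes[i] == nodes[j]:
        return None
    if not (c.allowed_at(i, nodes[j]) and c.allowed_at(j, nodes[i])):
        return None
    nodes[i], nodes[j] = nodes[j], nodes[i]
    return PathwayModel(tuple(nodes))


def _replace_position(
    p: PathwayModel, c: CandidateSets, i: int, candidate: str
) -> PathwayModel | None:
    if candidate in p.nodes or not c.allowed_at(i, candidate):
        return None
    nodes = list(p.nodes)
    nodes[i] = candidate
    return PathwayModel(tuple(nodes))


def _all_moves(p: PathwayModel, c: CandidateSets, kind: str) -> list[PathwayModel]:
    n = len(p.nodes)
    out = []
    if kind == "swap":
        for parity in (0, 1):
            idx = range(parity, n, 2)
            for a in idx:
                for b in idx:
                    if b <= a:
                        continue
                    q = _swap_positions(p, c, a, b)
                    if q is not None:
                        out.append(q)
    else:
        used = set(p.nodes)
        met_unused = sorted(set(c.metabolites) - used)
        prot_unused = sorted(set(c.proteins) - used)
        for i in range(n):
            pool = prot_unused if i % 2 else met_unused
            for cand in pool:
                q = _replace_position(p, c, i, cand)
                if q is not None:
                    out.append(q)
    return out


def propose_move(
    p: PathwayModel, c: CandidateSets, rng: np.random.Generator
) -> PathwayModel:
    """Propose one valid move: a same-type swap or an unused-candidate replace.

    The move type is chosen uniformly among the legal types; positions and
    candidates uniformly among the legal ones (via rejection sampling from
    the uniform product space, with an exhaustive fallback).  Raises when no
    legal move exists at all.
    """
    n = len(p.nodes)
    used = set(p.nodes)
    met_unused = sorted(set(c.metabolites) - used)
    prot_unused = sorted(set(c.proteins) - used)
    kinds = ["swap"]
    if met_unused or prot_unused:
        kinds.append("replace")
    rng.shuffle(kinds)
    for kind in kinds:
        for _ in range(200):
            if kind == "swap":
                parity = int(rng.integers(2)) if n > 3 else 0
                idx = list(range(parity, n, 2))
                if len(idx) < 2:
                    continue
                a, b = rng.choice(idx, size=2, replace=False)
                q = _swap_positions(p, c, int(min(a, b)), int(max(a, b)))
            else:
                i = int(rng.integers(n))
                pool = prot_unused if i % 2 else met_unused
                if not pool:
                    continue
                q = _replace_position(p, c, i, pool[int(rng.integers(len(pool)))])
            if q is not None:
                return q
        moves = _all_moves(p, c, kind)
        if moves:
            return moves[int(rng.integers(len(moves)))]
    raise RuntimeError("no legal Monte Carlo move exists for this instance")


def random_pathway(
    c: CandidateSets, k: int, rng: np.random.Generator, max_tries: int = 10_000
) -> PathwayModel:
    """Uniformly random valid pathway of length K (rejection sampling)."""
    prot_ids = sorted(c.proteins)
    met_ids = sorted(c.metabolites)
    if k > len(prot_ids) or k + 1 > len(met_ids):
        raise ValueError(f"candidate pools too small for K={k}")
    for _ in range(max_tries):
        prots = rng.choice(prot_ids, size=k, replace=False)
        ligs = rng.choice(met_ids, size=k + 1, replace=False)
        nodes = [""] * (2 * k + 1)
        nodes[0::2] = ligs
        nodes[1::2] = prots
        p = PathwayModel(tuple(nodes))
        ok, _ = validate_pathway(p, c)
        if ok:
            return p
    # Heavily constrained instance: place constrained positions first.
    nodes = [None] * (2 * k + 1)
    used: set[str] = set()
    for pos in sorted(c.position_constraints):
        if pos >= len(nodes):
            continue
        pool = c.metabolites if pos % 2 == 0 else c.proteins
        allowed = sorted(set(c.position_constraints[pos]) & set(pool) - used)
        if not allowed:
            raise RuntimeError(f"no assignment satisfies constraint at position {pos}")
        nodes[pos] = allowed[int(rng.integers(len(allowed)))]
        used.add(nodes[pos])
    for i in range(len(nodes)):
        if nodes[i] is None:
            pool = met_ids if i % 2 == 0 else prot_ids
            free = [x for x in pool if x not in used]
            nodes[i] = free[int(rng.integers(len(free)))]
            used.add(nodes[i])
    p = PathwayModel(tuple(nodes))
    ok, violations = validate_pathway(p, c)
    if not ok:
        raise RuntimeError(f"could not build a valid random pathway: {violations}")
    return p


def random_score_distribution(
    c: CandidateSets,
    scorer: Scorer,
    n: int,
    seed: int | np.random.SeedSequence,
    k: int | None = None,
) -> tuple[float, float]:
    """Mean and population SD of the scores of n uniformly random pathways."""
    if n < 2:
        raise ValueError("need at least 2 random models")
    if k is None:
        k = c.single_length()
    rng = np.random.default_rng(seed)
    totals = np.array(
        [scorer.score_pathway(random_pathway(c, k, rng)).total for _ in range(n)]
    )
    sd = float(totals.std(ddof=0))
    if sd < 1e-12:
        logger.warning("random-model score distribution has zero spread")
    return float(totals.mean()), sd


def run_mc(
    c: CandidateSets,
    scorer: Scorer,
    config: SamplerConfig,
    run_seed: int | np.random.SeedSequence,
    k: int | None = None,
) -> dict[str, ScoredPathway]:
    """One annealed MC run from a random start; returns the unique accepted
    models in visit order (the start model included)."""
    if k is None:
        k = c.single_length()
    rng = np.random.default_rng(run_seed)
    current = scorer.score_pathway(random_pathway(c, k, rng))
    visited: dict[str, ScoredPathway] = {current.key: current}
    n = config.n_steps
    for step in range(n):
        t = temperature(step / n, config.t_coeffs)
        proposal = scorer.score_pathway(propose_move(current.pathway, c, rng))
        if metropolis_accept(current.total, proposal.total, t, rng):
            current = proposal
            if current.key not in visited:
                visited[current.key] = current
    return visited


def run_ensemble(
    c: CandidateSets,
    scorer: Scorer,
    config: SamplerConfig,
    k: int | None = None,
) -> GoodScoringSet:
    """Merge independent runs and keep the good-scoring models.

    Per-run seeds are spawned from the master seed with a splittable seed
    sequence, so the ensemble is reproducible and order-independent.  The
    cutoff is ``best - cutoff_sd * sd``, with sd taken from the score
    distribution of ``n_random_models`` random pathways.
    """
    if k is None:
        k = c.single_length()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_runs + 1)
    all_models: dict[str, ScoredPathway] = {}
    run_keys: list[list[str]] = []
    for child in children[:-1]:
        visited = run_mc(c, scorer, config, child, k)
        run_keys.append(list(visited))
        for key, sp in visited.items():
            all_models.setdefault(key, sp)
    r_mean, r_sd = random_score_distribution(
        c, scorer, config.n_random_models, children[-1], k
    )
    best = max(s.total for s in all_models.values())
    cutoff = best - config.cutoff_sd * r_sd
    good = {key: s for key, s in all_models.items() if s.total >= cutoff}
    per_run_good = [[key for key in keys if key in good] for keys in run_keys]
    return GoodScoringSet(
        models=good,
        all_models=all_models,
        per_run_keys=per_run_good,
        cutoff=cutoff,
        best_score=best,
        random_mean=r_mean,
        random_sd=r_sd,
        cutoff_sd=config.cutoff_sd,
    )
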