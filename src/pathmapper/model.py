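"""Linear pathway representation, candidate pools, and an enumeration oracle.

A pathway model is a linear graph of alternating ligand and protein nodes:
``M0 - P1 - M1 - P2 - ... - PK - MK`` for K proteins and K+1 ligands.  Nodes
are identities only (metabolite / protein ids); no stoichiometry, cofactors,
or flux is modeled.  Each candidate appears at most once per pathway, and
only linear topologies are represented.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = [
    "Metabolite",
    "Protein",
    "Transformation",
    "PathwayModel",
    "CandidateSets",
    "validate_pathway",
    "canonical_key",
    "count_pathways",
    "enumerate_pathways",
    "EnumerationCeilingError",
]

PROTEIN_KINDS = ("enzyme", "transporter_sbp", "dummy")


@dataclass(frozen=True)
class Transformation:
    """A generic reaction encoded as a SMIRKS string.

    The SMIRKS describes a substrate motif and the corresponding product
    motif, at roughly the granularity of a third-level EC class (e.g.
    "primary alcohol -> aldehyde").  A protein may carry several.
    """

    smirks: str
    direction_label: str = ""


@dataclass
class Metabolite:
    """A small molecule identified by an opaque id and a SMILES string."""

    id: str
    smiles: str
    fingerprint: object | None = None


@dataclass
class Protein:
    """A pathway protein: enzyme, transporter solute-binding protein, or dummy.

    A dummy node stands for an unknown, uncharacterized protein: it carries
    no transforms and no docking table, and contributes to no scoring term
    except the chemical-transformation term.
    """

    id: str
    kind: str = "enzyme"
    transforms: tuple[Transformation, ...] = ()
    family_label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in PROTEIN_KINDS:
            raise ValueError(f"unknown protein kind {self.kind!r} for {self.id}")
        self.transforms = tuple(self.transforms)
        if self.kind == "dummy" and self.transforms:
            raise ValueError(f"dummy protein {self.id} must not carry transforms")

    @property
    def is_dummy(self) -> bool:
        return self.kind == "dummy"


@dataclass(frozen=True)
class PathwayModel:
    """An ordered, alternating ligand/protein node sequence.

    ``nodes`` holds ids; even indices are ligand positions, odd indices are
    protein positions.  K proteins imply 2K+1 nodes.
    """

    nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))

    @property
    def n_proteins(self) -> int:
        return len(self.nodes) // 2

    @property
    def ligands(self) -> tuple[str, ...]:
        return self.nodes[0::2]

    @property
    def proteins(self) -> tuple[str, ...]:
        return self.nodes[1::2]

    def triads(self) -> Iterator[tuple[str, str, str]]:
        """Yield (substrate, protein, product) node triads along the chain."""
        for i in range(1, len(self.nodes), 2):
            yield self.nodes[i - 1], self.nodes[i], self.nodes[i + 1]

    def protein_ligand_pairs(self) -> Iterator[tuple[str, str]]:
        """Yield every (protein, adjacent ligand) pair: substrate and product."""
        for sub, prot, prod in self.triads():
            yield prot, sub
            yield prot, prod

    def consecutive_protein_pairs(self) -> Iterator[tuple[str, str]]:
        prots = self.proteins
        for a, b in zip(prots, prots[1:]):
            yield a, b

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class CandidateSets:
    """Candidate node pools plus positional constraints.

    ``position_constraints`` maps a node-sequence index to the subset of ids
    allowed there (index 0 is the first ligand, index 1 the first protein).
    Anchors such as "transporter fixed at the pathway start with its ligand
    restricted" are expressed this way.  ``n_proteins_in_pathway`` is either
    a single K or a list of K values when the length is unknown.
    """

    proteins: dict[str, Protein]
    metabolites: dict[str, Metabolite]
    n_proteins_in_pathway: int | list[int] = 0
    position_constraints: dict[int, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.position_constraints = {
            int(k): frozenset(v) for k, v in self.position_constraints.items()
        }
        pool = set(self.proteins) | set(self.metabolites)
        for pos, allowed in self.position_constraints.items():
            extra = allowed - pool
            if extra:
                raise ValueError(
                    f"constraint at position {pos} names unknown ids {sorted(extra)}"
                )

    def lengths(self) -> list[int]:
        k = self.n_proteins_in_pathway
        return list(k) if isinstance(k, (list, tuple)) else [int(k)]

    def single_length(self) -> int:
        ks = self.lengths()
        if len(ks) != 1:
            raise ValueError("instance has multiple pathway lengths; pick one K")
        return ks[0]

    def allowed_at(self, pos: int, node_id: str) -> bool:
        allowed = self.position_constraints.get(pos)
        return allowed is None or node_id in allowed


class EnumerationCeilingError(RuntimeError):
    """Raised when an instance is too large for exhaustive enumeration."""


def validate_pathway(p: PathwayModel, c: CandidateSets) -> tuple[bool, list[str]]:
    """Check alternation, uniqueness, pool membership, and constraints.

    Never raises; returns (ok, violations) with one message per failed rule.
    """
    v: list[str] = []
    nodes = p.nodes
    if len(nodes) < 3 or len(nodes) % 2 == 0:
        v.append(f"length {len(nodes)} is not an odd count >= 3")
    for i, n in enumerate(nodes):
        if i % 2 == 0:
            if n not in c.metabolites:
                v.append(f"position {i} not a candidate metabolite: {n}")
        elif n not in c.proteins:
            v.append(f"position {i} not a candidate protein: {n}")
    ligs, prots = nodes[0::2], nodes[1::2]
    if len(set(ligs)) != len(ligs):
        v.append("metabolite repeated")
    if len(set(prots)) != len(prots):
        v.append("protein repeated")
    for pos in sorted(c.position_constraints):
        if pos < len(nodes) and not c.allowed_at(pos, nodes[pos]):
            v.append(f"constraint at position {pos}")
    return (not v), v


def canonical_key(p: PathwayModel) -> str:
    """Deterministic key; equal iff the node sequences are identical."""
    return "|".join(p.nodes)


def count_pathways(n_proteins: int, n_metabolites: int, k: int) -> int:
    """Closed-form unconstrained pathway count: P!/(P-K)! * L!/(L-K-1)!."""
    if k > n_proteins or k + 1 > n_metabolites:
        return 0
    return math.perm(n_proteins, k) * math.perm(n_metabolites, k + 1)


def enumerate_pathways(
    c: CandidateSets,
    k: int | None = None,
    ceiling: int = 10**7,
) -> Iterator[PathwayModel]:
    """Yield every valid pathway of length K exactly once.

    Brute-force oracle for small instances; the unconstrained closed-form
    count is checked against ``ceiling`` before any work is done.
    """
    if k is None:
        k = c.single_length()
    total = count_pathways(len(c.proteins), len(c.metabolites), k)
    if total > ceiling:
        raise EnumerationCeilingError(
            f"{total} unconstrained pathways exceeds ceiling {ceiling}"
        )
    prot_ids = sorted(c.proteins)
    met_ids = sorted(c.metabolites)
    cons = c.position_constraints
    prot_positions = [2 * i + 1 for i in range(k)]
    lig_positions = [2 * i for i in range(k + 1)]
    for prots in itertools.permutations(prot_ids, k):
        if any(not c.allowed_at(pos, prots[i]) for i, pos in enumerate(prot_positions)):
            continue
        for ligs in itertools.permutations(met_ids, k + 1):
            if any(not c.allowed_at(pos, ligs[i]) for i, pos in enumerate(lig_positions)):
                continue
            nodes = [""] * (2 * k + 1)
            nodes[0::2] = ligs
            nodes[1::2] = prots
            yield PathwayModel(tuple(nodes))
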