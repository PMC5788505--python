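"""Cheminformatics primitives: Morgan fingerprints, Tanimoto similarity,
SMIRKS transformation application, and stereoisomer-aware comparison.

Fingerprints are circular (Morgan) bit fingerprints with chirality encoded,
radius 2 and 2048 bits by default.  Molecules with undefined stereocenters
are compared by enumerating up to 16 stereoisomer assignments and taking the
highest Tanimoto coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, rdFingerprintGenerator
from rdkit.Chem.EnumerateStereoisomers import (
    EnumerateStereoisomers,
    StereoEnumerationOptions,
)

from .model import Metabolite, Transformation

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "FingerprintParams",
    "Fingerprint",
    "SimilarityStats",
    "parse_smiles",
    "canonical_smiles",
    "fingerprint",
    "tanimoto",
    "apply_transformation",
    "stereo_fingerprints",
    "max_stereo_tanimoto",
    "similarity_stats",
    "MAX_STEREOISOMERS",
]

MAX_STEREOISOMERS = 16


@dataclass(frozen=True)
class FingerprintParams:
    radius: int = 2
    nbits: int = 2048
    chirality: bool = True


DEFAULT_PARAMS = FingerprintParams()


@dataclass(frozen=True)
class Fingerprint:
    """A bit-set fingerprint with the parameters it was computed under."""

    bits: frozenset[int]
    params: FingerprintParams = DEFAULT_PARAMS

    @property
    def nbits(self) -> int:
        return self.params.nbits

    def __post_init__(self) -> None:
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.params.nbits):
            raise ValueError("fingerprint bit index out of range")


@dataclass(frozen=True)
class SimilarityStats:
    """Mean and population standard deviation of a Tanimoto distribution."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def parse_smiles(smiles: str, name: str | None = None) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        label = f" ({name})" if name else ""
        raise ValueError(f"unparseable SMILES{label}: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    return Chem.MolToSmiles(parse_smiles(smiles))


@lru_cache(maxsize=16)
def _generator(params: FingerprintParams):
    return rdFingerprintGenerator.GetMorganGenerator(
        radius=params.radius,
        fpSize=params.nbits,
        includeChirality=params.chirality,
    )


def _mol_of(m) -> Chem.Mol:
    if isinstance(m, Chem.Mol):
        return m
    if isinstance(m, Metabolite):
        return parse_smiles(m.smiles, m.id)
    return parse_smiles(m)


def fingerprint(m, params: FingerprintParams = DEFAULT_PARAMS) -> Fingerprint:
    """Morgan fingerprint of a Metabolite, Mol, or SMILES string.

    Deterministic for a given molecule and parameters; SMILES writing order
    does not matter because RDKit canonicalizes the molecular graph.
    """
    mol = _mol_of(m)
    bv = _generator(params).GetFingerprint(mol)
    return Fingerprint(frozenset(bv.GetOnBits()), params)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a & b| / |a | b|; 0.0 for two empty fingerprints by convention."""
    if a.params != b.params:
        raise ValueError(f"fingerprint params differ: {a.params} vs {b.params}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


@lru_cache(maxsize=512)
def _reaction(smirks: str):
    rxn = AllChem.ReactionFromSmarts(smirks)
    if rxn is None or rxn.GetNumReactantTemplates() != 1:
        raise ValueError(f"invalid single-reactant SMIRKS: {smirks!r}")
    return rxn


def apply_transformation(m, t: Transformation | str) -> list[str]:
    """Apply a SMIRKS transform at every matching site of the substrate.

    Returns canonical product SMILES, deduplicated and sorted; empty when
    the substrate motif does not match.  Products that fail sanitization
    (chemically inconsistent matches) are dropped.
    """
    smirks = t.smirks if isinstance(t, Transformation) else t
    rxn = _reaction(smirks)
    mol = _mol_of(m)
    products: set[str] = set()
    for prods in rxn.RunReactants((mol,)):
        for p in prods:
            try:
                Chem.SanitizeMol(p)
            except Exception:
                continue
            products.add(Chem.MolToSmiles(p))
    return sorted(products)


def _n_undefined_stereocenters(mol: Chem.Mol) -> int:
    centers = Chem.FindMolChiralCenters(
        mol, includeUnassigned=True, useLegacyImplementation=False
    )
    return sum(1 for _, tag in centers if tag == "?")


def stereo_fingerprints(
    m,
    params: FingerprintParams = DEFAULT_PARAMS,
    max_isomers: int = MAX_STEREOISOMERS,
) -> list[Fingerprint]:
    """Fingerprints of min(2^k, max_isomers) stereoisomer assignments.

    For a molecule with no undefined stereocenters this is a single
    fingerprint.  Enumeration is deterministic, so the cap is reproducible.
    """
    mol = _mol_of(m)
    if _n_undefined_stereocenters(mol) == 0:
        return [fingerprint(mol, params)]
    opts = StereoEnumerationOptions(
        maxIsomers=max_isomers, onlyUnassigned=True, unique=True
    )
    fps = [fingerprint(iso, params) for iso in EnumerateStereoisomers(mol, options=opts)]
    return fps or [fingerprint(mol, params)]


def max_stereo_tanimoto(a, b, params: FingerprintParams = DEFAULT_PARAMS) -> float:
    """Highest Tanimoto between stereoisomer assignments of ``a`` and ``b``.

    Reduces to a plain Tanimoto when ``a`` has no undefined stereocenters.
    ``b`` may be a molecule-like object or a precomputed Fingerprint.
    """
    fb = b if isinstance(b, Fingerprint) else fingerprint(b, params)
    return max(tanimoto(fa, fb) for fa in stereo_fingerprints(a, params))


def similarity_stats(population, reference=None) -> SimilarityStats:
    """Mean / population SD of a Tanimoto distribution.

    ``population`` is either a list of precomputed Tanimoto coefficients, or
    a list of fingerprints compared against ``reference`` (a fingerprint or
    a list of fingerprints, in which case all pairwise comparisons enter the
    population).
    """
    if reference is None:
        values = [float(v) for v in population]
    else:
        refs = reference if isinstance(reference, (list, tuple)) else [reference]
        values = [tanimoto(q, r) for q in population for r in refs]
    if not values:
        raise ValueError("empty similarity population")
    arr = np.asarray(values, dtype=float)
    return SimilarityStats(float(arr.mean()), float(arr.std(ddof=0)))
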