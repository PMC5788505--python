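"""Restraint terms and the composite pathway score.

Every information source (docking, ligand-set similarity, chemical
transformations, pathway endpoint, screening hits, homology, gene cluster)
is expressed as a Z-score so that heterogeneous restraints weigh
commensurately.  The pathway score is the sum of the applicable terms;
restraints with no data for a pathway are simply omitted.  Higher is
better: favorable (low) raw docking scores yield negative per-pair
Z-scores, and the leading minus sign in the docking term turns them into a
positive contribution.

A dummy protein contributes no score except to the chemical-transformation
term, where the substrate is compared directly to the product.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import chem
from .model import CandidateSets, Metabolite, PathwayModel, Transformation, canonical_key

logger = logging.getLogger(__name__)

__all__ = [
    "DockingTable",
    "SEAMatrix",
    "RestraintSet",
    "RestraintBreakdown",
    "ScoredPathway",
    "Scorer",
    "zscore",
    "sea_sab",
    "ALL_TERMS",
]

ALL_TERMS = ("vs", "ct", "sea", "cm", "hts", "hs", "gc")

_SD_EPS = 1e-12


def zscore(x: float, mean: float, sd: float) -> float:
    """(x - mean) / sd, returning 0 with a warning for a degenerate sd."""
    if sd < _SD_EPS:
        logger.warning("zero-variance population in z-score; returning 0.0")
        return 0.0
    return (x - mean) / sd


def sea_sab(evalue: float, w_aa: float = 50.0, w_bb: float = 50.0) -> float:
    """SEA pair score S_AB = w_AB * F_AB.

    w_AB = min(-log10 evalue, 50); F_AB = min(w_AA, w_BB)/50 models
    confidence in the ligand-set comparison via the self-similarity terms.
    """
    if evalue <= 0:
        raise ValueError(f"E-value must be positive, got {evalue}")
    w_ab = min(-math.log10(evalue), 50.0)
    return w_ab * min(w_aa, w_bb) / 50.0


@dataclass
class DockingTable:
    """Raw docking scores (lower = more favorable) for one protein.

    ``mean``/``sd`` are the population statistics over every scored
    metabolite in this table, used to convert raw scores to Z-scores.
    """

    protein_id: str
    scores: dict[str, float]
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.scores:
            raise ValueError(f"empty docking table for {self.protein_id}")
        arr = np.asarray(list(self.scores.values()), dtype=float)
        self.mean = float(arr.mean())
        self.sd = float(arr.std(ddof=0))

    def z(self, metabolite_id: str) -> float | None:
        x = self.scores.get(metabolite_id)
        if x is None:
            return None
        return zscore(x, self.mean, self.sd)


class SEAMatrix:
    """Symmetric protein-pair E-values from ligand-set comparison.

    Self pairs (A, A) supply the confidence terms w_AA; when a self pair is
    absent, w_AA defaults to the cap (50) with a warning.
    """

    def __init__(self, evalues: Mapping[tuple[str, str], float]):
        self.evalues: dict[tuple[str, str], float] = {}
        for (a, b), e in evalues.items():
            if e <= 0:
                raise ValueError(f"E-value for pair ({a}, {b}) must be positive")
            self.evalues[self._key(a, b)] = float(e)
        self._warned_self: set[str] = set()

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def evalue(self, a: str, b: str) -> float | None:
        return self.evalues.get(self._key(a, b))

    def w_self(self, a: str) -> float:
        e = self.evalues.get((a, a))
        if e is None:
            if a not in self._warned_self:
                logger.warning("no self E-value for %s; using w=50", a)
                self._warned_self.add(a)
            return 50.0
        return min(-math.log10(e), 50.0)

    def sab(self, a: str, b: str) -> float:
        """S_AB for a protein pair; a missing pair E-value counts as 1.0."""
        e = self.evalue(a, b)
        if e is None:
            e = 1.0
        return sea_sab(e, self.w_self(a), self.w_self(b))


@dataclass
class RestraintSet:
    """All loaded restraint data.  Any component may be absent (None).

    ``library`` may hold metabolites beyond the candidate pool (e.g. the
    central-metabolism compounds); ids in ``central_ids`` and ``hts_hits``
    resolve against it, falling back to the candidate pool.
    """

    docking: dict[str, DockingTable] | None = None
    sea: SEAMatrix | None = None
    transforms: dict[str, tuple[Transformation, ...]] | None = None
    central_ids: list[str] | None = None
    hts_hits: dict[str, list[str]] | None = None
    homology: dict[str, str] | None = None  # protein id -> reference SMILES
    gene_cluster: frozenset[str] | None = None  # member protein ids
    enable_gc: bool = False
    library: dict[str, Metabolite] | None = None

    def present_terms(self) -> set[str]:
        terms = set()
        if self.docking:
            terms.add("vs")
        if self.transforms is not None:
            terms.add("ct")
        if self.sea is not None:
            terms.add("sea")
        if self.central_ids:
            terms.add("cm")
        if self.hts_hits:
            terms.add("hts")
        if self.homology:
            terms.add("hs")
        if self.gene_cluster and self.enable_gc:
            terms.add("gc")
        return terms

    def drop(self, name: str) -> "RestraintSet":
        """Copy of this set with one named restraint removed."""
        aliases = {
            "docking": "docking", "vs": "docking",
            "transforms": "transforms", "ct": "transforms",
            "sea": "sea",
            "endpoint": "central_ids", "cm": "central_ids", "central": "central_ids",
            "hts": "hts_hits", "screening": "hts_hits",
            "homology": "homology", "hs": "homology",
            "gene_cluster": "gene_cluster", "gc": "gene_cluster",
        }
        attr = aliases.get(name)
        if attr is None:
            raise KeyError(f"unknown restraint {name!r}")
        current = getattr(self, attr)
        if current is None:
            raise KeyError(f"restraint {name!r} not present")
        kwargs = {f: getattr(self, f) for f in self.__dataclass_fields__}
        kwargs[attr] = None
        return RestraintSet(**kwargs)


@dataclass(frozen=True)
class RestraintBreakdown:
    """Per-term Z-scores; absent terms contribute exactly 0 to the total."""

    terms: dict[str, float]

    @property
    def total(self) -> float:
        return float(sum(self.terms.values()))


@dataclass(frozen=True)
class ScoredPathway:
    pathway: PathwayModel
    key: str
    terms: dict[str, float]
    total: float


class _TCCache:
    """Per-(reference) Tanimoto vector over the candidate metabolites."""

    __slots__ = ("vector", "mean", "sd")

    def __init__(self, vector: dict[str, float]):
        self.vector = vector
        arr = np.asarray(list(vector.values()), dtype=float)
        self.mean = float(arr.mean())
        self.sd = float(arr.std(ddof=0))

    def z_of(self, metabolite_id: str) -> float:
        return zscore(self.vector.get(metabolite_id, 0.0), self.mean, self.sd)


class Scorer:
    """Precomputes normalization statistics once, then scores pathways purely.

    All per-term populations are fixed at construction (or on first use, for
    the transformation caches), so the same pathway always receives the same
    score and breakdown.
    """

    def __init__(
        self,
        candidates: CandidateSets,
        restraints: RestraintSet,
        enabled: Iterable[str] | None = None,
        gc_subset_ceiling: int = 2**20,
        gc_sample_n: int = 10**5,
        gc_seed: int = 0,
    ):
        self.c = candidates
        self.r = restraints
        present = restraints.present_terms()
        self.enabled = present if enabled is None else (set(enabled) & present)

        self._lib: dict[str, Metabolite] = dict(candidates.metabolites)
        if restraints.library:
            for mid, m in restraints.library.items():
                self._lib.setdefault(mid, m)

        self._dummy_pids = {p.id for p in candidates.proteins.values() if p.is_dummy}
        self._kind = {p.id: p.kind for p in candidates.proteins.values()}

        # Candidate fingerprints (plain and stereo-enumerated substrate side).
        self._fp: dict[str, chem.Fingerprint] = {
            mid: chem.fingerprint(m) for mid, m in candidates.metabolites.items()
        }
        self._stereo: dict[str, list[chem.Fingerprint]] = {}

        self._dock_z: dict[str, dict[str, float]] = {}
        if "vs" in self.enabled and restraints.docking:
            for pid, table in restraints.docking.items():
                self._dock_z[pid] = {
                    mid: zscore(x, table.mean, table.sd)
                    for mid, x in table.scores.items()
                }

        self._sea_z: dict[tuple[str, str], float] = {}
        if "sea" in self.enabled and restraints.sea is not None:
            pids = sorted(set(candidates.proteins) - self._dummy_pids)
            pop = {}
            for a, b in itertools.combinations(pids, 2):
                pop[(a, b)] = restraints.sea.sab(a, b)
            if pop:
                arr = np.asarray(list(pop.values()), dtype=float)
                m, s = float(arr.mean()), float(arr.std(ddof=0))
                self._sea_z = {k: zscore(v, m, s) for k, v in pop.items()}

        self._cm_z: dict[str, float] = {}
        if "cm" in self.enabled and restraints.central_ids:
            central_fps = [
                chem.fingerprint(self._resolve(cid)) for cid in restraints.central_ids
            ]
            pop: list[float] = []
            best: dict[str, float] = {}
            for mid in candidates.metabolites:
                tcs = [
                    max(chem.tanimoto(fa, fc) for fa in self._stereo_fps(mid))
                    for fc in central_fps
                ]
                pop.extend(tcs)
                best[mid] = max(tcs)
            stats = chem.similarity_stats(pop)
            self._cm_z = {
                mid: zscore(tc, stats.mean, stats.sd) for mid, tc in best.items()
            }

        self._hts_z: dict[str, dict[str, float]] = {}
        if "hts" in self.enabled and restraints.hts_hits:
            for pid, hit_ids in restraints.hts_hits.items():
                hit_fps = [chem.fingerprint(self._resolve(h)) for h in hit_ids]
                vec = {
                    mid: max(
                        chem.tanimoto(fa, fh)
                        for fa in self._stereo_fps(mid)
                        for fh in hit_fps
                    )
                    for mid in candidates.metabolites
                }
                cache = _TCCache(vec)
                self._hts_z[pid] = {mid: cache.z_of(mid) for mid in vec}

        self._hs_z: dict[str, dict[str, float]] = {}
        if "hs" in self.enabled and restraints.homology:
            for pid, ref_smiles in restraints.homology.items():
                ref_fp = chem.fingerprint(ref_smiles)
                vec = {
                    mid: max(
                        chem.tanimoto(fa, ref_fp) for fa in self._stereo_fps(mid)
                    )
                    for mid in candidates.metabolites
                }
                cache = _TCCache(vec)
                self._hs_z[pid] = {mid: cache.z_of(mid) for mid in vec}

        self._gc_mean = self._gc_sd = 0.0
        self._gc_pairs: frozenset[frozenset[str]] = frozenset()
        if "gc" in self.enabled and restraints.gene_cluster:
            self._gc_pairs = frozenset(
                frozenset(p)
                for p in itertools.combinations(sorted(restraints.gene_cluster), 2)
            )
            self._gc_mean, self._gc_sd = self._gc_stats(
                gc_subset_ceiling, gc_sample_n, gc_seed
            )

        # Lazy transformation caches keyed by (protein id, substrate id).
        self._ct_cache: dict[tuple[str, str], _TCCache | None] = {}
        self._dummy_cache: dict[str, _TCCache] = {}

    # -- helpers ---------------------------------------------------------

    def _resolve(self, metabolite_id: str) -> Metabolite:
        m = self._lib.get(metabolite_id)
        if m is None:
            raise KeyError(f"metabolite id {metabolite_id!r} not in library")
        return m

    def _stereo_fps(self, mid: str) -> list[chem.Fingerprint]:
        fps = self._stereo.get(mid)
        if fps is None:
            fps = chem.stereo_fingerprints(self._resolve(mid))
            self._stereo[mid] = fps
        return fps

    def gene_cluster_overlap(self, protein_ids: Iterable[str]) -> float:
        """GC: pair-set intersection normalized by the larger pair count."""
        pairs = {
            frozenset(p) for p in itertools.combinations(sorted(set(protein_ids)), 2)
        }
        denom = max(len(self._gc_pairs), len(pairs))
        if denom == 0:
            return 0.0
        return len(self._gc_pairs & pairs) / denom

    def _gc_stats(self, ceiling: int, sample_n: int, seed: int) -> tuple[float, float]:
        """Distribution of GC over subsets (size 3..P) of candidate proteins."""
        pids = sorted(set(self.c.proteins) - self._dummy_pids)
        n = len(pids)
        sizes = range(3, n + 1)
        total = sum(math.comb(n, k) for k in sizes)
        values: list[float] = []
        if total == 0:
            return 0.0, 0.0
        if total <= ceiling:
            for k in sizes:
                for subset in itertools.combinations(pids, k):
                    values.append(self.gene_cluster_overlap(subset))
        else:
            rng = np.random.default_rng(seed)
            weights = np.array([math.comb(n, k) for k in sizes], dtype=float)
            weights /= weights.sum()
            for _ in range(sample_n):
                k = rng.choice(list(sizes), p=weights)
                subset = rng.choice(pids, size=int(k), replace=False)
                values.append(self.gene_cluster_overlap(subset))
        arr = np.asarray(values)
        return float(arr.mean()), float(arr.std(ddof=0))

    def _transform_cache(self, pid: str, sub_id: str) -> _TCCache | None:
        """TC vector of the transformed substrate vs every candidate.

        Aggregation over multiple transforms / reaction sites / product
        stereoisomers is by maximum: any consistent reaction is rewarded.
        Returns None when the substrate matches no transform motif.
        """
        key = (pid, sub_id)
        if key in self._ct_cache:
            return self._ct_cache[key]
        transforms = (self.r.transforms or {}).get(pid, ())
        products: set[str] = set()
        sub = self._resolve(sub_id)
        for t in transforms:
            products.update(chem.apply_transformation(sub, t))
        cache: _TCCache | None = None
        if products:
            prod_fps = [
                fp for smi in sorted(products) for fp in chem.stereo_fingerprints(smi)
            ]
            vec = {
                mid: max(chem.tanimoto(pf, self._fp[mid]) for pf in prod_fps)
                for mid in self.c.metabolites
            }
            cache = _TCCache(vec)
        self._ct_cache[key] = cache
        return cache

    def _dummy_triad_cache(self, sub_id: str) -> _TCCache:
        cache = self._dummy_cache.get(sub_id)
        if cache is None:
            vec = {
                mid: max(
                    chem.tanimoto(fa, self._fp[mid])
                    for fa in self._stereo_fps(sub_id)
                )
                for mid in self.c.metabolites
            }
            cache = _TCCache(vec)
            self._dummy_cache[sub_id] = cache
        return cache

    # -- individual restraint terms --------------------------------------

    def score_docking(self, p: PathwayModel) -> float | None:
        """Z_VS = -(1/N) sum of per-pair docking Z-scores.

        Pairs without a docking score (including all dummy pairs, which have
        no table) are excluded from N; N = 0 makes the term absent.
        """
        zs = [
            z
            for prot, lig in p.protein_ligand_pairs()
            if (z := self._dock_z.get(prot, {}).get(lig)) is not None
        ]
        if not zs:
            return None
        return -float(np.mean(zs))

    def score_transformations(self, p: PathwayModel) -> float | None:
        """Z_CT: mean per-triad Z of the transformed-substrate/product TC.

        A protein with no transforms (dummy node, transporter) compares the
        substrate directly to the product.  A substrate matching no motif
        contributes TC = 0 for its triad.
        """
        zs = []
        for sub, prot, prod in p.triads():
            if (self.r.transforms or {}).get(prot):
                cache = self._transform_cache(prot, sub)
                if cache is None:  # no motif match: TC 0 against a null population
                    zs.append(0.0)
                else:
                    zs.append(cache.z_of(prod))
            else:
                zs.append(self._dummy_triad_cache(sub).z_of(prod))
        if not zs:
            return None
        return float(np.mean(zs))

    def score_sea(self, p: PathwayModel) -> float | None:
        """Z_SEA: mean normalized S_AB over consecutive non-dummy protein pairs."""
        if not self._sea_z:
            return None
        ss = []
        for a, b in p.consecutive_protein_pairs():
            if a in self._dummy_pids or b in self._dummy_pids:
                continue
            key = (a, b) if a <= b else (b, a)
            s = self._sea_z.get(key)
            if s is not None:
                ss.append(s)
        if not ss:
            return None
        return float(np.mean(ss))

    def score_endpoint(self, p: PathwayModel) -> float | None:
        """Z_CM: normalized max TC of the final ligand vs central metabolism."""
        if not self._cm_z:
            return None
        return self._cm_z.get(p.nodes[-1])

    def score_hts(self, p: PathwayModel) -> float | None:
        """Z_HTS: normalized max TC of each screened protein's substrate vs hits.

        Absent when no screened protein occurs in the pathway; averaged when
        several do.
        """
        vals = []
        substrate = {prot: sub for sub, prot, _ in p.triads()}
        for pid, zmap in self._hts_z.items():
            sub = substrate.get(pid)
            if sub is not None and sub in zmap:
                vals.append(zmap[sub])
        if not vals:
            return None
        return float(np.mean(vals))

    def score_homology(self, p: PathwayModel) -> float | None:
        """Z_HS: normalized TC of an annotated protein's substrate vs its
        homolog's characterized substrate; absent when none is in the pathway."""
        vals = []
        substrate = {prot: sub for sub, prot, _ in p.triads()}
        for pid, zmap in self._hs_z.items():
            sub = substrate.get(pid)
            if sub is not None and sub in zmap:
                vals.append(zmap[sub])
        if not vals:
            return None
        return float(np.mean(vals))

    def score_gene_cluster(self, p: PathwayModel) -> float | None:
        """Z_GC: normalized pair-set overlap between the gene cluster and the
        pathway's non-dummy proteins."""
        if not self._gc_pairs:
            return None
        gc = self.gene_cluster_overlap(pid for pid in p.proteins if pid not in self._dummy_pids)
        return zscore(gc, self._gc_mean, self._gc_sd)

    # -- composite --------------------------------------------------------

    _TERM_FNS = {
        "vs": score_docking,
        "ct": score_transformations,
        "sea": score_sea,
        "cm": score_endpoint,
        "hts": score_hts,
        "hs": score_homology,
        "gc": score_gene_cluster,
    }

    def breakdown(self, p: PathwayModel) -> RestraintBreakdown:
        terms: dict[str, float] = {}
        for name in ALL_TERMS:
            if name not in self.enabled:
                continue
            value = self._TERM_FNS[name](self, p)
            if value is not None:
                terms[name] = value
        return RestraintBreakdown(terms)

    def score_pathway(self, p: PathwayModel) -> ScoredPathway:
        b = self.breakdown(p)
        return ScoredPathway(p, canonical_key(p), b.terms, b.total)


def score_pathway(p: PathwayModel, scorer: Scorer) -> ScoredPathway:
    """Module-level convenience wrapper around :meth:`Scorer.score_pathway`."""
    return scorer.score_pathway(p)
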