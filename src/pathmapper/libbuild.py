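"""Candidate-metabolite library construction.

The smallest candidate subset of a metabolite library is the union of (a)
the top-N scoring metabolites of every docking screen and (b) library
metabolites chemically similar (Tanimoto above a cutoff) to any product of
applying the candidate enzymes' reaction transforms to the docking hits.
Transformation expansion is a single pass: products of products are not
expanded further.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import chem
from .model import Metabolite, Transformation
from .restraints import DockingTable

__all__ = ["LibraryBuildConfig", "build_candidate_metabolites"]


@dataclass
class LibraryBuildConfig:
    top_n: int = 1000
    tc_cutoff: float = 0.75

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if not 0.0 < self.tc_cutoff <= 1.0:
            raise ValueError("tc_cutoff must be in (0, 1]")


def _top_n(table: DockingTable, n: int) -> list[str]:
    """Best-scoring metabolite ids (lower score = better), ties by id."""
    return [
        mid
        for mid, _ in sorted(table.scores.items(), key=lambda kv: (kv[1], kv[0]))[:n]
    ]


def build_candidate_metabolites(
    docking: Mapping[str, DockingTable],
    transforms: Mapping[str, Sequence[Transformation]] | None,
    library: Mapping[str, Metabolite],
    config: LibraryBuildConfig = LibraryBuildConfig(),
) -> tuple[set[str], pd.DataFrame]:
    """Return the candidate metabolite id set and a provenance table.

    Provenance rows carry (id, source: docking|transform, parent): the
    screen protein for docking hits, or the seed metabolite whose
    transformation product matched for similarity additions.  Metabolites
    whose SMILES match no substrate motif are simply not expanded.
    """
    if not docking:
        raise ValueError("at least one docking table is required")
    candidates: set[str] = set()
    rows: list[dict] = []
    seeds: list[str] = []
    for pid in sorted(docking):
        for mid in _top_n(docking[pid], config.top_n):
            if mid not in candidates:
                candidates.add(mid)
                seeds.append(mid)
            rows.append({"id": mid, "source": "docking", "parent": pid})

    if transforms:
        lib_fps = {mid: chem.fingerprint(m) for mid, m in library.items()}
        all_transforms = [
            t for pid in sorted(transforms) for t in transforms[pid]
        ]
        for seed_id in seeds:
            seed = library.get(seed_id)
            if seed is None:
                continue
            products: set[str] = set()
            for t in all_transforms:
                products.update(chem.apply_transformation(seed, t))
            if not products:
                continue
            prod_fps = [
                fp
                for smi in sorted(products)
                for fp in chem.stereo_fingerprints(smi)
            ]
            for mid, lib_fp in lib_fps.items():
                tc = max(chem.tanimoto(pf, lib_fp) for pf in prod_fps)
                if tc > config.tc_cutoff:
                    if mid not in candidates:
                        candidates.add(mid)
                    rows.append(
                        {"id": mid, "source": "transform", "parent": seed_id}
                    )

    prov = (
        pd.DataFrame(rows, columns=["id", "source", "parent"])
        .drop_duplicates(ignore_index=True)
        .sort_values(["id", "source", "parent"], ignore_index=True)
    )
    return candidates, prov
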