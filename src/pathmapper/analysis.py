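"""Ensemble analysis: clustering, edge frequencies, convergence, JSON export.

Good-scoring models are clustered by the Hamming distance between their
node sequences (fraction of differing positions over all protein and ligand
nodes) with average-linkage hierarchical clustering cut at 0.2.  Edge
frequencies over the ensemble re-rank enzyme-ligand pairings; the union
network of all models is exported as a versioned JSON document for network
visualization tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Collection, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .model import PathwayModel
from .restraints import ScoredPathway

__all__ = [
    "ClusterResult",
    "hamming_distance",
    "cluster_models",
    "edge_frequencies",
    "convergence_curve",
    "export_netimp_json",
    "import_netimp_json",
]

NETIMP_FORMAT = "netimp/1"


@dataclass
class ClusterResult:
    """Flat clustering of an ensemble.

    ``assignments`` maps model key to cluster id; ``representatives`` maps
    cluster id to the key of its best-scoring member (ties broken by
    lexicographic key).  Cluster ids are renumbered 1..C by decreasing
    representative score so they are deterministic.
    """

    assignments: dict[str, int]
    representatives: dict[int, str]
    cutoff: float
    linkage_method: str = "average"

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


def _nodes_of(m) -> tuple[str, ...]:
    if isinstance(m, PathwayModel):
        return m.nodes
    if isinstance(m, ScoredPathway):
        return m.pathway.nodes
    return tuple(m)


def hamming_distance(a, b) -> float:
    """Fraction of node positions at which two models differ.

    Models of different lengths are assigned distance 1.0, so per-length
    sub-ensembles cluster separately.
    """
    na, nb = _nodes_of(a), _nodes_of(b)
    if len(na) != len(nb):
        return 1.0
    return sum(x != y for x, y in zip(na, nb)) / len(na)


def cluster_models(
    models: Sequence[ScoredPathway],
    cutoff: float = 0.2,
    linkage_method: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of models, flat-cut at the given distance.

    Deterministic for a fixed input order; a model joins a cluster when its
    cophenetic distance to it is <= cutoff.
    """
    if not models:
        raise ValueError("cannot cluster an empty model set")
    keys = [m.key for m in models]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate model keys in cluster input")
    if len(models) == 1:
        labels = np.array([1])
    else:
        n = len(models)
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dm[i, j] = dm[j, i] = hamming_distance(models[i], models[j])
        z = linkage(squareform(dm, checks=False), method=linkage_method)
        labels = fcluster(z, t=cutoff, criterion="distance")
    by_label: dict[int, list[ScoredPathway]] = {}
    for m, lab in zip(models, labels):
        by_label.setdefault(int(lab), []).append(m)
    reps = {
        lab: max(members, key=lambda m: (m.total, m.key)).key
        for lab, members in by_label.items()
    }
    order = sorted(
        by_label,
        key=lambda lab: (
            -max(m.total for m in by_label[lab]),
            reps[lab],
        ),
    )
    renumber = {lab: i + 1 for i, lab in enumerate(order)}
    assignments = {
        m.key: renumber[int(lab)] for m, lab in zip(models, labels)
    }
    representatives = {renumber[lab]: reps[lab] for lab in by_label}
    return ClusterResult(assignments, representatives, cutoff, linkage_method)


def _model_edges(m) -> set[tuple[str, str, str]]:
    """(protein, ligand, role) edges of one model; role is the ligand's side."""
    edges = set()
    nodes = _nodes_of(m)
    for i in range(1, len(nodes), 2):
        edges.add((nodes[i], nodes[i - 1], "substrate"))
        edges.add((nodes[i], nodes[i + 1], "product"))
    return edges


def edge_frequencies(models: Sequence[ScoredPathway]) -> pd.DataFrame:
    """Relative frequency of each enzyme-ligand edge over the ensemble.

    Frequency = number of models containing the edge / number of models.
    Ranks are dense and descending per protein; tied frequencies share a
    rank.
    """
    if not models:
        raise ValueError("empty model set")
    counts: dict[tuple[str, str, str], int] = {}
    for m in models:
        for e in _model_edges(m):
            counts[e] = counts.get(e, 0) + 1
    rows = [
        {
            "protein": prot,
            "ligand": lig,
            "role": role,
            "frequency": n / len(models),
        }
        for (prot, lig, role), n in counts.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["protein", "frequency", "ligand", "role"],
        ascending=[True, False, True, True],
        ignore_index=True,
    )
    df["rank"] = (
        df.groupby("protein")["frequency"]
        .rank(method="dense", ascending=False)
        .astype(int)
    )
    return df


def convergence_curve(
    per_run_keys: Sequence[Collection[str]],
    assignments: Mapping[str, int],
) -> list[tuple[int, float]]:
    """Fraction of all clusters discovered after r runs, for r = 1..R.

    ``per_run_keys`` holds the good-scoring model keys found by each run;
    keys absent from ``assignments`` are ignored.  The curve is monotone
    non-decreasing and ends at 1.0 when every cluster was found by some run.
    """
    if len(per_run_keys) < 2:
        raise ValueError("need at least 2 runs for a convergence curve")
    total = len(set(assignments.values()))
    if total == 0:
        raise ValueError("no clustered models")
    seen: set[int] = set()
    curve = []
    for r, keys in enumerate(per_run_keys, start=1):
        seen.update(assignments[k] for k in keys if k in assignments)
        curve.append((r, len(seen) / total))
    return curve


def _canonical_document(doc: dict) -> str:
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def export_netimp_json(
    models: Sequence[ScoredPathway],
    clusters: ClusterResult | None = None,
) -> str:
    """Serialize an ensemble to the NetIMP JSON input format.

    The document carries the union network of all models (nodes typed as
    protein or metabolite; edges annotated with the models they occur in)
    plus each model's node sequence, total score, per-restraint scores, and
    cluster id.  Serialization is canonical, so equal ensembles produce
    byte-identical documents.
    """
    if not models:
        raise ValueError("empty ensemble")
    ordered = sorted(models, key=lambda m: (-m.total, m.key))
    nodes: dict[str, str] = {}
    edge_models: dict[tuple[str, str], list[str]] = {}
    for m in ordered:
        seq = m.pathway.nodes
        for i, nid in enumerate(seq):
            nodes.setdefault(nid, "metabolite" if i % 2 == 0 else "protein")
        for a, b in zip(seq, seq[1:]):
            edge_models.setdefault((a, b) if a <= b else (b, a), []).append(m.key)
    doc = {
        "format": NETIMP_FORMAT,
        "clustering": None
        if clusters is None
        else {
            "cutoff": clusters.cutoff,
            "linkage": clusters.linkage_method,
        },
        "nodes": [
            {"id": nid, "type": typ} for nid, typ in sorted(nodes.items())
        ],
        "edges": [
            {"source": a, "target": b, "models": sorted(set(keys))}
            for (a, b), keys in sorted(edge_models.items())
        ],
        "models": [
            {
                "key": m.key,
                "nodes": list(m.pathway.nodes),
                "score": m.total,
                "restraints": {k: v for k, v in sorted(m.terms.items())},
                "cluster": None
                if clusters is None
                else clusters.assignments.get(m.key),
            }
            for m in ordered
        ],
    }
    return _canonical_document(doc)


def import_netimp_json(
    text: str,
) -> tuple[list[ScoredPathway], ClusterResult | None]:
    """Parse a NetIMP document back into models (and clusters when present).

    Round-trips losslessly: re-exporting the imported ensemble reproduces
    the document byte for byte.
    """
    doc = json.loads(text)
    if doc.get("format") != NETIMP_FORMAT:
        raise ValueError(f"unsupported document format {doc.get('format')!r}")
    models = []
    assignments: dict[str, int] = {}
    for entry in doc["models"]:
        p = PathwayModel(tuple(entry["nodes"]))
        sp = ScoredPathway(
            p, entry["key"], dict(entry["restraints"]), float(entry["score"])
        )
        models.append(sp)
        if entry.get("cluster") is not None:
            assignments[sp.key] = int(entry["cluster"])
    clusters = None
    if doc.get("clustering") is not None and assignments:
        by_lab: dict[int, list[ScoredPathway]] = {}
        for m in models:
            if m.key in assignments:
                by_lab.setdefault(assignments[m.key], []).append(m)
        reps = {
            lab: max(ms, key=lambda m: (m.total, m.key)).key
            for lab, ms in by_lab.items()
        }
        clusters = ClusterResult(
            assignments,
            reps,
            float(doc["clustering"]["cutoff"]),
            doc["clustering"]["linkage"],
        )
    return models, clusters
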