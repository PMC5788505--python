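"""File formats: SMILES files, restraint TSVs, manifests, problem directories.

A problem directory holds all mapper inputs in plain-text formats:

* ``metabolites.smi`` — one record per line: ``SMILES<space>id`` (the full
  library, which may include non-candidate compounds such as the
  central-metabolism list)
* ``candidates.txt`` — candidate metabolite ids, one per line
* ``proteins.tsv`` — ``id  kind  family``
* ``transforms.tsv`` — ``protein_id  SMIRKS  label``
* ``docking/<protein>.tsv`` — ``metabolite_id  score`` (lower = better)
* ``sea.tsv`` — ``protein_a  protein_b  evalue`` (self pairs included)
* ``central.txt`` — central-metabolism metabolite ids, one per line
* ``hts.tsv`` — ``protein_id  hit_metabolite_id``
* ``homology.tsv`` — ``protein_id  reference_smiles``
* ``gene_cluster.txt`` — member protein ids, one per line
* ``manifest.yaml`` — names the files above plus constraints, pathway
  length, and sampler settings

Unparseable SMILES or SMIRKS are rejected at load time with the offending
record named.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import yaml

from . import chem
from .model import CandidateSets, Metabolite, PathwayModel, Protein, Transformation
from .restraints import DockingTable, RestraintSet, ScoredPathway, SEAMatrix

__all__ = [
    "read_smiles_file",
    "write_smiles_file",
    "load_problem",
    "write_problem",
    "load_truth",
    "write_models_jsonl",
    "read_models_jsonl",
]


def read_smiles_file(path: str | Path) -> dict[str, Metabolite]:
    """Read ``SMILES id`` records, validating every SMILES."""
    out: dict[str, Metabolite] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'SMILES id', got {line!r}")
        smiles, mid = parts[0], parts[1]
        chem.parse_smiles(smiles, name=f"{path}:{lineno} ({mid})")
        out[mid] = Metabolite(mid, smiles)
    return out


def write_smiles_file(path: str | Path, metabolites: Mapping[str, Metabolite]) -> None:
    lines = [f"{m.smiles} {mid}" for mid, m in sorted(metabolites.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def _read_tsv(path: Path, ncols: int) -> list[list[str]]:
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < ncols:
            raise ValueError(f"{path}:{lineno}: expected {ncols} columns")
        rows.append(parts)
    return rows


def _ids_file(path: Path) -> list[str]:
    return [
        line.strip()
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


def load_problem(
    path: str | Path,
) -> tuple[CandidateSets, RestraintSet, dict]:
    """Load a problem directory (or its manifest.yaml) into domain objects."""
    path = Path(path)
    manifest_path = path / "manifest.yaml" if path.is_dir() else path
    root = manifest_path.parent
    manifest = yaml.safe_load(manifest_path.read_text())
    files = manifest["files"]

    def fpath(key: str) -> Path | None:
        name = files.get(key)
        return root / name if name else None

    library = read_smiles_file(fpath("metabolites"))
    cand_path = fpath("candidates")
    if cand_path is not None:
        cand_ids = _ids_file(cand_path)
        missing = set(cand_ids) - set(library)
        if missing:
            raise ValueError(f"candidate ids not in library: {sorted(missing)}")
        metabolites = {mid: library[mid] for mid in cand_ids}
    else:
        metabolites = dict(library)

    transforms: dict[str, tuple[Transformation, ...]] | None = None
    tpath = fpath("transforms")
    if tpath is not None:
        transforms = {}
        for pid, smirks, *rest in _read_tsv(tpath, 2):
            label = rest[0] if rest else ""
            t = Transformation(smirks, label)
            chem.apply_transformation("CC", t)  # validates the SMIRKS
            transforms.setdefault(pid, ())
            transforms[pid] = transforms[pid] + (t,)

    proteins: dict[str, Protein] = {}
    for pid, kind, *rest in _read_tsv(fpath("proteins"), 2):
        family = rest[0] if rest else ""
        ts = tuple((transforms or {}).get(pid, ()))
        proteins[pid] = Protein(pid, kind, ts if kind != "dummy" else (), family)

    docking = None
    dock_dir = fpath("docking_dir")
    if dock_dir is not None and dock_dir.is_dir():
        docking = {}
        for table_path in sorted(dock_dir.glob("*.tsv")):
            pid = table_path.stem
            scores = {
                mid: float(score) for mid, score, *_ in _read_tsv(table_path, 2)
            }
            docking[pid] = DockingTable(pid, scores)

    sea = None
    spath = fpath("sea")
    if spath is not None:
        sea = SEAMatrix(
            {(a, b): float(e) for a, b, e, *_ in _read_tsv(spath, 3)}
        )

    central_ids = None
    cpath = fpath("central")
    if cpath is not None:
        central_ids = _ids_file(cpath)

    hts_hits = None
    hpath = fpath("hts")
    if hpath is not None:
        hts_hits = {}
        for pid, mid, *_ in _read_tsv(hpath, 2):
            hts_hits.setdefault(pid, []).append(mid)

    homology = None
    hopath = fpath("homology")
    if hopath is not None:
        homology = {}
        for pid, smiles, *_ in _read_tsv(hopath, 2):
            chem.parse_smiles(smiles, name=f"{hopath} ({pid})")
            homology[pid] = smiles

    gene_cluster = None
    gpath = fpath("gene_cluster")
    if gpath is not None:
        gene_cluster = frozenset(_ids_file(gpath))

    constraints = {
        int(pos): frozenset(ids)
        for pos, ids in (manifest.get("constraints") or {}).items()
    }
    candidates = CandidateSets(
        proteins=proteins,
        metabolites=metabolites,
        n_proteins_in_pathway=manifest.get("pathway_length", 0),
        position_constraints=constraints,
    )
    restraints = RestraintSet(
        docking=docking,
        sea=sea,
        transforms=transforms,
        central_ids=central_ids,
        hts_hits=hts_hits,
        homology=homology,
        gene_cluster=gene_cluster,
        enable_gc=bool(manifest.get("enable_gene_cluster", False)),
        library=library,
    )
    return candidates, restraints, manifest


def write_problem(problem, outdir: str | Path) -> Path:
    """Write a PlantedProblem as a problem directory (ground truth included
    as ``truth.json``, which the manifest deliberately does not reference)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    c, r = problem.candidates, problem.restraints

    library = dict(c.metabolites)
    if r.library:
        for mid, m in r.library.items():
            library.setdefault(mid, m)
    write_smiles_file(outdir / "metabolites.smi", library)
    (outdir / "candidates.txt").write_text(
        "\n".join(sorted(c.metabolites)) + "\n"
    )
    (outdir / "proteins.tsv").write_text(
        "\n".join(
            f"{p.id}\t{p.kind}\t{p.family_label}"
            for p in sorted(c.proteins.values(), key=lambda p: p.id)
        )
        + "\n"
    )
    files = {
        "metabolites": "metabolites.smi",
        "candidates": "candidates.txt",
        "proteins": "proteins.tsv",
    }

    if r.transforms is not None:
        lines = [
            f"{pid}\t{t.smirks}\t{t.direction_label}"
            for pid in sorted(r.transforms)
            for t in r.transforms[pid]
        ]
        (outdir / "transforms.tsv").write_text("\n".join(lines) + "\n")
        files["transforms"] = "transforms.tsv"
    if r.docking:
        dock_dir = outdir / "docking"
        dock_dir.mkdir(exist_ok=True)
        for pid, table in sorted(r.docking.items()):
            (dock_dir / f"{pid}.tsv").write_text(
                "\n".join(
                    f"{mid}\t{score!r}" for mid, score in sorted(table.scores.items())
                )
                + "\n"
            )
        files["docking_dir"] = "docking"
    if r.sea is not None:
        (outdir / "sea.tsv").write_text(
            "\n".join(
                f"{a}\t{b}\t{e!r}" for (a, b), e in sorted(r.sea.evalues.items())
            )
            + "\n"
        )
        files["sea"] = "sea.tsv"
    if r.central_ids:
        (outdir / "central.txt").write_text("\n".join(r.central_ids) + "\n")
        files["central"] = "central.txt"
    if r.hts_hits:
        (outdir / "hts.tsv").write_text(
            "\n".join(
                f"{pid}\t{mid}"
                for pid in sorted(r.hts_hits)
                for mid in r.hts_hits[pid]
            )
            + "\n"
        )
        files["hts"] = "hts.tsv"
    if r.homology:
        (outdir / "homology.tsv").write_text(
            "\n".join(f"{pid}\t{smi}" for pid, smi in sorted(r.homology.items()))
            + "\n"
        )
        files["homology"] = "homology.tsv"
    if r.gene_cluster:
        (outdir / "gene_cluster.txt").write_text(
            "\n".join(sorted(r.gene_cluster)) + "\n"
        )
        files["gene_cluster"] = "gene_cluster.txt"

    manifest = {
        "files": files,
        "constraints": {
            int(pos): sorted(ids) for pos, ids in c.position_constraints.items()
        },
        "pathway_length": c.single_length(),
        "enable_gene_cluster": bool(r.enable_gc),
        "generator": {
            "seed": problem.config.seed,
            "k": problem.config.k,
            "docking_signal": problem.config.docking_signal,
            "sea_signal": problem.config.sea_signal,
        },
    }
    (outdir / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=True)
    )
    if getattr(problem, "truth", None) is not None:
        (outdir / "truth.json").write_text(
            json.dumps({"nodes": list(problem.truth.nodes)}, indent=2, sort_keys=True)
            + "\n"
        )
    return outdir


def load_truth(problem_dir: str | Path) -> PathwayModel:
    doc = json.loads((Path(problem_dir) / "truth.json").read_text())
    return PathwayModel(tuple(doc["nodes"]))


def write_models_jsonl(path: str | Path, models) -> None:
    """One ScoredPathway per line: key, nodes, total, per-term breakdown."""
    with open(path, "w") as fh:
        for m in models:
            fh.write(
                json.dumps(
                    {
                        "key": m.key,
                        "nodes": list(m.pathway.nodes),
                        "total": m.total,
                        "terms": {k: v for k, v in sorted(m.terms.items())},
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_models_jsonl(path: str | Path) -> list[ScoredPathway]:
    models = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        doc = json.loads(line)
        models.append(
            ScoredPathway(
                PathwayModel(tuple(doc["nodes"])),
                doc["key"],
                dict(doc["terms"]),
                float(doc["total"]),
            )
        )
    return models
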