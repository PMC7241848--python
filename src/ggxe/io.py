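"""Readers/writers for the pipeline's flat-file artefacts.

All tables are tab-separated UTF-8 with a header row.  Validation errors name
the offending row and column so malformed inputs can be fixed quickly.

Formats
-------
genotypes : first column ``segregant``, remaining columns marker ids, cells 0/2
map       : columns ``marker``, ``chrom``, ``pos_bp``, ``pos_cM``
phenotypes: long format, columns ``segregant``, ``environment``, ``replicate``,
            ``growth``
interactions: columns ``locus_a``, ``locus_b``, ``environment``, ``lr``, ``p``,
            ``active``
network   : edge-list TSV plus GraphML via :func:`write_network`
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .simulate import GeneticMap, GenotypeMatrix, PhenotypeTable, SimArchitecture

__all__ = [
    "read_map",
    "write_map",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_interactions",
    "write_interactions",
    "read_architecture",
    "write_architecture",
    "write_network",
    "validate_files",
]


def read_map(path) -> GeneticMap:
    t = pd.read_csv(path, sep="\t")
    return GeneticMap(t)


def write_map(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


def read_genotypes(path, gmap: GeneticMap | None = None) -> GenotypeMatrix:
    t = pd.read_csv(path, sep="\t", index_col=0)
    t.index.name = "segregant"
    arr = t.to_numpy()
    bad = ~np.isin(arr, (0, 2))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: invalid genotype {arr[i, j]!r} at row {t.index[i]!r} "
            f"(file line {i + 2}), column {t.columns[j]!r}; expected 0 or 2"
        )
    return GenotypeMatrix(t.astype(np.int8), gmap=gmap)


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    out = geno.values.copy()
    out.index.name = "segregant"
    out.to_csv(path, sep="\t")


def read_phenotypes(path, environments: list[str] | None = None) -> PhenotypeTable:
    t = pd.read_csv(path, sep="\t")
    missing = set(PhenotypeTable.COLUMNS) - set(t.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if environments is not None:
        unknown = set(t["environment"]) - set(environments)
        if unknown:
            row = t.index[t["environment"].isin(unknown)][0]
            raise ValueError(
                f"{path}: unknown environment {t.loc[row, 'environment']!r} "
                f"at file line {row + 2}"
            )
    # long-format phenotypes are order-insensitive: normalise row order
    t = t.sort_values(["environment", "segregant", "replicate"], kind="stable")
    return PhenotypeTable(t.reset_index(drop=True))


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.records.to_csv(path, sep="\t", index=False)


INTERACTION_COLUMNS = ["locus_a", "locus_b", "environment", "lr", "p", "active"]


def read_interactions(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    missing = set(INTERACTION_COLUMNS) - set(t.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (t["lr"].dropna() < 0).any():
        row = t.index[t["lr"] < 0][0]
        raise ValueError(f"{path}: negative LR at file line {row + 2}")
    pvals = t["p"].dropna()
    if ((pvals < 0) | (pvals > 1)).any():
        row = t.index[(t["p"] < 0) | (t["p"] > 1)][0]
        raise ValueError(f"{path}: p-value outside [0,1] at file line {row + 2}")
    key = t.apply(
        lambda r: (tuple(sorted((r["locus_a"], r["locus_b"]))), r["environment"]),
        axis=1,
    )
    if key.duplicated().any():
        row = key.index[key.duplicated()][0]
        raise ValueError(
            f"{path}: duplicate (pair, environment) record at file line {row + 2}"
        )
    return t


def write_interactions(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, columns=list(records.columns))


def read_architecture(path) -> SimArchitecture:
    return SimArchitecture.from_json(Path(path).read_text())


def write_architecture(arch: SimArchitecture, path) -> None:
    Path(path).write_text(arch.to_json())


def write_network(net, edge_path, graphml_path=None) -> None:
    """Export a network as an edge-list TSV and optionally GraphML."""
    rows = []
    for a, b, env in net.graph.edges(keys=True):
        data = net.graph.get_edge_data(a, b, env)
        rows.append(
            {
                "locus_a": min(a, b),
                "locus_b": max(a, b),
                "environment": env,
                "p": data.get("p", float("nan")),
            }
        )
    pd.DataFrame(rows, columns=["locus_a", "locus_b", "environment", "p"]).to_csv(
        edge_path, sep="\t", index=False
    )
    if graphml_path is not None:
        g = nx.MultiGraph()
        g.add_nodes_from(net.graph.nodes)
        for a, b, env in net.graph.edges(keys=True):
            data = {
                k: v
                for k, v in net.graph.get_edge_data(a, b, env).items()
                if isinstance(v, (int, float, str, bool))
            }
            g.add_edge(a, b, key=str(env), environment=str(env), **data)
        nx.write_graphml(g, graphml_path)


def validate_files(
    geno_path=None, map_path=None, pheno_path=None, interactions_path=None
) -> dict:
    """Validate input files; returns a machine-readable JSON-able report."""
    report: dict = {"ok": True, "files": {}}
    gmap = None
    checks = []
    if map_path:
        checks.append(("map", map_path, lambda: read_map(map_path)))
    if geno_path:
        checks.append(("genotypes", geno_path, lambda: read_genotypes(geno_path, gmap)))
    if pheno_path:
        checks.append(("phenotypes", pheno_path, lambda: read_phenotypes(pheno_path)))
    if interactions_path:
        checks.append(
            ("interactions", interactions_path, lambda: read_interactions(interactions_path))
        )
    for name, path, fn in checks:
        entry = {"path": str(path)}
        try:
            obj = fn()
            if name == "map":
                gmap = obj
            entry["valid"] = True
        except (ValueError, KeyError, FileNotFoundError) as exc:
            entry["valid"] = False
            entry["error"] = str(exc)
            report["ok"] = False
        report["files"][name] = entry
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
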