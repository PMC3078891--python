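"""Readers and writers for the pipeline's plain-text formats.

Everything is tab-delimited text or standard community formats: long-format
spot tables, probe-map TSVs, expression matrices with a label sidecar, GMT
gene sets, a minimal OBO term graph (parsed with obonet), gene-association
tables and long Ct tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd

from .preprocess import ExpressionMatrix

__all__ = [
    "read_spot_table", "write_spot_table",
    "read_probe_map", "write_probe_map",
    "write_matrix", "read_matrix",
    "read_gmt", "write_gmt",
    "read_obo", "write_obo",
    "read_gene_associations", "write_gene_associations",
    "read_ct_table", "write_ct_table",
    "write_json",
]


def read_spot_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "signal_median", "bg_median", "flag"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spot table {path} missing columns: {sorted(missing)}")
    return df


def write_spot_table(spots: pd.DataFrame, path) -> None:
    spots.to_csv(path, sep="\t", index=False)


def read_probe_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "gene_symbol", "align_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"probe map {path} missing columns: {sorted(missing)}")
    return df


def write_probe_map(probe_map: pd.DataFrame, path) -> None:
    probe_map.to_csv(path, sep="\t", index=False)


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    """Matrix TSV (rows × samples) plus a .labels.tsv sidecar of groups."""
    path = Path(path)
    matrix.values.to_csv(path, sep="\t")
    matrix.groups.rename("group").to_csv(
        path.with_suffix(".labels.tsv"), sep="\t"
    )


def read_matrix(path) -> ExpressionMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col=0)
    groups = pd.read_csv(path.with_suffix(".labels.tsv"), sep="\t", index_col=0)[
        "group"
    ]
    return ExpressionMatrix(values=values, groups=groups)


def read_gmt(path) -> dict[str, set[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(gene_sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def write_obo(dag: nx.MultiDiGraph, path) -> None:
    """Minimal OBO serialisation (id, name, namespace, is_a) readable by obonet."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: custom\n")
        for node in sorted(dag.nodes):
            data = dag.nodes[node]
            fh.write("\n[Term]\n")
            fh.write(f"id: {node}\n")
            fh.write(f"name: {data.get('name', node)}\n")
            if data.get("namespace"):
                fh.write(f"namespace: {data['namespace']}\n")
            for _, parent, key in dag.out_edges(node, keys=True):
                if key == "is_a":
                    fh.write(f"is_a: {parent}\n")


def read_obo(path) -> nx.MultiDiGraph:
    return obonet.read_obo(path)


def read_gene_associations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_symbol", "term"} - set(df.columns)
    if missing:
        raise ValueError(f"association table missing columns: {sorted(missing)}")
    return df


def write_gene_associations(direct: pd.DataFrame, path) -> None:
    direct.to_csv(path, sep="\t", index=False)


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "group", "gene", "ct"} - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if "dilution" not in df.columns:
        df["dilution"] = float("nan")
    return df


def write_ct_table(ct: pd.DataFrame, path) -> None:
    ct.to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_coerce)
        fh.write("\n")


def _coerce(x):
    try:
        import numpy as np

        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        if isinstance(x, np.ndarray):
            return x.tolist()
    except Exception:
        pass
    raise TypeError(f"not JSON serialisable: {type(x)}")
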