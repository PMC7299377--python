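"""Readers and writers for the plain-text interchange formats.

All tables are TSV with a header row; edge lists are 3-column TSV
(``source  target  interaction``) or SIF (``source interaction target``,
whitespace-separated); gene sets are GMT.  Writers are deterministic:
sorted JSON keys and floats at 6 significant digits.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .network import SubnetworkComponent, TransOmicNetwork, VALID_LAYERS, centralities

__all__ = [
    "read_matrix", "write_matrix", "read_vector", "write_vector",
    "read_edges", "write_edges", "read_layers", "write_layers",
    "read_gmt", "write_gmt", "write_report", "read_report",
    "write_weights", "read_weights",
    "component_to_sif", "component_to_graphml", "write_centrality_table",
]


class FormatError(ValueError):
    """Malformed input file."""


def _check_ids(ids, what: str, path):
    dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
    if dupes:
        raise FormatError(f"duplicate {what} in {path}: {dupes[:5]}")


def read_matrix(path) -> pd.DataFrame:
    """Read a subjects x features TSV (first column subject IDs, header row).

    Rejects NA and non-numeric cells, naming the offending cell, and
    duplicate row/column identifiers.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_ids(header[1:], "column headers", path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    _check_ids(df.index, "row identifiers", path)
    try:
        num = df.apply(pd.to_numeric, errors="coerce")
    except Exception as exc:  # pragma: no cover - pandas raises rarely here
        raise FormatError(f"non-numeric data in {path}: {exc}") from exc
    bad = num.isna()
    if bad.to_numpy().any():
        r = bad.any(axis=1).idxmax()
        c = bad.loc[r].idxmax()
        raise FormatError(f"non-numeric or NA cell in {path} at row {r!r}, column {c!r}")
    return num


def write_matrix(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_vector(path) -> pd.Series:
    df = read_matrix(path)
    if df.shape[1] != 1:
        raise FormatError(f"{path} must have exactly one value column, found {df.shape[1]}")
    return df.iloc[:, 0]


def write_vector(s: pd.Series, path, name: str = "y"):
    s.rename(name).to_frame().to_csv(path, sep="\t", float_format="%.10g")


def read_edges(path, fmt: str | None = None) -> list[tuple[str, str, str]]:
    """Read an edge list; ``fmt`` is 'tsv', 'sif' or None (infer by suffix).

    TSV columns: source, target, interaction (header optional, detected).
    SIF columns: source, interaction, target (whitespace-separated).
    """
    path = Path(path)
    if fmt is None:
        fmt = "sif" if path.suffix.lower() == ".sif" else "tsv"
    if fmt not in ("tsv", "sif"):
        raise FormatError(f"unknown edge format {fmt!r}")
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if fmt == "tsv" else line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: edge line needs >= 2 fields")
            if lineno == 1 and fields[0].lower() in ("source", "node_a", "from"):
                continue  # header row
            if fmt == "sif":
                if len(fields) < 3:
                    raise FormatError(f"{path}:{lineno}: SIF line needs source interaction target")
                a, rel, b = fields[0], fields[1], fields[2]
            else:
                a, b = fields[0], fields[1]
                rel = fields[2] if len(fields) > 2 else "interacts"
            edges.append((a, b, rel))
    return edges


def write_edges(edges: Iterable[tuple], path, fmt: str = "tsv"):
    path = Path(path)
    with open(path, "w") as fh:
        if fmt == "tsv":
            fh.write("source\ttarget\tinteraction\n")
            for e in edges:
                a, b, *rest = e
                fh.write(f"{a}\t{b}\t{rest[0] if rest else 'interacts'}\n")
        elif fmt == "sif":
            for e in edges:
                a, b, *rest = e
                fh.write(f"{a} {rest[0] if rest else 'interacts'} {b}\n")
        else:
            raise FormatError(f"unknown edge format {fmt!r}")


def read_layers(path) -> dict[str, str]:
    """Read the 2-column node -> layer TSV."""
    layers: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'node<TAB>layer'")
            node, layer = fields
            if lineno == 1 and layer.lower() == "layer":
                continue
            if layer not in VALID_LAYERS:
                raise FormatError(
                    f"{path}:{lineno}: invalid layer {layer!r} (expected {VALID_LAYERS})"
                )
            if node in layers:
                raise FormatError(f"{path}:{lineno}: duplicate node {node!r}")
            layers[node] = layer
    return layers


def write_layers(layers: Mapping[str, str], path):
    with open(path, "w") as fh:
        fh.write("node\tlayer\n")
        for node in layers:
            fh.write(f"{node}\t{layers[node]}\n")


def read_gmt(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a GMT gene-set file -> (sets, descriptions)."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 member"
                )
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate pathway {name!r}")
            sets[name] = {m for m in members if m.strip()}
            descriptions[name] = desc
    return sets, descriptions


def write_gmt(sets: Mapping[str, Iterable[str]], path,
              descriptions: Mapping[str, str] | None = None):
    with open(path, "w") as fh:
        for name in sets:
            desc = (descriptions or {}).get(name, "na")
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def _round_floats(obj, sig: int = 6):
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        if not math.isfinite(x):
            return x
        return float(f"{x:.{sig}g}")
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), sig)
    return obj


def write_report(obj, path):
    """Deterministic JSON writer (sorted keys, 6 significant digits)."""
    with open(path, "w") as fh:
        json.dump(_round_floats(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path):
    with open(path) as fh:
        return json.load(fh)


def write_weights(w: pd.Series, layers: Mapping[str, str], path):
    """weights.tsv: feature, layer, weight, selected."""
    df = pd.DataFrame({
        "feature": w.index,
        "layer": [layers.get(f, "NA") for f in w.index],
        "weight": w.to_numpy(),
        "selected": (w.to_numpy() != 0).astype(int),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_weights(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"feature", "layer", "weight", "selected"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing weight columns {sorted(missing)}")
    return df


def component_to_sif(component: SubnetworkComponent, path):
    write_edges([(a, b, "interacts") for a, b in component.edges], path, fmt="sif")


def component_to_graphml(component: SubnetworkComponent,
                         net: TransOmicNetwork, path,
                         weights: pd.Series | None = None):
    """Export one component with layer/weight/centrality node attributes."""
    g = component.to_graph()
    tab = centralities(component) if component.size >= 2 else None
    for v in g.nodes:
        g.nodes[v]["layer"] = net.layers.get(v, "NA")
        if weights is not None and v in weights.index:
            g.nodes[v]["weight"] = float(weights[v])
        if tab is not None:
            g.nodes[v]["degree"] = int(tab.loc[v, "degree"])
            g.nodes[v]["betweenness"] = float(tab.loc[v, "betweenness"])
            g.nodes[v]["closeness"] = float(tab.loc[v, "closeness"])
    nx.write_graphml(g, path)


def write_centrality_table(component: SubnetworkComponent,
                           net: TransOmicNetwork, path):
    """Centrality TSV: node, layer, degree, avg_shortest_path, betweenness, closeness."""
    tab = centralities(component).reset_index()
    tab.insert(1, "layer", [net.layers.get(v, "NA") for v in tab["node"]])
    tab.to_csv(path, sep="\t", index=False, float_format="%.6g")
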