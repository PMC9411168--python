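"""Readers and writers for the pipeline's plain-text formats.

TSV for tabular data (signals, values, candidates, scores, sites), SIF
for interaction edge lists, GMT for pathway gene sets, JSON for ground
truth and run reports, YAML for configuration.  All writers emit stably
sorted, fixed-precision text so identical inputs produce byte-identical
files.
"""

from __future__ import annotations

import json
from typing import Mapping

import networkx as nx
import pandas as pd
import yaml

__all__ = [
    "read_signals",
    "write_signals",
    "write_table",
    "read_table",
    "read_sif",
    "write_sif",
    "read_gmt",
    "write_gmt",
    "write_json",
    "read_json",
    "read_yaml",
    "write_yaml",
]

_FLOAT_FMT = "%.10g"


def write_table(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_signals(frame: pd.DataFrame, path) -> None:
    write_table(frame[["sample_id", "group", "peptide_id", "exposure_ms", "signal"]], path)


def read_signals(path) -> pd.DataFrame:
    frame = read_table(path)
    missing = {"sample_id", "peptide_id", "exposure_ms", "signal"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: signal table missing columns {sorted(missing)}")
    return frame


def write_sif(graph: nx.Graph, path) -> None:
    """SIF-like edge list: node_a <TAB> interaction <TAB> node_b."""
    with open(path, "w") as fh:
        for a, b, data in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            fh.write(f"{a}\t{data.get('interaction', 'unspecified')}\t{b}\n")


def read_sif(path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2:  # plain edge list is tolerated
                a, rel, b = parts[0], "unspecified", parts[1]
            elif len(parts) == 3:
                a, rel, b = parts
            else:
                raise ValueError(f"{path}:{ln}: expected 2 or 3 whitespace-separated fields")
            if a != b:
                g.add_edge(a, b, interaction=rel)
            else:
                g.add_node(a)
    return g


def write_gmt(gene_sets: Mapping[str, list], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def read_gmt(path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = [g for g in parts[2:] if g]
    return out


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)
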