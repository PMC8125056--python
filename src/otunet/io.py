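"""Readers and writers for the formats the pipeline touches.

All tabular formats are tab-delimited UTF-8 text; lines starting with ``#`` are
comments. Orientation of count tables is always an explicit parameter — silent
transposition of a sample × OTU matrix is a classic source of wrong results, so
no auto-detection is attempted.
"""

from __future__ import annotations

import csv
import io as _io
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import OtuTable, RelAbundanceTable, SampleMetadata, TaxonomyMap

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "read_newick",
    "write_newick",
    "write_network",
    "read_network",
]

logger = logging.getLogger(__name__)


def _read_tsv_grid(path) -> list[list[str]]:
    """Parse a TSV file into rows, enforcing rectangular shape."""
    rows: list[list[str]] = []
    width: int | None = None
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").rstrip("\r").split("\t")
            if width is None:
                width = len(fields)
            elif len(fields) != width:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(fields)} fields, expected {width})"
                )
            rows.append(fields)
    if not rows:
        raise ValueError(f"{path}: empty table")
    return rows


def read_otu_table(path, orientation: str = "samples-as-rows", *, allow_rounding: bool = False) -> OtuTable:
    """Read a dense TSV count table.

    Parameters
    ----------
    path
        TSV file whose first row and first column hold ids.
    orientation
        ``"samples-as-rows"`` or ``"otus-as-rows"``. Never guessed.
    allow_rounding
        Accept non-integer values by rounding them (off by default so that
        accidentally loading relative abundances fails loudly).
    """
    if orientation not in ("samples-as-rows", "otus-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    rows = _read_tsv_grid(path)
    header = rows[0][1:]
    row_ids = [r[0] for r in rows[1:]]
    try:
        body = np.array([[float(x) for x in r[1:]] for r in rows[1:]], dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric value in table body ({exc})") from exc
    if allow_rounding:
        body = np.round(body)
    df = pd.DataFrame(body, index=row_ids, columns=header)
    if orientation == "otus-as-rows":
        df = df.T
    return OtuTable(df)


def write_otu_table(table: OtuTable, path, orientation: str = "samples-as-rows") -> None:
    df = table.data if orientation == "samples-as-rows" else table.data.T
    df.to_csv(path, sep="\t", index_label="id")


def read_metadata(
    path,
    *,
    sample_col: str = "sample_id",
    species_col: str = "host_species",
    habit_col: str = "feeding_habit",
    diet_col: str = "diet_group",
) -> SampleMetadata:
    """Read a per-sample metadata sheet (sample id, host species, feeding habit, diet group)."""
    rows = _read_tsv_grid(path)
    header, body = rows[0], rows[1:]
    required = [sample_col, species_col, habit_col, diet_col]
    missing = [c for c in required if c not in header]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; found {header}")
    idx = {c: header.index(c) for c in required}
    records = {}
    for r in body:
        sid = r[idx[sample_col]]
        if sid in records:
            raise ValueError(f"{path}: duplicate sample id {sid!r}")
        records[sid] = {
            "host_species": r[idx[species_col]],
            "feeding_habit": r[idx[habit_col]],
            "diet_group": r[idx[diet_col]],
        }
    return SampleMetadata(pd.DataFrame.from_dict(records, orient="index"))


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.data.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path) -> TaxonomyMap:
    """Read an OTU → lineage map: ``otu_id<TAB>rank1;rank2;...`` per line."""
    lineages: dict[str, tuple[str, ...]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: expected 2 columns at line {lineno}")
            otu, lineage = parts
            if otu in lineages:
                raise ValueError(f"{path}: duplicate OTU id {otu!r}")
            lineages[otu] = tuple(x.strip() for x in lineage.split(";"))
    return TaxonomyMap(lineages)


def read_newick(path_or_str, *, missing_lengths: str = "error") -> TreeNode:
    """Read a rooted newick tree with branch lengths.

    ``missing_lengths`` is ``"error"`` (required for patristic/PD use) or
    ``"zero"`` (set absent lengths to 0 and log how many were patched).
    """
    if missing_lengths not in ("error", "zero"):
        raise ValueError(f"missing_lengths must be 'error' or 'zero', got {missing_lengths!r}")
    src = path_or_str
    if isinstance(src, str) and src.lstrip().startswith("("):
        src = _io.StringIO(src)
    tree = TreeNode.read(src, format="newick")
    names = [t.name for t in tree.tips()]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate leaf label(s): {sorted(dupes)}")
    if any(n is None for n in names):
        raise ValueError("unlabeled leaf in tree")
    patched = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if missing_lengths == "error":
                raise ValueError(
                    "tree has missing branch lengths (pass missing_lengths='zero' to load anyway)"
                )
            node.length = 0.0
            patched += 1
        elif node.length < 0:
            raise ValueError(f"negative branch length {node.length} at node {node.name!r}")
    if patched:
        logger.warning("set %d missing branch lengths to 0", patched)
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


EDGE_HEADER = ["source", "target", "rho", "q_value", "sign"]
NODE_HEADER = ["otu_id", "sc_label", "degree"]


def _nodes_path(path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + ".nodes" + p.suffix)


def write_network(net, path, format: str = "edge-list") -> None:
    """Write a co-occurrence network as an edge-list TSV (+ sibling node TSV) or GraphML.

    The edge-list format writes two files: ``path`` with one row per edge
    (source, target, rho, q_value, sign) and ``<stem>.nodes<suffix>`` with one
    row per node (otu_id, sc_label, degree), so isolated nodes and
    subcommunity labels survive the round trip.
    """
    g = net.graph
    if format == "edge-list":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(EDGE_HEADER)
            for u, v, attrs in sorted(g.edges(data=True)):
                w.writerow([u, v, repr(attrs["rho"]), repr(attrs["q"]), attrs["sign"]])
        with open(_nodes_path(path), "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(NODE_HEADER)
            for n, attrs in sorted(g.nodes(data=True)):
                w.writerow([n, attrs.get("sc", ""), g.degree(n)])
    elif format == "graphml":
        out = g.copy()
        for n in out.nodes:
            out.nodes[n]["sc"] = out.nodes[n].get("sc") or ""  # GraphML cannot carry None
            out.nodes[n]["degree"] = g.degree(n)
        nx.write_graphml(out, str(path))
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "edge-list"):
    """Read a network written by :func:`write_network`."""
    from .network import CooccurrenceNetwork

    if format == "edge-list":
        g = nx.Graph()
        nrows = _read_tsv_grid(_nodes_path(path))
        if nrows[0] != NODE_HEADER:
            raise ValueError(f"unexpected node header {nrows[0]}")
        for otu, sc, _deg in nrows[1:]:
            g.add_node(otu, sc=sc or None)
        erows = _read_tsv_grid(path) if Path(path).stat().st_size else []
        if erows and erows[0] != EDGE_HEADER:
            raise ValueError(f"unexpected edge header {erows[0]}")
        for u, v, rho, q, sign in erows[1:]:
            g.add_edge(u, v, rho=float(rho), q=float(q), sign=sign)
        return CooccurrenceNetwork(graph=g)
    if format == "graphml":
        g = nx.read_graphml(str(path))
        for n in g.nodes:
            g.nodes[n].pop("degree", None)
            if g.nodes[n].get("sc") == "":
                g.nodes[n]["sc"] = None
        return CooccurrenceNetwork(graph=nx.Graph(g))
    raise ValueError(f"unknown network format {format!r}")
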