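"""Typed, partially oriented kinship graph assembly and export.

Nodes are accessions; edges carry one of three types:

* ``po_oriented`` — parent→offspring resolved through an accepted trio
  (the edge stores ``parent`` and ``child`` attributes),
* ``po_unoriented`` — a parent-offspring pair whose direction is unknown,
* ``full_sib`` — two offspring of the same parent pair.

A pair holds at most one edge; trio evidence upgrades an unoriented edge
to an oriented one.  Orientation is never inferred beyond trios — outside
evidence (e.g. historical precedence of a variety) can be asserted through
a manual-override list, recorded with its provenance note.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger("kinpipe")

from .ibd_relatedness import PairIBDProfile
from .trio_validation import TrioReport

EDGE_TYPES = ("po_oriented", "po_unoriented", "full_sib")


def build_graph(pair_calls: list[PairIBDProfile] | None,
                accepted_trios: list[TrioReport],
                full_sibs: list[tuple[str, str]] | None = None,
                ancestry: pd.DataFrame | None = None,
                orientation_overrides: list[tuple[str, str, str]] | None = None,
                ) -> nx.Graph:
    """Assemble the kinship graph.

    `orientation_overrides` is a list of (parent, child, note) assertions
    applied after trio orientation; they upgrade unoriented PO edges only.
    A trio whose PO pair was never called pairwise still contributes its two
    oriented edges (trio evidence dominates), with a warning-style note.
    """
    g = nx.Graph()
    for prof in pair_calls or []:
        if prof.call == "parent_offspring" and prof.a != prof.b:
            g.add_edge(prof.a, prof.b, type="po_unoriented")
    for r in accepted_trios:
        for parent in (r.p1, r.p2):
            if pair_calls is not None and not g.has_edge(parent, r.f):
                logger.warning("trio (%s × %s → %s) references PO pair (%s, %s) "
                               "absent from pairwise calls; edge added from trio "
                               "evidence", r.p1, r.p2, r.f, parent, r.f)
            g.add_edge(parent, r.f, type="po_oriented", parent=parent, child=r.f)
    for a, b in full_sibs if full_sibs is not None else infer_sibs_from_trios(accepted_trios):
        if a == b:
            continue
        if not g.has_edge(a, b):  # PO/trio evidence outranks a sib edge
            g.add_edge(a, b, type="full_sib")
    for parent, child, note in orientation_overrides or []:
        if g.has_edge(parent, child) and g.edges[parent, child]["type"] == "po_unoriented":
            g.add_edge(parent, child, type="po_oriented", parent=parent,
                       child=child, note=note)
    if ancestry is not None:
        for acc in g.nodes:
            if acc in ancestry.index:
                for comp in ancestry.columns:
                    g.nodes[acc][f"ancestry_{comp}"] = float(ancestry.loc[acc, comp])
    return g


def infer_sibs_from_trios(accepted_trios: list[TrioReport]) -> list[tuple[str, str]]:
    from .trio_validation import infer_full_sibs
    return infer_full_sibs(accepted_trios)


def descent_group(graph: nx.Graph, founders: set[str]) -> set[str]:
    """Accessions linked to any founder through a chain of PO edges.

    Traverses parent-offspring edges in either orientation; full-sib edges
    do not propagate descent.  The founders themselves are excluded.
    """
    unknown = founders - set(graph.nodes)
    if unknown:
        raise KeyError(f"unknown founders: {sorted(unknown)}")
    po = graph.edge_subgraph(
        [(a, b) for a, b, t in graph.edges(data="type") if t.startswith("po")]
    ) if graph.number_of_edges() else graph
    seen: set[str] = set()
    stack = [f for f in founders if f in po.nodes]
    visited = set(stack)
    while stack:
        node = stack.pop()
        for nb in po.neighbors(node):
            if nb not in visited:
                visited.add(nb)
                seen.add(nb)
                stack.append(nb)
    return seen - founders


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def export_graph(graph: nx.Graph, path: str | Path, fmt: str | None = None) -> None:
    """Write the graph as GraphML, DOT, or the canonical TSV edge list."""
    path = Path(path)
    fmt = fmt or {".graphml": "graphml", ".dot": "dot", ".gv": "dot",
                  ".tsv": "tsv"}.get(path.suffix, None)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "dot":
        _write_dot(graph, path)
    elif fmt == "tsv":
        edge_table(graph).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown graph format: {fmt!r}")


def import_graph(path: str | Path) -> nx.Graph:
    path = Path(path)
    if path.suffix == ".graphml":
        return nx.read_graphml(path)
    if path.suffix == ".tsv":
        g = nx.Graph()
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for rec in df.itertuples(index=False):
            attrs = {"type": rec.type}
            if rec.type == "po_oriented":
                attrs.update(parent=rec.parent, child=rec.child)
            g.add_edge(rec.a, rec.b, **attrs)
        return g
    raise ValueError(f"cannot import graph from {path.suffix!r}")


def edge_table(graph: nx.Graph) -> pd.DataFrame:
    """Canonical on-disk edge list (a, b, type, parent, child)."""
    rows = []
    for a, b, data in graph.edges(data=True):
        a, b = sorted((a, b))  # canonical endpoint order; orientation lives
        rows.append({"a": a, "b": b, "type": data["type"],  # in parent/child
                     "parent": data.get("parent", ""),
                     "child": data.get("child", "")})
    rows.sort(key=lambda r: (r["a"], r["b"]))
    return pd.DataFrame(rows, columns=["a", "b", "type", "parent", "child"])


_DOT_STYLE = {"po_oriented": 'color=red',
              "po_unoriented": 'color=pink, dir=none',
              "full_sib": 'color=blue, dir=none'}


def _write_dot(graph: nx.Graph, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("digraph kinship {\n")
        for node in sorted(graph.nodes):
            fh.write(f'  "{node}";\n')
        for a, b, data in sorted(graph.edges(data=True), key=lambda e: (e[0], e[1])):
            t = data["type"]
            if t == "po_oriented":
                a, b = data["parent"], data["child"]
            fh.write(f'  "{a}" -> "{b}" [{_DOT_STYLE[t]}, edgetype={t}];\n')
        fh.write("}\n")
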