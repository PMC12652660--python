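"""Directed gene regulatory network construction and topology metrics.

Nodes are gene symbols, directed edges mean "regulator activates/regulates
target", and self-loops encode autoregulation.  Edges carry a provenance tag:
``curated`` (literature), ``putative`` (suggested but unconfirmed), or
``binding-derived`` (from predicted binding sites).

Degree accounting around self-loops is convention-dependent, so it is an
explicit policy:

* ``out_only`` (default): a self-loop adds 1 to out-degree only — the
  convention under which the packaged floral network reproduces its reported
  hub degrees;
* ``both``: a self-loop adds 1 to both degrees;
* ``none``: self-loops are ignored for degrees.

Clustering coefficients are computed on the undirected simple projection
(directions and self-loops dropped).
"""

from __future__ import annotations

import importlib.resources
import io
import json

import networkx as nx
import pandas as pd

from .motif_io import TFGeneMap
from .scanner import HitTable

__all__ = [
    "RegulatoryNetwork",
    "read_edge_list",
    "write_edge_list",
    "load_floral_network",
    "degree_metrics",
    "clustering_coefficients",
    "derive_binding_edges",
    "SELFLOOP_POLICIES",
]

SELFLOOP_POLICIES = ("out_only", "both", "none")


class RegulatoryNetwork:
    """A directed gene graph with provenance-tagged, deduplicated edges."""

    def __init__(self) -> None:
        self.graph = nx.DiGraph()

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    def add_edge(self, regulator: str, target: str, provenance: str = "curated") -> None:
        self.graph.add_edge(regulator, target, provenance=provenance)

    def add_node(self, node: str) -> None:
        self.graph.add_node(node)

    def self_loops(self) -> list[str]:
        return [u for u, v in self.graph.edges if u == v]

    def to_json(self) -> str:
        payload = {
            "nodes": sorted(self.graph.nodes),
            "edges": [
                {"regulator": u, "target": v, "provenance": d.get("provenance", "curated")}
                for u, v, d in sorted(self.graph.edges(data=True))
            ],
        }
        return json.dumps(payload, indent=2)


def read_edge_list(stream) -> RegulatoryNetwork:
    """Parse a two-column TSV (regulator, target[, provenance]).

    Duplicate rows collapse to one edge; '#' lines are comments; malformed
    rows raise with their line number.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    net = RegulatoryNetwork()
    for ln, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            raise ValueError(f"edge list line {ln}: expected 'regulator<TAB>target[<TAB>provenance]'")
        prov = parts[2].strip() if len(parts) > 2 and parts[2].strip() else "curated"
        net.add_edge(parts[0].strip(), parts[1].strip(), prov)
    return net


def write_edge_list(net: RegulatoryNetwork) -> str:
    lines = [
        f"{u}\t{v}\t{d.get('provenance', 'curated')}"
        for u, v, d in sorted(net.graph.edges(data=True))
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def load_floral_network() -> RegulatoryNetwork:
    """The packaged Arabidopsis floral regulatory network fixture.

    A transcription of the reported activation relationships among the floral
    MADS-box and timing genes: PI and SEP3 autoregulate; PI and AP3 mutually
    activate each other; SEP3 and each of SEP1/SEP2/SEP4/AG activate each
    other; LFY activates AP1, AG and SOC1, and putatively AGL24, SVP and FUL.
    """
    data = importlib.resources.files("promotif.data").joinpath("floral_edges.tsv")
    return read_edge_list(data.read_text())


def degree_metrics(net: RegulatoryNetwork, selfloop_policy: str = "out_only") -> pd.DataFrame:
    """Per-node in/out degree, clustering coefficient and autoregulation flag."""
    if selfloop_policy not in SELFLOOP_POLICIES:
        raise ValueError(f"unknown selfloop_policy {selfloop_policy!r}; choose from {SELFLOOP_POLICIES}")
    loops = set(net.self_loops())
    clustering = clustering_coefficients(net)
    rows = []
    for node in sorted(net.graph.nodes):
        out_d = net.graph.out_degree(node)
        in_d = net.graph.in_degree(node)
        if node in loops:
            if selfloop_policy == "out_only":
                in_d -= 1
            elif selfloop_policy == "none":
                in_d -= 1
                out_d -= 1
        rows.append(
            {
                "node": node,
                "in_degree": in_d,
                "out_degree": out_d,
                "clustering": clustering[node],
                "autoregulatory": node in loops,
            }
        )
    return pd.DataFrame(rows).set_index("node")


def clustering_coefficients(net: RegulatoryNetwork) -> dict[str, float]:
    """Local clustering on the undirected simple projection.

    2 x (triangles through v) / (k (k-1)); nodes with fewer than two
    neighbours get 0.  Self-loops and edge directions are dropped first.
    """
    und = nx.Graph()
    und.add_nodes_from(net.graph.nodes)
    und.add_edges_from((u, v) for u, v in net.graph.edges if u != v)
    return nx.clustering(und)


def derive_binding_edges(
    hits: HitTable,
    tf_gene_map: TFGeneMap,
    gene_symbols: "dict[str, str] | None" = None,
) -> RegulatoryNetwork:
    """Turn predicted binding into directed edges TF's-own-gene -> target gene.

    Every (TF, target gene) pair with at least one lenient hit contributes one
    edge tagged ``binding-derived``; a hit of a TF in its own promoter becomes
    a self-loop.  TFs without a mapped own-gene contribute nothing.
    ``gene_symbols`` optionally maps gene ids to display symbols.
    """
    sym = gene_symbols or {}
    net = RegulatoryNetwork()
    seen = set()
    for h in hits:
        if h.tf_name not in tf_gene_map:
            continue
        regulator = tf_gene_map[h.tf_name]
        pair = (sym.get(regulator, regulator), sym.get(h.gene_id, h.gene_id))
        if pair not in seen:
            seen.add(pair)
            net.add_edge(*pair, provenance="binding-derived")
    return net
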