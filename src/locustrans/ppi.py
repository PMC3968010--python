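"""Protein-protein interaction network merging and subnetwork extraction.

Two (or more) physical-interaction edge lists are merged into one undirected,
deduplicated network: edges are keyed by their sorted endpoint pair, edges
present in several sources collapse to one edge carrying multi-source
provenance, and self-loops are dropped with a warning count. Subnetworks are
anchored on seed genes either as the seed-induced subgraph or as seeds plus
their direct neighbors (with the induced closure among included nodes), and
can be annotated with chromosome position, ortholog counterpart/E-value and
phenotype availability for overlay on a comparative map.

Node identity is the locus ID, case-normalized to uppercase; interaction
modes (activation/inhibition) are not modeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .catalog import StressGene
from .orthologs import OrthologCall
from .synteny import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "SubNetwork",
    "read_edge_list",
    "merge_ppi",
    "extract_subnetwork",
    "annotate_subnetwork",
    "format_evalue",
    "write_sif",
]


def _norm(node: str) -> str:
    return str(node).strip().upper()


def read_edge_list(path: str | Path, source: str | None = None) -> pd.DataFrame:
    """Read a PPI edge list TSV with columns node_a, node_b[, source]."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "source" not in frame.columns:
        frame["source"] = source if source is not None else Path(path).stem
    missing = {"node_a", "node_b"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame[["node_a", "node_b", "source"]]


def merge_ppi(edge_sets: Sequence[pd.DataFrame]) -> nx.Graph:
    """Merge edge lists into one undirected deduplicated network.

    Each input frame needs columns node_a/node_b/source. (a,b) and (b,a) are
    the same edge; duplicates across sources collapse to one edge whose
    ``sources`` attribute records every contributing dataset. Self-loops are
    dropped and counted in ``G.graph["n_self_loops_dropped"]``.
    """
    graph = nx.Graph()
    dropped = 0
    for frame in edge_sets:
        for row in frame.itertuples(index=False):
            a, b = _norm(row.node_a), _norm(row.node_b)
            if a == b:
                dropped += 1
                continue
            if graph.has_edge(a, b):
                graph.edges[a, b]["sources"].add(row.source)
            else:
                graph.add_edge(a, b, sources={row.source})
    if dropped:
        logger.warning("dropped %d self-loop rows while merging", dropped)
    graph.graph["n_self_loops_dropped"] = dropped
    graph.graph["n_nodes"] = graph.number_of_nodes()
    graph.graph["n_edges"] = graph.number_of_edges()
    return graph


@dataclass
class SubNetwork:
    """A seed-anchored subgraph with per-node flags."""

    graph: nx.Graph
    seeds: frozenset[str]
    rule: str
    components: list[frozenset[str]] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def extract_subnetwork(
    network: nx.Graph, seeds: Iterable[str], rule: str = "induced"
) -> SubNetwork:
    """Extract the subgraph anchored on *seeds*.

    rule="induced": edges with both endpoints in the seed set.
    rule="seed-plus-neighbors": seeds, their direct neighbors, and all edges
    of the network among those nodes (induced closure).

    Seeds absent from the network yield an empty subnetwork with a warning,
    not an error.
    """
    seed_set = {_norm(s) for s in seeds}
    if not seed_set:
        raise ValueError("seed set must be non-empty")
    present = seed_set & set(network.nodes)
    if not present:
        logger.warning("no seed gene present in the network; empty subnetwork")
    if rule == "induced":
        nodes = present
    elif rule == "seed-plus-neighbors":
        nodes = set(present)
        for s in present:
            nodes.update(network.neighbors(s))
    else:
        raise ValueError(f"unknown extraction rule {rule!r}")
    sub = network.subgraph(nodes).copy()
    for node in sub.nodes:
        sub.nodes[node]["is_seed"] = node in seed_set
    components = [frozenset(c) for c in nx.connected_components(sub)]
    return SubNetwork(graph=sub, seeds=frozenset(seed_set), rule=rule,
                      components=components)


def format_evalue(evalue: float | None) -> str:
    """Render an E-value the way interaction tables print it (9.00E-108; 0 for zero)."""
    if evalue is None:
        return "NA"
    if evalue == 0:
        return "0"
    return f"{evalue:.2E}"


def annotate_subnetwork(
    sub: SubNetwork,
    catalog: Sequence[StressGene] = (),
    models: Iterable[GeneModel] = (),
    phenotypes: pd.DataFrame | None = None,
    calls: Sequence[OrthologCall] = (),
) -> pd.DataFrame:
    """Annotate subnetwork nodes into a locus-link table.

    Each node gains, where resolvable: chromosome and start position, GO
    class from the catalog, its ortholog counterpart and formatted E-value,
    and a phenotype-availability flag from the *phenotypes* table (columns
    ``locus_id`` plus free annotation columns, e.g. symbol / phenotype).
    Unresolvable nodes are flagged ``placed=False`` rather than dropped.
    """
    by_locus = {_norm(m.locus_id): m for m in models}
    by_go = {_norm(g.locus_id): g.go_class for g in catalog}
    by_call = {_norm(c.query_locus): c for c in calls if c.subject_locus is not None}
    pheno: dict[str, dict] = {}
    if phenotypes is not None:
        if "locus_id" not in phenotypes.columns:
            raise ValueError("phenotypes table needs a locus_id column")
        for row in phenotypes.to_dict("records"):
            pheno[_norm(row["locus_id"])] = row
    rows = []
    for node in sorted(sub.graph.nodes):
        model = by_locus.get(node)
        call = by_call.get(node)
        prow = pheno.get(node, {})
        rows.append(
            {
                "locus_id": node,
                "is_seed": sub.graph.nodes[node].get("is_seed", False),
                "placed": model is not None,
                "chromosome": model.chromosome if model else None,
                "start": model.start + 1 if model else None,
                "go_class": by_go.get(node),
                "ortholog_locus": call.subject_locus if call else None,
                "evalue": format_evalue(call.evalue) if call else "NA",
                "remark": call.remark.name if call else None,
                "symbol": prow.get("symbol"),
                "annotation": prow.get("annotation"),
                "phenotype_available": bool(prow.get("phenotype")),
                "degree": sub.graph.degree(node),
            }
        )
    return pd.DataFrame(rows)


def write_sif(graph: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    """Write the network in SIF format (nodeA relation nodeB)."""
    with Path(path).open("w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")
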