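"""Thresholded bipartite enhancer-gene networks, Louvain community
detection, and redundant / non-redundant substructure classification.

A network edge is a predicted regulatory interaction whose model score is
strictly above the build threshold. Promoter-class elements keep only the
edge to their own gene (self-promoter rule). Communities found by seeded
multi-level modularity optimization are classified NR (non-redundant) when
they contain exactly one CRE, R otherwise; %NR summarizes how much of the
regulatory architecture lacks enhancer redundancy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import pandas as pd

from .intervals import CREClass

__all__ = [
    "EGNetwork",
    "Substructure",
    "NetworkSummary",
    "SCORE_THRESHOLD_STANDARD",
    "SCORE_THRESHOLD_MEGAMAP",
    "build_network",
    "detect_communities",
    "classify_substructures",
    "summarize",
]

logger = logging.getLogger(__name__)

# 70%-recall operating points for the two contact-map variants
SCORE_THRESHOLD_STANDARD = 0.283
SCORE_THRESHOLD_MEGAMAP = 0.234


@dataclass
class EGNetwork:
    """Bipartite edge list (cre_id, gene_id, score) plus node metadata."""

    edges: pd.DataFrame                      # columns: cre_id, gene_id, score
    cre_classes: dict[str, CREClass] = field(default_factory=dict)
    threshold: float = SCORE_THRESHOLD_STANDARD

    @property
    def cres(self) -> list[str]:
        return sorted(self.edges["cre_id"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.edges["gene_id"].unique())

    def to_graph(self, weighted: bool = False) -> nx.Graph:
        g = nx.Graph()
        for cre in self.edges["cre_id"].unique():
            g.add_node(("cre", cre), bipartite=0)
        for gene in self.edges["gene_id"].unique():
            g.add_node(("gene", gene), bipartite=1)
        for row in self.edges.itertuples(index=False):
            kw = {"weight": row.score} if weighted else {}
            g.add_edge(("cre", row.cre_id), ("gene", row.gene_id), **kw)
        return g


@dataclass
class Substructure:
    community_id: int
    cres: list[str]
    genes: list[str]
    type: str        # "R" | "NR" | "NA" (no CRE in the community)
    n_edges: int

    @property
    def n_cres(self) -> int:
        return len(self.cres)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class NetworkSummary:
    n_unique_cres: int
    n_unique_genes: int
    n_pairs: int
    n_communities: int
    n_nr: int
    pct_nr: float
    modularity: float | None = None


def build_network(
    scored_pairs: pd.DataFrame,
    threshold: float = SCORE_THRESHOLD_STANDARD,
    cre_classes: Mapping[str, CREClass] | None = None,
    promoter_owner: Mapping[str, str] | None = None,
) -> EGNetwork:
    """Keep edges with score strictly above ``threshold``; promoter-class
    CREs retain only the edge to their own gene (``promoter_owner`` maps
    promoter cre_id -> gene_id). Duplicate edges collapse to the first."""
    df = scored_pairs[["cre_id", "gene_id", "score"]].copy()
    df = df[df["score"] > threshold]
    cre_classes = dict(cre_classes or {})
    promoter_owner = dict(promoter_owner or {})
    if cre_classes:
        is_promoter = df["cre_id"].map(
            lambda c: cre_classes.get(c) == CREClass.PROMOTER
        )
        own = df["cre_id"].map(promoter_owner)
        df = df[~is_promoter | (df["gene_id"] == own)]
    df = df.drop_duplicates(["cre_id", "gene_id"]).sort_values(
        ["cre_id", "gene_id"], ignore_index=True
    )
    return EGNetwork(edges=df, cre_classes=cre_classes, threshold=threshold)


def detect_communities(
    network: EGNetwork,
    seed: int = 0,
    resolution: float = 1.0,
    weighted: bool = False,
) -> tuple[dict, float]:
    """Seeded Louvain (multi-level modularity optimization) on the bipartite
    graph treated as a simple undirected graph.

    Returns (node -> community id, achieved modularity). Deterministic for
    a fixed seed. By default edges are unweighted (presence only); pass
    ``weighted=True`` to let scores weight modularity.
    """
    if len(network.edges) == 0:
        raise ValueError("cannot detect communities in an empty network")
    g = network.to_graph(weighted=weighted)
    weight = "weight" if weighted else None
    comms = nx.community.louvain_communities(
        g, weight=weight, resolution=resolution, seed=seed
    )
    q = nx.community.modularity(g, comms, weight=weight, resolution=resolution)
    partition = {node: i for i, comm in enumerate(comms) for node in comm}
    return partition, float(q)


def classify_substructures(network: EGNetwork, partition: Mapping) -> list[Substructure]:
    """Classify each community: NR iff it contains exactly one CRE.

    Communities with zero CREs (isolated genes) are labeled "NA" and are
    excluded from the %NR denominator.
    """
    nodes = set()
    for row in network.edges.itertuples(index=False):
        nodes.add(("cre", row.cre_id))
        nodes.add(("gene", row.gene_id))
    missing = nodes - set(partition)
    if missing:
        raise ValueError(f"partition does not cover {len(missing)} node(s)")

    members: dict[int, dict[str, list[str]]] = {}
    for node in nodes:
        cid = partition[node]
        d = members.setdefault(cid, {"cre": [], "gene": []})
        d[node[0]].append(node[1])

    edge_comm = pd.Series(
        [partition[("cre", c)] for c in network.edges["cre_id"]]
    )
    same = edge_comm == pd.Series(
        [partition[("gene", g)] for g in network.edges["gene_id"]]
    )
    edge_counts = edge_comm[same].value_counts().to_dict()

    out = []
    for cid in sorted(members):
        cres = sorted(members[cid]["cre"])
        genes = sorted(members[cid]["gene"])
        if not cres:
            kind = "NA"
            logger.info("community %d has no CRE; excluded from %%NR", cid)
        elif len(cres) == 1:
            kind = "NR"
        else:
            kind = "R"
        out.append(
            Substructure(
                community_id=cid,
                cres=cres,
                genes=genes,
                type=kind,
                n_edges=int(edge_counts.get(cid, 0)),
            )
        )
    return out


def summarize(
    network: EGNetwork,
    substructures: list[Substructure] | None = None,
    modularity: float | None = None,
) -> NetworkSummary:
    """Unique-node and edge counts plus the NR-module percentage."""
    n_nr = n_comm = 0
    if substructures:
        scored = [s for s in substructures if s.type != "NA"]
        n_comm = len(scored)
        n_nr = sum(1 for s in scored if s.type == "NR")
    return NetworkSummary(
        n_unique_cres=len(network.cres),
        n_unique_genes=len(network.genes),
        n_pairs=len(network.edges),
        n_communities=n_comm,
        n_nr=n_nr,
        pct_nr=100.0 * n_nr / n_comm if n_comm else 0.0,
        modularity=modularity,
    )
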