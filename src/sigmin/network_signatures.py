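"""Network-topology gene scoring and conversion to probeset signatures.

Genes are ranked by their position in a directed interaction network
(STRING-actions-style edge list with a per-edge mode label) rather than
by the expression data itself: central genes, or genes downstream of many
transcriptional regulators, are candidates for maximally informative
signature membership.

Centralities are computed on the directed, unweighted graph (in/out-degree
criteria only make sense directed); an ``undirected=True`` escape hatch is
provided.  Betweenness is unnormalised with fractional counting of tied
shortest paths — only the ranking is consumed, and the normalising
constant cannot change it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .signatures import GeneSignature

__all__ = [
    "InteractionNetwork",
    "ProbesetGeneMap",
    "NETWORK_CRITERIA",
    "centrality_scores",
    "regulator_distance_scores",
    "nodes_to_signature",
]

NETWORK_CRITERIA: tuple[str, ...] = (
    "betweenness", "closeness", "degree", "in_degree", "out_degree", "regulator_distance",
)


@dataclass(frozen=True)
class InteractionNetwork:
    """Directed graph with labelled edge modes (e.g. 'expression', 'binding')."""

    nodes: frozenset[str]
    edges: tuple[tuple[str, str, str], ...]  # (source, target, mode)

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, str]], extra_nodes: Iterable[str] = ()
    ) -> "InteractionNetwork":
        dedup = tuple(dict.fromkeys(tuple(e) for e in edges))
        nodes = {n for s, t, _ in dedup for n in (s, t)} | set(extra_nodes)
        return cls(nodes=frozenset(nodes), edges=dedup)

    @classmethod
    def read_edges(cls, path: str | Path) -> "InteractionNetwork":
        """Edge-list TSV with columns source, target, mode."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in ("source", "target", "mode") if c not in df.columns]
        if missing:
            raise ValueError(f"edge file {path} lacks column(s): {missing}")
        return cls.from_edges(
            (row.source, row.target, row.mode) for row in df.itertuples(index=False)
        )

    def write_edges(self, path: str | Path) -> None:
        pd.DataFrame(self.edges, columns=["source", "target", "mode"]).to_csv(
            path, sep="\t", index=False
        )

    def to_digraph(self, undirected: bool = False) -> nx.DiGraph | nx.Graph:
        """Simple (mode-collapsed) graph for path computations."""
        g: nx.Graph = nx.Graph() if undirected else nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from((s, t) for s, t, _ in self.edges)
        return g

    def regulators(self) -> frozenset[str]:
        """Nodes with at least one outgoing edge of mode 'expression'."""
        return frozenset(s for s, _, mode in self.edges if mode == "expression")


@dataclass(frozen=True)
class ProbesetGeneMap:
    """Many-to-many probeset <-> gene bridge between the chip and the network."""

    pairs: tuple[tuple[str, str], ...]  # (probeset_id, gene_id)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "ProbesetGeneMap":
        return cls(pairs=tuple(dict.fromkeys(tuple(p) for p in pairs)))

    @classmethod
    def read(cls, path: str | Path) -> "ProbesetGeneMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in ("probeset_id", "gene_id") if c not in df.columns]
        if missing:
            raise ValueError(f"mapping file {path} lacks column(s): {missing}")
        return cls.from_pairs((row.probeset_id, row.gene_id) for row in df.itertuples(index=False))

    def write(self, path: str | Path) -> None:
        pd.DataFrame(self.pairs, columns=["probeset_id", "gene_id"]).to_csv(
            path, sep="\t", index=False
        )

    def probesets_for_gene(self, gene_id: str) -> list[str]:
        return sorted(p for p, g in self.pairs if g == gene_id)

    def genes_for_probesets(self, probeset_ids: Iterable[str]) -> frozenset[str]:
        wanted = set(probeset_ids)
        return frozenset(g for p, g in self.pairs if p in wanted)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for _, g in self.pairs)

    @property
    def probesets(self) -> frozenset[str]:
        return frozenset(p for p, _ in self.pairs)


def centrality_scores(
    net: InteractionNetwork, kind: str, undirected: bool = False
) -> dict[str, float]:
    """Per-node centrality of the requested kind.

    betweenness: unnormalised count of shortest (s, t) paths through the
    node, fractional over ties.  closeness: (number of nodes reachable
    *from* the node) / (sum of shortest-path distances to them), zero for
    sinks.  Degree kinds are raw counts of (source, target, mode) edge
    records, mode-agnostic.
    """
    if not net.nodes:
        raise ValueError("network is empty")
    if kind == "betweenness":
        g = net.to_digraph(undirected=undirected)
        return dict(nx.betweenness_centrality(g, normalized=False))
    if kind == "closeness":
        g = net.to_digraph(undirected=undirected)
        # outgoing closeness: nx measures incoming distances, so reverse first
        h = g.reverse() if g.is_directed() else g
        return dict(nx.closeness_centrality(h, wf_improved=False))
    if kind in ("degree", "in_degree", "out_degree"):
        scores = {n: 0.0 for n in net.nodes}
        for s, t, _ in net.edges:
            if kind in ("degree", "out_degree"):
                scores[s] += 1.0
            if kind in ("degree", "in_degree"):
                scores[t] += 1.0
        return scores
    raise ValueError(f"unknown centrality kind {kind!r}")


def regulator_distance_scores(net: InteractionNetwork) -> dict[str, float]:
    """Mean shortest-path distance from the expression-mode regulators.

    Regulatory nodes are those with >= 1 outgoing edge of mode
    'expression'.  Every non-regulator node reachable from at least one
    regulator is scored with the average shortest directed path length
    over exactly the regulators that reach it; ranking for signature use
    is descending, favouring genes far downstream of the regulatory layer.
    Regulators themselves and unreachable nodes carry no score.
    """
    regs = net.regulators()
    if not regs:
        raise ValueError("network contains no node with an outgoing 'expression' edge")
    g = net.to_digraph()
    totals: dict[str, float] = {}
    counts: dict[str, int] = {}
    for r in sorted(regs):
        for v, d in nx.single_source_shortest_path_length(g, r).items():
            if v in regs:
                continue
            totals[v] = totals.get(v, 0.0) + d
            counts[v] = counts.get(v, 0) + 1
    return {v: totals[v] / counts[v] for v in totals}


def nodes_to_signature(
    scores: Mapping[str, float], pmap: ProbesetGeneMap, k: int
) -> GeneSignature:
    """Convert a gene ranking into a k-probeset signature.

    Genes are traversed in descending score (ties by gene id); each gene
    contributes all of its probesets (sorted by id) until k probesets are
    collected.  A probeset shared by several genes is kept once, at its
    first occurrence.
    """
    by_gene: dict[str, list[str]] = {}
    for p, g in pmap.pairs:
        by_gene.setdefault(g, []).append(p)
    picked: list[str] = []
    seen: set[str] = set()
    for gene in sorted(scores, key=lambda g: (-scores[g], g)):
        for p in sorted(by_gene.get(gene, [])):
            if p not in seen:
                seen.add(p)
                picked.append(p)
                if len(picked) == k:
                    return GeneSignature(tuple(picked), origin="network")
    raise ValueError(
        f"only {len(picked)} probesets map to scored genes; cannot build a size-{k} signature"
    )
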