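"""Hypergeometric over-representation of signature genes in pathway sets.

For a query of n genes drawn from a universe of N, a pathway of K genes,
and an observed overlap of x, the p-value is the probability of an
intersection of at least x under the hypergeometric null — identical to a
one-sided Fisher's exact test.  The universe is the intersection of the
collection's universe and the genes represented on the chip, a choice
that must be held fixed when comparing enrichments across signatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .network_signatures import ProbesetGeneMap
from .signatures import GeneSignature

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "hypergeom_pvalue", "enrich", "read_gmt", "write_gmt"]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets plus the universe they are defined over."""

    sets: Mapping[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        restricted = {}
        dropped = 0
        for name, genes in self.sets.items():
            kept = frozenset(genes) & self.universe
            if kept:
                restricted[name] = kept
            else:
                dropped += 1
        if dropped:
            logger.info("GeneSetCollection: dropped %d set(s) empty after universe restriction", dropped)
        object.__setattr__(self, "sets", restricted)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """GMT: one set per line — name, description, then member genes (tab-separated)."""
    sets: dict[str, frozenset[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line[:60]!r}")
        name, _desc, *genes = fields
        if name in sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        sets[name] = frozenset(g for g in genes if g)
    uni = frozenset(universe) if universe is not None else frozenset().union(*sets.values())
    return GeneSetCollection(sets=sets, universe=uni)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *sorted(genes)])
        for name, genes in sorted(coll.sets.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeom_pvalue(universe_n: int, pathway_k: int, query_n: int, overlap_x: int) -> float:
    """P[X >= overlap_x] for X ~ Hypergeometric(universe_n, pathway_k, query_n)."""
    if not (0 <= pathway_k <= universe_n and 0 <= query_n <= universe_n):
        raise ValueError("pathway and query sizes must lie within the universe")
    if not 0 <= overlap_x <= min(pathway_k, query_n):
        raise ValueError(
            f"overlap {overlap_x} outside [0, min({pathway_k}, {query_n})]"
        )
    if overlap_x == 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap_x - 1, universe_n, pathway_k, query_n))


def enrich(
    sig: GeneSignature, pmap: ProbesetGeneMap, coll: GeneSetCollection
) -> pd.DataFrame:
    """Ranked enrichment table for a signature's genes.

    Probesets are translated to genes (deduplicated); the effective
    universe is ``coll.universe`` intersected with all genes mapped on the
    chip.  Rows are sorted by ascending p, ties by set name; raw p,
    -log10 p and Benjamini-Hochberg adjusted p are reported (the raw
    ordering is the comparison surface, adjustment is a convenience).
    """
    universe = coll.universe & pmap.genes
    query = pmap.genes_for_probesets(sig.probeset_ids) & universe
    if not query:
        raise ValueError("signature maps to no gene in the enrichment universe")
    rows = []
    for name in sorted(coll.sets):
        pathway = coll.sets[name] & universe
        if not pathway:
            continue
        overlap = len(query & pathway)
        p = hypergeom_pvalue(len(universe), len(pathway), len(query), overlap)
        rows.append(
            {
                "set_name": name,
                "set_size": len(pathway),
                "overlap": overlap,
                "p_value": p,
                "neg_log10_p": -np.log10(p) if p > 0 else np.inf,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["p_value", "set_name"], kind="mergesort"
    ).reset_index(drop=True)
    table["p_adjusted"] = stats.false_discovery_control(
        table["p_value"].to_numpy(), method="bh"
    )
    return table
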