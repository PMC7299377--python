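"""Pathway over-representation analysis of selected biomarkers.

Selected features are first collapsed to gene symbols (genes map to
themselves, proteins/peptides to their encoding gene, SNPs to their
downstream gene neighbours in the prior network).  The gene set is then
tested for over-representation in each pathway of a user-supplied GMT
collection with the hypergeometric upper tail ``P[X >= k]`` and Bonferroni
correction across the tested pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .network import TransOmicNetwork

__all__ = [
    "GeneSetCollection",
    "hypergeometric_pvalue",
    "hypergeometric_enrichment",
    "map_markers_to_genes",
]

logger = logging.getLogger(__name__)


def _norm(symbol: str) -> str:
    return str(symbol).strip().upper()


@dataclass
class GeneSetCollection:
    """Named pathway gene sets plus the background universe for testing."""

    sets: dict[str, set[str]]
    background: set[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.background = {_norm(g) for g in self.background}
        self.sets = {name: {_norm(g) for g in members}
                     for name, members in self.sets.items()}

    @classmethod
    def from_gmt(cls, sets: Mapping[str, Iterable[str]],
                 background: Iterable[str] | None = None,
                 descriptions: Mapping[str, str] | None = None
                 ) -> "GeneSetCollection":
        sets = {name: set(members) for name, members in sets.items()}
        if background is None:
            background = set().union(*sets.values()) if sets else set()
        return cls(sets=sets, background=set(background),
                   descriptions=dict(descriptions or {}))


def hypergeometric_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Over-representation tail ``P[X >= k]``, X ~ Hypergeometric(N, K, n).

    N: background size, K: pathway size, n: query size, k: overlap.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"invalid hypergeometric configuration k={k}, N={N}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeometric_enrichment(query: Iterable[str],
                              collection: GeneSetCollection,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Test each pathway for over-representation of the query gene set.

    Pathways are restricted to the background universe; empty restrictions
    are untestable and skipped.  Query genes outside the background are
    dropped (count logged).  Returns rows sorted by Bonferroni-corrected
    p-value with a ``significant`` flag at level ``alpha``.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if not collection.background:
        raise ValueError("empty background universe")
    query_all = {_norm(g) for g in query}
    query_bg = query_all & collection.background
    dropped = len(query_all) - len(query_bg)
    if dropped:
        logger.info("dropped %d query genes absent from background", dropped)
    if not query_bg:
        raise ValueError("query is empty after restriction to the background")
    N = len(collection.background)
    n = len(query_bg)
    rows = []
    testable = {name: members & collection.background
                for name, members in collection.sets.items()}
    testable = {name: mem for name, mem in testable.items() if mem}
    T = len(testable)
    for name, members in testable.items():
        K = len(members)
        k = len(members & query_bg)
        p = hypergeometric_pvalue(k, N, K, n)
        rows.append({
            "pathway": name, "overlap": k, "pathway_size": K,
            "query_size": n, "background_size": N,
            "p_value": p, "p_bonferroni": min(1.0, p * T),
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["significant"] = df["p_bonferroni"] <= alpha
    return df.sort_values(
        ["p_bonferroni", "p_value", "pathway"]).reset_index(drop=True)


def map_markers_to_genes(selected: Iterable[str],
                         layers: Mapping[str, str],
                         net: TransOmicNetwork | None = None,
                         peptide_to_gene: Mapping[str, str] | None = None
                         ) -> tuple[set[str], dict[str, set[str]], list[str]]:
    """Collapse selected multi-omic markers to a deduplicated gene set.

    Gene features map to themselves; protein features through
    ``peptide_to_gene`` (falling back to their gene neighbours in the prior
    network); SNP features to their gene neighbours in the prior network.
    Returns ``(genes, provenance by layer, unmapped features)``.
    """
    genes: set[str] = set()
    provenance: dict[str, set[str]] = {"SNP": set(), "gene": set(), "protein": set()}
    unmapped: list[str] = []
    for feat in selected:
        layer = layers.get(feat)
        if layer == "gene":
            g = _norm(feat)
            genes.add(g)
            provenance["gene"].add(g)
        elif layer == "protein":
            mapped = None
            if peptide_to_gene and feat in peptide_to_gene:
                mapped = {_norm(peptide_to_gene[feat])}
            elif net is not None and feat in net:
                mapped = {_norm(g) for g in net.graph.neighbors(feat)
                          if net.layers.get(g) == "gene"}
            if mapped:
                genes.update(mapped)
                provenance["protein"].update(mapped)
            else:
                unmapped.append(feat)
        elif layer == "SNP":
            if net is not None and feat in net:
                nbrs = {_norm(g) for g in net.graph.neighbors(feat)
                        if net.layers.get(g) == "gene"}
            else:
                nbrs = set()
            if nbrs:
                genes.update(nbrs)
                provenance["SNP"].update(nbrs)
            else:
                unmapped.append(feat)
        else:
            unmapped.append(feat)
    if unmapped:
        logger.info("could not map %d features to genes: %s",
                    len(unmapped), unmapped[:10])
    return genes, provenance, unmapped
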