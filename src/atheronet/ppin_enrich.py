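"""Protein-protein interaction subnetworks and local term enrichment.

A scored PPI edge list (STRING-export-style TSV: proteinA, proteinB,
combined_score) is thresholded at medium confidence (score strictly above
0.4 on the unit scale; 0-1000 integer scores are auto-normalized), the
query-gene-induced subgraph is extracted with isolated queried genes
removed, and node degrees are ranked.

Term enrichment is a local one-sided Fisher exact test: for a query of n
genes out of a universe of N, a term covering K universe genes, and k
genes in common, the p-value is the hypergeometric upper tail P[X >= k].
P-values are Benjamini-Hochberg adjusted within each library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd
from scipy import stats

from .data import DataValidationError
from .diffexpr import bh_adjust
from .genesets import GeneSetLibrary


def load_ppi_edges(path: str | Path, score_cut: float = 0.4) -> nx.Graph:
    """Load a scored PPI edge list, keeping edges with combined score
    strictly above ``score_cut``; self-loops and duplicate (A-B / B-A)
    rows are dropped and scores are normalized to (0, 1]."""
    df = pd.read_csv(path, sep="\t")
    needed = ["proteinA", "proteinB", "combined_score"]
    if not set(needed).issubset(df.columns):
        raise DataValidationError(
            f"PPI table must have columns {needed}, got {list(df.columns)}"
        )
    scores = pd.to_numeric(df["combined_score"], errors="coerce")
    bad = scores.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise DataValidationError(f"malformed combined_score at line {line}")
    if scores.max() > 1.0:  # STRING-style 0-1000 integer scale
        scores = scores / 1000.0
    g = nx.Graph()
    for (a, b), score in zip(
        zip(df["proteinA"].astype(str), df["proteinB"].astype(str)), scores
    ):
        a, b = a.strip().upper(), b.strip().upper()
        if a == b or score <= score_cut:
            continue
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], float(score))
        else:
            g.add_edge(a, b, score=float(score))
    return g


def induced_subgraph(net: nx.Graph, genes: set[str]) -> nx.Graph:
    """Subgraph induced by ``genes``; queried genes with no interaction
    among the query are excluded (the network keeps only connected
    participants)."""
    genes = {g.strip().upper() for g in genes}
    sub = net.subgraph(genes & set(net.nodes)).copy()
    isolated = [n for n in sub.nodes if sub.degree(n) == 0]
    sub.remove_nodes_from(isolated)
    if sub.number_of_nodes() == 0:
        warnings.warn("induced PPI subnetwork is empty")
    return sub


def node_degrees(net: nx.Graph) -> pd.DataFrame:
    """Degree table ranked by descending degree, ties lexicographic."""
    rows = sorted(net.degree, key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(rows, columns=["gene", "degree"])
    df["rank"] = range(1, len(df) + 1)
    return df


@dataclass
class EnrichmentRow:
    term: str
    library: str
    k: int  # overlap
    K: int  # term size within the universe
    n: int  # query size
    N: int  # universe size
    p: float
    p_bh: float = float("nan")
    overlap_genes: tuple[str, ...] = ()


def fisher_enrichment(
    query: set[str],
    lib: GeneSetLibrary,
    universe: set[str] | None = None,
    library_name: str = "library",
) -> list[EnrichmentRow]:
    """One-sided Fisher exact (hypergeometric upper tail) enrichment of a
    query set against every term in a library, BH-adjusted within the
    library and sorted by ascending p (ties by term name).

    The universe defaults to the union of the library's sets; the query
    and every term are intersected with it.
    """
    uni = set(universe) if universe is not None else lib.universe()
    uni = {g.strip().upper() for g in uni}
    if not uni:
        raise DataValidationError("enrichment universe is empty")
    q = {g.strip().upper() for g in query} & uni
    if {g.strip().upper() for g in query} - uni:
        warnings.warn("query genes outside the universe were ignored")
    N, n = len(uni), len(q)
    rows: list[EnrichmentRow] = []
    for term in sorted(lib.sets):
        members = lib.sets[term] & uni
        K = len(members)
        overlap = sorted(q & members)
        k = len(overlap)
        # P[X >= k] for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K and n else 1.0
        rows.append(
            EnrichmentRow(
                term=term, library=library_name, k=k, K=K, n=n, N=N,
                p=min(p, 1.0), overlap_genes=tuple(overlap),
            )
        )
    adj = bh_adjust([r.p for r in rows]) if rows else []
    for r, a in zip(rows, adj):
        r.p_bh = float(a)
    rows.sort(key=lambda r: (r.p, r.term))
    return rows


def top_k_terms(
    rows: list[EnrichmentRow], k: int = 10, p_cut: float = 0.05,
    use_adjusted: bool = False,
) -> list[EnrichmentRow]:
    """At most ``k`` terms with p (raw by default) below ``p_cut``,
    ascending p with ties by term name."""
    key = (lambda r: (r.p_bh, r.term)) if use_adjusted else (lambda r: (r.p, r.term))
    val = (lambda r: r.p_bh) if use_adjusted else (lambda r: r.p)
    passing = sorted((r for r in rows if val(r) < p_cut), key=key)
    if not passing:
        warnings.warn("no term passed the enrichment p-value cut")
    return passing[:k]


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [r.term for r in rows],
            "library": [r.library for r in rows],
            "overlap": [r.k for r in rows],
            "term_size": [r.K for r in rows],
            "query_size": [r.n for r in rows],
            "universe_size": [r.N for r in rows],
            "p": [r.p for r in rows],
            "p_bh": [r.p_bh for r in rows],
            "overlap_genes": [";".join(r.overlap_genes) for r in rows],
        }
    )
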