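"""3-node miRNA/TF feed-forward-loop construction and motif extraction.

A feed-forward loop (FFL) here is a closed triangle over one transcription
factor t, one miRNA m, and one target mRNA g: edges m->g (repression),
t->g (regulation), and a regulatory m<->t edge in either direction.  The
loop type records the master regulator: a *miRNA-FFL* when the miRNA
represses the TF, a *TF-FFL* when the TF drives the miRNA, and *composite*
when both directions are reported.

All enumerated triangles are unified into one undirected, unweighted
typed graph (regulatory directions survive only as annotations).  Nodes
are ranked within their class by degree, betweenness (Brandes, raw
unordered-pair counts) and closeness (harmonically component-scaled), and
the "highest-order subnetwork motif" is the enumerated FFL whose members
jointly top the rank aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .data import DataValidationError
from .synth import MIRNA_REPRESSES_TF, TF_REGULATES_MIRNA, InteractionTables

TF = "TF"
MIRNA = "miRNA"
MRNA = "mRNA"

LOOP_MIRNA = "miRNA-FFL"
LOOP_TF = "TF-FFL"
LOOP_COMPOSITE = "composite"


@dataclass(frozen=True, order=True)
class FFLTriple:
    tf: str
    mirna: str
    mrna: str
    loop_type: str = LOOP_MIRNA


# ---------------------------------------------------------------------------
# pair compilation and triangle enumeration
# ---------------------------------------------------------------------------

def compile_pairs(
    tables: InteractionTables,
    mrnas: set[str],
    validated_regulators: set[str] | None = None,
) -> InteractionTables:
    """Restrict the interaction tables to the given mRNA set (the
    PPI-participating CASS-DEGs): targets outside ``mrnas`` are dropped,
    regulators left without any mRNA edge are dropped, and the miRNA-TF
    table keeps only surviving regulators.  An optional allow-list of
    literature-validated regulators is applied first."""
    if not mrnas:
        raise DataValidationError("mrnas must be nonempty")
    mrnas = {g.strip().upper() for g in mrnas}
    mm = {(m, g) for m, g in tables.mirna_mrna if g in mrnas}
    tm = {(t, g) for t, g in tables.tf_mrna if g in mrnas}
    if validated_regulators is not None:
        mm = {(m, g) for m, g in mm if m in validated_regulators}
        tm = {(t, g) for t, g in tm if t in validated_regulators}
    mirnas = {m for m, _ in mm}
    tfs = {t for t, _ in tm}
    mt = {
        (m, t, d) for m, t, d in tables.mirna_tf if m in mirnas and t in tfs
    }
    out = InteractionTables(mirna_mrna=mm, tf_mrna=tm, mirna_tf=mt)
    if out.n_edges() == 0:
        import warnings

        warnings.warn("no regulatory pairs survive the mRNA restriction")
    return out


def enumerate_ffls(tables: InteractionTables) -> list[FFLTriple]:
    """All closed triangles (tf, m, g) with (m, g) in miRNA->mRNA,
    (t, g) in TF->mRNA and an (m, t) regulatory edge in either direction;
    sorted by (tf, mirna, mrna)."""
    mirnas_of: dict[str, set[str]] = {}
    for m, g in tables.mirna_mrna:
        mirnas_of.setdefault(g, set()).add(m)
    tfs_of: dict[str, set[str]] = {}
    for t, g in tables.tf_mrna:
        tfs_of.setdefault(g, set()).add(t)
    directions: dict[tuple[str, str], set[str]] = {}
    for m, t, d in tables.mirna_tf:
        directions.setdefault((m, t), set()).add(d)
    triples = []
    for g, mirnas in mirnas_of.items():
        for t in tfs_of.get(g, ()):
            for m in mirnas:
                tags = directions.get((m, t))
                if not tags:
                    continue
                if tags == {MIRNA_REPRESSES_TF}:
                    loop = LOOP_MIRNA
                elif tags == {TF_REGULATES_MIRNA}:
                    loop = LOOP_TF
                else:
                    loop = LOOP_COMPOSITE
                triples.append(FFLTriple(tf=t, mirna=m, mrna=g, loop_type=loop))
    return sorted(triples, key=lambda x: (x.tf, x.mirna, x.mrna))


# ---------------------------------------------------------------------------
# graph construction and statistics
# ---------------------------------------------------------------------------

@dataclass
class FFLGraph:
    """Undirected, unweighted typed FFL network plus its defining triples."""

    graph: nx.Graph
    triples: list[FFLTriple] = field(default_factory=list)

    def nodes_of_class(self, node_class: str) -> list[str]:
        return sorted(
            n for n, c in self.graph.nodes(data="node_class") if c == node_class
        )

    def class_counts(self) -> dict[str, int]:
        return {c: len(self.nodes_of_class(c)) for c in (TF, MIRNA, MRNA)}

    def edge_class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for a, b in self.graph.edges:
            key = "-".join(
                sorted(
                    (self.graph.nodes[a]["node_class"],
                     self.graph.nodes[b]["node_class"])
                )
            )
            out[key] = out.get(key, 0) + 1
        return out


def build_ffl_graph(
    triples: list[FFLTriple], mrna_status: dict[str, str] | None = None
) -> FFLGraph:
    """Union of all triple members and their three defining edges,
    undirected and deduplicated; mRNA nodes carry up/down status when a
    status map is supplied."""
    g = nx.Graph()
    for tr in triples:
        g.add_node(tr.tf, node_class=TF)
        g.add_node(tr.mirna, node_class=MIRNA)
        g.add_node(tr.mrna, node_class=MRNA)
        g.add_edge(tr.mirna, tr.mrna)
        g.add_edge(tr.tf, tr.mrna)
        g.add_edge(tr.mirna, tr.tf)
    if mrna_status:
        for n, c in g.nodes(data="node_class"):
            if c == MRNA and n in mrna_status:
                g.nodes[n]["status"] = mrna_status[n]
    return FFLGraph(graph=g, triples=list(triples))


def class_degree_stats(ffl: FFLGraph) -> pd.DataFrame:
    """Min / max / mean (2 decimals) node degree per node class."""
    if ffl.graph.number_of_nodes() == 0:
        raise DataValidationError("FFL graph is empty")
    rows = []
    for cls in (TF, MIRNA, MRNA):
        nodes = ffl.nodes_of_class(cls)
        if not nodes:
            continue
        degs = [ffl.graph.degree(n) for n in nodes]
        rows.append(
            {
                "class": cls,
                "n_nodes": len(nodes),
                "min_degree": int(min(degs)),
                "max_degree": int(max(degs)),
                "mean_degree": round(float(np.mean(degs)), 2),
            }
        )
    return pd.DataFrame(rows)


def _dense_rank_desc(values: pd.Series) -> pd.Series:
    """Dense rank, highest value = rank 1."""
    return values.rank(method="dense", ascending=False).astype(int)


def centralities(ffl: FFLGraph) -> pd.DataFrame:
    """Degree, betweenness and closeness per node, with dense per-class
    per-measure ranks (rank 1 = most central) and their mean as the
    aggregate rank.

    Betweenness is Brandes' unnormalized count over unordered vertex
    pairs (endpoints excluded); closeness is (n_c - 1)/sum(d) within the
    node's component, scaled by (n_c - 1)/(n - 1) on multi-component
    graphs, and 0 for isolated nodes.
    """
    g = ffl.graph
    btw = nx.betweenness_centrality(g, normalized=False)
    clo = nx.closeness_centrality(g, wf_improved=True)
    df = pd.DataFrame(
        {
            "node": sorted(g.nodes),
            "node_class": [g.nodes[n]["node_class"] for n in sorted(g.nodes)],
            "degree": [g.degree(n) for n in sorted(g.nodes)],
            "betweenness": [btw[n] for n in sorted(g.nodes)],
            "closeness": [clo[n] for n in sorted(g.nodes)],
        }
    ).set_index("node")
    for measure in ("degree", "betweenness", "closeness"):
        df[f"rank_{measure}"] = (
            df.groupby("node_class")[measure].transform(_dense_rank_desc)
        )
    df["aggregate_rank"] = df[
        ["rank_degree", "rank_betweenness", "rank_closeness"]
    ].mean(axis=1)
    return df


def top_nodes_per_class(
    cent: pd.DataFrame, k: int = 3
) -> dict[str, pd.DataFrame]:
    """Top-k nodes per class for each centrality measure (appendix-style
    summary tables)."""
    out = {}
    for measure in ("degree", "betweenness", "closeness"):
        frames = []
        for cls, sub in cent.groupby("node_class"):
            sub = sub.sort_values(
                by=[measure], ascending=False, kind="mergesort"
            )
            sub = sub.iloc[np.lexsort((sub.index, -sub[measure]))]
            frames.append(sub.head(k).assign(measure=measure))
        out[measure] = pd.concat(frames)
    return out


def highest_order_motif(
    ffl: FFLGraph, cent: pd.DataFrame
) -> tuple[FFLTriple, bool]:
    """The FFL formed by the top-ranked node of each class if that triple
    was enumerated; otherwise (fallback) the enumerated triple minimizing
    the sum of its members' aggregate ranks.  Returns (triple, fallback).
    Ties break on the sorted triple identity."""
    if not ffl.triples:
        raise DataValidationError("no FFL triples to extract a motif from")
    agg = cent["aggregate_rank"]
    tops = {}
    for cls in (TF, MIRNA, MRNA):
        sub = cent[cent["node_class"] == cls]
        if len(sub) == 0:
            raise DataValidationError(f"no nodes of class {cls} in the FFL graph")
        sub = sub.sort_index().sort_values(
            "aggregate_rank", kind="mergesort"
        )
        tops[cls] = sub.index[0]
    for tr in ffl.triples:
        if (tr.tf, tr.mirna, tr.mrna) == (tops[TF], tops[MIRNA], tops[MRNA]):
            return tr, False
    best = min(
        ffl.triples,
        key=lambda tr: (
            agg[tr.tf] + agg[tr.mirna] + agg[tr.mrna],
            tuple(sorted((tr.tf, tr.mirna, tr.mrna))),
        ),
    )
    return best, True
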