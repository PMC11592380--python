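"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive each quantity from its definition
(literal step-up, triple loops, Floyd-Warshall path counting, direct
hypergeometric summation) so they stay independent of the library code
paths they are used to check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from atheronet.data import CASE, CONTROL, ExpressionDataset


def make_dataset(
    values: np.ndarray,
    genes: list[str] | None = None,
    n_case: int | None = None,
    batches: list[str] | None = None,
) -> ExpressionDataset:
    """Wrap a raw matrix into an ExpressionDataset (first half case)."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"G{i:04d}" for i in range(1, n_genes + 1)]
    samples = [f"S{i:03d}" for i in range(1, n_samples + 1)]
    n_case = n_case if n_case is not None else n_samples // 2
    groups = pd.Series([CASE] * n_case + [CONTROL] * (n_samples - n_case),
                       index=samples)
    batch = pd.Series(batches if batches is not None else ["B1"] * n_samples,
                      index=samples)
    return ExpressionDataset(
        values=pd.DataFrame(values, index=genes, columns=samples),
        groups=groups,
        batches=batch,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: sort, scale by n/rank, running
    minimum from the largest p, cap at 1, unsort."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def tom_oracle(adj: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap."""
    n = adj.shape[0]
    k = adj.sum(axis=1)
    tom = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            l_ij = sum(adj[i, u] * adj[u, j] for u in range(n))
            tom[i, j] = (l_ij + adj[i, j]) / (min(k[i], k[j]) + 1 - adj[i, j])
    return tom


def hypergeom_sf_oracle(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] by direct summation of the hypergeometric pmf."""
    from math import comb

    denom = comb(N, n)
    total = 0
    for x in range(k, min(K, n) + 1):
        total += comb(K, x) * comb(N - K, n - x)
    return total / denom


def floyd_warshall_centralities(edges: list[tuple], nodes: list) -> tuple[dict, dict]:
    """Betweenness (unordered pair counts, endpoints excluded) and
    component-scaled closeness from Floyd-Warshall distances and path
    counts."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    INF = float("inf")
    dist = np.full((n, n), INF)
    cnt = np.zeros((n, n))
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        cnt[i, i] = 1
    for a, b in edges:
        i, j = idx[a], idx[b]
        dist[i, j] = dist[j, i] = 1.0
        cnt[i, j] = cnt[j, i] = 1
    for m in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, m] + dist[m, j] < dist[i, j]:
                    dist[i, j] = dist[i, m] + dist[m, j]
                    cnt[i, j] = cnt[i, m] * cnt[m, j]
                elif dist[i, m] + dist[m, j] == dist[i, j] and dist[i, j] < INF and m != i and m != j:
                    cnt[i, j] += cnt[i, m] * cnt[m, j]
    betweenness = {}
    for v in nodes:
        vi = idx[v]
        total = 0.0
        for s, t in itertools.combinations(range(n), 2):
            if s == vi or t == vi or dist[s, t] == INF:
                continue
            if dist[s, vi] + dist[vi, t] == dist[s, t]:
                total += cnt[s, vi] * cnt[vi, t] / cnt[s, t]
        betweenness[v] = total
    closeness = {}
    for v in nodes:
        vi = idx[v]
        reach = [j for j in range(n) if j != vi and dist[vi, j] < INF]
        if not reach:
            closeness[v] = 0.0
            continue
        total = sum(dist[vi, j] for j in reach)
        nc = len(reach)
        closeness[v] = (nc / total) * (nc / (n - 1))
    return betweenness, closeness


def brute_force_ffls(mirna_mrna, tf_mrna, mirna_tf_pairs):
    """Three-nested-loop FFL triangle enumeration."""
    mirnas = {m for m, _ in mirna_mrna} | {m for m, _ in mirna_tf_pairs}
    tfs = {t for t, _ in tf_mrna} | {t for _, t in mirna_tf_pairs}
    mrnas = {g for _, g in mirna_mrna} | {g for _, g in tf_mrna}
    found = set()
    for t in tfs:
        for m in mirnas:
            for g in mrnas:
                if (
                    (m, g) in mirna_mrna
                    and (t, g) in tf_mrna
                    and (m, t) in mirna_tf_pairs
                ):
                    found.add((t, m, g))
    return found
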