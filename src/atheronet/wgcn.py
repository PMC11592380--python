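"""Weighted gene co-expression network construction and module detection.

The network is unsigned: adjacency a_ij = |cor(x_i, x_j)|^beta, with the
soft-threshold power beta chosen as the smallest candidate whose degree
distribution satisfies the scale-free-topology criterion (squared Pearson
correlation of log10 frequency vs log10 mean connectivity over log-spaced
degree bins, with a negative slope required).

Gene-gene similarity is then the topological overlap

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),   l_ij = sum_u a_iu a_uj

and modules are branches of the average-linkage dendrogram of
dissTOM = 1 - TOM, extracted by a tree-variant dynamic cut: branches
joining above an absolute cut height are separated outright, and a branch
is further split wherever its joining height stands clear of the bulk of
the merge heights inside it (the height-gap criterion).  Branches smaller
than the minimum module size are left unassigned ("grey").

Each module is summarized by its eigengene, the first right singular
vector of the module's z-scored expression submatrix, and modules whose
eigengenes are highly correlated (dissimilarity 1 - cor below the merge
height, default 0.25, i.e. correlation above 0.75) are merged iteratively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data import DataValidationError, ExpressionDataset

GREY = "grey"

#: conventional size-ordered module color palette; labels carry no semantics
COLOR_SEQUENCE = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]


@dataclass(frozen=True)
class WGCNConfig:
    beta_candidates: tuple[int, ...] = tuple(range(1, 21))
    r2_target: float = 0.8
    n_degree_bins: int = 10
    min_module_size: int = 30
    merge_height: float = 0.25
    cut_height: float = 0.99
    gap_min: float = 0.1
    gap_quantile: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 < self.r2_target <= 1.0:
            raise DataValidationError("r2_target must be in (0, 1]")
        if not 0.0 < self.merge_height < 1.0:
            raise DataValidationError("merge_height must be in (0, 1)")


@dataclass
class ModulePartition:
    """Gene -> module color assignment; ``grey`` marks unassigned genes."""

    module_of: dict[str, str]

    @property
    def genes(self) -> list[str]:
        return list(self.module_of)

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.module_of.values():
            out[m] = out.get(m, 0) + 1
        return out

    def modules(self) -> list[str]:
        return sorted(m for m in set(self.module_of.values()) if m != GREY)

    def genes_in(self, module: str) -> list[str]:
        return [g for g, m in self.module_of.items() if m == module]

    def labels(self, genes: list[str] | None = None) -> list[str]:
        genes = genes if genes is not None else self.genes
        return [self.module_of[g] for g in genes]


@dataclass
class EigengeneSet:
    """Per-module eigengene profiles (samples x modules) and the fraction
    of module variance each explains."""

    profiles: pd.DataFrame
    variance_explained: dict[str, float] = field(default_factory=dict)


def merge_height_to_correlation(height: float) -> float:
    """Eigengene-dendrogram duality: a cut at dissimilarity height ``h``
    merges modules whose eigengene correlation exceeds ``1 - h``."""
    return 1.0 - height


# ---------------------------------------------------------------------------
# noisy-gene filter
# ---------------------------------------------------------------------------

def filter_noisy_genes(
    ds: ExpressionDataset, min_abs_cor: float = 0.3
) -> tuple[ExpressionDataset, list[str]]:
    """Drop genes whose maximum |correlation| with every other gene falls
    below ``min_abs_cor`` (a correlation-based noise filter).  Returns the
    filtered dataset and the list of dropped gene ids."""
    if ds.n_genes < 3:
        raise DataValidationError("need >= 3 genes for the noisy-gene filter")
    if min_abs_cor <= 0:
        return ds, []
    cor = np.abs(np.corrcoef(ds.values.to_numpy(dtype=float)))
    np.fill_diagonal(cor, 0.0)
    max_cor = cor.max(axis=1)
    keep_mask = max_cor >= min_abs_cor
    if not keep_mask.any():
        raise DataValidationError("noisy-gene filter would drop every gene")
    dropped = list(ds.values.index[~keep_mask])
    if not dropped:
        return ds, []
    return ds.subset_genes(list(ds.values.index[keep_mask])), dropped


# ---------------------------------------------------------------------------
# adjacency and soft threshold
# ---------------------------------------------------------------------------

def adjacency_matrix(ds: ExpressionDataset, beta: int) -> np.ndarray:
    """Unsigned adjacency |cor|^beta with zero diagonal."""
    x = ds.values.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if np.any(sd == 0):
        raise DataValidationError("constant-expression genes have no defined correlation")
    adj = np.abs(np.corrcoef(x)) ** beta
    np.fill_diagonal(adj, 0.0)
    return adj


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free-topology fit of a connectivity vector.

    Bins k > 0 into ``n_bins`` equal-width bins, regresses log10(frequency)
    on log10(mean k per bin), and returns (r2, slope).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.isclose(k.max(), k.min()):
        raise DataValidationError("degenerate connectivity: all degrees equal")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    edges[-1] *= 1.0 + 1e-12  # include the max in the last bin
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        raise DataValidationError("too few occupied degree bins for an SFT fit")
    fit = stats.linregress(xs, ys)
    return float(fit.rvalue**2), float(fit.slope)


@dataclass
class SoftThresholdResult:
    beta: int
    r2: float
    reached_target: bool
    table: pd.DataFrame  # beta, r2, slope, signed_r2, mean_k


def pick_soft_threshold(
    ds: ExpressionDataset, cfg: WGCNConfig = WGCNConfig()
) -> SoftThresholdResult:
    """Smallest candidate power with signed SFT fit >= the target; if none
    qualifies, the power maximizing the signed fit is returned with a
    warning.  The signed fit is -sign(slope) * R^2, so an increasing
    (anti-scale-free) degree trend can never satisfy the target."""
    rows = []
    for beta in cfg.beta_candidates:
        adj = adjacency_matrix(ds, beta)
        k = adj.sum(axis=1)
        r2, slope = scale_free_fit(k, cfg.n_degree_bins)
        signed = -np.sign(slope) * r2
        rows.append(
            {"beta": beta, "r2": r2, "slope": slope, "signed_r2": signed,
             "mean_k": float(k.mean())}
        )
    table = pd.DataFrame(rows)
    ok = table[table["signed_r2"] >= cfg.r2_target]
    if len(ok):
        row = ok.iloc[0]
        reached = True
    else:
        row = table.iloc[int(table["signed_r2"].idxmax())]
        reached = False
        warnings.warn(
            f"no candidate power reached the scale-free fit target "
            f"{cfg.r2_target}; using beta={int(row['beta'])} "
            f"(signed R2={row['signed_r2']:.3f})"
        )
    return SoftThresholdResult(
        beta=int(row["beta"]), r2=float(row["r2"]), reached_target=reached,
        table=table,
    )


# ---------------------------------------------------------------------------
# topological overlap
# ---------------------------------------------------------------------------

def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency matrix (unit diagonal)."""
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise DataValidationError("adjacency must be square")
    if not np.allclose(adj, adj.T, atol=1e-10):
        raise DataValidationError("adjacency must be symmetric")
    if np.any(np.diagonal(adj) != 0):
        raise DataValidationError("adjacency diagonal must be zero")
    if adj.min() < 0 or adj.max() > 1:
        raise DataValidationError("adjacency entries must lie in [0, 1]")
    k = adj.sum(axis=1)
    shared = adj @ adj
    denom = np.minimum.outer(k, k) + 1.0 - adj
    tom = (shared + adj) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


# ---------------------------------------------------------------------------
# dynamic tree cut ("tree" variant)
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("id", "left", "right", "dist", "leaves")

    def __init__(self, id_, left, right, dist, leaves):
        self.id, self.left, self.right, self.dist, self.leaves = (
            id_, left, right, dist, leaves
        )


def _build_tree(Z: np.ndarray, n: int) -> _Node:
    nodes: list[_Node] = [_Node(i, None, None, 0.0, [i]) for i in range(n)]
    for i, (a, b, dist, _cnt) in enumerate(Z):
        left, right = nodes[int(a)], nodes[int(b)]
        nodes.append(
            _Node(n + i, left, right, float(dist), left.leaves + right.leaves)
        )
    return nodes[-1]


def _internal_heights(node: _Node) -> list[float]:
    out: list[float] = []
    stack = [node]
    while stack:
        nd = stack.pop()
        if nd.left is None:
            continue
        out.append(nd.dist)
        stack.extend((nd.left, nd.right))
    return out


def cut_tree_dynamic(
    Z: np.ndarray,
    n: int,
    cut_height: float = 0.99,
    min_module_size: int = 30,
    gap_min: float = 0.1,
    gap_quantile: float = 0.9,
) -> list[list[int]]:
    """Tree-variant dynamic cut of an average-linkage dendrogram.

    Branches joining at or above ``cut_height`` are always separated.
    Below the cut, a branch is split when its joining height exceeds the
    ``gap_quantile`` quantile of the merge heights inside it by more than
    ``gap_min`` — i.e. when the join stands clear of the branch's internal
    structure.  Returned clusters smaller than ``min_module_size`` are the
    caller's to mark unassigned.
    """
    root = _build_tree(Z, n)
    clusters: list[list[int]] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node.left is None:
            clusters.append(node.leaves)
            continue
        if node.dist >= cut_height:
            stack.extend((node.left, node.right))
            continue
        inner = _internal_heights(node.left) + _internal_heights(node.right)
        if inner:
            bulk = float(np.quantile(inner, gap_quantile))
            if node.dist - bulk > gap_min and len(node.leaves) >= 2 * min_module_size:
                stack.extend((node.left, node.right))
                continue
        clusters.append(node.leaves)
    return clusters


def detect_modules(
    tom: np.ndarray, gene_ids: list[str], cfg: WGCNConfig = WGCNConfig()
) -> ModulePartition:
    """Detect co-expression modules from a TOM via average-linkage
    clustering of dissTOM and the tree-variant dynamic cut; clusters below
    the minimum size become grey; surviving modules get conventional color
    labels ordered by decreasing size."""
    n = len(gene_ids)
    if tom.shape != (n, n):
        raise DataValidationError("tom shape does not match gene list")
    if n < cfg.min_module_size:
        warnings.warn("fewer genes than min_module_size; all genes left grey")
        return ModulePartition({g: GREY for g in gene_ids})
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(diss, checks=False), method="average")
    clusters = cut_tree_dynamic(
        Z, n,
        cut_height=cfg.cut_height,
        min_module_size=cfg.min_module_size,
        gap_min=cfg.gap_min,
        gap_quantile=cfg.gap_quantile,
    )
    kept = [c for c in clusters if len(c) >= cfg.min_module_size]
    kept.sort(key=lambda c: (-len(c), min(c)))
    module_of = {g: GREY for g in gene_ids}
    for rank, cluster in enumerate(kept):
        color = (
            COLOR_SEQUENCE[rank]
            if rank < len(COLOR_SEQUENCE)
            else f"module{rank + 1}"
        )
        for i in cluster:
            module_of[gene_ids[i]] = color
    return ModulePartition(module_of)


# ---------------------------------------------------------------------------
# eigengenes and module merging
# ---------------------------------------------------------------------------

def _zscore_safe(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def module_eigengenes(
    ds: ExpressionDataset, partition: ModulePartition
) -> EigengeneSet:
    """First-singular-vector eigengene per non-grey module, unit variance,
    sign-oriented so that it correlates positively with the module's mean
    expression profile."""
    modules = partition.modules()
    if not modules:
        raise DataValidationError("partition has no non-grey modules")
    profiles = {}
    var_explained = {}
    for m in modules:
        genes = partition.genes_in(m)
        x = _zscore_safe(ds.values.loc[genes].to_numpy(dtype=float))
        if x.shape[0] == 1:
            me = x[0].copy()
            var_explained[m] = 1.0
        else:
            _u, s, vt = np.linalg.svd(x, full_matrices=False)
            me = vt[0]
            var_explained[m] = float(s[0] ** 2 / (s**2).sum())
        me = me / me.std(ddof=1)
        mean_profile = x.mean(axis=0)
        if np.corrcoef(me, mean_profile)[0, 1] < 0:
            me = -me
        profiles[m] = me
    return EigengeneSet(
        profiles=pd.DataFrame(profiles, index=ds.sample_ids),
        variance_explained=var_explained,
    )


def merge_close_modules(
    ds: ExpressionDataset,
    partition: ModulePartition,
    eigengenes: EigengeneSet | None = None,
    merge_height: float = 0.25,
) -> tuple[ModulePartition, EigengeneSet]:
    """Iteratively merge modules whose eigengene dissimilarity (1 - cor)
    falls below ``merge_height``; eigengenes are recomputed after every
    round until no pair remains below the threshold.  Grey is never merged.
    """
    part = ModulePartition(dict(partition.module_of))
    eg = eigengenes if eigengenes is not None else module_eigengenes(ds, part)
    for _ in range(200):
        modules = part.modules()
        if len(modules) < 2:
            break
        me = eg.profiles[modules].to_numpy(dtype=float)
        cor = np.corrcoef(me.T)
        diss = 1.0 - cor
        np.fill_diagonal(diss, 0.0)
        diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
        if diss[np.triu_indices(len(modules), 1)].min() >= merge_height:
            break
        Z = hierarchy.linkage(squareform(diss, checks=False), method="average")
        labels = hierarchy.fcluster(Z, t=merge_height, criterion="distance")
        sizes = part.sizes()
        for cl in np.unique(labels):
            members = [modules[i] for i in np.flatnonzero(labels == cl)]
            if len(members) < 2:
                continue
            # survivor label: largest member module, ties by color order
            survivor = max(members, key=lambda m: (sizes[m], m))
            for g, m in part.module_of.items():
                if m in members:
                    part.module_of[g] = survivor
        eg = module_eigengenes(ds, part)
    return part, eg


def drop_unassigned(partition: ModulePartition) -> list[str]:
    """All non-grey genes, in partition order, for downstream analysis."""
    kept = [g for g, m in partition.module_of.items() if m != GREY]
    if not kept:
        warnings.warn("every gene is unassigned (grey); nothing retained")
    return kept
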