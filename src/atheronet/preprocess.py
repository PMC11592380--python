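"""Expression preprocessing: batch adjustment, duplicate collapsing,
z-scoring, low-variance filtering, and sample-outlier removal.

Batch adjustment is a deterministic per-gene location(/scale)
standardization: within each batch a gene's values are re-centred on the
pooled gene mean (and optionally rescaled to the pooled standard deviation).
This removes additive (and multiplicative) batch offsets exactly and is
idempotent; it does not attempt empirical-Bayes shrinkage across genes.

Sample outliers are flagged by standardized network connectivity: the row
sums of the absolute sample-sample correlation matrix, z-scored across
samples.  Samples far below the bulk (default z < -2.5) are the ones a
sample-clustering dendrogram would show on long isolated branches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DataValidationError, ExpressionDataset


def correct_batches(ds: ExpressionDataset, scale: bool = False) -> ExpressionDataset:
    """Per-gene, per-batch location(/scale) standardization to the pooled
    gene statistics.  Single-batch input is returned unchanged."""
    batches = ds.batches
    labels = batches.unique()
    if len(labels) <= 1:
        return ds
    if scale:
        counts = batches.value_counts()
        singletons = counts[counts < 2]
        if len(singletons):
            raise DataValidationError(
                f"batches with a single sample ({sorted(singletons.index)}) "
                "cannot be scale-adjusted; use location-only mode"
            )
    x = ds.values.to_numpy(dtype=float).copy()
    pooled_mean = x.mean(axis=1, keepdims=True)
    pooled_sd = x.std(axis=1, ddof=1, keepdims=True)
    for b in labels:
        cols = (batches == b).to_numpy()
        bm = x[:, cols].mean(axis=1, keepdims=True)
        if scale:
            bsd = x[:, cols].std(axis=1, ddof=1, keepdims=True)
            safe = np.where(bsd > 0, bsd, 1.0)
            x[:, cols] = (x[:, cols] - bm) / safe * pooled_sd + pooled_mean
        else:
            x[:, cols] = x[:, cols] - bm + pooled_mean
    return ds.with_values(
        pd.DataFrame(x, index=ds.values.index, columns=ds.values.columns)
    )


def collapse_duplicates(ds: ExpressionDataset) -> ExpressionDataset:
    """Keep one row per gene symbol: the duplicate with the highest mean
    expression; ties go to the earliest original row."""
    idx = ds.values.index
    if idx.is_unique:
        return ds
    means = ds.values.mean(axis=1).to_numpy()
    keep_pos: dict[str, int] = {}
    for pos, gene in enumerate(idx):
        prev = keep_pos.get(gene)
        if prev is None or means[pos] > means[prev]:
            keep_pos[gene] = pos
    rows = sorted(keep_pos.values())
    return ds.with_values(ds.values.iloc[rows])


def zscore_rows(ds: ExpressionDataset) -> ExpressionDataset:
    """Standardize each gene to mean 0 and sample sd 1 (n-1 denominator)."""
    x = ds.values.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    zero = sd == 0
    if zero.any():
        bad = list(ds.values.index[zero])
        raise DataValidationError(
            f"zero-variance genes cannot be z-scored: {bad[:10]}"
            + (" ..." if len(bad) > 10 else "")
        )
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return ds.with_values(
        pd.DataFrame(z, index=ds.values.index, columns=ds.values.columns)
    )


def filter_low_variance(
    ds: ExpressionDataset, fraction: float = 0.5
) -> ExpressionDataset:
    """Drop the ``fraction`` lowest-variance genes, keeping the
    ceil((1 - fraction) * n) highest-variance ones in original order.
    Variance ties are broken in favour of lexicographically earlier gene ids.
    """
    if not 0.0 <= fraction < 1.0:
        raise DataValidationError(f"fraction must be in [0, 1), got {fraction}")
    if fraction == 0.0:
        return ds
    n = ds.n_genes
    n_keep = int(np.ceil((1.0 - fraction) * n))
    var = ds.values.var(axis=1, ddof=1)
    order = sorted(range(n), key=lambda i: (-var.iloc[i], ds.values.index[i]))
    keep = sorted(order[:n_keep])
    return ds.with_values(ds.values.iloc[keep])


@dataclass
class OutlierReport:
    removed: list[str]
    connectivity_z: pd.Series


def sample_connectivity_z(ds: ExpressionDataset) -> pd.Series:
    """Standardized network connectivity of each sample: z-score of the
    row sums of |cor| over the sample-sample correlation matrix."""
    cor = np.corrcoef(ds.values.to_numpy(dtype=float).T)
    k = np.abs(cor).sum(axis=1) - 1.0  # exclude self-correlation
    z = (k - k.mean()) / k.std(ddof=1)
    return pd.Series(z, index=ds.sample_ids)


def remove_sample_outliers(
    ds: ExpressionDataset, z_cut: float = -2.5, max_removed_frac: float = 0.2
) -> tuple[ExpressionDataset, OutlierReport]:
    """Drop samples whose standardized connectivity falls below ``z_cut``."""
    if ds.n_samples < 4:
        raise DataValidationError("need >= 4 samples for outlier detection")
    z = sample_connectivity_z(ds)
    removed = list(z.index[z < z_cut])
    if len(removed) > max_removed_frac * ds.n_samples:
        raise DataValidationError(
            f"outlier rule would remove {len(removed)}/{ds.n_samples} samples "
            "(> 20%); this suggests a data problem rather than isolated outliers"
        )
    report = OutlierReport(removed=removed, connectivity_z=z)
    if not removed:
        return ds, report
    keep = [s for s in ds.sample_ids if s not in set(removed)]
    return ds.subset_samples(keep), report


def preprocess(
    ds: ExpressionDataset,
    lv_fraction: float = 0.5,
    z_cut: float = -2.5,
    scale_batches: bool = False,
    filter_before_zscore: bool = True,
) -> tuple[ExpressionDataset, OutlierReport]:
    """Run the standard chain: batch correction, duplicate collapsing,
    low-variance filtering, z-scoring, and sample-outlier removal.

    ``filter_before_zscore`` applies the variance filter on the corrected
    (pre-z-score) values, where gene variances are still informative; after
    row z-scoring all variances are 1 and the filter would be vacuous.  Set
    it to False to z-score first (the filter then falls back to the
    pre-transform variances internally via tie-breaking on gene id order).
    """
    ds = correct_batches(ds, scale=scale_batches)
    ds = collapse_duplicates(ds)
    if filter_before_zscore:
        ds = filter_low_variance(ds, fraction=lv_fraction)
        ds = zscore_rows(ds)
    else:
        ds = zscore_rows(ds)
        ds = filter_low_variance(ds, fraction=lv_fraction)
    return remove_sample_outliers(ds, z_cut=z_cut)
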