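"""Two-group differential expression with an empirical-Bayes moderated t.

The test statistic shrinks each gene's residual variance toward a pooled
prior estimated from all genes.  With per-gene residual variance s_g^2 on
d = n1 + n2 - 2 degrees of freedom and a scaled-inverse-chi-square prior
(d0, s0^2), the posterior variance is

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

and the moderated statistic t_g = (mean_case - mean_control) /
(s~_g * sqrt(1/n1 + 1/n2)) follows a t distribution on d0 + d degrees of
freedom under the null.  The hyperparameters (d0, s0^2) are estimated by
matching the first two moments of log s_g^2 against the theoretical
log-F distribution (digamma/trigamma identities), with the trigamma
inverse solved by Newton iteration.  As d0 -> infinity every gene shares
the same variance and the statistic reduces to a pooled-variance t with
s0^2 plugged in.

Genes are then screened on the Benjamini-Hochberg adjusted p-value and a
log2 fold-change magnitude cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .data import DataValidationError, ExpressionDataset

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NS = "ns"


@dataclass
class DifferentialResult:
    """Per-gene differential expression table plus the fitted prior.

    ``table`` columns: log2fc, t, df, p, p_bh, status (status is ``ns``
    until :func:`screen_degs` is applied).
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    p_cut: float | None = None
    fc_cut: float | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def degs(self) -> pd.DataFrame:
        return self.table[self.table["status"] != STATUS_NS]

    def n_up(self) -> int:
        return int((self.table["status"] == STATUS_UP).sum())

    def n_down(self) -> int:
        return int((self.table["status"] == STATUS_DOWN).sum())


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/x scale."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif / x) < 1e-10:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-inverse-chi-square prior
    (d0, s0^2) to the observed residual variances ``s2`` on ``df``
    degrees of freedom each."""
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise DataValidationError("all genes have zero residual variance")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    n = e.size
    emean = e.mean()
    if n < 2:
        return np.inf, float(np.exp(emean))
    evar = ((e - emean) ** 2).sum() / (n - 1)
    rhs = evar * n / (n - 1.0) - special.polygamma(1, df / 2.0)
    if rhs <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * trigamma_inverse(rhs)
    s0_sq = np.exp(
        emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    )
    return float(d0), float(s0_sq)


def moderated_t_test(
    ds: ExpressionDataset, method: str = "moderated"
) -> DifferentialResult:
    """Per-gene two-sample test, case minus control.

    ``method`` is ``"moderated"`` (empirical-Bayes shrinkage, the default)
    or ``"welch"`` (ordinary unequal-variance t, no shrinkage).
    """
    case = ds.values[ds.case_samples].to_numpy(dtype=float)
    ctrl = ds.values[ds.control_samples].to_numpy(dtype=float)
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise DataValidationError(
            f"need >= 2 samples per group, got case={n1}, control={n2}"
        )
    effect = case.mean(axis=1) - ctrl.mean(axis=1)

    if method == "welch":
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
        df_t = np.full_like(t, np.nan)
        d0, s0_sq = np.nan, np.nan
    elif method == "moderated":
        d = n1 + n2 - 2
        ss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
            (ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2
        ).sum(axis=1)
        s2 = ss / d
        d0, s0_sq = fit_variance_prior(s2, d)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.inf
        else:
            s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
            df_total = d0 + d
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, effect / se, 0.0)
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        df_t = np.full_like(t, df_total)
    else:
        raise ValueError(f"unknown method {method!r}")

    table = pd.DataFrame(
        {
            "log2fc": effect,
            "t": t,
            "df": df_t,
            "p": p,
            "p_bh": bh_adjust(p),
            "status": STATUS_NS,
        },
        index=ds.values.index,
    )
    return DifferentialResult(table=table, d0=float(d0), s0_sq=float(s0_sq))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DataValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_degs(
    res: DifferentialResult,
    p_cut: float = 0.05,
    fc_cut: float = 0.1,
    signed: bool = False,
) -> DifferentialResult:
    """Assign up/down/ns status from the BH-adjusted p and fold-change cuts.

    By default the fold-change cut is on |log2FC| (so both directions are
    screened); ``signed=True`` applies the literal one-sided reading
    log2FC > fc_cut, labelling only upregulated genes.
    """
    tab = res.table.copy()
    sig = tab["p_bh"] < p_cut
    up = sig & (tab["log2fc"] > fc_cut)
    if signed:
        down = pd.Series(False, index=tab.index)
    else:
        down = sig & (tab["log2fc"] < -fc_cut)
    tab["status"] = STATUS_NS
    tab.loc[up, "status"] = STATUS_UP
    tab.loc[down, "status"] = STATUS_DOWN
    return DifferentialResult(
        table=tab, d0=res.d0, s0_sq=res.s0_sq, p_cut=p_cut, fc_cut=fc_cut
    )


def top_table(
    res: DifferentialResult, k: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k upregulated (descending log2FC) and top-k downregulated
    (ascending log2FC) genes among screened DEGs.  Fold-change ties break
    on smaller adjusted p, then gene id."""
    tab = res.table
    up = tab[tab["status"] == STATUS_UP].copy()
    down = tab[tab["status"] == STATUS_DOWN].copy()
    up = up.iloc[np.lexsort((up.index, up["p_bh"], -up["log2fc"]))]
    down = down.iloc[np.lexsort((down.index, down["p_bh"], down["log2fc"]))]
    return up.head(k), down.head(k)
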