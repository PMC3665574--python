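"""Differential-expression preprocessing: imputation, normalization, testing.

Produces the up- and down-regulated target gene sets that seed-to-target
shortest-path search consumes. The stages mirror a classic two-channel
cDNA microarray analysis:

1. KNN imputation of missing spots (gene-space neighbours, Euclidean
   distance over mutually observed samples, unweighted mean of the k
   nearest rows' values in the target sample).
2. Per-array LOWESS normalization of the M = log2(R/G) ratios against
   A = 0.5*log2(R*G), removing intensity-dependent dye bias.
3. Per-gene two-sided Welch (unequal-variance) t-test between the two
   conditions, with linear-scale fold changes.
4. Holm step-down adjustment (family-wise error control; Benjamini-
   Hochberg available as an alternative) and independent AND gates:
   adjusted p < alpha, fold change > 1.5 (up) or < 0.67 (down).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix


@dataclass
class DEGeneSets:
    """Called DE genes plus the full per-gene statistics table.

    ``table`` columns: fold_change (linear, condition2/condition1), raw_p,
    adjusted_p, call in {up, down, ns}.
    """

    up: set[str]
    down: set[str]
    table: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a gene cannot be both up- and down-regulated")


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------


def knn_impute(em: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Impute missing values from the k nearest gene rows.

    Distance between gene rows is the Euclidean distance over the columns
    both rows observe. For each missing cell, candidate neighbours are the
    rows observed in that column; the imputed value is the unweighted mean
    of the k nearest candidates' values there. Observed entries are never
    changed. A row with zero observed entries is an error.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = em.values.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    dead = np.where(~obs.any(axis=1))[0]
    if dead.size:
        names = [em.values.index[i] for i in dead]
        raise ValueError(f"gene rows with zero observed entries: {names}")
    if obs.all():
        return em

    out = X.copy()
    n_rows = X.shape[0]
    for r in np.where(~obs.all(axis=1))[0]:
        # distances from row r to every other row, over mutual columns
        mutual = obs & obs[r]
        diff = X - X[r]
        diff[~mutual] = 0.0
        d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        d[mutual.sum(axis=1) == 0] = np.inf
        d[r] = np.inf
        for c in np.where(~obs[r])[0]:
            cand = np.where(obs[:, c] & (np.arange(n_rows) != r) & np.isfinite(d))[0]
            if cand.size < k:
                raise ValueError(
                    f"column {em.values.columns[c]!r}: only {cand.size} candidate "
                    f"neighbours observed, need k={k}"
                )
            order = cand[np.lexsort((cand, d[cand]))][:k]
            out[r, c] = X[order, c].mean()
    values = pd.DataFrame(out, index=em.values.index, columns=em.values.columns)
    return ExpressionMatrix(values=values, design=em.design, channels=em.channels)


# ---------------------------------------------------------------------------
# Two-channel LOWESS normalization
# ---------------------------------------------------------------------------


def lowess_normalize(em: ExpressionMatrix, span: float = 0.4) -> ExpressionMatrix:
    """Per-array LOWESS normalization of two-channel intensities.

    For each array, M = log2(R/G) and A = 0.5*log2(R*G); the returned
    expression value is M' = M - lowess(M ~ A, frac=span). Non-positive
    intensities are floored at half the smallest positive intensity on
    that array. Arrays with fewer than 10 spots are rejected (the local
    regression is underdetermined).
    """
    if em.channels is None:
        raise ValueError("lowess_normalize needs two-channel (R, G) intensities")
    R, G = em.channels
    out = {}
    for sample in em.values.columns:
        r = R[sample].to_numpy(dtype=float)
        g = G[sample].to_numpy(dtype=float)
        ok = np.isfinite(r) & np.isfinite(g)
        if ok.sum() < 10:
            raise ValueError(f"array {sample!r}: fewer than 10 usable spots")
        pos = np.concatenate([r[ok & (r > 0)], g[ok & (g > 0)]])
        if pos.size == 0:
            raise ValueError(f"array {sample!r}: no positive intensities")
        floor = pos.min() / 2.0
        r = np.clip(r, floor, None)
        g = np.clip(g, floor, None)
        M = np.log2(r / g)
        A = 0.5 * np.log2(r * g)
        fit = _sm_lowess(M[ok], A[ok], frac=span, return_sorted=False)
        Mn = np.full_like(M, np.nan)
        Mn[ok] = M[ok] - fit
        out[sample] = Mn
    values = pd.DataFrame(out, index=em.values.index)[list(em.values.columns)]
    return ExpressionMatrix(values=values, design=em.design, channels=em.channels)


# ---------------------------------------------------------------------------
# Testing
# ---------------------------------------------------------------------------


def two_class_ttest(em: ExpressionMatrix, values_are_log2: bool | None = None) -> pd.DataFrame:
    """Per-gene Welch t-test and linear fold change between the two conditions.

    The test runs on the values as given. Fold change is
    mean(condition2)/mean(condition1) on the linear scale; values detected
    as log2 (99th percentile of finite values < 30, overridable via
    ``values_are_log2``) are exponentiated first. Degenerate genes (zero
    variance in both groups) get p = 1 when the means agree and p = 0,
    flagged, otherwise.

    Returns a DataFrame indexed by gene: fold_change, raw_p, degenerate.
    """
    cond1, cond2 = em.conditions
    s1, s2 = em.samples_of(cond1), em.samples_of(cond2)
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("each condition needs >= 2 samples for testing")
    X1 = em.values[s1].to_numpy(dtype=float)
    X2 = em.values[s2].to_numpy(dtype=float)
    if np.isnan(X1).any() or np.isnan(X2).any():
        raise ValueError("matrix contains missing values; impute first")

    if values_are_log2 is None:
        finite = em.values.to_numpy(dtype=float)
        values_are_log2 = bool(np.nanpercentile(finite, 99) < 30)
    L1, L2 = (np.power(2.0, X1), np.power(2.0, X2)) if values_are_log2 else (X1, X2)
    fold = L2.mean(axis=1) / L1.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(X1, X2, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    v1 = X1.var(axis=1, ddof=1)
    v2 = X2.var(axis=1, ddof=1)
    degenerate = (v1 == 0) & (v2 == 0)
    same_mean = np.isclose(X1.mean(axis=1), X2.mean(axis=1))
    p = np.where(degenerate & same_mean, 1.0, p)
    p = np.where(degenerate & ~same_mean, 0.0, p)

    return pd.DataFrame(
        {"fold_change": fold, "raw_p": p, "degenerate": degenerate & ~same_mean},
        index=em.values.index,
    )


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values, mapped back to input order.

    Controls the family-wise error rate. adj(i) >= raw(i); monotone
    nondecreasing along the sorted raw p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def call_de_genes(
    stats_table: pd.DataFrame,
    alpha: float = 0.05,
    up_threshold: float = 1.5,
    down_threshold: float = 0.67,
    method: str = "holm",
) -> DEGeneSets:
    """Gate the per-gene table into up/down/ns calls.

    up: adjusted_p < alpha AND fold_change > up_threshold;
    down: adjusted_p < alpha AND fold_change < down_threshold.
    ``method`` selects the adjustment: ``holm`` (default) or ``bh``.
    """
    table = stats_table.copy()
    if "adjusted_p" not in table.columns:
        if method == "holm":
            table["adjusted_p"] = holm_adjust(table["raw_p"].to_numpy())
        elif method == "bh":
            table["adjusted_p"] = multipletests(table["raw_p"].to_numpy(), method="fdr_bh")[1]
        else:
            raise ValueError(f"unknown adjustment method: {method}")
    sig = table["adjusted_p"] < alpha
    up = set(table.index[sig & (table["fold_change"] > up_threshold)])
    down = set(table.index[sig & (table["fold_change"] < down_threshold)])
    call = np.where(table.index.isin(up), "up", np.where(table.index.isin(down), "down", "ns"))
    table["call"] = call
    return DEGeneSets(up=up, down=down, table=table)
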