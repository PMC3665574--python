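"""Category overrepresentation per subnetwork and core-pathway profiling.

Each subnetwork's gene set is tested per category term with the
hypergeometric upper tail P(X >= k) for X ~ Hypergeom(N, K, n) — k term
members in the subnetwork, n subnetwork genes in the universe, K term
members in the universe of size N — followed by Benjamini-Hochberg
adjustment within that subnetwork's family of tests. Terms overrepresented
across many subnetworks are profiled by frequency; the most frequent ones
are the core-pathway candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats
from statsmodels.stats.multitest import multipletests

from .io import AnnotationMap

_EXACT_N_LIMIT = 2000


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int
    n: int
    K: int
    N: int
    raw_p: float
    adjusted_p: float


@dataclass
class CorePathwayProfile:
    """Per-term count of subnetworks significant at alpha, ranked by frequency."""

    table: pd.DataFrame = field(repr=False)  # term, n_significant, n_mssn, frequency, mean_adjusted_p
    n_mssn: int = 0
    alpha: float = 0.05


def _check_args(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(f"invalid hypergeometric arguments k={k} n={n} K={K} N={N}")


def hypergeom_pmf(k: int, n: int, K: int, N: int) -> float:
    """P(X = k), exact integer combinatorics for moderate N."""
    _check_args(k, n, K, N)
    if N <= _EXACT_N_LIMIT:
        return float(Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n)))
    return float(_scipy_stats.hypergeom.pmf(k, N, K, n))


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Exact integer combinatorics up to N = 2000 (a single final division,
    so the result is the correctly rounded rational); scipy's survival
    function beyond.
    """
    _check_args(k, n, K, N)
    if k == 0:
        return 1.0
    if N <= _EXACT_N_LIMIT:
        total = comb(N, n)
        hits = sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(n, K) + 1))
        return float(Fraction(hits, total))
    return float(_scipy_stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_subnetwork(
    nodes: Iterable[str],
    ann: AnnotationMap,
    alpha: float = 0.05,
    min_term_size: int = 2,
) -> list[EnrichmentResult]:
    """Hypergeometric overrepresentation of every term in one subnetwork.

    ``nodes`` may be an MSSN or any gene collection; membership is
    intersected with the annotation universe (the count enters as n).
    Terms annotating fewer than ``min_term_size`` universe genes are
    skipped. BH adjustment runs across this subnetwork's term family;
    results sort by adjusted p ascending, ties by k descending then term.
    """
    node_set = set(getattr(nodes, "nodes", nodes))
    members = node_set & ann.universe
    n = len(members)
    N = len(ann.universe)
    if n == 0:
        import logging

        logging.getLogger("drivernet").warning("subnetwork has no genes in the universe")
        return []

    rows: list[tuple[str, int, int]] = []
    sizes = ann.term_sizes()
    for term in sorted(sizes):
        K = sizes[term]
        if K < min_term_size:
            continue
        k = sum(1 for g in members if term in ann.gene_terms.get(g, ()))
        rows.append((term, k, K))
    if not rows:
        return []
    raw = [hypergeom_tail(k, n, K, N) for _, k, K in rows]
    adj = bh_adjust(raw)
    results = [
        EnrichmentResult(term=t, k=k, n=n, K=K, N=N, raw_p=rp, adjusted_p=ap)
        for (t, k, K), rp, ap in zip(rows, raw, adj)
    ]
    results.sort(key=lambda r: (r.adjusted_p, -r.k, r.term))
    return results


def core_pathways(
    all_results: Mapping[str, Sequence[EnrichmentResult]],
    alpha: float = 0.05,
) -> CorePathwayProfile:
    """Cross-subnetwork frequency profile of significant terms.

    ``all_results`` maps a subnetwork label (seed or seed/direction) to its
    enrichment list. A term counts once per subnetwork where its adjusted
    p < alpha. Ranked by frequency descending, ties by mean adjusted p
    ascending then term id; terms never significant are omitted.
    """
    if not all_results:
        raise ValueError("need at least one subnetwork result list")
    total = len(all_results)
    counts: dict[str, int] = {}
    padj: dict[str, list[float]] = {}
    for results in all_results.values():
        for r in results:
            padj.setdefault(r.term, []).append(r.adjusted_p)
            if r.adjusted_p < alpha:
                counts[r.term] = counts.get(r.term, 0) + 1
    rows = [
        {
            "term": t,
            "n_significant": c,
            "n_mssn": total,
            "frequency": c / total,
            "mean_adjusted_p": float(np.mean(padj[t])),
        }
        for t, c in counts.items()
    ]
    table = pd.DataFrame(rows, columns=["term", "n_significant", "n_mssn", "frequency", "mean_adjusted_p"])
    if len(table):
        table = table.sort_values(
            by=["frequency", "mean_adjusted_p", "term"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return CorePathwayProfile(table=table, n_mssn=total, alpha=alpha)


def core_frequency_null(
    node_sets: Mapping[str, Iterable[str]],
    ann: AnnotationMap,
    alpha: float = 0.05,
    n_permutations: int = 100,
    rng: int | np.random.Generator | None = 0,
    min_term_size: int = 2,
) -> pd.DataFrame:
    """Permutation null for core-pathway frequencies.

    Shuffles the gene labels of the annotation map (gene -> term-set
    assignments permuted over the universe), recomputes every subnetwork's
    enrichment and the per-term frequency, and reports for each observed
    term the fraction of permutations reaching at least its observed
    frequency.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    observed = core_pathways(
        {k: enrich_subnetwork(v, ann, alpha, min_term_size) for k, v in node_sets.items()},
        alpha,
    )
    obs_freq = dict(zip(observed.table["term"], observed.table["frequency"]))
    genes = sorted(ann.universe)
    annotated = sorted(ann.gene_terms)
    exceed = {t: 0 for t in obs_freq}
    for _ in range(n_permutations):
        relabel = rng.permutation(genes)[: len(annotated)]
        shuffled = AnnotationMap(
            gene_terms={new: set(ann.gene_terms[old]) for new, old in zip(relabel, annotated)},
            universe=set(ann.universe),
        )
        perm = core_pathways(
            {k: enrich_subnetwork(v, shuffled, alpha, min_term_size) for k, v in node_sets.items()},
            alpha,
        )
        freq = dict(zip(perm.table["term"], perm.table["frequency"]))
        for t in exceed:
            if freq.get(t, 0.0) >= obs_freq[t]:
                exceed[t] += 1
    return pd.DataFrame(
        {
            "term": list(exceed),
            "observed_frequency": [obs_freq[t] for t in exceed],
            "null_p": [(exceed[t] + 1) / (n_permutations + 1) for t in exceed],
        }
    )
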