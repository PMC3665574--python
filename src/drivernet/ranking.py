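"""Combine path significance and core-pathway enrichment into a driver ranking.

A candidate driver is a mutated (seed) gene whose subnetwork both (1)
reaches the differentially expressed genes by significantly shorter-than-
random paths and (2) is enriched for at least one designated core pathway.
Seeds satisfying both criteria form tier 1, exactly one criterion tier 2,
neither tier 3; within a tier, seeds sort by their best Welch t across the
two directions (descending), ties broken by gene id.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import pandas as pd

from .enrichment import CorePathwayProfile, EnrichmentResult
from .mssn import PathStatistics

logger = logging.getLogger("drivernet")


def designate_core(
    profile: CorePathwayProfile,
    mode: str = "top_k",
    k: int = 4,
    frequency_threshold: float | None = None,
    explicit: Sequence[str] | None = None,
    annotation_terms: set[str] | None = None,
) -> set[str]:
    """Pick the core-pathway term set the driver ranking will require.

    Modes: ``top_k`` — the k most frequent significant terms;
    ``frequency_threshold`` — terms with frequency >= the threshold;
    ``explicit_list`` — a user-supplied set (e.g. externally validated
    pathways), used verbatim; terms absent from the annotation map are
    kept with a warning.
    """
    if mode == "explicit_list":
        terms = set(explicit or ())
        if annotation_terms is not None:
            unknown = terms - annotation_terms
            if unknown:
                logger.warning("explicit core terms absent from annotation map: %s", sorted(unknown))
        return terms
    if profile.table.empty and mode in ("top_k", "frequency_threshold"):
        raise ValueError("core-pathway profile is empty")
    if mode == "top_k":
        sig = profile.table[profile.table["n_significant"] >= 1]
        return set(sig["term"].head(k))
    if mode == "frequency_threshold":
        if frequency_threshold is None:
            raise ValueError("frequency_threshold mode needs a threshold")
        return set(profile.table[profile.table["frequency"] >= frequency_threshold]["term"])
    raise ValueError(f"unknown core designation mode: {mode}")


def _stat(ps: PathStatistics | None, attr: str) -> float:
    if ps is None:
        return math.nan
    return getattr(ps, attr)


def rank_drivers(
    path_stats: Mapping[str, Mapping[str, PathStatistics | None]],
    enrich: Mapping[str, Sequence[EnrichmentResult]],
    core_terms: set[str],
    alpha: float = 0.05,
    mutations: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Order candidate driver genes by the two evidence channels.

    ``path_stats`` maps seed -> {"up": PathStatistics, "down": ...} (None
    where a direction could not be built); ``enrich`` maps seed -> its
    enrichment results (both directions merged). A seed qualifies on path
    significance if either direction's empirical p < alpha, and on
    enrichment if any designated core term has adjusted p < alpha. Seeds
    missing from either input get a missing-data flag and tier 3.

    Returns a DataFrame sorted by (tier, -best_t, gene) with rank 1..n.
    """
    seeds = sorted(set(path_stats) | set(enrich))
    rows = []
    for seed in seeds:
        stats = path_stats.get(seed, {})
        up, down = stats.get("up"), stats.get("down")
        results = enrich.get(seed)
        missing = seed not in path_stats or seed not in enrich

        p_up, p_down = _stat(up, "empirical_p"), _stat(down, "empirical_p")
        path_ok = (not math.isnan(p_up) and p_up < alpha) or (
            not math.isnan(p_down) and p_down < alpha
        )
        core_hits = {}
        if results:
            for r in results:
                if r.term in core_terms and r.adjusted_p < alpha:
                    core_hits[r.term] = min(core_hits.get(r.term, 1.0), r.adjusted_p)
        core_ok = bool(core_hits)
        if missing:
            tier = 3
        elif path_ok and core_ok:
            tier = 1
        elif path_ok or core_ok:
            tier = 2
        else:
            tier = 3

        t_up, t_down = _stat(up, "t"), _stat(down, "t")
        best_t = max((v for v in (t_up, t_down) if not math.isnan(v)), default=-math.inf)
        rows.append(
            {
                "gene": seed,
                "mutations": ",".join(mutations.get(seed, ())) if mutations else "",
                "t_up": t_up,
                "t_down": t_down,
                "z_up": _stat(up, "z"),
                "z_down": _stat(down, "z"),
                "empirical_p_up": p_up,
                "empirical_p_down": p_down,
                "core_terms_hit": ",".join(sorted(core_hits)),
                "min_core_adjusted_p": min(core_hits.values()) if core_hits else math.nan,
                "path_significant": path_ok,
                "core_enriched": core_ok,
                "missing_data": missing,
                "tier": tier,
                "_best_t": best_t,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df = df.sort_values(by=["tier", "_best_t", "gene"], ascending=[True, False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = range(1, len(df) + 1)
    return df.drop(columns="_best_t")
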