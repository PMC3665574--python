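"""Orchestration of the full workflow with one config, logging and provenance.

Stage order: differential expression -> mutation-seeded subnetworks ->
per-subnetwork enrichment -> core-pathway profile -> driver ranking, with
an optional coevolution stage per mutation when an alignment is supplied.
Each stage's outputs are written (with commented provenance headers:
tool version, config hash, rng seed) before the next stage starts; a
failing stage leaves a FAILED marker naming it. A rerun with the same
config and seed reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coevolution, dge, enrichment, io, mssn, ranking

logger = logging.getLogger("drivernet")


@dataclass
class PipelineConfig:
    """Flat, fully serializable run configuration.

    Thresholds default to the study's stated values: alpha 0.05, fold
    gates 1.5 (up) and 0.67 (down), sequence-identity 0.90. The STRING
    confidence cutoff (400, medium confidence), background replicate count
    (1000) and per-method flag quantile (0.95) are configurable because no
    canonical value exists for them.
    """

    network: str = ""
    mutations: str = ""
    expression: str = ""
    design: str = ""
    annotation: str = ""
    annotation_format: str = "tsv2col"
    universe: str | None = None
    alias: str | None = None
    msa: str | None = None
    msa_reference: str | None = None
    de_up: str | None = None    # precomputed DE lists bypass the dge stage
    de_down: str | None = None
    channels_r: str | None = None
    channels_g: str | None = None

    outdir: str = "results"
    rng_seed: int = 17

    score_threshold: int = 400
    weight_scheme: str = "unit"
    alpha: float = 0.05
    fc_up: float = 1.5
    fc_down: float = 0.67
    adjust: str = "holm"
    knn_k: int = 10
    lowess_span: float = 0.4
    n_replicates: int = 1000
    prune_targets: bool = False
    min_term_size: int = 2
    core_mode: str = "top_k"
    core_top_k: int = 4
    core_frequency_threshold: float | None = None
    core_terms: list[str] = field(default_factory=list)
    identity_threshold: float = 0.90
    max_gap_fraction: float = 0.5
    flag_quantile: float = 0.95

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def validate(self) -> None:
        required = {"network": self.network, "mutations": self.mutations}
        if not (self.de_up and self.de_down):
            required.update({"expression": self.expression, "design": self.design})
        required["annotation"] = self.annotation
        for name, path in required.items():
            if not path:
                raise ValueError(f"config is missing the {name} path")
            if not Path(path).exists():
                raise ValueError(f"{name} path does not exist: {path}")
        if self.msa and self.msa_reference is None:
            logger.info("no msa_reference given; the first alignment sequence is used")


@dataclass
class RunResult:
    drivers: pd.DataFrame
    de: dge.DEGeneSets | None
    subnetworks: dict[str, dict[str, mssn.MSSN | None]]
    path_stats: dict[str, dict[str, mssn.PathStatistics | None]]
    enrichments: dict[str, list[enrichment.EnrichmentResult]]
    core_profile: enrichment.CorePathwayProfile
    core_terms: set[str]
    consensus: dict[str, coevolution.ConsensusCouplings] = field(default_factory=dict)
    warnings: dict[str, int] = field(default_factory=dict)


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    have = {getattr(h, "_drivernet_tag", None) for h in logger.handlers}
    if "stderr" not in have:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        h._drivernet_tag = "stderr"
        logger.addHandler(h)
    fh = logging.FileHandler(outdir / "run.log", mode="a")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    fh._drivernet_tag = "file"
    logger.addHandler(fh)


def _stats_row(seed: str, direction: str, sub, st) -> dict:
    if st is None:
        return {"seed": seed, "direction": direction}
    return {
        "seed": seed, "direction": direction,
        "n_targets": st.n_observed, "n_unreachable": sub.n_unreachable if sub else 0,
        "mean_observed": st.mean_observed, "mean_background": st.mean_background,
        "t": st.t, "z": st.z, "empirical_p": st.empirical_p,
    }


def _read_de_list(path: str) -> set[str]:
    return {
        io.normalize_id(line.split()[0])
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }


def run_all(config: PipelineConfig, dry_run: bool = False) -> RunResult | None:
    """Execute the full workflow; returns the ranking and all intermediates."""
    config.validate()
    plan = ["load inputs", "dge" if not (config.de_up and config.de_down) else "dge (precomputed lists)",
            "mssn", "enrichment", "core pathways", "ranking"]
    if config.msa:
        plan.append("coevolution")
    if dry_run:
        print("execution plan: " + " -> ".join(plan))
        return None

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    chash = config.config_hash
    warnings: dict[str, int] = {}
    config.to_yaml(outdir / "config.yaml")

    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    stage = "load inputs"
    try:
        alias = io.read_alias_table(config.alias) if config.alias else None
        net = io.read_string_links(config.network, config.score_threshold,
                                   config.weight_scheme, alias)
        records = io.read_gene_list(config.mutations, alias)
        seeds = io.seed_genes(records)
        universe = None
        if config.universe:
            universe = {io.normalize_id(x) for x in Path(config.universe).read_text().split()}
        ann = io.read_annotation_map(config.annotation, config.annotation_format,
                                     universe=universe, alias=alias)
        logger.info("network: %d nodes, %d edges; %d seeds; %d annotated genes",
                    len(net.nodes), net.n_edges, len(seeds), len(ann.gene_terms))

        # ---------------- DGE ----------------
        stage = "dge"
        de_sets: dge.DEGeneSets | None = None
        if config.de_up and config.de_down:
            up, down = _read_de_list(config.de_up), _read_de_list(config.de_down)
            de_sets = dge.DEGeneSets(up=up, down=down, table=pd.DataFrame())
            logger.info("precomputed DE lists: %d up, %d down", len(up), len(down))
        else:
            em = io.read_expression_matrix(
                config.expression, config.design,
                channels=(config.channels_r, config.channels_g)
                if config.channels_r and config.channels_g else None,
            )
            if em.channels is not None:
                em = dge.lowess_normalize(em, span=config.lowess_span)
            if em.values.isna().any().any():
                em = dge.knn_impute(em, k=config.knn_k)
            stats_table = dge.two_class_ttest(em)
            de_sets = dge.call_de_genes(stats_table, alpha=config.alpha,
                                        up_threshold=config.fc_up,
                                        down_threshold=config.fc_down,
                                        method=config.adjust)
            io.write_table(de_sets.table, outdir / "de_genes.tsv", chash, config.rng_seed)
            logger.info("DE calls: %d up, %d down of %d genes",
                        len(de_sets.up), len(de_sets.down), len(de_sets.table))

        # ---------------- MSSN ----------------
        stage = "mssn"
        mssn_dir = outdir / "mssn"
        mssn_dir.mkdir(exist_ok=True)
        subnets: dict[str, dict[str, mssn.MSSN | None]] = {}
        path_stats: dict[str, dict[str, mssn.PathStatistics | None]] = {}
        rows = []
        for idx, seed in enumerate(seeds):
            if seed not in net.graph:
                logger.warning("seed %s absent from the network", seed)
                warnings["seeds_not_in_network"] = warnings.get("seeds_not_in_network", 0) + 1
                continue
            rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, idx]))
            per_dir = mssn.evaluate_seed(
                net, seed, {"up": de_sets.up, "down": de_sets.down},
                n_replicates=config.n_replicates, rng=rng, prune=config.prune_targets,
            )
            subnets[seed] = {d: v[0] for d, v in per_dir.items()}
            path_stats[seed] = {d: v[1] for d, v in per_dir.items()}
            for d, (sub, st) in per_dir.items():
                rows.append(_stats_row(seed, d, sub, st))
                if sub is not None:
                    edges = pd.DataFrame(sorted(tuple(sorted(e)) for e in sub.edges),
                                         columns=["protein1", "protein2"])
                    io.write_table(edges, mssn_dir / f"{seed}_{d}_edges.tsv",
                                   chash, config.rng_seed, index=False)
                    with open(mssn_dir / f"{seed}_{d}.sif", "w") as fh:
                        for a, b in sorted(tuple(sorted(e)) for e in sub.edges):
                            fh.write(f"{a}\tpp\t{b}\n")
                    warnings["unreachable_targets"] = (
                        warnings.get("unreachable_targets", 0) + sub.n_unreachable
                    )
        io.write_table(pd.DataFrame(rows), outdir / "mssn_stats.tsv", chash,
                       config.rng_seed, index=False)

        # ---------------- Enrichment ----------------
        stage = "enrichment"
        enrich_dir = outdir / "enrich"
        enrich_dir.mkdir(exist_ok=True)
        per_direction: dict[str, list[enrichment.EnrichmentResult]] = {}
        per_seed: dict[str, list[enrichment.EnrichmentResult]] = {}
        for seed, dirs in subnets.items():
            merged: dict[str, enrichment.EnrichmentResult] = {}
            for d, sub in dirs.items():
                if sub is None:
                    continue
                results = enrichment.enrich_subnetwork(sub.nodes, ann, config.alpha,
                                                       config.min_term_size)
                per_direction[f"{seed}|{d}"] = results
                df = pd.DataFrame([asdict(r) for r in results])
                io.write_table(df, enrich_dir / f"{seed}_{d}.tsv", chash,
                               config.rng_seed, index=False)
                for r in results:
                    if r.term not in merged or r.adjusted_p < merged[r.term].adjusted_p:
                        merged[r.term] = r
            per_seed[seed] = sorted(merged.values(), key=lambda r: (r.adjusted_p, -r.k, r.term))

        stage = "core pathways"
        profile = enrichment.core_pathways(per_direction or {"_": []}, config.alpha)
        io.write_table(profile.table, outdir / "core_pathways.tsv", chash,
                       config.rng_seed, index=False)
        core_terms = ranking.designate_core(
            profile, mode=config.core_mode, k=config.core_top_k,
            frequency_threshold=config.core_frequency_threshold,
            explicit=config.core_terms, annotation_terms=ann.terms,
        ) if (not profile.table.empty or config.core_mode == "explicit_list") else set()
        logger.info("designated core pathways: %s", sorted(core_terms))

        # ---------------- Ranking ----------------
        stage = "ranking"
        mut_by_gene: dict[str, list[str]] = {}
        for r in records:
            if r.substitution:
                mut_by_gene.setdefault(r.gene, []).append(r.substitution)
        drivers = ranking.rank_drivers(path_stats, per_seed, core_terms,
                                       alpha=config.alpha, mutations=mut_by_gene)
        io.write_table(drivers, outdir / "drivers.tsv", chash, config.rng_seed, index=False)

        # ---------------- Coevolution (optional) ----------------
        consensus: dict[str, coevolution.ConsensusCouplings] = {}
        if config.msa:
            stage = "coevolution"
            msa = coevolution.read_msa(config.msa, config.msa_reference)
            coevo_dir = outdir / "coevolution"
            coevo_dir.mkdir(exist_ok=True)
            for r in records:
                if not r.substitution:
                    continue
                try:
                    mats, cons = coevolution.analyze_mutation(
                        msa, r, config.identity_threshold,
                        config.max_gap_fraction, config.flag_quantile,
                    )
                except ValueError as exc:
                    logger.warning("coevolution skipped for %s %s: %s",
                                   r.gene, r.substitution, exc)
                    warnings["coevolution_skipped"] = warnings.get("coevolution_skipped", 0) + 1
                    continue
                consensus[f"{r.gene}:{r.substitution}"] = cons
                rows = [
                    {"column": j + 1, "supporting_methods": ",".join(sorted(m))}
                    for j, m in sorted(cons.support.items())
                ]
                io.write_table(pd.DataFrame(rows, columns=["column", "supporting_methods"]),
                               coevo_dir / f"{r.gene}_{r.substitution}_consensus.tsv",
                               chash, config.rng_seed, index=False)

        summary = "; ".join(f"{k}={v}" for k, v in sorted(warnings.items())) or "none"
        logger.info("run complete; warnings: %s", summary)
        return RunResult(drivers=drivers, de=de_sets, subnetworks=subnets,
                         path_stats=path_stats, enrichments=per_seed,
                         core_profile=profile, core_terms=core_terms,
                         consensus=consensus, warnings=warnings)
    except Exception as exc:
        failed_marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        logger.error("stage %r failed: %s", stage, exc)
        raise
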