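"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the study conditions end to end with no external
downloads: a scale-free PPI backbone with planted dense modules, a
two-condition log2 expression matrix with planted fold changes, and a
star-phylogeny alignment with planted covarying column pairs. The planted
DE genes live inside the planted modules and the planted driver seeds are
wired into those modules — encoding the generative hypothesis that driver
mutations collectively re-regulate a core pathway — so the subnetwork
statistic, the enrichment profile and the final ranking all have a known
answer. Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .coevolution import AA20, MSA, write_msa
from .io import (
    AnnotationMap,
    ExpressionMatrix,
    MutationRecord,
    PPINetwork,
    write_string_links,
)


@dataclass
class SyntheticTruth:
    """What was planted, sufficient to recompute the expected answers."""

    rng_seed: int
    params: dict = field(default_factory=dict)
    driver_seeds: list[str] = field(default_factory=list)
    module_nodes: list[list[str]] = field(default_factory=list)
    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> true linear fold change
    covarying_pairs: list[list] = field(default_factory=list)  # [i, j, coupling]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


def _shed_backbone_edges(
    g: nx.Graph, v: str, n: int, rng: np.random.Generator
) -> int:
    """Remove up to n non-planted edges at v, keeping the graph connected.

    Degree compensation for planted edges: module membership rewires a
    node's connectivity instead of inflating it, so planted genes stay at
    typical degree centrality and random-destination backgrounds remain
    calibrated.
    """
    removed = 0
    nbrs = [u for u in g.neighbors(v) if not g[v][u].get("planted")]
    for u in rng.permutation(nbrs):
        if removed >= n:
            break
        if g.degree(u) <= 2 or g.degree(v) <= 2:
            continue
        data = dict(g[v][u])
        g.remove_edge(v, u)
        if nx.is_connected(g):
            removed += 1
        else:
            g.add_edge(v, u, **data)
    return removed


def generate_network(
    n_nodes: int,
    attachment_m: int = 2,
    modules: tuple[tuple[int, float], ...] = (),
    rng_seed: int = 0,
    backbone_score: float = 700.0,
    module_score: float = 900.0,
    degree_preserving: bool = True,
) -> tuple[PPINetwork, SyntheticTruth]:
    """Scale-free backbone with planted modules.

    Preferential attachment starting from a complete graph on
    ``attachment_m`` nodes, each later node attaching to ``attachment_m``
    distinct existing nodes with probability proportional to degree; the
    backbone therefore has C(m,2) + m*(n-m) edges and is connected.
    ``modules`` is a list of (size, internal_edge_prob); each module's
    node set is sampled disjointly and every internal pair is connected
    with the stated probability. With ``degree_preserving`` (default),
    every planted edge at a module node sheds one of that node's backbone
    edges (connectivity permitting), so modules rewire rather than
    centralize their members.
    """
    m = attachment_m
    if m < 1:
        raise ValueError("attachment_m must be >= 1 for a connected backbone")
    if sum(size for size, _ in modules) > n_nodes:
        raise ValueError("module sizes exceed the node count")
    rng = _rng(rng_seed)
    names = [f"G{i:04d}" for i in range(n_nodes)]

    g = nx.Graph()
    g.add_nodes_from(names[: max(m, 1)])
    for a in range(m):
        for b in range(a + 1, m):
            g.add_edge(names[a], names[b], weight=1.0, score=backbone_score)
    # endpoint urn: nodes repeated by degree
    urn: list[int] = [i for i in range(m) for _ in range(max(g.degree(names[i]), 1))]
    for i in range(m, n_nodes):
        chosen: set[int] = set()
        while len(chosen) < min(m, i):
            chosen.add(int(urn[rng.integers(len(urn))]))
        for j in chosen:
            g.add_edge(names[i], names[j], weight=1.0, score=backbone_score)
            urn.append(j)
            urn.append(i)

    module_sets: list[list[str]] = []
    available = np.arange(n_nodes)
    n_planted: dict[str, int] = {}
    for size, p_int in modules:
        pick = rng.choice(available, size=size, replace=False)
        available = np.setdiff1d(available, pick)
        members = sorted(names[i] for i in pick)
        module_sets.append(members)
        for a_i, a in enumerate(members):
            for b in members[a_i + 1:]:
                if rng.random() < p_int:
                    if g.has_edge(a, b):
                        g[a][b]["planted"] = True  # claim the backbone edge
                        continue
                    g.add_edge(a, b, weight=1.0, score=module_score, planted=True)
                    n_planted[a] = n_planted.get(a, 0) + 1
                    n_planted[b] = n_planted.get(b, 0) + 1
    if degree_preserving:
        for v in sorted(n_planted):
            _shed_backbone_edges(g, v, n_planted[v], rng)

    truth = SyntheticTruth(
        rng_seed=int(rng_seed) if not isinstance(rng_seed, np.random.Generator) else -1,
        params={"n_nodes": n_nodes, "attachment_m": m, "modules": list(map(list, modules))},
        module_nodes=module_sets,
    )
    return PPINetwork(graph=g, metadata=f"synthetic n={n_nodes} m={m}"), truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def generate_expression(
    n_genes: int,
    n_per_arm: int = 6,
    de_genes: dict[str, float] | None = None,
    sigma: float = 0.25,
    missing_rate: float = 0.0,
    rng_seed: int = 0,
    genes: list[str] | None = None,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Two-condition log2 expression with planted fold changes.

    Values are Normal(mu_gene, sigma) on the log2 scale per arm; genes in
    ``de_genes`` (gene -> linear fold change > 0) have their second-arm
    mean shifted by log2(fold change). Conditions are "control" (arm 1)
    and "case" (arm 2), so the pipeline's condition2/condition1 fold
    change recovers the planted value. Missing entries are dropped
    uniformly at random at ``missing_rate`` (< 0.5).
    """
    if not 0 <= missing_rate < 0.5:
        raise ValueError("missing_rate must be in [0, 0.5)")
    de_genes = dict(de_genes or {})
    if any(fc <= 0 for fc in de_genes.values()):
        raise ValueError("fold changes must be > 0")
    rng = _rng(rng_seed)
    if genes is None:
        genes = [f"G{i:04d}" for i in range(n_genes)]
    if len(genes) != n_genes:
        raise ValueError("genes list length must equal n_genes")
    unknown = set(de_genes) - set(genes)
    if unknown:
        raise ValueError(f"planted DE genes not in gene list: {sorted(unknown)[:5]}")

    mu = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    shift = np.array([np.log2(de_genes.get(g, 1.0)) for g in genes])
    X1 = rng.normal(mu[:, None], sigma, size=(n_genes, n_per_arm))
    X2 = rng.normal((mu + shift)[:, None], sigma, size=(n_genes, n_per_arm))
    X = np.hstack([X1, X2])
    if missing_rate > 0:
        mask = rng.random(X.shape) < missing_rate
        X = np.where(mask, np.nan, X)
    samples = [f"ctrl{i+1}" for i in range(n_per_arm)] + [f"case{i+1}" for i in range(n_per_arm)]
    design = pd.Series(
        ["control"] * n_per_arm + ["case"] * n_per_arm, index=samples, name="condition"
    )
    em = ExpressionMatrix(values=pd.DataFrame(X, index=genes, columns=samples), design=design)
    truth = SyntheticTruth(
        rng_seed=int(rng_seed) if not isinstance(rng_seed, np.random.Generator) else -1,
        params={"n_genes": n_genes, "n_per_arm": n_per_arm, "sigma": sigma,
                "missing_rate": missing_rate},
        de_genes=de_genes,
    )
    return em, truth


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def generate_msa(
    n_seqs: int,
    n_cols: int,
    planted_pairs: tuple[tuple[int, int, float], ...] = (),
    profile_concentration: float = 1.0,
    rng_seed: int = 0,
) -> tuple[MSA, SyntheticTruth]:
    """Star-phylogeny alignment with planted covarying column pairs.

    Background columns draw residues independently from per-column
    Dirichlet(concentration)-sampled profiles. For a planted pair
    (i, j, coupling), each sequence's residue at j is a fixed random
    bijection of its residue at i with probability ``coupling``, else
    drawn from j's own profile. Several pairs may share a source column i;
    a column reused as a target, or as both source and target, is an
    error. The first sequence is the gap-free reference.
    """
    targets: set[int] = set()
    sources: set[int] = set()
    for i, j, coupling in planted_pairs:
        if not (0 <= i < n_cols and 0 <= j < n_cols) or i == j:
            raise ValueError(f"planted pair ({i}, {j}) out of bounds")
        if not 0 <= coupling <= 1:
            raise ValueError("coupling must be in [0, 1]")
        if j in targets or j in sources or i in targets:
            raise ValueError(f"planted pairs overlap at column {j if j in targets else i}")
        sources.add(i)
        targets.add(j)

    rng = _rng(rng_seed)
    profiles = rng.dirichlet(np.full(20, profile_concentration), size=n_cols)
    codes = np.empty((n_seqs, n_cols), dtype=np.int64)
    for c in range(n_cols):
        codes[:, c] = rng.choice(20, size=n_seqs, p=profiles[c])
    for i, j, coupling in planted_pairs:
        mapping = rng.permutation(20)
        coupled = rng.random(n_seqs) < coupling
        codes[coupled, j] = mapping[codes[coupled, i]]

    seqs = ["".join(AA20[c] for c in row) for row in codes]
    ids = [f"seq{i:04d}" for i in range(n_seqs)]
    msa = MSA(ids=ids, seqs=seqs, reference_id=ids[0])
    truth = SyntheticTruth(
        rng_seed=int(rng_seed) if not isinstance(rng_seed, np.random.Generator) else -1,
        params={"n_seqs": n_seqs, "n_cols": n_cols,
                "profile_concentration": profile_concentration},
        covarying_pairs=[[int(i), int(j), float(c)] for i, j, c in planted_pairs],
    )
    return msa, truth


# ---------------------------------------------------------------------------
# Coherent toy study
# ---------------------------------------------------------------------------


@dataclass
class ToyStudy:
    network: PPINetwork
    expression: ExpressionMatrix
    mutations: list[MutationRecord]
    annotation: AnnotationMap
    msa: MSA
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit every input in the exact formats the readers consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "network": outdir / "network.tsv",
            "expression": outdir / "expression.tsv",
            "design": outdir / "design.tsv",
            "mutations": outdir / "mutations.tsv",
            "annotation": outdir / "annotation.tsv",
            "universe": outdir / "universe.txt",
            "msa": outdir / "family.fasta",
            "truth": outdir / "truth.json",
        }
        write_string_links(self.network, paths["network"])
        self.expression.values.to_csv(paths["expression"], sep="\t", index_label="gene")
        self.expression.design.to_csv(paths["design"], sep="\t", header=False)
        with open(paths["mutations"], "w") as fh:
            for rec in self.mutations:
                fh.write(f"{rec.gene}\t{rec.substitution or ''}\n")
        with open(paths["annotation"], "w") as fh:
            for gene in sorted(self.annotation.gene_terms):
                for term in sorted(self.annotation.gene_terms[gene]):
                    fh.write(f"{gene}\t{term}\n")
        Path(paths["universe"]).write_text("\n".join(sorted(self.annotation.universe)) + "\n")
        write_msa(self.msa, paths["msa"])
        self.truth.to_json(paths["truth"])
        return paths


def make_toy_study(
    rng_seed: int = 0,
    n_nodes: int = 500,
    module_size: int = 25,
    internal_edge_prob: float = 0.08,
    n_seeds: int = 5,
    n_de_per_module: int = 20,
    seed_wiring: int = 6,
    fold_up: float = 2.0,
    fold_down: float = 0.5,
    sigma: float = 0.25,
    n_per_arm: int = 6,
    n_decoy_terms: int = 6,
    msa_seqs: int = 200,
    msa_cols: int = 50,
    msa_coupling: float = 0.9,
) -> ToyStudy:
    """One coherent small study with full planted truth.

    A 500-node network with two planted sparse modules; five driver seeds
    outside the modules, each wired to ``seed_wiring`` members of each
    module; 20 planted up-regulated genes inside module 1 (fold 2.0) and
    20 planted down-regulated genes inside module 2 (fold 0.5); an
    annotation map where each module is one category (plus decoy
    categories over the remaining genes); and one alignment with three
    planted pairs sharing the mutated column. Deterministic in
    ``rng_seed``.

    Module planting and seed wiring are degree-compensated (each planted
    edge at a module node sheds a backbone edge), so the target genes stay
    at typical centrality and random, non-wired seeds score at the
    nominal false-positive rate while the wired seeds' direct connections
    carry the planted signal.
    """
    rng = _rng(rng_seed)
    net, net_truth = generate_network(
        n_nodes,
        attachment_m=2,
        modules=((module_size, internal_edge_prob), (module_size, internal_edge_prob)),
        rng_seed=rng,
    )
    mod1, mod2 = net_truth.module_nodes
    names = sorted(net.graph.nodes)
    non_module = [g for g in names if g not in set(mod1) | set(mod2)]
    seeds = sorted(rng.choice(non_module, size=n_seeds, replace=False).tolist())
    wired: dict[str, int] = {}
    for s in seeds:
        for module in (mod1, mod2):
            for tgt in rng.choice(module, size=seed_wiring, replace=False):
                if not net.graph.has_edge(s, tgt):
                    net.graph.add_edge(s, tgt, weight=1.0, score=900.0, planted=True)
                    wired[tgt] = wired.get(tgt, 0) + 1
    # wiring, like module planting, replaces module-node backbone edges
    for v in sorted(wired):
        _shed_backbone_edges(net.graph, v, wired[v], rng)

    up_genes = sorted(rng.choice(mod1, size=n_de_per_module, replace=False).tolist())
    down_genes = sorted(rng.choice(mod2, size=n_de_per_module, replace=False).tolist())
    de = {g: fold_up for g in up_genes} | {g: fold_down for g in down_genes}
    em, _ = generate_expression(
        n_genes=len(names), n_per_arm=n_per_arm, de_genes=de, sigma=sigma,
        missing_rate=0.0, rng_seed=rng, genes=names,
    )

    gene_terms: dict[str, set[str]] = {}
    for g in mod1:
        gene_terms.setdefault(g, set()).add("MODULE1")
    for g in mod2:
        gene_terms.setdefault(g, set()).add("MODULE2")
    decoy_pool = [g for g in non_module if g not in seeds]
    for d in range(n_decoy_terms):
        for g in rng.choice(decoy_pool, size=module_size, replace=False):
            gene_terms.setdefault(g, set()).add(f"DECOY{d+1}")
    ann = AnnotationMap(gene_terms=gene_terms, universe=set(names))

    mutated_col = msa_cols // 5
    pairs = tuple((mutated_col, mutated_col + 10 * (k + 1), msa_coupling) for k in range(3))
    msa, msa_truth = generate_msa(msa_seqs, msa_cols, pairs, rng_seed=rng)
    ref_aa = msa.reference_seq[mutated_col]
    alt = next(a for a in AA20 if a != ref_aa)
    mutations = [MutationRecord(gene=s, substitution=f"{ref_aa}{mutated_col + 1}{alt}") for s in seeds]

    truth = SyntheticTruth(
        rng_seed=int(rng_seed),
        params={
            "n_nodes": n_nodes, "module_size": module_size,
            "internal_edge_prob": internal_edge_prob, "n_seeds": n_seeds,
            "n_de_per_module": n_de_per_module, "seed_wiring": seed_wiring,
            "fold_up": fold_up, "fold_down": fold_down, "sigma": sigma,
            "n_per_arm": n_per_arm, "msa_seqs": msa_seqs, "msa_cols": msa_cols,
            "msa_coupling": msa_coupling, "mutated_column": mutated_col,
        },
        driver_seeds=seeds,
        module_nodes=[mod1, mod2],
        de_genes=de,
        covarying_pairs=msa_truth.covarying_pairs,
    )
    return ToyStudy(network=net, expression=em, mutations=mutations,
                    annotation=ann, msa=msa, truth=truth)
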