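# Methods

## Problem and model

drivernet prioritizes *driver* mutations — variants that plausibly cause a
complex phenotype through network re-regulation — among a list of mutated
genes, given a two-condition expression contrast and a protein-protein
interaction (PPI) network. The working hypothesis is epistatic: several
mutated genes collectively re-regulate a small number of *core pathways*,
and the mutations on genes whose network neighbourhoods reach the
differentially expressed (DE) genes unusually directly are the candidate
drivers. A molecular-scale module scores residue coevolution between a
mutated position and the rest of its protein family alignment.

The pipeline runs in five stages.

### 1. Differential expression

Two-channel intensities are normalized per array by LOWESS on the M-A
representation (M = log2 R/G, A = ½·log2 R·G; the returned expression
value is the residual M′ = M − lowess(M ~ A)). Missing values are imputed
by k-nearest-neighbour rows (Euclidean distance over mutually observed
samples, unweighted mean of the k nearest rows observed in the target
column; default k = 10). Per gene, a two-sided Welch t-test compares the
two conditions and the linear fold change is mean(condition 2) /
mean(condition 1), exponentiating first when values are detected as log2
(99th percentile < 30; overridable). P-values are adjusted by the Holm
step-down procedure (default; this controls the family-wise error rate —
Benjamini-Hochberg is available via `--adjust bh` for users who want FDR
control). A gene is called up-regulated when adjusted p < 0.05 AND fold
change > 1.5, down-regulated when adjusted p < 0.05 AND fold change <
0.67; the two gates are independent AND conditions, so their order is
immaterial.

### 2. Mutation-seeded subnetworks (MSSN)

For each mutated gene (seed) and each direction, the targets are the DE
genes of that direction present in the network (the seed itself is
excluded as a target: its distance of zero carries no information about
its influence on *other* genes). Exact Dijkstra shortest paths are
computed from the seed; one path per reachable target is retained, and
ties among equal-cost paths break to the lexicographically smallest node
sequence so the subnetwork is fully reproducible. Edge weights default to
1 (distance = hop count, the most literal reading of "shortest path" on a
confidence-thresholded network); `string_confidence` weighting
(1000/score) is available since the scores are loaded anyway. The default
confidence cutoff is 400 (STRING "medium confidence") and is
configurable because no canonical value exists.

The observed distance sample x₂ is compared against *background random
networks*: each of n_replicates (default 1000) replicates draws one
random source and the same number of random distinct destinations and
collects the reachable shortest distances. Three statistics are reported
per seed and direction:

* the Welch unequal-variance t of pooled background (sample 1) vs
  observed (sample 2) distances, t = (x̄₁ − x̄₂)/√(s₁²/n₁ + s₂²/n₂) with
  unbiased variances — positive t means shorter-than-random paths;
* a z-score of the observed mean against the distribution of background
  per-replicate means, z = (mean(replicate means) − x̄₂)/sd(replicate
  means);
* an empirical p — the fraction of background replicate means ≤ the
  observed mean.

The empirical p, not the t-derived tail, is used for significance calls:
distance samples are small, discrete and non-normal, and the replicate
means form the exact reference distribution for the observed mean.
Backgrounds are redrawn independently per seed and direction from a
deterministic per-seed substream of the pipeline seed. Unreachable
targets are excluded from the distance sample but counted and reported.
An optional per-target pruning mode drops targets farther than the
background median before scoring.

### 3. Overrepresentation and core pathways

Each subnetwork's genes (all retained path nodes, including the seed) are
intersected with the annotation universe and tested per category term
with the hypergeometric upper tail P(X ≥ k), computed with exact integer
combinatorics up to N = 2000 and scipy's survival function beyond. Terms
annotating fewer than 2 universe genes are skipped. Benjamini-Hochberg
adjustment runs within each subnetwork's term family (each subnetwork is
its own test family, as cluster-wise GO tools do). The universe defaults
to all genes in the annotation map and can be overridden with an explicit
universe file; ontology-graph propagation is not performed — the
annotation map is taken as given.

Terms with adjusted p < 0.05 are counted across all subnetworks; the
frequency profile (count / number of subnetworks) ranks core-pathway
candidates, ties broken by mean adjusted p. The designated core set used
for ranking comes from one of three modes: `top_k` (default, k = 4),
`frequency_threshold`, or `explicit_list` (externally validated pathways
injected verbatim). An optional permutation null (annotation labels
shuffled over the universe) attaches a frequency p-value per term.

### 4. Driver ranking

Two evidence channels per seed: path significance (empirical p < α in at
least one direction) and core-pathway enrichment (adjusted p < α for at
least one designated core term). Tier 1 = both, tier 2 = exactly one,
tier 3 = neither (or missing data). Within a tier, seeds sort by their
best Welch t across directions, descending, ties by gene id. The
tier-then-t scheme is this package's resolution of how the two criteria
combine; both t and z are always reported so either convention can be
read off the output.

### 5. Residue coevolution

The alignment is first reduced at 90% identity by greedy longest-first
clustering (pairwise identity = matches / columns where both sequences
are non-gap; the reference is always retained). Columns with > 50% gaps
are masked. Five scores are computed for every valid column pair, each
over the sequences non-gapped at both columns:

* **MI** — mutual information in nats, Σ p(x,y)·ln[p(x,y)/(p(x)p(y))].
  No average-product correction by default (offered as an opt-in).
* **OMES** — (1/N)·Σ (N_obs(x,y) − N_exp(x,y))² over the product of
  observed marginal symbols, N_exp = N_i(x)·N_j(y)/N.
* **SCA** — subalignment perturbation: restrict to sequences carrying the
  modal residue at column i (minimum subset 5; a fully conserved column
  cannot be perturbed and is masked), then
  √Σ_x ln²((f_sub(x)+1)/(f_full(x)+1)) at column j, with the
  statistical-energy constant set to 1. The +1 regularization on
  frequencies keeps empty residue classes finite and makes the score
  exactly 0 when the subset composition equals the full-alignment
  composition.
* **ELSC** — −ln of the multivariate-hypergeometric likelihood ratio of
  the observed subalignment composition n_y at column j against the most
  likely composition m_y of an unbiased draw of the same size. m_y is
  found by largest-remainder rounding of the proportional allocation
  followed by single-unit exchange hill-climbing; because ln C(N, m) is
  concave in m the local optimum is global, which guarantees the score is
  non-negative.
* **ConservationSum** — c(i) + c(j) with c = 1 − H/ln 20 (Shannon entropy
  of the column's residue frequencies, gaps excluded). The exact
  normalization of the cited conservation score is not recoverable; this
  entropy form is the package's documented choice.

SCA and ELSC are directional (perturb i, observe j); the reported matrix
entry is the mean of the defined directions so all five matrices are
exactly symmetric. Per method, a column is *flagged* for the mutated
column when its score reaches the method's 0.95 quantile over all valid
pairs (a z > 2 alternative is available; quantile 1.0 is treated as
exclusive, flagging nothing). Columns flagged by ≥ 2 of the 5 methods are
the consensus co-evolving positions, reported with their supporting
method sets and mapped to reference residue numbering. A mismatch between
the mutation's stated reference residue and the reference sequence is a
hard error.

Note that the five methods are not independent under the null: MI and
OMES are functions of the same pair count table, and SCA and ELSC share
the same subalignment construction. The null consensus rate therefore
exceeds what independent 5%-flagging would give (roughly twice, in our
simulations); consensus membership is a screen, not a calibrated p-value.

## Synthetic benchmark

The generators emulate the study conditions with planted ground truth.

* **Network**: preferential-attachment backbone (complete graph on m
  nodes, each later node attaching to m = 2 distinct nodes by degree;
  C(m,2) + m(n−m) edges, connected by construction) with planted modules
  (each internal pair connected with probability `internal_edge_prob`).
  Planting is *degree-compensated*: every planted edge at a module node
  sheds one of that node's backbone edges when connectivity allows, so
  module membership rewires a gene's neighbourhood instead of making it a
  hub. Without this, module genes become systematically more central than
  the uniform random destinations of the background model and every seed
  — planted or not — scores significant; with it, random control seeds
  score at the nominal 5% rate while the planted seeds' direct wiring
  carries the signal.
* **Expression**: log2 values Normal(μ_gene, σ) per arm with μ shifted by
  log2(fold change) for planted DE genes; missing entries dropped
  uniformly at random.
* **Alignment**: star phylogeny; per-column Dirichlet(1)-sampled residue
  profiles, independent across columns, with planted pairs whose target
  residue is a fixed random bijection of the source residue with
  probability `coupling`. Several pairs may share a source column (a
  mutated position coupled to several others); reusing a target column is
  rejected.
* **Toy study** (the packaged end-to-end fixture): 500-node network,
  two 25-gene modules at internal edge probability 0.08, five driver
  seeds wired to 6 members of each module (degree-compensated), 20
  up-regulated genes (fold 2.0) in module 1 and 20 down-regulated (fold
  0.5) in module 2, σ = 0.25, 6 arrays per condition; each module is one
  annotation category, plus six 25-gene decoy categories; one 200 × 50
  alignment with three planted pairs at the mutated column, coupling 0.9.
  These sizes keep a full benchmark replicate around one second while
  preserving the qualitative behaviour of the statistics; the defaults
  were fixed from the design considerations above and from the nominal
  calibration of the control seeds, and are recorded in every truth file.

What the benchmark does *not* emulate: realistic STRING score
distributions, degree-corrected confidence weighting, phylogenetic
correlation between sequences (star phylogeny only), alignment gaps,
array spatial artifacts, and multi-factor designs. Passing tests
demonstrate the statistics behave as designed under their own generative
assumptions, not that those assumptions hold for any particular real
dataset.

## Numerical choices and degenerate inputs

* Hypergeometric tails use exact integer combinatorics (single final
  division) for N ≤ 2000, so small-universe p-values are correctly
  rounded rationals.
* Welch t with zero pooled standard error is flagged degenerate rather
  than ±inf; a gene with zero variance in both groups gets p = 1 when
  the means agree and p = 0 (flagged) otherwise.
* Empirical p counts ties (background means ≤ observed) in the tail,
  which is mildly conservative for discrete hop-count distances.
* Equal-cost shortest paths tie-break to the lexicographically smallest
  node sequence; path reconstruction uses a relative tolerance of 1e-9
  for float weights.
* Non-positive two-channel intensities are floored at half the smallest
  positive intensity on the array before taking logs.
* All randomness flows from a single pipeline seed through named
  SeedSequence substreams (one per seed gene and direction), so outputs
  are byte-identical across reruns and independent of iteration order.

## Known limitations

* The background model draws destinations uniformly; on real scale-free
  networks where pathway genes are hubs, path significance will be
  anticonservative. A degree-matched background would be the natural
  extension.
* Core-pathway frequency has no multiplicity control across terms unless
  the optional permutation null is run.
* The coevolution consensus threshold (per-method 95% quantile) is a
  rank screen; it is not calibrated against a sequence-evolution null.
* GO true-path propagation is delegated to the annotation file supplied
  by the user.
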