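"""Data model and readers/writers for every external format the pipeline touches.

Formats
-------
* STRING-style protein links: whitespace-delimited ``protein1 protein2
  combined_score`` with scores on the 0-1000 confidence scale.
* Mutation lists: TSV, one gene per line with an optional amino-acid
  substitution token (``Rad51D<TAB>S55N``) and optional protein accession.
* Expression matrices: TSV, first column gene id, header row of sample
  labels; a separate two-column design file maps each sample to one of
  exactly two conditions. Empty fields, ``NA`` and ``NaN`` parse as missing.
* Annotation maps: two-column ``gene<TAB>term`` TSV or GAF 2.x (columns 2
  and 5, rows with a NOT qualifier skipped).

Identifier handling: every gene identifier is normalized exactly once at
load time (surrounding whitespace stripped); all later comparisons are
exact and case-sensitive. An optional alias table (two-column TSV,
``raw<TAB>canonical``) reconciles namespaces between inputs; identifiers
without an alias are kept verbatim and reported, never silently dropped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger("drivernet")

AA20 = "ACDEFGHIKLMNPQRSTVWY"

_SUBSTITUTION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


def normalize_id(raw: str) -> str:
    """Single normalization pass for gene identifiers: strip whitespace."""
    token = raw.strip()
    if not token:
        raise ValueError("empty gene identifier")
    if any(c.isspace() for c in token):
        raise ValueError(f"gene identifier contains whitespace: {raw!r}")
    return token


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class PPINetwork:
    """Undirected weighted protein-protein interaction graph.

    Nodes are normalized gene-id strings. Each edge carries ``weight``
    (the distance used by shortest-path search; strictly positive) and
    ``score`` (the 0-1000 confidence it came from, when known). No
    self-loops.
    """

    graph: nx.Graph
    metadata: str = ""

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def same_as(self, other: "PPINetwork") -> bool:
        """Graph equality: node set, edge set and per-edge weights."""
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        mine = {frozenset(e): d.get("weight") for *e, d in self.graph.edges(data=True)}
        theirs = {frozenset(e): d.get("weight") for *e, d in other.graph.edges(data=True)}
        return mine == theirs


@dataclass(frozen=True)
class MutationRecord:
    """One mutated gene with an optional amino-acid substitution.

    ``substitution`` has the form ``<ref><position><alt>`` with single-letter
    codes, e.g. ``S55N``; ``None`` for a bare gene line.
    """

    gene: str
    substitution: str | None = None
    accession: str | None = None

    @property
    def ref_aa(self) -> str | None:
        return self.substitution[0] if self.substitution else None

    @property
    def position(self) -> int | None:
        return int(self.substitution[1:-1]) if self.substitution else None

    @property
    def alt_aa(self) -> str | None:
        return self.substitution[-1] if self.substitution else None


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values under a two-condition design.

    ``values`` may contain NaN (missing spots). ``design`` maps each sample
    label to its condition; exactly two conditions. For two-channel arrays,
    ``channels`` holds the per-spot (R, G) intensity frames aligned with
    ``values``.
    """

    values: pd.DataFrame
    design: pd.Series
    channels: tuple[pd.DataFrame, pd.DataFrame] | None = None

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"samples absent from design: {missing}")
        conds = self.conditions
        if len(conds) != 2:
            raise ValueError(f"design must have exactly 2 conditions, got {conds}")

    @property
    def conditions(self) -> list[str]:
        """The two condition labels, in order of first appearance."""
        seen: list[str] = []
        for s in self.values.columns:
            c = self.design[s]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.design[s] == condition]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


@dataclass
class AnnotationMap:
    """Gene -> category-term map plus the enrichment universe.

    Every annotated gene belongs to the universe. ``term_names`` maps term
    ids to human-readable names where known.
    """

    gene_terms: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set(self.gene_terms)
        stray = set(self.gene_terms) - self.universe
        if stray:
            raise ValueError(f"annotated genes outside the universe: {sorted(stray)[:5]}")

    @property
    def terms(self) -> set[str]:
        return {t for ts in self.gene_terms.values() for t in ts}

    def genes_for(self, term: str) -> set[str]:
        return {g for g, ts in self.gene_terms.items() if term in ts}

    def term_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for ts in self.gene_terms.values():
            for t in ts:
                sizes[t] = sizes.get(t, 0) + 1
        return sizes


# ---------------------------------------------------------------------------
# Alias table
# ---------------------------------------------------------------------------


def read_alias_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping raw identifiers to canonical ones."""
    alias: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise ValueError(f"alias table line {lineno}: expected 2 columns")
        alias[normalize_id(parts[0])] = normalize_id(parts[1])
    return alias


def apply_aliases(ids: Iterable[str], alias: Mapping[str, str] | None) -> tuple[list[str], list[str]]:
    """Map ids through the alias table.

    Returns (mapped ids, ids that had no alias and were kept verbatim).
    """
    if not alias:
        ids = list(ids)
        return ids, []
    mapped, unmatched = [], []
    for i in ids:
        if i in alias:
            mapped.append(alias[i])
        else:
            mapped.append(i)
            unmatched.append(i)
    if unmatched:
        logger.warning("%d identifiers had no alias and were kept verbatim", len(unmatched))
    return mapped, unmatched


# ---------------------------------------------------------------------------
# STRING protein links
# ---------------------------------------------------------------------------


def read_string_links(
    path: str | Path,
    score_threshold: int = 400,
    weight_scheme: str = "unit",
    alias: Mapping[str, str] | None = None,
) -> PPINetwork:
    """Load a STRING-style protein-links file into a PPINetwork.

    Edges with combined_score below ``score_threshold`` are dropped;
    duplicate and reciprocal lines are merged keeping the maximum score.
    ``weight_scheme``:

    * ``unit`` — every kept edge gets weight 1 (distance = hop count);
    * ``string_confidence`` — weight = 1000/score (higher confidence,
      shorter distance).
    """
    if weight_scheme not in ("unit", "string_confidence"):
        raise ValueError(f"unknown weight_scheme: {weight_scheme}")
    if not 0 <= score_threshold <= 1000:
        raise ValueError(f"score_threshold outside [0, 1000]: {score_threshold}")

    best: dict[frozenset, float] = {}
    n_self = 0
    lines = Path(path).read_text().splitlines()
    first_data = True
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}: line {lineno}: expected >= 3 columns")
        if first_data:
            first_data = False
            try:
                float(parts[2])
            except ValueError:
                continue  # header line
        try:
            score = float(parts[2])
        except ValueError:
            raise ValueError(f"{path}: line {lineno}: malformed score {parts[2]!r}") from None
        if not 0 <= score <= 1000:
            raise ValueError(f"{path}: line {lineno}: score {score} outside [0, 1000]")
        a, b = normalize_id(parts[0]), normalize_id(parts[1])
        if alias:
            a, b = alias.get(a, a), alias.get(b, b)
        if a == b:
            n_self += 1
            continue
        key = frozenset((a, b))
        if score > best.get(key, -1.0):
            best[key] = score

    if n_self:
        logger.warning("dropped %d self-loop lines", n_self)

    g = nx.Graph()
    for key, score in best.items():
        if score < score_threshold:
            continue
        a, b = sorted(key)
        weight = 1.0 if weight_scheme == "unit" else 1000.0 / score
        g.add_edge(a, b, weight=weight, score=score)
    if g.number_of_edges() == 0:
        logger.warning("network from %s is empty after thresholding", path)
    return PPINetwork(graph=g, metadata=f"{path} threshold={score_threshold} scheme={weight_scheme}")


def write_string_links(net: PPINetwork, path: str | Path) -> None:
    """Write the canonical protein-links TSV (one line per undirected edge)."""
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b, data in sorted(net.graph.edges(data=True)):
            a, b = sorted((a, b))
            score = data.get("score", 1000.0)
            fh.write(f"{a}\t{b}\t{score:g}\n")


# ---------------------------------------------------------------------------
# Mutation lists
# ---------------------------------------------------------------------------


def parse_substitution(token: str) -> str:
    m = _SUBSTITUTION_RE.match(token.strip())
    if not m:
        raise ValueError(f"malformed substitution token: {token!r}")
    ref, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    if ref not in AA20 or alt not in AA20:
        raise ValueError(f"substitution {token!r}: not single-letter amino-acid codes")
    if ref == alt:
        raise ValueError(f"substitution {token!r}: reference and alternate are identical")
    if pos < 1:
        raise ValueError(f"substitution {token!r}: position must be >= 1")
    return f"{ref}{pos}{alt}"


def read_gene_list(path: str | Path, alias: Mapping[str, str] | None = None) -> list[MutationRecord]:
    """Read a mutated-gene list (gene, optional substitution, optional accession).

    Order-preserving; exact duplicate records are collapsed with a warning.
    Bare gene lines yield records with ``substitution=None``.
    """
    records: list[MutationRecord] = []
    seen: set[tuple] = set()
    n_dup = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        gene = normalize_id(parts[0])
        if alias:
            gene = alias.get(gene, gene)
        sub = parse_substitution(parts[1]) if len(parts) > 1 and parts[1].strip() else None
        acc = normalize_id(parts[2]) if len(parts) > 2 and parts[2].strip() else None
        rec = MutationRecord(gene=gene, substitution=sub, accession=acc)
        key = (rec.gene, rec.substitution, rec.accession)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        records.append(rec)
    if n_dup:
        logger.warning("collapsed %d duplicate mutation records", n_dup)
    return records


def seed_genes(records: Sequence[MutationRecord]) -> list[str]:
    """Unique seed genes from a mutation list, order preserved."""
    out: list[str] = []
    for r in records:
        if r.gene not in out:
            out.append(r.gene)
    return out


# ---------------------------------------------------------------------------
# Annotation maps
# ---------------------------------------------------------------------------


def read_annotation_map(
    path: str | Path,
    fmt: str = "tsv2col",
    universe: Iterable[str] | None = None,
    alias: Mapping[str, str] | None = None,
) -> AnnotationMap:
    """Load a gene -> category map from two-column TSV or GAF 2.x.

    GAF rows use column 2 (DB object id) and column 5 (GO id); rows whose
    qualifier contains ``NOT`` are skipped; data rows with fewer than 15
    columns are an error. The universe defaults to all genes in the map.
    """
    gene_terms: dict[str, set[str]] = {}

    def add(gene: str, term: str) -> None:
        gene = normalize_id(gene)
        if alias:
            gene = alias.get(gene, gene)
        term = term.strip()
        if not term:
            raise ValueError(f"empty term for gene {gene}")
        gene_terms.setdefault(gene, set()).add(term)

    lines = Path(path).read_text().splitlines()
    if fmt == "tsv2col":
        for lineno, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected gene<TAB>term")
            add(parts[0], parts[1])
    elif fmt == "gaf":
        for lineno, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            parts = line.split("\t")
            if len(parts) < 15:
                raise ValueError(f"{path}: line {lineno}: GAF data row has {len(parts)} < 15 columns")
            qualifier = parts[3]
            if "NOT" in qualifier.split("|"):
                continue
            add(parts[1], parts[4])
    else:
        raise ValueError(f"unknown annotation format: {fmt}")

    uni = set(universe) if universe is not None else set(gene_terms)
    uni |= set(gene_terms)  # annotated genes always eligible
    return AnnotationMap(gene_terms=gene_terms, universe=uni)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

_NA_TOKENS = ["", "NA", "NaN", "nan"]


def read_design(path: str | Path) -> pd.Series:
    """Two-column TSV sample -> condition."""
    rows = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}: line {lineno}: expected sample<TAB>condition")
        rows[parts[0].strip()] = parts[1].strip()
    return pd.Series(rows, name="condition")


def read_expression_matrix(
    path: str | Path,
    design_path: str | Path,
    channels: tuple[str | Path, str | Path] | None = None,
) -> ExpressionMatrix:
    """Expression TSV (first column gene id, header = sample labels) + design.

    ``channels`` optionally names (R, G) intensity TSVs of the same shape
    for two-channel arrays.
    """
    values = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                         na_values=_NA_TOKENS, keep_default_na=False)
    values.index = [normalize_id(str(g)) for g in values.index]
    design = read_design(design_path)
    chan = None
    if channels is not None:
        r = pd.read_csv(channels[0], sep="\t", index_col=0, comment="#",
                        na_values=_NA_TOKENS, keep_default_na=False)
        g = pd.read_csv(channels[1], sep="\t", index_col=0, comment="#",
                        na_values=_NA_TOKENS, keep_default_na=False)
        chan = (r, g)
    return ExpressionMatrix(values=values, design=design, channels=chan)


# ---------------------------------------------------------------------------
# Output tables with provenance headers
# ---------------------------------------------------------------------------


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config_hash: str | None = None,
    rng_seed: int | None = None,
    index: bool = True,
    comments: Sequence[str] = (),
) -> None:
    """Write a TSV with commented provenance header lines."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# drivernet {__version__}\n")
        if config_hash is not None:
            fh.write(f"# config_hash: {config_hash}\n")
        if rng_seed is not None:
            fh.write(f"# rng_seed: {rng_seed}\n")
        for c in comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index=index)
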