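"""Residue coevolution between a mutated alignment column and all others.

Five per-column-pair scores are computed on a redundancy-reduced multiple
sequence alignment and a column is called co-evolving with the mutated
column when at least two methods flag it (each method flags its own top
(1 - flag_quantile) score fraction):

* MI   — mutual information of the two columns' residue distributions,
  natural-log units, frequencies from sequences non-gapped at both columns.
* OMES — observed-minus-expected-squared: mean over the marginal symbol
  product of (N_obs - N_exp)^2 / N_valid.
* SCA  — subalignment perturbation: restrict to sequences carrying the
  modal residue at column i and measure the composition shift at column j,
  sqrt(sum_x ln^2((f_sub(x)+1)/(f_full(x)+1))) (statistical-energy
  constant 1; the +1 on frequencies regularizes empty classes).
* ELSC — explicit likelihood of subset covariation: -ln of the multivariate
  hypergeometric likelihood ratio of the observed subalignment composition
  at column j against the most likely composition an unbiased draw of the
  same size would give.
* ConservationSum — c(i) + c(j) with c = 1 - H/ln(20), H the Shannon
  entropy (nats) of the column's residue frequencies, gaps excluded.

SCA and ELSC are directional (perturb at i, observe at j); their matrices
are symmetrized by averaging the defined directions. Columns with more
than 50% gaps are masked throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .io import AA20, MutationRecord

GAP_CODE = 20
_AA_INDEX = {aa: i for i, aa in enumerate(AA20)}

METHODS = ("SCA", "ELSC", "OMES", "MI", "ConservationSum")


# ---------------------------------------------------------------------------
# Alignment container
# ---------------------------------------------------------------------------


@dataclass
class MSA:
    """Aligned sequences with a designated reference.

    Columns are 0-based internally; residue numbers on the reference are
    1-based over its ungapped positions.
    """

    ids: list[str]
    seqs: list[str]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.seqs:
            raise ValueError("empty alignment")
        L = len(self.seqs[0])
        if any(len(s) != L for s in self.seqs):
            raise ValueError("aligned sequences differ in length")
        if self.reference_id not in self.ids:
            raise ValueError(f"reference {self.reference_id!r} not in alignment")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def n_seqs(self) -> int:
        return len(self.seqs)

    @property
    def n_cols(self) -> int:
        return len(self.seqs[0])

    @property
    def reference_seq(self) -> str:
        return self.seqs[self.ids.index(self.reference_id)]

    def codes(self) -> np.ndarray:
        """(n_seqs, n_cols) uint8 matrix; 0-19 amino acids, 20 gap/unknown."""
        arr = np.full((self.n_seqs, self.n_cols), GAP_CODE, dtype=np.uint8)
        for r, s in enumerate(self.seqs):
            for c, ch in enumerate(s):
                arr[r, c] = _AA_INDEX.get(ch, GAP_CODE)
        return arr

    def reference_positions(self) -> dict[int, int]:
        """Column index (0-based) -> reference residue number (1-based)."""
        pos, out = 0, {}
        for c, ch in enumerate(self.reference_seq):
            if ch in _AA_INDEX:
                pos += 1
                out[c] = pos
        return out

    def column_of_residue(self, residue_number: int) -> int:
        for c, p in self.reference_positions().items():
            if p == residue_number:
                return c
        raise ValueError(f"reference has no residue {residue_number}")


def read_msa(path: str | Path, reference_id: str | None = None) -> MSA:
    """Read a FASTA alignment; the first record is the default reference."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    ids = [r.id for r in records]
    return MSA(ids=ids, seqs=[str(r.seq) for r in records],
               reference_id=reference_id or ids[0])


def write_msa(msa: MSA, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, s in zip(msa.ids, msa.seqs):
            fh.write(f">{i}\n{s}\n")


def map_mutation_to_column(msa: MSA, mutation: MutationRecord) -> int:
    """Alignment column (0-based) of the mutation's reference residue.

    A mismatch between the mutation's reference amino acid and the
    reference sequence at that position is a hard error.
    """
    if mutation.substitution is None:
        raise ValueError(f"mutation record for {mutation.gene} has no substitution")
    col = msa.column_of_residue(mutation.position)
    found = msa.reference_seq[col]
    if found != mutation.ref_aa:
        raise ValueError(
            f"reference residue mismatch at position {mutation.position}: "
            f"alignment has {found}, mutation says {mutation.ref_aa}"
        )
    return col


# ---------------------------------------------------------------------------
# Redundancy removal
# ---------------------------------------------------------------------------


def pairwise_identity(a: str, b: str) -> float:
    """Matches over aligned columns where both sequences are non-gap."""
    both = matches = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in _AA_INDEX and y in _AA_INDEX:
            both += 1
            if x == y:
                matches += 1
    return matches / both if both else 0.0


def remove_redundancy(msa: MSA, identity_threshold: float = 0.90) -> MSA:
    """Greedy longest-first clustering at the identity threshold.

    Sequences are visited reference-first, then by ungapped length
    descending (stable); each joins the first existing representative it
    matches at >= threshold identity, otherwise founds a new cluster.
    Representatives are returned in original alignment order; the
    reference is always retained.
    """
    ref_idx = msa.ids.index(msa.reference_id)
    order = sorted(
        range(msa.n_seqs),
        key=lambda i: (i != ref_idx, -sum(ch in _AA_INDEX for ch in msa.seqs[i]), i),
    )
    reps: list[int] = []
    for i in order:
        if not any(pairwise_identity(msa.seqs[i], msa.seqs[r]) >= identity_threshold for r in reps):
            reps.append(i)
    keep = sorted(reps)
    return MSA(ids=[msa.ids[i] for i in keep], seqs=[msa.seqs[i] for i in keep],
               reference_id=msa.reference_id)


# ---------------------------------------------------------------------------
# Column masking and count helpers
# ---------------------------------------------------------------------------


def valid_columns(msa: MSA, max_gap_fraction: float = 0.5) -> np.ndarray:
    """Boolean mask of columns with <= max_gap_fraction gaps."""
    codes = msa.codes()
    return (codes == GAP_CODE).mean(axis=0) <= max_gap_fraction


def _column_counts(codes: np.ndarray, col: int) -> np.ndarray:
    c = codes[:, col]
    return np.bincount(c[c != GAP_CODE], minlength=20)[:20]


def _pair_table(codes: np.ndarray, i: int, j: int) -> np.ndarray:
    """20x20 joint count table over rows non-gapped at both columns."""
    rows = (codes[:, i] != GAP_CODE) & (codes[:, j] != GAP_CODE)
    ci, cj = codes[rows, i].astype(int), codes[rows, j].astype(int)
    table = np.zeros((20, 20), dtype=np.int64)
    np.add.at(table, (ci, cj), 1)
    return table


# ---------------------------------------------------------------------------
# Per-pair scores
# ---------------------------------------------------------------------------


def mutual_information(msa: MSA, i: int, j: int, codes: np.ndarray | None = None) -> float:
    """MI (nats) of columns i and j over sequences non-gapped at both."""
    codes = msa.codes() if codes is None else codes
    table = _pair_table(codes, i, j)
    n = table.sum()
    if n < 2:
        return math.nan
    p = table / n
    pi, pj = p.sum(axis=1), p.sum(axis=0)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / np.outer(pi, pj)[nz])))


def omes(msa: MSA, i: int, j: int, codes: np.ndarray | None = None) -> float:
    """Observed-minus-expected-squared over the marginal symbol product."""
    codes = msa.codes() if codes is None else codes
    table = _pair_table(codes, i, j)
    n = table.sum()
    if n < 2:
        return math.nan
    ni, nj = table.sum(axis=1), table.sum(axis=0)
    expected = np.outer(ni, nj) / n
    cells = np.outer(ni > 0, nj > 0)
    return float(np.sum((table[cells] - expected[cells]) ** 2) / n)


def column_conservation(msa: MSA, col: int, codes: np.ndarray | None = None) -> float:
    """c(col) = 1 - H/ln(20); 1 for a constant column, 0 for uniform-over-20."""
    codes = msa.codes() if codes is None else codes
    counts = _column_counts(codes, col)
    n = counts.sum()
    if n < 2:
        return math.nan
    f = counts[counts > 0] / n
    H = float(-np.sum(f * np.log(f)))
    return 1.0 - H / math.log(20.0)


def conservation_sum(msa: MSA, i: int, j: int, codes: np.ndarray | None = None) -> float:
    codes = msa.codes() if codes is None else codes
    return column_conservation(msa, i, codes) + column_conservation(msa, j, codes)


def _subalignment_rows(codes: np.ndarray, i: int, min_subset: int) -> np.ndarray | None:
    """Rows carrying the modal residue at column i, or None when masked.

    Masked when the subset is smaller than ``min_subset`` or equals the
    whole non-gapped column (a fully conserved column cannot be perturbed).
    Modal ties break to the alphabetically smallest residue.
    """
    counts = _column_counts(codes, i)
    n_valid = counts.sum()
    if n_valid == 0:
        return None
    modal = int(np.argmax(counts))  # ties -> smallest code = alphabetical
    rows = np.flatnonzero(codes[:, i] == modal)
    if rows.size < min_subset or rows.size == n_valid:
        return None
    return rows


def sca_perturbation(msa: MSA, i: int, j: int, min_subset: int = 5,
                     codes: np.ndarray | None = None) -> float:
    """SCA: composition shift at column j under the column-i perturbation."""
    codes = msa.codes() if codes is None else codes
    rows = _subalignment_rows(codes, i, min_subset)
    if rows is None:
        return math.nan
    full = _column_counts(codes, j)
    sub = _column_counts(codes[rows], j)
    if full.sum() < 2 or sub.sum() < 1:
        return math.nan
    f_full = full / full.sum()
    f_sub = sub / sub.sum()
    terms = np.log((f_sub + 1.0) / (f_full + 1.0))
    return float(math.sqrt(np.sum(terms**2)))


def _ln_comb(n: int, k: int) -> float:
    return math.log(math.comb(n, k))


def _mode_composition(N: np.ndarray, n_tot: int) -> np.ndarray:
    """Most likely multivariate-hypergeometric composition summing to n_tot.

    Starts from largest-remainder rounding of the proportional allocation
    and hill-climbs single-unit exchanges; log C(N_y, m) is concave in m,
    so the local optimum is global.
    """
    N_tot = int(N.sum())
    ideal = n_tot * N / N_tot
    m = np.floor(ideal).astype(int)
    short = n_tot - int(m.sum())
    if short > 0:
        frac = ideal - m
        frac[m >= N] = -1.0  # cannot exceed the class size
        for idx in np.argsort(-frac, kind="stable")[:short]:
            m[idx] += 1
    improved = True
    while improved:
        improved = False
        gain_up = np.full(len(N), -np.inf)
        ok_up = m < N
        gain_up[ok_up] = [_ln_comb(N[y], m[y] + 1) - _ln_comb(N[y], m[y]) for y in np.flatnonzero(ok_up)]
        gain_dn = np.full(len(N), -np.inf)
        ok_dn = m > 0
        gain_dn[ok_dn] = [_ln_comb(N[y], m[y] - 1) - _ln_comb(N[y], m[y]) for y in np.flatnonzero(ok_dn)]
        a, b = int(np.argmax(gain_up)), int(np.argmax(gain_dn))
        if a != b and gain_up[a] + gain_dn[b] > 1e-12:
            m[a] += 1
            m[b] -= 1
            improved = True
    return m


def elsc(msa: MSA, i: int, j: int, min_subset: int = 5,
         codes: np.ndarray | None = None) -> float:
    """ELSC: likelihood-ratio surprise of the subalignment composition at j."""
    codes = msa.codes() if codes is None else codes
    rows = _subalignment_rows(codes, i, min_subset)
    if rows is None:
        return math.nan
    N = _column_counts(codes, j)
    n = _column_counts(codes[rows], j)
    n_tot = int(n.sum())
    if N.sum() < 2 or n_tot < 1:
        return math.nan
    present = N > 0
    m = np.zeros_like(N)
    m[present] = _mode_composition(N[present], n_tot)
    score = sum(_ln_comb(int(Ny), int(my)) - _ln_comb(int(Ny), int(ny))
                for Ny, ny, my in zip(N[present], n[present], m[present]))
    return float(score)


# ---------------------------------------------------------------------------
# Full matrices and consensus
# ---------------------------------------------------------------------------


@dataclass
class CouplingMatrix:
    """Symmetric per-method column-pair scores with a validity mask."""

    method: str
    scores: np.ndarray = field(repr=False)  # L x L, NaN where undefined
    valid: np.ndarray = field(repr=False)   # boolean column mask

    def pair_scores(self) -> np.ndarray:
        """Finite upper-triangle scores over valid column pairs."""
        L = self.scores.shape[0]
        iu = np.triu_indices(L, k=1)
        vals = self.scores[iu]
        return vals[np.isfinite(vals)]


@dataclass
class ConsensusCouplings:
    """Columns coupled to the mutated column by >= 2 methods."""

    mutated_column: int
    support: dict[int, set[str]]          # column -> supporting methods (|.| >= 2)
    flagged: dict[str, set[int]]          # per-method flagged columns
    thresholds: dict[str, float]
    flag_quantile: float

    def reference_residues(self, msa: MSA) -> dict[int, int]:
        """Consensus columns mapped to reference residue numbers (where ungapped)."""
        pos = msa.reference_positions()
        return {c: pos[c] for c in self.support if c in pos}


def coupling_matrix(
    msa: MSA,
    method: str,
    max_gap_fraction: float = 0.5,
    min_subset: int = 5,
    codes: np.ndarray | None = None,
) -> CouplingMatrix:
    """L x L symmetric score matrix for one method.

    MI, OMES and ConservationSum are symmetric by construction; SCA and
    ELSC entries are the mean of the defined perturbation directions.
    Masked columns (gap fraction over the threshold) carry no scores.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method: {method}")
    codes = msa.codes() if codes is None else codes
    L = msa.n_cols
    valid = valid_columns(msa, max_gap_fraction)
    scores = np.full((L, L), np.nan)
    cols = np.flatnonzero(valid)

    if method == "ConservationSum":
        c = {int(k): column_conservation(msa, int(k), codes) for k in cols}
        for a_idx, a in enumerate(cols):
            for b in cols[a_idx + 1:]:
                scores[a, b] = scores[b, a] = c[int(a)] + c[int(b)]
        return CouplingMatrix(method, scores, valid)

    for a_idx, a in enumerate(cols):
        for b in cols[a_idx + 1:]:
            a, b = int(a), int(b)
            if method == "MI":
                s = mutual_information(msa, a, b, codes)
            elif method == "OMES":
                s = omes(msa, a, b, codes)
            elif method == "SCA":
                fwd = sca_perturbation(msa, a, b, min_subset, codes)
                rev = sca_perturbation(msa, b, a, min_subset, codes)
                defined = [v for v in (fwd, rev) if not math.isnan(v)]
                s = float(np.mean(defined)) if defined else math.nan
            else:  # ELSC
                fwd = elsc(msa, a, b, min_subset, codes)
                rev = elsc(msa, b, a, min_subset, codes)
                defined = [v for v in (fwd, rev) if not math.isnan(v)]
                s = float(np.mean(defined)) if defined else math.nan
            scores[a, b] = scores[b, a] = s
    return CouplingMatrix(method, scores, valid)


def consensus_couplings(
    matrices: Sequence[CouplingMatrix] | Mapping[str, CouplingMatrix],
    mutated_column: int,
    flag_quantile: float = 0.95,
) -> ConsensusCouplings:
    """Columns flagged for the mutated column by at least two methods.

    Per method, a column j is flagged when score(i, j) reaches that
    method's ``flag_quantile`` over all its valid pairs.
    """
    if isinstance(matrices, Mapping):
        matrices = list(matrices.values())
    if not matrices:
        raise ValueError("need at least one coupling matrix")
    i = mutated_column
    for m in matrices:
        if i >= m.scores.shape[0] or not m.valid[i]:
            raise ValueError(
                f"mutated column {i} is masked for {m.method} (gap content or out of range)"
            )

    flagged: dict[str, set[int]] = {}
    thresholds: dict[str, float] = {}
    for m in matrices:
        pool = m.pair_scores()
        if pool.size == 0 or flag_quantile >= 1.0:
            # quantile 1.0 is exclusive: nothing exceeds the maximum
            flagged[m.method] = set()
            thresholds[m.method] = math.inf if flag_quantile >= 1.0 else math.nan
            continue
        thr = float(np.quantile(pool, flag_quantile))
        thresholds[m.method] = thr
        row = m.scores[i]
        flagged[m.method] = {int(j) for j in np.flatnonzero(np.isfinite(row) & (row >= thr))}

    support: dict[int, set[str]] = {}
    for method, cols in flagged.items():
        for j in cols:
            support.setdefault(j, set()).add(method)
    support = {j: s for j, s in support.items() if len(s) >= 2}
    return ConsensusCouplings(mutated_column=i, support=support, flagged=flagged,
                              thresholds=thresholds, flag_quantile=flag_quantile)


def analyze_mutation(
    msa: MSA,
    mutation: MutationRecord,
    identity_threshold: float = 0.90,
    max_gap_fraction: float = 0.5,
    flag_quantile: float = 0.95,
    min_subset: int = 5,
) -> tuple[dict[str, CouplingMatrix], ConsensusCouplings]:
    """End-to-end coevolution call for one mutation on one alignment."""
    msa = remove_redundancy(msa, identity_threshold)
    col = map_mutation_to_column(msa, mutation)
    codes = msa.codes()
    mats = {
        name: coupling_matrix(msa, name, max_gap_fraction, min_subset, codes)
        for name in METHODS
    }
    cons = consensus_couplings(mats, col, flag_quantile)
    return mats, cons
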