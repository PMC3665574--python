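"""Five coupling scores, redundancy removal and the two-method consensus."""

import math
from collections import Counter

import numpy as np
import pytest

from drivernet import coevolution as co
from drivernet.io import MutationRecord
from drivernet.synthetic import generate_msa


def msa_from_cols(*cols, ref="s0"):
    """Build an MSA from per-column strings (one char per sequence)."""
    n = len(cols[0])
    seqs = ["".join(col[i] for col in cols) for i in range(n)]
    return co.MSA(ids=[f"s{i}" for i in range(n)], seqs=seqs, reference_id=ref)


def random_msa(rng, n_seqs, n_cols):
    seqs = ["".join(rng.choice(list(co.AA20), size=n_cols)) for _ in range(n_seqs)]
    return co.MSA(ids=[f"s{i}" for i in range(n_seqs)], seqs=seqs, reference_id="s0")


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation's count helpers)
# ---------------------------------------------------------------------------


def brute_mi(msa, i, j):
    pairs = [(s[i], s[j]) for s in msa.seqs if s[i] in co.AA20 and s[j] in co.AA20]
    n = len(pairs)
    joint = Counter(pairs)
    pi = Counter(p[0] for p in pairs)
    pj = Counter(p[1] for p in pairs)
    return sum(
        (c / n) * math.log((c / n) / ((pi[x] / n) * (pj[y] / n)))
        for (x, y), c in joint.items()
    )


def brute_omes(msa, i, j):
    pairs = [(s[i], s[j]) for s in msa.seqs if s[i] in co.AA20 and s[j] in co.AA20]
    n = len(pairs)
    joint = Counter(pairs)
    ni = Counter(p[0] for p in pairs)
    nj = Counter(p[1] for p in pairs)
    return sum(
        (joint.get((x, y), 0) - ni[x] * nj[y] / n) ** 2 for x in ni for y in nj
    ) / n


def brute_conservation(msa, col):
    res = [s[col] for s in msa.seqs if s[col] in co.AA20]
    n = len(res)
    H = -sum((c / n) * math.log(c / n) for c in Counter(res).values())
    return 1 - H / math.log(20)


class TestMutualInformation:
    def test_constant_column_gives_zero(self):
        msa = msa_from_cols("AAAA", "ACDF")
        assert co.mutual_information(msa, 0, 1) == pytest.approx(0.0)

    def test_perfectly_correlated_half_half_is_ln2(self):
        msa = msa_from_cols("AACC", "CCAA")
        assert co.mutual_information(msa, 0, 1) == pytest.approx(math.log(2))

    def test_symmetry(self, rng):
        msa = random_msa(rng, 12, 6)
        for i in range(5):
            assert co.mutual_information(msa, i, i + 1) == pytest.approx(
                co.mutual_information(msa, i + 1, i)
            )


class TestOmes:
    def test_factorized_counts_give_zero(self):
        msa = msa_from_cols("AACC", "ACAC")
        assert co.omes(msa, 0, 1) == pytest.approx(0.0)

    def test_hand_counted_two_by_two(self):
        # (A,A),(A,A),(C,C),(C,C): every cell deviates by 1 from expected 1
        msa = msa_from_cols("AACC", "AACC")
        assert co.omes(msa, 0, 1) == pytest.approx(1.0)

    def test_doubling_sequences_doubles_score(self):
        msa = msa_from_cols("AACC", "AACC")
        doubled = msa_from_cols("AACCAACC", "AACCAACC")
        assert co.omes(doubled, 0, 1) == pytest.approx(2 * co.omes(msa, 0, 1))
        assert co.omes(doubled, 0, 1) == pytest.approx(brute_omes(doubled, 0, 1))


class TestConservationSum:
    def test_two_conserved_columns_sum_to_two(self):
        msa = msa_from_cols("AAAA", "CCCC")
        assert co.conservation_sum(msa, 0, 1) == pytest.approx(2.0)

    def test_uniform_over_twenty_contributes_zero(self):
        msa = msa_from_cols(co.AA20, co.AA20[::-1])
        assert co.column_conservation(msa, 0) == pytest.approx(0.0)

    def test_half_half_closed_form(self):
        msa = msa_from_cols("AACC", "AAAA")
        expected = 1 - math.log(2) / math.log(20)
        assert co.column_conservation(msa, 0) == pytest.approx(expected)
        assert expected == pytest.approx(0.7687, abs=1e-4)


class TestSca:
    def test_identical_composition_scores_zero(self):
        # modal subset at col 0 (A-rows) sees the same col-1 composition as full
        msa = msa_from_cols("AAACCC", "GHIGHI")
        assert co.sca_perturbation(msa, 0, 1, min_subset=2) == pytest.approx(0.0)

    def test_fully_conserved_column_masked(self):
        msa = msa_from_cols("AAAA", "ACDF")
        assert math.isnan(co.sca_perturbation(msa, 0, 1, min_subset=2))

    def test_invariant_to_sequence_order(self, rng):
        msa = random_msa(rng, 15, 5)
        perm = rng.permutation(15)
        shuffled = co.MSA(ids=[msa.ids[i] for i in perm],
                          seqs=[msa.seqs[i] for i in perm], reference_id="s0")
        for i, j in [(0, 1), (2, 4)]:
            a = co.sca_perturbation(msa, i, j, min_subset=2)
            b = co.sca_perturbation(shuffled, i, j, min_subset=2)
            assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)

    def test_planted_dependence_ranks_top(self):
        msa, _ = generate_msa(150, 20, ((3, 11, 1.0),), rng_seed=8)
        mat = co.coupling_matrix(msa, "SCA")
        pool = mat.pair_scores()
        cut = np.quantile(pool, 0.95)
        assert mat.scores[3, 11] >= cut


class TestElsc:
    def test_proportional_subset_scores_zero(self):
        msa = msa_from_cols("AAACCC", "GHIGHI")
        assert co.elsc(msa, 0, 1, min_subset=2) == pytest.approx(0.0)

    def test_nonnegative_on_random_alignments(self, rng):
        for _ in range(10):
            msa = random_msa(rng, 20, 6)
            for i in range(5):
                s = co.elsc(msa, i, i + 1, min_subset=2)
                if not math.isnan(s):
                    assert s >= -1e-12

    def test_planted_dependence_ranks_top(self):
        msa, _ = generate_msa(150, 20, ((3, 11, 1.0),), rng_seed=8)
        mat = co.coupling_matrix(msa, "ELSC")
        cut = np.quantile(mat.pair_scores(), 0.95)
        assert mat.scores[3, 11] >= cut


class TestBruteForceAgreement:
    def test_mi_omes_conservation_match_count_oracles(self, rng):
        for _ in range(10):
            msa = random_msa(rng, int(rng.integers(5, 20)), int(rng.integers(4, 10)))
            i, j = rng.choice(msa.n_cols, size=2, replace=False)
            assert co.mutual_information(msa, i, j) == pytest.approx(brute_mi(msa, i, j), abs=1e-10)
            assert co.omes(msa, i, j) == pytest.approx(brute_omes(msa, i, j), abs=1e-10)
            assert co.conservation_sum(msa, i, j) == pytest.approx(
                brute_conservation(msa, i) + brute_conservation(msa, j), abs=1e-10
            )


class TestCouplingMatrixSymmetry:
    @pytest.mark.parametrize("method", co.METHODS)
    def test_exactly_symmetric(self, method, rng):
        msa = random_msa(rng, 25, 8)
        m = co.coupling_matrix(msa, method, min_subset=2)
        s, st = m.scores, m.scores.T
        both = np.isfinite(s) & np.isfinite(st)
        assert np.array_equal(s[both], st[both])
        assert np.array_equal(np.isnan(s), np.isnan(st))


class TestRemoveRedundancy:
    def test_identical_sequences_collapse(self):
        msa = co.MSA(ids=["a", "b"], seqs=["ACDEF", "ACDEF"], reference_id="a")
        assert co.remove_redundancy(msa).n_seqs == 1

    def test_distinct_sequences_all_kept(self):
        msa = co.MSA(ids=["a", "b", "c"],
                     seqs=["ACDEFGHIKL", "LMNPQRSTVW", "WVTSRQPNML"], reference_id="a")
        assert co.remove_redundancy(msa).n_seqs == 3

    def test_three_cluster_fixture_keeps_three(self, rng):
        # 3 clusters: >=95% identity within, ~50% between
        L = 40
        reps = []
        base = rng.choice(list(co.AA20), size=L)
        for c in range(3):
            rep = base.copy()
            flip = rng.choice(L, size=L // 2, replace=False) if c else []
            for pos in flip:
                rep[pos] = co.AA20[(co.AA20.index(rep[pos]) + 7 + c) % 20]
            reps.append(rep)
        seqs = []
        for rep in reps:
            for m in range(3):
                s = rep.copy()
                for pos in rng.choice(L, size=2, replace=False):  # 95% identity
                    s[pos] = co.AA20[(co.AA20.index(s[pos]) + 1 + m) % 20]
                seqs.append("".join(s))
        seqs.append("".join(reps[0]))
        msa = co.MSA(ids=[f"s{i}" for i in range(10)], seqs=seqs, reference_id="s0")
        reduced = co.remove_redundancy(msa, 0.90)
        assert reduced.n_seqs == 3

    def test_reference_always_retained(self):
        msa = co.MSA(ids=["a", "b"], seqs=["ACDEF", "ACDEF"], reference_id="b")
        assert "b" in co.remove_redundancy(msa).ids


class TestMutationMapping:
    def test_reference_residue_numbering_skips_gaps(self):
        msa = co.MSA(ids=["r", "x"], seqs=["A-CD", "AACD"], reference_id="r")
        assert msa.reference_positions() == {0: 1, 2: 2, 3: 3}
        assert msa.column_of_residue(2) == 2

    def test_mismatched_reference_aa_is_hard_error(self):
        msa = co.MSA(ids=["r"], seqs=["ACDEF"], reference_id="r")
        rec = MutationRecord(gene="g", substitution="S2N")
        with pytest.raises(ValueError, match="mismatch"):
            co.map_mutation_to_column(msa, rec)


def fake_matrix(method, L, hot_pairs, seed=0):
    rng = np.random.default_rng(seed)
    scores = rng.uniform(0, 1, size=(L, L))
    scores = (scores + scores.T) / 2
    np.fill_diagonal(scores, np.nan)
    for i, j in hot_pairs:
        scores[i, j] = scores[j, i] = 10.0
    return co.CouplingMatrix(method, scores, np.ones(L, dtype=bool))


class TestConsensus:
    def test_two_method_support_included_single_excluded(self):
        mats = [
            fake_matrix("MI", 6, [(0, 2)]),
            fake_matrix("OMES", 6, [(0, 2)]),
            fake_matrix("SCA", 6, [(0, 4)]),
            fake_matrix("ELSC", 6, []),
            fake_matrix("ConservationSum", 6, []),
        ]
        cons = co.consensus_couplings(mats, mutated_column=0, flag_quantile=0.9)
        assert cons.support == {2: {"MI", "OMES"}}

    def test_quantile_one_is_exclusive(self):
        mats = [fake_matrix(m, 6, [(0, 2)]) for m in co.METHODS]
        cons = co.consensus_couplings(mats, 0, flag_quantile=1.0)
        assert cons.support == {}

    def test_masked_mutated_column_is_error(self):
        m = fake_matrix("MI", 6, [])
        m.valid[3] = False
        with pytest.raises(ValueError, match="column 3"):
            co.consensus_couplings([m], 3)


class TestAnalyzeMutation:
    def test_planted_pairs_recovered_end_to_end(self):
        msa, truth = generate_msa(200, 30, ((4, 12, 0.9), (4, 20, 0.9)), rng_seed=2)
        ref = msa.reference_seq
        rec = MutationRecord(gene="g", substitution=f"{ref[4]}5{'A' if ref[4] != 'A' else 'C'}")
        _, cons = co.analyze_mutation(msa, rec)
        assert {12, 20} <= set(cons.support)
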