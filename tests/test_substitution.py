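"""Ortholog criteria, deterministic global alignment, replacement counting
and directional bias statistics."""
import math

import numpy as np
import pytest

from protniche import substitution as sub
from protniche.io_core import OrthologHit, ValidationError
from protniche.residues import RESIDUES
from protniche.substitution import (DEFAULT_SCORING, PairwiseAlignment,
                                    ReplacementMatrix, alignment_score,
                                    check_ortholog_criteria,
                                    count_replacements, global_align,
                                    pair_bias_statistics, rank_bias_pairs)
from protniche.synthetic_data import SubstitutionBias, simulate_ortholog_pair

IDX = {a: i for i, a in enumerate(RESIDUES)}


def matrix_with(entries):
    N = np.zeros((20, 20), dtype=int)
    for (a, b), n in entries.items():
        N[IDX[a], IDX[b]] = n
    return ReplacementMatrix(N)


class TestOrthologCriteria:
    @pytest.mark.parametrize("sim,lq,ls,ev,expected", [
        (67.0, 330, 335, 1e-50, True),    # typical accepted ortholog
        (40.0, 100, 100, 1e-10, True),    # all three boundaries inclusive
        (39.9, 100, 100, 1e-50, False),   # similarity below threshold
        (90.0, 100, 125, 0.0, False),     # 25/125 = exactly 20%, excluded
        (90.0, 100, 130, 0.0, False),     # >20% length difference
        (90.0, 100, 120, 0.0, True),      # 20/120 = 16.7% passes
        (90.0, 100, 101, 1e-9, False),    # e-value above threshold
    ])
    def test_criteria(self, sim, lq, ls, ev, expected):
        hit = OrthologHit("q", "s", sim, lq, ls, ev)
        assert check_ortholog_criteria(hit) is expected


def exhaustive_best_score(a, b, scoring=DEFAULT_SCORING):
    """Brute-force optimum over every global alignment (tiny inputs only):
    recursively enumerate column sequences, scoring gap runs with
    open + (L-1)*extend."""
    mat = scoring.matrix
    go, ge = scoring.gap_open, scoring.gap_extend
    best = -math.inf

    def rec(i, j, score, last):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + float(mat[a[i], b[j]]), "M")
        if i < len(a):
            rec(i + 1, j, score - (ge if last == "X" else go), "X")
        if j < len(b):
            rec(i, j + 1, score - (ge if last == "Y" else go), "Y")

    rec(0, 0, 0.0, None)
    return best


class TestGlobalAlign:
    def test_identical_sequences_align_gap_free(self):
        aln = global_align("MKVLANDERS", "MKVLANDERS")
        assert aln.aligned_query == aln.aligned_subject == "MKVLANDERS"

    def test_deletion_forces_single_gap(self):
        aln = global_align("ACD", "AD")
        assert aln.aligned_query == "ACD"
        assert aln.aligned_subject == "A-D"

    def test_degapped_strings_equal_inputs(self, rng):
        res = list(RESIDUES)
        for _ in range(10):
            a = "".join(rng.choice(res, size=int(rng.integers(5, 30))))
            b = "".join(rng.choice(res, size=int(rng.integers(5, 30))))
            aln = global_align(a, b)
            assert aln.aligned_query.replace("-", "") == a
            assert aln.aligned_subject.replace("-", "") == b

    def test_score_is_optimal_on_tiny_instances(self, rng):
        res = list(RESIDUES)
        for _ in range(8):
            a = "".join(rng.choice(res, size=int(rng.integers(3, 7))))
            b = "".join(rng.choice(res, size=int(rng.integers(3, 7))))
            aln = global_align(a, b)
            assert alignment_score(aln) == pytest.approx(
                exhaustive_best_score(a, b))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            global_align("", "ACD")


class TestCountReplacements:
    def test_single_mismatch_column(self):
        m = count_replacements([PairwiseAlignment("q", "s", "ACD", "ACE")])
        assert m["D", "E"] == 1
        off = m.counts.copy()
        np.fill_diagonal(off, 0)
        assert off.sum() == 1
        assert m["A", "A"] == 1 and m["C", "C"] == 1

    def test_identical_pair_all_diagonal(self):
        m = count_replacements([PairwiseAlignment("q", "s", "ACDEF", "ACDEF")])
        off = m.counts.copy()
        np.fill_diagonal(off, 0)
        assert off.sum() == 0 and m.counts.trace() == 5

    def test_gap_and_ambiguity_columns_skipped(self):
        m = count_replacements([PairwiseAlignment("q", "s", "A-XD", "GCCE")])
        assert m.counts.sum() == 2  # A->G and D->E only

    def test_off_diagonal_total_matches_column_rescan(self, rng):
        res = list(RESIDUES)
        alns = []
        mismatches = 0
        for _ in range(100):
            a = "".join(rng.choice(res, size=40))
            b = "".join(rng.choice(res, size=40))
            alns.append(PairwiseAlignment("q", "s", a, b))
            mismatches += sum(x != y for x, y in zip(a, b))
        m = count_replacements(alns)
        off = m.counts.copy()
        np.fill_diagonal(off, 0)
        assert off.sum() == mismatches

    def test_generator_truth_counts_recovered_exactly(self):
        sim = simulate_ortholog_pair(
            2000, 0.2, SubstitutionBias(pair=("C", "A"), multiplier=2.0,
                                        focal_share=0.2), seed=5)
        m = count_replacements([PairwiseAlignment("a", "b", sim.seq_a, sim.seq_b)])
        off = m.counts.copy()
        np.fill_diagonal(off, 0)
        assert (off == sim.true_counts).all()


class TestPairBiasStatistics:
    def test_printed_count_arithmetic(self):
        m = matrix_with({("R", "K"): 871, ("K", "R"): 443,
                         ("Q", "W"): 8, ("W", "Q"): 1})
        recs = {(r.source, r.target): r for r in pair_bias_statistics(m)}
        rk = recs[("R", "K")]
        assert rk.ratio_str == "1.97" and rk.gain == 428
        qw = recs[("Q", "W")]
        assert qw.ratio_str == "8.00" and qw.gain == 7

    def test_symmetric_pair_is_null(self):
        m = matrix_with({("A", "C"): 5, ("C", "A"): 5,
                         ("A", "D"): 7, ("C", "D"): 7})
        rec = [r for r in pair_bias_statistics(m)
               if {r.source, r.target} == {"A", "C"}][0]
        assert rec.ratio == pytest.approx(1.0)
        assert rec.gain == 0
        assert rec.chi_square == pytest.approx(0.0)
        assert rec.significance_tier == 0

    def test_always_190_pairs(self):
        m = matrix_with({("A", "C"): 3})
        assert len(pair_bias_statistics(m)) == 190

    def test_forward_never_smaller_than_reverse(self, rng):
        N = rng.integers(0, 50, size=(20, 20))
        recs = pair_bias_statistics(ReplacementMatrix(N))
        for r in recs:
            assert r.forward_count >= r.reverse_count
            assert r.gain >= 0
            assert math.isinf(r.ratio) or r.ratio >= 1.0

    def test_direction_antisymmetry(self, rng):
        """Swapping source and target transposes the matrix but leaves the
        orientation-free content of every record unchanged: the unordered
        pair, forward/reverse counts, ratio and gain. (The chi-square
        conditions on replacements *out of* the source residue, so it is
        defined relative to the chosen direction.)"""
        N = rng.integers(0, 40, size=(20, 20))
        m = ReplacementMatrix(N)

        def bare(records):
            return sorted((frozenset((r.source, r.target)), r.forward_count,
                           r.reverse_count, r.gain,
                           None if math.isinf(r.ratio) else round(r.ratio, 12))
                          for r in records)

        assert bare(pair_bias_statistics(m)) == bare(
            pair_bias_statistics(m.transpose()))

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValidationError):
            pair_bias_statistics(ReplacementMatrix(np.zeros((20, 20), int)))


class TestRankBiasPairs:
    def test_known_gains_rank_in_order(self):
        m = matrix_with({("R", "K"): 871, ("K", "R"): 443,
                         ("E", "K"): 615, ("K", "E"): 303,
                         ("D", "E"): 723, ("E", "D"): 458})
        ranked = rank_bias_pairs(pair_bias_statistics(m), k=3, key="gain")
        assert list(ranked["gain"]) == [428, 312, 265]
        assert list(ranked.index) == ["R->K", "E->K", "D->E"]

    def test_single_record(self):
        m = matrix_with({("A", "C"): 4, ("C", "A"): 1})
        ranked = rank_bias_pairs(pair_bias_statistics(m), k=1, key="ratio")
        assert list(ranked.index) == ["A->C"]

    def test_order_matches_independent_sort(self, rng):
        N = rng.integers(1, 100, size=(20, 20))
        recs = pair_bias_statistics(ReplacementMatrix(N))
        ranked = rank_bias_pairs(recs, k=190, key="gain")
        expected = sorted(recs, key=lambda r: (-r.gain, -r.ratio, r.pair_label))
        assert list(ranked["gain"]) == [r.gain for r in expected]

    def test_undefined_ratios_listed_last_in_ratio_panel(self):
        m = matrix_with({("A", "C"): 9, ("A", "D"): 6, ("D", "A"): 2})
        ranked = rank_bias_pairs(pair_bias_statistics(m), k=190, key="ratio")
        finite = ranked[~ranked["undefined_ratio"]]
        assert list(finite.index)[0] == "A->D"
        # the A->C pair (reverse 0) is flagged and comes after finite ratios
        pos = list(ranked.index)
        assert pos.index("A->C") > pos.index("A->D")
        assert ranked.loc["A->C", "undefined_ratio"]

    def test_k_clipped_to_pair_count(self, rng):
        N = rng.integers(1, 10, size=(20, 20))
        recs = pair_bias_statistics(ReplacementMatrix(N))
        assert len(rank_bias_pairs(recs, k=500, key="gain")) == 190
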