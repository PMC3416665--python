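"""Directional amino-acid substitution-bias analysis between ortholog sets.

Given pairwise global alignments of orthologous proteins from a *source*
organism (e.g. a methanogen) to a *target* organism (e.g. a
sulphur-metaboliser), every aligned column with two differing standard
residues increments a 20x20 directed replacement-count matrix
N[source][target]; identity columns land on the diagonal and gap/ambiguity
columns are skipped. For each of the 190 unordered residue pairs {i, j} the
*forward* direction is the more common of the two replacements; the bias is
summarised by the forward/reverse ratio, the gain (forward - reverse), and
a 1-df chi-square from a 2x2 contingency table whose rows hold each
direction's count next to the remaining replacements out of its source
residue. Under no directional pressure forward:reverse is expected 1:1.

Alignment is deterministic Needleman–Wunsch with affine gaps (default
BLOSUM62, open 10, extend 0.5; a run of L gaps costs open + (L-1)*extend)
with tie preference diagonal > up > left, so results are reproducible.
Precomputed alignments can be supplied instead, bypassing this stage.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy.stats import chi2_contingency

from .io_core import OrthologHit, ValidationError
from .residues import RESIDUES, RESIDUE_SET

_IDX = {a: i for i, a in enumerate(RESIDUES)}

SIMILARITY_MIN = 40.0
LENGTH_DIFF_MAX = 0.20
EVALUE_MAX = 1e-10

SIGNIFICANCE_TIERS = (1e-3, 1e-4, 1e-5, 1e-6)


def check_ortholog_criteria(hit: OrthologHit) -> bool:
    """Ortholog filter: similarity >= 40%, length difference < 20% of the
    longer sequence, e-value <= 1e-10 (all boundaries as stated)."""
    len_diff = abs(hit.query_length - hit.subject_length) / max(
        hit.query_length, hit.subject_length)
    return (hit.similarity_percent >= SIMILARITY_MIN
            and len_diff < LENGTH_DIFF_MAX
            and hit.evalue <= EVALUE_MAX)


# ---------------------------------------------------------------------------
# alignment


@dataclass(frozen=True)
class AlignmentScoring:
    """Substitution matrix plus affine gap penalties (positive costs)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    @property
    def matrix(self):
        return substitution_matrices.load(self.matrix_name)


DEFAULT_SCORING = AlignmentScoring()


@dataclass(frozen=True)
class PairwiseAlignment:
    query_id: str
    subject_id: str
    aligned_query: str
    aligned_subject: str

    def __post_init__(self):
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValidationError("aligned strings differ in length")

    def columns(self):
        return zip(self.aligned_query, self.aligned_subject)


def _score_lookup(matrix, a: str, b: str) -> float:
    alphabet = matrix.alphabet
    a = a if a in alphabet else "X"
    b = b if b in alphabet else "X"
    return float(matrix[a, b])


def global_align(seq_a: str, seq_b: str,
                 scoring: AlignmentScoring = DEFAULT_SCORING,
                 query_id: str = "a", subject_id: str = "b") -> PairwiseAlignment:
    """Optimal global alignment (Gotoh affine-gap DP, deterministic traceback).

    State M aligns two residues, X gaps the subject (consumes query), Y gaps
    the query (consumes subject). Opening a run costs ``gap_open``; each
    additional gap column costs ``gap_extend``. Traceback ties prefer
    diagonal, then up (X), then left (Y).
    """
    if not seq_a or not seq_b:
        raise ValidationError("both sequences must be non-empty")
    mat = scoring.matrix
    go, ge = scoring.gap_open, scoring.gap_extend
    n, m = len(seq_a), len(seq_b)
    NEG = -math.inf
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in seq_b
    Y = np.full((n + 1, m + 1), NEG)  # gap in seq_a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -go - (i - 1) * ge
    for j in range(1, m + 1):
        Y[0, j] = -go - (j - 1) * ge
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _score_lookup(mat, seq_a[i - 1], seq_b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - go, X[i - 1, j] - ge, Y[i - 1, j] - go)
            Y[i, j] = max(M[i, j - 1] - go, X[i, j - 1] - go, Y[i, j - 1] - ge)
    # traceback: pick best end state with tie order M > X > Y
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda st: ({"M": M, "X": X, "Y": Y}[st][i, j],
                                                 {"M": 2, "X": 1, "Y": 0}[st]))
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            s = _score_lookup(mat, seq_a[i - 1], seq_b[j - 1])
            prev = M[i, j] - s
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            i, j = i - 1, j - 1
            for st, arr in (("M", M), ("X", X), ("Y", Y)):
                if math.isclose(arr[i, j], prev, rel_tol=0.0, abs_tol=1e-9):
                    state = st
                    break
        elif state == "X":
            cur = X[i, j]
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            i -= 1
            for st, arr, cost in (("M", M, go), ("X", X, ge), ("Y", Y, go)):
                if math.isclose(arr[i, j] - cost, cur, rel_tol=0.0, abs_tol=1e-9):
                    state = st
                    break
        else:  # Y
            cur = Y[i, j]
            out_a.append("-")
            out_b.append(seq_b[j - 1])
            j -= 1
            for st, arr, cost in (("M", M, go), ("X", X, go), ("Y", Y, ge)):
                if math.isclose(arr[i, j] - cost, cur, rel_tol=0.0, abs_tol=1e-9):
                    state = st
                    break
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"
    return PairwiseAlignment(query_id=query_id, subject_id=subject_id,
                             aligned_query="".join(reversed(out_a)),
                             aligned_subject="".join(reversed(out_b)))


def alignment_score(aln: PairwiseAlignment,
                    scoring: AlignmentScoring = DEFAULT_SCORING) -> float:
    """Score an existing alignment under the affine-gap convention (used to
    verify optimality and by the tiny-scale oracle tests)."""
    mat = scoring.matrix
    total = 0.0
    gap_a = gap_b = False
    for a, b in aln.columns():
        if a == "-":
            total -= scoring.gap_extend if gap_a else scoring.gap_open
            gap_a, gap_b = True, False
        elif b == "-":
            total -= scoring.gap_extend if gap_b else scoring.gap_open
            gap_b, gap_a = True, False
        else:
            total += _score_lookup(mat, a, b)
            gap_a = gap_b = False
    return total


# ---------------------------------------------------------------------------
# replacement counting


@dataclass
class ReplacementMatrix:
    """20x20 directed replacement counts, source rows -> target columns;
    the diagonal stores identity columns."""

    counts: np.ndarray
    source_label: str = "source"
    target_label: str = "target"

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (20, 20):
            raise ValidationError("replacement matrix must be 20x20")
        if (self.counts < 0).any():
            raise ValidationError("negative replacement count")

    def __getitem__(self, pair: tuple[str, str]) -> int:
        i, j = pair
        return int(self.counts[_IDX[i], _IDX[j]])

    def transpose(self) -> "ReplacementMatrix":
        return ReplacementMatrix(self.counts.T.copy(),
                                 source_label=self.target_label,
                                 target_label=self.source_label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(RESIDUES), columns=list(RESIDUES))


def count_replacements(alignments: Sequence[PairwiseAlignment],
                       source_label: str = "source",
                       target_label: str = "target") -> ReplacementMatrix:
    """Tally directed replacements over a set of alignments with fixed
    source (query) and target (subject) roles."""
    if not alignments:
        raise ValidationError("no alignments given")
    N = np.zeros((20, 20), dtype=np.int64)
    for aln in alignments:
        for a, b in aln.columns():
            if a in RESIDUE_SET and b in RESIDUE_SET:
                N[_IDX[a], _IDX[b]] += 1
    return ReplacementMatrix(N, source_label=source_label, target_label=target_label)


# ---------------------------------------------------------------------------
# bias statistics


@dataclass(frozen=True)
class PairBiasRecord:
    """Directional bias summary for one unordered residue pair, oriented so
    ``source -> target`` is the forward (more common) direction."""

    source: str
    target: str
    forward_count: int
    reverse_count: int
    ratio: float               # inf when reverse_count == 0
    gain: int
    chi_square: float
    p_value: float
    significance_tier: int     # 0 = not significant, else 3..6 (p < 10^-tier)

    @property
    def pair_label(self) -> str:
        return f"{self.source}->{self.target}"

    @property
    def ratio_str(self) -> str:
        """Ratio to 2 decimals, half-up, matching printed-table style."""
        if math.isinf(self.ratio):
            return "inf"
        exact = Decimal(self.forward_count) / Decimal(self.reverse_count)
        return str(exact.quantize(Decimal("0.01"), ROUND_HALF_UP))


def _chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction), 1 df; degenerate
    margins give (0, 1)."""
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    chi2, p, _, _ = chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def _tier(p: float) -> int:
    tier = 0
    for level, exponent in zip(SIGNIFICANCE_TIERS, (3, 4, 5, 6)):
        if p < level:
            tier = exponent
    return tier


def pair_bias_statistics(matrix: ReplacementMatrix,
                         pooled_remainder: bool = False) -> list[PairBiasRecord]:
    """Forward/reverse bias statistics for all 190 unordered residue pairs.

    The 2x2 contingency table for pair {i, j} is::

        [[ N[i][j],  remaining replacements out of i (k != i, j) ],
         [ N[j][i],  remaining replacements out of j (k != i, j) ]]

    oriented so the first row is the forward direction. With
    ``pooled_remainder=True`` both remainder cells instead hold the pooled
    remainder of the two rows (the alternative reading of the contingency
    design). Identities (diagonal) never enter the table.
    """
    N = matrix.counts
    off = N.copy()
    np.fill_diagonal(off, 0)
    if off.sum() == 0:
        raise ValidationError("replacement matrix has no off-diagonal counts")
    row_sums = off.sum(axis=1)
    records: list[PairBiasRecord] = []
    for a in range(20):
        for b in range(a + 1, 20):
            n_ab, n_ba = int(off[a, b]), int(off[b, a])
            if n_ab >= n_ba:
                src, tgt, fwd, rev = a, b, n_ab, n_ba
            else:
                src, tgt, fwd, rev = b, a, n_ba, n_ab
            rem_src = int(row_sums[src] - off[src, tgt])
            rem_tgt = int(row_sums[tgt] - off[tgt, src])
            if pooled_remainder:
                rem_src = rem_tgt = rem_src + rem_tgt
            chi2, p = _chi_square_2x2(np.array([[fwd, rem_src], [rev, rem_tgt]]))
            ratio = math.inf if rev == 0 else fwd / rev
            records.append(PairBiasRecord(
                source=RESIDUES[src], target=RESIDUES[tgt],
                forward_count=fwd, reverse_count=rev, ratio=ratio,
                gain=fwd - rev, chi_square=chi2, p_value=p,
                significance_tier=_tier(p)))
    return records


def bias_frame(records: Sequence[PairBiasRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "pair": r.pair_label, "source": r.source, "target": r.target,
        "ratio": r.ratio, "ratio_2dp": r.ratio_str,
        "forward": r.forward_count, "reverse": r.reverse_count,
        "gain": r.gain, "chi_square": r.chi_square, "p_value": r.p_value,
        "significance_tier": r.significance_tier,
    } for r in records]).set_index("pair")


def rank_bias_pairs(records: Sequence[PairBiasRecord], k: int = 20,
                    key: str = "gain") -> pd.DataFrame:
    """Top-k pairs by ``gain`` or ``ratio`` (descending); ties break on the
    other key, then lexicographic pair label. In the ratio panel, pairs with
    reverse == 0 (undefined ratio) are listed after all finite ratios and
    flagged in the ``undefined_ratio`` column."""
    if key not in ("gain", "ratio"):
        raise ValueError("key must be 'gain' or 'ratio'")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(records):
        k = len(records)
    other = "ratio" if key == "gain" else "gain"

    def sort_key(r: PairBiasRecord):
        primary = getattr(r, key)
        secondary = getattr(r, other)
        undefined = math.isinf(r.ratio)
        if key == "ratio":
            # finite ratios first (descending), undefined block last
            return (undefined, -(0.0 if undefined else primary),
                    -secondary, r.pair_label)
        return (-primary, -(0.0 if math.isinf(secondary) else secondary),
                r.pair_label)

    ranked = sorted(records, key=sort_key)[:k]
    df = bias_frame(ranked)
    df["undefined_ratio"] = [math.isinf(r.ratio) for r in ranked]
    return df


# ---------------------------------------------------------------------------
# end-to-end


def replacement_matrix_from_proteomes(
        pairs: Sequence[tuple[str, str]],
        id_pairs: Sequence[tuple[str, str]] | None = None,
        scoring: AlignmentScoring = DEFAULT_SCORING,
        source_label: str = "source",
        target_label: str = "target") -> ReplacementMatrix:
    """Align each (source_seq, target_seq) pair and tally replacements."""
    if id_pairs is None:
        id_pairs = [(f"q{i}", f"s{i}") for i in range(len(pairs))]
    alignments = [global_align(a, b, scoring, qid, sid)
                  for (a, b), (qid, sid) in zip(pairs, id_pairs)]
    return count_replacements(alignments, source_label, target_label)
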