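"""Multivariate structure of usage matrices: complete-linkage clustering on
Euclidean distances and correspondence analysis (CA).

Complete linkage is implemented directly (naive agglomeration) so the
tie-break — merge the pair whose lexicographically smallest label pair comes
first — is a documented contract. CA follows the classical recipe: with
P = X / grand total, row masses r and column masses c, the standardised
residual matrix S = D_r^{-1/2} (P - r c^T) D_c^{-1/2} is decomposed by SVD;
principal coordinates are F = D_r^{-1/2} U Sigma (rows) and
G = D_c^{-1/2} V Sigma (columns); axis k explains sigma_k^2 / sum sigma^2
of the total inertia. Axis signs are arbitrary.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats
from skbio import DistanceMatrix

from .io_core import ValidationError

_SV_TOL = 1e-12


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: the two clusters (as sorted label tuples)
    fused at ``height``."""

    left: tuple[str, ...]
    right: tuple[str, ...]
    height: float

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(sorted(self.left + self.right))


@dataclass(frozen=True)
class Dendrogram:
    leaves: tuple[str, ...]
    merges: tuple[Merge, ...]

    def cophenetic(self) -> DistanceMatrix:
        """Cophenetic distances: height of the first merge uniting each pair."""
        labels = list(self.leaves)
        idx = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        coph = np.zeros((n, n))
        for m in self.merges:
            for a in m.left:
                for b in m.right:
                    coph[idx[a], idx[b]] = coph[idx[b], idx[a]] = m.height
        return DistanceMatrix(coph, ids=labels)

    def to_newick(self) -> str:
        """Ultrametric Newick; a child's branch length is the parent merge
        height minus the child's own merge height (0 for leaves)."""
        node_repr: dict[tuple[str, ...], tuple[str, float]] = {
            (l,): (l, 0.0) for l in self.leaves}
        for m in self.merges:
            ltxt, lh = node_repr.pop(m.left)
            rtxt, rh = node_repr.pop(m.right)
            txt = f"({ltxt}:{m.height - lh:.6g},{rtxt}:{m.height - rh:.6g})"
            node_repr[m.members] = (txt, m.height)
        (txt, _), = node_repr.values()
        return txt + ";"


@dataclass(frozen=True)
class CAResult:
    row_scores: pd.DataFrame      # organisms x axes, principal coordinates
    col_scores: pd.DataFrame      # residues x axes
    singular_values: np.ndarray
    inertia_percent: np.ndarray   # per axis, sums to 100 (or empty)

    @property
    def n_axes(self) -> int:
        return len(self.singular_values)


@dataclass(frozen=True)
class AxisCorrelation:
    axis: int
    covariate: str
    r: float
    p_value: float


def euclidean_distances(matrix: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distances between matrix rows."""
    if matrix.isna().any().any():
        raise ValidationError("matrix contains missing values")
    d = squareform(pdist(matrix.to_numpy(), metric="euclidean"))
    return DistanceMatrix(d, ids=[str(i) for i in matrix.index])


def complete_linkage(dist: DistanceMatrix) -> Dendrogram:
    """Agglomerative clustering under the maximum (complete) linkage.

    At each step the pair of clusters with the smallest maximum inter-point
    distance is merged; among ties, the pair whose sorted (min-label,
    min-label) identifier is lexicographically smallest wins. Merge heights
    are non-decreasing (complete linkage is monotone).
    """
    labels = list(dist.ids)
    if len(labels) < 2:
        raise ValidationError("clustering needs >= 2 leaves")
    base = {l: i for i, l in enumerate(labels)}
    d = dist.data
    clusters: list[tuple[str, ...]] = [(l,) for l in sorted(labels)]
    merges: list[Merge] = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                h = max(d[base[x], base[y]] for x in a for y in b)
                key = (h, min(a[0], b[0]), max(a[0], b[0]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (h, _, _), i, j = best
        a, b = clusters[i], clusters[j]
        left, right = (a, b) if a[0] <= b[0] else (b, a)
        merges.append(Merge(left=left, right=right, height=float(h)))
        merged = tuple(sorted(a + b))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        clusters.sort(key=lambda c: c[0])
    return Dendrogram(leaves=tuple(labels), merges=tuple(merges))


def correspondence_analysis(table: pd.DataFrame) -> CAResult:
    """Classical correspondence analysis of a non-negative table.

    Returns principal row and column coordinates on axes ordered by
    decreasing inertia. A table whose rows are all proportional (rank-1
    independence) has zero total inertia and yields no axes.
    """
    X = table.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValidationError("CA requires a non-negative table")
    if (X.sum(axis=1) == 0).any() or (X.sum(axis=0) == 0).any():
        raise ValidationError("CA forbids all-zero rows or columns")
    total = X.sum()
    if total <= 0:
        raise ValidationError("degenerate (all-zero) table")
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    keep = sv > _SV_TOL * max(1.0, sv[0] if len(sv) else 0.0)
    U, sv, Vt = U[:, keep], sv[keep], Vt[keep, :]
    axes = [f"axis{k + 1}" for k in range(len(sv))]
    F = (U * sv) / np.sqrt(r)[:, None]
    G = (Vt.T * sv) / np.sqrt(c)[:, None]
    inertia = sv ** 2
    pct = inertia / inertia.sum() * 100.0 if len(sv) else np.array([])
    return CAResult(
        row_scores=pd.DataFrame(F, index=table.index, columns=axes),
        col_scores=pd.DataFrame(G, index=table.columns, columns=axes),
        singular_values=sv,
        inertia_percent=pct,
    )


def axis_variable_correlation(row_scores: pd.DataFrame, axis: int,
                              covariate_values: Sequence[float],
                              covariate_name: str = "covariate") -> AxisCorrelation:
    """Pearson correlation (two-sided p from the t transform) between one CA
    axis and an organism-level covariate, aligned by row order.

    ``axis`` is 1-based, matching the axis labels.
    """
    scores = row_scores.iloc[:, axis - 1].to_numpy(dtype=float)
    cov = np.asarray(list(covariate_values), dtype=float)
    if len(scores) != len(cov):
        raise ValidationError(
            f"length mismatch: {len(scores)} scores vs {len(cov)} covariates")
    if len(scores) < 3:
        raise ValidationError("correlation needs >= 3 observations")
    if np.ptp(scores) == 0 or np.ptp(cov) == 0:
        raise ValidationError("zero variance in scores or covariate")
    r, p = stats.pearsonr(scores, cov)
    return AxisCorrelation(axis=axis, covariate=covariate_name,
                           r=float(r), p_value=float(p))
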