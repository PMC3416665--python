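"""Relative amino-acid usage profiling.

An organism's usage profile is the residue-weighted relative frequency of
each of the 20 standard amino acids over its whole (length-filtered)
proteome: concatenated counts divided by total countable residues, with
ambiguity codes excluded from numerator and denominator. Matrices are
pandas DataFrames with organisms as rows and the alphabetical residue order
:data:`protniche.residues.RESIDUES` as columns.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import Proteome, ValidationError
from .residues import RESIDUES, UNBIASED_RESIDUES, THREE_LETTER

log = logging.getLogger(__name__)

ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class UsageProfile:
    organism_id: str
    freq: Mapping[str, float]

    def __post_init__(self):
        total = sum(self.freq.values())
        if abs(total - 1.0) > ROW_SUM_TOL:
            raise ValidationError(
                f"{self.organism_id}: frequencies sum to {total}, not 1")
        if any(v < 0 for v in self.freq.values()):
            raise ValidationError(f"{self.organism_id}: negative frequency")


def compute_relative_usage(proteome: Proteome) -> UsageProfile:
    """Residue-weighted relative usage over the whole proteome."""
    counts = Counter()
    for record in proteome:
        counts.update(record.sequence)
    total = sum(counts[a] for a in RESIDUES)
    if total == 0:
        raise ValidationError(
            f"{proteome.organism_id}: no countable (standard) residues")
    return UsageProfile(
        organism_id=proteome.organism_id,
        freq={a: counts[a] / total for a in RESIDUES})


def build_usage_matrix(profiles: Sequence[UsageProfile]) -> pd.DataFrame:
    """Stack profiles into an organisms x 20 frequency matrix.

    Rows keep the given order; columns are :data:`RESIDUES`.
    """
    if not profiles:
        raise ValidationError("no profiles given")
    ids = [p.organism_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate organism_id(s): {dupes}")
    data = np.array([[p.freq[a] for a in RESIDUES] for p in profiles])
    return pd.DataFrame(data, index=ids, columns=list(RESIDUES))


def standardize_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores (x - column mean) / column SD, population SD.

    Constant columns map to all-zero. This is the transformation behind the
    red-to-green heat-map colouring: within each residue column, values are
    expressed relative to the across-organism spread.
    """
    if len(matrix) < 2:
        raise ValidationError("standardisation needs >= 2 rows")
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=0)
    z = (matrix - mean).div(sd.replace(0.0, np.nan), axis=1)
    return z.fillna(0.0)


def reduce_to_unbiased(matrix: pd.DataFrame) -> pd.DataFrame:
    """Collapse to the eight residues with no G+C bias in their codons
    (Val, Ser, Thr, His, Gln, Asp, Glu, Cys) plus an ``other`` column
    holding the summed frequency of the remaining twelve.

    Row sums are preserved exactly up to float addition order.
    """
    retained = list(UNBIASED_RESIDUES)
    missing = set(retained) - set(matrix.columns)
    if missing:
        raise ValidationError(f"matrix lacks residue column(s) {sorted(missing)}")
    rest = [c for c in matrix.columns if c not in retained]
    out = matrix[retained].copy()
    out["other"] = matrix[rest].sum(axis=1)
    return out


def summarize_extremes(matrix: pd.DataFrame, metadata: pd.DataFrame,
                       group_field: str = "order_") -> pd.DataFrame:
    """Per-residue extreme group means, Table-1 style.

    For each residue, group organisms by ``metadata[group_field]``, average
    the frequencies within each group (as percentages), and report the group
    with the highest and the lowest mean, rounded to 2 decimals. Ties are
    broken by lexicographic group name. Groups with no organisms present in
    the matrix are excluded with a warning.
    """
    groups = metadata.loc[metadata.index.intersection(matrix.index), group_field]
    absent = set(metadata[group_field].unique()) - set(groups.unique())
    if absent:
        log.warning("groups with no organisms in matrix excluded: %s", sorted(absent))
    if groups.empty:
        raise ValidationError("no organism of the matrix appears in metadata")
    pct = matrix.loc[groups.index] * 100.0
    group_means = pct.groupby(groups).mean().sort_index()  # lexicographic ties
    rows = []
    for residue in matrix.columns:
        col = group_means[residue]
        max_group = col.idxmax()  # first occurrence wins -> lexicographic
        min_group = col.idxmin()
        rows.append({
            "residue": residue,
            "residue_name": THREE_LETTER.get(residue, residue),
            "max_group": max_group,
            "max_value": round(float(col.loc[max_group]), 2),
            "min_group": min_group,
            "min_value": round(float(col.loc[min_group]), 2),
        })
    return pd.DataFrame(rows).set_index("residue")
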