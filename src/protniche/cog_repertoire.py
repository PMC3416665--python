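"""COG repertoire analysis: functional-category profiles, core and
group-exclusive COG identification, and 4-way Venn partitions.

A *core* COG of a group is present in every member organism's COG set; an
*exclusive core* COG is additionally absent from every organism outside the
group. Category percentages are per-protein: a COG-annotated protein counts
once towards each category letter it carries (multi-letter strings count
fully toward every letter, so column sums can exceed 100%).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import CogAnnotation, ValidationError
from .residues import COG_CATEGORIES

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CogSet:
    organism_id: str
    cog_ids: frozenset[str]

    def __len__(self) -> int:
        return len(self.cog_ids)


@dataclass(frozen=True)
class CategoryProfile:
    organism_id: str
    percent: Mapping[str, float]  # one entry per category letter

    def as_series(self) -> pd.Series:
        return pd.Series({c: self.percent[c] for c in COG_CATEGORIES},
                         name=self.organism_id)


@dataclass(frozen=True)
class VennPartition:
    """Counts for the 15 non-empty membership regions of four labelled sets.

    Regions are keyed by the sorted tuple of member labels; per-set totals
    are reported alongside (the parenthesised totals of a 4-way Venn plot).
    """

    labels: tuple[str, str, str, str]
    regions: Mapping[tuple[str, ...], int]
    set_totals: Mapping[str, int]

    def exclusive(self, label: str) -> int:
        return self.regions[(label,)]

    @property
    def centre(self) -> int:
        return self.regions[tuple(sorted(self.labels))]


def cog_set(annotations: Iterable[CogAnnotation], organism_id: str) -> CogSet:
    """Distinct COG IDs annotated in one organism."""
    return CogSet(organism_id=organism_id,
                  cog_ids=frozenset(a.cog_id for a in annotations))


def category_profile(annotations: Sequence[CogAnnotation],
                     organism_id: str,
                     total_proteins: int | None = None) -> CategoryProfile:
    """Percentage of proteins per COG functional category.

    The denominator is the number of distinct COG-annotated proteins
    (un-annotated proteins were already excluded on read); pass
    ``total_proteins`` to normalise by the full ORF count instead. A protein
    with several annotations contributes once to each category letter in the
    union of its category strings.
    """
    if not annotations:
        raise ValidationError(f"{organism_id}: no annotations")
    letters_by_protein: dict[str, set[str]] = {}
    for a in annotations:
        letters_by_protein.setdefault(a.protein_id, set()).update(a.categories)
    denom = total_proteins if total_proteins is not None else len(letters_by_protein)
    if denom <= 0:
        raise ValidationError(f"{organism_id}: zero annotated proteins")
    percent = {
        c: 100.0 * sum(c in letters for letters in letters_by_protein.values()) / denom
        for c in COG_CATEGORIES}
    return CategoryProfile(organism_id=organism_id, percent=percent)


def profile_matrix(profiles: Sequence[CategoryProfile]) -> pd.DataFrame:
    """Organisms x 25 category-percentage matrix."""
    return pd.DataFrame([p.as_series() for p in profiles])


def group_profile_stats(profiles: Sequence[CategoryProfile],
                        metadata: pd.DataFrame,
                        group_field: str = "metabolic_group") -> pd.DataFrame:
    """Per-group mean and sample SD of category percentages.

    Returns a DataFrame indexed by (group, statistic in {mean, sd}) with the
    25 category columns. Singleton groups get SD 0 with a warning.
    """
    mat = profile_matrix(profiles)
    groups = metadata.loc[mat.index.intersection(metadata.index), group_field]
    if groups.empty:
        raise ValidationError("no profiled organism appears in metadata")
    rows = {}
    for group, members in mat.loc[groups.index].groupby(groups):
        rows[(group, "mean")] = members.mean()
        if len(members) == 1:
            log.warning("group %r has a single organism; SD reported as 0", group)
            rows[(group, "sd")] = pd.Series(0.0, index=mat.columns)
        else:
            rows[(group, "sd")] = members.std(ddof=1)
    out = pd.DataFrame(rows).T
    out.index.names = ["group", "statistic"]
    return out


def core_cogs(cog_sets: Sequence[CogSet]) -> frozenset[str]:
    """COG IDs present in every given organism (set intersection)."""
    if not cog_sets:
        raise ValidationError("no COG sets given")
    core = set(cog_sets[0].cog_ids)
    for s in cog_sets[1:]:
        core &= s.cog_ids
    return frozenset(core)


def exclusive_core_cogs(group_sets: Sequence[CogSet],
                        other_sets: Sequence[CogSet]) -> frozenset[str]:
    """Group-core COGs absent from every organism outside the group."""
    core = core_cogs(group_sets)
    others: set[str] = set()
    for s in other_sets:
        others |= s.cog_ids
    return frozenset(core - others)


def union_cogs(cog_sets: Sequence[CogSet]) -> frozenset[str]:
    out: set[str] = set()
    for s in cog_sets:
        out |= s.cog_ids
    return frozenset(out)


def venn4_partition(sets: Mapping[str, frozenset[str] | set[str]]) -> VennPartition:
    """Partition four labelled ID sets into their 15 membership regions."""
    if len(sets) != 4:
        raise ValidationError(f"need exactly 4 sets, got {len(sets)}")
    labels = tuple(sets.keys())
    universe = set().union(*sets.values())
    regions: dict[tuple[str, ...], int] = {}
    for mask in range(1, 16):
        members = tuple(sorted(l for k, l in enumerate(labels) if mask >> k & 1))
        regions[members] = 0
    for cog in universe:
        members = tuple(sorted(l for l in labels if cog in sets[l]))
        regions[members] += 1
    totals = {l: len(sets[l]) for l in labels}
    return VennPartition(labels=labels, regions=regions, set_totals=totals)


def venn_frame(partition: VennPartition) -> pd.DataFrame:
    rows = [{"region": "&".join(members), "n_sets": len(members), "count": count}
            for members, count in sorted(partition.regions.items(),
                                         key=lambda kv: (len(kv[0]), kv[0]))]
    return pd.DataFrame(rows).set_index("region")
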