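"""Synthetic study generator: GC-driven proteomes, bias-injected ortholog
pairs, and planted COG universes, with full truth bookkeeping.

Everything is a pure function of its parameters plus a seed, so fixtures
are byte-identical across runs and every recovery test can be scored
against the returned truth record without re-deriving parameters.

Proteome model
    Codons are drawn i.i.d. from the 61 sense codons with weight
    proportional to g^(GC nucleotides) * (1-g)^(AT nucleotides) for a GC
    target g, then translated by the standard genetic code. This is the
    simplest model that couples genomic GC to the known residue split
    (Pro/Ala/Arg/Gly up with GC, Phe/Tyr/Lys/Asn/Ile down). Optional
    multipliers on the codons of Asp/Glu or Lys/Arg plant acidic- or
    basic-shifted proteomes, emulating the charge contrast between
    methanogen-like and sulphur-metaboliser-like groups.

Ortholog model
    Substitution-only divergence (no indels) from a common layout: identity
    columns carry one uniform residue; substituted columns carry a directed
    replacement event. A configurable share of events involves a focal
    residue pair (i, j), taking direction i -> j with probability
    m/(m+1), so the forward/reverse count ratio estimates the injected
    multiplier m without model bias; all remaining events are uniform over
    the other directed pairs. True directed counts are returned exactly.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .io_core import (CogAnnotation, OrganismMetadata, OrthologHit, Proteome,
                      ProteinRecord, ValidationError, write_cog_annotations,
                      write_hit_table, write_metadata_table,
                      write_proteome_fasta)
from .residues import RESIDUES

_CODON_TABLE = unambiguous_dna_by_id[1]
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_CODON_TABLE.forward_table))
_CODON_AA = np.array([_CODON_TABLE.forward_table[c] for c in SENSE_CODONS])
_CODON_GC = np.array([sum(n in "GC" for n in c) for c in SENSE_CODONS])

ACIDIC = ("D", "E")
BASIC_PLANT = ("K", "R")


@dataclass(frozen=True)
class LengthDist:
    """Protein-length model: min + Poisson(mean - min), clipped at max."""

    min: int = 100
    mean: int = 300
    max: int = 1500

    def __post_init__(self):
        if not self.min <= self.mean <= self.max:
            raise ValidationError(
                f"infeasible length bounds min={self.min} mean={self.mean} max={self.max}")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.minimum(self.min + rng.poisson(self.mean - self.min, size=n),
                          self.max)


def codon_probabilities(gc_target: float, de_boost: float = 1.0,
                        kr_boost: float = 1.0) -> np.ndarray:
    """Sense-codon probabilities for a GC target, with optional charge
    plants (multipliers on Asp/Glu or Lys/Arg codons)."""
    if not 0.25 <= gc_target <= 0.75:
        raise ValidationError(f"gc_target {gc_target} outside [0.25, 0.75]")
    w = gc_target ** _CODON_GC * (1.0 - gc_target) ** (3 - _CODON_GC)
    w = w * np.where(np.isin(_CODON_AA, ACIDIC), de_boost, 1.0)
    w = w * np.where(np.isin(_CODON_AA, BASIC_PLANT), kr_boost, 1.0)
    return w / w.sum()


def expected_aa_frequencies(gc_target: float, de_boost: float = 1.0,
                            kr_boost: float = 1.0) -> dict[str, float]:
    """Analytic residue frequencies implied by the codon distribution."""
    p = codon_probabilities(gc_target, de_boost, kr_boost)
    return {a: float(p[_CODON_AA == a].sum()) for a in RESIDUES}


@dataclass(frozen=True)
class ProteomeTruth:
    organism_id: str
    gc_target: float
    realized_gc: float
    de_boost: float
    kr_boost: float
    n_proteins: int
    n_residues: int
    expected_freq: Mapping[str, float]


def simulate_proteome(gc_target: float, n_proteins: int = 100,
                      length_dist: LengthDist = LengthDist(),
                      seed: int = 0, organism_id: str = "org",
                      de_boost: float = 1.0, kr_boost: float = 1.0
                      ) -> tuple[Proteome, ProteomeTruth]:
    """Draw a whole proteome from the GC-parameterised codon model."""
    rng = np.random.default_rng(seed)
    probs = codon_probabilities(gc_target, de_boost, kr_boost)
    lengths = length_dist.draw(rng, n_proteins)
    codon_idx = rng.choice(len(SENSE_CODONS), size=int(lengths.sum()), p=probs)
    records = []
    pos = 0
    for i, L in enumerate(lengths):
        chunk = codon_idx[pos:pos + L]
        pos += L
        records.append(ProteinRecord(
            id=f"{organism_id}_p{i:05d}",
            sequence="".join(_CODON_AA[chunk])))
    realized_gc = float(_CODON_GC[codon_idx].sum() / (3 * len(codon_idx)))
    truth = ProteomeTruth(
        organism_id=organism_id, gc_target=gc_target, realized_gc=realized_gc,
        de_boost=de_boost, kr_boost=kr_boost, n_proteins=n_proteins,
        n_residues=int(lengths.sum()),
        expected_freq=expected_aa_frequencies(gc_target, de_boost, kr_boost))
    return Proteome(organism_id=organism_id, records=records), truth


# ---------------------------------------------------------------------------
# ortholog pairs


@dataclass(frozen=True)
class SubstitutionBias:
    """Injected directional preference: among substituted columns, a
    ``focal_share`` fraction involves ``pair`` = (i, j), directed i -> j
    with probability multiplier/(multiplier + 1)."""

    pair: tuple[str, str] = ("R", "K")
    multiplier: float = 1.0
    focal_share: float = 0.1
    n_columns: int | None = None   # exact substituted-column count, else binomial

    def __post_init__(self):
        if self.multiplier < 1.0:
            raise ValidationError("multiplier must be >= 1")
        if not 0.0 <= self.focal_share <= 1.0:
            raise ValidationError("focal_share must be in [0, 1]")
        if self.pair[0] == self.pair[1]:
            raise ValidationError("focal pair must be two distinct residues")


@dataclass(frozen=True)
class OrthologSim:
    seq_a: str                 # source (e.g. methanogen-like)
    seq_b: str                 # target (e.g. sulphur-metaboliser-like)
    true_counts: np.ndarray    # 20x20 directed replacement counts a -> b
    n_substituted: int


_RES_IDX = {a: i for i, a in enumerate(RESIDUES)}


def simulate_ortholog_pair(ancestor_length: int, divergence: float,
                           bias_spec: SubstitutionBias = SubstitutionBias(),
                           seed: int = 0) -> OrthologSim:
    """Simulate one ungapped ortholog pair with exact truth counts."""
    if not 0.0 <= divergence < 0.5:
        raise ValidationError(f"divergence {divergence} outside [0, 0.5)")
    rng = np.random.default_rng(seed)
    L = ancestor_length
    if bias_spec.n_columns is not None:
        if bias_spec.n_columns > L:
            raise ValidationError("n_columns exceeds ancestor_length")
        sub_pos = rng.choice(L, size=bias_spec.n_columns, replace=False)
        sub_mask = np.zeros(L, dtype=bool)
        sub_mask[sub_pos] = True
    else:
        sub_mask = rng.random(L) < divergence
    n_sub = int(sub_mask.sum())

    a = rng.integers(0, 20, size=L)
    b = a.copy()
    counts = np.zeros((20, 20), dtype=np.int64)

    fi, fj = _RES_IDX[bias_spec.pair[0]], _RES_IDX[bias_spec.pair[1]]
    # directed pairs available to non-focal events (exclude both focal directions)
    others = [(s, t) for s in range(20) for t in range(20)
              if s != t and {s, t} != {fi, fj}]
    others = np.array(others)

    focal = rng.random(n_sub) < bias_spec.focal_share
    forward = rng.random(n_sub) < bias_spec.multiplier / (bias_spec.multiplier + 1.0)
    other_idx = rng.integers(0, len(others), size=n_sub)

    src = np.where(focal, np.where(forward, fi, fj), others[other_idx, 0])
    tgt = np.where(focal, np.where(forward, fj, fi), others[other_idx, 1])
    a[sub_mask] = src
    b[sub_mask] = tgt
    np.add.at(counts, (src, tgt), 1)

    res = np.array(list(RESIDUES))
    return OrthologSim(seq_a="".join(res[a]), seq_b="".join(res[b]),
                       true_counts=counts, n_substituted=n_sub)


# ---------------------------------------------------------------------------
# COG universes


@dataclass(frozen=True)
class CogUniverseSpec:
    seed: int = 0
    universe_size: int = 2000
    groups: Mapping[str, int] = field(
        default_factory=lambda: {"methanogen": 25, "sulphur_metaboliser": 26,
                                 "other": 18})
    core_size: Mapping[str, int] = field(
        default_factory=lambda: {"methanogen": 488, "sulphur_metaboliser": 196,
                                 "other": 50})
    exclusive_size: Mapping[str, int] = field(
        default_factory=lambda: {"methanogen": 22, "sulphur_metaboliser": 0,
                                 "other": 0})
    noise_mean: float = 40.0   # extra random (non-exclusive) IDs per organism

    def __post_init__(self):
        total_exclusive = sum(self.exclusive_size.values())
        if total_exclusive > self.universe_size:
            raise ValidationError("exclusive IDs exceed universe")
        for g, core in self.core_size.items():
            if core + 0 > self.universe_size:
                raise ValidationError(f"group {g}: core exceeds universe")
            if self.exclusive_size.get(g, 0) > core:
                raise ValidationError(f"group {g}: exclusive exceeds core")


@dataclass(frozen=True)
class CogUniverse:
    spec: CogUniverseSpec
    organisms: Mapping[str, tuple[CogAnnotation, ...]]   # org -> annotation rows
    group_of: Mapping[str, str]
    truth_core: Mapping[str, frozenset[str]]
    truth_exclusive: Mapping[str, frozenset[str]]
    categories_of: Mapping[str, str]

    def cog_ids(self, organism_id: str) -> frozenset[str]:
        return frozenset(a.cog_id for a in self.organisms[organism_id])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for org in sorted(self.organisms):
            write_cog_annotations(self.organisms[org], outdir / f"{org}.tsv")


def _random_categories(rng: np.random.Generator) -> str:
    from .residues import COG_CATEGORIES
    k = 1 + int(rng.random() < 0.2)   # ~20% of COGs carry two letters
    picks = rng.choice(len(COG_CATEGORIES), size=k, replace=False)
    return "".join(COG_CATEGORIES[i] for i in sorted(picks))


def simulate_cog_universe(spec: CogUniverseSpec = CogUniverseSpec()) -> CogUniverse:
    """Plant group cores and group-exclusive COG sets in a synthetic universe.

    Every group member carries its group core (which contains the group's
    exclusive set); exclusive IDs never appear outside their group. Noise
    IDs are sprinkled from the non-exclusive part of the universe, and every
    non-exclusive core ID is guaranteed to occur in at least one organism
    outside its group, so an exclusive-core search recovers exactly the
    planted exclusive sets (and the empty set for groups planted with none).
    """
    rng = np.random.default_rng(spec.seed)
    width = max(4, len(str(spec.universe_size)))
    universe = [f"COG{i:0{width}d}" for i in range(1, spec.universe_size + 1)]
    categories_of = {cid: _random_categories(rng) for cid in universe}

    pool = list(universe)
    rng.shuffle(pool)
    exclusive: dict[str, frozenset[str]] = {}
    cursor = 0
    for g in spec.groups:
        k = spec.exclusive_size.get(g, 0)
        exclusive[g] = frozenset(pool[cursor:cursor + k])
        cursor += k
    shared_pool = pool[cursor:]   # never exclusive to anyone

    core: dict[str, frozenset[str]] = {}
    for g in spec.groups:
        extra = spec.core_size[g] - len(exclusive[g])
        if extra > len(shared_pool):
            raise ValidationError(f"group {g}: core size exceeds shared pool")
        picks = rng.choice(len(shared_pool), size=extra, replace=False)
        core[g] = exclusive[g] | frozenset(shared_pool[i] for i in picks)

    org_sets: dict[str, set[str]] = {}
    group_of: dict[str, str] = {}
    for g, n in spec.groups.items():
        for i in range(n):
            org = f"{g}_{i:03d}"
            group_of[org] = g
            ids = set(core[g])
            n_noise = rng.poisson(spec.noise_mean)
            noise = rng.choice(len(shared_pool), size=min(n_noise, len(shared_pool)),
                               replace=False)
            ids |= {shared_pool[j] for j in noise}
            # noise must not fake exclusivity elsewhere: shared_pool is safe
            org_sets[org] = ids

    # Exclusivity must be exactly the planted sets: every core ID that is
    # *not* planted exclusive is leaked round-robin into organisms outside
    # its group. This also makes reverse searches (zero-exclusive groups)
    # provably come back empty.
    for g in spec.groups:
        outside = sorted(o for o in org_sets if group_of[o] != g)
        if not outside:
            continue
        for k, cid in enumerate(sorted(core[g] - exclusive[g])):
            org_sets[outside[k % len(outside)]].add(cid)

    organisms = {}
    for org in sorted(org_sets):
        rows = tuple(
            CogAnnotation(protein_id=f"{org}_g{i:05d}", cog_id=cid,
                          categories=categories_of[cid])
            for i, cid in enumerate(sorted(org_sets[org])))
        organisms[org] = rows
    return CogUniverse(spec=spec, organisms=organisms, group_of=group_of,
                       truth_core=core,
                       truth_exclusive=exclusive, categories_of=categories_of)


# ---------------------------------------------------------------------------
# full study bundles


@dataclass(frozen=True)
class StudySpec:
    seed: int = 0
    n_organisms: int = 8
    gc_range: tuple[float, float] = (0.30, 0.70)
    n_proteins: int = 60
    length_dist: LengthDist = LengthDist(min=100, mean=250, max=800)
    charge_boost: float = 2.0     # D/E boost for methanogens, K/R for sulphur
    n_ortholog_pairs: int = 40
    ortholog_length: int = 300
    divergence: float = 0.15
    bias: SubstitutionBias = SubstitutionBias(pair=("R", "K"), multiplier=1.0,
                                              focal_share=0.0)
    cog_spec: CogUniverseSpec | None = None


@dataclass(frozen=True)
class StudyBundle:
    root: Path
    metadata_path: Path
    proteome_paths: Mapping[str, Path]
    cog_paths: Mapping[str, Path]
    hit_table_path: Path
    manifest_path: Path
    truths: Mapping[str, ProteomeTruth]


def simulate_study(spec: StudySpec, outdir: str | Path) -> StudyBundle:
    """Write a complete synthetic study bundle the pipeline can consume:
    metadata TSV, per-organism proteome FASTAs and COG annotation TSVs, an
    ortholog hit table, and a JSON manifest of all planted parameters.

    Organisms alternate between a methanogen-like group (acidic plant,
    Asp/Glu codons boosted) and a sulphur-metaboliser-like group (basic
    plant, Lys/Arg boosted); GC targets are evenly spaced over
    ``gc_range``.
    """
    outdir = Path(outdir)
    (outdir / "proteomes").mkdir(parents=True, exist_ok=True)
    (outdir / "cogs").mkdir(exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    n = spec.n_organisms
    if n < 2:
        raise ValidationError("need at least 2 organisms")
    gcs = np.linspace(*spec.gc_range, n)
    metadata: list[OrganismMetadata] = []
    truths: dict[str, ProteomeTruth] = {}
    proteome_paths: dict[str, Path] = {}
    temp_cycle = ("mesophile", "thermophile", "hyperthermophile")
    oxy_cycle = ("anaerobe", "aerobe", "microaerophile", "facultative")
    seen_ids: set[str] = set()
    for i in range(n):
        group = "methanogen" if i % 2 == 0 else "sulphur_metaboliser"
        org = f"syn{i:02d}_{'met' if group == 'methanogen' else 'sul'}"
        if org in seen_ids:
            raise ValidationError(f"organism ID collision: {org}")
        seen_ids.add(org)
        de = spec.charge_boost if group == "methanogen" else 1.0
        kr = spec.charge_boost if group == "sulphur_metaboliser" else 1.0
        proteome, truth = simulate_proteome(
            gc_target=float(gcs[i]), n_proteins=spec.n_proteins,
            length_dist=spec.length_dist,
            seed=int(rng.integers(0, 2**31 - 1)), organism_id=org,
            de_boost=de, kr_boost=kr)
        path = outdir / "proteomes" / f"{org}.fasta"
        write_proteome_fasta(proteome, path)
        proteome_paths[org] = path
        truths[org] = truth
        metadata.append(OrganismMetadata(
            organism_id=org, short_name=org[:8],
            phylum="euryarchaeota" if group == "methanogen" else "crenarchaeota",
            class_=f"class_{group[:4]}", order_=f"order_{group[:4]}{i % 2}",
            gc_percent=round(truth.realized_gc * 100.0, 2),
            temp_adaptation=temp_cycle[i % 3], oxygen=oxy_cycle[i % 4],
            metabolic_group=group, salinity="non_halophile"))

    metadata_path = outdir / "metadata.tsv"
    write_metadata_table(metadata, metadata_path)

    cog_spec = spec.cog_spec or CogUniverseSpec(
        seed=int(rng.integers(0, 2**31 - 1)), universe_size=400,
        groups={"methanogen": (n + 1) // 2, "sulphur_metaboliser": n // 2},
        core_size={"methanogen": 60, "sulphur_metaboliser": 40},
        exclusive_size={"methanogen": 5, "sulphur_metaboliser": 0},
        noise_mean=20.0)
    universe = simulate_cog_universe(cog_spec)
    cog_paths: dict[str, Path] = {}
    meta_by_group: dict[str, list[str]] = {}
    for m in metadata:
        meta_by_group.setdefault(m.metabolic_group, []).append(m.organism_id)
    universe_orgs = sorted(universe.organisms)
    mapping: dict[str, str] = {}
    for g, members in meta_by_group.items():
        pool = [o for o in universe_orgs if universe.group_of[o] == g]
        for org, uorg in zip(members, pool):
            mapping[org] = uorg
    for org, uorg in mapping.items():
        path = outdir / "cogs" / f"{org}.tsv"
        write_cog_annotations(universe.organisms[uorg], path)
        cog_paths[org] = path

    # ortholog hit table + pair FASTAs between the first organisms of each group
    sims = [simulate_ortholog_pair(spec.ortholog_length, spec.divergence,
                                   spec.bias, seed=int(rng.integers(0, 2**31 - 1)))
            for _ in range(spec.n_ortholog_pairs)]
    hits = []
    for k, sim in enumerate(sims):
        ident = 1.0 - sim.n_substituted / spec.ortholog_length
        hits.append(OrthologHit(
            query_id=f"orth{k:03d}_a", subject_id=f"orth{k:03d}_b",
            similarity_percent=round(100.0 * ident, 2),
            query_length=spec.ortholog_length,
            subject_length=spec.ortholog_length, evalue=1e-50))
    hit_table_path = outdir / "hits.tsv"
    write_hit_table(hits, hit_table_path)
    src = Proteome("ortholog_source",
                   [ProteinRecord(f"orth{k:03d}_a", s.seq_a) for k, s in enumerate(sims)])
    tgt = Proteome("ortholog_target",
                   [ProteinRecord(f"orth{k:03d}_b", s.seq_b) for k, s in enumerate(sims)])
    write_proteome_fasta(src, outdir / "ortholog_source.fasta")
    write_proteome_fasta(tgt, outdir / "ortholog_target.fasta")

    manifest = {
        "seed": spec.seed,
        "n_organisms": n,
        "gc_targets": {m.organism_id: truths[m.organism_id].gc_target for m in metadata},
        "charge_boost": spec.charge_boost,
        "groups": {m.organism_id: m.metabolic_group for m in metadata},
        "cog_truth": {
            "core": {g: sorted(s) for g, s in universe.truth_core.items()},
            "exclusive": {g: sorted(s) for g, s in universe.truth_exclusive.items()},
        },
        "ortholog_bias": asdict(spec.bias),
        "ortholog_true_counts_total": int(sum(s.true_counts.sum() for s in sims)),
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return StudyBundle(root=outdir, metadata_path=metadata_path,
                       proteome_paths=proteome_paths, cog_paths=cog_paths,
                       hit_table_path=hit_table_path, manifest_path=manifest_path,
                       truths=truths)
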