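"""Readers, writers and validation for proteomes, metadata, COG annotations
and ortholog hit tables.

All tabular formats are UTF-8, tab-separated with a header row; protein
sequences travel as standard FASTA. Sequences may contain the ambiguity
codes B/Z/X/U; they are retained in records but excluded from composition
denominators downstream. A trailing ``*`` (stop) is stripped before the
length filter is applied.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .residues import RESIDUE_SET, AMBIGUOUS, COG_CATEGORY_SET

log = logging.getLogger(__name__)

DEFAULT_MIN_LENGTH = 100

TEMP_VOCAB = frozenset({"mesophile", "thermophile", "hyperthermophile", "unknown"})
OXYGEN_VOCAB = frozenset({"aerobe", "anaerobe", "microaerophile", "facultative", "unknown"})
METABOLIC_VOCAB = frozenset({"methanogen", "sulphur_metaboliser", "other"})
SALINITY_VOCAB = frozenset({"halophile", "non_halophile", "unknown"})

_VALID_CHARS = RESIDUE_SET | frozenset(AMBIGUOUS)


class ValidationError(ValueError):
    """Input violates a documented invariant."""


class SchemaError(ValidationError):
    """A table is missing required columns or has an unusable layout."""


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence.

    ``sequence`` is upper-case over the 20 standard one-letter codes plus the
    ambiguity codes B/Z/X/U; terminal stop characters have been removed.
    """

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Proteome:
    """An organism's protein set surviving the minimum-length filter."""

    organism_id: str
    records: list[ProteinRecord]
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)


@dataclass(frozen=True)
class OrganismMetadata:
    organism_id: str
    short_name: str
    phylum: str
    class_: str
    order_: str
    gc_percent: float
    temp_adaptation: str
    oxygen: str
    metabolic_group: str
    salinity: str

    def __post_init__(self):
        if not 0.0 <= self.gc_percent <= 100.0:
            raise ValidationError(
                f"{self.organism_id}: gc_percent {self.gc_percent} outside [0, 100]")
        for name, value, vocab in (
            ("temp_adaptation", self.temp_adaptation, TEMP_VOCAB),
            ("oxygen", self.oxygen, OXYGEN_VOCAB),
            ("metabolic_group", self.metabolic_group, METABOLIC_VOCAB),
            ("salinity", self.salinity, SALINITY_VOCAB),
        ):
            if value not in vocab:
                raise ValidationError(
                    f"{self.organism_id}: {name} value {value!r} not in {sorted(vocab)}")


@dataclass(frozen=True)
class CogAnnotation:
    protein_id: str
    cog_id: str
    categories: str

    def __post_init__(self):
        if not (self.cog_id.startswith("COG") and self.cog_id[3:].isdigit()
                and len(self.cog_id) > 3):
            raise ValidationError(f"malformed COG ID {self.cog_id!r}")
        if not self.categories:
            raise ValidationError(f"{self.protein_id}: empty category string")
        bad = set(self.categories) - COG_CATEGORY_SET
        if bad:
            raise ValidationError(
                f"{self.protein_id}: category letter(s) {sorted(bad)} outside alphabet")


class CogAnnotationTable(list):
    """List of :class:`CogAnnotation` that remembers how many un-annotated
    rows (no COG ID) were dropped on read."""

    def __init__(self, annotations: Sequence[CogAnnotation], n_dropped: int = 0):
        super().__init__(annotations)
        self.n_dropped = n_dropped


@dataclass(frozen=True)
class OrthologHit:
    query_id: str
    subject_id: str
    similarity_percent: float
    query_length: int
    subject_length: int
    evalue: float

    def __post_init__(self):
        if self.query_length <= 0 or self.subject_length <= 0:
            raise ValidationError(
                f"{self.query_id}/{self.subject_id}: non-positive length")
        if self.evalue < 0:
            raise ValidationError(f"{self.query_id}: negative e-value")
        if not 0.0 <= self.similarity_percent <= 100.0:
            raise ValidationError(
                f"{self.query_id}: similarity {self.similarity_percent} outside [0, 100]")


# ---------------------------------------------------------------------------
# proteomes


def _clean_sequence(raw: str, record_id: str) -> str:
    seq = str(raw).upper().strip("*")
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise ValidationError(
            f"record {record_id}: invalid sequence character(s) {sorted(bad)}")
    return seq


def read_proteome_fasta(path: str | Path, min_length: int = DEFAULT_MIN_LENGTH,
                        organism_id: str | None = None) -> Proteome:
    """Read a protein FASTA, dropping records shorter than ``min_length``.

    Terminal stop characters (``*``) are stripped before the length check.
    Raises :class:`ValidationError` on duplicate IDs or if nothing survives
    the filter.
    """
    path = Path(path)
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    dropped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"{path.name}: duplicate record ID {rec.id!r}")
        seen.add(rec.id)
        seq = _clean_sequence(str(rec.seq), rec.id)
        if len(seq) >= min_length:
            records.append(ProteinRecord(id=rec.id, sequence=seq))
        else:
            dropped += 1
    if not records:
        raise ValidationError(
            f"{path.name}: no records of length >= {min_length}")
    log.info("%s: kept %d records, dropped %d (< %d residues)",
             path.name, len(records), dropped, min_length)
    return Proteome(organism_id=organism_id or path.stem,
                    records=records, n_dropped=dropped)


def write_proteome_fasta(proteome: Proteome, path: str | Path,
                         width: int = 60) -> None:
    """Write a proteome as wrapped FASTA (deterministic byte layout)."""
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="")
                   for r in proteome.records]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def filter_proteome(proteome: Proteome, min_length: int = DEFAULT_MIN_LENGTH) -> Proteome:
    """Apply the minimum-length filter to an in-memory proteome (idempotent)."""
    kept = [r for r in proteome.records if r.length >= min_length]
    dropped = len(proteome.records) - kept.__len__()
    if not kept:
        raise ValidationError(
            f"{proteome.organism_id}: no records of length >= {min_length}")
    return Proteome(proteome.organism_id, kept, proteome.n_dropped + dropped)


# ---------------------------------------------------------------------------
# metadata

_META_COLUMNS = ["organism_id", "short_name", "phylum", "class", "order",
                 "gc_percent", "temp_adaptation", "oxygen", "metabolic_group",
                 "salinity"]


def read_metadata_table(path: str | Path) -> list[OrganismMetadata]:
    """Read the organism metadata TSV; every categorical token is validated
    against its closed vocabulary."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_META_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    out: list[OrganismMetadata] = []
    for idx, row in df.iterrows():
        try:
            gc = float(row["gc_percent"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"{path}: row {idx}: non-numeric gc_percent {row['gc_percent']!r}") from exc
        try:
            out.append(OrganismMetadata(
                organism_id=row["organism_id"], short_name=row["short_name"],
                phylum=row["phylum"], class_=row["class"], order_=row["order"],
                gc_percent=gc, temp_adaptation=row["temp_adaptation"],
                oxygen=row["oxygen"], metabolic_group=row["metabolic_group"],
                salinity=row["salinity"]))
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from exc
    return out


def write_metadata_table(metadata: Sequence[OrganismMetadata], path: str | Path) -> None:
    rows = [{"organism_id": m.organism_id, "short_name": m.short_name,
             "phylum": m.phylum, "class": m.class_, "order": m.order_,
             "gc_percent": m.gc_percent, "temp_adaptation": m.temp_adaptation,
             "oxygen": m.oxygen, "metabolic_group": m.metabolic_group,
             "salinity": m.salinity} for m in metadata]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)


def metadata_frame(metadata: Sequence[OrganismMetadata]) -> pd.DataFrame:
    """Metadata as a DataFrame indexed by organism_id (attribute field names)."""
    return pd.DataFrame(
        [{"organism_id": m.organism_id, "short_name": m.short_name,
          "phylum": m.phylum, "class_": m.class_, "order_": m.order_,
          "gc_percent": m.gc_percent, "temp_adaptation": m.temp_adaptation,
          "oxygen": m.oxygen, "metabolic_group": m.metabolic_group,
          "salinity": m.salinity} for m in metadata]).set_index("organism_id")


# ---------------------------------------------------------------------------
# COG annotations

_NO_COG_TOKENS = {"", "-", "NA", "na", "none", "None"}


def read_cog_annotations(path: str | Path) -> CogAnnotationTable:
    """Read a per-organism COG annotation TSV (protein_id, cog_id, categories).

    Rows without a COG ID are dropped and counted on the returned table's
    ``n_dropped`` attribute; malformed COG IDs or out-of-alphabet category
    letters raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"protein_id", "cog_id", "categories"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    annotations: list[CogAnnotation] = []
    dropped = 0
    for idx, row in df.iterrows():
        if row["cog_id"].strip() in _NO_COG_TOKENS:
            dropped += 1
            continue
        try:
            annotations.append(CogAnnotation(
                protein_id=row["protein_id"], cog_id=row["cog_id"].strip(),
                categories=row["categories"].strip()))
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from exc
    log.info("%s: %d annotations, %d rows without COG ID dropped",
             path, len(annotations), dropped)
    return CogAnnotationTable(annotations, n_dropped=dropped)


def write_cog_annotations(annotations: Sequence[CogAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [{"protein_id": a.protein_id, "cog_id": a.cog_id, "categories": a.categories}
         for a in annotations],
        columns=["protein_id", "cog_id", "categories"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ortholog hit tables

_HIT_COLUMNS = ["query_id", "subject_id", "similarity_percent",
                "query_length", "subject_length", "evalue"]


def read_hit_table(path: str | Path,
                   columns: Sequence[str] = tuple(_HIT_COLUMNS)) -> list[OrthologHit]:
    """Read an ortholog hit table (BLAST-tabular-like dialect).

    ``columns`` maps the file's column order onto the canonical field names,
    so tables with extra or re-ordered columns can be consumed. No filtering
    is applied here; ortholog criteria live in :mod:`protniche.substitution`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_HIT_COLUMNS) - set(columns)
    if missing:
        raise SchemaError(f"column mapping lacks {sorted(missing)}")
    if list(df.columns) != list(columns):
        if len(df.columns) < len(columns):
            raise SchemaError(
                f"{path}: expected >= {len(columns)} columns, found {len(df.columns)}")
        df.columns = list(columns) + list(df.columns[len(columns):])
    hits: list[OrthologHit] = []
    for idx, row in df.iterrows():
        try:
            hits.append(OrthologHit(
                query_id=row["query_id"], subject_id=row["subject_id"],
                similarity_percent=float(row["similarity_percent"]),
                query_length=int(row["query_length"]),
                subject_length=int(row["subject_length"]),
                evalue=float(row["evalue"])))
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from exc
    return hits


def write_hit_table(hits: Sequence[OrthologHit], path: str | Path) -> None:
    pd.DataFrame(
        [{"query_id": h.query_id, "subject_id": h.subject_id,
          "similarity_percent": h.similarity_percent,
          "query_length": h.query_length, "subject_length": h.subject_length,
          "evalue": h.evalue} for h in hits],
        columns=_HIT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write any result table as UTF-8 TSV."""
    df.to_csv(path, sep="\t", index=index)
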