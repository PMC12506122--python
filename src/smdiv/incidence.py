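"""Ingestion of BGC→GCF clustering tables and species × GCF incidence matrices.

The sampling substrate for all richness estimation in this package is a
binary incidence matrix: rows are sampling units (species by default, or
individual genomes), columns are gene cluster families (GCFs), and a cell is
1 when at least one biosynthetic gene cluster (BGC) of that family occurs in
that unit.  Multiple BGC copies of the same family within a unit collapse to
a single presence.

Input follows the BiG-SCAPE clustering-table convention: a tab-separated
file whose default columns are ``#BGC Name`` and ``Family Number``.  Because
that file carries no taxonomy, a sidecar metadata table maps each BGC to its
genome and species (and, optionally, a BGC class label and a contig-edge
flag).
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BgcRecord",
    "ClusteringDialect",
    "IncidenceMatrix",
    "DatasetSummary",
    "read_clustering_table",
    "read_bgc_metadata",
    "filter_bgcs",
    "build_incidence",
    "summarize",
]


@dataclass(frozen=True)
class BgcRecord:
    """One putative BGC with its family assignment and provenance.

    ``genome_id``/``species_id`` may be ``None`` when a clustering table is
    read without its metadata sidecar; such records cannot enter an
    incidence matrix.
    """

    bgc_id: str
    gcf_id: str
    genome_id: str | None = None
    species_id: str | None = None
    bgc_class: str | None = None
    contig_edge: bool | None = None


@dataclass(frozen=True)
class ClusteringDialect:
    """Column naming for a BiG-SCAPE-style clustering table."""

    bgc_col: str = "#BGC Name"
    family_col: str = "Family Number"
    sep: str = "\t"


DEFAULT_DIALECT = ClusteringDialect()

#: expected sidecar columns; class and contig_edge are optional
_META_REQUIRED = ("bgc_id", "genome_id", "species_id")


@dataclass
class IncidenceMatrix:
    """Binary presence/absence of each GCF across sampling units."""

    unit_ids: list[str]
    gcf_ids: list[str]
    cells: np.ndarray  # shape (T, S_obs), dtype uint8

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.uint8)
        if self.cells.shape != (len(self.unit_ids), len(self.gcf_ids)):
            raise ValueError("cell block shape does not match id lists")
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise ValueError("duplicate unit_ids")
        if len(set(self.gcf_ids)) != len(self.gcf_ids):
            raise ValueError("duplicate gcf_ids")
        if not np.isin(self.cells, (0, 1)).all():
            raise ValueError("incidence cells must be 0/1")
        if self.cells.size and (self.cells.sum(axis=0) == 0).any():
            raise ValueError("every GCF column must have at least one presence")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_gcfs(self) -> int:
        return len(self.gcf_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=pd.Index(self.unit_ids, name="species_id"),
                            columns=self.gcf_ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "IncidenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
        return cls(unit_ids=[str(u) for u in df.index],
                   gcf_ids=[str(g) for g in df.columns],
                   cells=df.to_numpy())


@dataclass(frozen=True)
class DatasetSummary:
    """Headline counts for a BGC/GCF dataset."""

    n_bgcs: int
    n_gcfs: int
    n_units: int
    mean_bgcs_per_unit: float
    singleton_count: int
    singleton_fraction: float
    class_tally: dict[str, int] = field(default_factory=dict)


def read_bgc_metadata(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read the sidecar ``bgc_id -> genome_id, species_id[, class, contig_edge]`` table."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in _META_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table missing columns: {missing}")
    return df.set_index("bgc_id")


def read_clustering_table(
    path: str | Path,
    dialect: ClusteringDialect = DEFAULT_DIALECT,
    metadata: str | Path | pd.DataFrame | None = None,
) -> list[BgcRecord]:
    """Parse a clustering table into :class:`BgcRecord` objects.

    Rows with a missing BGC or family identifier are dropped; the number of
    rejected rows is reported through :func:`warnings.warn`.  When
    ``metadata`` is given (path or frame from :func:`read_bgc_metadata`),
    genome/species/class/edge fields are joined in by ``bgc_id``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=dialect.sep, dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise ValueError(f"unparseable clustering table {path}: {exc}") from exc
    for col in (dialect.bgc_col, dialect.family_col):
        if col not in df.columns:
            # tolerate a '#'-prefixed or unprefixed variant of the configured name
            alt = col.lstrip("#") if col.startswith("#") else "#" + col
            if alt in df.columns:
                df = df.rename(columns={alt: col})
            else:
                raise ValueError(
                    f"clustering table {path} lacks column {col!r} (columns: {list(df.columns)})")

    bad = df[dialect.bgc_col].isna() | (df[dialect.bgc_col].str.strip() == "") \
        | df[dialect.family_col].isna() | (df[dialect.family_col].str.strip() == "")
    n_rejected = int(bad.sum())
    if n_rejected:
        first = df.index[bad][0] + 2  # 1-based, after header
        warnings.warn(
            f"rejected {n_rejected} row(s) with missing bgc_id/gcf_id "
            f"(first offending line {first})", stacklevel=2)
    df = df[~bad]
    if df.empty:
        raise ValueError(f"no parseable BGC rows in {path}")

    meta = None
    if metadata is not None:
        meta = metadata if isinstance(metadata, pd.DataFrame) else read_bgc_metadata(metadata)

    records = []
    for bgc_id, gcf_id in zip(df[dialect.bgc_col], df[dialect.family_col]):
        bgc_id, gcf_id = bgc_id.strip(), gcf_id.strip()
        if meta is not None and bgc_id in meta.index:
            row = meta.loc[bgc_id]
            edge = row.get("contig_edge")
            records.append(BgcRecord(
                bgc_id=bgc_id, gcf_id=gcf_id,
                genome_id=row["genome_id"], species_id=row["species_id"],
                bgc_class=row.get("class") if pd.notna(row.get("class")) else None,
                contig_edge=None if edge is None or pd.isna(edge)
                else str(edge).lower() in ("1", "true", "yes"),
            ))
        else:
            records.append(BgcRecord(bgc_id=bgc_id, gcf_id=gcf_id))
    dupes = [b for b, k in Counter(r.bgc_id for r in records).items() if k > 1]
    if dupes:
        raise ValueError(f"duplicate bgc_id values: {dupes[:5]}")
    return records


def filter_bgcs(records: list[BgcRecord], drop_contig_edge: bool = False) -> list[BgcRecord]:
    """Optionally drop BGCs lying on a contig edge (truncated clusters).

    With the flag off this is the identity: no other filtering criteria are
    built in, since upstream filtering conventions vary; callers apply their
    own predicates before :func:`build_incidence` if needed.
    """
    if not drop_contig_edge:
        return list(records)
    kept = [r for r in records if not r.contig_edge]
    logger.info("contig-edge filter: kept %d of %d BGCs", len(kept), len(records))
    return kept


def build_incidence(records: list[BgcRecord], unit_level: str = "species") -> IncidenceMatrix:
    """Collapse BGC records to a binary unit × GCF incidence matrix.

    ``unit_level`` is ``"species"`` (default) or ``"genome"``.  At species
    level, when several genomes share a species, only the lexicographically
    smallest genome_id is kept (deterministic deduplication); dropped
    genomes are logged.
    """
    if unit_level not in ("species", "genome"):
        raise ValueError(f"unit_level must be 'species' or 'genome', got {unit_level!r}")
    if not records:
        raise ValueError("cannot build an incidence matrix from zero records")
    for r in records:
        if r.species_id is None or r.genome_id is None:
            raise ValueError(
                f"record {r.bgc_id!r} lacks genome/species metadata; "
                "supply the metadata sidecar to read_clustering_table")

    if unit_level == "species":
        keep: dict[str, str] = {}
        for r in records:
            cur = keep.get(r.species_id)
            if cur is None or r.genome_id < cur:
                keep[r.species_id] = r.genome_id
        dropped = sorted({(r.species_id, r.genome_id) for r in records
                          if r.genome_id != keep[r.species_id]})
        if dropped:
            logger.info("species dedup dropped genomes: %s", dropped)
        records = [r for r in records if r.genome_id == keep[r.species_id]]
        unit_of = lambda r: r.species_id
    else:
        unit_of = lambda r: r.genome_id

    unit_ids = sorted({unit_of(r) for r in records})
    gcf_ids = sorted({r.gcf_id for r in records})
    u_index = {u: i for i, u in enumerate(unit_ids)}
    g_index = {g: j for j, g in enumerate(gcf_ids)}
    cells = np.zeros((len(unit_ids), len(gcf_ids)), dtype=np.uint8)
    for r in records:
        cells[u_index[unit_of(r)], g_index[r.gcf_id]] = 1
    return IncidenceMatrix(unit_ids=unit_ids, gcf_ids=gcf_ids, cells=cells)


def summarize(records: list[BgcRecord], matrix: IncidenceMatrix) -> DatasetSummary:
    """Headline counts: BGC/GCF totals, mean BGCs per unit, singleton GCFs.

    A singleton GCF occurs in exactly one sampling unit.  The mean is kept
    at full precision; display rounding (one decimal) is the caller's
    concern.
    """
    occupancy = matrix.cells.sum(axis=0)
    singleton_count = int((occupancy == 1).sum())
    class_tally = Counter(r.bgc_class for r in records if r.bgc_class is not None)
    return DatasetSummary(
        n_bgcs=len(records),
        n_gcfs=matrix.n_gcfs,
        n_units=matrix.n_units,
        mean_bgcs_per_unit=len(records) / matrix.n_units,
        singleton_count=singleton_count,
        singleton_fraction=singleton_count / matrix.n_gcfs,
        class_tally=dict(class_tally),
    )
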