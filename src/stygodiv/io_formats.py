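"""Readers and writers for the pipeline's on-disk formats.

Everything downstream consumes the domain types defined here: species-labelled
nucleotide sequences (FASTA), the ASV-by-replicate read count matrix with its
replicate metadata sheet (TSV), citizen-science specimen tables with per-site
sampling effort (TSV), and generic result tables (TSV).

Conventions
-----------
* FASTA headers may carry a species label after a configurable delimiter,
  ``>seqid|Genus species``. Sequences are upper-cased on read and restricted to
  IUPAC nucleotide codes.
* All dates are ISO-8601 (``YYYY-MM-DD``); no other format is accepted, so the
  exact-date comparison mode is unambiguous.
* Read counts are non-negative integers. Fractional abundances are rejected:
  the decontamination arithmetic is defined on raw read counts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "SequenceRecord",
    "ReplicateMeta",
    "ReadCountTable",
    "SpecimenRecord",
    "EffortTable",
    "read_fasta",
    "write_fasta",
    "read_count_table",
    "write_count_table",
    "read_specimen_table",
    "write_specimen_table",
    "write_table",
]

IUPAC_NT = frozenset("ACGTURYSWKMBDHVN")
REPLICATE_STATUSES = ("used", "unused", "control")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates a domain-type invariant."""


@dataclass(frozen=True)
class SequenceRecord:
    """A nucleotide sequence with an optional species label."""

    id: str
    sequence: str
    species: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record with empty id")
        seq = self.sequence.upper()
        if not seq:
            raise ValidationError(f"sequence {self.id!r} is empty")
        bad = set(seq) - IUPAC_NT
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class ReplicateMeta:
    """One sequencing replicate (index combination) and its role.

    Used replicates belong to a site; unused index combinations and negative
    controls have no site.
    """

    replicate_id: str
    status: str
    site_id: str | None = None
    filter_id: str | None = None
    pcr_tag: str | None = None

    def __post_init__(self) -> None:
        if self.status not in REPLICATE_STATUSES:
            raise ValidationError(
                f"replicate {self.replicate_id!r}: status {self.status!r} "
                f"not in {REPLICATE_STATUSES}"
            )
        if self.status == "used" and not self.site_id:
            raise ValidationError(
                f"used replicate {self.replicate_id!r} has no site_id"
            )
        if self.status != "used" and self.site_id:
            raise ValidationError(
                f"{self.status} replicate {self.replicate_id!r} must not have a site_id"
            )


@dataclass
class ReadCountTable:
    """ASV x replicate matrix of non-negative integer read counts.

    ``counts`` is a DataFrame indexed by ASV id with one column per replicate,
    matched one-to-one to ``replicates``. Per-ASV dataset totals are always
    recomputed from the matrix (never stored), so they cannot go stale.
    """

    counts: pd.DataFrame
    replicates: list[ReplicateMeta]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate ASV ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate replicate ids: {dups}")
        ids = [r.replicate_id for r in self.replicates]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate replicate ids in metadata")
        missing = [c for c in counts.columns if c not in set(ids)]
        if missing:
            raise ValidationError(f"count columns without metadata: {missing}")
        extra = [i for i in ids if i not in set(counts.columns)]
        if extra:
            raise ValidationError(f"metadata rows without count column: {extra}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            frac = values != np.floor(values)
            if np.any(frac) or not np.all(np.isfinite(values)):
                r, c = np.argwhere(frac | ~np.isfinite(values))[0]
                raise ValidationError(
                    f"non-integer count at ASV {counts.index[r]!r}, "
                    f"replicate {counts.columns[c]!r}"
                )
            self.counts = counts = counts.astype(np.int64)
            values = counts.to_numpy()
        if np.any(values < 0):
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at ASV {counts.index[r]!r}, "
                f"replicate {counts.columns[c]!r}"
            )
        # keep metadata in column order
        by_id = {r.replicate_id: r for r in self.replicates}
        self.replicates = [by_id[c] for c in counts.columns]

    # -- convenience views ------------------------------------------------
    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def meta(self) -> dict[str, ReplicateMeta]:
        return {r.replicate_id: r for r in self.replicates}

    def columns_with_status(self, status: str) -> list[str]:
        return [r.replicate_id for r in self.replicates if r.status == status]

    @property
    def used_columns(self) -> list[str]:
        return self.columns_with_status("used")

    @property
    def unused_columns(self) -> list[str]:
        return self.columns_with_status("unused")

    @property
    def control_columns(self) -> list[str]:
        return self.columns_with_status("control")

    @property
    def site_groups(self) -> dict[str, list[str]]:
        """Used replicate ids grouped by site, in column order."""
        groups: dict[str, list[str]] = {}
        for r in self.replicates:
            if r.status == "used":
                groups.setdefault(r.site_id, []).append(r.replicate_id)
        return groups

    @property
    def asv_totals(self) -> pd.Series:
        """Whole-dataset read total per ASV, recomputed from the matrix."""
        return self.counts.sum(axis=1)

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def copy(self) -> "ReadCountTable":
        return ReadCountTable(self.counts.copy(), list(self.replicates))


@dataclass(frozen=True)
class SpecimenRecord:
    """One citizen-science amphipod specimen."""

    specimen_id: str
    site_id: str
    collection_date: date
    species: str | None = None
    sequence_id: str | None = None


@dataclass
class EffortTable:
    """Per-site sampling duration (days) and, optionally, the eDNA sampling date."""

    durations: dict[str, int]
    edna_dates: dict[str, date | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for site, days in self.durations.items():
            if int(days) != days or days < 1:
                raise ValidationError(
                    f"site {site!r}: sampling duration must be a positive "
                    f"integer number of days, got {days!r}"
                )
            self.durations[site] = int(days)

    def duration(self, site: str) -> int:
        if site not in self.durations:
            raise ValidationError(f"site {site!r} missing from effort table")
        return self.durations[site]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, species_delimiter: str = "|") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    A species label may follow ``species_delimiter`` in the header; text after
    a second delimiter (or whitespace following the label) is ignored.
    Sequences are upper-cased; order is preserved. Malformed headers or
    illegal sequence characters raise :class:`ParseError` naming the line.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    header: tuple[str, str | None] | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        try:
            records.append(SequenceRecord(header[0], seq, species=header[1]))
        except ValidationError as exc:
            raise ParseError(f"{path}, record at line {header_line}: {exc}") from exc

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].strip()
                if not name:
                    raise ParseError(f"{path}, line {lineno}: empty FASTA header")
                if species_delimiter and species_delimiter in name:
                    seq_id, species = name.split(species_delimiter, 1)
                    species = species.split(species_delimiter, 1)[0].strip() or None
                    seq_id = seq_id.strip()
                else:
                    seq_id, species = name.split()[0], None
                header, chunks, header_line = (seq_id, species), [], lineno
            else:
                if header is None:
                    raise ParseError(
                        f"{path}, line {lineno}: sequence data before first header"
                    )
                bad = set(line.upper()) - IUPAC_NT
                if bad:
                    raise ParseError(
                        f"{path}, line {lineno}: illegal sequence "
                        f"character(s) {sorted(bad)}"
                    )
                chunks.append(line)
    flush()
    return records


def write_fasta(
    records: Iterable[SequenceRecord],
    path: str | Path,
    species_delimiter: str = "|",
    width: int = 80,
) -> Path:
    """Write records as FASTA, encoding the species label in the header."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            header = rec.id
            if rec.species:
                header = f"{rec.id}{species_delimiter}{rec.species}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# Count table + replicate metadata
# ---------------------------------------------------------------------------

_META_COLUMNS = ["replicate_id", "site_id", "filter_id", "pcr_tag", "status"]


def read_count_table(counts_path: str | Path, meta_path: str | Path) -> ReadCountTable:
    """Read an ASV x replicate count TSV plus its replicate metadata TSV.

    The counts file has ASV ids in the first column and one column per
    replicate; the metadata file has one row per replicate column.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
    missing_cols = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ParseError(f"{meta_path}: missing metadata columns {missing_cols}")
    replicates = [
        ReplicateMeta(
            replicate_id=row.replicate_id,
            status=row.status,
            site_id=row.site_id or None,
            filter_id=row.filter_id or None,
            pcr_tag=row.pcr_tag or None,
        )
        for row in meta.itertuples()
    ]
    return ReadCountTable(counts, replicates)


def write_count_table(
    table: ReadCountTable, counts_path: str | Path, meta_path: str | Path
) -> tuple[Path, Path]:
    counts_path, meta_path = Path(counts_path), Path(meta_path)
    out = table.counts.copy()
    out.index.name = "asv_id"
    out.to_csv(counts_path, sep="\t")
    meta = pd.DataFrame(
        [
            {
                "replicate_id": r.replicate_id,
                "site_id": r.site_id or "",
                "filter_id": r.filter_id or "",
                "pcr_tag": r.pcr_tag or "",
                "status": r.status,
            }
            for r in table.replicates
        ],
        columns=_META_COLUMNS,
    )
    meta.to_csv(meta_path, sep="\t", index=False)
    return counts_path, meta_path


# ---------------------------------------------------------------------------
# Specimens + effort
# ---------------------------------------------------------------------------

def _parse_iso_date(text: str, where: str) -> date:
    try:
        return date.fromisoformat(text)
    except ValueError as exc:
        raise ParseError(f"{where}: unparseable ISO-8601 date {text!r}") from exc


def read_specimen_table(
    path: str | Path, effort_path: str | Path
) -> tuple[list[SpecimenRecord], EffortTable]:
    """Read specimen records and the companion per-site effort file.

    Specimen TSV columns: specimen_id, site_id, collection_date, species
    (optional), sequence_id (optional). Effort TSV columns: site_id,
    duration_days, edna_date (optional).
    """
    spec_df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("specimen_id", "site_id", "collection_date"):
        if col not in spec_df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    records = [
        SpecimenRecord(
            specimen_id=row.specimen_id,
            site_id=row.site_id,
            collection_date=_parse_iso_date(
                row.collection_date, f"{path}, specimen {row.specimen_id}"
            ),
            species=(getattr(row, "species", "") or None),
            sequence_id=(getattr(row, "sequence_id", "") or None),
        )
        for row in spec_df.itertuples()
    ]
    eff_df = pd.read_csv(effort_path, sep="\t", dtype=str).fillna("")
    for col in ("site_id", "duration_days"):
        if col not in eff_df.columns:
            raise ParseError(f"{effort_path}: missing column {col!r}")
    durations: dict[str, int] = {}
    edna_dates: dict[str, date | None] = {}
    for row in eff_df.itertuples():
        try:
            durations[row.site_id] = int(row.duration_days)
        except ValueError as exc:
            raise ParseError(
                f"{effort_path}, site {row.site_id}: bad duration "
                f"{row.duration_days!r}"
            ) from exc
        raw = getattr(row, "edna_date", "")
        edna_dates[row.site_id] = (
            _parse_iso_date(raw, f"{effort_path}, site {row.site_id}") if raw else None
        )
    effort = EffortTable(durations, edna_dates)
    for rec in records:
        if rec.site_id not in effort.durations:
            raise ValidationError(
                f"specimen {rec.specimen_id!r}: site {rec.site_id!r} "
                f"missing from effort table"
            )
    return records, effort


def write_specimen_table(
    records: Sequence[SpecimenRecord],
    effort: EffortTable,
    path: str | Path,
    effort_path: str | Path,
) -> tuple[Path, Path]:
    path, effort_path = Path(path), Path(effort_path)
    pd.DataFrame(
        [
            {
                "specimen_id": r.specimen_id,
                "site_id": r.site_id,
                "collection_date": r.collection_date.isoformat(),
                "species": r.species or "",
                "sequence_id": r.sequence_id or "",
            }
            for r in records
        ],
        columns=["specimen_id", "site_id", "collection_date", "species", "sequence_id"],
    ).to_csv(path, sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "site_id": site,
                "duration_days": days,
                "edna_date": (
                    effort.edna_dates.get(site).isoformat()
                    if effort.edna_dates.get(site)
                    else ""
                ),
            }
            for site, days in effort.durations.items()
        ],
        columns=["site_id", "duration_days", "edna_date"],
    ).to_csv(effort_path, sep="\t", index=False)
    return path, effort_path


# ---------------------------------------------------------------------------
# Generic result tables
# ---------------------------------------------------------------------------

def write_table(rows: Sequence, path: str | Path) -> Path:
    """Write homogeneous result records (dataclasses, dicts or namedtuples) as
    a TSV with a header and deterministic column order.

    An empty list still writes a header-only file when the rows carry no
    schema; dataclass rows define the columns.
    """
    path = Path(path)
    dicts: list[dict] = []
    for row in rows:
        if dataclasses.is_dataclass(row):
            dicts.append(dataclasses.asdict(row))
        elif isinstance(row, Mapping):
            dicts.append(dict(row))
        elif hasattr(row, "_asdict"):
            dicts.append(row._asdict())
        else:
            raise TypeError(f"unsupported row type {type(row)!r}")
    df = pd.DataFrame(dicts)
    df.to_csv(path, sep="\t", index=False)
    return path
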