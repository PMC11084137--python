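"""Central table artifacts and their on-disk conventions.

The workflow's central artifact is the run-level metadata table: one row
per sequencing run, in either the ``ena`` dialect (ENA Portal API
filereport column canon) or a ``generic`` dialect.  Tables are UTF-8,
tab-separated, header row, Unix newlines.  Missing cells are the empty
string on disk; the token set ``{"", "NA", "na", "NaN", "nan", "None"}``
parses to missing and writing always emits ``""``.  Multi-file cells
(``fastq_ftp``, ``fastq_md5``, ...) hold one URL/checksum per file of the
run, separated by ``";"`` (ENA filereport convention).
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import DialectError, FormatError, InputError

#: Tokens that parse to a missing cell.  Writing always emits "".
NA_TOKENS = frozenset({"", "NA", "na", "NaN", "nan", "None"})

#: Separator for multi-file cells (ENA filereport convention).
MULTIVALUE_SEP = ";"

ENA_DIALECT = "ena"
GENERIC_DIALECT = "generic"

#: Column canon of the ena dialect (ENA Portal API filereport field names).
ENA_REQUIRED_COLUMNS = (
    "run_accession",
    "sample_accession",
    "library_layout",
    "fastq_ftp",
    "fastq_md5",
    "scientific_name",
    "tax_id",
    "instrument_platform",
    "instrument_model",
    "library_strategy",
    "library_source",
    "submitted_ftp",
)

VALID_LAYOUTS = ("PAIRED", "SINGLE")


def is_missing(cell) -> bool:
    """True for a missing cell (None/NaN after parsing)."""
    return cell is None or (not isinstance(cell, str) and pd.isna(cell))


def _normalise_na(df: pd.DataFrame) -> pd.DataFrame:
    df = df.astype(object)
    return df.mask(df.isin(NA_TOKENS), other=None).where(df.notna(), None)


@dataclass
class MetadataTable:
    """Run-level metadata table: ordered columns, string-or-missing cells.

    Wraps a pandas DataFrame of object dtype with ``None`` as the missing
    marker.  Construction validates the declared dialect's invariants:
    the ena dialect requires the filereport column canon, unique
    non-missing ``run_accession`` values and ``library_layout`` cells in
    {PAIRED, SINGLE} when present.
    """

    df: pd.DataFrame
    dialect: str = GENERIC_DIALECT

    def __post_init__(self):
        if self.dialect not in (ENA_DIALECT, GENERIC_DIALECT):
            raise InputError(f"unknown table dialect: {self.dialect!r}")
        cols = list(self.df.columns)
        if any(not isinstance(c, str) or c == "" for c in cols):
            raise FormatError("column names must be non-empty strings")
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        if dupes:
            raise FormatError(f"duplicated column names: {', '.join(dupes)}")
        self.df = _normalise_na(self.df)
        self.df.index = pd.RangeIndex(len(self.df))
        if self.dialect == ENA_DIALECT:
            self._validate_ena()

    def _validate_ena(self) -> None:
        missing = [c for c in ENA_REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise DialectError(
                "ena dialect requires columns: " + ", ".join(missing),
                missing_columns=missing,
            )
        runs = self.df["run_accession"]
        if runs.isna().any():
            raise DialectError("run_accession contains missing values")
        if runs.duplicated().any():
            dupes = sorted(runs[runs.duplicated()].unique())
            raise DialectError(f"duplicated run_accession values: {', '.join(dupes)}")
        layouts = self.df["library_layout"].dropna()
        bad = sorted(set(layouts) - set(VALID_LAYOUTS))
        if bad:
            raise DialectError(f"invalid library_layout values: {', '.join(bad)}")

    # -- construction ---------------------------------------------------
    @classmethod
    def from_records(cls, columns, rows, dialect: str = GENERIC_DIALECT) -> "MetadataTable":
        """Build from an ordered column list and row records (dicts or lists)."""
        columns = list(columns)
        data = []
        for row in rows:
            if isinstance(row, dict):
                data.append([row.get(c) for c in columns])
            else:
                if len(row) != len(columns):
                    raise FormatError(
                        f"row has {len(row)} cells for {len(columns)} columns"
                    )
                data.append(list(row))
        return cls(pd.DataFrame(data, columns=columns, dtype=object), dialect=dialect)

    # -- accessors ------------------------------------------------------
    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def rows(self):
        """Iterate rows as dicts of string-or-None cells."""
        for _, row in self.df.iterrows():
            yield {c: row[c] for c in self.df.columns}

    def column(self, name: str) -> pd.Series:
        if name not in self.df.columns:
            raise InputError(f"column not present in table: {name!r}")
        return self.df[name]

    def copy(self) -> "MetadataTable":
        return MetadataTable(self.df.copy(), dialect=self.dialect)

    def equals(self, other: "MetadataTable") -> bool:
        return (
            self.columns == other.columns
            and self.n_rows == other.n_rows
            and self.df.fillna("\0NA").equals(other.df.fillna("\0NA"))
        )


@dataclass(frozen=True)
class MultiValueCell:
    """A ";"-separated multi-file cell (one entry per file of a run)."""

    raw: str
    values: tuple[str, ...]

    @classmethod
    def from_raw(cls, cell) -> "MultiValueCell":
        if cell is None or (not isinstance(cell, str) and pd.isna(cell)):
            return cls(raw="", values=())
        raw = str(cell).strip()
        values = () if raw == "" else tuple(raw.split(MULTIVALUE_SEP))
        return cls(raw=raw, values=values)


def split_multivalue(cell) -> MultiValueCell:
    """Split a cell on ";". Empty / missing cells yield no values."""
    return MultiValueCell.from_raw(cell)


MANIFEST_COLUMNS = ("fastq_file_name", "sample_name")


@dataclass
class ManifestTable:
    """Generic mapping of fastq file names to sample names (non-ENA mode).

    Columns: ``fastq_file_name`` (unique), ``sample_name`` (non-missing),
    optional ``md5``.
    """

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in MANIFEST_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError("manifest requires columns: " + ", ".join(missing))
        self.df = _normalise_na(self.df)
        self.df.index = pd.RangeIndex(len(self.df))
        if self.df["sample_name"].isna().any():
            raise FormatError("manifest sample_name contains missing values")

    @classmethod
    def from_records(cls, rows) -> "ManifestTable":
        cols = list(MANIFEST_COLUMNS)
        if any("md5" in r for r in rows):
            cols.append("md5")
        return cls(pd.DataFrame([{c: r.get(c) for c in cols} for r in rows], columns=cols))

    @property
    def file_names(self) -> list[str]:
        return [v for v in self.df["fastq_file_name"] if v is not None]

    @property
    def sample_names(self) -> list[str]:
        return list(self.df["sample_name"])

    def md5_map(self) -> dict[str, str]:
        if "md5" not in self.df.columns:
            return {}
        return {
            f: m
            for f, m in zip(self.df["fastq_file_name"], self.df["md5"])
            if f is not None and m is not None
        }


# -- readers / writers --------------------------------------------------

def _read_header(path: Path) -> list[str]:
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"empty table file: {path}") from None
    return header


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header = _read_header(path)
    dupes = sorted({c for c in header if header.count(c) > 1})
    if dupes:
        raise FormatError(f"duplicated header names in {path}: {', '.join(dupes)}")
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[], encoding="utf-8"
    )
    df.columns = header
    return df


def read_table(path, dialect: str = GENERIC_DIALECT) -> MetadataTable:
    """Read a TSV metadata table; NA tokens become missing cells."""
    return MetadataTable(_read_tsv(path), dialect=dialect)


def write_table(table: MetadataTable, path) -> None:
    """Write a table so that reading it back reproduces it cell-for-cell."""
    table.df.to_csv(path, sep="\t", index=False, na_rep="", lineterminator="\n")


def read_manifest(path) -> ManifestTable:
    return ManifestTable(_read_tsv(path))


def write_manifest(manifest: ManifestTable, path) -> None:
    manifest.df.to_csv(path, sep="\t", index=False, na_rep="", lineterminator="\n")
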