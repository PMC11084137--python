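"""Check Metadata Values and Concat Datasets.

A user-authored variables dictionary gives each curated variable a
requiredness (required/optional), a class (character/numeric), a
uniqueness constraint (unique/nonunique), an allowed-value analysis
(any, subset, wholeset, or numeric range) and optional cross-check
variables.  Validation runs the per-variable checks in a fixed order —
presence, class, uniqueness, cross-check, allowed values — and dataset
concatenation uses the same dictionary to append datasets safely,
re-checking cross-dataset uniqueness.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ConcatError, FormatError, InputError
from .findings import CheckReport, Finding
from .model import (
    GENERIC_DIALECT,
    MULTIVALUE_SEP,
    MetadataTable,
    _read_tsv,
    is_missing,
)

REQUIREDNESS = ("required", "optional")
CLASSES = ("character", "numeric")
UNIQUENESS = ("unique", "nonunique")
ANALYSES = ("any", "subset", "wholeset", "range")

#: Boolean tokens accepted (not coerced) under class=character.
BOOLEAN_TOKENS = frozenset({"true", "false", "True", "False", "TRUE", "FALSE"})

RANGE_SEP = ".."
DATASET_ORIGIN_COLUMN = "dataset"


def _parse_number(text: str) -> float:
    return float(str(text).strip())


def _is_numeric(text) -> bool:
    try:
        _parse_number(text)
        return True
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class VariableSpec:
    """Validation schema of one curated variable."""

    name: str
    requiredness: str = "optional"
    var_class: str = "character"
    uniqueness: str = "nonunique"
    allowed_analysis: str = "any"
    allowed_values: tuple[str, ...] = ()
    value_range: tuple[float, float] | None = None
    crosscheck_variables: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.name:
            raise FormatError("variable name must be non-empty")
        if self.requiredness not in REQUIREDNESS:
            raise FormatError(f"{self.name}: unknown requiredness {self.requiredness!r}")
        if self.var_class not in CLASSES:
            raise FormatError(f"{self.name}: unknown class {self.var_class!r}")
        if self.uniqueness not in UNIQUENESS:
            raise FormatError(f"{self.name}: unknown uniqueness {self.uniqueness!r}")
        if self.allowed_analysis not in ANALYSES:
            raise FormatError(
                f"{self.name}: unknown allowed analysis {self.allowed_analysis!r}"
            )
        if self.allowed_analysis == "range":
            if self.var_class != "numeric":
                raise FormatError(f"{self.name}: range analysis requires class=numeric")
            if self.value_range is None:
                raise FormatError(f"{self.name}: range analysis requires bounds")
        if self.allowed_analysis in ("subset", "wholeset") and not self.allowed_values:
            raise FormatError(
                f"{self.name}: {self.allowed_analysis} analysis requires allowed values"
            )
        if self.allowed_analysis == "any" and (self.allowed_values or self.value_range):
            raise FormatError(f"{self.name}: analysis 'any' takes no allowed values")
        object.__setattr__(self, "allowed_values", tuple(self.allowed_values))
        object.__setattr__(self, "crosscheck_variables", tuple(self.crosscheck_variables))


@dataclass
class VariablesDictionary:
    """Ordered variable specs with unique names and resolvable cross-checks."""

    specs: list[VariableSpec] = field(default_factory=list)

    def __post_init__(self):
        names = [s.name for s in self.specs]
        dupes = sorted({n for n in names if names.count(n) > 1})
        if dupes:
            raise FormatError(f"duplicated variable names: {', '.join(dupes)}")
        defined = set(names)
        for spec in self.specs:
            unknown = sorted(set(spec.crosscheck_variables) - defined)
            if unknown:
                raise FormatError(
                    f"{spec.name}: cross-check references undefined variables: "
                    + ", ".join(unknown)
                )

    def __iter__(self):
        return iter(self.specs)

    def __len__(self):
        return len(self.specs)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def get(self, name: str) -> VariableSpec:
        for spec in self.specs:
            if spec.name == name:
                return spec
        raise KeyError(name)

    @classmethod
    def read(cls, path) -> "VariablesDictionary":
        df = _read_tsv(Path(path))
        required = ("name", "requiredness", "class", "uniqueness", "allowed_analysis")
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"dictionary requires columns: {', '.join(missing)}")
        specs = []
        for i, rec in df.iterrows():
            analysis = rec["allowed_analysis"] or "any"
            allowed_raw = rec.get("allowed_values") or ""
            value_range = None
            allowed_values: tuple[str, ...] = ()
            if analysis == "range":
                parts = allowed_raw.split(RANGE_SEP)
                if len(parts) != 2:
                    raise FormatError(
                        f"dictionary line {i + 2}: range bounds must be 'min{RANGE_SEP}max'"
                    )
                try:
                    value_range = (_parse_number(parts[0]), _parse_number(parts[1]))
                except ValueError:
                    raise FormatError(
                        f"dictionary line {i + 2}: non-numeric range bounds {allowed_raw!r}"
                    ) from None
            elif analysis in ("subset", "wholeset"):
                allowed_values = tuple(
                    v for v in allowed_raw.split(MULTIVALUE_SEP) if v != ""
                )
            crosscheck = tuple(
                v
                for v in (rec.get("crosscheck_variables") or "").split(MULTIVALUE_SEP)
                if v != ""
            )
            try:
                specs.append(
                    VariableSpec(
                        name=rec["name"] or "",
                        requiredness=rec["requiredness"] or "optional",
                        var_class=rec["class"] or "character",
                        uniqueness=rec["uniqueness"] or "nonunique",
                        allowed_analysis=analysis,
                        allowed_values=allowed_values,
                        value_range=value_range,
                        crosscheck_variables=crosscheck,
                    )
                )
            except FormatError as exc:
                raise FormatError(f"dictionary line {i + 2}: {exc}") from exc
        return cls(specs)

    def write(self, path) -> None:
        rows = []
        for s in self.specs:
            if s.allowed_analysis == "range" and s.value_range is not None:
                allowed = f"{s.value_range[0]:g}{RANGE_SEP}{s.value_range[1]:g}"
            else:
                allowed = MULTIVALUE_SEP.join(s.allowed_values)
            rows.append(
                {
                    "name": s.name,
                    "requiredness": s.requiredness,
                    "class": s.var_class,
                    "uniqueness": s.uniqueness,
                    "allowed_analysis": s.allowed_analysis,
                    "allowed_values": allowed,
                    "crosscheck_variables": MULTIVALUE_SEP.join(s.crosscheck_variables),
                }
            )
        pd.DataFrame(
            rows,
            columns=[
                "name",
                "requiredness",
                "class",
                "uniqueness",
                "allowed_analysis",
                "allowed_values",
                "crosscheck_variables",
            ],
        ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _crosscheck(name_a: str, values_a, name_b: str, values_b) -> list[Finding]:
    """Symmetric multi-match check between two aligned value columns."""
    findings: list[Finding] = []
    for src, src_vals, dst, dst_vals in (
        (name_a, values_a, name_b, values_b),
        (name_b, values_b, name_a, values_a),
    ):
        mapping: dict[str, set[str]] = defaultdict(set)
        for a, b in zip(src_vals, dst_vals):
            if not is_missing(a) and not is_missing(b):
                mapping[str(a)].add(str(b))
        conflicted = sorted(v for v, targets in mapping.items() if len(targets) > 1)
        if conflicted:
            findings.append(
                Finding(
                    code="VARIABLE_MULTIMATCH",
                    message=(
                        f"{len(conflicted)} value(s) of {src!r} map to multiple "
                        f"values of {dst!r}"
                    ),
                    subjects=tuple([src, dst] + conflicted),
                )
            )
    return findings


def check_variable(spec: VariableSpec, table: MetadataTable) -> list[Finding]:
    """Validate one variable in fixed order: presence, class, uniqueness,
    cross-check, allowed values.  Missing cells never violate the allowed
    analyses (missingness is governed by requiredness)."""
    findings: list[Finding] = []
    if spec.name not in table.columns:
        if spec.requiredness == "required":
            findings.append(
                Finding(
                    code="VARIABLE_MISSING",
                    message=f"required variable {spec.name!r} is absent from the table",
                    subjects=(spec.name,),
                )
            )
        else:
            findings.append(
                Finding(
                    code="VARIABLE_OPTIONAL_ABSENT",
                    message=f"optional variable {spec.name!r} is absent from the table",
                    subjects=(spec.name,),
                )
            )
        return findings

    values = list(table.column(spec.name))
    present = [str(v) for v in values if not is_missing(v)]

    if spec.var_class == "numeric":
        bad = sorted({v for v in present if not _is_numeric(v)})
        if bad:
            findings.append(
                Finding(
                    code="VARIABLE_NOT_NUMERIC",
                    message=(
                        f"variable {spec.name!r} has non-numeric cells: "
                        + ", ".join(bad)
                    ),
                    subjects=tuple([spec.name] + bad),
                )
            )

    if spec.uniqueness == "unique":
        counts: dict[str, int] = defaultdict(int)
        for v in present:
            counts[v] += 1
        dupes = sorted(v for v, n in counts.items() if n > 1)
        if dupes:
            findings.append(
                Finding(
                    code="VARIABLE_NOT_UNIQUE",
                    message=(
                        f"variable {spec.name!r} has duplicated values: "
                        + ", ".join(dupes)
                    ),
                    subjects=tuple([spec.name] + dupes),
                )
            )

    for other in spec.crosscheck_variables:
        if other not in table.columns:
            continue
        findings.extend(
            _crosscheck(spec.name, values, other, list(table.column(other)))
        )

    if spec.allowed_analysis == "subset":
        outliers = sorted(set(present) - set(spec.allowed_values))
        if outliers:
            findings.append(
                Finding(
                    code="VALUE_NOT_ALLOWED",
                    message=(
                        f"variable {spec.name!r} has values outside the allowed "
                        "set: " + ", ".join(outliers)
                    ),
                    subjects=tuple([spec.name] + outliers),
                )
            )
    elif spec.allowed_analysis == "wholeset":
        observed = set(present)
        allowed = set(spec.allowed_values)
        extra = sorted(observed - allowed)
        uncovered = sorted(allowed - observed)
        if extra or uncovered:
            parts = []
            if extra:
                parts.append("unexpected: " + ", ".join(extra))
            if uncovered:
                parts.append("uncovered: " + ", ".join(uncovered))
            findings.append(
                Finding(
                    code="VALUE_SET_MISMATCH",
                    message=(
                        f"variable {spec.name!r} does not cover the allowed set "
                        f"exactly ({'; '.join(parts)})"
                    ),
                    subjects=tuple([spec.name] + extra + uncovered),
                )
            )
    elif spec.allowed_analysis == "range" and spec.value_range is not None:
        low, high = spec.value_range
        out = sorted(
            {
                v
                for v in present
                if _is_numeric(v) and not (low <= _parse_number(v) <= high)
            }
        )
        if out:
            findings.append(
                Finding(
                    code="VALUE_OUT_OF_RANGE",
                    message=(
                        f"variable {spec.name!r} has values outside "
                        f"[{low:g}, {high:g}]: " + ", ".join(out)
                    ),
                    subjects=tuple([spec.name] + out),
                )
            )
    return findings


def check_metadata_values(
    dictionary: VariablesDictionary, table: MetadataTable
) -> CheckReport:
    """Run check_variable over every spec in dictionary order, then report
    table columns absent from the dictionary at info level."""
    report = CheckReport()
    for spec in dictionary:
        report.extend(check_variable(spec, table))
    declared = set(dictionary.names)
    for col in table.columns:
        if col not in declared:
            report.add(
                Finding(
                    code="UNDECLARED_VARIABLE",
                    message=f"table column {col!r} is not declared in the dictionary",
                    subjects=(col,),
                )
            )
    return report


def concat_datasets(
    tables: list[MetadataTable],
    dictionary: VariablesDictionary,
    dataset_names: list[str] | None = None,
) -> tuple[MetadataTable, CheckReport]:
    """Append the datasets' rows under the dictionary's column order.

    Each table must pass check_metadata_values without errors (warnings
    tolerated); absent optional columns are filled as missing; a
    dataset-origin column is appended; cross-dataset uniqueness is
    re-checked for every uniqueness=unique variable.
    """
    if len(tables) < 2:
        raise InputError("concat requires at least 2 metadata tables")
    if dataset_names is None:
        dataset_names = [f"dataset_{i + 1}" for i in range(len(tables))]
    if len(dataset_names) != len(tables):
        raise InputError("dataset_names must match the number of tables")

    report = CheckReport()
    for name, table in zip(dataset_names, tables):
        table_report = check_metadata_values(dictionary, table)
        if table_report.status == "error":
            raise ConcatError(
                f"dataset {name!r} fails validation and cannot be concatenated",
                report=table_report,
            )

    columns = dictionary.names + [DATASET_ORIGIN_COLUMN]
    rows: list[dict] = []
    for name, table in zip(dataset_names, tables):
        for row in table.rows():
            rec = {var: row.get(var) for var in dictionary.names}
            rec[DATASET_ORIGIN_COLUMN] = name
            rows.append(rec)
    combined = MetadataTable.from_records(columns, rows, dialect=GENERIC_DIALECT)

    for spec in dictionary:
        if spec.uniqueness != "unique" or spec.name not in combined.columns:
            continue
        owners: dict[str, list[str]] = defaultdict(list)
        for row in combined.rows():
            v = row.get(spec.name)
            if not is_missing(v):
                owners[str(v)].append(str(row[DATASET_ORIGIN_COLUMN]))
        for value in sorted(owners):
            origins = owners[value]
            if len(origins) > 1:
                report.add(
                    Finding(
                        code="CROSS_DATASET_DUPLICATE",
                        message=(
                            f"unique variable {spec.name!r} value {value!r} occurs "
                            f"in datasets: " + ", ".join(sorted(set(origins)))
                        ),
                        subjects=tuple([spec.name, value] + sorted(set(origins))),
                    )
                )
    return combined, report
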