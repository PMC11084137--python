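"""Merge Metadata and Filter Metadata.

Merging combines a main metadata table (typically the ENA filereport)
with an extra table (typically the publication's metadata), left join by
default, and analyses the intersection of the two key columns to report
non-common unique values.  Filtering applies categorical and numerical
row filters strictly in the order of the filter specification file, with
an explicit NA policy per step.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FilterError, FormatError, InputError
from .findings import CheckReport, Finding
from .model import (
    GENERIC_DIALECT,
    MULTIVALUE_SEP,
    MetadataTable,
    _read_tsv,
    is_missing,
)

MERGE_MODES = ("left", "right", "inner", "outer")
FILTER_MODES = ("keep_values", "drop_values", "numeric")
NUMERIC_OPERATORS = ("<", "<=", ">", ">=", "==", "!=")
NA_POLICIES = ("keep", "drop")

MAIN_SUFFIX = "_main"
EXTRA_SUFFIX = "_extra"


def _key(value) -> str | None:
    """Join keys compare by exact string equality after trimming whitespace."""
    if is_missing(value):
        return None
    return str(value).strip()


def merge_metadata(
    main: MetadataTable,
    extra: MetadataTable,
    main_key: str,
    extra_key: str,
    mode: str = "left",
) -> tuple[MetadataTable, CheckReport]:
    """Join the two tables on the key pair under the given mode.

    Column-name collisions are suffixed ``_main`` / ``_extra``.  Findings
    report the unique key values found only in main and only in extra; a
    key occurring on multiple extra rows fans out and is reported as
    KEY_MULTIMATCH.
    """
    if mode not in MERGE_MODES:
        raise InputError(f"unknown merge mode: {mode!r} (expected one of {MERGE_MODES})")
    if main_key not in main.columns:
        raise InputError(f"key column not present in main table: {main_key!r}")
    if extra_key not in extra.columns:
        raise InputError(f"key column not present in extra table: {extra_key!r}")

    report = CheckReport()
    main_keys = {k for k in (_key(v) for v in main.column(main_key)) if k is not None}
    extra_keys = {k for k in (_key(v) for v in extra.column(extra_key)) if k is not None}
    main_only = sorted(main_keys - extra_keys)
    extra_only = sorted(extra_keys - main_keys)
    if not main_only and not extra_only:
        report.add(
            Finding(
                code="MERGE_KEYS_ALIGNED",
                message="the two key columns share exactly the same unique values",
            )
        )
    if main_only:
        report.add(
            Finding(
                code="MERGE_MAIN_ONLY_KEYS",
                message=f"{len(main_only)} key value(s) occur only in the main table",
                subjects=tuple(main_only),
            )
        )
    if extra_only:
        report.add(
            Finding(
                code="MERGE_EXTRA_ONLY_KEYS",
                message=f"{len(extra_only)} key value(s) occur only in the extra table",
                subjects=tuple(extra_only),
            )
        )
    extra_counts = pd.Series(
        [_key(v) for v in extra.column(extra_key)]
    ).value_counts()
    fanout = sorted(extra_counts[extra_counts > 1].index)
    if fanout:
        report.add(
            Finding(
                code="KEY_MULTIMATCH",
                message=(
                    f"{len(fanout)} key value(s) occur on multiple extra rows "
                    "and fan out in the join"
                ),
                subjects=tuple(str(k) for k in fanout),
            )
        )

    left = main.df.copy()
    right = extra.df.copy()
    # missing keys never match (SQL semantics); pandas would join NaN to
    # NaN, so missing keys get per-row sentinels instead
    left["__key__"] = [
        _key(v) if _key(v) is not None else f"\x1fmain{i}"
        for i, v in enumerate(left[main_key])
    ]
    right["__key__"] = [
        _key(v) if _key(v) is not None else f"\x1fextra{i}"
        for i, v in enumerate(right[extra_key])
    ]
    merged = left.merge(
        right, how=mode, on="__key__", suffixes=(MAIN_SUFFIX, EXTRA_SUFFIX), sort=False
    )
    merged = merged.drop(columns="__key__").astype(object)
    merged = merged.where(merged.notna(), None)
    return MetadataTable(merged, dialect=GENERIC_DIALECT), report


@dataclass(frozen=True)
class FilterStep:
    """One sequential row filter.

    ``keep_values`` retains rows whose cell is in ``values``;
    ``drop_values`` removes them; ``numeric`` parses the cell and applies
    ``operator threshold``.  NA cells are retained iff ``na_policy`` is
    ``keep``.
    """

    column: str
    mode: str
    values: tuple[str, ...] = ()
    operator: str = ""
    threshold: float = 0.0
    na_policy: str = "drop"

    def __post_init__(self):
        if not self.column:
            raise FormatError("filter step column must be non-empty")
        if self.mode not in FILTER_MODES:
            raise FormatError(f"unknown filter mode: {self.mode!r}")
        if self.na_policy not in NA_POLICIES:
            raise FormatError(f"unknown na_policy: {self.na_policy!r}")
        if self.mode == "numeric":
            if self.operator not in NUMERIC_OPERATORS:
                raise FormatError(f"unknown numeric operator: {self.operator!r}")
            if self.values:
                raise FormatError("numeric steps take a threshold, not values")
        else:
            if self.operator:
                raise FormatError(f"{self.mode} steps take values, not an operator")
        object.__setattr__(self, "values", tuple(self.values))


@dataclass
class FilterSpecFile:
    """Ordered filter steps; order on disk is execution order."""

    steps: list[FilterStep] = field(default_factory=list)

    def __iter__(self):
        return iter(self.steps)

    def __len__(self):
        return len(self.steps)

    @classmethod
    def read(cls, path) -> "FilterSpecFile":
        df = _read_tsv(Path(path))
        required = {"column", "mode"}
        missing = sorted(required - set(df.columns))
        if missing:
            raise FormatError(f"filter spec requires columns: {', '.join(missing)}")
        steps = []
        for i, row in df.iterrows():
            rec = {c: (None if row[c] in ("", None) else row[c]) for c in df.columns}
            mode = rec.get("mode") or ""
            try:
                if mode == "numeric":
                    threshold_raw = rec.get("values") or ""
                    steps.append(
                        FilterStep(
                            column=rec.get("column") or "",
                            mode=mode,
                            operator=rec.get("operator") or "",
                            threshold=parse_number(threshold_raw),
                            na_policy=rec.get("na_policy") or "drop",
                        )
                    )
                else:
                    values = (rec.get("values") or "").split(MULTIVALUE_SEP)
                    values = tuple(v for v in values if v != "")
                    steps.append(
                        FilterStep(
                            column=rec.get("column") or "",
                            mode=mode,
                            values=values,
                            na_policy=rec.get("na_policy") or "drop",
                        )
                    )
            except (FormatError, ValueError) as exc:
                raise FormatError(f"filter spec line {i + 2}: {exc}") from exc
        return cls(steps)

    def write(self, path) -> None:
        rows = []
        for s in self.steps:
            rows.append(
                {
                    "column": s.column,
                    "mode": s.mode,
                    "operator": s.operator,
                    "values": (
                        format(s.threshold, "g")
                        if s.mode == "numeric"
                        else MULTIVALUE_SEP.join(s.values)
                    ),
                    "na_policy": s.na_policy,
                }
            )
        pd.DataFrame(rows, columns=["column", "mode", "operator", "values", "na_policy"]).to_csv(
            path, sep="\t", index=False, lineterminator="\n"
        )


def parse_number(cell: str) -> float:
    """Integers and decimals with '.' separator only; no locale handling."""
    text = str(cell).strip()
    if text == "":
        raise ValueError("empty numeric value")
    try:
        return float(text)
    except ValueError:
        raise ValueError(f"not a number: {cell!r}") from None


_OPS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
}


def _step_keeps(step: FilterStep, value, row_label: str) -> bool:
    if is_missing(value):
        return step.na_policy == "keep"
    text = str(value)
    if step.mode == "keep_values":
        return text in step.values
    if step.mode == "drop_values":
        return text not in step.values
    try:
        number = parse_number(text)
    except ValueError:
        raise FilterError(
            f"cell {text!r} at {row_label}, column {step.column!r} is not numeric",
            code="CELL_NOT_NUMERIC",
        ) from None
    return _OPS[step.operator](number, step.threshold)


@dataclass
class FilterStepReport:
    step_index: int
    column: str
    mode: str
    rows_before: int
    rows_removed: int
    rows_after: int


def filter_metadata(
    table: MetadataTable, spec: FilterSpecFile
) -> tuple[MetadataTable, list[FilterStepReport]]:
    """Apply the spec's steps strictly in order with exact row accounting."""
    df = table.df
    reports: list[FilterStepReport] = []
    for i, step in enumerate(spec):
        if step.column not in df.columns:
            raise InputError(
                f"filter step {i + 1} references absent column {step.column!r}"
            )
        before = len(df)
        mask = [
            _step_keeps(step, value, row_label=f"row {j + 1}")
            for j, value in enumerate(df[step.column])
        ]
        df = df[pd.Series(mask, index=df.index, dtype=bool)]
        df.index = pd.RangeIndex(len(df))
        reports.append(
            FilterStepReport(
                step_index=i + 1,
                column=step.column,
                mode=step.mode,
                rows_before=before,
                rows_removed=before - len(df),
                rows_after=len(df),
            )
        )
    return MetadataTable(df.copy(), dialect=table.dialect), reports


def step_report_frame(reports: list[FilterStepReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "step": r.step_index,
                "column": r.column,
                "mode": r.mode,
                "rows_before": r.rows_before,
                "rows_removed": r.rows_removed,
                "rows_after": r.rows_after,
            }
            for r in reports
        ],
        columns=["step", "column", "mode", "rows_before", "rows_removed", "rows_after"],
    )
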