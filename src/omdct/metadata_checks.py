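"""Check Metadata ENA: statistics and consistency checks on run-level tables.

Summaries count runs and samples and tally organism (scientific name and
tax id), sequencing platform (instrument model and platform), library
layout and data type (library strategy and source), plus a grouping of
samples by their number of associated runs.  Checks compare the library
layout against the number of available fastqs, the availability of the
originally submitted files, and per-sample consistency of fields that
should be single-valued.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .errors import InputError
from .findings import CheckReport, Finding
from .model import MetadataTable, is_missing, split_multivalue

MISSING_BUCKET = "(missing)"

DEFAULT_SAMPLE_COLUMN = "sample_accession"

#: Columns tallied in the run/sample summary.
TALLY_COLUMNS = (
    "scientific_name",
    "tax_id",
    "instrument_model",
    "instrument_platform",
    "library_layout",
    "library_strategy",
    "library_source",
)

#: Field groups that should be single-valued per sample; each maps to a
#: SAMPLE_MULTIMATCH_* finding code.
MULTIMATCH_FIELDS = {
    "SAMPLE_MULTIMATCH_ORGANISM": ("scientific_name", "tax_id"),
    "SAMPLE_MULTIMATCH_PLATFORM": ("instrument_platform", "instrument_model"),
    "SAMPLE_MULTIMATCH_LAYOUT": ("library_layout",),
    "SAMPLE_MULTIMATCH_DATATYPE": ("library_strategy", "library_source"),
}


@dataclass
class RunSampleSummary:
    """Counts and frequency tables for a run-level metadata table.

    Tallies include a ``(missing)`` bucket, so each tally's frequencies
    sum to ``n_runs``; the runs-per-sample histogram maps a run count to
    the samples with that many runs.
    """

    n_runs: int
    n_samples: int
    tallies: dict[str, Counter] = field(default_factory=dict)
    runs_per_sample_histogram: dict[int, list[str]] = field(default_factory=dict)

    def tally_frame(self, column: str) -> pd.DataFrame:
        counter = self.tallies[column]
        rows = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(rows, columns=[column, "n_runs"])

    def histogram_frame(self) -> pd.DataFrame:
        rows = [
            {"runs_per_sample": k, "n_samples": len(v), "samples": ";".join(sorted(v))}
            for k, v in sorted(self.runs_per_sample_histogram.items())
        ]
        return pd.DataFrame(rows, columns=["runs_per_sample", "n_samples", "samples"])


def _cell(value) -> str:
    return MISSING_BUCKET if is_missing(value) else str(value)


def summarize_runs(
    table: MetadataTable, sample_column: str = DEFAULT_SAMPLE_COLUMN
) -> RunSampleSummary:
    """Compute run/sample statistics; missing cells count as ``(missing)``."""
    if sample_column not in table.columns:
        raise InputError(f"sample column not present in table: {sample_column!r}")
    tallies = {
        col: Counter(_cell(v) for v in table.column(col)) for col in TALLY_COLUMNS
    }
    by_sample: dict[str, int] = Counter(
        _cell(v) for v in table.column(sample_column)
    )
    histogram: dict[int, list[str]] = defaultdict(list)
    for sample, n in sorted(by_sample.items()):
        histogram[n].append(sample)
    return RunSampleSummary(
        n_runs=table.n_rows,
        n_samples=len(by_sample),
        tallies=tallies,
        runs_per_sample_histogram=dict(histogram),
    )


def check_layout_vs_fastq_count(table: MetadataTable) -> list[Finding]:
    """Compare each run's library layout with its number of fastq URLs.

    SINGLE expects exactly 1 URL and PAIRED exactly 2; a PAIRED run with
    3 files is reported at info level (ENA convention allows an extra
    unpaired-reads file); everything else warns.
    """
    findings: list[Finding] = []
    for row in table.rows():
        run = str(row["run_accession"])
        layout = row.get("library_layout")
        n = len(split_multivalue(row.get("fastq_ftp")).values)
        if is_missing(layout):
            findings.append(
                Finding(
                    code="MISSING_LAYOUT",
                    message=f"run {run} has no library_layout ({n} fastq URL(s))",
                    subjects=(run,),
                )
            )
            continue
        if layout == "SINGLE" and n == 1:
            continue
        if layout == "PAIRED" and n == 2:
            continue
        if layout == "PAIRED" and n == 3:
            findings.append(
                Finding(
                    code="PAIRED_WITH_ORPHAN",
                    message=(
                        f"run {run} is PAIRED with 3 fastqs "
                        "(likely an extra unpaired-reads file)"
                    ),
                    subjects=(run,),
                )
            )
            continue
        findings.append(
            Finding(
                code="LAYOUT_FILECOUNT_MISMATCH",
                message=f"run {run} is {layout} but has {n} fastq URL(s)",
                subjects=(run,),
            )
        )
    return findings


def check_submitted_files(table: MetadataTable) -> list[Finding]:
    """Check availability of submitted files and duplicated basenames."""
    findings: list[Finding] = []
    unavailable: list[str] = []
    owners: dict[str, list[str]] = defaultdict(list)
    for row in table.rows():
        run = str(row["run_accession"])
        cell = split_multivalue(row.get("submitted_ftp"))
        if not cell.values:
            unavailable.append(run)
            continue
        for url in cell.values:
            owners[url.rsplit("/", 1)[-1]].append(run)
    if unavailable:
        findings.append(
            Finding(
                code="SUBMITTED_UNAVAILABLE",
                message=(
                    f"{len(unavailable)} run(s) have no originally submitted "
                    "files available"
                ),
                subjects=tuple(unavailable),
            )
        )
    for basename in sorted(owners):
        runs = owners[basename]
        if len(runs) > 1:
            findings.append(
                Finding(
                    code="DUPLICATED_SUBMITTED_NAME",
                    message=(
                        f"submitted file name {basename!r} appears under "
                        f"{len(runs)} run entries"
                    ),
                    subjects=tuple([basename] + sorted(set(runs))),
                )
            )
    return findings


def _grouping_key(row: dict, columns: tuple[str, ...]):
    return tuple(None if is_missing(row.get(c)) else str(row.get(c)) for c in columns)


def check_sample_consistency(
    table: MetadataTable, sample_columns: list[str] | None = None
) -> list[Finding]:
    """Per-sample checks: runs-vs-samples relation, agreement between the
    provided sample columns, and multi-matches per sample for organism,
    platform, layout and data type (missing values are not conflicts)."""
    sample_columns = list(sample_columns or [DEFAULT_SAMPLE_COLUMN])
    for col in sample_columns:
        if col not in table.columns:
            raise InputError(f"sample column not present in table: {col!r}")
    findings: list[Finding] = []
    primary = sample_columns[0]
    samples = {
        _cell(v) for v in table.column(primary)
    }
    n_runs, n_samples = table.n_rows, len(samples)
    relation = "equal" if n_runs == n_samples else (
        "more runs than samples" if n_runs > n_samples else "fewer runs than samples"
    )
    findings.append(
        Finding(
            code="RUNS_SAMPLES_RELATION",
            message=f"{n_runs} runs over {n_samples} samples ({relation}, by {primary})",
        )
    )

    rows = list(table.rows())
    # pairwise grouping agreement between sample columns: two rows equal in
    # one column but different in the other refine/contradict each other
    for i, col_a in enumerate(sample_columns):
        for col_b in sample_columns[i + 1:]:
            disagreeing: set[str] = set()
            by_a: dict[str, set[str]] = defaultdict(set)
            by_b: dict[str, set[str]] = defaultdict(set)
            for row in rows:
                a, b = _cell(row.get(col_a)), _cell(row.get(col_b))
                by_a[a].add(b)
                by_b[b].add(a)
            for a, bs in by_a.items():
                if len(bs) > 1:
                    disagreeing.add(a)
            for b, as_ in by_b.items():
                if len(as_) > 1:
                    disagreeing.add(b)
            if disagreeing:
                findings.append(
                    Finding(
                        code="SAMPLE_COLUMN_DISAGREEMENT",
                        message=(
                            f"columns {col_a!r} and {col_b!r} group runs "
                            "differently"
                        ),
                        subjects=tuple(sorted(disagreeing)),
                    )
                )

    for code, cols in MULTIMATCH_FIELDS.items():
        present = [c for c in cols if c in table.columns]
        if len(present) != len(cols):
            continue
        per_sample: dict[str, set[tuple]] = defaultdict(set)
        for row in rows:
            sample = _cell(row.get(primary))
            key = _grouping_key(row, cols)
            if all(k is None for k in key):
                continue  # fully missing is not-a-value
            per_sample[sample].add(key)
        for sample in sorted(per_sample):
            values = per_sample[sample]
            if len(values) > 1:
                rendered = sorted(
                    "/".join("" if v is None else v for v in key) for key in values
                )
                findings.append(
                    Finding(
                        code=code,
                        message=(
                            f"sample {sample} maps to {len(values)} distinct "
                            f"values of {'/'.join(cols)}: {', '.join(rendered)}"
                        ),
                        subjects=tuple([sample] + rendered),
                    )
                )
    return findings


def check_metadata_ena(
    table: MetadataTable, sample_columns: list[str] | None = None
) -> CheckReport:
    """Full Check Metadata ENA program: summary tables plus all checks."""
    sample_columns = list(sample_columns or [DEFAULT_SAMPLE_COLUMN])
    summary = summarize_runs(table, sample_columns[0])
    report = CheckReport()
    report.add_summary(
        "counts",
        pd.DataFrame(
            [{"n_runs": summary.n_runs, "n_samples": summary.n_samples}]
        ),
    )
    for col in TALLY_COLUMNS:
        report.add_summary(col, summary.tally_frame(col))
    report.add_summary("runs_per_sample", summary.histogram_frame())
    report.extend(check_layout_vs_fastq_count(table))
    report.extend(check_submitted_files(table))
    report.extend(check_sample_consistency(table, sample_columns))
    return report
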