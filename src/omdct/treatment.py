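"""Make Treatment Template, Treat Fastqs, Treat Metadata.

The treatment template is the curated plan linking raw downloaded fastqs
to canonical per-sample files through three operations: ``copy`` (file is
already canonical), ``rename`` (one file, new canonical name) and
``merge`` (several runs' files concatenated per read side).  Canonical
names are ``<sample>_1.fastq.gz`` / ``<sample>_2.fastq.gz`` for paired
reads and ``<sample>.fastq.gz`` for single reads.  Merging is raw
gzip-member concatenation: lossless, fast, and itself a valid gzip
stream.

Treat Metadata collapses the run-level metadata to one row per template
sample; columns whose runs disagree are ";"-joined and reported as
warnings, except declared run-specific columns which aggregate silently.
"""
from __future__ import annotations

import shutil
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FormatError, InputError, TreatmentError
from .fastq_checks import FASTQ_SUFFIXES, DirectoryInventory
from .findings import CheckReport, Finding
from .model import (
    GENERIC_DIALECT,
    MULTIVALUE_SEP,
    ManifestTable,
    MetadataTable,
    _read_tsv,
    is_missing,
    split_multivalue,
)

OPERATIONS = ("copy", "rename", "merge")
READ_SIDES = ("R1", "R2", "single")

#: Columns aggregated by ";"-joining without a conflict warning.
DEFAULT_RUN_SPECIFIC_COLUMNS = (
    "run_accession",
    "run_alias",
    "fastq_ftp",
    "fastq_md5",
    "fastq_bytes",
    "submitted_ftp",
    "submitted_md5",
)

TEMPLATE_COLUMNS = ("sample_name", "operation", "input_files", "read_side", "output_file")


def strip_fastq_suffix(name: str) -> str:
    for suffix in FASTQ_SUFFIXES:
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


def infer_read_side(basename: str) -> str | None:
    """Infer R1/R2 from basename suffixes (_1/_2, _R1/_R2, .1/.2)."""
    stem = strip_fastq_suffix(basename)
    for side, tails in (("R1", ("_1", "_R1", ".1")), ("R2", ("_2", "_R2", ".2"))):
        if any(stem.endswith(t) for t in tails):
            return side
    return None


def canonical_output(sample_name: str, read_side: str) -> str:
    if read_side == "R1":
        return f"{sample_name}_1.fastq.gz"
    if read_side == "R2":
        return f"{sample_name}_2.fastq.gz"
    if read_side == "single":
        return f"{sample_name}.fastq.gz"
    raise InputError(f"unknown read side: {read_side!r}")


@dataclass(frozen=True)
class TreatmentRow:
    """One output file of the treatment plan."""

    sample_name: str
    operation: str  # copy | rename | merge | "" (left for the curator)
    input_files: tuple[str, ...]
    read_side: str  # R1 | R2 | single | ""
    output_file: str

    def __post_init__(self):
        object.__setattr__(self, "input_files", tuple(self.input_files))


@dataclass
class TreatmentTemplate:
    """Ordered treatment rows; invariants are enforced by validation, not
    construction, because a raw template may contain blanks for curation."""

    rows: list[TreatmentRow] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)

    @property
    def samples(self) -> list[str]:
        seen: list[str] = []
        for row in self.rows:
            if row.sample_name and row.sample_name not in seen:
                seen.append(row.sample_name)
        return seen

    @classmethod
    def read(cls, path) -> "TreatmentTemplate":
        df = _read_tsv(Path(path))
        missing = [c for c in TEMPLATE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"template requires columns: {', '.join(missing)}")
        rows = []
        for _, rec in df.iterrows():
            rows.append(
                TreatmentRow(
                    sample_name=rec["sample_name"] or "",
                    operation=rec["operation"] or "",
                    input_files=split_multivalue(rec["input_files"]).values,
                    read_side=rec["read_side"] or "",
                    output_file=rec["output_file"] or "",
                )
            )
        return cls(rows)

    def write(self, path) -> None:
        pd.DataFrame(
            [
                {
                    "sample_name": r.sample_name,
                    "operation": r.operation,
                    "input_files": MULTIVALUE_SEP.join(r.input_files),
                    "read_side": r.read_side,
                    "output_file": r.output_file,
                }
                for r in self.rows
            ],
            columns=list(TEMPLATE_COLUMNS),
        ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _claims_from_metadata(table: MetadataTable):
    """(sample, run, layout, [present basenames]) per run, in table order."""
    out = []
    for row in table.rows():
        files = [
            u.rsplit("/", 1)[-1] for u in split_multivalue(row.get("fastq_ftp")).values
        ]
        layout = row.get("library_layout")
        out.append(
            (
                "" if is_missing(row.get("sample_accession")) else str(row["sample_accession"]),
                str(row["run_accession"]),
                "" if is_missing(layout) else str(layout),
                files,
            )
        )
    return out


def _plan_single_file(sample: str, basename: str, read_side: str) -> TreatmentRow:
    target = canonical_output(sample, read_side)
    if basename == target:
        return TreatmentRow(sample, "copy", (basename,), read_side, basename)
    return TreatmentRow(sample, "rename", (basename,), read_side, target)


def make_treatment_template(
    expected: MetadataTable | ManifestTable, inventory: DirectoryInventory
) -> tuple[TreatmentTemplate, CheckReport]:
    """Pre-fill a raw treatment plan from the expected table and the files
    actually present.

    Single-run samples become copy/rename rows; multi-run samples of one
    layout become merge rows per read side with inputs ordered by run
    accession; ambiguous cases (mixed layouts, uninferable read sides)
    are left with a blank operation for the curator.  Files owned by no
    sample get a blank-sample row and a warning.
    """
    report = CheckReport()
    present = set(inventory.files)
    rows: list[TreatmentRow] = []
    claimed: set[str] = set()

    if isinstance(expected, MetadataTable):
        per_sample: dict[str, list[tuple[str, str, list[str]]]] = defaultdict(list)
        for sample, run, layout, files in _claims_from_metadata(expected):
            files_here = [f for f in files if f in present]
            claimed.update(files_here)
            if files_here:
                per_sample[sample].append((run, layout, files_here))
        for sample in per_sample:
            runs = sorted(per_sample[sample], key=lambda t: t[0])
            layouts = {layout for _, layout, _ in runs}
            if len(layouts) != 1 or "" in layouts:
                report.add(
                    Finding(
                        code="MIXED_LAYOUT_SAMPLE",
                        message=(
                            f"sample {sample} mixes library layouts; treatment "
                            "left blank for manual curation"
                        ),
                        subjects=(sample,),
                    )
                )
                for run, _layout, files in runs:
                    for basename in files:
                        rows.append(
                            TreatmentRow(sample, "", (basename,), "", "")
                        )
                continue
            layout = layouts.pop()
            if layout == "SINGLE":
                inputs = [f for run, _, files in runs for f in files]
                if len(runs) == 1 and len(inputs) == 1:
                    rows.append(_plan_single_file(sample, inputs[0], "single"))
                else:
                    rows.append(
                        TreatmentRow(
                            sample,
                            "merge",
                            tuple(inputs),
                            "single",
                            canonical_output(sample, "single"),
                        )
                    )
            else:  # PAIRED
                by_side: dict[str, list[str]] = {"R1": [], "R2": []}
                ambiguous: list[str] = []
                for run, _, files in runs:
                    for basename in files:
                        side = infer_read_side(basename)
                        if side is None:
                            ambiguous.append(basename)
                        else:
                            by_side[side].append(basename)
                for basename in ambiguous:
                    rows.append(TreatmentRow(sample, "", (basename,), "", ""))
                for side in ("R1", "R2"):
                    inputs = by_side[side]
                    if not inputs:
                        continue
                    if len(runs) == 1 and len(inputs) == 1:
                        rows.append(_plan_single_file(sample, inputs[0], side))
                    else:
                        rows.append(
                            TreatmentRow(
                                sample,
                                "merge",
                                tuple(inputs),
                                side,
                                canonical_output(sample, side),
                            )
                        )
    else:  # manifest mode: no run/layout structure, infer from read sides
        per_sample2: dict[str, list[str]] = defaultdict(list)
        for rec in expected.df.itertuples(index=False):
            name = rec.fastq_file_name
            if name in present:
                claimed.add(name)
                per_sample2[str(rec.sample_name)].append(str(name))
        for sample, files in per_sample2.items():
            files = sorted(files)
            sides = [infer_read_side(f) for f in files]
            if all(s is not None for s in sides):
                by_side2: dict[str, list[str]] = defaultdict(list)
                for f, s in zip(files, sides):
                    by_side2[s].append(f)
                for side in ("R1", "R2"):
                    inputs = by_side2.get(side, [])
                    if not inputs:
                        continue
                    if len(inputs) == 1:
                        rows.append(_plan_single_file(sample, inputs[0], side))
                    else:
                        rows.append(
                            TreatmentRow(
                                sample, "merge", tuple(inputs), side,
                                canonical_output(sample, side),
                            )
                        )
            elif all(s is None for s in sides):
                if len(files) == 1:
                    rows.append(_plan_single_file(sample, files[0], "single"))
                else:
                    rows.append(
                        TreatmentRow(
                            sample, "merge", tuple(files), "single",
                            canonical_output(sample, "single"),
                        )
                    )
            else:
                for basename in files:
                    rows.append(TreatmentRow(sample, "", (basename,), "", ""))

    for basename in sorted(present - claimed):
        rows.append(TreatmentRow("", "", (basename,), "", ""))
        report.add(
            Finding(
                code="UNOWNED_FILE",
                message=f"fastq {basename!r} is owned by no sample in the table",
                subjects=(basename,),
            )
        )
    return TreatmentTemplate(rows), report


def validate_treatment_template(
    template: TreatmentTemplate, inventory: DirectoryInventory
) -> list[Finding]:
    """Gate for the executors: returns an empty list iff the template is
    executable (all problems are error findings, never exceptions)."""
    findings: list[Finding] = []
    present = set(inventory.files)
    seen_inputs: dict[str, int] = defaultdict(int)
    seen_outputs: dict[str, int] = defaultdict(int)
    sides_per_sample: dict[str, set[str]] = defaultdict(set)

    for i, row in enumerate(template):
        label = f"template row {i + 1}"
        if not row.sample_name or not row.operation or not row.input_files:
            findings.append(
                Finding(
                    code="TEMPLATE_BLANK_FIELD",
                    message=f"{label}: sample_name, operation and input_files are required",
                    subjects=(label,),
                )
            )
            continue
        if row.operation not in OPERATIONS:
            findings.append(
                Finding(
                    code="TEMPLATE_BLANK_FIELD",
                    message=f"{label}: unknown operation {row.operation!r}",
                    subjects=(label,),
                )
            )
            continue
        for basename in row.input_files:
            seen_inputs[basename] += 1
            if basename not in present:
                findings.append(
                    Finding(
                        code="TEMPLATE_UNKNOWN_INPUT",
                        message=f"{label}: input {basename!r} not present in directory",
                        subjects=(basename,),
                    )
                )
        if row.operation in ("copy", "rename") and len(row.input_files) != 1:
            findings.append(
                Finding(
                    code="TEMPLATE_BAD_ARITY",
                    message=f"{label}: {row.operation} requires exactly 1 input file",
                    subjects=(label,),
                )
            )
        if row.operation == "merge" and len(row.input_files) < 2:
            findings.append(
                Finding(
                    code="TEMPLATE_BAD_ARITY",
                    message=f"{label}: merge requires at least 2 input files",
                    subjects=(label,),
                )
            )
        if row.read_side not in READ_SIDES:
            findings.append(
                Finding(
                    code="TEMPLATE_READSIDE_INCONSISTENT",
                    message=f"{label}: read_side must be one of {READ_SIDES}",
                    subjects=(label,),
                )
            )
        else:
            sides_per_sample[row.sample_name].add(row.read_side)
            expected_name = (
                row.input_files[0]
                if row.operation == "copy"
                else canonical_output(row.sample_name, row.read_side)
            )
            if row.output_file != expected_name:
                findings.append(
                    Finding(
                        code="TEMPLATE_BAD_OUTPUT_NAME",
                        message=(
                            f"{label}: output {row.output_file!r} should be "
                            f"{expected_name!r} for {row.operation}/{row.read_side}"
                        ),
                        subjects=(label,),
                    )
                )
        if row.output_file:
            seen_outputs[row.output_file] += 1

    for basename, n in sorted(seen_inputs.items()):
        if n > 1:
            findings.append(
                Finding(
                    code="TEMPLATE_DUPLICATE_INPUT",
                    message=f"input {basename!r} appears in {n} template rows",
                    subjects=(basename,),
                )
            )
    for output, n in sorted(seen_outputs.items()):
        if n > 1:
            findings.append(
                Finding(
                    code="TEMPLATE_DUPLICATE_OUTPUT",
                    message=f"output {output!r} is produced by {n} template rows",
                    subjects=(output,),
                )
            )
    for sample, sides in sorted(sides_per_sample.items()):
        if "single" in sides and sides != {"single"}:
            findings.append(
                Finding(
                    code="TEMPLATE_READSIDE_INCONSISTENT",
                    message=(
                        f"sample {sample} mixes 'single' with paired read sides"
                    ),
                    subjects=(sample,),
                )
            )
    return findings


@dataclass
class ExecutionRecord:
    output_file: str
    operation: str
    input_files: tuple[str, ...]


@dataclass
class ExecutionReport:
    records: list[ExecutionRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "output_file": r.output_file,
                    "operation": r.operation,
                    "input_files": MULTIVALUE_SEP.join(r.input_files),
                }
                for r in self.records
            ],
            columns=["output_file", "operation", "input_files"],
        )


def treat_fastqs(
    template: TreatmentTemplate,
    in_dir,
    out_dir,
    overwrite: bool = False,
) -> ExecutionReport:
    """Execute a validated template.

    copy/rename produce byte-identical copies; merge concatenates the
    gzipped inputs in template order (multi-member gzip).  Inputs are
    never modified.  A failure aborts with the list of partial outputs
    attached for cleanup.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    if in_dir.resolve() == out_dir.resolve():
        raise TreatmentError("output directory must be distinct from input directory")
    inventory = DirectoryInventory.scan(in_dir)
    problems = validate_treatment_template(template, inventory)
    if problems:
        raise TreatmentError(
            "template is not executable: "
            + "; ".join(f"{f.code}: {f.message}" for f in problems[:5])
            + ("" if len(problems) <= 5 else f" (+{len(problems) - 5} more)")
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    if not overwrite:
        existing = [r.output_file for r in template if (out_dir / r.output_file).exists()]
        if existing:
            raise TreatmentError(
                "output file(s) already exist (use overwrite): " + ", ".join(existing)
            )
    report = ExecutionReport()
    produced: list[str] = []
    try:
        for row in template:
            target = out_dir / row.output_file
            if row.operation in ("copy", "rename"):
                shutil.copyfile(in_dir / row.input_files[0], target)
            else:  # merge: raw gzip-member concatenation
                with open(target, "wb") as out:
                    for basename in row.input_files:
                        with open(in_dir / basename, "rb") as src:
                            shutil.copyfileobj(src, out)
            produced.append(row.output_file)
            report.records.append(
                ExecutionRecord(row.output_file, row.operation, row.input_files)
            )
    except OSError as exc:
        err = TreatmentError(
            f"I/O failure during treatment: {exc}; partial outputs: {', '.join(produced)}"
        )
        err.partial_outputs = produced
        raise err from exc
    return report


def treat_metadata(
    template: TreatmentTemplate,
    metadata: MetadataTable,
    sample_column: str = "sample_accession",
    run_specific_columns: tuple[str, ...] = DEFAULT_RUN_SPECIFIC_COLUMNS,
) -> tuple[MetadataTable, CheckReport]:
    """Collapse run-level metadata to one row per template sample.

    Columns where all contributing runs agree (ignoring missing) keep the
    value; disagreeing columns are ";"-joined in run order with a warning
    per (sample, column); declared run-specific columns aggregate by
    ";"-joining without warning.
    """
    if sample_column not in metadata.columns:
        raise InputError(f"sample column not present in metadata: {sample_column!r}")
    report = CheckReport()
    by_sample: dict[str, list[dict]] = defaultdict(list)
    for row in metadata.rows():
        key = row.get(sample_column)
        if not is_missing(key):
            by_sample[str(key)].append(row)

    out_rows: list[dict] = []
    for sample in template.samples:
        runs = by_sample.get(sample)
        if not runs:
            report.add(
                Finding(
                    code="SAMPLE_NOT_IN_METADATA",
                    message=f"template sample {sample} has no metadata rows",
                    subjects=(sample,),
                )
            )
            continue
        rec: dict = {}
        for col in metadata.columns:
            values = [r[col] for r in runs if not is_missing(r[col])]
            if not values:
                rec[col] = None
            elif col in run_specific_columns:
                rec[col] = MULTIVALUE_SEP.join(str(v) for v in values)
            else:
                distinct: list[str] = []
                for v in values:
                    if str(v) not in distinct:
                        distinct.append(str(v))
                if len(distinct) == 1:
                    rec[col] = distinct[0]
                else:
                    rec[col] = MULTIVALUE_SEP.join(distinct)
                    report.add(
                        Finding(
                            code="SAMPLE_VALUE_CONFLICT",
                            message=(
                                f"sample {sample}, column {col!r}: conflicting "
                                f"values {', '.join(distinct)}"
                            ),
                            subjects=(sample, col),
                        )
                    )
        out_rows.append(rec)
    table = MetadataTable.from_records(metadata.columns, out_rows, dialect=GENERIC_DIALECT)
    return table, report
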