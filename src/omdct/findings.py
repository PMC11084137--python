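"""Severity-coded findings and check reports.

Every control-check program in the workflow reports its results as an
ordered list of :class:`Finding` wrapped in a :class:`CheckReport`.  A
finding's code is drawn from a single registry (:data:`REGISTRY`) with a
fixed severity per code, so downstream scripting can rely on stable
machine identifiers.  Severity drives the uniform exit-code policy:
``info`` → 0, ``warning`` → 1, ``error`` → 2.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

INFO = "info"
WARNING = "warning"
ERROR = "error"

_SEVERITY_RANK = {INFO: 0, WARNING: 1, ERROR: 2}

#: Registry of every finding code the toolkit can emit, with its fixed
#: severity.  Codes are grouped by the program family that emits them.
REGISTRY: dict[str, str] = {
    # acquisition
    "ATTRIBUTE_COLUMN_COLLISION": WARNING,
    "NO_URLS_FOR_RUN": WARNING,
    "DUPLICATE_URL": INFO,
    "NAME_COLLISION": ERROR,
    # check-metadata-ena
    "LAYOUT_FILECOUNT_MISMATCH": WARNING,
    "MISSING_LAYOUT": WARNING,
    "PAIRED_WITH_ORPHAN": INFO,
    "SUBMITTED_UNAVAILABLE": INFO,
    "DUPLICATED_SUBMITTED_NAME": WARNING,
    "RUNS_SAMPLES_RELATION": INFO,
    "SAMPLE_COLUMN_DISAGREEMENT": WARNING,
    "SAMPLE_MULTIMATCH_ORGANISM": WARNING,
    "SAMPLE_MULTIMATCH_PLATFORM": WARNING,
    "SAMPLE_MULTIMATCH_LAYOUT": WARNING,
    "SAMPLE_MULTIMATCH_DATATYPE": WARNING,
    # check-fastqs
    "MISSING_FILE": ERROR,
    "UNEXPECTED_FILE": WARNING,
    "FILE_MULTIMATCH": WARNING,
    "MD5_MISMATCH": ERROR,
    "MD5_UNAVAILABLE": INFO,
    "FILE_UNREADABLE": ERROR,
    "MANIFEST_METADATA_DIVERGENCE": WARNING,
    "SAMPLE_SET_DIVERGENCE": WARNING,
    # merge / filter
    "MERGE_KEYS_ALIGNED": INFO,
    "MERGE_MAIN_ONLY_KEYS": WARNING,
    "MERGE_EXTRA_ONLY_KEYS": WARNING,
    "KEY_MULTIMATCH": WARNING,
    "CELL_NOT_NUMERIC": ERROR,
    # treatment
    "UNOWNED_FILE": WARNING,
    "MIXED_LAYOUT_SAMPLE": WARNING,
    "TEMPLATE_UNKNOWN_INPUT": ERROR,
    "TEMPLATE_DUPLICATE_INPUT": ERROR,
    "TEMPLATE_DUPLICATE_OUTPUT": ERROR,
    "TEMPLATE_BAD_ARITY": ERROR,
    "TEMPLATE_BLANK_FIELD": ERROR,
    "TEMPLATE_BAD_OUTPUT_NAME": ERROR,
    "TEMPLATE_READSIDE_INCONSISTENT": ERROR,
    "OUTPUT_EXISTS": ERROR,
    "SAMPLE_VALUE_CONFLICT": WARNING,
    "SAMPLE_NOT_IN_METADATA": ERROR,
    # check-metadata-values / concat-datasets
    "VARIABLE_MISSING": ERROR,
    "VARIABLE_OPTIONAL_ABSENT": INFO,
    "VARIABLE_NOT_NUMERIC": ERROR,
    "VARIABLE_NOT_UNIQUE": ERROR,
    "VARIABLE_MULTIMATCH": WARNING,
    "VALUE_NOT_ALLOWED": ERROR,
    "VALUE_SET_MISMATCH": ERROR,
    "VALUE_OUT_OF_RANGE": ERROR,
    "UNDECLARED_VARIABLE": INFO,
    "CROSS_DATASET_DUPLICATE": ERROR,
}


@dataclass(frozen=True)
class Finding:
    """One severity-coded observation about a run, sample, file or variable.

    ``severity`` is never passed by callers; it is looked up from
    :data:`REGISTRY` so that a code can never drift in severity.
    """

    code: str
    message: str
    subjects: tuple[str, ...] = ()
    severity: str = field(default="", compare=True)

    def __post_init__(self):
        if self.code not in REGISTRY:
            raise KeyError(f"unregistered finding code: {self.code!r}")
        object.__setattr__(self, "severity", REGISTRY[self.code])
        object.__setattr__(self, "subjects", tuple(self.subjects))


@dataclass
class CheckReport:
    """Ordered findings plus named summary tables.

    ``status`` is the worst severity present (``info`` when empty);
    serialization is deterministic for a fixed input.
    """

    findings: list[Finding] = field(default_factory=list)
    summaries: dict[str, pd.DataFrame] = field(default_factory=dict)

    def add(self, finding: Finding) -> None:
        self.findings.append(finding)

    def extend(self, findings) -> None:
        self.findings.extend(findings)

    def add_summary(self, name: str, table: pd.DataFrame) -> None:
        self.summaries[name] = table

    @property
    def status(self) -> str:
        worst = INFO
        for f in self.findings:
            if _SEVERITY_RANK[f.severity] > _SEVERITY_RANK[worst]:
                worst = f.severity
        return worst

    @property
    def exit_code(self) -> int:
        return _SEVERITY_RANK[self.status]

    def by_severity(self, severity: str) -> list[Finding]:
        return [f for f in self.findings if f.severity == severity]

    @property
    def codes(self) -> list[str]:
        return [f.code for f in self.findings]

    def findings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "severity": f.severity,
                    "code": f.code,
                    "subjects": ";".join(f.subjects),
                    "message": f.message,
                }
                for f in self.findings
            ],
            columns=["severity", "code", "subjects", "message"],
        )

    def write_findings_tsv(self, path) -> None:
        self.findings_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")

    def to_text(self) -> str:
        """Human-readable rendering: summary tables, then findings, then status."""
        blocks: list[str] = []
        for name, table in self.summaries.items():
            blocks.append(f"== {name} ==")
            blocks.append(table.to_string(index=False) if len(table) else "(empty)")
            blocks.append("")
        if self.findings:
            blocks.append("== findings ==")
            for f in self.findings:
                subj = f" [{';'.join(f.subjects)}]" if f.subjects else ""
                blocks.append(f"{f.severity.upper():7s} {f.code}{subj}: {f.message}")
        else:
            blocks.append("No findings.")
        blocks.append("")
        blocks.append(f"status: {self.status}")
        return "\n".join(blocks) + "\n"


def merge_reports(*reports: CheckReport) -> CheckReport:
    """Concatenate findings and summaries of several reports, in order."""
    out = CheckReport()
    for rep in reports:
        out.extend(rep.findings)
        for name, table in rep.summaries.items():
            out.summaries[name] = table
    return out
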