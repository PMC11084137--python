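"""Check Fastqs: reconcile a download directory against metadata or a
manifest, and verify file integrity with MD5 checksums.

File matching is by basename (ENA URL basenames are unique per run); for
generic datasets with colliding names the FILE_MULTIMATCH finding covers
the ambiguity.  MD5 digests are computed streaming in fixed-size blocks,
so arbitrarily large files need constant memory.
"""
from __future__ import annotations

import hashlib
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InputError
from .findings import CheckReport, Finding
from .model import ManifestTable, MetadataTable, split_multivalue

FASTQ_SUFFIXES = (".fastq.gz", ".fq.gz", ".fastq", ".fq")

_MD5_BLOCK = 1 << 20  # 1 MiB


def is_fastq_name(name: str) -> bool:
    return name.endswith(FASTQ_SUFFIXES)


@dataclass
class DirectoryInventory:
    """Sorted unique fastq basenames present in a download directory."""

    directory: Path
    files: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.directory = Path(self.directory)
        self.files = sorted(set(self.files))

    @classmethod
    def scan(cls, directory) -> "DirectoryInventory":
        directory = Path(directory)
        if not directory.is_dir():
            raise FileNotFoundError(f"not a directory: {directory}")
        names = [p.name for p in directory.iterdir() if p.is_file() and is_fastq_name(p.name)]
        return cls(directory=directory, files=names)

    def path(self, basename: str) -> Path:
        return self.directory / basename


def expected_basenames(
    expected: MetadataTable | ManifestTable, source_column: str = "fastq_ftp"
) -> dict[str, list[str]]:
    """Map each expected fastq basename to the rows (run/sample ids) claiming it."""
    claims: dict[str, list[str]] = defaultdict(list)
    if isinstance(expected, ManifestTable):
        for row in expected.df.itertuples(index=False):
            name = row.fastq_file_name
            if name is not None:
                claims[str(name)].append(str(row.sample_name))
        return dict(claims)
    if source_column not in expected.columns:
        raise InputError(f"column not present in table: {source_column!r}")
    id_col = "run_accession" if "run_accession" in expected.columns else None
    for i, row in enumerate(expected.rows()):
        owner = str(row[id_col]) if id_col else f"row {i + 1}"
        for url in split_multivalue(row.get(source_column)).values:
            claims[url.rsplit("/", 1)[-1]].append(owner)
    return dict(claims)


def reconcile_files(
    expected: MetadataTable | ManifestTable,
    inventory: DirectoryInventory,
    source_column: str = "fastq_ftp",
) -> list[Finding]:
    """Three finding families: expected-but-absent (error MISSING_FILE),
    present-but-unlisted (warning UNEXPECTED_FILE), and basenames claimed
    by more than one row (warning FILE_MULTIMATCH)."""
    claims = expected_basenames(expected, source_column=source_column)
    present = set(inventory.files)
    findings: list[Finding] = []
    for name in sorted(set(claims) - present):
        findings.append(
            Finding(
                code="MISSING_FILE",
                message=f"expected fastq {name!r} not found in {inventory.directory}",
                subjects=(name,),
            )
        )
    for name in sorted(present - set(claims)):
        findings.append(
            Finding(
                code="UNEXPECTED_FILE",
                message=f"fastq {name!r} present but not listed in the expected table",
                subjects=(name,),
            )
        )
    for name in sorted(claims):
        owners = claims[name]
        if len(owners) > 1:
            findings.append(
                Finding(
                    code="FILE_MULTIMATCH",
                    message=(
                        f"fastq {name!r} is claimed by {len(owners)} rows: "
                        + ", ".join(sorted(set(owners)))
                    ),
                    subjects=tuple([name] + sorted(set(owners))),
                )
            )
    return findings


def md5_of_file(path) -> str:
    """Streaming MD5 over raw bytes (constant memory)."""
    digest = hashlib.md5()
    with open(path, "rb") as fh:
        while block := fh.read(_MD5_BLOCK):
            digest.update(block)
    return digest.hexdigest()


def expected_md5_map(
    expected: MetadataTable | ManifestTable, source_column: str = "fastq_ftp"
) -> dict[str, str]:
    """Basename → expected hex digest, pairing URL and md5 multi-value cells."""
    if isinstance(expected, ManifestTable):
        return expected.md5_map()
    md5_column = {"fastq_ftp": "fastq_md5", "submitted_ftp": "submitted_md5"}.get(
        source_column
    )
    out: dict[str, str] = {}
    if md5_column is None or md5_column not in expected.columns:
        return out
    for row in expected.rows():
        urls = split_multivalue(row.get(source_column)).values
        digests = split_multivalue(row.get(md5_column)).values
        for url, digest in zip(urls, digests):
            out[url.rsplit("/", 1)[-1]] = digest
    return out


def verify_md5(
    inventory: DirectoryInventory, expected_md5: dict[str, str]
) -> list[Finding]:
    """Check integrity of present files against expected digests.

    Files without an expected digest are reported at info level; missing
    files are reconcile_files' concern and are skipped here.
    """
    findings: list[Finding] = []
    for name in inventory.files:
        expected = expected_md5.get(name)
        if expected is None:
            findings.append(
                Finding(
                    code="MD5_UNAVAILABLE",
                    message=f"no expected MD5 digest for {name!r}",
                    subjects=(name,),
                )
            )
            continue
        try:
            observed = md5_of_file(inventory.path(name))
        except OSError as exc:
            findings.append(
                Finding(
                    code="FILE_UNREADABLE",
                    message=f"could not read {name!r}: {exc}",
                    subjects=(name,),
                )
            )
            continue
        if observed.lower() != expected.lower():
            findings.append(
                Finding(
                    code="MD5_MISMATCH",
                    message=(
                        f"{name!r}: expected md5 {expected}, observed {observed}"
                    ),
                    subjects=(name,),
                )
            )
    return findings


def compare_manifest_metadata(
    manifest: ManifestTable,
    metadata: MetadataTable,
    sample_column: str = "sample_accession",
    source_column: str = "fastq_ftp",
) -> list[Finding]:
    """Generic-mode cross-check: file basenames and sample names present in
    exactly one of the two sources are reported as divergences."""
    if sample_column not in metadata.columns:
        raise InputError(f"sample column not present in metadata: {sample_column!r}")
    findings: list[Finding] = []
    manifest_files = set(manifest.file_names)
    metadata_files = set(expected_basenames(metadata, source_column=source_column))
    only = sorted(manifest_files.symmetric_difference(metadata_files))
    for name in only:
        where = "manifest" if name in manifest_files else "metadata"
        findings.append(
            Finding(
                code="MANIFEST_METADATA_DIVERGENCE",
                message=f"fastq {name!r} listed only in the {where} table",
                subjects=(name,),
            )
        )
    manifest_samples = {s for s in manifest.sample_names if s is not None}
    metadata_samples = {
        str(v) for v in metadata.column(sample_column) if v is not None
    }
    for sample in sorted(manifest_samples.symmetric_difference(metadata_samples)):
        where = "manifest" if sample in manifest_samples else "metadata"
        findings.append(
            Finding(
                code="SAMPLE_SET_DIVERGENCE",
                message=f"sample {sample!r} present only in the {where} table",
                subjects=(sample,),
            )
        )
    return findings


def check_fastqs(
    expected: MetadataTable | ManifestTable,
    directory,
    manifest: ManifestTable | None = None,
    md5: bool = False,
    source_column: str = "fastq_ftp",
    sample_column: str = "sample_accession",
) -> CheckReport:
    """Full Check Fastqs program over a download directory."""
    inventory = DirectoryInventory.scan(directory)
    report = CheckReport()
    report.extend(reconcile_files(expected, inventory, source_column=source_column))
    if manifest is not None and isinstance(expected, MetadataTable):
        report.extend(
            compare_manifest_metadata(
                manifest, expected, sample_column=sample_column, source_column=source_column
            )
        )
    if md5:
        report.extend(
            verify_md5(inventory, expected_md5_map(expected, source_column=source_column))
        )
    return report
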