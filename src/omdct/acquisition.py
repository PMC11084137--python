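"""Collection programs: ENA study metadata retrieval and parallel downloads.

The metadata source is a contract (:class:`MetadataFetcher`): anything that
can supply a run-level filereport table and per-sample attribute records.
Tests use recorded fixtures; :class:`EnaPortalFetcher` is the live HTTP
implementation against the ENA Portal API.

Downloads are plain HTTP(S)/FTP GETs fetched in parallel with bounded
retries; failed URLs are written to an error list that can be re-fed to
the same operation (relaunch closure).
"""
from __future__ import annotations

import concurrent.futures
import io
import json
import re
import shutil
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import pandas as pd

from .errors import AcquisitionError, InputError
from .findings import CheckReport, Finding
from .model import ENA_DIALECT, MetadataTable, split_multivalue

#: ENA/INSDC study accession patterns: BioProject (PRJEB/PRJNA/PRJDB...)
#: and secondary study accessions (ERP/SRP/DRP).
ACCESSION_RE = re.compile(r"^(PRJ[EDN][A-Z]\d+|[ESD]RP\d+)$")

#: Suffix applied when a sample attribute collides with a filereport column.
ATTR_COLLISION_SUFFIX = "_attr"

DEFAULT_PARALLELISM = 4
DEFAULT_RETRIES = 2
ERROR_LIST_NAME = "download_errors.txt"


@dataclass
class UrlList:
    """Ordered list of absolute URLs, one per line on disk."""

    urls: list[str] = field(default_factory=list)

    def __post_init__(self):
        if any(not u or not u.strip() for u in self.urls):
            raise InputError("URL list contains blank entries")
        self.urls = [u.strip() for u in self.urls]

    def __len__(self) -> int:
        return len(self.urls)

    def __iter__(self):
        return iter(self.urls)

    @classmethod
    def read(cls, path) -> "UrlList":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        return cls([ln.strip() for ln in lines if ln.strip()])

    def write(self, path) -> None:
        Path(path).write_text(
            "".join(u + "\n" for u in self.urls), encoding="utf-8"
        )


@dataclass
class DownloadRecord:
    url: str
    destination: str
    outcome: str  # "ok" | "failed"
    detail: str = ""


@dataclass
class DownloadReport:
    """Per-URL outcomes; the failed set is exactly the error-list output."""

    records: list[DownloadRecord] = field(default_factory=list)

    @property
    def n_ok(self) -> int:
        return sum(1 for r in self.records if r.outcome == "ok")

    @property
    def n_failed(self) -> int:
        return sum(1 for r in self.records if r.outcome == "failed")

    @property
    def failed_urls(self) -> list[str]:
        return [r.url for r in self.records if r.outcome == "failed"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "url": r.url,
                    "destination": r.destination,
                    "outcome": r.outcome,
                    "detail": r.detail,
                }
                for r in self.records
            ],
            columns=["url", "destination", "outcome", "detail"],
        )


class MetadataFetcher(Protocol):
    """Contract for an ENA-like metadata source.

    ``filereport`` returns the run-level table (ena dialect columns);
    ``sample_attributes`` returns per-sample attribute records keyed by
    sample accession.
    """

    def filereport(self, study_accession: str) -> MetadataTable: ...

    def sample_attributes(self, study_accession: str) -> dict[str, dict[str, str]]: ...


class EnaPortalFetcher:
    """Live fetcher against the ENA Portal API (network access required)."""

    PORTAL = "https://www.ebi.ac.uk/ena/portal/api"
    FIELDS = (
        "run_accession,sample_accession,secondary_sample_accession,sample_alias,"
        "library_layout,fastq_ftp,fastq_md5,fastq_bytes,scientific_name,tax_id,"
        "instrument_platform,instrument_model,library_strategy,library_source,"
        "submitted_ftp,submitted_md5"
    )

    def __init__(self, timeout: float = 60.0):
        self.timeout = timeout

    def _get(self, url: str) -> bytes:
        try:
            with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                return resp.read()
        except urllib.error.URLError as exc:  # pragma: no cover - network
            raise AcquisitionError(f"ENA portal request failed: {url}: {exc}") from exc

    def filereport(self, study_accession: str) -> MetadataTable:
        url = (
            f"{self.PORTAL}/filereport?accession={study_accession}"
            f"&result=read_run&fields={self.FIELDS}&format=tsv"
        )
        raw = self._get(url).decode("utf-8")
        df = pd.read_csv(
            io.StringIO(raw), sep="\t", dtype=str, keep_default_na=False, na_values=[]
        )
        return MetadataTable(df, dialect=ENA_DIALECT)

    def sample_attributes(self, study_accession: str) -> dict[str, dict[str, str]]:
        url = (
            f"{self.PORTAL}/search?result=sample&query=study_accession%3D%22"
            f"{urllib.parse.quote(study_accession)}%22&fields=all&format=json"
        )
        records = json.loads(self._get(url).decode("utf-8"))
        out: dict[str, dict[str, str]] = {}
        for rec in records:
            acc = rec.get("sample_accession")
            if acc:
                out[acc] = {k: v for k, v in rec.items() if k != "sample_accession"}
        return out


def fetch_ena_metadata(
    study_accession: str, fetcher: MetadataFetcher
) -> tuple[MetadataTable, CheckReport]:
    """Fetch a study's run metadata and join per-sample attributes onto it.

    Attribute names become additional columns, replicated across the
    sample's runs.  A name colliding with an existing filereport column
    is suffixed ``_attr`` and a warning is emitted.
    """
    if not ACCESSION_RE.match(study_accession):
        raise InputError(
            f"not a recognised ENA study accession: {study_accession!r} "
            "(expected PRJ[EDN]xNNN or [ESD]RPNNN)"
        )
    report = CheckReport()
    try:
        table = fetcher.filereport(study_accession)
        attributes = fetcher.sample_attributes(study_accession)
    except (InputError, AcquisitionError):
        raise
    except Exception as exc:
        raise AcquisitionError(f"metadata fetcher failed: {exc}") from exc
    if table.n_rows == 0:
        raise AcquisitionError(f"no runs found for study {study_accession}")

    # stable attribute-column order: first appearance across samples in
    # sample-accession order
    attr_names: list[str] = []
    for acc in sorted(attributes):
        for name in attributes[acc]:
            if name not in attr_names:
                attr_names.append(name)

    df = table.df.copy()
    for name in attr_names:
        target = name
        if target in df.columns:
            target = name + ATTR_COLLISION_SUFFIX
            report.add(
                Finding(
                    code="ATTRIBUTE_COLUMN_COLLISION",
                    message=(
                        f"sample attribute {name!r} collides with a metadata "
                        f"column; stored as {target!r}"
                    ),
                    subjects=(name,),
                )
            )
        df[target] = [
            attributes.get(acc, {}).get(name) for acc in df["sample_accession"]
        ]
    return MetadataTable(df, dialect=ENA_DIALECT), report


def plan_fastq_urls(
    table: MetadataTable, source_column: str = "fastq_ftp"
) -> tuple[UrlList, CheckReport]:
    """Concatenate, in row order, each run's multi-value URLs.

    Runs with a missing source cell contribute nothing but are reported;
    duplicate URLs are retained and reported at info level.
    """
    if source_column not in ("fastq_ftp", "submitted_ftp"):
        raise InputError(f"unsupported URL source column: {source_column!r}")
    if source_column not in table.columns:
        raise InputError(f"column not present in table: {source_column!r}")
    report = CheckReport()
    urls: list[str] = []
    empty_runs: list[str] = []
    for row in table.rows():
        cell = split_multivalue(row.get(source_column))
        if not cell.values:
            empty_runs.append(str(row.get("run_accession")))
            continue
        urls.extend(cell.values)
    if empty_runs:
        report.add(
            Finding(
                code="NO_URLS_FOR_RUN",
                message=(
                    f"{len(empty_runs)} run(s) have no {source_column} URLs "
                    "and contribute no downloads"
                ),
                subjects=tuple(empty_runs),
            )
        )
    seen: dict[str, int] = {}
    for u in urls:
        seen[u] = seen.get(u, 0) + 1
    dupes = sorted(u for u, n in seen.items() if n > 1)
    if dupes:
        report.add(
            Finding(
                code="DUPLICATE_URL",
                message=f"{len(dupes)} URL(s) appear more than once in the plan",
                subjects=tuple(dupes),
            )
        )
    return UrlList(urls), report


def _normalise_url(url: str) -> str:
    # ENA filereport URLs omit the scheme (ftp.sra.ebi.ac.uk/...); default
    # to https so stdlib urllib can fetch them.
    if "://" not in url:
        return "https://" + url
    return url


def _fetch_one(url: str, dest: Path, retries: int, timeout: float) -> DownloadRecord:
    basename = Path(urllib.parse.urlparse(_normalise_url(url)).path).name
    last_error = ""
    for _attempt in range(retries + 1):
        try:
            with urllib.request.urlopen(_normalise_url(url), timeout=timeout) as resp:
                tmp = dest / (basename + ".part")
                with open(tmp, "wb") as out:
                    shutil.copyfileobj(resp, out)
                tmp.replace(dest / basename)
            return DownloadRecord(url=url, destination=basename, outcome="ok")
        except Exception as exc:
            last_error = str(exc)
    return DownloadRecord(url=url, destination=basename, outcome="failed", detail=last_error)


def download_urls(
    urls: UrlList,
    dest,
    parallelism: int = DEFAULT_PARALLELISM,
    retries: int = DEFAULT_RETRIES,
    timeout: float = 60.0,
) -> DownloadReport:
    """Fetch every URL to ``dest`` under its basename; never abort the batch.

    Transport errors are captured per URL with up to ``retries``
    re-attempts.  Distinct URLs sharing a basename all fail with
    ``NAME_COLLISION``.  When any outcome is failed, the failed URLs are
    written to ``dest/download_errors.txt`` (one per line) so the list is
    directly reusable as input.
    """
    dest = Path(dest)
    if not dest.is_dir():
        raise InputError(f"download destination is not a directory: {dest}")
    if parallelism < 1:
        raise InputError("parallelism must be a positive integer")
    if retries < 0:
        raise InputError("retries must be non-negative")

    basenames: dict[str, set[str]] = {}
    for u in urls:
        name = Path(urllib.parse.urlparse(_normalise_url(u)).path).name
        basenames.setdefault(name, set()).add(u)
    colliding = {u for name, us in basenames.items() if len(us) > 1 for u in us}

    records: dict[int, DownloadRecord] = {}
    with concurrent.futures.ThreadPoolExecutor(max_workers=parallelism) as pool:
        futures = {}
        for i, u in enumerate(urls):
            if u in colliding:
                name = Path(urllib.parse.urlparse(_normalise_url(u)).path).name
                records[i] = DownloadRecord(
                    url=u,
                    destination=name,
                    outcome="failed",
                    detail="NAME_COLLISION: basename shared by multiple distinct URLs",
                )
            else:
                futures[pool.submit(_fetch_one, u, dest, retries, timeout)] = i
        for fut in concurrent.futures.as_completed(futures):
            records[futures[fut]] = fut.result()

    report = DownloadReport([records[i] for i in sorted(records)])
    if report.n_failed:
        UrlList(report.failed_urls).write(dest / ERROR_LIST_NAME)
    return report
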