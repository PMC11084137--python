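"""Synthetic ENA-like datasets for offline, deterministic testing.

``generate_dataset`` fabricates a small study: run-level metadata in the
ena dialect (synthetic ERR/SAMEA accessions), matching gzipped FASTQ
files whose true MD5 digests fill the ``fastq_md5`` column, a generic
manifest, and variables dictionaries for the run-level table and for the
per-sample curated table.  Reads are uniform-random ACGT with constant
quality; biological realism is irrelevant to file-level curation.

Run counts and layouts are apportioned to samples by largest remainder
from the configured proportions (then shuffled with the seed), so every
seed realizes the configured mix exactly.

``inject_defect`` applies exactly one minimal mutation realizing a named
defect and returns which finding code, on which subject, the checks must
now produce — the ground truth for the defect-detection matrix.
"""
from __future__ import annotations

import gzip
import hashlib
import random
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InputError
from .model import (
    ENA_DIALECT,
    MULTIVALUE_SEP,
    ManifestTable,
    MetadataTable,
    split_multivalue,
    write_manifest,
    write_table,
)
from .fastq_checks import DirectoryInventory
from .validation import VariableSpec, VariablesDictionary

DEFAULT_URL_BASE = "https://fixture.invalid/vol1"

ORGANISM_POOL = (("Homo sapiens", "9606"), ("Mus musculus", "10090"))
PLATFORM_POOL = (("ILLUMINA", "Illumina MiSeq"), ("ILLUMINA", "Illumina NovaSeq 6000"))
DATATYPE_POOL = (("AMPLICON", "METAGENOMIC"), ("WGS", "METAGENOMIC"))
SEX_POOL = ("male", "female")
COUNTRY_POOL = ("Spain", "France", "Italy")
ISOLATION_POOL = ("stool", "saliva", "skin swab")
AGE_RANGE = (18, 80)

#: Defect codes and the finding code + check program each must trigger.
DEFECT_FINDING_MAP = {
    "DELETE_FILE": ("MISSING_FILE", "check-fastqs"),
    "EXTRA_FILE": ("UNEXPECTED_FILE", "check-fastqs"),
    "CORRUPT_FILE": ("MD5_MISMATCH", "check-fastqs"),
    "WRONG_MD5": ("MD5_MISMATCH", "check-fastqs"),
    "PAIRED_MISSING_MATE": ("LAYOUT_FILECOUNT_MISMATCH", "check-metadata-ena"),
    "DUP_SUBMITTED_NAME": ("DUPLICATED_SUBMITTED_NAME", "check-metadata-ena"),
    "SAMPLE_LAYOUT_CONFLICT": ("SAMPLE_MULTIMATCH_LAYOUT", "check-metadata-ena"),
    "SAMPLE_ORGANISM_CONFLICT": ("SAMPLE_MULTIMATCH_ORGANISM", "check-metadata-ena"),
    "REQUIRED_VAR_DROPPED": ("VARIABLE_MISSING", "check-metadata-values"),
    "VALUE_OUT_OF_RANGE": ("VALUE_OUT_OF_RANGE", "check-metadata-values"),
    "DUP_UNIQUE_ID_ACROSS_DATASETS": ("CROSS_DATASET_DUPLICATE", "concat-datasets"),
    "CONFLICTING_SAMPLE_VALUES": ("SAMPLE_VALUE_CONFLICT", "treat-metadata"),
}

DEFECT_CODES = tuple(DEFECT_FINDING_MAP)


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions of the synthetic dataset.

    ``runs_per_sample`` and ``layout_mix`` are proportions realized
    exactly (largest remainder) over ``n_samples``.
    """

    seed: int
    n_samples: int = 6
    runs_per_sample: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.35, 3: 0.15}
    )
    layout_mix: float = 0.5  # proportion of PAIRED samples
    reads_per_file: int = 20
    read_length: int = 75
    url_base: str = DEFAULT_URL_BASE

    def __post_init__(self):
        if self.n_samples < 1 or self.reads_per_file < 1 or self.read_length < 1:
            raise InputError("fixture counts must be positive")
        if not 0.0 <= self.layout_mix <= 1.0:
            raise InputError("layout_mix must be in [0, 1]")
        if any(p < 0 for p in self.runs_per_sample.values()):
            raise InputError("runs_per_sample proportions must be non-negative")


def _apportion(weights: dict, n: int) -> dict:
    """Largest-remainder apportionment of n units over weighted classes."""
    total = sum(weights.values())
    if total <= 0:
        raise InputError("weights must sum to a positive value")
    quotas = {k: n * w / total for k, w in weights.items()}
    counts = {k: int(q) for k, q in quotas.items()}
    leftover = n - sum(counts.values())
    by_remainder = sorted(
        weights, key=lambda k: (-(quotas[k] - counts[k]), str(k))
    )
    for k in by_remainder[:leftover]:
        counts[k] += 1
    return counts


@dataclass
class FixtureDataset:
    """A generated dataset and the file artifacts it was written to."""

    config: FixtureConfig
    out_dir: Path
    metadata: MetadataTable
    manifest: ManifestTable
    dictionary: VariablesDictionary
    curated_dictionary: VariablesDictionary
    fastq_dir: Path

    @property
    def metadata_path(self) -> Path:
        return self.out_dir / "metadata.tsv"

    @property
    def manifest_path(self) -> Path:
        return self.out_dir / "manifest.tsv"

    @property
    def dictionary_path(self) -> Path:
        return self.out_dir / "dictionary.tsv"

    @property
    def curated_dictionary_path(self) -> Path:
        return self.out_dir / "dictionary_curated.tsv"

    def inventory(self) -> DirectoryInventory:
        return DirectoryInventory.scan(self.fastq_dir)

    def save_tables(self) -> None:
        write_table(self.metadata, self.metadata_path)
        write_manifest(self.manifest, self.manifest_path)
        self.dictionary.write(self.dictionary_path)
        self.curated_dictionary.write(self.curated_dictionary_path)


def _fastq_bytes(rng: random.Random, run: str, mate: int, config: FixtureConfig) -> bytes:
    lines = []
    for i in range(1, config.reads_per_file + 1):
        seq = "".join(rng.choice("ACGT") for _ in range(config.read_length))
        lines.append(f"@{run}.{i} {i}/{mate}")
        lines.append(seq)
        lines.append("+")
        lines.append("I" * config.read_length)
    payload = ("\n".join(lines) + "\n").encode("ascii")
    return gzip.compress(payload, compresslevel=6, mtime=0)


def _dictionary_specs(unique_subject: bool) -> list[VariableSpec]:
    char = dict(var_class="character", uniqueness="nonunique")
    specs = [
        VariableSpec("run_accession", "required", "character",
                     "unique" if not unique_subject else "nonunique", "any"),
        VariableSpec("sample_accession", "required", **char, allowed_analysis="any"),
        VariableSpec("secondary_sample_accession", "optional", **char,
                     allowed_analysis="any",
                     crosscheck_variables=("sample_accession",)),
        VariableSpec("sample_alias", "optional", **char, allowed_analysis="any",
                     crosscheck_variables=("sample_accession",)),
        VariableSpec("library_layout", "required", **char,
                     allowed_analysis="subset", allowed_values=("PAIRED", "SINGLE")),
        VariableSpec("fastq_ftp", "optional", **char, allowed_analysis="any"),
        VariableSpec("fastq_md5", "optional", **char, allowed_analysis="any"),
        VariableSpec("fastq_bytes", "optional", **char, allowed_analysis="any"),
        VariableSpec("submitted_ftp", "optional", **char, allowed_analysis="any"),
        VariableSpec("submitted_md5", "optional", **char, allowed_analysis="any"),
        VariableSpec("scientific_name", "required", **char,
                     allowed_analysis="subset",
                     allowed_values=tuple(o[0] for o in ORGANISM_POOL)),
        VariableSpec("tax_id", "required", "numeric", "nonunique", "any"),
        VariableSpec("instrument_platform", "required", **char,
                     allowed_analysis="subset",
                     allowed_values=tuple({p[0] for p in PLATFORM_POOL})),
        VariableSpec("instrument_model", "required", **char,
                     allowed_analysis="subset",
                     allowed_values=tuple(p[1] for p in PLATFORM_POOL)),
        VariableSpec("library_strategy", "required", **char,
                     allowed_analysis="subset",
                     allowed_values=tuple(d[0] for d in DATATYPE_POOL)),
        VariableSpec("library_source", "required", **char,
                     allowed_analysis="subset",
                     allowed_values=tuple({d[1] for d in DATATYPE_POOL})),
        VariableSpec("subject_id", "required", "character",
                     "unique" if unique_subject else "nonunique", "any",
                     crosscheck_variables=("sample_accession",)),
        VariableSpec("host_sex", "optional", **char,
                     allowed_analysis="subset", allowed_values=SEX_POOL),
        VariableSpec("host_age", "optional", "numeric", "nonunique", "range",
                     value_range=(float(AGE_RANGE[0]), float(AGE_RANGE[1]))),
        VariableSpec("country", "optional", **char,
                     allowed_analysis="subset", allowed_values=COUNTRY_POOL),
        # free-text: no allowed-value analysis, so multi-valued cells produced
        # by per-sample metadata combination still validate
        VariableSpec("isolation_source", "optional", **char, allowed_analysis="any"),
    ]
    return specs


def generate_dataset(config: FixtureConfig, out_dir) -> FixtureDataset:
    """Write a deterministic clean dataset under ``out_dir``.

    Layout on disk: ``metadata.tsv``, ``manifest.tsv``, ``dictionary.tsv``
    (run-level table schema), ``dictionary_curated.tsv`` (per-sample
    schema: subject_id unique), and ``fastqs/`` with the gzipped files.
    """
    rng = random.Random(config.seed)
    out_dir = Path(out_dir)
    fastq_dir = out_dir / "fastqs"
    fastq_dir.mkdir(parents=True, exist_ok=True)

    n = config.n_samples
    run_count_alloc = _apportion(config.runs_per_sample, n)
    run_counts = [k for k, c in sorted(run_count_alloc.items()) for _ in range(c)]
    layout_alloc = _apportion(
        {"PAIRED": config.layout_mix, "SINGLE": 1.0 - config.layout_mix}, n
    )
    layouts = ["PAIRED"] * layout_alloc.get("PAIRED", 0) + [
        "SINGLE"
    ] * layout_alloc.get("SINGLE", 0)
    rng.shuffle(run_counts)
    rng.shuffle(layouts)

    n_runs = sum(run_counts)
    run_numbers = sorted(rng.sample(range(1_000_000, 9_999_999), n_runs))
    sample_numbers = sorted(rng.sample(range(10_000_000, 99_999_999), n))
    organism = ORGANISM_POOL[0]

    metadata_rows: list[dict] = []
    manifest_rows: list[dict] = []
    run_iter = iter(run_numbers)
    for s in range(n):
        sample = f"SAMEA{sample_numbers[s]}"
        layout = layouts[s]
        platform = rng.choice(PLATFORM_POOL)
        datatype = rng.choice(DATATYPE_POOL)
        attrs = {
            "subject_id": f"subj_{sample}",
            "host_sex": rng.choice(SEX_POOL),
            "host_age": str(rng.randint(*AGE_RANGE)),
            "country": rng.choice(COUNTRY_POOL),
            "isolation_source": rng.choice(ISOLATION_POOL),
        }
        for _ in range(run_counts[s]):
            run = f"ERR{next(run_iter)}"
            mates = (1, 2) if layout == "PAIRED" else (0,)
            basenames, digests, sizes = [], [], []
            for mate in mates:
                suffix = f"_{mate}" if mate else ""
                basename = f"{run}{suffix}.fastq.gz"
                payload = _fastq_bytes(rng, run, mate or 1, config)
                (fastq_dir / basename).write_bytes(payload)
                digest = hashlib.md5(payload).hexdigest()
                basenames.append(basename)
                digests.append(digest)
                sizes.append(str(len(payload)))
                manifest_rows.append(
                    {"fastq_file_name": basename, "sample_name": sample, "md5": digest}
                )
            submitted = [
                f"{config.url_base}/submitted/{run}_submitted{f'_{m}' if m else ''}.fq.gz"
                for m in mates
            ]
            metadata_rows.append(
                {
                    "run_accession": run,
                    "sample_accession": sample,
                    "secondary_sample_accession": f"ERS{sample_numbers[s]}",
                    "sample_alias": f"sample_{sample}",
                    "library_layout": layout,
                    "fastq_ftp": MULTIVALUE_SEP.join(
                        f"{config.url_base}/fastqs/{b}" for b in basenames
                    ),
                    "fastq_md5": MULTIVALUE_SEP.join(digests),
                    "fastq_bytes": MULTIVALUE_SEP.join(sizes),
                    "submitted_ftp": MULTIVALUE_SEP.join(submitted),
                    "submitted_md5": MULTIVALUE_SEP.join(
                        hashlib.md5(u.rsplit("/", 1)[-1].encode()).hexdigest()
                        for u in submitted
                    ),
                    "scientific_name": organism[0],
                    "tax_id": organism[1],
                    "instrument_platform": platform[0],
                    "instrument_model": platform[1],
                    "library_strategy": datatype[0],
                    "library_source": datatype[1],
                    **attrs,
                }
            )

    columns = list(metadata_rows[0])
    metadata = MetadataTable.from_records(columns, metadata_rows, dialect=ENA_DIALECT)
    manifest = ManifestTable.from_records(manifest_rows)
    dataset = FixtureDataset(
        config=config,
        out_dir=out_dir,
        metadata=metadata,
        manifest=manifest,
        dictionary=VariablesDictionary(_dictionary_specs(unique_subject=False)),
        curated_dictionary=VariablesDictionary(_dictionary_specs(unique_subject=True)),
        fastq_dir=fastq_dir,
    )
    dataset.save_tables()
    return dataset


@dataclass(frozen=True)
class DefectExpectation:
    """Ground truth for one injected defect."""

    defect: str
    finding_code: str
    check_program: str
    subject: str


def _multirun_samples(metadata: MetadataTable) -> list[str]:
    counts: dict[str, int] = {}
    for row in metadata.rows():
        counts[str(row["sample_accession"])] = counts.get(str(row["sample_accession"]), 0) + 1
    return sorted(s for s, c in counts.items() if c > 1)


def _set_cell(metadata: MetadataTable, row_idx: int, column: str, value) -> None:
    metadata.df.loc[row_idx, column] = value


def inject_defect(
    dataset: FixtureDataset,
    defect: str,
    rng_seed: int,
    other: FixtureDataset | None = None,
) -> DefectExpectation:
    """Apply one minimal mutation realizing ``defect`` and persist it.

    ``DUP_UNIQUE_ID_ACROSS_DATASETS`` needs a second dataset (``other``);
    the duplicate is planted in ``other``.  Raises InputError when the
    defect is inapplicable to the dataset's configuration.
    """
    if defect not in DEFECT_FINDING_MAP:
        raise InputError(f"unknown defect code: {defect!r}")
    rng = random.Random(rng_seed)
    metadata = dataset.metadata
    finding_code, program = DEFECT_FINDING_MAP[defect]
    df = metadata.df

    if defect == "DELETE_FILE":
        basename = rng.choice(dataset.inventory().files)
        (dataset.fastq_dir / basename).unlink()
        return DefectExpectation(defect, finding_code, program, basename)

    if defect == "EXTRA_FILE":
        basename = "planted_extra.fastq.gz"
        (dataset.fastq_dir / basename).write_bytes(
            gzip.compress(b"@planted.1 1/1\nACGT\n+\nIIII\n", mtime=0)
        )
        return DefectExpectation(defect, finding_code, program, basename)

    if defect == "CORRUPT_FILE":
        basename = rng.choice(dataset.inventory().files)
        path = dataset.fastq_dir / basename
        blob = bytearray(path.read_bytes())
        pos = rng.randrange(len(blob))
        blob[pos] ^= 1 << rng.randrange(8)
        path.write_bytes(bytes(blob))
        return DefectExpectation(defect, finding_code, program, basename)

    if defect == "WRONG_MD5":
        row_idx = rng.randrange(len(df))
        digests = list(split_multivalue(df.loc[row_idx, "fastq_md5"]).values)
        which = rng.randrange(len(digests))
        d = digests[which]
        flip = "0" if d[0] != "0" else "1"
        digests[which] = flip + d[1:]
        _set_cell(metadata, row_idx, "fastq_md5", MULTIVALUE_SEP.join(digests))
        basename = split_multivalue(df.loc[row_idx, "fastq_ftp"]).values[which].rsplit("/", 1)[-1]
        dataset.save_tables()
        return DefectExpectation(defect, finding_code, program, basename)

    if defect == "PAIRED_MISSING_MATE":
        paired = [i for i in range(len(df)) if df.loc[i, "library_layout"] == "PAIRED"]
        if not paired:
            raise InputError("PAIRED_MISSING_MATE requires a PAIRED run")
        row_idx = rng.choice(paired)
        for col in ("fastq_ftp", "fastq_md5", "fastq_bytes"):
            values = split_multivalue(df.loc[row_idx, col]).values
            _set_cell(metadata, row_idx, col, MULTIVALUE_SEP.join(values[:1]))
        dataset.save_tables()
        return DefectExpectation(
            defect, finding_code, program, str(df.loc[row_idx, "run_accession"])
        )

    if defect == "DUP_SUBMITTED_NAME":
        if len(df) < 2:
            raise InputError("DUP_SUBMITTED_NAME requires at least 2 runs")
        a, b = rng.sample(range(len(df)), 2)
        stolen = split_multivalue(df.loc[a, "submitted_ftp"]).values[0]
        basename = stolen.rsplit("/", 1)[-1]
        own = list(split_multivalue(df.loc[b, "submitted_ftp"]).values)
        own[0] = own[0].rsplit("/", 1)[0] + "/" + basename
        _set_cell(metadata, b, "submitted_ftp", MULTIVALUE_SEP.join(own))
        dataset.save_tables()
        return DefectExpectation(defect, finding_code, program, basename)

    if defect in ("SAMPLE_LAYOUT_CONFLICT", "SAMPLE_ORGANISM_CONFLICT",
                  "CONFLICTING_SAMPLE_VALUES"):
        candidates = _multirun_samples(metadata)
        if not candidates:
            raise InputError(f"{defect} requires a sample with several runs")
        sample = rng.choice(candidates)
        rows = [i for i in range(len(df)) if df.loc[i, "sample_accession"] == sample]
        row_idx = rows[0]
        if defect == "SAMPLE_LAYOUT_CONFLICT":
            # toggle layout and fix the URL count so only the per-sample
            # multi-match is violated, not the layout/file-count rule
            if df.loc[row_idx, "library_layout"] == "PAIRED":
                _set_cell(metadata, row_idx, "library_layout", "SINGLE")
                for col in ("fastq_ftp", "fastq_md5", "fastq_bytes"):
                    values = split_multivalue(df.loc[row_idx, col]).values
                    _set_cell(metadata, row_idx, col, MULTIVALUE_SEP.join(values[:1]))
            else:
                _set_cell(metadata, row_idx, "library_layout", "PAIRED")
                run = df.loc[row_idx, "run_accession"]
                for col, extra in (
                    ("fastq_ftp", f"{dataset.config.url_base}/fastqs/{run}_2.fastq.gz"),
                    ("fastq_md5", "0" * 32),
                    ("fastq_bytes", "0"),
                ):
                    values = list(split_multivalue(df.loc[row_idx, col]).values)
                    _set_cell(metadata, row_idx, col, MULTIVALUE_SEP.join(values + [extra]))
        elif defect == "SAMPLE_ORGANISM_CONFLICT":
            current = df.loc[row_idx, "scientific_name"]
            name, tax = next(o for o in ORGANISM_POOL if o[0] != current)
            _set_cell(metadata, row_idx, "scientific_name", name)
            _set_cell(metadata, row_idx, "tax_id", tax)
        else:  # CONFLICTING_SAMPLE_VALUES
            current = df.loc[row_idx, "isolation_source"]
            flipped = next(v for v in ISOLATION_POOL if v != current)
            _set_cell(metadata, row_idx, "isolation_source", flipped)
        dataset.save_tables()
        return DefectExpectation(defect, finding_code, program, sample)

    if defect == "REQUIRED_VAR_DROPPED":
        metadata.df = df.drop(columns=["subject_id"])
        dataset.save_tables()
        return DefectExpectation(defect, finding_code, program, "subject_id")

    if defect == "VALUE_OUT_OF_RANGE":
        sample = rng.choice(sorted({str(v) for v in df["sample_accession"]}))
        bad = str(AGE_RANGE[1] + 54)
        for i in range(len(df)):
            if df.loc[i, "sample_accession"] == sample:
                _set_cell(metadata, i, "host_age", bad)
        dataset.save_tables()
        return DefectExpectation(defect, finding_code, program, bad)

    # DUP_UNIQUE_ID_ACROSS_DATASETS
    if other is None:
        raise InputError("DUP_UNIQUE_ID_ACROSS_DATASETS requires a second dataset")
    subject = rng.choice(sorted({str(v) for v in df["subject_id"]}))
    target_sample = rng.choice(
        sorted({str(v) for v in other.metadata.df["sample_accession"]})
    )
    for i in range(len(other.metadata.df)):
        if other.metadata.df.loc[i, "sample_accession"] == target_sample:
            _set_cell(other.metadata, i, "subject_id", subject)
    other.save_tables()
    return DefectExpectation(defect, finding_code, program, subject)
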