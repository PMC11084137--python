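# Methods

## Scope and model

`omdct` curates public sequencing datasets at the *file and metadata*
level. It never inspects read content beyond file bytes: no quality
trimming, no pairing-order verification, no record-level FASTQ parsing.
That boundary is deliberate — read processing belongs to downstream
pipelines; what is chronically missing upstream is a consistent, checkable
path from "study accession" to "validated per-sample files plus a
per-sample metadata table".

The data model is the ENA/INSDC run–sample model. A *run* is one
sequencing event and owns one (SINGLE) or two (PAIRED) fastq files; a
*sample* may own several runs. The run-level metadata table is the ENA
Portal filereport dialect; multi-file cells (`fastq_ftp`, `fastq_md5`,
`submitted_ftp`, …) hold one entry per file joined with `";"`. Generic
datasets enter through a manifest table (`fastq_file_name`, `sample_name`,
optional `md5`) instead.

## On-disk conventions

* Tables are UTF-8, tab-separated, header row, Unix newlines. Cells may
  not contain tabs or newlines (unquoted TSV keeps round-tripping exact
  and diff-able).
* Missing cells are written as the empty string; the token set
  `{"", "NA", "na", "NaN", "nan", "None"}` parses to missing. The token
  set is generous on read and canonical on write so that repeated
  read/write cycles converge immediately.
* Control files (filter specifications, variables dictionaries, treatment
  templates) are themselves TSV, one record per row, so that the curation
  decisions are archivable artifacts rather than shell history.

## Findings and the exit-code policy

Every check emits findings drawn from a single registry with a fixed
severity per code: `error` — curation cannot proceed safely; `warning` —
likely problem needing human review; `info` — descriptive. Programs exit
0/1/2 by the worst severity present, and 2 for usage or I/O failures.
Severity lives in the registry, not at the emission site, so a code can
never drift between runs or call sites. Reports serialize
deterministically (stable iteration orders, sorted subject lists), which
the tests assert byte-for-byte.

## Checks

**Layout vs file count.** SINGLE expects exactly 1 fastq URL, PAIRED
exactly 2. PAIRED with 3 is reported at info level (`PAIRED_WITH_ORPHAN`):
ENA conventionally publishes an extra unpaired-reads file for some paired
runs, and treating that as a warning would make most real paired studies
noisy. Anything else is a warning; a missing layout is its own warning.

**Per-sample consistency.** Organism (scientific name + tax id),
instrument (platform + model), layout, and data type (strategy + source)
should each be single-valued per sample. Missing cells are *not-a-value*:
a sample with one real organism plus missing cells is not a conflict.
Several sample-identity columns (`sample_accession`,
`secondary_sample_accession`, `sample_alias`) can be compared pairwise;
two rows equal in one column but separated by the other raise a grouping
disagreement.

**File reconciliation.** Matching is by basename — ENA URL basenames are
unique per run. For generic datasets with colliding names the
`FILE_MULTIMATCH` finding covers the ambiguity; this is a documented
limitation, not silent behavior. MD5 digests are computed streaming in
1 MiB blocks (constant memory on arbitrarily large files) and checking is
opt-in (`--md5`) because it dominates runtime on real datasets.

**Merging.** Left join by default, with `right`, `inner`, `outer` as the
standard relational alternatives. Keys compare by exact string equality
after trimming surrounding whitespace; no case folding. Missing keys
never match (SQL semantics) — pandas would join NaN to NaN, so missing
keys are sentineled per row before the join. The two key columns'
unique-value sets are intersected and the one-sided leftovers reported;
extra-side key fan-out is reported as `KEY_MULTIMATCH`.

**Filtering.** Steps apply strictly in file order; each step declares its
own NA policy (`keep`/`drop`), so "unavailable" is an explicit decision
per filter, never a default. Numeric parsing accepts integers and
`.`-decimals only. The per-step row accounting
(`rows_before − rows_removed = rows_after`, chained) is exact and tested
against a row-by-row predicate oracle.

**Treatment.** Canonical per-sample names are `<sample>_1.fastq.gz` /
`<sample>_2.fastq.gz` / `<sample>.fastq.gz`. Read sides are inferred from
basename suffixes (`_1/_2`, `_R1/_R2`, `.1/.2` before the fastq suffix);
uninferable files are left blank for the curator, as are samples mixing
PAIRED and SINGLE runs — the template is a *plan to be reviewed*, and the
validator refuses to execute a template with blanks, duplicate inputs or
outputs, wrong arities, or non-canonical output names. Merging
concatenates the gzipped inputs byte-wise in template order:
multi-member gzip is itself a valid gzip stream, so the operation is
lossless and never recompresses. Per-sample metadata combination keeps
agreeing values (ignoring missing), `";"`-joins disagreeing ones with a
warning per (sample, column), and aggregates declared run-specific
columns (`run_accession`, `fastq_ftp`, `fastq_md5`, …) silently.

**Validation and concatenation.** Per-variable checks run in a fixed
order — presence, class, uniqueness, cross-check, allowed values — so
reports are comparable across runs. `wholeset` means set equality in both
directions (subset already covers one direction). Boolean tokens
(`true/True/TRUE/...`) are accepted, not coerced, under `character`.
Range bounds are inclusive; missing cells never violate an allowed-value
analysis (missingness is governed by requiredness). The cross-check is
run symmetrically and each direction reports separately. Concatenation
validates every input first (errors block, warnings pass), lays columns
out in dictionary order with missing-filled optional columns, appends a
dataset-origin column, and re-checks every `unique` variable across
datasets (`CROSS_DATASET_DUPLICATE`).

## Acquisition

The metadata source is a contract — anything providing a filereport table
and per-sample attribute records — so tests run against recorded fixtures
and the live ENA Portal client is just one implementation. Sample
attributes join onto run rows by sample accession; a name colliding with
a filereport column is suffixed `_attr` with a warning rather than
overwritten. The downloader is a plain HTTP(S)/FTP GET pool (default
parallelism 4, retries 2 — conservative politeness toward public
mirrors); failures never abort the batch, and failed URLs are written to
`download_errors.txt`, which is itself valid downloader input
(relaunch closure). MD5 verification is deliberately *not* done at
download time; that is the fastq check's job.

## The synthetic dataset generator

`omdct.fixtures` fabricates a study the rest of the toolkit can be tested
against offline: synthetic ERR/SAMEA accessions, gzipped fastq files of
uniform-random ACGT reads with constant quality (default 6 samples,
20 reads × 75 bp per file), true MD5 digests in `fastq_md5`, per-sample
attributes (subject id, sex, age in 18–80, country, isolation source),
a matching manifest, and variables dictionaries for both the run-level
table and the per-sample curated table (where the subject identifier
becomes `unique`). Run counts per sample (proportions 0.5/0.35/0.15 for
1/2/3 runs) and the PAIRED share (0.5) are realized *exactly* by
largest-remainder apportionment and then shuffled with the seed, so every
seed contains multi-run samples and paired runs — the structures the
checks exist for. Generation is byte-deterministic for a fixed
(config, seed): gzip members carry mtime 0.

What the generator does **not** emulate: sequencing error models, quality
profiles, realistic attribute distributions, ENA server behavior, or
name collisions across studies. Passing tests therefore demonstrate the
correctness of the curation logic on structurally faithful data, not
robustness to every pathology of real repositories.

The defect injector applies exactly one minimal mutation per defect code
and returns the finding code and subject the checks must now produce.
One mutation is deliberately compound: toggling a run's layout also
adjusts its URL/digest lists to the new layout, so the injected defect is
*only* a per-sample layout conflict and not additionally a layout/file
count mismatch.

## Numerical and sizing choices

Randomized-oracle tests use ≥100 tables of ≤30 rows per operation;
clean-fixture silence is checked across 5 seeds; the end-to-end workflow
runs on two 6-sample datasets (≈20 runs, ≈32 files). These sizes exercise
every code path (multi-run samples, both layouts, merges per read side)
while keeping the full suite and the acceptance script fast enough to run
on every change. Problem sizes are reported alongside every quantity the
acceptance script emits.

## Known limitations

* File identity is basename-based; two distinct URLs sharing a basename
  cannot coexist in one download directory (reported, not resolved).
* No Aspera/FTP-resume; plain GET semantics only.
* No ontology mapping or controlled-vocabulary normalization of metadata
  values; the variables dictionary is user-authored.
* R1/R2 pairing order inside files is not verified (out of scope:
  file-level curation only).
* The live ENA fetcher is exercised only through its contract; network
  behavior (rate limits, partial responses) is not simulated.
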