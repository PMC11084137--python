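# omdct — curation toolkit for public omics datasets

`omdct` is a workflow of command-line programs for the in-house curation of
public sequencing datasets: collecting run-level metadata and fastq files,
checking them for the inconsistencies that plague public repositories,
treating raw per-run files into canonical per-sample files, and integrating
several curated datasets into one meta-analysis-ready table.

It is written for researchers who re-use public data — building microbiome,
metagenomic or RNA-seq meta-analyses from studies deposited in the European
Nucleotide Archive (ENA) and its INSDC mirrors (SRA, DDBJ) — and who know
that the deposited metadata is rarely usable as-is: samples with several
sequencing runs, PAIRED runs with a missing mate file, duplicated submitted
file names, conflicting per-sample annotations, subject identifiers silently
shared between cohorts. Most programs also have a generic mode (manifest
tables, URL lists) for datasets hosted elsewhere.

## The model

The central artifact is the **run-level metadata table**: one row per
sequencing run, in the ENA filereport dialect (`run_accession`,
`sample_accession`, `library_layout`, `fastq_ftp`, `fastq_md5`, organism,
platform, library strategy/source, …). A sample may own several runs; a
PAIRED run owns two fastq files (`_1`/`_2`), a SINGLE run one. Multi-file
cells use the ENA `";"` separator; missing values are empty cells (the
tokens `NA`, `nan`, `None`, … parse to missing).

Every control-check program reports **findings** — severity-coded
observations with stable machine codes (`MISSING_FILE`,
`SAMPLE_MULTIMATCH_LAYOUT`, `CROSS_DATASET_DUPLICATE`, …) — and exits 0
(informational only), 1 (warnings) or 2 (errors), so the workflow is
scriptable. Final validation is driven by a user-authored **variables
dictionary** that assigns each curated variable a requiredness, a class
(character/numeric), a uniqueness constraint, an allowed-value analysis
(`any`, `subset`, `wholeset`, or numeric `range`) and optional cross-check
variables; the same dictionary drives the safe concatenation of several
curated datasets.

The workflow, in order:

| step | program |
|---|---|
| collection | `download-metadata-ena`, `download-fastqs` |
| control checks | `check-metadata-ena`, `check-fastqs` |
| curation | `merge-metadata`, `filter-metadata` |
| treatment | `make-treatment-template`, `treat-fastqs`, `treat-metadata` |
| integration & validation | `concat-datasets`, `check-metadata-values` |

plus `make-fixture`, which generates a fully synthetic ENA-like dataset
(metadata, manifest, dictionaries and gzipped fastq files with true MD5
digests) so the whole workflow can be exercised offline.

## Worked example

Generate a small synthetic study and screen its metadata:

```sh
$ omdct make-fixture --seed 11 --samples 4 -o study
7 runs / 4 samples written to study

$ omdct check-metadata-ena -t study/metadata.tsv
== counts ==
 n_runs  n_samples
      7          4
...
== library_layout ==
library_layout  n_runs
        SINGLE       5
        PAIRED       2
...
== runs_per_sample ==
 runs_per_sample  n_samples                     samples
               1          2 SAMEA22169593;SAMEA29031420
               2          1               SAMEA82302218
               3          1               SAMEA95154811
```

Seven runs map onto four samples (one sample has three runs — its files
will later be merged per read side by the treatment programs), layouts and
platforms tally correctly, and no warnings are raised, so the program exits
with code 0. Reconciling the download directory and verifying file
integrity is equally quiet on intact data:

```sh
$ omdct check-fastqs -t study/metadata.tsv -d study/fastqs --md5
No findings.

status: info
```

Delete one downloaded file and the same check pinpoints it and exits 2:

```sh
$ rm study/fastqs/ERR2579129_1.fastq.gz
$ omdct check-fastqs -t study/metadata.tsv -d study/fastqs
== findings ==
ERROR   MISSING_FILE [ERR2579129_1.fastq.gz]: expected fastq 'ERR2579129_1.fastq.gz' not found in study/fastqs

status: error
```

Every check also writes a machine-readable findings TSV
(`severity  code  subjects  message`) next to its input.

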