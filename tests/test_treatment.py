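"""Treatment planning and execution: copy/rename/merge of per-sample fastqs
and per-sample metadata combination."""
import gzip
import hashlib

import pytest

from omdct.errors import TreatmentError
from omdct.fastq_checks import DirectoryInventory, md5_of_file
from omdct.model import ENA_DIALECT, ENA_REQUIRED_COLUMNS, ManifestTable, MetadataTable
from omdct.treatment import (
    TreatmentRow,
    TreatmentTemplate,
    canonical_output,
    infer_read_side,
    make_treatment_template,
    treat_fastqs,
    treat_metadata,
    validate_treatment_template,
)


def fastq_gz(n_records, tag=b"r"):
    payload = b"".join(
        b"@%s.%d\nACGT\n+\nIIII\n" % (tag, i) for i in range(n_records)
    )
    return gzip.compress(payload, mtime=0)


def write_files(tmp_path, names, n_records=4):
    d = tmp_path / "raw"
    d.mkdir(exist_ok=True)
    for name in names:
        (d / name).write_bytes(fastq_gz(n_records, tag=name.encode()))
    return d


def ena_rows(rows):
    records = []
    for rec in rows:
        base = {c: None for c in ENA_REQUIRED_COLUMNS}
        base.update(rec)
        records.append(base)
    return MetadataTable.from_records(ENA_REQUIRED_COLUMNS, records, dialect=ENA_DIALECT)


class TestReadSideInference:
    @pytest.mark.parametrize(
        "name,side",
        [
            ("x_1.fastq.gz", "R1"),
            ("x_2.fq.gz", "R2"),
            ("x_R1.fastq", "R1"),
            ("x_R2.fastq.gz", "R2"),
            ("x.1.fq", "R1"),
            ("x.2.fastq.gz", "R2"),
            ("x.fastq.gz", None),
        ],
    )
    def test_inference(self, name, side):
        assert infer_read_side(name) == side

    def test_canonical_names(self):
        assert canonical_output("S", "R1") == "S_1.fastq.gz"
        assert canonical_output("S", "R2") == "S_2.fastq.gz"
        assert canonical_output("S", "single") == "S.fastq.gz"


class TestMakeTemplate:
    def test_multirun_paired_sample_grouped_per_side(self, tmp_path):
        table = ena_rows(
            [
                {"run_accession": "ERR1", "sample_accession": "S",
                 "library_layout": "PAIRED",
                 "fastq_ftp": "h/ERR1_1.fastq.gz;h/ERR1_2.fastq.gz"},
                {"run_accession": "ERR2", "sample_accession": "S",
                 "library_layout": "PAIRED",
                 "fastq_ftp": "h/ERR2_1.fastq.gz;h/ERR2_2.fastq.gz"},
            ]
        )
        d = write_files(
            tmp_path,
            ["ERR1_1.fastq.gz", "ERR1_2.fastq.gz", "ERR2_1.fastq.gz", "ERR2_2.fastq.gz"],
        )
        template, report = make_treatment_template(table, DirectoryInventory.scan(d))
        merges = {r.read_side: r for r in template if r.operation == "merge"}
        assert set(merges) == {"R1", "R2"}
        assert merges["R1"].input_files == ("ERR1_1.fastq.gz", "ERR2_1.fastq.gz")
        assert merges["R1"].output_file == "S_1.fastq.gz"
        assert merges["R2"].input_files == ("ERR1_2.fastq.gz", "ERR2_2.fastq.gz")
        assert report.findings == []

    def test_canonical_single_becomes_copy(self, tmp_path):
        table = ena_rows(
            [{"run_accession": "ERR1", "sample_accession": "T",
              "library_layout": "SINGLE", "fastq_ftp": "h/T.fastq.gz"}]
        )
        d = write_files(tmp_path, ["T.fastq.gz"])
        template, _ = make_treatment_template(table, DirectoryInventory.scan(d))
        assert len(template) == 1
        row = template.rows[0]
        assert (row.operation, row.output_file) == ("copy", "T.fastq.gz")

    def test_noncanonical_single_becomes_rename(self, tmp_path):
        table = ena_rows(
            [{"run_accession": "ERR1", "sample_accession": "T",
              "library_layout": "SINGLE", "fastq_ftp": "h/ERR1.fastq.gz"}]
        )
        d = write_files(tmp_path, ["ERR1.fastq.gz"])
        template, _ = make_treatment_template(table, DirectoryInventory.scan(d))
        row = template.rows[0]
        assert (row.operation, row.output_file) == ("rename", "T.fastq.gz")

    def test_orphan_file_gets_blank_row_and_warning(self, tmp_path):
        table = ena_rows(
            [{"run_accession": "ERR1", "sample_accession": "T",
              "library_layout": "SINGLE", "fastq_ftp": "h/ERR1.fastq.gz"}]
        )
        d = write_files(tmp_path, ["ERR1.fastq.gz", "x.fq.gz"])
        template, report = make_treatment_template(table, DirectoryInventory.scan(d))
        orphans = [r for r in template if r.sample_name == ""]
        assert len(orphans) == 1 and orphans[0].input_files == ("x.fq.gz",)
        assert report.codes == ["UNOWNED_FILE"]

    def test_mixed_layout_sample_left_blank(self, tmp_path):
        table = ena_rows(
            [
                {"run_accession": "ERR1", "sample_accession": "S",
                 "library_layout": "PAIRED",
                 "fastq_ftp": "h/ERR1_1.fastq.gz;h/ERR1_2.fastq.gz"},
                {"run_accession": "ERR2", "sample_accession": "S",
                 "library_layout": "SINGLE", "fastq_ftp": "h/ERR2.fastq.gz"},
            ]
        )
        d = write_files(
            tmp_path, ["ERR1_1.fastq.gz", "ERR1_2.fastq.gz", "ERR2.fastq.gz"]
        )
        template, report = make_treatment_template(table, DirectoryInventory.scan(d))
        assert all(r.operation == "" for r in template)
        assert report.codes == ["MIXED_LAYOUT_SAMPLE"]

    def test_manifest_mode_groups_by_inferred_sides(self, tmp_path):
        manifest = ManifestTable.from_records(
            [
                {"fastq_file_name": "a_1.fq.gz", "sample_name": "S"},
                {"fastq_file_name": "a_2.fq.gz", "sample_name": "S"},
                {"fastq_file_name": "b_1.fq.gz", "sample_name": "S"},
                {"fastq_file_name": "b_2.fq.gz", "sample_name": "S"},
            ]
        )
        d = write_files(tmp_path, ["a_1.fq.gz", "a_2.fq.gz", "b_1.fq.gz", "b_2.fq.gz"])
        template, _ = make_treatment_template(manifest, DirectoryInventory.scan(d))
        merges = {r.read_side: r.input_files for r in template if r.operation == "merge"}
        assert merges == {
            "R1": ("a_1.fq.gz", "b_1.fq.gz"),
            "R2": ("a_2.fq.gz", "b_2.fq.gz"),
        }


class TestValidateTemplate:
    def _inventory(self, tmp_path, names):
        return DirectoryInventory.scan(write_files(tmp_path, names))

    def test_valid_template_is_empty_list(self, tmp_path):
        inv = self._inventory(tmp_path, ["a_1.fq.gz", "b_1.fq.gz"])
        template = TreatmentTemplate(
            [TreatmentRow("S", "merge", ("a_1.fq.gz", "b_1.fq.gz"), "R1", "S_1.fastq.gz")]
        )
        assert validate_treatment_template(template, inv) == []

    def test_unknown_input(self, tmp_path):
        inv = self._inventory(tmp_path, ["a.fq.gz"])
        template = TreatmentTemplate(
            [TreatmentRow("S", "rename", ("ghost.fq.gz",), "single", "S.fastq.gz")]
        )
        codes = [f.code for f in validate_treatment_template(template, inv)]
        assert codes == ["TEMPLATE_UNKNOWN_INPUT"]

    def test_duplicate_input_across_rows(self, tmp_path):
        inv = self._inventory(tmp_path, ["a.fq.gz"])
        template = TreatmentTemplate(
            [
                TreatmentRow("S", "rename", ("a.fq.gz",), "single", "S.fastq.gz"),
                TreatmentRow("T", "rename", ("a.fq.gz",), "single", "T.fastq.gz"),
            ]
        )
        codes = [f.code for f in validate_treatment_template(template, inv)]
        assert codes == ["TEMPLATE_DUPLICATE_INPUT"]

    def test_duplicate_output_and_bad_arity(self, tmp_path):
        inv = self._inventory(tmp_path, ["a.fq.gz", "b.fq.gz"])
        template = TreatmentTemplate(
            [
                TreatmentRow("S", "merge", ("a.fq.gz",), "single", "S.fastq.gz"),
                TreatmentRow("S", "rename", ("b.fq.gz",), "single", "S.fastq.gz"),
            ]
        )
        codes = {f.code for f in validate_treatment_template(template, inv)}
        assert codes == {"TEMPLATE_BAD_ARITY", "TEMPLATE_DUPLICATE_OUTPUT"}

    def test_blank_operation_flagged(self, tmp_path):
        inv = self._inventory(tmp_path, ["a.fq.gz"])
        template = TreatmentTemplate([TreatmentRow("", "", ("a.fq.gz",), "", "")])
        codes = [f.code for f in validate_treatment_template(template, inv)]
        assert codes == ["TEMPLATE_BLANK_FIELD"]

    def test_mixed_single_and_paired_sides_flagged(self, tmp_path):
        inv = self._inventory(tmp_path, ["a_1.fq.gz", "b.fq.gz"])
        template = TreatmentTemplate(
            [
                TreatmentRow("S", "rename", ("a_1.fq.gz",), "R1", "S_1.fastq.gz"),
                TreatmentRow("S", "rename", ("b.fq.gz",), "single", "S.fastq.gz"),
            ]
        )
        codes = [f.code for f in validate_treatment_template(template, inv)]
        assert codes == ["TEMPLATE_READSIDE_INCONSISTENT"]


class TestTreatFastqs:
    def test_merge_concatenates_gzip_members(self, tmp_path):
        d = tmp_path / "raw"
        d.mkdir()
        (d / "a.fastq.gz").write_bytes(fastq_gz(4, tag=b"a"))
        (d / "b.fastq.gz").write_bytes(fastq_gz(6, tag=b"b"))
        template = TreatmentTemplate(
            [TreatmentRow("S", "merge", ("a.fastq.gz", "b.fastq.gz"), "single",
                          "S.fastq.gz")]
        )
        out = tmp_path / "out"
        treat_fastqs(template, d, out)
        text = gzip.open(out / "S.fastq.gz", "rt").read().splitlines()
        assert len(text) == 40  # 10 records x 4 lines
        first_input = gzip.open(d / "a.fastq.gz", "rt").read().splitlines()
        assert text[:16] == first_input

    def test_copy_preserves_md5(self, tmp_path):
        d = write_files(tmp_path, ["S.fastq.gz"])
        template = TreatmentTemplate(
            [TreatmentRow("S", "copy", ("S.fastq.gz",), "single", "S.fastq.gz")]
        )
        out = tmp_path / "out"
        treat_fastqs(template, d, out)
        assert md5_of_file(out / "S.fastq.gz") == md5_of_file(d / "S.fastq.gz")

    def test_rename_preserves_bytes(self, tmp_path):
        d = write_files(tmp_path, ["r1_1.fastq.gz"])
        template = TreatmentTemplate(
            [TreatmentRow("S", "rename", ("r1_1.fastq.gz",), "R1", "S_1.fastq.gz")]
        )
        out = tmp_path / "out"
        treat_fastqs(template, d, out)
        assert (out / "S_1.fastq.gz").read_bytes() == (d / "r1_1.fastq.gz").read_bytes()

    def test_existing_output_rejected_without_overwrite(self, tmp_path):
        d = write_files(tmp_path, ["S.fastq.gz"])
        template = TreatmentTemplate(
            [TreatmentRow("S", "copy", ("S.fastq.gz",), "single", "S.fastq.gz")]
        )
        out = tmp_path / "out"
        treat_fastqs(template, d, out)
        with pytest.raises(TreatmentError, match="exist"):
            treat_fastqs(template, d, out)
        # overwrite reproduces byte-identical output (idempotence)
        before = (out / "S.fastq.gz").read_bytes()
        treat_fastqs(template, d, out, overwrite=True)
        assert (out / "S.fastq.gz").read_bytes() == before

    def test_same_in_out_dir_rejected(self, tmp_path):
        d = write_files(tmp_path, ["S.fastq.gz"])
        template = TreatmentTemplate(
            [TreatmentRow("S", "copy", ("S.fastq.gz",), "single", "S.fastq.gz")]
        )
        with pytest.raises(TreatmentError, match="distinct"):
            treat_fastqs(template, d, d)

    def test_invalid_template_rejected(self, tmp_path):
        d = write_files(tmp_path, ["a.fq.gz"])
        template = TreatmentTemplate(
            [TreatmentRow("S", "rename", ("ghost.fq.gz",), "single", "S.fastq.gz")]
        )
        with pytest.raises(TreatmentError, match="TEMPLATE_UNKNOWN_INPUT"):
            treat_fastqs(template, d, tmp_path / "out")

    def test_inputs_never_modified_and_bijection(self, dataset, tmp_path):
        inv = dataset.inventory()
        before = {f: md5_of_file(inv.path(f)) for f in inv.files}
        template, _ = make_treatment_template(dataset.metadata, inv)
        report = treat_fastqs(template, dataset.fastq_dir, tmp_path / "out")
        after = {f: md5_of_file(inv.path(f)) for f in inv.files}
        assert before == after
        # bijection: one record per template row, inputs consumed exactly once
        assert len(report.records) == len(template)
        consumed = [f for r in report.records for f in r.input_files]
        assert sorted(consumed) == sorted(set(consumed))


class TestTreatMetadata:
    def _table(self, rows):
        cols = ["run_accession", "sample_accession", "fastq_ftp", "host_age",
                "host_sex"]
        return MetadataTable.from_records(cols, rows)

    def _template(self, samples):
        return TreatmentTemplate(
            [
                TreatmentRow(s, "merge", (f"{s}_a.fq.gz", f"{s}_b.fq.gz"),
                             "single", f"{s}.fastq.gz")
                for s in samples
            ]
        )

    def test_agreeing_values_kept_without_warning(self):
        table = self._table(
            [
                ["r1", "S", "h/f1.fq.gz", "34", "male"],
                ["r2", "S", "h/f2.fq.gz", "34", "male"],
            ]
        )
        out, report = treat_metadata(self._template(["S"]), table)
        assert out.n_rows == 1
        assert out.df.loc[0, "host_age"] == "34"
        assert report.findings == []

    def test_conflicting_values_joined_with_warning(self):
        table = self._table(
            [
                ["r1", "S", "h/f1.fq.gz", "34", "male"],
                ["r2", "S", "h/f2.fq.gz", "34", "female"],
            ]
        )
        out, report = treat_metadata(self._template(["S"]), table)
        assert out.df.loc[0, "host_sex"] == "male;female"
        assert [f.code for f in report.findings] == ["SAMPLE_VALUE_CONFLICT"]
        assert report.findings[0].subjects == ("S", "host_sex")

    def test_run_specific_columns_aggregate_silently(self):
        table = self._table(
            [
                ["r1", "S", "h/f1.fq.gz", "34", "male"],
                ["r2", "S", "h/f2.fq.gz", "34", "male"],
            ]
        )
        out, report = treat_metadata(self._template(["S"]), table)
        assert out.df.loc[0, "run_accession"] == "r1;r2"
        assert out.df.loc[0, "fastq_ftp"] == "h/f1.fq.gz;h/f2.fq.gz"
        assert report.findings == []

    def test_missing_values_ignored_in_agreement(self):
        table = self._table(
            [
                ["r1", "S", None, "34", None],
                ["r2", "S", None, None, "male"],
            ]
        )
        out, report = treat_metadata(self._template(["S"]), table)
        assert out.df.loc[0, "host_age"] == "34"
        assert out.df.loc[0, "host_sex"] == "male"
        assert report.findings == []

    def test_template_sample_absent_from_metadata_is_error(self):
        table = self._table([["r1", "S", None, "34", "male"]])
        out, report = treat_metadata(self._template(["S", "GHOST"]), table)
        assert out.n_rows == 1
        assert [f.code for f in report.findings] == ["SAMPLE_NOT_IN_METADATA"]
        assert report.status == "error"

    def test_row_count_equals_distinct_template_samples(self, dataset):
        template, _ = make_treatment_template(dataset.metadata, dataset.inventory())
        out, _ = treat_metadata(template, dataset.metadata)
        assert out.n_rows == len(template.samples)


class TestTemplateFile:
    def test_roundtrip(self, tmp_path):
        template = TreatmentTemplate(
            [
                TreatmentRow("S", "merge", ("a.fq.gz", "b.fq.gz"), "R1", "S_1.fastq.gz"),
                TreatmentRow("", "", ("x.fq.gz",), "", ""),
            ]
        )
        path = tmp_path / "template.tsv"
        template.write(path)
        back = TreatmentTemplate.read(path)
        assert back.rows == template.rows
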