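"""Dictionary-driven validation and multi-dataset concatenation."""
import random

import pytest

from omdct.errors import ConcatError, FormatError, InputError
from omdct.model import MetadataTable
from omdct.validation import (
    VariableSpec,
    VariablesDictionary,
    check_metadata_values,
    check_variable,
    concat_datasets,
)


def table_of(columns, rows):
    return MetadataTable.from_records(columns, rows)


class TestCheckVariable:
    def test_required_absent_is_error_and_stops(self):
        spec = VariableSpec("age", "required", "numeric", "unique", "any")
        findings = check_variable(spec, table_of(["other"], [["x"]]))
        assert [(f.code, f.severity) for f in findings] == [
            ("VARIABLE_MISSING", "error")
        ]

    def test_optional_absent_is_info(self):
        spec = VariableSpec("age", "optional", "numeric", "nonunique", "any")
        findings = check_variable(spec, table_of(["other"], [["x"]]))
        assert [(f.code, f.severity) for f in findings] == [
            ("VARIABLE_OPTIONAL_ABSENT", "info")
        ]

    def test_numeric_class_lists_offending_cells(self):
        spec = VariableSpec("age", "optional", "numeric", "nonunique", "any")
        findings = check_variable(
            spec, table_of(["age"], [["12"], ["twelve"], [None], ["13.5"]])
        )
        assert [f.code for f in findings] == ["VARIABLE_NOT_NUMERIC"]
        assert "twelve" in findings[0].subjects

    def test_character_accepts_strings_and_boolean_tokens(self):
        spec = VariableSpec("flag", "optional", "character", "nonunique", "any")
        table = table_of(["flag"], [["true"], ["FALSE"], ["hello"], [None]])
        assert check_variable(spec, table) == []

    def test_uniqueness_lists_duplicates(self):
        spec = VariableSpec("id", "optional", "character", "unique", "any")
        findings = check_variable(
            spec, table_of(["id"], [["a"], ["b"], ["a"], [None], [None]])
        )
        assert [f.code for f in findings] == ["VARIABLE_NOT_UNIQUE"]
        assert "a" in findings[0].subjects and "b" not in findings[0].subjects

    def test_subset_within_allowed_is_silent(self):
        spec = VariableSpec("g", "optional", "character", "nonunique", "subset",
                            allowed_values=("A", "B", "C"))
        assert check_variable(spec, table_of(["g"], [["A"], ["B"], [None]])) == []

    def test_subset_outlier_reported(self):
        spec = VariableSpec("g", "optional", "character", "nonunique", "subset",
                            allowed_values=("A", "B"))
        findings = check_variable(spec, table_of(["g"], [["A"], ["Z"]]))
        assert [f.code for f in findings] == ["VALUE_NOT_ALLOWED"]
        assert "Z" in findings[0].subjects

    def test_wholeset_reports_uncovered_values(self):
        spec = VariableSpec("g", "optional", "character", "nonunique", "wholeset",
                            allowed_values=("A", "B", "C"))
        findings = check_variable(spec, table_of(["g"], [["A"], ["B"]]))
        assert [f.code for f in findings] == ["VALUE_SET_MISMATCH"]
        assert "C" in findings[0].subjects and "uncovered: C" in findings[0].message

    def test_wholeset_exact_cover_is_silent(self):
        spec = VariableSpec("g", "optional", "character", "nonunique", "wholeset",
                            allowed_values=("A", "B"))
        assert check_variable(spec, table_of(["g"], [["A"], ["B"], ["A"]])) == []

    def test_range_inclusive_bounds(self):
        spec = VariableSpec("age", "optional", "numeric", "nonunique", "range",
                            value_range=(0.0, 120.0))
        assert check_variable(spec, table_of(["age"], [["0"], ["120"], [None]])) == []
        findings = check_variable(spec, table_of(["age"], [["134"]]))
        assert [f.code for f in findings] == ["VALUE_OUT_OF_RANGE"]
        assert "134" in findings[0].subjects

    def test_crosscheck_symmetric_multimatch(self):
        spec = VariableSpec("subject", "optional", "character", "nonunique", "any",
                            crosscheck_variables=("sample",))
        table = table_of(
            ["subject", "sample"],
            [["P1", "S1"], ["P1", "S2"], ["P2", "S3"]],
        )
        findings = check_variable(spec, table)
        assert [f.code for f in findings] == ["VARIABLE_MULTIMATCH"]
        assert findings[0].subjects[:2] == ("subject", "sample")
        assert "P1" in findings[0].subjects

    def test_check_order_presence_class_uniqueness_crosscheck_allowed(self):
        spec = VariableSpec("v", "required", "numeric", "unique", "range",
                            value_range=(0.0, 10.0),
                            crosscheck_variables=("w",))
        table = table_of(
            ["v", "w"],
            [["99", "a"], ["99", "b"], ["nope", "c"]],
        )
        codes = [f.code for f in check_variable(spec, table)]
        assert codes == [
            "VARIABLE_NOT_NUMERIC",
            "VARIABLE_NOT_UNIQUE",
            "VARIABLE_MULTIMATCH",
            "VALUE_OUT_OF_RANGE",
        ]

    def test_allowed_analysis_oracle_random(self):
        """subset/wholeset/range agree with set/interval oracles."""
        rng = random.Random(5)
        pool = ["A", "B", "C", "D", "E"]
        for _ in range(40):
            observed = [rng.choice(pool + [None]) for _ in range(rng.randint(0, 12))]
            allowed = tuple(sorted(rng.sample(pool, rng.randint(1, 5))))
            table = table_of(["g"], [[v] for v in observed])
            present = {v for v in observed if v is not None}
            sub = check_variable(
                VariableSpec("g", "optional", "character", "nonunique", "subset",
                             allowed_values=allowed), table)
            assert (sub == []) == (present <= set(allowed))
            whole = check_variable(
                VariableSpec("g", "optional", "character", "nonunique", "wholeset",
                             allowed_values=allowed), table)
            assert (whole == []) == (present == set(allowed))
            numbers = [str(rng.randint(-5, 15)) for _ in range(rng.randint(0, 10))]
            lo, hi = sorted(rng.sample(range(-5, 16), 2))
            rng_spec = VariableSpec("n", "optional", "numeric", "nonunique", "range",
                                    value_range=(float(lo), float(hi)))
            in_range = all(lo <= int(x) <= hi for x in numbers)
            assert (
                check_variable(rng_spec, table_of(["n"], [[x] for x in numbers])) == []
            ) == in_range


class TestSpecInvariants:
    def test_range_requires_numeric_class(self):
        with pytest.raises(FormatError):
            VariableSpec("v", "optional", "character", "nonunique", "range",
                         value_range=(0.0, 1.0))

    def test_any_takes_no_values(self):
        with pytest.raises(FormatError):
            VariableSpec("v", "optional", "character", "nonunique", "any",
                         allowed_values=("x",))

    def test_dictionary_rejects_duplicate_names(self):
        with pytest.raises(FormatError):
            VariablesDictionary(
                [VariableSpec("v", "optional", "character", "nonunique", "any")] * 2
            )

    def test_dictionary_rejects_unresolvable_crosscheck(self):
        with pytest.raises(FormatError, match="ghost"):
            VariablesDictionary(
                [VariableSpec("v", "optional", "character", "nonunique", "any",
                              crosscheck_variables=("ghost",))]
            )

    def test_dictionary_file_roundtrip(self, tmp_path):
        dictionary = VariablesDictionary(
            [
                VariableSpec("id", "required", "character", "unique", "any"),
                VariableSpec("g", "optional", "character", "nonunique", "subset",
                             allowed_values=("A", "B"),
                             crosscheck_variables=("id",)),
                VariableSpec("age", "optional", "numeric", "nonunique", "range",
                             value_range=(0.0, 120.0)),
            ]
        )
        path = tmp_path / "dict.tsv"
        dictionary.write(path)
        back = VariablesDictionary.read(path)
        assert back.specs == dictionary.specs

    def test_malformed_range_bounds_rejected(self, tmp_path):
        path = tmp_path / "dict.tsv"
        path.write_text(
            "name\trequiredness\tclass\tuniqueness\tallowed_analysis\tallowed_values\tcrosscheck_variables\n"
            "age\toptional\tnumeric\tnonunique\trange\t0-120\t\n"
        )
        with pytest.raises(FormatError, match="range"):
            VariablesDictionary.read(path)


class TestCheckMetadataValues:
    def _dictionary(self):
        return VariablesDictionary(
            [
                VariableSpec("id", "required", "character", "unique", "any"),
                VariableSpec("age", "optional", "numeric", "nonunique", "range",
                             value_range=(0.0, 120.0)),
            ]
        )

    def test_exact_match_is_info_status(self):
        table = table_of(["id", "age"], [["a", "30"], ["b", "40"]])
        report = check_metadata_values(self._dictionary(), table)
        assert report.status == "info"
        assert report.findings == []

    def test_undeclared_column_is_info(self):
        table = table_of(["id", "age", "notes"], [["a", "30", "hello"]])
        report = check_metadata_values(self._dictionary(), table)
        assert report.codes == ["UNDECLARED_VARIABLE"]
        assert report.findings[0].subjects == ("notes",)

    def test_one_failing_spec_gives_error_status(self):
        table = table_of(["id", "age"], [["a", "200"]])
        report = check_metadata_values(self._dictionary(), table)
        assert report.status == "error"
        assert report.codes == ["VALUE_OUT_OF_RANGE"]


class TestConcatDatasets:
    def _dictionary(self):
        return VariablesDictionary(
            [
                VariableSpec("subject_id", "required", "character", "unique", "any"),
                VariableSpec("group", "optional", "character", "nonunique", "any"),
            ]
        )

    def test_row_count_additivity_and_origin_column(self):
        t1 = table_of(["subject_id", "group"], [["P1", "a"], ["P2", "a"]])
        t2 = table_of(["subject_id", "group"], [["P3", "b"], ["P4", "b"], ["P5", "b"]])
        combined, report = concat_datasets([t1, t2], self._dictionary(),
                                           dataset_names=["d1", "d2"])
        assert combined.n_rows == 5
        assert combined.columns == ["subject_id", "group", "dataset"]
        assert list(combined.column("dataset")) == ["d1", "d1", "d2", "d2", "d2"]
        assert report.findings == []

    def test_cross_dataset_duplicate_detected(self):
        t1 = table_of(["subject_id"], [["P01"], ["P02"]])
        t2 = table_of(["subject_id"], [["P01"], ["P03"]])
        combined, report = concat_datasets([t1, t2], self._dictionary())
        assert combined.n_rows == 4
        dup = [f for f in report.findings if f.code == "CROSS_DATASET_DUPLICATE"]
        assert len(dup) == 1
        assert "P01" in dup[0].subjects

    def test_optional_column_missing_filled(self):
        t1 = table_of(["subject_id", "group"], [["P1", "a"]])
        t2 = table_of(["subject_id"], [["P2"]])
        combined, _ = concat_datasets([t1, t2], self._dictionary())
        assert combined.df.loc[1, "group"] is None

    def test_failing_table_aborts_with_report(self):
        t1 = table_of(["subject_id"], [["P1"]])
        t2 = table_of(["other"], [["x"]])  # required subject_id absent
        with pytest.raises(ConcatError) as exc:
            concat_datasets([t1, t2], self._dictionary())
        assert exc.value.report is not None
        assert "VARIABLE_MISSING" in exc.value.report.codes

    def test_fewer_than_two_tables_rejected(self):
        with pytest.raises(InputError):
            concat_datasets([table_of(["subject_id"], [["P1"]])], self._dictionary())

    def test_validation_idempotence_on_concatenated_output(self):
        rng = random.Random(11)
        names = [f"P{i}" for i in range(20)]
        rng.shuffle(names)
        t1 = table_of(["subject_id", "group"], [[n, "a"] for n in names[:8]])
        t2 = table_of(["subject_id", "group"], [[n, "b"] for n in names[8:15]])
        combined, report = concat_datasets([t1, t2], self._dictionary())
        assert report.findings == []
        revalidated = check_metadata_values(self._dictionary(), combined)
        new_errors = [f for f in revalidated.findings if f.severity == "error"]
        assert new_errors == []
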