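import pytest
from pydantic import ValidationError

from dqaudit.model import (
    AnalysisPlan,
    CodebookSpec,
    ParseFlag,
    TabularDataset,
    VariableKind,
    VariableSpec,
    read_codebook,
    read_dataset,
    read_submission,
    write_codebook,
    write_dataset,
    write_plan,
    write_meta,
)
from conftest import META


def rich_codebook():
    variables = [
        VariableSpec(name=f"num{i}", kind=VariableKind.NUMERIC, plausible_range=(i, i + 10), label=f"var {i} (u)")
        for i in range(5)
    ] + [
        VariableSpec(name=f"code{i}", kind=VariableKind.CODED, code_domain={"1": "a", "2": "b, c and d"})
        for i in range(5)
    ] + [
        VariableSpec(name="when", kind=VariableKind.DATE, format_pattern="%Y-%m-%d"),
        VariableSpec(name="pid", kind=VariableKind.IDENTIFIER, required=False),
    ]
    return CodebookSpec(variables=variables, version="v2")


class TestVariableSpec:
    def test_coded_requires_code_domain(self):
        with pytest.raises(ValidationError, match="code_domain"):
            VariableSpec(name="sex", kind=VariableKind.CODED)

    def test_code_domain_forbidden_elsewhere(self):
        with pytest.raises(ValidationError, match="code_domain"):
            VariableSpec(name="age", kind=VariableKind.NUMERIC, code_domain={"1": "x"})

    def test_range_only_on_numeric_and_ordered(self):
        with pytest.raises(ValidationError, match="plausible_range"):
            VariableSpec(name="when", kind=VariableKind.DATE, plausible_range=(0, 1))
        with pytest.raises(ValidationError, match="min must be"):
            VariableSpec(name="age", kind=VariableKind.NUMERIC, plausible_range=(90, 18))


class TestCodebook:
    def test_requires_a_variable(self):
        with pytest.raises(ValidationError):
            CodebookSpec(variables=[])

    def test_names_unique_case_insensitive(self):
        v1 = VariableSpec(name="Age", kind=VariableKind.NUMERIC)
        v2 = VariableSpec(name="age", kind=VariableKind.NUMERIC)
        with pytest.raises(ValidationError, match="duplicate"):
            CodebookSpec(variables=[v1, v2])

    @pytest.mark.parametrize("suffix", [".json", ".csv"])
    def test_round_trip_is_identity(self, tmp_path, suffix):
        cb = rich_codebook()
        path = tmp_path / f"codebook{suffix}"
        write_codebook(cb, path)
        back = read_codebook(path)
        assert back.variables == cb.variables
        if suffix == ".json":  # the flat CSV dialect does not carry version text
            assert back == cb

    def test_single_variable_round_trip(self, tmp_path):
        cb = CodebookSpec(variables=[VariableSpec(name="x", kind=VariableKind.TEXT)])
        path = tmp_path / "cb.json"
        write_codebook(cb, path)
        assert read_codebook(path) == cb


class TestAnalysisPlan:
    def test_outcome_required(self):
        with pytest.raises(ValidationError):
            AnalysisPlan(outcome_variables=[])

    def test_lists_disjoint(self):
        with pytest.raises(ValidationError, match="overlap"):
            AnalysisPlan(outcome_variables=["y"], analytic_variables=["y", "x"])


class TestDatasetReader:
    def write(self, tmp_path, text):
        p = tmp_path / "d.csv"
        p.write_text(text, encoding="utf-8")
        return p

    def test_clean_csv_has_no_flags(self, tmp_path):
        ds = read_dataset(self.write(tmp_path, "a,b,c\n1,2,3\n4,5,6\n"))
        assert ds.parse_flags == set()
        assert ds.columns == ["a", "b", "c"]
        assert ds.rows == [["1", "2", "3"], ["4", "5", "6"]]

    @pytest.mark.parametrize(
        "text,flag",
        [
            ("a,a,b\n1,2,3\n", ParseFlag.DUPLICATE_COLUMN_NAMES),
            ("a,,b\n1,2,3\n", ParseFlag.BLANK_HEADER_CELLS),
            ("a,b\n1,2,3\n", ParseFlag.RAGGED_ROWS),
            ("a,b\n1,2\na,b\n3,4\n", ParseFlag.REPEATED_HEADER_ROWS),
            ("a,b\n1,2\n,\n3,4\n", ParseFlag.BLANK_ROW_BLOCKS),
        ],
    )
    def test_each_anomaly_is_flagged_not_repaired(self, tmp_path, text, flag):
        ds = read_dataset(self.write(tmp_path, text))
        assert flag in ds.parse_flags

    def test_trailing_blank_row_is_not_an_anomaly(self, tmp_path):
        ds = read_dataset(self.write(tmp_path, "a,b\n1,2\n,\n"))
        assert ds.parse_flags == set()

    def test_rectangular_round_trip(self, tmp_path):
        ds = TabularDataset(columns=["x", "y"], rows=[["1", "a b"], ['q"t', ""]])
        path = tmp_path / "rt.csv"
        write_dataset(ds, path)
        back = read_dataset(path)
        assert back.columns == ds.columns and back.rows == ds.rows
        assert back.parse_flags == set()

    def test_flagged_anomalies_survive_round_trip(self, tmp_path):
        ds = TabularDataset(
            columns=["x", "y"],
            rows=[["1", "2"], ["3", "4"]],
            parse_flags={ParseFlag.REPEATED_HEADER_ROWS, ParseFlag.BLANK_ROW_BLOCKS},
        )
        path = tmp_path / "rt.csv"
        write_dataset(ds, path)
        back = read_dataset(path)
        assert back.parse_flags == ds.parse_flags
        assert back.rows == ds.rows

    def test_ragged_without_flag_rejected(self):
        with pytest.raises(ValueError, match="RAGGED"):
            TabularDataset(columns=["a", "b"], rows=[["1"]])


class TestReadSubmission:
    def _write_parts(self, tmp_path):
        (tmp_path / "d.csv").write_text("age,outcome\n30,1\n", encoding="utf-8")
        write_plan(AnalysisPlan(outcome_variables=["outcome"]), tmp_path / "plan.json")
        write_meta(META, tmp_path / "meta.json")
        cb = CodebookSpec(
            variables=[
                VariableSpec(name="age", kind=VariableKind.NUMERIC),
                VariableSpec(name="outcome", kind=VariableKind.CODED, code_domain={"0": "n", "1": "y"}),
            ]
        )
        write_codebook(cb, tmp_path / "cb.json")

    def test_well_formed_submission(self, tmp_path):
        self._write_parts(tmp_path)
        sub = read_submission(
            tmp_path / "d.csv", tmp_path / "plan.json", tmp_path / "meta.json",
            codebook_path=tmp_path / "cb.json",
        )
        assert sub.dataset.parse_flags == set()
        assert sub.codebook is not None and sub.meta == META

    def test_absent_codebook_is_not_an_error(self, tmp_path):
        self._write_parts(tmp_path)
        sub = read_submission(
            tmp_path / "d.csv", tmp_path / "plan.json", tmp_path / "meta.json"
        )
        assert sub.codebook is None

    def test_missing_dataset_file_is_fatal(self, tmp_path):
        self._write_parts(tmp_path)
        with pytest.raises(OSError):
            read_submission(
                tmp_path / "nope.csv", tmp_path / "plan.json", tmp_path / "meta.json"
            )

    def test_malformed_codebook_names_offending_field(self, tmp_path):
        self._write_parts(tmp_path)
        (tmp_path / "bad.json").write_text(
            '{"variables": [{"name": "x", "kind": "no-such-kind"}]}', encoding="utf-8"
        )
        with pytest.raises(ValidationError, match="kind"):
            read_submission(
                tmp_path / "d.csv", tmp_path / "plan.json", tmp_path / "meta.json",
                codebook_path=tmp_path / "bad.json",
            )
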