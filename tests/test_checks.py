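import copy

import pytest

from dqaudit.checks import (
    CheckConfig,
    DefectItem,
    check_plan_variables,
    check_structural,
    check_values,
    run_checklist,
)
from dqaudit.model import (
    AnalysisPlan,
    CodebookSpec,
    ParseFlag,
    StudySubmission,
    TabularDataset,
    VariableKind,
    VariableSpec,
)
from dqaudit.synth import GeneratorConfig, InjectionSpec, generate_clean, inject_defects
from conftest import META


def small_submission(cells, codebook=True, plan=None):
    """One-variable-per-kind submission with a single data row per entry in
    ``cells`` (a dict variable -> list of raw cell texts)."""
    variables = [
        VariableSpec(name="sex", kind=VariableKind.CODED, code_domain={"1": "m", "2": "f"}),
        VariableSpec(name="sbp", kind=VariableKind.NUMERIC, plausible_range=(50, 260)),
        VariableSpec(name="when", kind=VariableKind.DATE, format_pattern="%Y-%m-%d"),
        VariableSpec(name="note", kind=VariableKind.TEXT, required=False),
    ]
    columns = list(cells)
    n = max(len(v) for v in cells.values())
    rows = [[cells[c][r] if r < len(cells[c]) else "x" for c in columns] for r in range(n)]
    return StudySubmission(
        dataset=TabularDataset(columns=columns, rows=rows),
        codebook=CodebookSpec(variables=[v for v in variables if v.name in columns]) if codebook else None,
        plan=plan or AnalysisPlan(outcome_variables=["sex"]),
        meta=META,
        submission_id="t",
    )


class TestCellClassification:
    @pytest.mark.parametrize(
        "variable,cell,expected",
        [
            ("sex", "male", DefectItem.UNCODED_VALUES),
            ("sex", "3", DefectItem.MISCODED_VALUES),
            ("sex", "2.0", None),  # numerically equal to a permitted code
            ("sbp", "120/80", DefectItem.EMBEDDED_VALUES),
            ("sbp", "45 kg", DefectItem.EMBEDDED_VALUES),
            ("sbp", "100-120", DefectItem.EMBEDDED_VALUES),
            ("sbp", "350", DefectItem.IMPLAUSIBLE_VALUES),
            ("sbp", " 120 ", DefectItem.UNFORMATTED_VALUES),
            ("sbp", "abc", DefectItem.UNFORMATTED_VALUES),
            ("sbp", "120", None),
            ("when", "31-12-2020", DefectItem.UNFORMATTED_VALUES),
            ("when", "2020-12-31", None),
            ("sex", "", DefectItem.MISSING_VALUES),
            ("sex", "NA", DefectItem.MISSING_VALUES),
            ("note", "", None),  # not required: missing is tolerated
        ],
    )
    def test_single_cell(self, variable, cell, expected):
        sub = small_submission({variable: [cell], "sex": [cell] if variable == "sex" else ["1"]})
        findings = check_values(sub)
        items = {f.item for f in findings}
        if expected is None:
            assert items == set()
        else:
            assert items == {expected}
            (finding,) = findings
            assert finding.variable == variable and finding.row_index == 0

    def test_each_cell_yields_at_most_one_item(self):
        # "2600/2600" is embedded AND each part implausible: embedded wins
        sub = small_submission({"sex": ["1"], "sbp": ["2600/2600"]})
        findings = check_values(sub)
        assert [f.item for f in findings] == [DefectItem.EMBEDDED_VALUES]

    def test_missing_outranks_sentinel_lookalikes(self):
        cfg = CheckConfig(missing_sentinels=("", "-9"))
        sub = small_submission({"sex": ["1"], "sbp": ["-9"]})
        assert {f.item for f in check_values(sub, cfg)} == {DefectItem.MISSING_VALUES}

    def test_requires_codebook(self):
        sub = small_submission({"sex": ["1"]}, codebook=False)
        with pytest.raises(ValueError, match="check_structural"):
            check_values(sub)


class TestStructural:
    def test_absent_codebook_is_the_only_finding(self):
        sub = small_submission({"sex": ["1"], "sbp": ["120"]}, codebook=False)
        findings = check_structural(sub)
        assert [f.item for f in findings] == [DefectItem.MISSING_CODEBOOK]

    def test_undocumented_column_names_the_column(self):
        sub = small_submission({"sex": ["1"]})
        sub.dataset.columns.append("bmi")
        for row in sub.dataset.rows:
            row.append("22")
        findings = check_structural(sub)
        assert [f.item for f in findings] == [DefectItem.CODEBOOK_INCONSISTENCY]
        assert findings[0].variable == "bmi"

    def test_required_variable_without_column(self):
        sub = small_submission({"sex": ["1"], "sbp": ["120"]})
        sub.codebook.variables.append(
            VariableSpec(name="ghost", kind=VariableKind.NUMERIC)
        )
        items = [f.item for f in check_structural(sub)]
        assert items == [DefectItem.CODEBOOK_INCONSISTENCY]

    def test_disjoint_code_values_flagged(self):
        sub = small_submission({"sex": ["9", "8"], "sbp": ["120", "130"]})
        items = [f.item for f in check_structural(sub)]
        assert items == [DefectItem.CODEBOOK_INCONSISTENCY]

    def test_overlapping_code_values_not_flagged(self):
        sub = small_submission({"sex": ["1", "9"], "sbp": ["120", "130"]})
        assert check_structural(sub) == []

    @pytest.mark.parametrize(
        "flag,item",
        [
            (ParseFlag.RAGGED_ROWS, DefectItem.INACCURATE_FORMAT),
            (ParseFlag.DUPLICATE_COLUMN_NAMES, DefectItem.INACCURATE_FORMAT),
            (ParseFlag.BLANK_HEADER_CELLS, DefectItem.INACCURATE_FORMAT),
            (ParseFlag.REPEATED_HEADER_ROWS, DefectItem.UNANALYZABLE_STRUCTURE),
            (ParseFlag.BLANK_ROW_BLOCKS, DefectItem.UNANALYZABLE_STRUCTURE),
        ],
    )
    def test_parse_flags_map_to_items(self, flag, item):
        sub = small_submission({"sex": ["1"]})
        sub.dataset.parse_flags.add(flag)
        assert item in {f.item for f in check_structural(sub)}

    def test_multi_point_without_identifier_is_unanalyzable(self, clean_multi_submission):
        sub = copy.deepcopy(clean_multi_submission)
        # strip identifiers: no identifier variable, first column not unique
        sub.codebook.variables = [
            v for v in sub.codebook.variables if v.kind is not VariableKind.IDENTIFIER
        ]
        for name in ("record_id", "subject_id"):
            idx = sub.dataset.column_index(name)
            sub.dataset.columns.pop(idx)
            for row in sub.dataset.rows:
                row.pop(idx)
        items = {f.item for f in check_structural(sub)}
        assert DefectItem.UNANALYZABLE_STRUCTURE in items


class TestPlanVariables:
    def test_missing_outcome(self):
        plan = AnalysisPlan(outcome_variables=["mortality"], analytic_variables=[])
        sub = small_submission({"sex": ["1"]}, plan=plan)
        findings = check_plan_variables(sub)
        assert [f.item for f in findings] == [DefectItem.MISSING_OUTCOME_VARS]
        assert findings[0].variable == "mortality"

    def test_one_finding_per_missing_analytic_name(self):
        plan = AnalysisPlan(outcome_variables=["sex"], analytic_variables=["a1", "a2"])
        sub = small_submission({"sex": ["1"]}, plan=plan)
        findings = check_plan_variables(sub)
        assert [f.item for f in findings] == [DefectItem.MISSING_ANALYTIC_VARS] * 2

    def test_all_present_is_silent(self):
        plan = AnalysisPlan(outcome_variables=["sex"], analytic_variables=["sbp"])
        sub = small_submission({"sex": ["1"], "sbp": ["120"]}, plan=plan)
        assert check_plan_variables(sub) == []


class TestRunChecklist:
    def test_clean_submission_scores_zero(self, clean_submission):
        profile = run_checklist(clean_submission)
        assert profile.score == 0 and profile.present_items == frozenset()

    def test_item_counted_once_regardless_of_cell_count(self, clean_submission):
        sub = copy.deepcopy(clean_submission)
        idx = sub.dataset.column_index("sex")
        sub.dataset.rows[0][idx] = "1"  # keep one valid code
        for row in sub.dataset.rows[1:]:  # miscode every other row
            row[idx] = "9"
        profile = run_checklist(sub)
        assert profile.present_items == {DefectItem.MISCODED_VALUES}
        assert profile.score == 1
        assert len(profile.findings) == sub.dataset.n_rows - 1

    def test_score_equals_distinct_item_count(self, clean_submission):
        items = frozenset(
            {
                DefectItem.MISSING_VALUES,
                DefectItem.UNCODED_VALUES,
                DefectItem.EMBEDDED_VALUES,
                DefectItem.IMPLAUSIBLE_VALUES,
                DefectItem.UNFORMATTED_VALUES,
            }
        )
        mutated, truth = inject_defects(clean_submission, InjectionSpec(items=items, seed=1))
        profile = run_checklist(mutated)
        assert profile.present_items == truth
        assert profile.score == 5

    def test_profile_invariants_and_idempotence(self, clean_submission):
        mutated, _ = inject_defects(
            clean_submission,
            InjectionSpec(items=frozenset({DefectItem.MISSING_CODEBOOK}), seed=0),
        )
        p1, p2 = run_checklist(mutated), run_checklist(mutated)
        assert p1 == p2
        assert p1.present_items == {f.item for f in p1.findings}
        assert 0 <= p1.score <= 12

    def test_monotone_in_injected_items(self):
        items = [
            DefectItem.MISSING_VALUES,
            DefectItem.UNCODED_VALUES,
            DefectItem.MISCODED_VALUES,
            DefectItem.EMBEDDED_VALUES,
            DefectItem.IMPLAUSIBLE_VALUES,
            DefectItem.UNFORMATTED_VALUES,
            DefectItem.CODEBOOK_INCONSISTENCY,
            DefectItem.INACCURATE_FORMAT,
            DefectItem.UNANALYZABLE_STRUCTURE,
        ]
        previous = -1
        for k in range(len(items) + 1):
            clean = generate_clean(GeneratorConfig(seed=5))
            mutated, _ = inject_defects(
                clean, InjectionSpec(items=frozenset(items[:k]), seed=2)
            )
            score = run_checklist(mutated).score
            assert score >= previous
            previous = score
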