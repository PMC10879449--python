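"""Cohort aggregation: analyzable Ns, percentage rounding, Cohen's kappa."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dyadsync.dsem import SynchronyCall
from dyadsync.errors import UndefinedKappaError
from dyadsync.summary import (
    analyzable_counts,
    build_agreement_table,
    cohens_kappa,
    round_percentage,
    synchrony_percentages,
)


def call(dyad, task="conflict", pd="null", cd="null"):
    return SynchronyCall(dyad_id=dyad, task=task, parent_driven=pd, child_driven=cd)


def manifest_rows(n=28, unusable_t1=(), absent_t2=()):
    rows = []
    for i in range(1, n + 1):
        d = f"dyad{i:03d}"
        rows.append({"dyad_id": d, "task": "conflict", "usable": d not in unusable_t1})
        if d not in absent_t2:
            rows.append({"dyad_id": d, "task": "planning", "usable": True})
    return rows


class TestAnalyzableCounts:
    def test_study_exclusion_arithmetic(self):
        # 28 enrolled; 2 no usable data in task 1; 1 further dyad absent task 2
        counts = analyzable_counts(
            manifest_rows(unusable_t1=("dyad001", "dyad002"), absent_t2=("dyad003",))
        )
        assert counts.as_tuple("conflict", "planning") == (26, 27, 25)

    def test_all_usable(self):
        counts = analyzable_counts(manifest_rows(n=10))
        assert counts.as_tuple("conflict", "planning") == (10, 10, 10)

    def test_disjoint_unusable_sets_intersect(self):
        counts = analyzable_counts(
            manifest_rows(n=20, unusable_t1=("dyad001", "dyad002", "dyad003"),
                          absent_t2=("dyad010", "dyad011"))
        )
        assert counts.n_both == 20 - 3 - 2


class TestSynchronyPercentages:
    def test_printed_count_percentage_pairs(self):
        # the reporting convention: one decimal, half away from zero
        assert round_percentage(100 * 9 / 26) == 34.6
        assert round_percentage(100 * 10 / 26) == 38.5
        calls = [call(f"d{i}", cd="positive") for i in range(9)] + [
            call(f"e{i}") for i in range(17)
        ]
        table = synchrony_percentages(calls, denominator=26)
        row = table[(table.direction == "child_driven") & (table.sign == "positive")]
        assert row["count"].item() == 9
        assert row["percentage"].item() == 34.6

    def test_zero_count(self):
        table = synchrony_percentages([call("d1")], denominator=26)
        row = table[(table.direction == "parent_driven") & (table.sign == "positive")]
        assert row["percentage"].item() == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            synchrony_percentages([], denominator=0)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.sampled_from(["positive", "negative", "null"]),
                    min_size=1, max_size=40))
    def test_percentages_sum_to_100_within_rounding(self, signs):
        calls = [call(f"d{i}", cd=s) for i, s in enumerate(signs)]
        table = synchrony_percentages(calls, denominator=len(calls))
        total = table[table.direction == "child_driven"]["percentage"].sum()
        assert abs(total - 100.0) <= 0.15  # three roundings of half a unit


class TestCohensKappa:
    def test_perfect_agreement(self):
        res = cohens_kappa([1, 0, 1, 0, 1], [1, 0, 1, 0, 1])
        assert res.kappa == 1.0

    def test_hand_computed_two_by_two_table(self):
        # both-yes 5, x-only 5, y-only 5, both-no 10:
        # p_o = 15/25 = 0.6, p_e = 0.4*0.4 + 0.6*0.6 = 0.52, kappa = 1/6
        x = [1] * 10 + [0] * 15
        y = [1] * 5 + [0] * 5 + [1] * 5 + [0] * 10
        res = cohens_kappa(x, y)
        assert res.kappa == pytest.approx(1.0 / 6.0)

    def test_complete_disagreement_symmetric_marginals(self):
        res = cohens_kappa([1] * 5 + [0] * 5, [0] * 5 + [1] * 5)
        assert res.kappa == -1.0

    def test_undefined_when_chance_agreement_is_one(self):
        with pytest.raises(UndefinedKappaError):
            cohens_kappa([1, 1, 1], [1, 1, 1])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=4, max_size=40))
    def test_invariant_to_swapping_category_labels(self, pairs):
        x = [a for a, _ in pairs]
        y = [b for _, b in pairs]
        try:
            direct = cohens_kappa(x, y)
        except UndefinedKappaError:
            with pytest.raises(UndefinedKappaError):
                cohens_kappa([not a for a in x], [not b for b in y])
            return
        swapped = cohens_kappa([not a for a in x], [not b for b in y])
        assert direct.kappa == pytest.approx(swapped.kappa)

    def test_zero_in_expectation_under_independence(self):
        # permutation oracle: shuffling one vector kills the association
        rng = np.random.default_rng(0)
        x = rng.random(40) < 0.4
        kappas = []
        for _ in range(300):
            y = rng.permutation(x)
            try:
                kappas.append(cohens_kappa(x, y).kappa)
            except UndefinedKappaError:
                pass
        assert abs(np.mean(kappas)) < 0.05


class TestBuildAgreementTable:
    def test_identical_calls_give_unit_kappas(self):
        signs = ["positive", "negative", "null"]
        calls1 = [call(f"d{i}", "conflict", pd=signs[i % 3], cd=signs[(i + 1) % 3])
                  for i in range(12)]
        calls2 = [SynchronyCall(c.dyad_id, "planning", c.parent_driven, c.child_driven)
                  for c in calls1]
        table = build_agreement_table(calls1, calls2)
        assert table.n_both == 12
        assert np.allclose(table.rows["kappa"], 1.0)

    def test_independent_calls_give_near_zero_kappas(self):
        rng = np.random.default_rng(5)
        signs = ["positive", "negative", "null"]
        calls1 = [call(f"d{i}", "conflict", pd=rng.choice(signs), cd=rng.choice(signs))
                  for i in range(200)]
        calls2 = [call(f"d{i}", "planning", pd=rng.choice(signs), cd=rng.choice(signs))
                  for i in range(200)]
        table = build_agreement_table(calls1, calls2)
        assert np.all(np.abs(table.rows["kappa"]) < 0.15)

    def test_reproduces_reported_marginal_percentages(self):
        # task-1 9/26 positive child-driven, task-2 7/27 -> 34.6% and 25.9%
        calls1 = [call(f"d{i:02d}", "conflict", cd="positive" if i < 9 else "null")
                  for i in range(26)]
        calls2 = [call(f"d{i:02d}", "planning", cd="positive" if i < 7 else "null")
                  for i in range(27)]
        table = build_agreement_table(calls1, calls2)
        row = table.rows[(table.rows.direction == "child_driven")
                         & (table.rows.sign == "positive")]
        assert row["pct_task1"].item() == 34.6
        assert row["pct_task2"].item() == 25.9
        assert table.n_both == 26

    def test_undefined_kappa_flagged_not_raised(self):
        calls1 = [call(f"d{i}", "conflict", pd="positive") for i in range(6)]
        calls2 = [call(f"d{i}", "planning", pd="positive") for i in range(6)]
        table = build_agreement_table(calls1, calls2)
        row = table.rows[(table.rows.direction == "parent_driven")
                         & (table.rows.sign == "positive")]
        assert not row["kappa_defined"].item()
        assert np.isnan(row["kappa"].item())
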