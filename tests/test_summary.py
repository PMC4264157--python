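from fractions import Fraction
from math import factorial

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from vtmap3d import (
    blocked_categories,
    chi_square_2x2,
    control_records,
    fisher_exact_two_tailed,
    load_study_fixture,
    reproducible_categories,
    summarize_group,
)
from vtmap3d.errors import InvalidArgumentError, UndefinedTestError
from vtmap3d.fixtures import InductionOutcome, InductionRecord
from vtmap3d.summary import GroupSummary, proarrhythmia_tally


def _record(dog, group, *inds):
    outs = []
    for spec in inds:
        if spec in ("NI", "nd"):
            outs.append(InductionOutcome(spec, frozenset()))
        else:
            etype, mechs = spec.split(":")
            outs.append(InductionOutcome(etype, frozenset(mechs.split(";"))))
    return InductionRecord(dog, group, group if group != "CONTROL" else "APO", tuple(outs))


def _dog(group, dog_id):
    return next(r for r in load_study_fixture(group) if r.dog_id == dog_id)


class TestReproducibility:
    def test_both_categories_reproducible(self):
        assert reproducible_categories(_dog("APO", "A4")) == {"focal", "reentry"}

    def test_reentry_labels_pool(self):
        # R at baseline I and RE at II are the same category
        assert reproducible_categories(_dog("OXY", "O9")) == {"reentry"}

    def test_not_inducible_baseline(self):
        rec = _record("X", "APO", "NI", "VT:EFo", "NI", "NI")
        assert reproducible_categories(rec) == set()

    def test_category_present_only_once_not_reproducible(self):
        # A3: RE at I only -> reentry not reproducible
        assert reproducible_categories(_dog("APO", "A3")) == {"focal"}


class TestBlocking:
    def test_focal_blocked_after_double_ni(self):
        assert blocked_categories(_dog("APO", "A1")) == {"focal"}

    def test_block_assessed_at_final_completed_induction(self):
        # B8: still inducible at III, NI at IV -> reentry blocked
        assert blocked_categories(_dog("BOTH", "B8")) == {"reentry"}
        # A10: VT EFo at III, NI at IV -> focal blocked
        assert blocked_categories(_dog("APO", "A10")) == {"focal"}

    def test_partial_block(self):
        # O1: focal persists at the final induction, reentry gone
        assert blocked_categories(_dog("OXY", "O1")) == {"reentry"}

    def test_nonsustained_counts_as_absence(self):
        # A8: VT ns at III and IV -> focal blocked
        assert blocked_categories(_dog("APO", "A8")) == {"focal"}

    def test_control_c23_blocked(self):
        assert blocked_categories(_dog("CONTROL", "C23")) == {"reentry"}

    def test_no_completed_post_treatment_indeterminate(self):
        rec = _record("X", "APO", "VT:EFo", "VT:EFo", "nd", "nd")
        with pytest.raises(InvalidArgumentError):
            blocked_categories(rec)


class TestGroupSummaries:
    @pytest.mark.parametrize(
        "group,focal,reentry,total,n",
        [
            ("APO", 6, 2, 6, 10),
            ("OXY", 2, 3, 4, 9),
            ("BOTH", 3, 2, 5, 8),
            ("CONTROL", 0, 1, 1, 27),
        ],
    )
    def test_printed_group_counts(self, group, focal, reentry, total, n):
        s = summarize_group(load_study_fixture(group))
        assert (s.focal_blocked, s.reentry_blocked, s.total_blocked, s.n) == (
            focal, reentry, total, n,
        )

    def test_treated_totals(self):
        treated = [summarize_group(load_study_fixture(g)) for g in ("APO", "OXY", "BOTH")]
        assert sum(s.total_blocked for s in treated) == 15
        assert sum(s.focal_blocked for s in treated) == 11
        assert sum(s.reentry_blocked for s in treated) == 7

    def test_pooled_focal_fraction(self):
        # counting the blocked control too: 11 of 16 blocked experiments focal
        records = [r for g in ("APO", "OXY", "BOTH", "CONTROL") for r in load_study_fixture(g)]
        blocked = [blocked_categories(r) for r in records]
        blocked = [b for b in blocked if b]
        assert len(blocked) == 16
        assert sum("focal" in b for b in blocked) == 11

    def test_concurrent_control_totals(self):
        for cohort, n in (("APO", 10), ("OXY", 9), ("BOTH", 8)):
            s = summarize_group(control_records(cohort))
            assert s.n == n
            assert s.total_blocked == (1 if cohort == "BOTH" else 0)

    def test_all_ni_synthetic_group(self):
        recs = [
            _record(f"X{i}", "APO", "NI", "NI", "NI", "NI") for i in range(3)
        ]
        s = summarize_group(recs)
        assert (s.focal_blocked, s.reentry_blocked, s.total_blocked) == (0, 0, 0)

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidArgumentError):
            summarize_group([])

    def test_mixed_groups_rejected(self):
        recs = load_study_fixture("APO")[:1] + load_study_fixture("OXY")[:1]
        with pytest.raises(InvalidArgumentError):
            summarize_group(recs)

    def test_summary_invariant_validation(self):
        with pytest.raises(InvalidArgumentError):
            GroupSummary("APO", 5, focal_blocked=4, reentry_blocked=0, total_blocked=2)


def test_proarrhythmia_tally():
    outcomes = [
        InductionOutcome("VT", frozenset({"R"})),
        InductionOutcome("NI", frozenset()),
        InductionOutcome("VT", frozenset({"EFo"})),
    ]
    tally = proarrhythmia_tally(outcomes)
    assert tally == {"induced": 2, "not_induced": 1, "focal": 1, "reentry": 1}


class TestChiSquare:
    def test_apo_versus_controls(self):
        stat, p = chi_square_2x2([[6, 4], [0, 10]])
        assert stat == pytest.approx(8.571, abs=1e-3)
        assert p == pytest.approx(0.0034, abs=2e-4)

    def test_independence(self):
        stat, p = chi_square_2x2([[5, 5], [5, 5]])
        assert stat == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        stat, p = chi_square_2x2([[5, 3], [1, 7]])
        assert stat == pytest.approx(4.267, abs=1e-3)
        assert p == pytest.approx(0.039, abs=1e-3)

    def test_yates_variant_smaller_statistic(self):
        plain, _ = chi_square_2x2([[6, 4], [0, 10]])
        yates, _ = chi_square_2x2([[6, 4], [0, 10]], correction=True)
        assert yates < plain

    def test_zero_margin_rejected(self):
        with pytest.raises(UndefinedTestError):
            chi_square_2x2([[0, 0], [3, 4]])

    def test_non_integer_rejected(self):
        with pytest.raises(InvalidArgumentError):
            chi_square_2x2([[1.5, 2], [3, 4]])

    def test_swap_rows_and_columns_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 12, size=4)
            s1, p1 = chi_square_2x2([[a, b], [c, d]])
            s2, p2 = chi_square_2x2([[d, c], [b, a]])
            assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_monotone_in_treated_block_count(self):
        # adding one more blocked treated dog (n fixed) never raises p
        last = 1.0
        for blocked in range(1, 11):
            _, p = chi_square_2x2([[blocked, 10 - blocked], [0, 10]])
            assert p <= last + 1e-12
            last = p


def _fisher_oracle(a, b, c, d):
    """Exhaustive enumeration with exact rational hypergeometric masses."""

    def prob(a, b, c, d):
        n = a + b + c + d
        return Fraction(
            factorial(a + b) * factorial(c + d) * factorial(a + c) * factorial(b + d),
            factorial(n) * factorial(a) * factorial(b) * factorial(c) * factorial(d),
        )

    p_obs = prob(a, b, c, d)
    r1, c1 = a + b, a + c
    n = a + b + c + d
    total = Fraction(0)
    for aa in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        bb, cc = r1 - aa, c1 - aa
        dd = n - r1 - cc
        p = prob(aa, bb, cc, dd)
        if p <= p_obs:
            total += p
    return total


class TestFisher:
    def test_apo_versus_controls(self):
        assert fisher_exact_two_tailed([[6, 4], [0, 10]]) == pytest.approx(
            0.01084, abs=1e-5
        )

    def test_balanced_unit_table(self):
        assert fisher_exact_two_tailed([[1, 1], [1, 1]]) == 1.0

    def test_zero_cells_allowed(self):
        assert 0.0 < fisher_exact_two_tailed([[0, 5], [5, 0]]) <= 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            a, b, c, d = (int(v) for v in rng.integers(0, 12, size=4))
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            got = fisher_exact_two_tailed([[a, b], [c, d]])
            assert abs(got - float(_fisher_oracle(a, b, c, d))) < 1e-12

    def test_matches_scipy(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            a, b, c, d = (int(v) for v in rng.integers(0, 15, size=4))
            got = fisher_exact_two_tailed([[a, b], [c, d]])
            _, expected = scipy_fisher([[a, b], [c, d]], alternative="two-sided")
            assert got == pytest.approx(expected, abs=5e-9)

    def test_swap_rows_and_columns_invariance(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            a, b, c, d = (int(v) for v in rng.integers(0, 10, size=4))
            assert fisher_exact_two_tailed([[a, b], [c, d]]) == pytest.approx(
                fisher_exact_two_tailed([[d, c], [b, a]]), abs=1e-12
            )

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            a, b, c, d = (int(v) for v in rng.integers(0, 8, size=4))
            p = fisher_exact_two_tailed([[a, b], [c, d]])
            assert 0.0 < p <= 1.0
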