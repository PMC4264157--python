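"""Study-level tally: reproducibility, block-of-induction, group summaries
and 2x2 contingency statistics.

A mechanism *category* (focal = {EFo, EpFo}; reentry = {R, RE}) is
reproducible when it appears in both baseline inductions.  It is blocked
when it is reproducible and no sustained episode at the final completed
post-treatment induction carries it — "not inducible", non-sustained VT
and a truncated series all count as absence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from scipy.stats import chi2 as _chi2_dist

from .errors import InvalidArgumentError, UndefinedTestError
from .fixtures import InductionOutcome, InductionRecord

FOCAL_LABELS = frozenset({"EFo", "EpFo"})
REENTRY_LABELS = frozenset({"R", "RE"})
CATEGORIES = ("focal", "reentry")

_CATEGORY_LABELS = {"focal": FOCAL_LABELS, "reentry": REENTRY_LABELS}


def _categories_of(outcome: InductionOutcome) -> set[str]:
    if not outcome.sustained:
        return set()
    return {
        c for c, labels in _CATEGORY_LABELS.items() if outcome.mechanisms & labels
    }


def reproducible_categories(record: InductionRecord) -> set[str]:
    """Categories present at BOTH baseline inductions."""
    first, second = record.baseline
    return _categories_of(first) & _categories_of(second)


def blocked_categories(record: InductionRecord) -> set[str]:
    """Reproducible categories absent from the final completed
    post-treatment induction."""
    final = record.final_completed
    if final is None:
        raise InvalidArgumentError(
            f"{record.dog_id}: no completed post-treatment induction"
        )
    persisting = _categories_of(final)
    return {c for c in reproducible_categories(record) if c not in persisting}


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    focal_blocked: int
    reentry_blocked: int
    total_blocked: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.total_blocked <= self.n
            and self.total_blocked <= self.focal_blocked + self.reentry_blocked
            and max(self.focal_blocked, self.reentry_blocked) <= self.total_blocked
        )
        if not ok:
            raise InvalidArgumentError("inconsistent summary counts")


def summarize_group(records: list[InductionRecord]) -> GroupSummary:
    """Blocked-experiment counts for one group."""
    if not records:
        raise InvalidArgumentError("empty group")
    groups = {r.group for r in records}
    if len(groups) != 1:
        raise InvalidArgumentError("records span multiple groups")
    blocked_sets = [blocked_categories(r) for r in records]
    return GroupSummary(
        group=groups.pop(),
        n=len(records),
        focal_blocked=sum("focal" in b for b in blocked_sets),
        reentry_blocked=sum("reentry" in b for b in blocked_sets),
        total_blocked=sum(bool(b) for b in blocked_sets),
    )


def proarrhythmia_tally(outcomes: list[InductionOutcome]) -> dict[str, int]:
    """Descriptive count of post-drug inductions in previously non-inducible
    dogs (no statistics)."""
    tally = {"induced": 0, "not_induced": 0, "focal": 0, "reentry": 0}
    for o in outcomes:
        cats = _categories_of(o)
        if cats:
            tally["induced"] += 1
            for c in cats:
                tally[c] += 1
        else:
            tally["not_induced"] += 1
    return tally


# ---------------------------------------------------------------------------
# 2x2 contingency statistics
# ---------------------------------------------------------------------------


def _check_table(table) -> tuple[int, int, int, int]:
    (a, b), (c, d) = table
    vals = (a, b, c, d)
    if any(v < 0 or v != int(v) for v in vals):
        raise InvalidArgumentError("table entries must be nonnegative integers")
    return tuple(int(v) for v in vals)


def chi_square_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table, 1 df.

    No continuity correction by default; set ``correction=True`` for the
    Yates variant.  Returns (statistic, two-sided p).
    """
    a, b, c, d = _check_table(table)
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise UndefinedTestError("zero margin: chi-square undefined")
    num = abs(a * d - b * c)
    if correction:
        num = max(num - n / 2.0, 0.0)
    stat = n * num * num / (r1 * r2 * c1 * c2)
    return float(stat), float(_chi2_dist.sf(stat, df=1))


def fisher_exact_two_tailed(table) -> float:
    """Two-sided Fisher's exact test.

    Sums, over all tables with the observed margins, the hypergeometric
    probabilities no larger than the observed table's.  The tail
    membership test is exact integer arithmetic; the returned p is the
    exact rational sum rounded to float.
    """
    a, b, c, d = _check_table(table)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    # unnormalized weight of a table with a' in the top-left cell
    w_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = Fraction(0)
    denom = math.comb(n, c1)
    for ap in range(lo, hi + 1):
        w = math.comb(r1, ap) * math.comb(r2, c1 - ap)
        if w <= w_obs:
            total += Fraction(w, denom)
    return float(min(total, Fraction(1)))
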