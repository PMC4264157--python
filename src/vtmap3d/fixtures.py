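"""Packaged per-dog induction-outcome fixtures.

Each of the 54 dogs has four programmed inductions: two baseline (saline)
and two after treatment (drug or saline for the concurrent controls).
Every induction records an episode type (VT, VF, non-sustained VT, not
inducible, or not done) and the set of mechanisms of the sustained
episode.  ``cohort`` identifies the concurrent-control pairing of the
control dogs (which treated group they were studied alongside).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .errors import InvalidArgumentError

GROUPS = ("APO", "OXY", "BOTH", "CONTROL")
EPISODE_TYPES = ("VT", "VF", "VT_ns", "NI", "nd")
MECHANISM_LABELS = ("EFo", "EpFo", "R", "RE")

#: Expected group sizes.
GROUP_SIZES = {"APO": 10, "OXY": 9, "BOTH": 8, "CONTROL": 27}


@dataclass(frozen=True)
class InductionOutcome:
    episode_type: str
    mechanisms: frozenset[str]

    def __post_init__(self) -> None:
        if self.episode_type not in EPISODE_TYPES:
            raise InvalidArgumentError(f"unknown episode type {self.episode_type!r}")
        bad = self.mechanisms - set(MECHANISM_LABELS)
        if bad:
            raise InvalidArgumentError(f"unknown mechanism labels {sorted(bad)}")
        if self.episode_type in ("NI", "nd") and self.mechanisms:
            raise InvalidArgumentError("NI/nd inductions carry no mechanisms")

    @property
    def sustained(self) -> bool:
        return self.episode_type in ("VT", "VF")

    @property
    def completed(self) -> bool:
        return self.episode_type != "nd"


@dataclass(frozen=True)
class InductionRecord:
    """One dog's four induction outcomes (the unit of the study tally)."""

    dog_id: str
    group: str
    cohort: str
    inductions: tuple[InductionOutcome, ...]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise InvalidArgumentError(f"unknown group {self.group!r}")
        if len(self.inductions) != 4:
            raise InvalidArgumentError("each record holds 4 inductions")

    @property
    def baseline(self) -> tuple[InductionOutcome, InductionOutcome]:
        return self.inductions[0], self.inductions[1]

    @property
    def post_treatment(self) -> tuple[InductionOutcome, InductionOutcome]:
        return self.inductions[2], self.inductions[3]

    @property
    def final_completed(self) -> InductionOutcome | None:
        """The last completed post-treatment induction ('nd' truncates)."""
        done = [o for o in self.post_treatment if o.completed]
        return done[-1] if done else None


def _load_all() -> list[InductionRecord]:
    path = resources.files("vtmap3d").joinpath("data", "induction_tables.csv")
    by_dog: dict[str, dict] = {}
    with path.open(newline="") as f:
        for row in csv.DictReader(f):
            d = by_dog.setdefault(
                row["dog_id"],
                {"group": row["group"], "cohort": row["cohort"], "inds": {}},
            )
            mechs = frozenset(m for m in row["mechanisms"].split(";") if m)
            d["inds"][int(row["induction_index"])] = InductionOutcome(
                row["episode_type"], mechs
            )
    records = []
    for dog_id, d in by_dog.items():
        inds = tuple(d["inds"][i] for i in sorted(d["inds"]))
        records.append(InductionRecord(dog_id, d["group"], d["cohort"], inds))
    return records


def load_study_fixture(group: str) -> list[InductionRecord]:
    """All records of one group (APO 10, OXY 9, BOTH 8, CONTROL 27)."""
    if group not in GROUPS:
        raise InvalidArgumentError(f"unknown group {group!r}")
    return [r for r in _load_all() if r.group == group]


def control_records(cohort: str) -> list[InductionRecord]:
    """The saline controls studied concurrently with one treated group."""
    if cohort not in ("APO", "OXY", "BOTH"):
        raise InvalidArgumentError(f"unknown cohort {cohort!r}")
    return [r for r in _load_all() if r.group == "CONTROL" and r.cohort == cohort]
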