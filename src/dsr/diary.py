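"""Participant-level dietary species richness from 4-day food diaries.

A diary is a long table (participant_id, day, food_code, grams) covering
up to four consecutive reporting days.  Participant-level DSR is the
count of distinct biological species across all foods and drinks
consumed; per-day new-species counts and the cumulative accumulation
curve are derived from the day-wise union of the species sets of the
consumed foods.  Amounts never enter the calculation: DSR is a presence
metric.  Only participants completing at least three diary days are
analysed, matching standard survey completer rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AGE_GROUPS",
    "DSRResult",
    "UnknownFoodCodeError",
    "validate_cohort",
    "cumulative_dsr",
    "cohort_results",
    "results_frame",
    "cohort_accumulation_summary",
    "two_day_coverage",
]

AGE_GROUPS = ("children", "adolescents", "adults", "elders")
MIN_DAYS = 3
MAX_DAYS = 4


class UnknownFoodCodeError(KeyError):
    """A diary references a food code absent from the food database."""


@dataclass(frozen=True)
class DSRResult:
    """Per-day species accumulation for one participant.

    ``new_species_per_day[k]`` counts species first seen on day k+1;
    ``cumulative_dsr`` is its running sum and ``total_dsr`` its last
    value, the participant's DSR over all completed days.
    """

    participant_id: str
    days_completed: int
    new_species_per_day: tuple[int, ...]
    cumulative_dsr: tuple[int, ...]
    total_dsr: int

    def __post_init__(self) -> None:
        cum = np.cumsum(self.new_species_per_day)
        if tuple(int(c) for c in cum) != self.cumulative_dsr:
            raise ValueError("cumulative_dsr must be the running sum of new species")
        if self.cumulative_dsr and self.total_dsr != self.cumulative_dsr[-1]:
            raise ValueError("total_dsr must equal the last cumulative value")


def validate_cohort(
    diaries: pd.DataFrame, participants: pd.DataFrame | None = None
) -> list[str]:
    """Participant ids completing >= 3 distinct diary days.

    A day counts as completed when it has at least one consumption.
    Exclusions are logged.  An empty cohort yields an empty list.
    """
    if diaries.empty:
        return []
    bad_day = ~diaries["day"].isin(range(1, MAX_DAYS + 1))
    if bad_day.any():
        raise ValueError(f"day index outside 1..{MAX_DAYS} at rows {list(diaries.index[bad_day][:5])}")
    if (diaries["grams"] <= 0).any():
        raise ValueError("grams must be > 0")
    days_per = diaries.groupby("participant_id")["day"].nunique()
    included = sorted(days_per.index[days_per >= MIN_DAYS].astype(str))
    excluded = sorted(days_per.index[days_per < MIN_DAYS].astype(str))
    if excluded:
        logger.info(
            "excluded %d participants with < %d diary days: %s%s",
            len(excluded),
            MIN_DAYS,
            excluded[:10],
            "..." if len(excluded) > 10 else "",
        )
    if participants is not None:
        known = set(participants["participant_id"].astype(str))
        included = [p for p in included if p in known]
    return included


def cumulative_dsr(
    participant_diary: pd.DataFrame, species_by_code: Mapping[str, frozenset[str]]
) -> DSRResult:
    """Species accumulation across one participant's diary days.

    ``species_by_code`` maps food_code to the food's annotated species
    set.  Day-k species set is the union over that day's foods; the new
    count is its difference from all earlier days.  Gram amounts are
    ignored.  An unresolvable food code raises
    :class:`UnknownFoodCodeError` naming the code.
    """
    pid = str(participant_diary["participant_id"].iloc[0])
    days = sorted(participant_diary["day"].unique())
    seen: set[str] = set()
    new_counts: list[int] = []
    for day in days:
        codes = participant_diary.loc[participant_diary["day"] == day, "food_code"]
        day_set: set[str] = set()
        for code in codes.astype(str):
            try:
                day_set |= species_by_code[code]
            except KeyError:
                raise UnknownFoodCodeError(
                    f"unknown food_code {code!r} (participant {pid}, day {day})"
                ) from None
        new_counts.append(len(day_set - seen))
        seen |= day_set
    cum = tuple(int(c) for c in np.cumsum(new_counts))
    return DSRResult(
        participant_id=pid,
        days_completed=len(days),
        new_species_per_day=tuple(new_counts),
        cumulative_dsr=cum,
        total_dsr=cum[-1] if cum else 0,
    )


def species_map(annotated_foods: pd.DataFrame) -> dict[str, frozenset[str]]:
    """food_code -> species_set lookup from an annotated food table."""
    if "species_set" not in annotated_foods.columns:
        raise ValueError("food table must be annotated first")
    return dict(
        zip(annotated_foods["food_code"].astype(str), annotated_foods["species_set"])
    )


def cohort_results(
    diaries: pd.DataFrame,
    annotated_foods: pd.DataFrame,
    participants: pd.DataFrame | None = None,
) -> list[DSRResult]:
    """Validate the cohort and compute a :class:`DSRResult` per included
    participant, in participant-id order."""
    lookup = species_map(annotated_foods)
    included = validate_cohort(diaries, participants)
    diaries = diaries[diaries["participant_id"].astype(str).isin(included)]
    out = []
    for pid, sub in diaries.groupby(diaries["participant_id"].astype(str), sort=True):
        out.append(cumulative_dsr(sub, lookup))
    return out


def results_frame(results: Iterable[DSRResult]) -> pd.DataFrame:
    """One row per participant: per-day new species, cumulative DSR, total."""
    rows = []
    for r in results:
        row = {"participant_id": r.participant_id, "days_completed": r.days_completed}
        for k in range(MAX_DAYS):
            row[f"new_day{k + 1}"] = (
                r.new_species_per_day[k] if k < len(r.new_species_per_day) else np.nan
            )
            row[f"cumulative_day{k + 1}"] = (
                r.cumulative_dsr[k] if k < len(r.cumulative_dsr) else np.nan
            )
        row["total_dsr"] = r.total_dsr
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_accumulation_summary(
    results: list[DSRResult], include_three_day_totals: bool = True
) -> pd.DataFrame:
    """Per-day cohort medians and quartiles of new and cumulative species.

    Three-day completers contribute to days 1-3 only; day-4 rows are
    computed over four-day completers.  ``include_three_day_totals``
    controls whether three-day completers' totals enter the "total"
    row (the default keeps them, flagged by the n column).
    """
    if not results:
        raise ValueError("no results to summarize")
    rows = []
    for day in range(1, MAX_DAYS + 1):
        new = np.array(
            [r.new_species_per_day[day - 1] for r in results if r.days_completed >= day],
            dtype=float,
        )
        if len(new) == 0:
            continue
        cum = np.array(
            [r.cumulative_dsr[day - 1] for r in results if r.days_completed >= day],
            dtype=float,
        )
        nq1, nmed, nq3 = np.quantile(new, [0.25, 0.5, 0.75])
        cq1, cmed, cq3 = np.quantile(cum, [0.25, 0.5, 0.75])
        rows.append(
            {
                "day": day,
                "n": len(new),
                "new_median": float(nmed),
                "new_q1": float(nq1),
                "new_q3": float(nq3),
                "cumulative_median": float(cmed),
                "cumulative_q1": float(cq1),
                "cumulative_q3": float(cq3),
            }
        )
    totals = np.array(
        [
            r.total_dsr
            for r in results
            if include_three_day_totals or r.days_completed >= MAX_DAYS
        ],
        dtype=float,
    )
    tq1, tmed, tq3 = np.quantile(totals, [0.25, 0.5, 0.75])
    rows.append(
        {
            "day": 0,
            "n": len(totals),
            "new_median": np.nan,
            "new_q1": np.nan,
            "new_q3": np.nan,
            "cumulative_median": float(tmed),
            "cumulative_q1": float(tq1),
            "cumulative_q3": float(tq3),
        }
    )
    frame = pd.DataFrame(rows)
    frame["day"] = frame["day"].replace(0, "total").astype(str)
    return frame


def two_day_coverage(results: list[DSRResult]) -> float:
    """Fraction of the 4-day median DSR captured in the first two days.

    Ratio of cohort medians (not median of per-person ratios): median
    cumulative DSR at day 2 over median cumulative DSR at day 4,
    computed over four-day completers for the denominator.
    """
    day2 = [r.cumulative_dsr[1] for r in results if r.days_completed >= 2]
    day4 = [r.cumulative_dsr[3] for r in results if r.days_completed >= 4]
    if not day4:
        raise ValueError("no four-day completers for the denominator")
    med4 = float(np.median(day4))
    if med4 == 0:
        raise ValueError("median 4-day DSR is zero")
    return float(np.median(day2)) / med4
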