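"""Time-to-onset: days from drug administration start to adverse-event
date, under strict date-validity rules.

Both dates must be full 8-digit YYYYMMDD strings parsing as real calendar
dates, with event year <= 2024, start year >= 1980 and a non-negative
interval; anything else is a categorized rejection (rejections are data,
not errors — their counts are part of the output).
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from faerspv.cohort import DrugDictionary, match_drug
from faerspv.faers_io import CaseReport

_EIGHT_DIGITS = re.compile(r"^\d{8}$")

#: Rejection categories; they partition the rejected set.
REJECT_NON_8_DIGIT = "non-8-digit"
REJECT_UNPARSEABLE = "unparseable"
REJECT_YEAR_BOUND = "year-bound"
REJECT_NEGATIVE = "negative-interval"

MAX_YEAR = 2024
MIN_START_YEAR = 1980


@dataclass(frozen=True)
class TteRecord:
    caseid: str
    drug_id: str
    start_date: dt.date
    event_date: dt.date
    days: int


@dataclass(frozen=True)
class TteSummary:
    group: str
    n_valid: int
    group_size: int
    share: float
    median: float
    q1: float
    q3: float


def _parse8(raw: str) -> dt.date | None:
    try:
        return dt.datetime.strptime(raw, "%Y%m%d").date()
    except ValueError:
        return None


def validate_dates(start_raw: str, event_raw: str):
    """Validate a (start, event) date pair.

    Returns ``(start_date, event_date, days)`` on acceptance, or a
    rejection-category string.
    """
    start_raw = start_raw.strip()
    event_raw = event_raw.strip()
    if not (_EIGHT_DIGITS.match(start_raw) and _EIGHT_DIGITS.match(event_raw)):
        return REJECT_NON_8_DIGIT
    start = _parse8(start_raw)
    event = _parse8(event_raw)
    if start is None or event is None:
        return REJECT_UNPARSEABLE
    if event.year > MAX_YEAR or start.year > MAX_YEAR or start.year < MIN_START_YEAR:
        return REJECT_YEAR_BOUND
    days = (event - start).days
    if days < 0:
        return REJECT_NEGATIVE
    return start, event, days


def earliest_suspect_start(
    case: CaseReport, drug_id: str, dictionary: list[DrugDictionary]
) -> str | None:
    """Earliest 8-digit-format start date among the report's primary-suspect
    rows matching ``drug_id``; None when no such row carries one."""
    starts = [
        d.start_dt.strip()
        for d in case.drugs
        if d.role_cod == "PS"
        and drug_id in match_drug(d.drugname, d.prod_ai, dictionary)
        and _EIGHT_DIGITS.match(d.start_dt.strip())
    ]
    return min(starts) if starts else None


def compute_tte(
    cases: Iterable[CaseReport],
    drug_id: str,
    dictionary: list[DrugDictionary],
) -> tuple[list[TteRecord], dict[str, int]]:
    """Time-to-event records for one drug's primary-suspect subset, plus a
    rejection tally. Reports with no start date at all are tallied under
    the non-8-digit category (no usable date)."""
    records: list[TteRecord] = []
    rejects = {
        REJECT_NON_8_DIGIT: 0,
        REJECT_UNPARSEABLE: 0,
        REJECT_YEAR_BOUND: 0,
        REJECT_NEGATIVE: 0,
    }
    for case in cases:
        start_raw = earliest_suspect_start(case, drug_id, dictionary)
        outcome = validate_dates(start_raw or "", case.event_dt)
        if isinstance(outcome, str):
            rejects[outcome] += 1
            continue
        start, event, days = outcome
        records.append(
            TteRecord(
                caseid=case.caseid,
                drug_id=drug_id,
                start_date=start,
                event_date=event,
                days=days,
            )
        )
    return records, rejects


def summarize_tte(
    days_by_group: dict[str, Sequence[int]],
    group_sizes: dict[str, int] | None = None,
) -> list[TteSummary]:
    """Median and IQR of onset days per group (linear-interpolation
    quantiles). Groups with no valid records are omitted; ``group_sizes``
    supplies the denominators for the availability share."""
    summaries = []
    for group, days in days_by_group.items():
        arr = np.asarray(list(days), dtype=float)
        if arr.size == 0:
            continue
        q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
        size = group_sizes.get(group, arr.size) if group_sizes else arr.size
        summaries.append(
            TteSummary(
                group=group,
                n_valid=int(arr.size),
                group_size=size,
                share=100.0 * arr.size / size if size else float("nan"),
                median=float(med),
                q1=float(q1),
                q3=float(q3),
            )
        )
    return summaries
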