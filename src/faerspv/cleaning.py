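"""Report-cleaning cascade: erroneous-case removal, two-stage
deduplication, and age validation.

Stage order matters and mirrors the selection flow: deleted cases are
dropped first, then one report version is kept per caseid, then
cross-caseid duplicates are collapsed, then reports without interpretable
age are excluded. Each stage only ever shrinks the corpus; counts for every
stage are accumulated in a manifest dict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from faerspv.cohort import normalized_drugnames
from faerspv.faers_io import CaseReport

logger = logging.getLogger(__name__)

#: Conversion factors from FAERS age unit codes to years.
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.143,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

#: Plausibility bounds on converted age, in years.
AGE_BOUNDS = (0.0, 120.0)


def age_to_years(age: str, age_cod: str) -> float | None:
    """Convert a raw FAERS age string and unit code to years.

    Returns ``None`` when the age is missing, non-numeric, carries an
    unknown unit code, or falls outside the plausibility bounds. A missing
    unit code with a numeric age is treated as years (the dominant FAERS
    convention).
    """
    text = age.strip()
    if not text:
        return None
    try:
        value = float(text)
    except ValueError:
        return None
    code = age_cod.strip().upper()
    if code == "":
        factor = 1.0
    else:
        factor = AGE_UNIT_TO_YEARS.get(code)
        if factor is None:
            return None
    years = value * factor
    lo, hi = AGE_BOUNDS
    if not (lo <= years <= hi):
        return None
    return years


@dataclass(frozen=True)
class DedupKey:
    """Identity key for cross-caseid deduplication: two reports with equal
    keys describe the same event. Missing fields compare equal to missing."""

    age_years: float | None
    event_dt: str
    reporter_country: str
    pts: tuple[str, ...]
    drugnames: tuple[str, ...]

    @classmethod
    def from_case(cls, case: CaseReport) -> "DedupKey":
        years = age_to_years(case.age, case.age_cod)
        return cls(
            age_years=round(years, 6) if years is not None else None,
            event_dt=case.event_dt.strip(),
            reporter_country=case.reporter_country.strip(),
            pts=tuple(sorted(case.pts)),
            drugnames=normalized_drugnames(case),
        )


def _recency(case: CaseReport) -> tuple[str, int, str]:
    # "most recent" = max (FDA receipt date, caseversion, primaryid);
    # primaryid is unique so ties are impossible.
    return (case.fda_dt, case.caseversion, case.primaryid)


def drop_deleted(
    cases: list[CaseReport], deleted_caseids: set[str], manifest: dict | None = None
) -> list[CaseReport]:
    """Remove reports whose caseid appears in the FDA deleted-case lists."""
    kept = [c for c in cases if c.caseid not in deleted_caseids]
    removed = len(cases) - len(kept)
    logger.info("drop_deleted removed %d of %d reports", removed, len(cases))
    if manifest is not None:
        manifest["deleted_removed"] = removed
    return kept


def keep_latest_per_caseid(
    cases: list[CaseReport], manifest: dict | None = None
) -> list[CaseReport]:
    """Collapse initial/follow-up versions to the most recent report per
    caseid."""
    latest: dict[str, CaseReport] = {}
    for case in cases:
        cur = latest.get(case.caseid)
        if cur is None or _recency(case) > _recency(cur):
            latest[case.caseid] = case
    kept = list(latest.values())
    removed = len(cases) - len(kept)
    logger.info("keep_latest_per_caseid removed %d follow-up versions", removed)
    if manifest is not None:
        manifest["version_removed"] = removed
    return kept


def dedup_cross_caseid(
    cases: list[CaseReport], manifest: dict | None = None
) -> list[CaseReport]:
    """Collapse duplicate reports filed under different caseids.

    Reports with identical age, event date, reporter country, reaction-term
    set and normalized drug-name set are regarded as the same event; the
    most recent one is retained.
    """
    best: dict[DedupKey, CaseReport] = {}
    order: list[DedupKey] = []
    for case in cases:
        key = DedupKey.from_case(case)
        cur = best.get(key)
        if cur is None:
            best[key] = case
            order.append(key)
        elif _recency(case) > _recency(cur):
            best[key] = case
    kept = [best[k] for k in order]
    removed = len(cases) - len(kept)
    logger.info("dedup_cross_caseid removed %d cross-caseid duplicates", removed)
    if manifest is not None:
        manifest["crossdup_removed"] = removed
    return kept


def filter_valid_age(
    cases: list[CaseReport], manifest: dict | None = None
) -> list[CaseReport]:
    """Exclude reports with unclear age information; populate ``age_years``
    on the retained reports."""
    kept = []
    assumed_years = 0
    for case in cases:
        years = age_to_years(case.age, case.age_cod)
        if years is None:
            continue
        if case.age.strip() and not case.age_cod.strip():
            assumed_years += 1
        case.age_years = years
        kept.append(case)
    removed = len(cases) - len(kept)
    logger.info(
        "filter_valid_age removed %d reports (%d retained ages assumed YR)",
        removed,
        assumed_years,
    )
    if manifest is not None:
        manifest["age_removed"] = removed
        manifest["age_assumed_years"] = assumed_years
    return kept


def clean_cases(
    cases: list[CaseReport], deleted_caseids: set[str]
) -> tuple[list[CaseReport], dict]:
    """Run the full cleaning cascade; returns the cleaned corpus and a
    stage-count manifest."""
    manifest: dict = {"raw": len(cases)}
    cases = drop_deleted(cases, deleted_caseids, manifest)
    manifest["after_deleted"] = len(cases)
    cases = keep_latest_per_caseid(cases, manifest)
    manifest["after_latest"] = len(cases)
    cases = dedup_cross_caseid(cases, manifest)
    manifest["after_crossdup"] = len(cases)
    cases = filter_valid_age(cases, manifest)
    manifest["after_age"] = len(cases)
    return cases, manifest
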