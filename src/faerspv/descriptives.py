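"""Cohort characteristic tables: age, sex, reporter occupation, serious
outcomes, and time-to-event availability."""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from faerspv.faers_io import CaseReport

#: Default mapping of FAERS reporter occupation codes to reporting classes.
#: Codes not listed (and non-empty) fall in "other"; empty code is
#: "unknown".
DEFAULT_OCCUPATION_MAPPING = {
    "MD": "healthcare_professional",
    "PH": "healthcare_professional",
    "RN": "healthcare_professional",
    "HP": "healthcare_professional",
    "CN": "consumer",
}

OUTCOME_LABELS = {
    "DE": "death",
    "LT": "life_threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "congenital_anomaly",
    "RI": "required_intervention",
    "OT": "other",
}


def percent(count: float, n: float, decimals: int = 1) -> float:
    """``100 * count / n`` rounded half-up to ``decimals`` places.

    Half-up (not banker's) rounding so printed percentages are stable and
    conventional: 12.85 -> 12.9.
    """
    if n == 0:
        return float("nan")
    quantum = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(count) / Decimal(n)).quantize(quantum, rounding=ROUND_HALF_UP)
    )


def classify_occupation(
    occp_cod: str, mapping: dict[str, str] | None = None
) -> str:
    """Map a reporter occupation code to one of healthcare_professional /
    consumer / other / unknown."""
    if mapping is None:
        mapping = DEFAULT_OCCUPATION_MAPPING
    code = occp_cod.strip().upper()
    if not code:
        return "unknown"
    return mapping.get(code, "other")


@dataclass
class CohortSummary:
    group: str
    n: int
    age_median: float | None
    age_q1: float | None
    age_q3: float | None
    sex: dict[str, tuple[int, float]] = dc_field(default_factory=dict)
    occupation: dict[str, tuple[int, float]] = dc_field(default_factory=dict)
    outcomes: dict[str, tuple[int, float]] = dc_field(default_factory=dict)
    tte_available: tuple[int, float] = (0, float("nan"))


def summarize_cohort(
    cases: list[CaseReport],
    group: str = "all",
    occupation_mapping: dict[str, str] | None = None,
    tte_valid_caseids: set[str] | None = None,
) -> CohortSummary:
    """Tabulate one group's characteristics.

    Category percents use the group size as denominator. Sex "unknown"
    pools empty and UNK codes. Outcome categories are non-exclusive (a
    report can be both hospitalized and dead), so their percents need not
    sum to 100.
    """
    n = len(cases)
    ages = np.array([c.age_years for c in cases if c.age_years is not None], dtype=float)
    if ages.size:
        q1, med, q3 = np.quantile(ages, [0.25, 0.5, 0.75])
        age_stats = (float(med), float(q1), float(q3))
    else:
        age_stats = (None, None, None)

    sex_counts = {"female": 0, "male": 0, "unknown": 0}
    occ_counts = {"healthcare_professional": 0, "consumer": 0, "other": 0, "unknown": 0}
    out_counts = {label: 0 for label in OUTCOME_LABELS.values()}
    for c in cases:
        sex = c.sex.strip().upper()
        if sex == "F":
            sex_counts["female"] += 1
        elif sex == "M":
            sex_counts["male"] += 1
        else:
            sex_counts["unknown"] += 1
        occ_counts[classify_occupation(c.occp_cod, occupation_mapping)] += 1
        for code in c.outcomes:
            label = OUTCOME_LABELS.get(code)
            if label:
                out_counts[label] += 1

    n_tte = (
        sum(1 for c in cases if c.caseid in tte_valid_caseids)
        if tte_valid_caseids is not None
        else 0
    )
    return CohortSummary(
        group=group,
        n=n,
        age_median=age_stats[0],
        age_q1=age_stats[1],
        age_q3=age_stats[2],
        sex={k: (v, percent(v, n)) for k, v in sex_counts.items()},
        occupation={k: (v, percent(v, n)) for k, v in occ_counts.items()},
        outcomes={k: (v, percent(v, n)) for k, v in out_counts.items()},
        tte_available=(n_tte, percent(n_tte, n)),
    )


def summary_rows(summary: CohortSummary) -> list[dict]:
    """Flatten a CohortSummary into long-format rows for CSV output."""
    rows = [
        {"group": summary.group, "field": "n", "category": "", "count": summary.n, "percent": ""},
        {
            "group": summary.group,
            "field": "age_median_iqr",
            "category": "",
            "count": "",
            "percent": ""
            if summary.age_median is None
            else f"{summary.age_median:g} ({summary.age_q1:g}-{summary.age_q3:g})",
        },
    ]
    for fieldname, table in (
        ("sex", summary.sex),
        ("occupation", summary.occupation),
        ("outcome", summary.outcomes),
    ):
        for category, (count, pct) in table.items():
            rows.append(
                {
                    "group": summary.group,
                    "field": fieldname,
                    "category": category,
                    "count": count,
                    "percent": pct,
                }
            )
    count, pct = summary.tte_available
    rows.append(
        {
            "group": summary.group,
            "field": "tte_available",
            "category": "",
            "count": count,
            "percent": pct,
        }
    )
    return rows
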