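"""Mapping report reaction terms to named queries (SOC- or SMQ-style
Preferred Term sets).

MedDRA itself is licensed and is never bundled: query definitions are
user-supplied YAML files listing narrow-scope Preferred Terms. The repo
ships a small synthetic vocabulary for tests and simulations. PT matching
is exact string match after whitespace trimming — FAERS reaction rows are
already dictionary-coded, and fuzziness would silently change counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

from faerspv.descriptives import percent
from faerspv.faers_io import CaseReport


class ConfigurationError(ValueError):
    pass


@dataclass
class SmqDefinition:
    """A named retrieval query: an SMQ (or SOC) with its narrow-scope
    Preferred Term set."""

    name: str
    smq_code: str
    pts: set[str]
    scope: str = "narrow"

    def __post_init__(self) -> None:
        if self.scope != "narrow":
            raise ConfigurationError(
                f"query {self.name!r}: only narrow scope is supported, got {self.scope!r}"
            )
        self.pts = {" ".join(pt.split()) for pt in self.pts if pt.strip()}
        if not self.pts:
            raise ConfigurationError(f"query {self.name!r} has an empty PT list")


def load_query(path: str) -> SmqDefinition:
    """Load one query definition from YAML (keys: name, code, scope, pts)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: not a query definition")
    return SmqDefinition(
        name=str(raw.get("name", "")),
        smq_code=str(raw.get("code", "")),
        scope=str(raw.get("scope", "narrow")),
        pts=set(raw.get("pts", [])),
    )


def load_bundled_queries() -> dict[str, SmqDefinition]:
    """The toy query vocabulary shipped for tests and simulations (synthetic
    terms, no licensed dictionary content). Keyed by query name."""
    from importlib import resources

    queries: dict[str, SmqDefinition] = {}
    root = resources.files("faerspv.data").joinpath("queries")
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if not entry.name.endswith(".yaml"):
            continue
        raw = yaml.safe_load(entry.read_text(encoding="utf-8"))
        q = SmqDefinition(
            name=str(raw.get("name", "")),
            smq_code=str(raw.get("code", "")),
            scope=str(raw.get("scope", "narrow")),
            pts=set(raw.get("pts", [])),
        )
        queries[q.name] = q
    return queries


def save_query(query: SmqDefinition, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {
                "name": query.name,
                "code": query.smq_code,
                "scope": query.scope,
                "pts": sorted(query.pts),
            },
            fh,
            sort_keys=False,
        )


def flag_reports(cases: list[CaseReport], query: SmqDefinition) -> list[CaseReport]:
    """Reports whose PT set intersects the query's PT set. Each report is
    flagged at most once per query regardless of how many PTs match."""
    return [case for case in cases if case.pts & query.pts]


def pt_frequency(
    cases: list[CaseReport], vocabulary: set[str] | None = None, top: int | None = None
) -> pd.DataFrame:
    """Report-level reporting-frequency table of Preferred Terms.

    ``cases`` should already be restricted to the subset of interest (e.g.
    reports with at least one SOC-member PT); the percent denominator is
    ``len(cases)``. With ``vocabulary`` given, only member PTs are counted.
    Rows are ranked by descending count, ties broken alphabetically.
    """
    n = len(cases)
    counts: dict[str, int] = {}
    for case in cases:
        pts = case.pts if vocabulary is None else case.pts & vocabulary
        for pt in pts:
            counts[pt] = counts.get(pt, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top is not None:
        rows = rows[:top]
    return pd.DataFrame(
        [{"pt": pt, "count": c, "percent": percent(c, n)} for pt, c in rows],
        columns=["pt", "count", "percent"],
    )
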