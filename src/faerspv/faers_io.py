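"""Reading, joining and writing FAERS-style "$"-delimited quarterly tables.

All field values are kept as opaque strings at this layer; typing of ages
and dates happens downstream in :mod:`faerspv.cleaning` so that malformed
entries survive ingestion and can be counted as exclusions.
"""

from __future__ import annotations

import csv
import glob
import logging
import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DELIMITER = "$"

#: Valid drug role codes: primary suspect, secondary suspect, concomitant,
#: interacting.
ROLE_CODES = frozenset({"PS", "SS", "C", "I"})

#: Valid outcome codes: death, life-threatening, hospitalization,
#: disability, congenital anomaly, required intervention, other.
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})


class TableKind(str, Enum):
    """The FAERS quarterly table families handled by this module."""

    DEMO = "DEMO"
    DRUG = "DRUG"
    REAC = "REAC"
    THER = "THER"
    OUTC = "OUTC"


@dataclass(frozen=True)
class DemoRecord:
    primaryid: str
    caseid: str = ""
    caseversion: str = ""
    fda_dt: str = ""
    event_dt: str = ""
    age: str = ""
    age_cod: str = ""
    sex: str = ""
    occp_cod: str = ""
    occr_country: str = ""


@dataclass(frozen=True)
class DrugRecord:
    primaryid: str
    drug_seq: str = ""
    role_cod: str = ""
    drugname: str = ""
    prod_ai: str = ""
    start_dt: str = ""


@dataclass(frozen=True)
class ReacRecord:
    primaryid: str
    pt: str = ""


@dataclass(frozen=True)
class TherRecord:
    primaryid: str
    dsg_drug_seq: str = ""
    start_dt: str = ""
    end_dt: str = ""


@dataclass(frozen=True)
class OutcRecord:
    primaryid: str
    outc_cod: str = ""


_RECORD_TYPES = {
    TableKind.DEMO: DemoRecord,
    TableKind.DRUG: DrugRecord,
    TableKind.REAC: ReacRecord,
    TableKind.THER: TherRecord,
    TableKind.OUTC: OutcRecord,
}

# Historical column aliases across quarters (old name -> canonical name).
_ALIASES = {
    "gndr_cod": "sex",
    "isr": "primaryid",
    "case": "caseid",
}


@dataclass
class CaseReport:
    """One adverse-event report version: demographics joined with its drug,
    reaction and outcome rows.

    ``age_years`` is populated by :func:`faerspv.cleaning.filter_valid_age`;
    until then it is ``None``.
    """

    caseid: str
    primaryid: str
    caseversion: int
    fda_dt: str
    event_dt: str
    age: str
    age_cod: str
    sex: str
    occp_cod: str
    reporter_country: str
    age_years: float | None = None
    pts: set[str] = field(default_factory=set)
    drugs: list[DrugRecord] = field(default_factory=list)
    outcomes: set[str] = field(default_factory=set)


class FormatError(ValueError):
    """Raised when a table header does not carry the required key column."""


def parse_table(path: str | os.PathLike, table_kind: TableKind | str) -> list:
    """Parse one "$"-delimited FAERS table into a list of records.

    Parsing is header-name driven: columns may appear in any order, unknown
    columns are ignored, and columns absent from the file yield empty-string
    fields. Undecodable bytes are replaced rather than dropping the line.

    Raises
    ------
    FormatError
        If the header lacks the ``primaryid`` key column.
    OSError
        If the file cannot be read.
    """
    kind = TableKind(table_kind)
    record_type = _RECORD_TYPES[kind]
    fields = [f for f in record_type.__dataclass_fields__]

    with open(path, encoding="utf-8", errors="replace", newline="") as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file, no header")
        header = [
            _ALIASES.get(h.strip().lower(), h.strip().lower())
            for h in header_line.rstrip("\r\n").split(DELIMITER)
        ]
        if "primaryid" not in header:
            raise FormatError(f"{path}: header lacks 'primaryid': {header}")
        index = {name: i for i, name in enumerate(header)}

        records = []
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            values = line.split(DELIMITER)
            kwargs = {}
            for name in fields:
                i = index.get(name)
                kwargs[name] = values[i].strip() if i is not None and i < len(values) else ""
            records.append(record_type(**kwargs))
    return records


def write_table(records: Sequence, path: str | os.PathLike) -> None:
    """Serialize records back to the FAERS "$"-delimited dialect."""
    if not records:
        raise ValueError("cannot infer a header from an empty record list")
    fields = list(records[0].__dataclass_fields__)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(DELIMITER.join(fields) + "\n")
        for rec in records:
            fh.write(DELIMITER.join(getattr(rec, f) for f in fields) + "\n")


def read_deleted_caseids(path: str | os.PathLike) -> set[str]:
    """Read a deleted-case list: either a "$"-delimited table with a
    ``caseid`` column or a plain one-caseid-per-line file."""
    deleted: set[str] = set()
    with open(path, encoding="utf-8", errors="replace") as fh:
        first = fh.readline()
        if DELIMITER in first or first.strip().lower() == "caseid":
            header = [h.strip().lower() for h in first.rstrip("\r\n").split(DELIMITER)]
            try:
                col = header.index("caseid")
            except ValueError:
                raise FormatError(f"{path}: deleted-case header lacks 'caseid'")
            for line in fh:
                values = line.rstrip("\r\n").split(DELIMITER)
                if col < len(values) and values[col].strip():
                    deleted.add(values[col].strip())
        else:
            if first.strip():
                deleted.add(first.strip())
            for line in fh:
                if line.strip():
                    deleted.add(line.strip())
    return deleted


def assemble_cases(
    demo: Iterable[DemoRecord],
    drug: Iterable[DrugRecord] = (),
    reac: Iterable[ReacRecord] = (),
    outc: Iterable[OutcRecord] = (),
    ther: Iterable[TherRecord] = (),
) -> list[CaseReport]:
    """Join record lists on ``primaryid`` with DEMO rows as the spine.

    Drug/reaction/outcome rows without a matching DEMO row are dropped; the
    dropped counts are logged. When a DRUG row has no start date but a THER
    row exists for the same (primaryid, drug_seq), the THER start date is
    adopted.
    """
    cases: dict[str, CaseReport] = {}
    for d in demo:
        try:
            version = int(d.caseversion) if d.caseversion else 1
        except ValueError:
            version = 1
        cases[d.primaryid] = CaseReport(
            caseid=d.caseid,
            primaryid=d.primaryid,
            caseversion=version,
            fda_dt=d.fda_dt,
            event_dt=d.event_dt,
            age=d.age,
            age_cod=d.age_cod,
            sex=d.sex,
            occp_cod=d.occp_cod,
            reporter_country=d.occr_country,
        )

    ther_start = {
        (t.primaryid, t.dsg_drug_seq): t.start_dt for t in ther if t.start_dt
    }

    orphans = {"drug": 0, "reac": 0, "outc": 0}
    for r in drug:
        case = cases.get(r.primaryid)
        if case is None:
            orphans["drug"] += 1
            continue
        if not r.start_dt:
            fallback = ther_start.get((r.primaryid, r.drug_seq))
            if fallback:
                r = DrugRecord(
                    primaryid=r.primaryid,
                    drug_seq=r.drug_seq,
                    role_cod=r.role_cod,
                    drugname=r.drugname,
                    prod_ai=r.prod_ai,
                    start_dt=fallback,
                )
        case.drugs.append(r)
    for r in reac:
        case = cases.get(r.primaryid)
        if case is None:
            orphans["reac"] += 1
            continue
        pt = " ".join(r.pt.split())
        if pt:
            case.pts.add(pt)
    for r in outc:
        case = cases.get(r.primaryid)
        if case is None:
            orphans["outc"] += 1
            continue
        if r.outc_cod:
            case.outcomes.add(r.outc_cod)

    if any(orphans.values()):
        logger.info(
            "assemble_cases dropped orphan rows without DEMO spine: %s", orphans
        )
    return list(cases.values())


def load_corpus(input_dir: str | os.PathLike) -> tuple[list[CaseReport], set[str]]:
    """Load every quarterly table found under ``input_dir`` and assemble
    case reports.

    Files are discovered by prefix: ``DEMO*.txt``, ``DRUG*.txt``,
    ``REAC*.txt``, ``OUTC*.txt``, ``THER*.txt`` and ``DELETED*.txt``
    (case-insensitive). Returns the assembled reports and the union of
    deleted caseids.
    """
    input_dir = os.fspath(input_dir)

    def find(prefix: str) -> list[str]:
        hits = []
        for pat in (f"{prefix}*.txt", f"{prefix.lower()}*.txt"):
            hits.extend(glob.glob(os.path.join(input_dir, "**", pat), recursive=True))
        return sorted(set(hits))

    tables: dict[TableKind, list] = {kind: [] for kind in TableKind}
    for kind in TableKind:
        for path in find(kind.value):
            tables[kind].extend(parse_table(path, kind))
        logger.info("loaded %d %s rows", len(tables[kind]), kind.value)

    deleted: set[str] = set()
    for path in find("DELETED"):
        deleted |= read_deleted_caseids(path)

    cases = assemble_cases(
        tables[TableKind.DEMO],
        tables[TableKind.DRUG],
        tables[TableKind.REAC],
        tables[TableKind.OUTC],
        tables[TableKind.THER],
    )
    return cases, deleted


def write_results(records, path: str | os.PathLike, columns: Sequence[str] | None = None) -> None:
    """Write tabular results as UTF-8 CSV with a header and stable column
    order. Accepts a DataFrame or an iterable of dicts/dataclasses; an empty
    result set with an explicit ``columns`` list yields a header-only file."""
    if records is None:
        raise ValueError("records must not be None")
    if isinstance(records, pd.DataFrame):
        records.to_csv(path, index=False, encoding="utf-8")
        return
    rows = list(records)
    if rows and hasattr(rows[0], "__dataclass_fields__"):
        fields = list(rows[0].__dataclass_fields__)
        rows = [{f: getattr(r, f) for f in fields} for r in rows]
    fieldnames = list(columns) if columns is not None else (list(rows[0].keys()) if rows else [])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if fieldnames:
            writer = csv.DictWriter(fh, fieldnames=fieldnames)
            writer.writeheader()
            writer.writerows(rows)
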