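"""Synthetic FAERS-dialect corpora with known ground truth.

The generator emits DEMO/DRUG/REAC/OUTC/THER tables (plus a deleted-case
list) in the quarterly ASCII dialect, together with a :class:`Ledger`
recording the planted truth for every report: drug assignment, planted
query events, follow-up versions, cross-caseid duplicate clusters, age and
date validity, and true onset days. The ledger also carries the exact
counts the cleaning/cohort/query pipeline must reproduce, computed from
the construction itself (never by running the pipeline), so it serves as
an independent oracle in tests.

Determinism: a fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import datetime as dt
import os
from dataclasses import dataclass, field

import numpy as np

from faerspv.faers_io import (
    DemoRecord,
    DrugRecord,
    OutcRecord,
    ReacRecord,
    TherRecord,
    write_table,
)
from faerspv.meddra_map import SmqDefinition, load_bundled_queries


class ConfigurationError(ValueError):
    pass


#: Verbatim drug-name spellings planted for the study drugs, exercising the
#: case/punctuation/strength variation of real free-text names.
STUDY_DRUG_SPELLINGS = {
    "palbociclib": ["IBRANCE", "Ibrance", "PALBOCICLIB", "IBRANCE 125MG"],
    "ribociclib": ["KISQALI", "RIBOCICLIB", "KISQALI FEMARA CO-PACK", "Kisqali"],
    "abemaciclib": ["VERZENIO", "ABEMACICLIB", "Verzenio (abemaciclib)"],
}
STUDY_DRUG_INGREDIENT = {
    "palbociclib": "PALBOCICLIB",
    "ribociclib": "RIBOCICLIB",
    "abemaciclib": "ABEMACICLIB",
}
BACKGROUND_DRUGS = [
    "LETROZOLE",
    "ANASTROZOLE",
    "FULVESTRANT",
    "METFORMIN",
    "ATORVASTATIN",
    "OMEPRAZOLE",
    "LISINOPRIL",
    "TAMOXIFEN",
]

_COUNTRIES = ["US", "US", "US", "JP", "FR", "DE", "KR", "GB", ""]
_SEXES = ["F"] * 92 + ["M"] * 5 + ["UNK"] * 2 + [""]
_OCCUPATIONS = (
    ["MD"] * 20 + ["PH"] * 10 + ["RN"] * 5 + ["HP"] * 5
    + ["CN"] * 40 + ["OT"] * 10 + ["LW"] * 2 + [""] * 8
)
_NOISE_POOL = [f"Unrelated event {i:03d}" for i in range(1, 401)]

_DATE_REJECT_KINDS = ("non-8-digit", "unparseable", "year-bound", "negative-interval")


def default_queries() -> dict[str, set[str]]:
    """PT sets of the bundled toy queries, keyed by query name."""
    return {name: set(q.pts) for name, q in load_bundled_queries().items()}


@dataclass
class SimConfig:
    """Knobs of the generator. ``planted_rr`` maps (drug_id, query name) to
    the reporting-rate ratio rho: reports of that drug receive the query's
    event with probability rho * background probability."""

    n_reports: int = 1000
    seed: int = 0
    drugs: dict[str, float] = field(
        default_factory=lambda: {"palbociclib": 0.30, "ribociclib": 0.12, "abemaciclib": 0.08}
    )
    query_background: dict[str, float] = field(
        default_factory=lambda: {
            "Toy torsade/QT prolongation": 0.01,
            "Toy cardiac failure": 0.02,
            "Toy hypertension": 0.02,
        }
    )
    planted_rr: dict[tuple[str, str], float] = field(default_factory=dict)
    soc_only_background: float = 0.02  # SOC-member PTs outside any toy SMQ
    followup_rate: float = 0.15
    cross_dup_rate: float = 0.05
    deleted_rate: float = 0.02
    missing_age_rate: float = 0.08
    invalid_age_rate: float = 0.02
    invalid_date_rate: float = 0.20
    tte_lognorm: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "palbociclib": (4.4, 1.2),
            "ribociclib": (4.1, 1.2),
            "abemaciclib": (3.5, 1.1),
            "background": (4.2, 1.1),
        }
    )

    def validate(self, queries: dict[str, set[str]]) -> None:
        if sum(self.drugs.values()) > 1.0 + 1e-12:
            raise ConfigurationError("drug PS probabilities sum above 1")
        for (drug, query), rho in self.planted_rr.items():
            if query not in self.query_background:
                raise ConfigurationError(f"planted_rr names unknown query {query!r}")
            if rho < 0 or not np.isfinite(rho):
                raise ConfigurationError(f"rho for {(drug, query)} must be finite and >= 0")
            if rho * self.query_background[query] > 1:
                raise ConfigurationError(
                    f"rho * background probability exceeds 1 for {(drug, query)}"
                )
        for query in self.query_background:
            if query not in queries:
                raise ConfigurationError(f"no PT list for query {query!r}")


@dataclass
class LedgerEntry:
    caseid: str
    drug: str | None  # study drug id or None for background reports
    pts: tuple[str, ...]
    age_valid: bool
    dates_valid: bool
    date_reject: str | None
    onset_days: int | None
    deleted: bool = False
    dup_cluster: int | None = None
    dup_role: str | None = None  # "original" | "clone"
    n_versions: int = 1


@dataclass
class Ledger:
    """Planted truth plus the exact counts the pipeline must reproduce."""

    entries: dict[str, LedgerEntry]
    deleted_caseids: set[str]
    clusters: list[tuple[str, str]]  # (original caseid, clone caseid)
    expected: dict
    drug_rows_total: int = 0
    reac_rows_total: int = 0


@dataclass
class SyntheticCorpus:
    demo: list[DemoRecord]
    drug: list[DrugRecord]
    reac: list[ReacRecord]
    outc: list[OutcRecord]
    ther: list[TherRecord]
    deleted_caseids: list[str]
    ledger: Ledger | None = None


@dataclass
class _Proto:
    """One base case before serialization to record rows."""

    caseid: str
    fda: dt.date
    event_dt: str
    age: str
    age_cod: str
    age_valid: bool
    sex: str
    occp: str
    country: str
    pts: list[str]
    drugs: list[tuple[str, str, str, str]]  # (role, drugname, prod_ai, start_dt)
    outcomes: list[str]
    drug_id: str | None
    dates_valid: bool
    date_reject: str | None
    onset_days: int | None


def _fmt(d: dt.date) -> str:
    return d.strftime("%Y%m%d")


def generate_corpus(
    config: SimConfig, queries: dict[str, set[str]] | None = None
) -> SyntheticCorpus:
    """Generate a synthetic corpus plus its ground-truth ledger."""
    if queries is None:
        queries = default_queries()
    config.validate(queries)
    rng = np.random.default_rng(config.seed)

    query_names = sorted(config.query_background)
    query_pts = {q: sorted(queries[q]) for q in query_names}
    soc_pts = sorted(queries.get("Toy cardiac disorders", set()))
    smq_union = set().union(*(queries[q] for q in query_names)) if query_names else set()
    soc_only = [pt for pt in soc_pts if pt not in smq_union]

    drug_ids = sorted(config.drugs)
    drug_probs = np.array([config.drugs[d] for d in drug_ids])

    protos: list[_Proto] = []
    epoch = dt.date(2016, 1, 1)
    for i in range(config.n_reports):
        caseid = str(2_000_000 + i)

        # --- drug assignment ---------------------------------------------
        u = rng.random()
        drug_id = None
        acc = 0.0
        for d, p in zip(drug_ids, drug_probs):
            acc += p
            if u < acc:
                drug_id = d
                break
        if drug_id is not None:
            spelling = str(rng.choice(STUDY_DRUG_SPELLINGS[drug_id]))
            prod_ai = STUDY_DRUG_INGREDIENT[drug_id]
        else:
            spelling = str(rng.choice(BACKGROUND_DRUGS))
            prod_ai = spelling
        concomitants = [
            str(rng.choice(BACKGROUND_DRUGS)) for _ in range(int(rng.integers(0, 3)))
        ]

        # --- reactions ----------------------------------------------------
        pts: list[str] = []
        for q in query_names:
            p = config.query_background[q] * config.planted_rr.get((drug_id, q), 1.0)
            if rng.random() < p:
                pts.append(str(rng.choice(query_pts[q])))
        if soc_only and rng.random() < config.soc_only_background:
            pts.append(str(rng.choice(soc_only)))
        for _ in range(1 + int(rng.random() < 0.5)):
            pts.append(str(rng.choice(_NOISE_POOL)))
        # set semantics downstream; keep the written rows unique too
        pts = list(dict.fromkeys(pts))

        # --- age ----------------------------------------------------------
        roll = rng.random()
        if roll < config.missing_age_rate:
            age, age_cod, age_valid = "", "", False
        elif roll < config.missing_age_rate + config.invalid_age_rate:
            age, age_cod, age_valid = "999", "YR", False
        else:
            years = float(np.clip(rng.normal(62.0, 12.0), 18.0, 95.0))
            unit = rng.random()
            if unit < 0.80:
                age, age_cod = f"{years:.2f}", "YR"
            elif unit < 0.90:
                age, age_cod = f"{years / 10.0:.3f}", "DEC"
            elif unit < 0.95:
                age, age_cod = f"{years * 12.0:.1f}", "MON"
            else:
                age, age_cod = f"{years:.2f}", ""  # missing unit, treated as years
            age_valid = True

        # --- dates --------------------------------------------------------
        fda = epoch + dt.timedelta(days=int(rng.integers(0, 2700)))
        event = fda - dt.timedelta(days=int(rng.integers(0, 30)))
        mu, sigma = config.tte_lognorm.get(
            drug_id if drug_id is not None else "background",
            config.tte_lognorm["background"],
        )
        onset = min(int(rng.lognormal(mu, sigma)), 2500)
        start = event - dt.timedelta(days=onset)
        event_raw, start_raw = _fmt(event), _fmt(start)
        dates_valid, reject, onset_out = True, None, onset
        if rng.random() < config.invalid_date_rate:
            kind = _DATE_REJECT_KINDS[int(rng.integers(0, 4))]
            if kind == "non-8-digit":
                start_raw = start_raw[:6]
            elif kind == "unparseable":
                event_raw = event_raw[:6] + "99"
            elif kind == "year-bound":
                start_raw = "1979" + start_raw[4:]
            else:  # negative interval: event strictly before start
                shift = max(onset, 1)
                start_raw = _fmt(event + dt.timedelta(days=shift))
            dates_valid, reject, onset_out = False, kind, None

        drugs = [("PS", spelling, prod_ai, start_raw)]
        drugs += [("C", name, name, "") for name in concomitants]

        outcomes = []
        for code, p in (("HO", 0.20), ("DE", 0.10), ("LT", 0.02), ("DS", 0.01), ("RI", 0.005), ("OT", 0.30)):
            if rng.random() < p:
                outcomes.append(code)

        protos.append(
            _Proto(
                caseid=caseid,
                fda=fda,
                event_dt=event_raw,
                age=age,
                age_cod=age_cod,
                age_valid=age_valid,
                sex=str(rng.choice(_SEXES)),
                occp=str(rng.choice(_OCCUPATIONS)),
                country=str(rng.choice(_COUNTRIES)),
                pts=pts,
                drugs=drugs,
                outcomes=outcomes,
                drug_id=drug_id,
                dates_valid=dates_valid,
                date_reject=reject,
                onset_days=onset_out,
            )
        )

    # --- guarantee distinct dedup keys across base cases ------------------
    # Accidental key collisions would make the cross-caseid dedup remove
    # unplanned reports; disambiguate by appending extra noise terms. The
    # key mirrors the cleaning stage's duplicate identity exactly.
    from faerspv.cleaning import age_to_years
    from faerspv.cohort import normalize_name

    def key(p: _Proto) -> tuple:
        years = age_to_years(p.age, p.age_cod)
        names = tuple(sorted({normalize_name(n or ai) for (_r, n, ai, _s) in p.drugs} - {""}))
        return (
            round(years, 6) if years is not None else None,
            p.event_dt,
            p.country,
            tuple(sorted(p.pts)),
            names,
        )

    seen: set[tuple] = set()
    for p in protos:
        k = key(p)
        j = 0
        while k in seen:
            p.pts.append(_NOISE_POOL[(hash(k) + j) % len(_NOISE_POOL)])
            p.pts = list(dict.fromkeys(p.pts))
            k = key(p)
            j += 1
        seen.add(k)

    # --- deleted cases ----------------------------------------------------
    n_deleted = int(config.n_reports * config.deleted_rate)
    deleted_idx = set(
        rng.choice(config.n_reports, size=n_deleted, replace=False).tolist()
    ) if n_deleted else set()

    # --- follow-up versions ----------------------------------------------
    followup_idx = {i for i in range(config.n_reports) if rng.random() < config.followup_rate}

    # --- cross-caseid duplicate clones (of non-deleted originals) ---------
    clone_idx = [
        i
        for i in range(config.n_reports)
        if i not in deleted_idx and rng.random() < config.cross_dup_rate
    ]

    entries: dict[str, LedgerEntry] = {}
    for i, p in enumerate(protos):
        entries[p.caseid] = LedgerEntry(
            caseid=p.caseid,
            drug=p.drug_id,
            pts=tuple(sorted(p.pts)),
            age_valid=p.age_valid,
            dates_valid=p.dates_valid,
            date_reject=p.date_reject,
            onset_days=p.onset_days,
            deleted=i in deleted_idx,
            n_versions=2 if i in followup_idx else 1,
        )

    demo: list[DemoRecord] = []
    drug_rows: list[DrugRecord] = []
    reac: list[ReacRecord] = []
    outc: list[OutcRecord] = []

    def emit(p: _Proto, caseid: str, version: int, fda: dt.date) -> None:
        primaryid = f"{caseid}{version}"
        demo.append(
            DemoRecord(
                primaryid=primaryid,
                caseid=caseid,
                caseversion=str(version),
                fda_dt=_fmt(fda),
                event_dt=p.event_dt,
                age=p.age,
                age_cod=p.age_cod,
                sex=p.sex,
                occp_cod=p.occp,
                occr_country=p.country,
            )
        )
        for seq, (role, name, ai, start) in enumerate(p.drugs, start=1):
            drug_rows.append(
                DrugRecord(
                    primaryid=primaryid,
                    drug_seq=str(seq),
                    role_cod=role,
                    drugname=name,
                    prod_ai=ai,
                    start_dt=start,
                )
            )
        for pt in p.pts:
            reac.append(ReacRecord(primaryid=primaryid, pt=pt))
        for code in p.outcomes:
            outc.append(OutcRecord(primaryid=primaryid, outc_cod=code))

    for i, p in enumerate(protos):
        emit(p, p.caseid, 1, p.fda)
        if i in followup_idx:
            emit(p, p.caseid, 2, p.fda + dt.timedelta(days=30))

    clusters: list[tuple[str, str]] = []
    for j, i in enumerate(clone_idx):
        p = protos[i]
        clone_caseid = str(4_000_000 + j)
        # clone always more recent than any version of the original
        emit(p, clone_caseid, 1, p.fda + dt.timedelta(days=60))
        clusters.append((p.caseid, clone_caseid))
        entries[p.caseid].dup_cluster = j
        entries[p.caseid].dup_role = "original"
        entries[clone_caseid] = LedgerEntry(
            caseid=clone_caseid,
            drug=p.drug_id,
            pts=tuple(sorted(p.pts)),
            age_valid=p.age_valid,
            dates_valid=p.dates_valid,
            date_reject=p.date_reject,
            onset_days=p.onset_days,
            deleted=False,
            dup_cluster=j,
            dup_role="clone",
        )

    deleted_caseids = {protos[i].caseid for i in sorted(deleted_idx)}

    # --- expected pipeline counts, derived from the construction ----------
    raw_rows = len(demo)
    deleted_rows = sum(entries[c].n_versions for c in deleted_caseids)
    after_deleted = raw_rows - deleted_rows
    distinct_alive = (config.n_reports - len(deleted_caseids)) + len(clusters)
    after_latest = after_deleted - sum(
        entries[p.caseid].n_versions - 1
        for p in protos
        if p.caseid not in deleted_caseids
    )
    assert after_latest == distinct_alive
    # clone outranks the original by FDA date, so the original is removed
    survivors = [
        e
        for e in entries.values()
        if not e.deleted and not (e.dup_role == "original")
    ]
    after_crossdup = after_latest - len(clusters)
    assert after_crossdup == len(survivors)
    final = [e for e in survivors if e.age_valid]
    final_caseids = {e.caseid for e in final}

    per_drug = {d: sum(1 for e in final if e.drug == d) for d in drug_ids}
    flagged = {
        name: sum(1 for e in final if set(e.pts) & queries[name])
        for name in sorted(queries)
    }
    a_counts = {
        (d, name): sum(1 for e in final if e.drug == d and set(e.pts) & queries[name])
        for d in drug_ids
        for name in sorted(queries)
    }
    tte_valid = {
        d: sum(1 for e in final if e.drug == d and e.dates_valid) for d in drug_ids
    }
    onset_days = {
        d: [e.onset_days for e in final if e.drug == d and e.dates_valid]
        for d in drug_ids
    }

    ledger = Ledger(
        entries=entries,
        deleted_caseids=deleted_caseids,
        clusters=clusters,
        expected={
            "raw": raw_rows,
            "after_deleted": after_deleted,
            "deleted_removed": raw_rows - after_deleted,
            "after_latest": after_latest,
            "version_removed": after_deleted - after_latest,
            "after_crossdup": after_crossdup,
            "crossdup_removed": len(clusters),
            "after_age": len(final),
            "age_removed": after_crossdup - len(final),
            "final_caseids": final_caseids,
            "per_drug": per_drug,
            "flagged": flagged,
            "a_counts": a_counts,
            "tte_valid": tte_valid,
            "onset_days": onset_days,
        },
        drug_rows_total=len(drug_rows),
        reac_rows_total=len(reac),
    )
    return SyntheticCorpus(
        demo=demo,
        drug=drug_rows,
        reac=reac,
        outc=outc,
        ther=[],
        deleted_caseids=sorted(deleted_caseids),
        ledger=ledger,
    )


def write_corpus(corpus: SyntheticCorpus, outdir: str | os.PathLike, quarter: str = "24Q1") -> None:
    """Write a corpus as FAERS-dialect quarterly files under ``outdir``."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    write_table(corpus.demo, os.path.join(outdir, f"DEMO{quarter}.txt"))
    write_table(corpus.drug, os.path.join(outdir, f"DRUG{quarter}.txt"))
    write_table(corpus.reac, os.path.join(outdir, f"REAC{quarter}.txt"))
    if corpus.outc:
        write_table(corpus.outc, os.path.join(outdir, f"OUTC{quarter}.txt"))
    if corpus.ther:
        write_table(corpus.ther, os.path.join(outdir, f"THER{quarter}.txt"))
    with open(os.path.join(outdir, f"DELETED{quarter}.txt"), "w", encoding="utf-8") as fh:
        fh.write("caseid\n")
        for caseid in corpus.deleted_caseids:
            fh.write(caseid + "\n")


# ---------------------------------------------------------------------------
# Handcrafted deterministic fixtures
# ---------------------------------------------------------------------------

def _demo(primaryid, caseid, version, fda, event="", age="60", cod="YR",
          sex="F", occp="MD", country="US"):
    return DemoRecord(
        primaryid=primaryid, caseid=caseid, caseversion=str(version),
        fda_dt=fda, event_dt=event, age=age, age_cod=cod, sex=sex,
        occp_cod=occp, occr_country=country,
    )


def _drug(primaryid, seq, role, name, ai="", start=""):
    return DrugRecord(
        primaryid=primaryid, drug_seq=str(seq), role_cod=role,
        drugname=name, prod_ai=ai, start_dt=start,
    )


def make_fixture_suite() -> dict[str, SyntheticCorpus]:
    """Small handcrafted corpora with constructed truth, covering duplicate
    clusters, follow-up chains, every age unit code, every date-rejection
    category, multi-PT and multi-drug reports."""
    suite: dict[str, SyntheticCorpus] = {}

    # Three different caseids, identical dedup identity -> 2 removals.
    dup = SyntheticCorpus(
        demo=[
            _demo("11", "1", 1, "20200101", event="20191215"),
            _demo("21", "2", 1, "20200201", event="20191215"),
            _demo("31", "3", 1, "20200301", event="20191215"),
        ],
        drug=[_drug(p, 1, "PS", "IBRANCE", "PALBOCICLIB") for p in ("11", "21", "31")],
        reac=[ReacRecord(p, "Toy cardiac failure") for p in ("11", "21", "31")],
        outc=[], ther=[], deleted_caseids=[],
    )
    suite["dup_cluster_3"] = dup

    # Every date-rejection category plus one valid pair.
    bad_dates = SyntheticCorpus(
        demo=[
            _demo("101", "10", 1, "20200401", event="20200311"),  # valid, 70 d
            _demo("111", "11", 1, "20200401", event="20200311"),  # 6-digit start
            _demo("121", "12", 1, "20200401", event="20200399"),  # unparseable event
            _demo("131", "13", 1, "20200401", event="20200311"),  # start before 1980
            _demo("141", "14", 1, "20200401", event="20200311"),  # event before start
        ],
        drug=[
            _drug("101", 1, "PS", "IBRANCE", start="20200101"),
            _drug("111", 1, "PS", "IBRANCE", start="197912"),
            _drug("121", 1, "PS", "IBRANCE", start="20200101"),
            _drug("131", 1, "PS", "IBRANCE", start="19791231"),
            _drug("141", 1, "PS", "IBRANCE", start="20200401"),
        ],
        reac=[ReacRecord(p, "Toy QT prolonged") for p in ("101", "111", "121", "131", "141")],
        outc=[], ther=[], deleted_caseids=[],
    )
    suite["date_rejects"] = bad_dates

    all_invalid = SyntheticCorpus(
        demo=[
            _demo("201", "20", 1, "20200401", event="202003"),
            _demo("211", "21", 1, "20200401", event=""),
        ],
        drug=[
            _drug("201", 1, "PS", "IBRANCE", start="20200101"),
            _drug("211", 1, "PS", "IBRANCE", start="20200101"),
        ],
        reac=[ReacRecord("201", "Toy QT prolonged"), ReacRecord("211", "Toy QT prolonged")],
        outc=[], ther=[], deleted_caseids=[],
    )
    suite["all_invalid_dates"] = all_invalid

    # One report per age unit code; expected years in tests: 70, 65, 0.5,
    # 1.0, 2.0, 1.0, 40 (missing code treated as years).
    unit_rows = [
        ("301", "30", "7", "DEC"),
        ("311", "31", "65", "YR"),
        ("321", "32", "6", "MON"),
        ("331", "33", "52.143", "WK"),
        ("341", "34", "730.5", "DY"),
        ("351", "35", "8766", "HR"),
        ("361", "36", "40", ""),
    ]
    suite["unit_codes"] = SyntheticCorpus(
        demo=[
            _demo(p, c, 1, "20200101", event=f"201906{int(c) - 29:02d}", age=a, cod=k)
            for (p, c, a, k) in unit_rows
        ],
        drug=[_drug(p, 1, "PS", "IBRANCE") for (p, _c, _a, _k) in unit_rows],
        reac=[ReacRecord(p, "Toy palpitations") for (p, _c, _a, _k) in unit_rows],
        outc=[], ther=[], deleted_caseids=[],
    )

    # Follow-up chain: three versions of one case, latest wins.
    suite["followup_chain"] = SyntheticCorpus(
        demo=[
            _demo("401", "40", 1, "20190101", event="20181201"),
            _demo("402", "40", 2, "20190601", event="20181201"),
            _demo("403", "40", 3, "20200101", event="20181201"),
        ],
        drug=[_drug(p, 1, "PS", "KISQALI", "RIBOCICLIB") for p in ("401", "402", "403")],
        reac=[ReacRecord(p, "Toy torsade event") for p in ("401", "402", "403")],
        outc=[OutcRecord("403", "HO")], ther=[], deleted_caseids=[],
    )

    # Deleted case + multi-PT, multi-PS-drug report.
    suite["mixed"] = SyntheticCorpus(
        demo=[
            _demo("501", "50", 1, "20210101", event="20201201"),
            _demo("511", "51", 1, "20210101", event="20201111"),
        ],
        drug=[
            _drug("501", 1, "PS", "IBRANCE", "PALBOCICLIB", "20200901"),
            _drug("501", 2, "PS", "KISQALI", "RIBOCICLIB", "20201001"),
            _drug("501", 3, "C", "LETROZOLE"),
            _drug("511", 1, "PS", "VERZENIO", "ABEMACICLIB", "20201001"),
        ],
        reac=[
            ReacRecord("501", "Toy QT prolonged"),
            ReacRecord("501", "Toy atrial fibrillation"),
            ReacRecord("501", "Toy QT prolonged"),
            ReacRecord("511", "Toy cardiac failure"),
        ],
        outc=[OutcRecord("501", "DE"), OutcRecord("501", "HO")],
        ther=[], deleted_caseids=["51"],
    )
    return suite
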