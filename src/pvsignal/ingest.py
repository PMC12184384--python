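"""Reading raw spontaneous-report extracts and building clean case sets.

Two source dialects are supported:

* **FAERS-style** quarterly ASCII extracts: ``$``-delimited text tables
  (DEMO/DRUG/REAC/THER/OUTC/INDI) keyed by PRIMARYID/CASEID, plus optional
  deleted-case lists (one case id per line).
* **JADER-style** extracts: comma-separated DEMO/DRUG/REAC/HIST tables in a
  Japanese legacy codepage, keyed by a per-case identification number.

Both are mapped onto the shared :class:`~pvsignal.model.SafetyReport` type.
Cleaning follows the standard pharmacovigilance workflow: version
deduplication (same case id → keep the most recent receipt date, ties broken
by the higher primary id), removal of centrally deleted cases, restriction
to reports where the target drug is the *primary suspect*, an optional
country exclusion, and PT→SOC coding through a user-supplied MedDRA-style
mapping table.  Every filter reports how many records it dropped so the
full flow is reconstructible as a conservation ledger.
"""

from __future__ import annotations

import collections
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .dates import PartialDate, date_sort_key, parse_date_token
from .model import (
    AdverseEvent,
    DrugEntry,
    SafetyReport,
    UNMAPPED_SOC,
    normalize_term,
)

# ---------------------------------------------------------------------------
# Column vocabularies

FAERS_FILES = ("demo", "drug", "reac", "ther", "outc", "indi")
_FAERS_MANDATORY = {"demo": ("PRIMARYID", "CASEID")}

#: JADER column names → shared vocabulary
JADER_COLUMNS = {
    "識別番号": "CASEID",
    "報告回数": "SEQ",
    "性別": "SEX",
    "年齢": "AGE",
    "体重": "WT",
    "医薬品の関与": "ROLE_COD",
    "医薬品（一般名）": "DRUGNAME",
    "投与開始日": "START_DT",
    "投与終了日": "END_DT",
    "有害事象": "PT",
    "発現日": "EVENT_DT",
    "転帰": "OUTC_COD",
    "原疾患等": "INDI_PT",
}

#: JADER suspect-flag vocabulary → FAERS-style role codes
JADER_ROLE_MAP = {"被疑薬": "PS", "併用薬": "C", "相互作用": "I"}

JADER_SEX_MAP = {"女性": "F", "男性": "M"}

#: outcome codes counted as death when computing case-fatality
DEATH_OUTCOMES = {"DE", "死亡"}


class IngestError(ValueError):
    """Raised for unrecoverable problems in a raw extract."""


@dataclass
class RawTables:
    """Typed row collections parsed from one raw extract."""

    source_db: str
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: Optional[pd.DataFrame] = None
    outc: Optional[pd.DataFrame] = None
    indi: Optional[pd.DataFrame] = None
    malformed: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Parsers


def _read_delimited(path: str | Path, sep: str, encoding: str = "utf-8",
                    text: Optional[str] = None) -> tuple[pd.DataFrame, int]:
    """Read one table, skipping (but counting) rows with a bad field count."""
    bad = []

    def _on_bad(row):  # pragma: no cover - exercised via malformed fixtures
        bad.append(row)
        return None

    src = io.StringIO(text) if text is not None else path
    df = pd.read_csv(
        src,
        sep=sep,
        dtype=str,
        keep_default_na=False,
        engine="python",
        encoding=None if text is not None else encoding,
        on_bad_lines=_on_bad,
    )
    df.columns = [c.strip().upper() for c in df.columns]
    return df, len(bad)


def parse_faers_quarter(paths: dict[str, str | Path]) -> RawTables:
    """Parse a FAERS-style quarter: ``$``-delimited DEMO/DRUG/REAC/... files.

    ``paths`` maps lower-case file kinds (``demo``, ``drug``, ``reac``,
    optionally ``ther``/``outc``/``indi``) to file paths.  Unknown extra
    columns are carried through untouched.  Rows with a wrong field count
    are counted in ``malformed`` and skipped, never fatal; a *missing
    mandatory column* is a hard error naming the file and column.
    """
    tables: dict[str, Optional[pd.DataFrame]] = {k: None for k in FAERS_FILES}
    malformed: dict[str, int] = {}
    for kind in FAERS_FILES:
        if kind not in paths:
            if kind in ("demo", "drug", "reac"):
                raise IngestError(f"required FAERS file missing: {kind}")
            continue
        path = Path(paths[kind])
        if not path.exists():
            raise IngestError(f"file not found: {path}")
        df, nbad = _read_delimited(path, sep="$")
        for col in _FAERS_MANDATORY.get(kind, ()):
            if col not in df.columns:
                raise IngestError(f"{path.name}: mandatory column {col} missing")
        tables[kind] = df
        malformed[kind] = nbad
    return RawTables(
        source_db="FAERS",
        demo=tables["demo"],
        drug=tables["drug"],
        reac=tables["reac"],
        ther=tables["ther"],
        outc=tables["outc"],
        indi=tables["indi"],
        malformed=malformed,
    )


def _decode_file(path: Path, encoding: str) -> str:
    raw = path.read_bytes()
    try:
        return raw.decode(encoding)
    except UnicodeDecodeError as exc:
        raise IngestError(
            f"{path.name}: undecodable byte at offset {exc.start} under encoding {encoding!r}"
        ) from exc


def parse_jader_tables(paths: dict[str, str | Path], encoding: str = "cp932") -> RawTables:
    """Parse JADER-style comma-separated demo/drug/reac/hist tables.

    Files are decoded from ``encoding`` (default the Japanese legacy
    codepage) to UTF-8 before parsing; an undecodable byte is a hard error
    carrying the byte offset.  Japanese column names and the suspect-flag
    vocabulary are mapped onto the shared FAERS-style row types, so all
    downstream stages are dialect-agnostic.
    """
    out: dict[str, Optional[pd.DataFrame]] = {}
    malformed: dict[str, int] = {}
    for kind in ("demo", "drug", "reac", "hist"):
        if kind not in paths:
            if kind == "hist":
                out[kind] = None
                continue
            raise IngestError(f"required JADER file missing: {kind}")
        path = Path(paths[kind])
        if not path.exists():
            raise IngestError(f"file not found: {path}")
        text = _decode_file(path, encoding)
        df, nbad = _read_delimited(path, sep=",", text=text)
        df.columns = [JADER_COLUMNS.get(c, c) for c in df.columns]
        out[kind] = df
        malformed[kind] = nbad
    demo = out["demo"]
    if "CASEID" not in demo.columns:
        raise IngestError("JADER demo: mandatory column 識別番号 (CASEID) missing")
    drug = out["drug"].copy()
    if "ROLE_COD" in drug.columns:
        drug["ROLE_COD"] = drug["ROLE_COD"].map(lambda v: JADER_ROLE_MAP.get(str(v).strip(), "C"))
    return RawTables(
        source_db="JADER",
        demo=demo,
        drug=drug,
        reac=out["reac"],
        indi=out.get("hist"),
        malformed=malformed,
    )


def read_deleted_case_list(paths: Iterable[str | Path]) -> set[str]:
    """Union of deleted case ids from one-id-per-line text files."""
    deleted: set[str] = set()
    for p in paths:
        for line in Path(p).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if line and not line.upper().startswith("CASEID"):
                deleted.add(line)
    return deleted


# ---------------------------------------------------------------------------
# Deduplication


def _primaryid_key(pid: str):
    s = str(pid).strip()
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


def deduplicate_faers(demo: pd.DataFrame) -> pd.DataFrame:
    """One row per CASEID: keep the most recent FDA_DT, ties → higher PRIMARYID.

    A missing FDA_DT sorts lowest, so any dated version of a case outranks
    an undated one.  PRIMARYIDs compare numerically when both parse as
    integers, lexicographically otherwise.  Idempotent by construction.
    """
    df = demo.copy()
    df["_dt_key"] = df.get("FDA_DT", pd.Series("", index=df.index)).map(
        lambda v: date_sort_key(parse_date_token(v))
    )
    df["_pid_key"] = df["PRIMARYID"].map(_primaryid_key)
    df = df.sort_values(["CASEID", "_dt_key", "_pid_key"], kind="mergesort")
    df = df.groupby("CASEID", sort=False).tail(1)
    return df.drop(columns=["_dt_key", "_pid_key"]).reset_index(drop=True)


def deduplicate_jader(demo: pd.DataFrame) -> pd.DataFrame:
    """One row per case id; among resubmissions keep the highest report sequence."""
    if "SEQ" not in demo.columns:
        return demo.drop_duplicates("CASEID", keep="last").reset_index(drop=True)
    df = demo.copy()
    df["_seq"] = pd.to_numeric(df["SEQ"], errors="coerce").fillna(0)
    df = df.sort_values(["CASEID", "_seq"], kind="mergesort").groupby("CASEID", sort=False).tail(1)
    return df.drop(columns=["_seq"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Assembly into SafetyReports


def _age_years(age: str, unit: str) -> Optional[float]:
    try:
        v = float(str(age).strip())
    except (TypeError, ValueError):
        return None
    unit = str(unit).strip().upper()
    factor = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12, "WK": 1 / 52.18, "DY": 1 / 365.25, "HR": 1 / 8766}
    return v * factor.get(unit, 1.0)


def _jader_age_years(text: str) -> Optional[float]:
    digits = "".join(ch for ch in str(text) if ch.isdigit())
    return float(digits) if digits else None


def _jader_weight_kg(text: str) -> Optional[float]:
    digits = "".join(ch for ch in str(text) if ch.isdigit())
    return float(digits) if digits else None


def _norm_sex(v: str) -> str:
    s = str(v).strip().upper()
    if s in {"F", "M"}:
        return s
    return JADER_SEX_MAP.get(str(v).strip(), "unknown")


def assemble_reports(tables: RawTables, country_default: str = "") -> list[SafetyReport]:
    """Join the (already deduplicated) raw tables into SafetyReports.

    The FAERS dialect keys every table by PRIMARYID and carries the report
    onset date in DEMO (EVENT_DT); therapy start dates join from THER onto
    drug entries by drug sequence number.  The JADER dialect keys by case
    id, carries per-event onset dates in REAC and therapy dates in DRUG.
    Reports with no events are dropped (they cannot enter any analysis).
    """
    is_faers = tables.source_db == "FAERS"
    key = "PRIMARYID" if is_faers else "CASEID"

    def _grouped(df: Optional[pd.DataFrame]) -> dict[str, list[dict]]:
        if df is None or key not in df.columns:
            return {}
        out: dict[str, list[dict]] = collections.defaultdict(list)
        for rec in df.to_dict("records"):
            out[str(rec[key]).strip()].append(rec)
        return out

    drug_by = _grouped(tables.drug)
    reac_by = _grouped(tables.reac)
    ther_by = _grouped(tables.ther)
    outc_by = _grouped(tables.outc)
    indi_by = _grouped(tables.indi)

    reports: list[SafetyReport] = []
    for rec in tables.demo.to_dict("records"):
        rid = str(rec[key]).strip()
        case_id = str(rec.get("CASEID", rid)).strip()
        # therapy dates: map drug sequence -> start/end
        ther_dates: dict[str, tuple] = {}
        for t in ther_by.get(rid, []):
            seq = str(t.get("DSG_DRUG_SEQ", t.get("DRUG_SEQ", ""))).strip()
            ther_dates[seq] = (
                parse_date_token(t.get("START_DT")),
                parse_date_token(t.get("END_DT")),
            )
        drugs = []
        for d in drug_by.get(rid, []):
            name = str(d.get("DRUGNAME", "")).strip()
            if not name:
                continue
            role = str(d.get("ROLE_COD", "C")).strip().upper()
            if role not in ("PS", "SS", "C", "I"):
                role = "C"
            if is_faers:
                seq = str(d.get("DRUG_SEQ", "")).strip()
                start, end = ther_dates.get(seq, (None, None))
            else:
                start = parse_date_token(d.get("START_DT"))
                end = parse_date_token(d.get("END_DT"))
            drugs.append(DrugEntry(name=name, role=role, start_date=start, end_date=end))

        demo_event_dt = parse_date_token(rec.get("EVENT_DT")) if is_faers else None
        events = []
        outcomes: list[str] = []
        for e in reac_by.get(rid, []):
            pt = str(e.get("PT", "")).strip()
            if not pt:
                continue
            ev_dt = demo_event_dt if is_faers else parse_date_token(e.get("EVENT_DT"))
            events.append(AdverseEvent(pt=pt, event_date=ev_dt))
            if not is_faers and str(e.get("OUTC_COD", "")).strip():
                outcomes.append(str(e["OUTC_COD"]).strip())
        if not events:
            continue
        if is_faers:
            outcomes = [
                str(o.get("OUTC_COD", "")).strip()
                for o in outc_by.get(rid, [])
                if str(o.get("OUTC_COD", "")).strip()
            ]
        indications = [
            str(i.get("INDI_PT", "")).strip()
            for i in indi_by.get(rid, [])
            if str(i.get("INDI_PT", "")).strip()
        ]
        if is_faers:
            age = _age_years(rec.get("AGE", ""), rec.get("AGE_COD", "YR"))
            weight = None
            try:
                weight = float(str(rec.get("WT", "")).strip())
            except (TypeError, ValueError):
                pass
            country = str(rec.get("REPORTER_COUNTRY", "") or rec.get("OCCR_COUNTRY", "")).strip().upper()
        else:
            age = _jader_age_years(rec.get("AGE", ""))
            weight = _jader_weight_kg(rec.get("WT", ""))
            country = country_default or "JP"
        reports.append(
            SafetyReport(
                report_id=rid,
                case_id=case_id,
                source_db=tables.source_db,
                receipt_date=parse_date_token(rec.get("FDA_DT")),
                sex=_norm_sex(rec.get("SEX", rec.get("GNDR_COD", ""))),
                age_years=age,
                weight_kg=weight,
                country=country,
                reporter_type=str(rec.get("OCCP_COD", "")).strip(),
                outcomes=outcomes,
                indications=indications,
                drugs=drugs,
                events=events,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# Report-level filters (each returns kept reports + dropped count)


def remove_deleted_cases(
    reports: Sequence[SafetyReport], deleted: set[str]
) -> tuple[list[SafetyReport], int]:
    kept = [r for r in reports if r.case_id not in deleted]
    return kept, len(reports) - len(kept)


def filter_target_drug_ps(
    reports: Sequence[SafetyReport], lexicon: Sequence[str]
) -> tuple[list[SafetyReport], int]:
    """Keep reports with ≥1 lexicon drug in the *primary suspect* role.

    Matching is exact after normalization (trim, case-fold, collapse
    whitespace); no substring matching, so combination-product names do not
    leak in.  An empty lexicon is a configuration error.
    """
    if not lexicon:
        raise IngestError("drug lexicon is empty")
    lex = {normalize_term(t) for t in lexicon}
    kept = [
        r
        for r in reports
        if any(d.role == "PS" and normalize_term(d.name) in lex for d in r.drugs)
    ]
    return kept, len(reports) - len(kept)


def exclude_country(
    reports: Sequence[SafetyReport], code: str
) -> tuple[list[SafetyReport], int]:
    """Drop reports whose country equals ``code``; unknown country is kept."""
    code = code.strip().upper()
    kept = [r for r in reports if r.country.strip().upper() != code]
    return kept, len(reports) - len(kept)


# ---------------------------------------------------------------------------
# MedDRA-style PT -> SOC mapping


@dataclass
class MeddraMap:
    """A PT→SOC lookup table (stand-in for a licensed MedDRA dictionary).

    Keys are normalized preferred terms; each PT maps to exactly one SOC.
    """

    mapping: dict[str, str]
    version: str = "unversioned"

    @classmethod
    def from_tsv(cls, path: str | Path, version: str = "") -> "MeddraMap":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        cols = [c.lower() for c in df.columns]
        df.columns = cols
        if "pt" not in cols or "soc" not in cols:
            raise IngestError(f"{path}: PT→SOC map needs 'pt' and 'soc' columns")
        mapping = {normalize_term(r["pt"]): r["soc"].strip() for _, r in df.iterrows()}
        return cls(mapping=mapping, version=version or str(path))

    def lookup(self, pt: str) -> Optional[str]:
        return self.mapping.get(normalize_term(pt))


def map_events(
    reports: Sequence[SafetyReport], meddra: MeddraMap
) -> tuple[list[SafetyReport], collections.Counter]:
    """Annotate every event with its SOC (``UNMAPPED`` when absent from the map)."""
    unmapped: collections.Counter = collections.Counter()
    for r in reports:
        for ev in r.events:
            soc = meddra.lookup(ev.pt)
            if soc is None:
                unmapped[normalize_term(ev.pt)] += 1
                ev.soc = UNMAPPED_SOC
            else:
                ev.soc = soc
    return list(reports), unmapped


# ---------------------------------------------------------------------------
# Demographics summary


def _percent(n: int, denom: int, digits: int = 1) -> float:
    return round(100.0 * n / denom, digits) if denom else 0.0


def summarize_demographics(
    reports: Sequence[SafetyReport],
    top_k: int = 5,
    outcome_denominator: str = "reports",
) -> dict[str, pd.DataFrame]:
    """Counts and percentages by sex, age band, weight band, country, outcome
    and indication.

    Age bands follow each database's reporting convention (18–65 / >65 for
    FAERS-style US data, 20–70 / >70 for JADER-style data).  Demographic
    percentages use the report count as denominator.  Outcome percentages
    use the report count when ``outcome_denominator="reports"`` (the FAERS
    table convention) or the total number of outcome entries when
    ``"entries"`` (the JADER convention, where outcome is recorded per
    event).
    """
    n = len(reports)
    source = reports[0].source_db if reports else "FAERS"
    lo, hi = (18, 65) if source == "FAERS" else (20, 70)

    def _table(counter: dict[str, int], denom: int) -> pd.DataFrame:
        rows = [
            {"category": k, "n": v, "percent": _percent(v, denom)}
            for k, v in counter.items()
        ]
        return pd.DataFrame(rows, columns=["category", "n", "percent"])

    sex = collections.Counter(r.sex for r in reports)
    age = collections.Counter()
    for r in reports:
        if r.age_years is None:
            age["unknown"] += 1
        elif r.age_years < lo:
            age[f"<{lo}"] += 1
        elif r.age_years <= hi:
            age[f"{lo}-{hi}"] += 1
        else:
            age[f">{hi}"] += 1
    weight = collections.Counter()
    for r in reports:
        if r.weight_kg is None:
            weight["unknown"] += 1
        elif r.weight_kg < 50:
            weight["<50"] += 1
        elif r.weight_kg <= 100:
            weight["50-100"] += 1
        else:
            weight[">100"] += 1
    country = collections.Counter(r.country or "unknown" for r in reports)
    outcome = collections.Counter(o for r in reports for o in r.outcomes)
    n_outcome_entries = sum(outcome.values())
    outcome_denom = n if outcome_denominator == "reports" else n_outcome_entries
    indication = collections.Counter(
        normalize_term(i) for r in reports for i in set(r.indications)
    )

    return {
        "sex": _table(dict(sex), n),
        "age": _table(dict(age), n),
        "weight": _table(dict(weight), n),
        "country": _table(dict(country.most_common(top_k)), n),
        "outcome": _table(dict(outcome), outcome_denom),
        "indication": _table(dict(indication.most_common(top_k)), n),
    }


# ---------------------------------------------------------------------------
# End-to-end cleaning with a conservation ledger


def clean_reports(
    tables: RawTables,
    lexicon: Sequence[str],
    meddra: MeddraMap,
    deleted: Optional[set[str]] = None,
    exclude_country_code: Optional[str] = None,
) -> tuple[list[SafetyReport], list[SafetyReport], dict[str, int]]:
    """Full cleaning pass: dedup → deleted-case removal → country exclusion
    → SOC coding → primary-suspect split.

    Returns ``(target_reports, background_reports, ledger)``.  The
    background set is the *whole* cleaned database (target included) — the
    disproportionality denominator — while the target set contains only
    reports where a lexicon drug is the primary suspect.  The ledger's drop
    counts sum back to the assembled input count.
    """
    if tables.source_db == "FAERS":
        demo = deduplicate_faers(tables.demo)
    else:
        demo = deduplicate_jader(tables.demo)
    n_versions = len(tables.demo)
    dedup_dropped = n_versions - len(demo)
    tables = RawTables(
        source_db=tables.source_db,
        demo=demo,
        drug=tables.drug,
        reac=tables.reac,
        ther=tables.ther,
        outc=tables.outc,
        indi=tables.indi,
        malformed=tables.malformed,
    )
    reports = assemble_reports(tables)
    n0 = len(reports)
    reports, n_deleted = remove_deleted_cases(reports, deleted or set())
    n_country = 0
    if exclude_country_code:
        reports, n_country = exclude_country(reports, exclude_country_code)
    background, unmapped = map_events(reports, meddra)
    target, n_not_ps = filter_target_drug_ps(background, lexicon)
    ledger = {
        "demo_rows": n_versions,
        "dropped_duplicate_versions": dedup_dropped,
        "assembled_reports": n0,
        "dropped_deleted_case": n_deleted,
        "dropped_excluded_country": n_country,
        "background_reports": len(background),
        "dropped_not_primary_suspect": n_not_ps,
        "retained_target_reports": len(target),
        "unmapped_pt_occurrences": int(sum(unmapped.values())),
    }
    assert (
        ledger["assembled_reports"]
        - ledger["dropped_deleted_case"]
        - ledger["dropped_excluded_country"]
        == ledger["background_reports"]
    )
    assert (
        ledger["background_reports"] - ledger["dropped_not_primary_suspect"]
        == ledger["retained_target_reports"]
    )
    return target, background, ledger
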