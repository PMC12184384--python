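"""Core record types shared by every pipeline stage.

A :class:`SafetyReport` is one deduplicated case: demographics, outcome
codes, suspect-drug entries, MedDRA-coded events and the dates needed for
time-to-onset work.  Collections of reports round-trip losslessly through a
one-record-per-line JSON interchange format so intermediate pipeline stages
can be inspected and replayed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .dates import PartialDate, parse_date_token

#: drug role vocabulary: primary suspect, secondary suspect, concomitant,
#: interacting — the FAERS ROLE_COD code set.
ROLE_CODES = ("PS", "SS", "C", "I")

UNMAPPED_SOC = "UNMAPPED"


@dataclass
class DrugEntry:
    name: str
    role: str  # one of ROLE_CODES
    start_date: Optional[PartialDate] = None
    end_date: Optional[PartialDate] = None

    def __post_init__(self) -> None:
        if self.role not in ROLE_CODES:
            raise ValueError(f"unknown role code: {self.role!r}")


@dataclass
class AdverseEvent:
    pt: str
    soc: Optional[str] = None
    event_date: Optional[PartialDate] = None


@dataclass
class SafetyReport:
    report_id: str
    case_id: str
    source_db: str  # "FAERS" | "JADER"
    receipt_date: Optional[PartialDate] = None
    sex: str = "unknown"  # "F" | "M" | "unknown"
    age_years: Optional[float] = None
    weight_kg: Optional[float] = None
    country: str = ""
    reporter_type: str = ""
    outcomes: list[str] = field(default_factory=list)
    indications: list[str] = field(default_factory=list)
    drugs: list[DrugEntry] = field(default_factory=list)
    events: list[AdverseEvent] = field(default_factory=list)

    def pts(self) -> list[str]:
        """Distinct preferred terms on this report, first-seen order."""
        seen: dict[str, None] = {}
        for ev in self.events:
            seen.setdefault(ev.pt, None)
        return list(seen)

    def socs(self) -> list[str]:
        """Distinct system organ classes on this report."""
        seen: dict[str, None] = {}
        for ev in self.events:
            seen.setdefault(ev.soc or UNMAPPED_SOC, None)
        return list(seen)

    def earliest_start_date(self, names: Optional[set[str]] = None) -> Optional[PartialDate]:
        """Earliest therapy start among drug entries (optionally name-restricted)."""
        dates = [
            d.start_date
            for d in self.drugs
            if d.start_date is not None and (names is None or d.name in names)
        ]
        return min(dates, key=lambda d: d.sort_key()) if dates else None

    def earliest_event_date(self) -> Optional[PartialDate]:
        dates = [e.event_date for e in self.events if e.event_date is not None]
        return min(dates, key=lambda d: d.sort_key()) if dates else None


# ---------------------------------------------------------------------------
# JSON-lines interchange


def _date_out(d: Optional[PartialDate]) -> Optional[str]:
    return None if d is None else d.token()


def report_to_dict(r: SafetyReport) -> dict:
    return {
        "report_id": r.report_id,
        "case_id": r.case_id,
        "source_db": r.source_db,
        "receipt_date": _date_out(r.receipt_date),
        "sex": r.sex,
        "age_years": r.age_years,
        "weight_kg": r.weight_kg,
        "country": r.country,
        "reporter_type": r.reporter_type,
        "outcomes": list(r.outcomes),
        "indications": list(r.indications),
        "drugs": [
            {
                "name": d.name,
                "role": d.role,
                "start_date": _date_out(d.start_date),
                "end_date": _date_out(d.end_date),
            }
            for d in r.drugs
        ],
        "events": [
            {"pt": e.pt, "soc": e.soc, "event_date": _date_out(e.event_date)}
            for e in r.events
        ],
    }


def report_from_dict(d: dict) -> SafetyReport:
    return SafetyReport(
        report_id=d["report_id"],
        case_id=d["case_id"],
        source_db=d["source_db"],
        receipt_date=parse_date_token(d.get("receipt_date")),
        sex=d.get("sex", "unknown"),
        age_years=d.get("age_years"),
        weight_kg=d.get("weight_kg"),
        country=d.get("country", ""),
        reporter_type=d.get("reporter_type", ""),
        outcomes=list(d.get("outcomes", [])),
        indications=list(d.get("indications", [])),
        drugs=[
            DrugEntry(
                name=x["name"],
                role=x["role"],
                start_date=parse_date_token(x.get("start_date")),
                end_date=parse_date_token(x.get("end_date")),
            )
            for x in d.get("drugs", [])
        ],
        events=[
            AdverseEvent(
                pt=x["pt"],
                soc=x.get("soc"),
                event_date=parse_date_token(x.get("event_date")),
            )
            for x in d.get("events", [])
        ],
    )


def write_reports(reports: Iterable[SafetyReport], path: str | Path) -> int:
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for r in reports:
            fh.write(json.dumps(report_to_dict(r), ensure_ascii=False) + "\n")
            n += 1
    return n


def read_reports(path: str | Path) -> Iterator[SafetyReport]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield report_from_dict(json.loads(line))


def normalize_term(term: str) -> str:
    """Trim, case-fold and collapse internal whitespace."""
    return " ".join(str(term).strip().split()).casefold()
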