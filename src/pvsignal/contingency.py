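"""2×2 drug–event contingency tables.

For each adverse-event term (at PT or SOC level) the database collapses to
the classic four-fold table::

                     target term    other terms
    target drug          a               b
    other drugs          c               d

The counting unit is the *drug–event pair*: a report with k distinct PTs
contributes k pairs (duplicate identical PTs within one report count once).
``a+b`` is the target drug's total event count at the chosen level and
``a+c`` is the term's database-wide count, so a report collection and its
term vocabulary fully determine every table.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import SafetyReport, normalize_term


@dataclass(frozen=True)
class ContingencyTable:
    term: str
    level: str  # "PT" | "SOC"
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def degenerate(self) -> bool:
        """True when any margin is zero — estimators are undefined there."""
        return 0 in (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    @property
    def expected(self) -> float:
        """Expected count of cell *a* under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n


def count_events(reports: Iterable[SafetyReport], level: str = "PT") -> collections.Counter:
    """Multiset of term occurrences: one per (report, distinct term)."""
    if level not in ("PT", "SOC"):
        raise ValueError(f"level must be PT or SOC, got {level!r}")
    counter: collections.Counter = collections.Counter()
    for r in reports:
        terms = r.pts() if level == "PT" else r.socs()
        counter.update(normalize_term(t) for t in set(terms))
    return counter


def build_tables(
    target_counts: Mapping[str, int],
    background_counts: Mapping[str, int],
    level: str = "PT",
) -> list[ContingencyTable]:
    """One table per term observed for the target drug.

    ``background_counts`` must cover the full database (all drugs, target
    included) at the same level.  Terms the target drug never reported
    (a = 0) are not emitted: every estimator is untestable there and the
    case-count signal thresholds exclude them regardless.
    """
    if not target_counts:
        raise ValueError("target event multiset is empty")
    total_target = sum(target_counts.values())
    total_all = sum(background_counts.values())
    tables = []
    for term, a in sorted(target_counts.items()):
        term_total = background_counts.get(term, 0)
        if term_total < a:
            raise ValueError(
                f"background does not cover target: term {term!r} has a={a} > database count {term_total}"
            )
        b = total_target - a
        c = term_total - a
        d = total_all - total_target - c
        tables.append(ContingencyTable(term=term, level=level, a=a, b=b, c=c, d=d))
    return tables


def build_tables_from_reports(
    target_reports: Sequence[SafetyReport],
    background_reports: Sequence[SafetyReport],
    level: str = "PT",
) -> list[ContingencyTable]:
    return build_tables(
        count_events(target_reports, level), count_events(background_reports, level), level
    )


def reporting_rate(a: int, total: int, digits: int = 2) -> float:
    """Share (%) of one term among all of the target drug's events.

    This is the percentage printed beside per-term case counts in
    pharmacovigilance report tables (2 decimals for PT shares by default,
    1 for demographic-style shares).
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= a <= total:
        raise ValueError(f"a={a} outside [0, {total}]")
    return round(100.0 * a / total, digits)
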