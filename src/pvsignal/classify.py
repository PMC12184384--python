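"""Signal classification: four-way positives, expectedness, database overlap
and clinical priority scoring.

A term is a *positive signal* only when all four disproportionality
detectors flag it simultaneously; positives absent from the drug-label term
list are *unexpected*.  Each positive is then graded for clinical priority
on four criteria worth 0–2 points each (reporting rate, signal stability
across detectors, case-fatality, and membership on the Designated /
Important Medical Event lists), with totals of 0–2, 3–5 and 6–8 mapping to
low, medium and high priority.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from scipy import stats

from .contingency import build_tables_from_reports
from .disproportionality import DisproMetrics, Thresholds, compute_all_metrics
from .ingest import DEATH_OUTCOMES, filter_target_drug_ps
from .mgps import MgpsPrior
from .model import SafetyReport, normalize_term

logger = logging.getLogger(__name__)


@dataclass
class SignalRecord:
    term: str
    level: str
    source_db: str
    metrics: DisproMetrics
    positive: bool = False
    unexpected: bool = False


@dataclass
class PriorityScore:
    rate_points: int
    stability_points: int
    fatality_points: int
    relevance_points: int

    @property
    def total(self) -> int:
        return self.rate_points + self.stability_points + self.fatality_points + self.relevance_points

    @property
    def category(self) -> str:
        t = self.total
        return "low" if t <= 2 else ("medium" if t <= 5 else "high")


def intersect_signals(
    metrics: Iterable[DisproMetrics], source_db: str = ""
) -> list[SignalRecord]:
    """Mark each term positive iff all four detector flags are true."""
    return [
        SignalRecord(
            term=m.term, level=m.level, source_db=source_db, metrics=m, positive=m.positive
        )
        for m in metrics
    ]


def flag_unexpected(
    signals: Sequence[SignalRecord], label_terms: Sequence[str]
) -> list[SignalRecord]:
    """Unexpected = positive and not on the product label's term list."""
    if not label_terms:
        warnings.warn("label-term list is empty: every positive signal is unexpected")
    label = {normalize_term(t) for t in label_terms}
    for s in signals:
        s.unexpected = bool(s.positive and normalize_term(s.term) not in label)
    return list(signals)


def cross_database_overlap(
    signals_a: Iterable[SignalRecord], signals_b: Iterable[SignalRecord]
) -> dict[str, list[str]]:
    """Positive-term overlap between two databases at the same level."""
    a = {normalize_term(s.term) for s in signals_a if s.positive}
    b = {normalize_term(s.term) for s in signals_b if s.positive}
    return {
        "overlap": sorted(a & b),
        "a_only": sorted(a - b),
        "b_only": sorted(b - a),
    }


def _rate_points(reporting_rate_pct: float) -> int:
    if reporting_rate_pct > 10.0:
        return 2
    if reporting_rate_pct >= 1.0:
        return 1
    return 0


def _stability_points(n_algorithms: int) -> int:
    if n_algorithms >= 3:
        return 2
    if n_algorithms == 2:
        return 1
    return 0


def _fatality_points(fatality_fraction: float) -> int:
    if fatality_fraction > 0.5:
        return 2
    if fatality_fraction >= 0.25:
        return 1
    return 0


def score_priority(
    term: str,
    reporting_rate_pct: float,
    n_algorithms_positive: int,
    fatality_fraction: float,
    ime_terms: Iterable[str],
    dme_terms: Iterable[str],
) -> PriorityScore:
    """Clinical priority score for one signal, four 0–2-point criteria.

    Reporting rate: >10% → 2, 1–10% → 1, <1% → 0.  Stability: flagged by
    ≥3 of the four detectors → 2, exactly 2 → 1, else 0.  Case-fatality
    (share of reports carrying the term with a death outcome): >50% → 2,
    25–50% → 1, else 0.  Relevance: Designated Medical Event → 2,
    Important Medical Event → 1, else 0; a term on both lists scores as
    DME (logged).
    """
    ime = {normalize_term(t) for t in ime_terms}
    dme = {normalize_term(t) for t in dme_terms}
    key = normalize_term(term)
    if key in dme and key in ime:
        logger.info("term %r on both DME and IME lists; scoring as DME", term)
    relevance = 2 if key in dme else (1 if key in ime else 0)
    return PriorityScore(
        rate_points=_rate_points(reporting_rate_pct),
        stability_points=_stability_points(n_algorithms_positive),
        fatality_points=_fatality_points(fatality_fraction),
        relevance_points=relevance,
    )


def fatality_fraction(reports: Sequence[SafetyReport], term: str) -> float:
    """Share of reports containing ``term`` whose outcome includes death."""
    key = normalize_term(term)
    with_term = [r for r in reports if key in {normalize_term(p) for p in r.pts()}]
    if not with_term:
        return 0.0
    deaths = sum(1 for r in with_term if set(r.outcomes) & DEATH_OUTCOMES)
    return deaths / len(with_term)


def soc_composition_test(
    counts_a: Sequence[int], counts_b: Sequence[int]
) -> tuple[float, float]:
    """Pearson chi-squared comparing two SOC composition vectors.

    The two count vectors (same SOC vocabulary, aligned) form a 2×K table;
    the statistic has K−1 degrees of freedom.  SOCs with zero pooled count
    are dropped (their expected counts are zero on both rows).
    """
    if len(counts_a) != len(counts_b):
        raise ValueError("count vectors must align on the same SOC vocabulary")
    pairs = [(a, b) for a, b in zip(counts_a, counts_b) if a + b > 0]
    if len(pairs) < 2:
        raise ValueError("need at least two SOCs with nonzero pooled count")
    table = list(zip(*pairs))
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def sensitivity_monotherapy(
    target_reports: Sequence[SafetyReport],
    background_reports: Sequence[SafetyReport],
    lexicon: Sequence[str],
    prior: Optional[MgpsPrior] = None,
    thresholds: Optional[Thresholds] = None,
    level: str = "PT",
) -> tuple[list[SafetyReport], list[DisproMetrics]]:
    """Re-run detection on the monotherapy stratum.

    Keeps only target reports whose *entire* drug list matches the lexicon
    (no concomitant, interacting or other-suspect drug of any kind), then
    rebuilds the tables against the unchanged full-database background and
    recomputes all four detectors through the identical code path.
    """
    lex = {normalize_term(t) for t in lexicon}
    mono = [
        r
        for r in target_reports
        if r.drugs and all(normalize_term(d.name) in lex for d in r.drugs)
    ]
    mono, _ = filter_target_drug_ps(mono, list(lexicon))
    if not mono:
        raise ValueError(
            "monotherapy stratum is empty: no report lists only lexicon drugs"
        )
    tables = build_tables_from_reports(mono, background_reports, level)
    metrics = compute_all_metrics(tables, prior, thresholds)
    return mono, metrics
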