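"""Disproportionality statistics on 2×2 report tables.

Four detectors are computed per table, the standard quartet of
spontaneous-report signal mining:

* **ROR** — reporting odds ratio ``ad/bc`` with a Woolf (log-normal) 95% CI.
* **PRR** — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with the
  uncorrected Pearson chi-squared of the table.
* **BCPNN IC** — the information component ``log2`` observed/expected under
  the Bate et al. (1998) Bayesian model, with its closed-form mean and
  variance; ``IC025 = E(IC) − 2·sqrt(V(IC))``.
* **MGPS EBGM** — empirical-Bayes geometric mean under the DuMouchel
  gamma-mixture model (see :mod:`pvsignal.mgps`).

A term is a *positive signal* only when all four detectors clear their
thresholds simultaneously; the per-detector default thresholds follow the
conventional criteria (a ≥ 3 and ROR CI low > 1; a ≥ 3, PRR ≥ 2, χ² ≥ 4;
IC025 > 0; EBGM05 > 2), each overridable in :class:`Thresholds`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .contingency import ContingencyTable
from .mgps import MgpsPrior, mgps_ebgm

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class Thresholds:
    """Per-detector signal thresholds (conventional defaults)."""

    min_cases: int = 3
    ror_ci_low: float = 1.0  # strict >
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0  # strict >
    ebgm05_min: float = 2.0  # strict >


@dataclass
class DisproMetrics:
    term: str
    level: str
    a: int
    ror: float = math.nan
    ror_low: float = math.nan
    ror_high: float = math.nan
    prr: float = math.nan
    chi2: float = math.nan
    ic: float = math.nan
    ic025: float = math.nan
    ebgm: float = math.nan
    ebgm05: float = math.nan
    flag_ror: bool = False
    flag_prr: bool = False
    flag_bcpnn: bool = False
    flag_mgps: bool = False
    estimable: bool = True

    @property
    def flags(self) -> tuple[bool, bool, bool, bool]:
        return (self.flag_ror, self.flag_prr, self.flag_bcpnn, self.flag_mgps)

    @property
    def n_algorithms_positive(self) -> int:
        return sum(self.flags)

    @property
    def positive(self) -> bool:
        return all(self.flags)


def ror(t: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio with Woolf 95% CI: exp(ln ROR ± 1.96·SE).

    Requires all four cells positive; a zero in b, c or d makes the odds
    ratio non-estimable (tables like that are flagged upstream).
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        raise ZeroDivisionError("ROR undefined for tables with a zero cell")
    est = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return est, est * math.exp(-_Z95 * se), est * math.exp(_Z95 * se)


def prr(t: ContingencyTable) -> float:
    if t.c == 0 or t.a + t.b == 0 or t.c + t.d == 0:
        raise ZeroDivisionError("PRR undefined when c = 0 or a margin is empty")
    return (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))


def chi2(t: ContingencyTable) -> float:
    """Uncorrected Pearson chi-squared via the shortcut N(ad−bc)²/(margins)."""
    r1, r0 = t.a + t.b, t.c + t.d
    c1, c0 = t.a + t.c, t.b + t.d
    if 0 in (r1, r0, c1, c0):
        raise ZeroDivisionError("chi-squared undefined for a zero margin")
    return t.n * (t.a * t.d - t.b * t.c) ** 2 / (r1 * r0 * c1 * c0)


def bcpnn_ic(t: ContingencyTable) -> tuple[float, float]:
    """Information component and its lower bound, Bate-1998 closed form.

    Standard hyperparameters: α = β = 2, α₁ = β₁ = 1, γ₁₁ = 1 with
    γ = γ₁₁ (N+α)(N+β) / ((a+b+α₁)(a+c+β₁)), which centres the prior so
    E(IC) → 0 under independence.  IC025 is the conventional
    E(IC) − 2·sqrt(V(IC)).  The priors regularize zero cells, so this is
    defined for every non-empty table.
    """
    a, n = t.a, t.n
    r1 = t.a + t.b  # drug margin
    c1 = t.a + t.c  # event margin
    alpha = beta = 2.0
    alpha1 = beta1 = 1.0
    gamma11 = 1.0
    gamma = gamma11 * (n + alpha) * (n + beta) / ((r1 + alpha1) * (c1 + beta1))
    e_ic = math.log2(
        (a + gamma11) * (n + alpha) * (n + beta)
        / ((n + gamma) * (r1 + alpha1) * (c1 + beta1))
    )
    ln2sq = math.log(2) ** 2
    v_ic = (
        (n - a + gamma - gamma11) / ((a + gamma11) * (1 + n + gamma))
        + (n - r1 + alpha - alpha1) / ((r1 + alpha1) * (1 + n + alpha))
        + (n - c1 + beta - beta1) / ((c1 + beta1) * (1 + n + beta))
    ) / ln2sq
    return e_ic, e_ic - 2.0 * math.sqrt(v_ic)


def evaluate_thresholds(m: DisproMetrics, th: Optional[Thresholds] = None) -> DisproMetrics:
    """Set the per-detector flags in place (and return the metrics)."""
    th = th or Thresholds()
    floor = m.a >= th.min_cases
    m.flag_ror = bool(floor and math.isfinite(m.ror_low) and m.ror_low > th.ror_ci_low)
    m.flag_prr = bool(
        floor
        and math.isfinite(m.prr)
        and math.isfinite(m.chi2)
        and m.prr >= th.prr_min
        and m.chi2 >= th.chi2_min
    )
    m.flag_bcpnn = bool(math.isfinite(m.ic025) and m.ic025 > th.ic025_min)
    m.flag_mgps = bool(math.isfinite(m.ebgm05) and m.ebgm05 > th.ebgm05_min)
    return m


def compute_metrics(
    t: ContingencyTable,
    prior: Optional[MgpsPrior] = None,
    thresholds: Optional[Thresholds] = None,
) -> DisproMetrics:
    """All four detectors for one table.

    Degenerate tables (a zero margin) and zero cells are flagged
    non-estimable for the frequentist detectors rather than
    continuity-corrected; the Bayesian detectors are defined regardless.
    ``prior=None`` skips MGPS (its flag stays False).
    """
    m = DisproMetrics(term=t.term, level=t.level, a=t.a)
    try:
        m.ror, m.ror_low, m.ror_high = ror(t)
        m.prr = prr(t)
        m.chi2 = chi2(t)
    except ZeroDivisionError:
        m.estimable = False
    m.ic, m.ic025 = bcpnn_ic(t)
    if prior is not None and t.expected > 0:
        m.ebgm, m.ebgm05 = mgps_ebgm(t.a, t.expected, prior)
    return evaluate_thresholds(m, thresholds)


def compute_all_metrics(
    tables: Sequence[ContingencyTable],
    prior: Optional[MgpsPrior] = None,
    thresholds: Optional[Thresholds] = None,
) -> list[DisproMetrics]:
    return [compute_metrics(t, prior, thresholds) for t in tables]


def metrics_frame(
    metrics: Sequence[DisproMetrics], tables: Optional[Sequence[ContingencyTable]] = None
) -> pd.DataFrame:
    """Tabular (TSV-ready) view of per-term metrics, signal tables schema."""
    by_term = {(t.term, t.level): t for t in tables} if tables else {}
    rows = []
    for m in metrics:
        t = by_term.get((m.term, m.level))
        rows.append(
            {
                "term": m.term,
                "level": m.level,
                "a": m.a,
                "b": t.b if t else None,
                "c": t.c if t else None,
                "d": t.d if t else None,
                "ROR": m.ror,
                "ROR_CI95_low": m.ror_low,
                "ROR_CI95_high": m.ror_high,
                "PRR": m.prr,
                "chi2": m.chi2,
                "IC": m.ic,
                "IC025": m.ic025,
                "EBGM": m.ebgm,
                "EBGM05": m.ebgm05,
                "flag_ROR": m.flag_ror,
                "flag_PRR": m.flag_prr,
                "flag_BCPNN": m.flag_bcpnn,
                "flag_MGPS": m.flag_mgps,
                "positive": m.positive,
            }
        )
    return pd.DataFrame(rows)
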