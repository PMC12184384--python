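"""Time-to-onset (TTO) analysis and Weibull hazard-shape classification.

TTO is the calendar-day interval between the start of therapy and the onset
of the adverse event.  Only day-precision dates qualify; records with a
missing date, an imprecise (month- or year-only) date, or an onset before
the therapy start are excluded with an explicit reason, so the included and
excluded counts always sum to the candidates.

Included intervals are summarised by median/IQR and a 30-day-bin histogram,
and fitted with a two-parameter Weibull distribution.  The shape parameter
β indexes the hazard trend: a 95% CI entirely below 1 is the *early
failure* pattern (risk front-loaded after exposure), entirely above 1 is
*wear-out* (risk growing with time on drug), and a CI straddling 1 is
indistinguishable from a constant hazard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .dates import PartialDate, Precision
from .model import SafetyReport


@dataclass
class TTORecord:
    report_id: str
    start: Optional[PartialDate]
    event: Optional[PartialDate]
    tto_days: Optional[int]
    status: str  # included | excluded_missing | excluded_imprecise | excluded_negative

    def __post_init__(self) -> None:
        if (self.status == "included") != (self.tto_days is not None):
            raise ValueError("tto_days present iff status is 'included'")
        if self.tto_days is not None and self.tto_days < 0:
            raise ValueError("tto_days must be non-negative")


@dataclass
class WeibullFit:
    scale: float  # α, days
    shape: float  # β
    shape_low: float
    shape_high: float
    loglik: float
    n: int

    def __post_init__(self) -> None:
        if self.scale <= 0 or self.shape <= 0:
            raise ValueError("Weibull parameters must be positive")
        if not (self.shape_low <= self.shape <= self.shape_high):
            raise ValueError("shape CI must bracket the estimate")


def compute_tto(
    report_id: str, start: Optional[PartialDate], event: Optional[PartialDate]
) -> TTORecord:
    """Classify one (start, event) date pair and compute the interval.

    Inclusion requires both dates at day precision and event ≥ start;
    otherwise the record is excluded as missing, imprecise, or negative.
    """
    if start is None or event is None:
        return TTORecord(report_id, start, event, None, "excluded_missing")
    if start.precision is not Precision.DAY or event.precision is not Precision.DAY:
        return TTORecord(report_id, start, event, None, "excluded_imprecise")
    delta = (event.as_date() - start.as_date()).days
    if delta < 0:
        return TTORecord(report_id, start, event, None, "excluded_negative")
    return TTORecord(report_id, start, event, delta, "included")


def tto_records(
    reports: Sequence[SafetyReport], lexicon: Optional[Sequence[str]] = None
) -> list[TTORecord]:
    """One TTO record per report: earliest therapy start (optionally
    restricted to lexicon drugs) against the earliest event date."""
    from .model import normalize_term

    names = {normalize_term(t) for t in lexicon} if lexicon else None
    records = []
    for r in reports:
        if names is None:
            start = r.earliest_start_date()
        else:
            matching = {d.name for d in r.drugs if normalize_term(d.name) in names}
            start = r.earliest_start_date(matching or None) if matching else None
        records.append(compute_tto(r.report_id, start, r.earliest_event_date()))
    return records


#: histogram bin edges in days: (0–30], (30–60], …, (330–360], >360.  Day-0
#: onsets are folded into the first bin.
_BIN_EDGES = list(range(0, 361, 30))


def summarize_tto(records: Sequence[TTORecord]) -> dict:
    """Median, IQR (linear-interpolation quantiles) and 30-day histogram."""
    values = np.array([r.tto_days for r in records if r.status == "included"], dtype=float)
    if values.size == 0:
        raise ValueError("no included TTO records to summarise")
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    bins: list[dict] = []
    n = values.size
    for lo, hi in zip(_BIN_EDGES[:-1], _BIN_EDGES[1:]):
        label = f"{lo + 1}-{hi}"
        count = int(((values > lo) & (values <= hi)).sum())
        if lo == 0:
            count += int((values == 0).sum())
        bins.append({"bin": label, "n": count, "percent": round(100.0 * count / n, 1)})
    over = int((values > _BIN_EDGES[-1]).sum())
    bins.append({"bin": f">{_BIN_EDGES[-1]}", "n": over, "percent": round(100.0 * over / n, 1)})
    return {
        "n": int(n),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "bins": pd.DataFrame(bins),
    }


def _weibull_loglik(x: np.ndarray, scale: float, shape: float) -> float:
    z = x / scale
    return float(
        x.size * (math.log(shape) - math.log(scale))
        + (shape - 1) * np.log(z).sum()
        - (z**shape).sum()
    )


def weibull_fit(
    tto_days: Sequence[float], zero_shift: float = 0.5, min_n: int = 10
) -> WeibullFit:
    """Maximum-likelihood Weibull fit with a normal-approximation CI on β.

    Zero-day onsets are shifted to ``zero_shift`` (the likelihood needs
    strictly positive support).  The shape MLE solves the profile score
    equation by bracketed root finding (deterministic); the scale then has
    the closed form ``(mean(x^β))^{1/β}``.  The 95% CI for β comes from the
    observed information on the log scale, exponentiated so the bounds stay
    positive.
    """
    x = np.asarray(tto_days, dtype=float)
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} intervals, got {x.size}")
    if np.any(x < 0):
        raise ValueError("negative intervals should have been excluded upstream")
    x = np.where(x == 0, zero_shift, x)
    if np.ptp(x) == 0:
        raise ValueError("degenerate data: all intervals identical")

    logx = np.log(x)
    mean_log = logx.mean()

    def score(shape: float) -> float:
        xk = x**shape
        return 1.0 / shape + mean_log - float((xk * logx).sum() / xk.sum())

    lo, hi = 1e-3, 1.0
    while score(hi) > 0 and hi < 1e3:
        hi *= 2.0
    if score(lo) < 0 or score(hi) > 0:
        raise RuntimeError("Weibull shape root bracketing failed")
    shape = float(optimize.brentq(score, lo, hi, xtol=1e-10))
    scale = float((x**shape).mean() ** (1.0 / shape))
    ll = _weibull_loglik(x, scale, shape)

    # observed information on (log scale, log shape), central differences
    def nll(theta):
        return -_weibull_loglik(x, math.exp(theta[0]), math.exp(theta[1]))

    theta_hat = np.array([math.log(scale), math.log(shape)])
    h = 1e-4
    hess = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            t = theta_hat.copy()
            pp = t.copy(); pp[i] += h; pp[j] += h
            pm = t.copy(); pm[i] += h; pm[j] -= h
            mp = t.copy(); mp[i] -= h; mp[j] += h
            mm = t.copy(); mm[i] -= h; mm[j] -= h
            hess[i, j] = (nll(pp) - nll(pm) - nll(mp) + nll(mm)) / (4 * h * h)
    cov = np.linalg.inv(hess)
    se_log_shape = math.sqrt(max(cov[1, 1], 0.0))
    z = 1.959963984540054
    return WeibullFit(
        scale=scale,
        shape=shape,
        shape_low=shape * math.exp(-z * se_log_shape),
        shape_high=shape * math.exp(z * se_log_shape),
        loglik=ll,
        n=int(x.size),
    )


def classify_hazard(fit: WeibullFit) -> str:
    """Hazard-trend class from the shape-parameter CI.

    ``early_failure`` when the CI lies entirely below 1 (decreasing
    hazard), ``wear_out`` entirely above 1, ``random_failure`` otherwise.
    """
    if fit.shape_high < 1.0:
        return "early_failure"
    if fit.shape_low > 1.0:
        return "wear_out"
    return "random_failure"
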