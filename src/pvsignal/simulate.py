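"""Synthetic spontaneous-report generator with known ground truth.

Emits FAERS-dialect (``$``-delimited DEMO/DRUG/REAC/THER/OUTC/INDI files
plus a deleted-case list) and JADER-dialect (comma-separated demo/drug/
reac/hist) raw files from a single simulated truth, so every pipeline stage
— parsing, deduplication, filtering, disproportionality, time-to-onset —
can be exercised offline against planted parameters.

The generative model, per report: a suspect drug (the target drug with a
configurable share, otherwise a background drug), a geometric number of
event draws from a Zipf-weighted PT vocabulary, with planted
``(drug, pt, λ)`` signals multiplying that PT's draw weight for reports of
that drug — λ is the planted relative reporting ratio.  Therapy start and
event dates are generated with a Weibull onset delay, then degraded with
configurable missingness, month/year imprecision, and a small rate of
pre-treatment onsets.  Duplicate cases are emitted as later-dated
resubmissions of the same case id with a higher primary id and perturbed
demographics, so deduplication has observable work to do.

Demographic, outcome and country mixes default to the composition reported
for irinotecan surveillance data (≈46% male, ≈19% death outcomes, ≈3.15
distinct PTs per report, onset-delay Weibull with shape 0.7 and median
≈28 days); the generator makes no attempt to match real per-term
frequencies or co-prescription structure.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ingest import RawTables

TARGET_DRUG_DEFAULT = "IRINOTECAN"

_FAERS_OUTCOMES = ("OT", "HO", "DE", "LT", "DS", "RI", "CA")
_JADER_OUTCOME_MAP = {
    "DE": "死亡", "HO": "軽快", "OT": "回復", "LT": "未回復",
    "DS": "回復したが後遺症あり", "RI": "回復", "CA": "不明",
}
_INDICATIONS = (
    "Colorectal cancer metastatic", "Pancreatic carcinoma", "Colon cancer",
    "Colorectal cancer", "Gastric cancer",
)


@dataclass(frozen=True)
class PlantedSignal:
    drug: str
    pt: str
    lam: float  # true relative reporting ratio λ
    tto_alpha: Optional[float] = None
    tto_beta: Optional[float] = None
    death_prob: Optional[float] = None


@dataclass
class SimConfig:
    """Simulation parameters; the defaults are the study conditions."""

    n_reports: int = 50_000
    seed: int = 0  # mandatory: every run names its seed
    n_drugs: int = 20  # background drug vocabulary size
    n_events: int = 150  # PT vocabulary size
    n_socs: int = 12
    target_drug: str = TARGET_DRUG_DEFAULT
    target_share: float = 0.10  # share of reports with the target as suspect
    planted_signals: list[PlantedSignal] = field(default_factory=list)
    events_per_report_mean: float = 3.15  # geometric draws per report
    max_event_draws: int = 12
    duplicate_rate: float = 0.05
    deleted_rate: float = 0.01
    monotherapy_fraction: float = 0.30
    #: log-normal sd of per-(background drug, PT) draw-weight multipliers —
    #: every drug has its own adverse-event profile, so background
    #: reporting ratios are heterogeneous (the regime the empirical-Bayes
    #: prior is designed for).  The target drug's weights are never
    #: perturbed: its planted λ values stay exact relative ratios.
    background_sigma: float = 0.5
    # date degradation
    date_missing_rate: float = 0.30  # per date field
    date_imprecise_rate: float = 0.08  # per date field (month or year token)
    negative_tto_rate: float = 0.02
    tto_alpha: float = 47.1  # Weibull scale (days): median ≈ 28 d at β = 0.7
    tto_beta: float = 0.7
    # composition mixes
    sex_probs: tuple[float, float, float] = (0.337, 0.456, 0.207)  # F, M, unknown
    death_prob: float = 0.19
    country_mix: dict[str, float] = field(default_factory=lambda: {
        "US": 0.271, "FR": 0.121, "IT": 0.098, "GB": 0.064, "CA": 0.063,
        "JP": 0.125, "OTHER": 0.258,
    })

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if not 0 < self.target_share < 1:
            raise ValueError("target_share must be in (0,1)")
        probs = self._event_probs()
        for s in self.planted_signals:
            if not (s.lam > 0 and math.isfinite(s.lam)):
                raise ValueError(f"planted λ must be positive and finite: {s}")
            idx = self._pt_index(s.pt)
            if s.lam * probs[idx] > 1.0:
                raise ValueError(
                    f"infeasible config: λ={s.lam} at {s.pt!r} forces a per-draw "
                    f"probability above 1"
                )
        total = sum(self.country_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"country mix must sum to 1, got {total}")

    # --- vocabulary helpers -------------------------------------------------
    def pt_name(self, i: int) -> str:
        return f"PT_{i + 1:03d}"

    def soc_name(self, i: int) -> str:
        return f"SOC_{(i % self.n_socs) + 1:02d}"

    def drug_name(self, i: int) -> str:
        return f"DRUG_{i + 1:03d}"

    def _pt_index(self, pt: str) -> int:
        try:
            return int(pt.split("_")[1]) - 1
        except (IndexError, ValueError):
            raise ValueError(f"unknown PT name {pt!r}; expected PT_###")

    def _event_probs(self) -> np.ndarray:
        """Zipf-like background PT draw probabilities."""
        w = 1.0 / np.arange(1, self.n_events + 1, dtype=float)
        return w / w.sum()

    def meddra_map_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pt": [self.pt_name(i) for i in range(self.n_events)],
             "soc": [self.soc_name(i) for i in range(self.n_events)]}
        )


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    pair_truth: pd.DataFrame  # drug, pt, lambda, expected_a
    report_truth: pd.DataFrame  # case_id, primaryid, duplicate_of, true_tto
    deleted_cases: list[str]


@dataclass
class SimulationResult:
    config: SimConfig
    faers: RawTables
    deleted_cases: list[str]
    truth: GroundTruth

    def write_faers(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for kind in ("demo", "drug", "reac", "ther", "outc", "indi"):
            df = getattr(self.faers, kind)
            p = out / f"{kind.upper()}.txt"
            df.to_csv(p, sep="$", index=False)
            paths[kind] = p
        p = out / "deleted_cases.txt"
        p.write_text("\n".join(self.deleted_cases) + ("\n" if self.deleted_cases else ""))
        paths["deleted"] = p
        return paths

    def write_jader(self, out_dir: str | Path, encoding: str = "cp932") -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = jader_tables(self)
        paths = {}
        for kind, df in tables.items():
            p = out / f"{kind}.csv"
            df.to_csv(p, index=False, encoding=encoding)
            paths[kind] = p
        return paths

    def write_truth(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        p1 = out / "truth_pairs.tsv"
        p2 = out / "truth_reports.tsv"
        self.truth.pair_truth.to_csv(p1, sep="\t", index=False)
        self.truth.report_truth.to_csv(p2, sep="\t", index=False)
        return {"pairs": p1, "reports": p2}


def _date_str(base: np.datetime64, offset_days: int) -> str:
    d = pd.Timestamp(base) + pd.Timedelta(days=int(offset_days))
    return f"{d.year:04d}{d.month:02d}{d.day:02d}"


def _degrade(token: str, u_missing: float, u_prec: float, cfg: SimConfig) -> str:
    if u_missing < cfg.date_missing_rate:
        return ""
    if u_prec < cfg.date_imprecise_rate:
        # half month-precision, half year-precision
        return token[:6] if u_prec < cfg.date_imprecise_rate / 2 else token[:4]
    return token


def simulate(config: SimConfig) -> SimulationResult:
    """Generate one database worth of raw tables plus its ground truth.

    Deterministic given ``config.seed``: identical configs produce
    byte-identical files.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reports
    probs = cfg._event_probs()

    # per-report suspect drug: index -1 = target, 0..D-1 = background drugs
    is_target = rng.random(n) < cfg.target_share
    bg_drug = rng.integers(0, cfg.n_drugs, size=n)
    suspect = np.where(is_target, -1, bg_drug)

    # per-drug draw-weight vectors: heterogeneous background profiles,
    # exact base weights for the target drug, planted λ multipliers on top
    weights_by_drug: dict[int, np.ndarray] = {}
    if cfg.background_sigma > 0:
        for di in range(cfg.n_drugs):
            weights_by_drug[di] = probs * rng.lognormal(
                0.0, cfg.background_sigma, size=cfg.n_events
            )
    planted_by_drug: dict[int, list[PlantedSignal]] = {}
    for s in cfg.planted_signals:
        di = -1 if s.drug == cfg.target_drug else int(s.drug.split("_")[1]) - 1
        w = weights_by_drug.setdefault(di, probs.copy())
        w[cfg._pt_index(s.pt)] = w[cfg._pt_index(s.pt)] * s.lam
        planted_by_drug.setdefault(di, []).append(s)

    # number of PT draws per report: geometric, truncated
    p_geom = 1.0 / cfg.events_per_report_mean
    k_draws = np.minimum(rng.geometric(p_geom, size=n), cfg.max_event_draws)

    # draw PT indices per report, grouped by suspect drug for shared weights
    pt_lists: list[np.ndarray] = [None] * n  # type: ignore[list-item]
    for di in np.unique(suspect):
        w = weights_by_drug.get(int(di), probs)
        w = w / w.sum()
        idx = np.flatnonzero(suspect == di)
        total = int(k_draws[idx].sum())
        draws = rng.choice(cfg.n_events, size=total, p=w)
        pos = 0
        for i in idx:
            k = int(k_draws[i])
            pt_lists[i] = np.unique(draws[pos:pos + k])
            pos += k

    # expected a per planted (target-drug) pair given realized draw counts:
    # P(term in report) = 1 - (1 - p̃)^k with p̃ the normalized draw weight
    pair_rows = []
    for di, signals in planted_by_drug.items():
        w = weights_by_drug[di] / weights_by_drug[di].sum()
        idx = np.flatnonzero(suspect == di)
        for s in signals:
            ptil = w[cfg._pt_index(s.pt)]
            expected_a = float((1.0 - (1.0 - ptil) ** k_draws[idx]).sum())
            drug_label = cfg.target_drug if di == -1 else cfg.drug_name(di)
            pair_rows.append({"drug": drug_label, "pt": s.pt, "lambda": s.lam,
                              "expected_a": expected_a})

    # demographics
    sex = rng.choice(["F", "M", ""], size=n, p=list(cfg.sex_probs))
    age = np.where(rng.random(n) < 0.71, rng.integers(18, 90, size=n), -1)
    weight = np.where(rng.random(n) < 0.35, rng.normal(72, 18, size=n).clip(35, 160), -1.0)
    countries = list(cfg.country_mix)
    country = rng.choice(countries, size=n, p=[cfg.country_mix[c] for c in countries])

    # dates: receipt uniform over the 2004–2024 window; start a bit earlier
    epoch = np.datetime64("2004-01-01")
    window_days = (np.datetime64("2024-12-31") - epoch).astype(int)
    start_off = rng.integers(0, window_days - 400, size=n)
    # onset delay per report: Weibull, possibly overridden by a planted signal
    death_p = np.full(n, cfg.death_prob)
    tto = np.zeros(n)
    u = rng.random(n)
    for i in range(n):
        alpha, beta = cfg.tto_alpha, cfg.tto_beta
        for s in planted_by_drug.get(int(suspect[i]), []):
            if cfg._pt_index(s.pt) in pt_lists[i]:
                alpha = s.tto_alpha if s.tto_alpha is not None else alpha
                beta = s.tto_beta if s.tto_beta is not None else beta
                if s.death_prob is not None:
                    death_p[i] = s.death_prob
        tto[i] = alpha * (-math.log(1.0 - u[i])) ** (1.0 / beta)
    tto_days = np.floor(tto).astype(int)
    negative = rng.random(n) < cfg.negative_tto_rate
    tto_days = np.where(negative, -rng.integers(1, 60, size=n), tto_days)
    receipt_off = start_off + np.maximum(tto_days, 0) + rng.integers(5, 90, size=n)

    # outcome codes: death with per-report probability, else a serious mix
    outc_other = rng.choice(["OT", "HO", "LT", "DS", "RI", "CA"], size=n,
                            p=[0.50, 0.39, 0.065, 0.008, 0.004, 0.033])
    is_death = rng.random(n) < death_p
    outcome = np.where(is_death, "DE", outc_other)
    indication = rng.choice(_INDICATIONS, size=n)

    # concomitant drugs
    n_concomitant = np.where(
        rng.random(n) < cfg.monotherapy_fraction, 0, rng.poisson(1.2, size=n) + 1
    )

    # duplicates and deletions
    dup = rng.random(n) < cfg.duplicate_rate
    deleted_mask = rng.random(n) < cfg.deleted_rate

    u_start_m, u_start_p = rng.random(n), rng.random(n)
    u_event_m, u_event_p = rng.random(n), rng.random(n)

    demo_rows, drug_rows, reac_rows, ther_rows, outc_rows, indi_rows = [], [], [], [], [], []
    report_truth_rows = []
    deleted_cases: list[str] = []

    for i in range(n):
        case_num = i + 1
        case_id = f"{case_num}"
        pid = f"{case_num}01"
        receipt = _date_str(epoch, receipt_off[i])
        start_token = _date_str(epoch, start_off[i])
        event_token = _date_str(epoch, start_off[i] + tto_days[i])
        start_out = _degrade(start_token, u_start_m[i], u_start_p[i], cfg)
        event_out = _degrade(event_token, u_event_m[i], u_event_p[i], cfg)
        age_s = "" if age[i] < 0 else str(int(age[i]))
        wt_s = "" if weight[i] < 0 else f"{weight[i]:.1f}"
        drug_label = cfg.target_drug if suspect[i] == -1 else cfg.drug_name(int(suspect[i]))

        demo_rows.append((pid, case_id, receipt, event_out, sex[i], age_s, "YR",
                          wt_s, country[i], "MD"))
        drug_rows.append((pid, case_id, "1", "PS", drug_label))
        ther_rows.append((pid, case_id, "1", start_out, ""))
        for j in range(int(n_concomitant[i])):
            con = cfg.drug_name(int(rng.integers(0, cfg.n_drugs)))
            drug_rows.append((pid, case_id, str(j + 2), "C", con))
        for e in pt_lists[i]:
            reac_rows.append((pid, case_id, cfg.pt_name(int(e))))
        outc_rows.append((pid, case_id, outcome[i]))
        indi_rows.append((pid, case_id, indication[i]))
        report_truth_rows.append({
            "case_id": case_id, "primaryid": pid, "duplicate_of": "",
            "true_tto": int(tto_days[i]), "suspect_drug": drug_label,
            "country": country[i], "death": bool(is_death[i]),
        })
        if dup[i]:
            # resubmission: same case, later receipt date, higher primary id,
            # perturbed demographics — the canonical version is the resubmission
            pid2 = f"{case_num}02"
            receipt2 = _date_str(epoch, receipt_off[i] + int(rng.integers(30, 400)))
            sex2 = rng.choice(["F", "M", ""])
            demo_rows.append((pid2, case_id, receipt2, event_out, sex2, age_s,
                              "YR", wt_s, country[i], "MD"))
            drug_rows.append((pid2, case_id, "1", "PS", drug_label))
            ther_rows.append((pid2, case_id, "1", start_out, ""))
            for e in pt_lists[i]:
                reac_rows.append((pid2, case_id, cfg.pt_name(int(e))))
            outc_rows.append((pid2, case_id, outcome[i]))
            indi_rows.append((pid2, case_id, indication[i]))
            report_truth_rows.append({
                "case_id": case_id, "primaryid": pid2, "duplicate_of": pid,
                "true_tto": int(tto_days[i]), "suspect_drug": drug_label,
                "country": country[i], "death": bool(is_death[i]),
            })
        if deleted_mask[i]:
            deleted_cases.append(case_id)

    faers = RawTables(
        source_db="FAERS",
        demo=pd.DataFrame(demo_rows, columns=[
            "PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "SEX", "AGE",
            "AGE_COD", "WT", "REPORTER_COUNTRY", "OCCP_COD"]),
        drug=pd.DataFrame(drug_rows, columns=[
            "PRIMARYID", "CASEID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME"]),
        reac=pd.DataFrame(reac_rows, columns=["PRIMARYID", "CASEID", "PT"]),
        ther=pd.DataFrame(ther_rows, columns=[
            "PRIMARYID", "CASEID", "DSG_DRUG_SEQ", "START_DT", "END_DT"]),
        outc=pd.DataFrame(outc_rows, columns=["PRIMARYID", "CASEID", "OUTC_COD"]),
        indi=pd.DataFrame(indi_rows, columns=["PRIMARYID", "CASEID", "INDI_PT"]),
    )
    truth = GroundTruth(
        pair_truth=pd.DataFrame(pair_rows, columns=["drug", "pt", "lambda", "expected_a"]),
        report_truth=pd.DataFrame(report_truth_rows),
        deleted_cases=deleted_cases,
    )
    return SimulationResult(config=cfg, faers=faers, deleted_cases=deleted_cases, truth=truth)


def jader_tables(result: SimulationResult) -> dict[str, pd.DataFrame]:
    """Re-express the simulated truth in the JADER column vocabulary.

    One row set per *canonical* case (JADER extracts are already versioned
    by a report-count column, set to 1 here), with the suspect flag in
    Japanese and per-event onset dates/outcomes in REAC.
    """
    faers = result.faers
    canonical = faers.demo.sort_values(["CASEID", "FDA_DT", "PRIMARYID"]).groupby(
        "CASEID", sort=False).tail(1)
    keep = set(canonical["PRIMARYID"])
    sex_map = {"F": "女性", "M": "男性", "": ""}
    role_map = {"PS": "被疑薬", "SS": "被疑薬", "C": "併用薬", "I": "相互作用"}

    demo = pd.DataFrame({
        "識別番号": canonical["CASEID"].values,
        "報告回数": "1",
        "性別": [sex_map.get(s, "") for s in canonical["SEX"]],
        "年齢": [f"{int(float(a)) // 10 * 10}歳代" if a else "" for a in canonical["AGE"]],
        "体重": [f"{int(float(w)) // 10 * 10}kg台" if w else "" for w in canonical["WT"]],
    })
    start_by_pid = dict(zip(faers.ther["PRIMARYID"], faers.ther["START_DT"]))
    drug = faers.drug[faers.drug["PRIMARYID"].isin(keep)]
    drug_df = pd.DataFrame({
        "識別番号": drug["CASEID"].values,
        "医薬品の関与": [role_map.get(r, "併用薬") for r in drug["ROLE_COD"]],
        "医薬品（一般名）": drug["DRUGNAME"].values,
        "投与開始日": [
            start_by_pid.get(p, "") if r == "PS" else ""
            for p, r in zip(drug["PRIMARYID"], drug["ROLE_COD"])
        ],
        "投与終了日": "",
    })
    event_by_pid = dict(zip(faers.demo["PRIMARYID"], faers.demo["EVENT_DT"]))
    outc_by_pid = dict(zip(faers.outc["PRIMARYID"], faers.outc["OUTC_COD"]))
    reac = faers.reac[faers.reac["PRIMARYID"].isin(keep)]
    reac_df = pd.DataFrame({
        "識別番号": reac["CASEID"].values,
        "有害事象": reac["PT"].values,
        "発現日": [event_by_pid.get(p, "") for p in reac["PRIMARYID"]],
        "転帰": [_JADER_OUTCOME_MAP.get(outc_by_pid.get(p, "OT"), "回復")
                 for p in reac["PRIMARYID"]],
    })
    indi = faers.indi[faers.indi["PRIMARYID"].isin(keep)]
    hist_df = pd.DataFrame({
        "識別番号": indi["CASEID"].values,
        "原疾患等": indi["INDI_PT"].values,
    })
    return {"demo": demo, "drug": drug_df, "reac": reac_df, "hist": hist_df}


def generate(config: SimConfig, out_dir: str | Path) -> SimulationResult:
    """Simulate and write the FAERS-dialect files, JADER-dialect files,
    PT→SOC map, and ground-truth TSVs under ``out_dir``."""
    result = simulate(config)
    out = Path(out_dir)
    result.write_faers(out / "faers")
    result.write_jader(out / "jader")
    result.write_truth(out / "truth")
    (out / "meddra_map.tsv").parent.mkdir(parents=True, exist_ok=True)
    config.meddra_map_frame().to_csv(out / "meddra_map.tsv", sep="\t", index=False)
    return result


# ---------------------------------------------------------------------------
# Hand-auditable mini-fixture


def fixture_small() -> tuple[RawTables, list[str], pd.DataFrame]:
    """A deterministic 20-case FAERS-dialect fixture exercising every branch.

    Contents (constructed, not sampled): a duplicate case pair (case 2), a
    deleted case (case 3), a Japan-country report (case 4), a report where
    the target drug is only concomitant (case 5), a report without the
    target drug (case 6), a month-precision start date (case 7), a negative
    onset interval (case 8), and a report with no target drug as PS but a
    secondary suspect (case 9).  Cases 1 and 10–20 are clean target-drug
    reports.  Returns (tables, deleted case ids, PT→SOC map frame).
    """
    target = TARGET_DRUG_DEFAULT
    demo, drug, reac, ther, outc, indi = [], [], [], [], [], []

    def add(case: int, pid_ver: int, receipt: str, event: str, sex: str,
            country: str, drugs: list[tuple[str, str]], pts: list[str],
            start: str, outcome: str = "OT", age: str = "60"):
        pid = f"{case}{pid_ver:02d}"
        cid = str(case)
        demo.append((pid, cid, receipt, event, sex, age, "YR", "70", country, "MD"))
        for seq, (name, role) in enumerate(drugs, start=1):
            drug.append((pid, cid, str(seq), role, name))
            if seq == 1:
                ther.append((pid, cid, str(seq), start, ""))
        for pt in pts:
            reac.append((pid, cid, pt))
        outc.append((pid, cid, outcome))
        indi.append((pid, cid, "Colon cancer"))

    add(1, 1, "20200115", "20200129", "M", "US", [(target, "PS")],
        ["Diarrhoea", "Nausea"], "20200101", outcome="HO")
    # duplicate pair: version 2 has the later receipt date and must win
    add(2, 1, "20200301", "20200310", "F", "US", [(target, "PS")], ["Neutropenia"],
        "20200301")
    add(2, 2, "20210301", "20200310", "M", "US", [(target, "PS")], ["Neutropenia"],
        "20200301")
    # deleted case
    add(3, 1, "20200401", "20200410", "M", "US", [(target, "PS")], ["Vomiting"],
        "20200401")
    # Japan-country report (excluded by the country filter)
    add(4, 1, "20200501", "20200510", "F", "JP", [(target, "PS")], ["Diarrhoea"],
        "20200501")
    # target drug present but only as concomitant -> dropped by the PS filter
    add(5, 1, "20200601", "20200610", "M", "US",
        [("OXALIPLATIN", "PS"), (target, "C")], ["Alopecia"], "20200601")
    # no target drug at all
    add(6, 1, "20200701", "20200710", "F", "US", [("CETUXIMAB", "PS")],
        ["Rash"], "20200701")
    # month-precision start date -> TTO excluded_imprecise
    add(7, 1, "20200801", "20200810", "M", "US", [(target, "PS")], ["Diarrhoea"],
        "202008")
    # onset before therapy start -> TTO excluded_negative
    add(8, 1, "20200901", "20200801", "F", "US", [(target, "PS")], ["Pyrexia"],
        "20200901", outcome="DE")
    # target drug as secondary suspect only -> dropped by the PS filter
    add(9, 1, "20201001", "20201010", "M", "US", [("FLUOROURACIL", "PS"),
        (target, "SS")], ["Stomatitis"], "20201001")
    for case in range(10, 21):
        day = case - 9
        add(case, 1, f"202011{day:02d}", f"202011{day + 10:02d}", "M" if case % 2 else "F",
            "US", [(target, "PS")], ["Diarrhoea"] if case % 2 else ["Neutropenia"],
            f"202011{day:02d}", outcome="DE" if case in (10, 12) else "OT")

    tables = RawTables(
        source_db="FAERS",
        demo=pd.DataFrame(demo, columns=["PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT",
                                          "SEX", "AGE", "AGE_COD", "WT",
                                          "REPORTER_COUNTRY", "OCCP_COD"]),
        drug=pd.DataFrame(drug, columns=["PRIMARYID", "CASEID", "DRUG_SEQ",
                                          "ROLE_COD", "DRUGNAME"]),
        reac=pd.DataFrame(reac, columns=["PRIMARYID", "CASEID", "PT"]),
        ther=pd.DataFrame(ther, columns=["PRIMARYID", "CASEID", "DSG_DRUG_SEQ",
                                          "START_DT", "END_DT"]),
        outc=pd.DataFrame(outc, columns=["PRIMARYID", "CASEID", "OUTC_COD"]),
        indi=pd.DataFrame(indi, columns=["PRIMARYID", "CASEID", "INDI_PT"]),
    )
    deleted = ["3"]
    meddra = pd.DataFrame({
        "pt": ["Diarrhoea", "Nausea", "Vomiting", "Neutropenia", "Stomatitis",
               "Pyrexia", "Rash", "Alopecia"],
        "soc": ["Gastrointestinal disorders", "Gastrointestinal disorders",
                "Gastrointestinal disorders", "Blood and lymphatic system disorders",
                "Gastrointestinal disorders",
                "General disorders and administration site conditions",
                "Skin and subcutaneous tissue disorders",
                "Skin and subcutaneous tissue disorders"],
    })
    return tables, deleted, meddra


def write_fixture_small(out_dir: str | Path) -> dict[str, Path]:
    """Write the mini-fixture as FAERS-dialect files plus map and delete list."""
    tables, deleted, meddra = fixture_small()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for kind in ("demo", "drug", "reac", "ther", "outc", "indi"):
        p = out / f"{kind.upper()}.txt"
        getattr(tables, kind).to_csv(p, sep="$", index=False)
        paths[kind] = p
    (out / "deleted_cases.txt").write_text("\n".join(deleted) + "\n")
    paths["deleted"] = out / "deleted_cases.txt"
    meddra.to_csv(out / "meddra_map.tsv", sep="\t", index=False)
    paths["meddra"] = out / "meddra_map.tsv"
    return paths
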