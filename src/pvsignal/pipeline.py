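"""End-to-end pipeline: raw extracts → cleaned reports → signal tables.

One :class:`RunConfig` drives the whole analysis for one or two databases
(FAERS-dialect and/or JADER-dialect): ingest and clean, build PT- and
SOC-level contingency tables, fit the MGPS prior on the full background,
compute all four detectors, classify and priority-score positive signals,
compare databases, run the monotherapy sensitivity re-analysis, and
summarise time to onset.  Every stage appends to a conservation ledger and
the run manifest records versions, seed and per-filter counts, so the
flow-chart of any run is reconstructible from its outputs alone.
"""

from __future__ import annotations

import collections
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    cross_database_overlap,
    fatality_fraction,
    flag_unexpected,
    intersect_signals,
    score_priority,
    sensitivity_monotherapy,
    soc_composition_test,
)
from .contingency import build_tables_from_reports, count_events, reporting_rate
from .disproportionality import Thresholds, compute_all_metrics, metrics_frame
from .ingest import (
    MeddraMap,
    clean_reports,
    parse_faers_quarter,
    parse_jader_tables,
    read_deleted_case_list,
    summarize_demographics,
)
from .mgps import MgpsPrior, mgps_fit_prior
from .model import SafetyReport, normalize_term, write_reports
from .tto import classify_hazard, summarize_tto, tto_records, weibull_fit


def drug_event_cells(reports: Sequence[SafetyReport]) -> pd.DataFrame:
    """Observed and independence-expected counts for every (suspect drug, PT)
    cell of a database — the MGPS prior's training set.

    A report contributes one count per (primary-suspect drug, distinct PT)
    pair; expected counts are row-total × column-total / N.
    """
    counts: collections.Counter = collections.Counter()
    for r in reports:
        suspects = {normalize_term(d.name) for d in r.drugs if d.role == "PS"}
        for drug in suspects:
            for pt in {normalize_term(p) for p in r.pts()}:
                counts[(drug, pt)] += 1
    if not counts:
        raise ValueError("no primary-suspect drug-event pairs in the database")
    df = pd.DataFrame(
        [(d, p, a) for (d, p), a in counts.items()], columns=["drug", "pt", "a"]
    )
    n = df["a"].sum()
    row = df.groupby("drug")["a"].transform("sum")
    col = df.groupby("pt")["a"].transform("sum")
    df["expected"] = row * col / n
    return df


def fit_database_prior(
    reports: Sequence[SafetyReport], seed: int = 0
) -> MgpsPrior:
    cells = drug_event_cells(reports)
    return mgps_fit_prior(cells["a"].to_numpy(), cells["expected"].to_numpy(), seed=seed)


@dataclass
class RunConfig:
    faers_dir: Optional[Path] = None
    jader_dir: Optional[Path] = None
    lexicon_path: Optional[Path] = None
    meddra_map_path: Optional[Path] = None
    label_terms_path: Optional[Path] = None
    ime_path: Optional[Path] = None
    dme_path: Optional[Path] = None
    exclude_country_code: Optional[str] = "JP"
    out_dir: Path = Path("pvsignal_out")
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    jader_encoding: str = "cp932"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        th = Thresholds(**raw.pop("thresholds", {}))
        paths = {}
        for k, v in raw.items():
            if v is not None and (k.endswith("_dir") or k.endswith("_path")):
                paths[k] = Path(v)
            else:
                paths[k] = v
        cfg = cls(**paths, thresholds=th)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.faers_dir is None and self.jader_dir is None:
            raise ValueError("configure at least one of faers_dir / jader_dir")
        for name in ("faers_dir", "jader_dir", "lexicon_path", "meddra_map_path",
                     "label_terms_path", "ime_path", "dme_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")


def _read_term_list(path: Optional[Path]) -> list[str]:
    if path is None:
        return []
    return [
        line.strip()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.startswith("#")
    ]


def _faers_paths(data_dir: Path) -> dict[str, Path]:
    paths = {}
    for kind in ("demo", "drug", "reac", "ther", "outc", "indi"):
        for cand in data_dir.glob(f"{kind.upper()}*.txt"):
            paths[kind] = cand
            break
    return paths


def annual_counts(
    reports: Sequence[SafetyReport], window: tuple[int, int] = (2004, 2024)
) -> pd.DataFrame:
    """Report counts per receipt year, restricted to the study window."""
    years = [r.receipt_date.year for r in reports if r.receipt_date is not None]
    counter = collections.Counter(y for y in years if window[0] <= y <= window[1])
    outside = sum(1 for y in years if not window[0] <= y <= window[1])
    if outside:
        warnings.warn(f"{outside} reports dated outside the study window {window}")
    return pd.DataFrame(
        sorted(counter.items()), columns=["year", "n"]
    )


def analyze_database(
    target: Sequence[SafetyReport],
    background: Sequence[SafetyReport],
    lexicon: Sequence[str],
    label_terms: Sequence[str],
    ime_terms: Sequence[str],
    dme_terms: Sequence[str],
    thresholds: Thresholds,
    seed: int = 0,
    source_db: str = "FAERS",
) -> dict:
    """All analysis stages for one cleaned database; returns a result bundle."""
    prior = fit_database_prior(background, seed=seed)
    out: dict = {"prior": prior}

    for level in ("PT", "SOC"):
        tables = build_tables_from_reports(target, background, level)
        metrics = compute_all_metrics(tables, prior, thresholds)
        out[f"tables_{level}"] = tables
        out[f"metrics_{level}"] = metrics
        out[f"frame_{level}"] = metrics_frame(metrics, tables)

    signals = intersect_signals(out["metrics_PT"], source_db=source_db)
    signals = flag_unexpected(signals, label_terms)
    out["signals"] = signals

    total_events = sum(t.a for t in out["tables_PT"])
    priority_rows = []
    for s in signals:
        if not s.positive:
            continue
        rate = reporting_rate(s.metrics.a, total_events)
        score = score_priority(
            s.term, rate, s.metrics.n_algorithms_positive,
            fatality_fraction(target, s.term), ime_terms, dme_terms,
        )
        priority_rows.append({
            "term": s.term, "a": s.metrics.a, "reporting_rate_pct": rate,
            "unexpected": s.unexpected,
            "rate_points": score.rate_points,
            "stability_points": score.stability_points,
            "fatality_points": score.fatality_points,
            "relevance_points": score.relevance_points,
            "total": score.total, "category": score.category,
        })
    out["priority"] = pd.DataFrame(priority_rows, columns=[
        "term", "a", "reporting_rate_pct", "unexpected", "rate_points",
        "stability_points", "fatality_points", "relevance_points", "total",
        "category"])

    # monotherapy sensitivity re-analysis (may be empty on tiny inputs)
    try:
        mono, mono_metrics = sensitivity_monotherapy(
            target, background, lexicon, prior, thresholds
        )
        out["sensitivity"] = metrics_frame(mono_metrics)
        out["n_monotherapy"] = len(mono)
    except ValueError:
        out["sensitivity"] = pd.DataFrame()
        out["n_monotherapy"] = 0

    # time to onset
    records = tto_records(target, lexicon)
    status = collections.Counter(r.status for r in records)
    out["tto_records"] = records
    out["tto_status"] = dict(status)
    included = [r.tto_days for r in records if r.status == "included"]
    if included:
        out["tto_summary"] = summarize_tto(records)
        if len(included) >= 10 and len(set(included)) > 1:
            fit = weibull_fit(included)
            out["weibull"] = fit
            out["hazard_class"] = classify_hazard(fit)
    out["annual"] = annual_counts(target)
    out["demographics"] = summarize_demographics(
        target,
        outcome_denominator="reports" if source_db == "FAERS" else "entries",
    )
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured run end to end and write the output bundle.

    Outputs per database: demographics, SOC signal table, PT signal table,
    priority table, sensitivity table, TTO summary, annual counts, and the
    cleaned-report interchange file; plus an overlap table when both
    databases are configured, and a machine-readable run manifest carrying
    the per-stage conservation ledgers.
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lexicon = _read_term_list(cfg.lexicon_path)
    label_terms = _read_term_list(cfg.label_terms_path)
    ime = _read_term_list(cfg.ime_path)
    dme = _read_term_list(cfg.dme_path)
    meddra = MeddraMap.from_tsv(cfg.meddra_map_path) if cfg.meddra_map_path else MeddraMap({})

    manifest: dict = {"pvsignal_version": __version__, "seed": cfg.seed, "databases": {}}
    results: dict = {"manifest": manifest}

    for db, data_dir in (("FAERS", cfg.faers_dir), ("JADER", cfg.jader_dir)):
        if data_dir is None:
            continue
        data_dir = Path(data_dir)
        if db == "FAERS":
            tables = parse_faers_quarter(_faers_paths(data_dir))
            deleted_files = sorted(data_dir.glob("deleted*"))
            deleted = read_deleted_case_list(deleted_files) if deleted_files else set()
            target, background, ledger = clean_reports(
                tables, lexicon, meddra, deleted, cfg.exclude_country_code
            )
        else:
            paths = {k: data_dir / f"{k}.csv" for k in ("demo", "drug", "reac", "hist")
                     if (data_dir / f"{k}.csv").exists()}
            tables = parse_jader_tables(paths, encoding=cfg.jader_encoding)
            target, background, ledger = clean_reports(tables, lexicon, meddra)
        ledger["malformed_rows"] = dict(tables.malformed)
        analysis = analyze_database(
            target, background, lexicon, label_terms, ime, dme,
            cfg.thresholds, seed=cfg.seed, source_db=db,
        )
        results[db] = analysis
        results[f"{db}_target"] = target
        manifest["databases"][db] = {
            "ledger": ledger,
            "tto_status": analysis.get("tto_status", {}),
            "n_positive_signals": int(sum(s.positive for s in analysis["signals"])),
            "n_monotherapy": analysis.get("n_monotherapy", 0),
        }

        db_dir = out_dir / db.lower()
        db_dir.mkdir(exist_ok=True)
        write_reports(target, db_dir / "reports.jsonl")
        analysis["frame_PT"].to_csv(db_dir / "pt_signals.tsv", sep="\t", index=False)
        analysis["frame_SOC"].to_csv(db_dir / "soc_signals.tsv", sep="\t", index=False)
        analysis["priority"].to_csv(db_dir / "priority.tsv", sep="\t", index=False)
        analysis["sensitivity"].to_csv(db_dir / "sensitivity.tsv", sep="\t", index=False)
        analysis["annual"].to_csv(db_dir / "annual_counts.tsv", sep="\t", index=False)
        demo_frames = []
        for section, frame in analysis["demographics"].items():
            frame = frame.assign(section=section)
            demo_frames.append(frame)
        pd.concat(demo_frames).to_csv(db_dir / "demographics.tsv", sep="\t", index=False)
        if "tto_summary" in analysis:
            s = analysis["tto_summary"]
            s["bins"].to_csv(db_dir / "tto_bins.tsv", sep="\t", index=False)
            tto_row = {"n": s["n"], "median": s["median"], "q1": s["q1"], "q3": s["q3"]}
            if "weibull" in analysis:
                fit = analysis["weibull"]
                tto_row.update(
                    weibull_scale=fit.scale, weibull_shape=fit.shape,
                    shape_ci_low=fit.shape_low, shape_ci_high=fit.shape_high,
                    hazard_class=analysis["hazard_class"],
                )
            pd.DataFrame([tto_row]).to_csv(db_dir / "tto_summary.tsv", sep="\t", index=False)

    if "FAERS" in results and "JADER" in results:
        overlap = cross_database_overlap(results["FAERS"]["signals"],
                                         results["JADER"]["signals"])
        results["overlap"] = overlap
        pd.DataFrame(
            [(t, "both") for t in overlap["overlap"]]
            + [(t, "faers_only") for t in overlap["a_only"]]
            + [(t, "jader_only") for t in overlap["b_only"]],
            columns=["term", "where"],
        ).to_csv(out_dir / "overlap.tsv", sep="\t", index=False)
        manifest["overlap_count"] = len(overlap["overlap"])
        # SOC composition comparison
        soc_a = count_events(results["FAERS_target"], "SOC")
        soc_b = count_events(results["JADER_target"], "SOC")
        vocab = sorted(set(soc_a) | set(soc_b))
        try:
            stat, p = soc_composition_test(
                [soc_a.get(s, 0) for s in vocab], [soc_b.get(s, 0) for s in vocab]
            )
            manifest["soc_composition_chi2"] = stat
            manifest["soc_composition_p"] = p
        except ValueError:
            pass

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return results
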