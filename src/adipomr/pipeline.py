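"""Orchestration of the full multi-outcome MR study design.

For each binary outcome: harmonize the instruments, run the primary
random-effects IVW analysis, then the sensitivity sequence (MR-PRESSO
outlier exclusion, weighted median, MR-Egger), classify the evidence tier
against a Bonferroni-corrected family threshold, and emit a forest-style
report table sorted by descending primary odds ratio. Optionally runs
multivariable MR when a second exposure file is supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import diagnostics, estimators, presso as presso_mod
from .sumstats import (
    InstrumentSet,
    harmonize,
    read_summary_stats,
    select_instruments,
)

__all__ = [
    "AnalysisConfig",
    "AnalysisResult",
    "bonferroni_threshold",
    "classify_evidence",
    "run_analysis",
]

TIERS = ("significant", "suggestive", "null")
DEFAULT_METHODS = ("ivw", "presso", "weighted_median", "mr_egger")


@dataclass
class BonferroniThreshold:
    exact: float
    display: str  # two significant figures, e.g. "3.6e-03"


def bonferroni_threshold(alpha_family: float, n_outcomes: int) -> BonferroniThreshold:
    """Family-wise threshold alpha / n_outcomes, exact and at 2 s.f."""
    if n_outcomes < 1:
        raise ValueError("n_outcomes must be at least 1")
    if not 0.0 < alpha_family < 1.0:
        raise ValueError("alpha_family must be in (0, 1)")
    exact = alpha_family / n_outcomes
    return BonferroniThreshold(exact=exact, display=f"{exact:.1e}")


def classify_evidence(pval: float, threshold: float, alpha_family: float = 0.05) -> str:
    """Evidence tier: strict '<' at the corrected threshold, then the
    uncorrected family alpha; boundary values fall into the weaker tier."""
    if not 0.0 < pval <= 1.0:
        raise ValueError("pval must be in (0, 1]")
    if pval < threshold:
        return "significant"
    if pval < alpha_family:
        return "suggestive"
    return "null"


@dataclass
class AnalysisConfig:
    """Configuration for one exposure against a family of binary outcomes."""

    exposure_file: str
    outcome_files: dict[str, str]
    second_exposure_file: Optional[str] = None
    methods: tuple[str, ...] = DEFAULT_METHODS
    alpha_family: float = 0.05
    n_outcomes: Optional[int] = None          # defaults to len(outcome_files)
    p_threshold: float = 5e-8
    min_info: float = 0.8
    min_hwe_p: float = 1e-6
    palindromic_eaf_window: float = 0.08
    presso_n_sim: int = 1000
    presso_alpha: float = 0.10
    presso_multiple_testing: str = "bonferroni"
    n_boot: int = 1000
    n_cases: dict = field(default_factory=dict)  # optional per-outcome case counts
    exposure_name: str = "exposure"
    unit: str = "kg/m^2"
    seed: int = 0
    out_dir: Optional[str] = None
    sort_report: bool = True

    def __post_init__(self) -> None:
        if not self.outcome_files:
            raise ValueError("at least one outcome file is required")
        self.methods = tuple(self.methods)
        if self.n_outcomes is None:
            self.n_outcomes = len(self.outcome_files)
        if self.n_outcomes < 1:
            raise ValueError("n_outcomes must be at least 1")
        if not 0.0 < self.alpha_family < 1.0:
            raise ValueError("alpha_family must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class AnalysisResult:
    report: pd.DataFrame
    estimates: pd.DataFrame
    log: list[str]
    instrument_sets: dict[str, InstrumentSet] = field(default_factory=dict)


def _fmt_or(est: estimators.MREstimate) -> str:
    return f"{est.odds_ratio:.2f} ({est.or_ci_low:.2f}-{est.or_ci_high:.2f})"


def _analyse_outcome(
    name: str,
    instruments: InstrumentSet,
    config: AnalysisConfig,
    seed: int,
    log: list[str],
) -> tuple[dict, list[dict]]:
    row: dict = {"outcome": name, "n_snps": len(instruments)}
    estimates: list[dict] = []

    primary = estimators.ivw(instruments, "multiplicative_random")
    row["ivw_or"] = _fmt_or(primary)
    row["ivw_p"] = primary.pval
    row["_primary_or"] = primary.odds_ratio
    row["_primary_p"] = primary.pval
    estimates.append({**primary.to_dict(), "outcome": name})

    if "presso" in config.methods and len(instruments) >= 4:
        res = presso_mod.presso(
            instruments,
            n_sim=config.presso_n_sim,
            seed=seed,
            alpha=config.presso_alpha,
            multiple_testing=config.presso_multiple_testing,
        )
        row["presso_global_p"] = res.global_p
        row["presso_n_outliers"] = len(res.outliers)
        if res.outliers:
            log.append(f"{name}: MR-PRESSO outliers {','.join(res.outliers)}")
        corrected = res.corrected_estimate
        row["presso_or"] = _fmt_or(corrected)
        row["presso_p"] = corrected.pval
        estimates.append(
            {**corrected.to_dict(), "method": "presso_corrected_ivw", "outcome": name}
        )

    if "weighted_median" in config.methods and len(instruments) >= 3:
        wm = estimators.weighted_median(instruments, n_boot=config.n_boot, seed=seed + 1)
        row["wmedian_or"] = _fmt_or(wm)
        row["wmedian_p"] = wm.pval
        estimates.append({**wm.to_dict(), "outcome": name})

    if "mr_egger" in config.methods and len(instruments) >= 3:
        egger = estimators.mr_egger(instruments)
        row["egger_or"] = _fmt_or(egger)
        row["egger_p"] = egger.pval
        row["egger_intercept_p"] = egger.egger_intercept_pval
        estimates.append({**egger.to_dict(), "outcome": name})

    return row, estimates


def run_analysis(config: AnalysisConfig) -> AnalysisResult:
    """Run the configured analysis for every outcome; deterministic given seed.

    A failed outcome (unreadable file, empty harmonized set, estimator error)
    yields a report row carrying the failure reason; the run continues.
    """
    log: list[str] = []
    parsed = read_summary_stats(config.exposure_file)
    for lineno, reason in parsed.rejected:
        log.append(f"exposure line {lineno}: rejected ({reason})")
    selection = select_instruments(
        parsed.records, config.p_threshold, config.min_info, config.min_hwe_p
    )
    for vid, reason in selection.dropped:
        log.append(f"exposure {vid}: excluded ({reason})")
    exposure_records = selection.kept

    exposure2_records = None
    if config.second_exposure_file:
        parsed2 = read_summary_stats(config.second_exposure_file)
        sel2 = select_instruments(
            parsed2.records, config.p_threshold, config.min_info, config.min_hwe_p
        )
        exposure2_records = parsed2.records  # second exposure enters jointly, unfiltered
        for vid, reason in sel2.dropped:
            log.append(f"second exposure {vid}: note ({reason})")

    thr = bonferroni_threshold(config.alpha_family, config.n_outcomes)
    log.append(f"bonferroni threshold: {thr.exact:.6g} (displayed {thr.display})")

    master = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(len(config.outcome_files))]

    rows: list[dict] = []
    all_estimates: list[dict] = []
    instrument_sets: dict[str, InstrumentSet] = {}
    for (name, path), seed in zip(config.outcome_files.items(), seeds):
        try:
            parsed_out = read_summary_stats(path)
            for lineno, reason in parsed_out.rejected:
                log.append(f"{name} line {lineno}: rejected ({reason})")
            inst = harmonize(
                exposure_records,
                parsed_out.records,
                second_exposure_records=exposure2_records,
                palindromic_eaf_window=config.palindromic_eaf_window,
                exposure_name=config.exposure_name,
                unit=config.unit,
            )
            for vid, reason in inst.dropped:
                log.append(f"{name} {vid}: dropped ({reason})")
            if len(inst) == 0:
                raise ValueError("no instruments after harmonization")
            instrument_sets[name] = inst
            row, estimates = _analyse_outcome(name, inst, config, seed, log)
            if exposure2_records is not None and inst.has_second_exposure:
                mv = estimators.mvmr(inst, (config.exposure_name, "exposure2"))
                for est in mv.values():
                    if est is not None:
                        all_estimates.append({**est.to_dict(), "outcome": name})
            row["n_cases"] = config.n_cases.get(name)
            row["tier"] = classify_evidence(row["_primary_p"], thr.exact, config.alpha_family)
            rows.append(row)
            all_estimates.extend(estimates)
        except (ValueError, OSError) as exc:
            log.append(f"{name}: FAILED ({exc})")
            rows.append({"outcome": name, "tier": "failed", "failure": str(exc)})

    report = pd.DataFrame(rows)
    if config.sort_report and "_primary_or" in report.columns:
        report = report.sort_values(
            "_primary_or", ascending=False, na_position="last", kind="mergesort"
        ).reset_index(drop=True)
    report = report.drop(columns=[c for c in ("_primary_or", "_primary_p") if c in report.columns])
    estimates_df = pd.DataFrame(all_estimates)

    result = AnalysisResult(
        report=report, estimates=estimates_df, log=log, instrument_sets=instrument_sets
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "report.tsv", sep="\t", index=False, float_format="%.6g")
        estimates_df.to_csv(out / "estimates.tsv", sep="\t", index=False, float_format="%.10g")
        (out / "log.txt").write_text("\n".join(log) + "\n")
    return result
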