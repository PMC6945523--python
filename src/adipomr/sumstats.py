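"""Reading, validation, instrument selection, and allele harmonization of
GWAS summary statistics.

File dialect: tab-separated, UTF-8, header row with required columns
``variant_id effect_allele other_allele beta se pval n`` and optional
``eaf info hwe_p``. Betas are per effect-allele copy (exposure units for
continuous traits, log odds ratios for binary ones).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SummaryStatRecord",
    "HarmonizedInstrument",
    "InstrumentSet",
    "ParsedSumstats",
    "SelectionResult",
    "read_summary_stats",
    "write_summary_stats",
    "records_to_frame",
    "frame_to_records",
    "select_instruments",
    "harmonize",
]

REQUIRED_COLUMNS = ["variant_id", "effect_allele", "other_allele", "beta", "se", "pval", "n"]
OPTIONAL_COLUMNS = ["eaf", "info", "hwe_p"]

VALID_ALLELES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SummaryStatRecord:
    """One SNP's association with one trait, oriented to its effect allele."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: float
    eaf: Optional[float] = None
    info: Optional[float] = None
    hwe_p: Optional[float] = None

    def invalid_reason(self) -> Optional[str]:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            return "invalid allele code"
        if self.effect_allele == self.other_allele:
            return "effect and other allele identical"
        if not self.se > 0:
            return "non-positive SE"
        if not 0.0 < self.pval <= 1.0:
            return "p-value outside (0, 1]"
        if self.eaf is not None and not 0.0 < self.eaf < 1.0:
            return "EAF outside (0, 1)"
        if self.info is not None and not 0.0 <= self.info <= 1.0:
            return "imputation quality outside [0, 1]"
        return None

    def flipped(self) -> "SummaryStatRecord":
        """The same association expressed on the other allele."""
        return SummaryStatRecord(
            variant_id=self.variant_id,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            se=self.se,
            pval=self.pval,
            n=self.n,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
            info=self.info,
            hwe_p=self.hwe_p,
        )

    def is_palindromic(self) -> bool:
        return _COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass
class HarmonizedInstrument:
    """One SNP with exposure and outcome associations on a common allele."""

    variant_id: str
    gamma: float
    se_gamma: float
    Gamma: float
    se_Gamma: float
    aligned_allele: str
    gamma2: Optional[float] = None
    se_gamma2: Optional[float] = None
    eaf: Optional[float] = None


@dataclass
class InstrumentSet:
    """Analysis-ready instruments plus a provenance log of every drop."""

    exposure_name: str
    unit: str
    instruments: list[HarmonizedInstrument]
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.instruments)

    def __post_init__(self) -> None:
        ids = [i.variant_id for i in self.instruments]
        if len(set(ids)) != len(ids):
            raise ValueError("variant_ids in an InstrumentSet must be unique")

    @property
    def has_second_exposure(self) -> bool:
        return bool(self.instruments) and self.instruments[0].gamma2 is not None

    def arrays(self) -> dict[str, np.ndarray]:
        get = lambda attr: np.array([getattr(i, attr) for i in self.instruments], dtype=float)
        out = {
            "gamma": get("gamma"),
            "se_gamma": get("se_gamma"),
            "Gamma": get("Gamma"),
            "se_Gamma": get("se_Gamma"),
        }
        if self.has_second_exposure:
            out["gamma2"] = get("gamma2")
            out["se_gamma2"] = get("se_gamma2")
        return out

    def subset(self, keep_ids: Iterable[str]) -> "InstrumentSet":
        keep = set(keep_ids)
        return InstrumentSet(
            exposure_name=self.exposure_name,
            unit=self.unit,
            instruments=[i for i in self.instruments if i.variant_id in keep],
            dropped=list(self.dropped),
        )


@dataclass
class ParsedSumstats:
    records: list[SummaryStatRecord]
    rejected: list[tuple[int, str]]  # (1-based line number, reason)


@dataclass
class SelectionResult:
    kept: list[SummaryStatRecord]
    dropped: list[tuple[str, str]]  # (variant_id, failing criterion)


# ---------------------------------------------------------------------------
# file I/O


def _parse_float(value: str, column: str) -> float:
    try:
        return float(value)
    except ValueError as exc:
        raise ValueError(f"unparseable {column} value {value!r}") from exc


def read_summary_stats(path: str | Path) -> ParsedSumstats:
    """Parse a summary-statistics TSV, rejecting invalid rows with reasons.

    A missing mandatory column raises; a malformed row is skipped and logged
    with its line number. Alleles are upper-cased. Records are returned in
    file order.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, header required")
        header = [h.strip() for h in reader.fieldnames]
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: missing mandatory column(s) {missing}")

        records: list[SummaryStatRecord] = []
        rejected: list[tuple[int, str]] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = SummaryStatRecord(
                    variant_id=(row["variant_id"] or "").strip(),
                    effect_allele=(row["effect_allele"] or "").strip().upper(),
                    other_allele=(row["other_allele"] or "").strip().upper(),
                    beta=_parse_float(row["beta"], "beta"),
                    se=_parse_float(row["se"], "se"),
                    pval=_parse_float(row["pval"], "pval"),
                    n=_parse_float(row["n"], "n"),
                )
                for col in OPTIONAL_COLUMNS:
                    raw = (row.get(col) or "").strip()
                    if raw and raw.upper() != "NA":
                        setattr(rec, col, _parse_float(raw, col))
            except (ValueError, TypeError) as exc:
                rejected.append((lineno, str(exc)))
                continue
            if not rec.variant_id:
                rejected.append((lineno, "missing variant_id"))
                continue
            reason = rec.invalid_reason()
            if reason is not None:
                rejected.append((lineno, reason))
            else:
                records.append(rec)
    return ParsedSumstats(records=records, rejected=rejected)


def records_to_frame(records: Sequence[SummaryStatRecord]) -> pd.DataFrame:
    cols = REQUIRED_COLUMNS + OPTIONAL_COLUMNS
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])
    return df.dropna(axis=1, how="all") if len(df) else pd.DataFrame(columns=REQUIRED_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[SummaryStatRecord]:
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            SummaryStatRecord(
                variant_id=str(d["variant_id"]),
                effect_allele=str(d["effect_allele"]).upper(),
                other_allele=str(d["other_allele"]).upper(),
                beta=float(d["beta"]),
                se=float(d["se"]),
                pval=float(d["pval"]),
                n=float(d["n"]),
                eaf=None if "eaf" not in d or pd.isna(d["eaf"]) else float(d["eaf"]),
                info=None if "info" not in d or pd.isna(d["info"]) else float(d["info"]),
                hwe_p=None if "hwe_p" not in d or pd.isna(d["hwe_p"]) else float(d["hwe_p"]),
            )
        )
    return records


def write_summary_stats(data: pd.DataFrame | Sequence[SummaryStatRecord], path: str | Path) -> None:
    """Write records in the TSV dialect with stable float formatting."""
    df = data if isinstance(data, pd.DataFrame) else records_to_frame(list(data))
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


# ---------------------------------------------------------------------------
# instrument selection


def select_instruments(
    records: Sequence[SummaryStatRecord],
    p_threshold: float = 5e-8,
    min_info: float = 0.8,
    min_hwe_p: float = 1e-6,
) -> SelectionResult:
    """Filter candidate instruments on significance, imputation quality, HWE.

    A record is kept when ``pval < p_threshold`` (strict), and — only where
    the optional fields are present — ``info > min_info`` and
    ``hwe_p >= min_hwe_p``. Missing optional columns never exclude a record.
    """
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError("p_threshold must be in (0, 1]")
    kept, dropped = [], []
    for rec in records:
        if not rec.pval < p_threshold:
            dropped.append((rec.variant_id, f"pval >= {p_threshold:g}"))
        elif rec.info is not None and not rec.info > min_info:
            dropped.append((rec.variant_id, f"imputation quality <= {min_info:g}"))
        elif rec.hwe_p is not None and rec.hwe_p < min_hwe_p:
            dropped.append((rec.variant_id, f"HWE p < {min_hwe_p:g}"))
        else:
            kept.append(rec)
    if not kept:
        warnings.warn("all candidate instruments excluded", stacklevel=2)
    return SelectionResult(kept=kept, dropped=dropped)


# ---------------------------------------------------------------------------
# harmonization


def _orientation(
    exp: SummaryStatRecord, other: SummaryStatRecord, window: float
) -> tuple[Optional[int], Optional[str]]:
    """Sign to apply to ``other``'s beta to express it on exp's effect allele.

    Returns (sign, None) or (None, drop reason). Palindromic (A/T, C/G) SNPs
    cannot be resolved by allele letters across strands, so effect-allele
    frequencies must agree on a side of 0.5, outside ``window`` of it.
    """
    e1, o1 = exp.effect_allele, exp.other_allele
    e2, o2 = other.effect_allele, other.other_allele

    if exp.is_palindromic():
        if {e2, o2} != {e1, o1}:
            return None, "allele mismatch"
        if exp.eaf is None or other.eaf is None:
            return None, "palindromic without EAF"
        eaf2 = other.eaf if e2 == e1 else 1.0 - other.eaf
        if abs(exp.eaf - 0.5) <= window or abs(eaf2 - 0.5) <= window:
            return None, "palindromic EAF near 0.5"
        if (exp.eaf - 0.5) * (eaf2 - 0.5) < 0:
            return None, "palindromic EAF inconsistent"
        return (1 if e2 == e1 else -1), None

    if (e2, o2) == (e1, o1):
        return 1, None
    if (e2, o2) == (o1, e1):
        return -1, None
    c2, co2 = _COMPLEMENT[e2], _COMPLEMENT[o2]
    if (c2, co2) == (e1, o1):
        return 1, None
    if (c2, co2) == (o1, e1):
        return -1, None
    return None, "allele mismatch"


def harmonize(
    exposure_records: Sequence[SummaryStatRecord],
    outcome_records: Sequence[SummaryStatRecord],
    second_exposure_records: Optional[Sequence[SummaryStatRecord]] = None,
    palindromic_eaf_window: float = 0.08,
    exposure_name: str = "exposure",
    unit: str = "kg/m^2",
) -> InstrumentSet:
    """Align outcome (and second-exposure) records to the exposure's alleles.

    Intersects on ``variant_id`` in exposure order; sign-flips betas reported
    on the opposite allele (handling strand complements); resolves or drops
    palindromic SNPs by EAF agreement; logs every drop with its reason.
    """
    out_by_id = {r.variant_id: r for r in outcome_records}
    exp2_by_id = (
        {r.variant_id: r for r in second_exposure_records}
        if second_exposure_records is not None
        else None
    )
    instruments: list[HarmonizedInstrument] = []
    dropped: list[tuple[str, str]] = []
    seen: set[str] = set()
    for exp in exposure_records:
        vid = exp.variant_id
        if vid in seen:
            dropped.append((vid, "duplicate variant_id in exposure"))
            continue
        seen.add(vid)
        out = out_by_id.get(vid)
        if out is None:
            dropped.append((vid, "missing in outcome"))
            continue
        sign, reason = _orientation(exp, out, palindromic_eaf_window)
        if sign is None:
            dropped.append((vid, reason))
            continue
        gamma2 = se_gamma2 = None
        if exp2_by_id is not None:
            exp2 = exp2_by_id.get(vid)
            if exp2 is None:
                dropped.append((vid, "missing in second exposure"))
                continue
            sign2, reason2 = _orientation(exp, exp2, palindromic_eaf_window)
            if sign2 is None:
                dropped.append((vid, f"second exposure: {reason2}"))
                continue
            gamma2, se_gamma2 = sign2 * exp2.beta, exp2.se
        instruments.append(
            HarmonizedInstrument(
                variant_id=vid,
                gamma=exp.beta,
                se_gamma=exp.se,
                Gamma=sign * out.beta,
                se_Gamma=out.se,
                aligned_allele=exp.effect_allele,
                gamma2=gamma2,
                se_gamma2=se_gamma2,
                eaf=exp.eaf,
            )
        )
    return InstrumentSet(
        exposure_name=exposure_name, unit=unit, instruments=instruments, dropped=dropped
    )
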