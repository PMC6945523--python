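"""Ground-truth simulation of two-sample GWAS summary statistics.

Generates individual-level genotypes and phenotypes under a known structural
model and reduces them to the per-SNP association tables that the inference
modules consume:

* a cohort of unrelated individuals with ``J`` independent biallelic SNPs
  (dosages in {0, 1, 2}, per-SNP minor-allele frequencies drawn uniformly),
* a continuous exposure ``X = sum_j gamma_j g_j + eps`` with the residual
  scaled so the instruments explain a chosen fraction ``h2`` of var(X),
* a binary outcome with ``logit P(Y=1) = b0 + theta * X + sum_j alpha_j g_j``,
  where ``theta`` is the causal log-odds ratio per exposure unit the
  estimators target and ``alpha_j`` are direct (pleiotropic) SNP effects,
* exposure associations estimated in one cohort and outcome associations in a
  disjoint cohort, mirroring a two-sample design.

The true per-SNP effects are returned alongside the summary files so every
downstream test has ground truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm, t as t_dist

from .sumstats import OPTIONAL_COLUMNS, REQUIRED_COLUMNS, write_summary_stats

__all__ = [
    "SecondExposureConfig",
    "SyntheticConfig",
    "TrueModel",
    "SyntheticDataset",
    "simulate_genotypes",
    "simulate_phenotypes",
    "compute_summary_stats",
    "generate_two_sample_dataset",
]

PLEIOTROPY_MODES = ("none", "balanced", "directional", "planted_outliers")

# non-palindromic (effect, other) pairs only, so simulated datasets harmonize
# without strand ambiguity by default
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
]


@dataclass
class SecondExposureConfig:
    """Second (correlated) exposure for multivariable MR scenarios.

    ``effect_correlation`` is the correlation between the two exposures'
    per-SNP instrument effect vectors (fat mass and fat-free mass indices
    share many loci); ``true_effect`` is its direct causal log-OR per unit.
    """

    h2: float = 0.008
    effect_correlation: float = 0.5
    true_effect: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError("second exposure h2 must be in [0, 1)")
        if not -1.0 <= self.effect_correlation <= 1.0:
            raise ValueError("effect_correlation must be in [-1, 1]")


@dataclass
class SyntheticConfig:
    """Full parameterization of the data-generating process.

    Defaults emulate the primary BMI analysis: ~96 independent instruments
    explaining 1.6% of exposure variance, exposure associations from a
    339,224-strong meta-analysis-sized cohort, outcome log-odds associations
    from a disjoint 367,703-strong cohort, a causal OR of 1.10 per unit, and
    a 10% outcome prevalence.
    """

    n_exposure_cohort: int = 339_224
    n_outcome_cohort: int = 367_703
    n_snps: int = 96
    maf_low: float = 0.05
    maf_high: float = 0.5
    exposure_h2: float = 0.016
    true_effect: float = math.log(1.10)
    outcome_prevalence: float = 0.10
    effect_distribution: str = "normal"
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_frac: float = 1.0
    n_outliers: int = 0
    outlier_effect: float = 0.0
    second_exposure: Optional[SecondExposureConfig] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.second_exposure, dict):
            self.second_exposure = SecondExposureConfig(**self.second_exposure)
        self.validate()

    def validate(self) -> None:
        if self.n_exposure_cohort < 1 or self.n_outcome_cohort < 1:
            raise ValueError("cohort sizes must be positive")
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")
        if not 0.0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
        if not 0.0 <= self.exposure_h2 < 1.0:
            raise ValueError("exposure_h2 must be in [0, 1)")
        if not 0.0 < self.outcome_prevalence < 1.0:
            raise ValueError("outcome_prevalence must be in (0, 1)")
        if self.effect_distribution not in ("normal", "equal"):
            raise ValueError("effect_distribution must be 'normal' or 'equal'")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}")
        if not 0.0 <= self.pleiotropy_frac <= 1.0:
            raise ValueError("pleiotropy_frac must be in [0, 1]")
        if self.n_outliers < 0 or self.n_outliers > self.n_snps:
            raise ValueError("n_outliers must be in [0, n_snps]")
        if self.n_outliers and self.pleiotropy_mode != "planted_outliers":
            raise ValueError("n_outliers > 0 requires pleiotropy_mode='planted_outliers'")
        if self.second_exposure is not None:
            self.second_exposure.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class TrueModel:
    """The structural parameters a simulated dataset was drawn from."""

    gamma: np.ndarray                 # per-SNP exposure effects (units per allele)
    alpha: np.ndarray                 # per-SNP direct outcome effects (log-OR per allele)
    true_effect: float                # causal log-OR per exposure unit
    mafs: np.ndarray
    variant_ids: list[str]
    effect_alleles: list[str]
    other_alleles: list[str]
    gamma2: Optional[np.ndarray] = None
    true_effect2: Optional[float] = None
    outlier_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        if len(self.gamma) != len(self.alpha) or len(self.gamma) != len(self.mafs):
            raise ValueError("model vectors must share length n_snps")

    @property
    def outlier_ids(self) -> list[str]:
        return [self.variant_ids[i] for i in self.outlier_indices]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "effect_allele": self.effect_alleles,
                "other_allele": self.other_alleles,
                "maf": self.mafs,
                "gamma": self.gamma,
                "alpha": self.alpha,
                "is_outlier": np.isin(np.arange(len(self.gamma)), self.outlier_indices),
            }
        )
        if self.gamma2 is not None:
            df["gamma2"] = self.gamma2
        return df


@dataclass
class SyntheticDataset:
    """In-memory result of :func:`generate_two_sample_dataset`."""

    exposure: pd.DataFrame
    outcome: pd.DataFrame
    model: TrueModel
    exposure2: Optional[pd.DataFrame] = None
    paths: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(
    n: int,
    n_snps: int,
    maf_bounds: tuple[float, float],
    seed: int | np.random.SeedSequence = 0,
    mafs: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw an ``n x J`` dosage matrix of independent biallelic SNPs.

    Column ``j`` is Binomial(2, maf_j); ``maf_j`` is drawn uniformly within
    ``maf_bounds`` unless ``mafs`` is supplied. Each column uses its own
    spawned random stream so growing ``n_snps`` leaves earlier columns
    unchanged. Returns ``(dosages, mafs)`` with dosages stored as int8.
    """
    low, high = maf_bounds
    if n < 1 or n_snps < 1:
        raise ValueError("n and n_snps must be positive")
    if not 0.0 < low <= high <= 0.5:
        raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    maf_ss, geno_ss = ss.spawn(2)
    if mafs is None:
        mafs = np.random.default_rng(maf_ss).uniform(low, high, n_snps)
    else:
        mafs = np.asarray(mafs, dtype=float)
        if mafs.shape != (n_snps,):
            raise ValueError("mafs must have length n_snps")
    geno = np.empty((n, n_snps), dtype=np.int8, order="F")
    for j, child in enumerate(geno_ss.spawn(n_snps)):
        rng = np.random.default_rng(child)
        geno[:, j] = rng.binomial(2, mafs[j], n).astype(np.int8)
    return geno, mafs


def _matvec(geno: np.ndarray, v: np.ndarray) -> np.ndarray:
    """geno @ v without materializing a float copy of the dosage matrix."""
    out = np.zeros(geno.shape[0], dtype=float)
    for j in range(geno.shape[1]):
        if v[j] != 0.0:
            out += v[j] * geno[:, j]
    return out


# ---------------------------------------------------------------------------
# structural model and phenotypes


def draw_true_model(config: SyntheticConfig, seed: int | np.random.SeedSequence) -> TrueModel:
    """Draw per-SNP effects consistent with the configured variance budget.

    Exposure effects are scaled so the theoretical instrument variance
    ``sum_j 2 p_j (1-p_j) gamma_j^2`` equals ``exposure_h2`` on a
    unit-variance exposure scale.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    J = config.n_snps
    mafs = rng.uniform(config.maf_low, config.maf_high, J)
    het = 2.0 * mafs * (1.0 - mafs)

    if config.effect_distribution == "equal":
        # every instrument explains h2/J of the exposure variance, so IVW
        # weights are homogeneous (contamination fractions by count and by
        # weight then coincide)
        raw = rng.choice([-1.0, 1.0], J)
        gamma = raw * np.sqrt(config.exposure_h2 / (J * het))
    else:
        raw = rng.normal(size=J)
        if config.exposure_h2 > 0.0:
            gamma = raw * math.sqrt(config.exposure_h2 / float(het @ raw**2))
        else:
            gamma = np.zeros(J)

    alpha = np.zeros(J)
    outlier_idx = np.array([], dtype=int)
    mode = config.pleiotropy_mode
    if mode in ("balanced", "directional"):
        mu = config.pleiotropy_mean if mode == "directional" else 0.0
        if mode == "balanced" and config.pleiotropy_mean != 0.0:
            raise ValueError("balanced pleiotropy requires pleiotropy_mean == 0")
        affected = rng.choice(J, size=int(round(config.pleiotropy_frac * J)), replace=False)
        draws = rng.normal(mu, config.pleiotropy_sd, len(affected))
        if mode == "directional":
            # direct effects act in a common direction on the ratio scale:
            # instruments are conventionally oriented exposure-increasing, so
            # align each alpha_j with the sign of gamma_j
            sign = np.sign(gamma[affected])
            draws = draws * np.where(sign == 0, 1.0, sign)
        alpha[affected] = draws
    elif mode == "planted_outliers":
        outlier_idx = np.sort(rng.choice(J, size=config.n_outliers, replace=False))
        # direct effects sign-aligned with each SNP's exposure effect, so all
        # planted outliers distort the ratio estimates in a common direction
        sign = np.sign(gamma[outlier_idx])
        alpha[outlier_idx] = config.outlier_effect * np.where(sign == 0, 1.0, sign)

    gamma2 = None
    true_effect2 = None
    if config.second_exposure is not None:
        se_cfg = config.second_exposure
        r = se_cfg.effect_correlation
        z = r * raw + math.sqrt(1.0 - r * r) * rng.normal(size=J)
        if se_cfg.h2 > 0.0:
            gamma2 = z * math.sqrt(se_cfg.h2 / float(het @ z**2))
        else:
            gamma2 = np.zeros(J)
        true_effect2 = se_cfg.true_effect

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), J)
    width = len(str(J))
    return TrueModel(
        gamma=gamma,
        alpha=alpha,
        true_effect=config.true_effect,
        mafs=mafs,
        variant_ids=[f"rs{j + 1:0{width}d}" for j in range(J)],
        effect_alleles=[_ALLELE_PAIRS[i][0] for i in pair_idx],
        other_alleles=[_ALLELE_PAIRS[i][1] for i in pair_idx],
        gamma2=gamma2,
        true_effect2=true_effect2,
        outlier_indices=outlier_idx,
    )


def solve_intercept(linear: np.ndarray, prevalence: float, tol: float = 1e-10) -> float:
    """Bisection (Brent) for the logistic intercept hitting a target event rate."""
    def gap(b0: float) -> float:
        return float(np.mean(expit(b0 + linear))) - prevalence

    return float(brentq(gap, -40.0, 40.0, xtol=tol))


def simulate_phenotypes(
    geno: np.ndarray,
    model: TrueModel,
    config: SyntheticConfig,
    seed: int | np.random.SeedSequence,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the exposure(s) and the binary outcome for one cohort.

    Returns ``(X, y)`` where ``X`` has one column per exposure. The logistic
    intercept is solved numerically so the realized marginal event rate
    matches ``outcome_prevalence`` in expectation.
    """
    if geno.shape[1] != len(model.gamma):
        raise ValueError("model vectors must conform to genotype columns")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    n = geno.shape[0]

    resid_var = 1.0 - config.exposure_h2
    x1 = _matvec(geno, model.gamma) + rng.normal(0.0, math.sqrt(resid_var), n)
    X = x1[:, None]
    linear = model.true_effect * x1
    if model.gamma2 is not None:
        resid2 = 1.0 - config.second_exposure.h2
        x2 = _matvec(geno, model.gamma2) + rng.normal(0.0, math.sqrt(resid2), n)
        X = np.column_stack([x1, x2])
        linear = linear + (model.true_effect2 or 0.0) * x2
    if np.any(model.alpha != 0.0):
        linear = linear + _matvec(geno, model.alpha)

    b0 = solve_intercept(linear, config.outcome_prevalence)
    y = (rng.random(n) < expit(b0 + linear)).astype(np.int8)
    return X, y


# ---------------------------------------------------------------------------
# per-SNP association scans


def _genotype_tables(geno: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP genotype counts and per-genotype phenotype sums.

    Dosages in {0,1,2} make the univariable regressions functions of six
    sufficient statistics per SNP, so a single bincount pass per column
    replaces per-SNP model fits.
    """
    J = geno.shape[1]
    counts = np.empty((J, 3))
    ysums = np.empty((J, 3))
    yf = np.asarray(y, dtype=float)
    for j in range(J):
        col = geno[:, j]
        counts[j] = np.bincount(col, minlength=3)[:3]
        ysums[j] = np.bincount(col, weights=yf, minlength=3)[:3]
    return counts, ysums


def _linear_scan(counts: np.ndarray, ysums: np.ndarray, y: np.ndarray) -> dict:
    g = np.array([0.0, 1.0, 2.0])
    n = counts.sum(axis=1)
    sg = counts @ g
    sgg = counts @ g**2
    sy = float(np.sum(y))
    syy = float(np.sum(np.asarray(y, dtype=float) ** 2))
    sgy = ysums @ g
    sxx = sgg - sg**2 / n
    sxy = sgy - sg * sy / n
    syy_c = syy - sy**2 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = np.maximum(syy_c - beta * sxy, 0.0)
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        tstat = beta / se
    pval = 2.0 * t_dist.sf(np.abs(tstat), n - 2)
    return {"beta": beta, "se": se, "pval": pval, "sxx": sxx, "syy_c": syy_c}


def _logistic_scan(counts: np.ndarray, ysums: np.ndarray, max_iter: int = 40) -> dict:
    """Vectorized per-SNP univariable logistic regression via 3x2 tables."""
    g = np.array([0.0, 1.0, 2.0])
    n = counts.sum(axis=1)
    cases = ysums.sum(axis=1)
    p0 = np.clip(cases / n, 1e-12, 1 - 1e-12)
    a = logit(p0)
    b = np.zeros_like(a)
    converged = np.zeros(len(a), dtype=bool)
    for _ in range(max_iter):
        eta = a[:, None] + np.outer(b, g)
        p = expit(eta)
        w = counts * p * (1.0 - p)
        u1 = (ysums - counts * p).sum(axis=1)
        u2 = ((ysums - counts * p) @ g)
        h11 = w.sum(axis=1)
        h12 = w @ g
        h22 = w @ g**2
        det = h11 * h22 - h12**2
        with np.errstate(divide="ignore", invalid="ignore"):
            da = (h22 * u1 - h12 * u2) / det
            db = (h11 * u2 - h12 * u1) / det
        da = np.nan_to_num(da)
        db = np.nan_to_num(db)
        a += da
        b += db
        step = np.maximum(np.abs(da), np.abs(db))
        converged = step < 1e-10
        if converged.all():
            break
    eta = a[:, None] + np.outer(b, g)
    p = expit(eta)
    w = counts * p * (1.0 - p)
    h11 = w.sum(axis=1)
    h12 = w @ g
    h22 = w @ g**2
    det = h11 * h22 - h12**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(h11 / det)
        z = b / se
    pval = 2.0 * norm.sf(np.abs(z))
    bad = ~np.isfinite(se) | (np.abs(b) > 50.0)
    return {"beta": b, "se": se, "pval": pval, "diverged": bad}


def compute_summary_stats(
    geno: np.ndarray,
    phenotype: np.ndarray,
    kind: str,
    variant_ids: Optional[list[str]] = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Univariable per-SNP association scan.

    ``kind`` is ``"continuous"`` (linear regression slope per allele) or
    ``"binary"`` (logistic log-OR per allele, Wald p). Monomorphic or
    non-converging SNPs are excluded; the second return value lists one
    log line per exclusion.
    """
    if kind not in ("continuous", "binary"):
        raise ValueError("kind must be 'continuous' or 'binary'")
    phenotype = np.asarray(phenotype)
    if geno.shape[0] != len(phenotype):
        raise ValueError("phenotype length must equal genotype rows")
    if kind == "binary" and not np.isin(phenotype, (0, 1)).all():
        raise ValueError("binary phenotype must be coded 0/1")

    n, J = geno.shape
    if variant_ids is None:
        variant_ids = [f"snp{j + 1}" for j in range(J)]
    counts, ysums = _genotype_tables(geno, phenotype)
    monomorphic = (counts > 0).sum(axis=1) <= 1

    if kind == "continuous":
        res = _linear_scan(counts, ysums, phenotype)
        # a zero-variance phenotype is degenerate; an exact fit (se = 0 with
        # phenotype variance present) is legitimate and kept
        bad = monomorphic | ~np.isfinite(res["beta"]) | (res["syy_c"] <= 0.0)
        bad |= ~np.isfinite(res["se"])
    else:
        res = _logistic_scan(counts, ysums)
        bad = monomorphic | res["diverged"] | (res["se"] <= 0.0)
        bad |= ~np.isfinite(res["se"])

    eaf = (counts @ np.array([0.0, 1.0, 2.0])) / (2.0 * n)
    df = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "eaf": eaf,
            "beta": res["beta"],
            "se": res["se"],
            "pval": np.clip(res["pval"], np.nextafter(0, 1), 1.0),
            "n": n,
        }
    )
    constant = kind == "continuous" and bool(np.all(res["syy_c"] <= 0.0))

    def _reason(j: int) -> str:
        if monomorphic[j]:
            return "monomorphic"
        if constant:
            return "constant phenotype"
        return "fit failed (degenerate or non-converged)"

    log = [f"{variant_ids[j]}\t{_reason(j)}" for j in np.flatnonzero(bad)]
    return df.loc[~bad].reset_index(drop=True), log


# ---------------------------------------------------------------------------
# two-sample dataset


def _attach_alleles(df: pd.DataFrame, model: TrueModel) -> pd.DataFrame:
    meta = pd.DataFrame(
        {
            "variant_id": model.variant_ids,
            "effect_allele": model.effect_alleles,
            "other_allele": model.other_alleles,
        }
    )
    out = meta.merge(df, on="variant_id", how="inner")
    cols = REQUIRED_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in out.columns]
    return out[cols]


def generate_two_sample_dataset(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> SyntheticDataset:
    """Simulate both cohorts and reduce them to summary-statistics tables.

    Exposure associations (linear regression) come from cohort A; outcome
    log-odds associations (logistic regression) from the disjoint cohort B.
    With a second exposure configured, both exposures are scanned in cohort A
    (they are measured in the same sample, as with fat mass and fat-free mass
    indices). Fully reproducible from ``config.seed``; when ``out_dir`` is
    given the tables, the true model, and a provenance log are written as TSV.
    """
    master = np.random.SeedSequence(config.seed)
    model_ss, geno_a_ss, pheno_a_ss, geno_b_ss, pheno_b_ss = master.spawn(5)

    model = draw_true_model(config, model_ss)

    geno_a, _ = simulate_genotypes(
        config.n_exposure_cohort, config.n_snps, (config.maf_low, config.maf_high),
        geno_a_ss, mafs=model.mafs,
    )
    xa, _ = simulate_phenotypes(geno_a, model, config, pheno_a_ss)
    exposure, log_a = compute_summary_stats(
        geno_a, xa[:, 0], "continuous", model.variant_ids
    )
    exposure = _attach_alleles(exposure, model)
    exposure2 = None
    log_a2: list[str] = []
    if xa.shape[1] > 1:
        exposure2, log_a2 = compute_summary_stats(
            geno_a, xa[:, 1], "continuous", model.variant_ids
        )
        exposure2 = _attach_alleles(exposure2, model)
    del geno_a

    geno_b, _ = simulate_genotypes(
        config.n_outcome_cohort, config.n_snps, (config.maf_low, config.maf_high),
        geno_b_ss, mafs=model.mafs,
    )
    _, yb = simulate_phenotypes(geno_b, model, config, pheno_b_ss)
    outcome, log_b = compute_summary_stats(geno_b, yb, "binary", model.variant_ids)
    outcome = _attach_alleles(outcome, model)
    del geno_b

    dataset = SyntheticDataset(
        exposure=exposure, outcome=outcome, model=model, exposure2=exposure2
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "exposure": out / "exposure.tsv",
            "outcome": out / "outcome.tsv",
            "true_model": out / "true_model.tsv",
            "log": out / "simulate.log",
        }
        write_summary_stats(exposure, paths["exposure"])
        write_summary_stats(outcome, paths["outcome"])
        if exposure2 is not None:
            paths["exposure2"] = out / "exposure2.tsv"
            write_summary_stats(exposure2, paths["exposure2"])
        model.to_frame().to_csv(
            paths["true_model"], sep="\t", index=False, float_format="%.10g"
        )
        with open(paths["log"], "w") as fh:
            fh.write(f"true_effect\t{model.true_effect:.10g}\n")
            if model.true_effect2 is not None:
                fh.write(f"true_effect2\t{model.true_effect2:.10g}\n")
            for line in log_a + log_a2 + log_b:
                fh.write(line + "\n")
        dataset.paths = {k: str(v) for k, v in paths.items()}
    n_dropped = config.n_snps - len(exposure)
    if n_dropped:
        warnings.warn(f"{n_dropped} SNP(s) excluded from the exposure scan", stacklevel=2)
    return dataset
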