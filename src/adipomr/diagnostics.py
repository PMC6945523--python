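"""Instrument-strength and power diagnostics.

Variance explained and the F statistic quantify weak-instrument risk for a
single exposure; the conditional F statistic does the same for each exposure
in a multivariable model given the other; the power calculation is the
normal-approximation method for a binary outcome, driven by the
non-centrality parameter N * R^2 * cf * (1 - cf) * log(OR)^2 with case
fraction cf.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .sumstats import HarmonizedInstrument, InstrumentSet

__all__ = [
    "StrengthReport",
    "variance_explained",
    "variance_explained_raw",
    "f_statistic",
    "conditional_f",
    "mr_power",
]


@dataclass
class StrengthReport:
    r_squared: float
    f_stat: float
    n: float
    k: int
    strong: bool  # F > 10 rule of thumb
    conditional_f: Optional[dict[str, float]] = None


def variance_explained(
    records: Sequence[HarmonizedInstrument] | InstrumentSet | None = None,
    eaf: Optional[np.ndarray] = None,
    beta: Optional[np.ndarray] = None,
    var_exposure: float = 1.0,
) -> float:
    """Exposure variance explained from summary data: sum 2p(1-p)beta^2 / var(X).

    Accepts a harmonized instrument set (using its exposure betas and EAFs)
    or explicit ``eaf``/``beta`` arrays. ``var_exposure`` is 1 for
    standardized betas. Raises when an EAF is missing.
    """
    if records is not None:
        instruments = records.instruments if isinstance(records, InstrumentSet) else records
        if any(i.eaf is None for i in instruments):
            raise ValueError("variance_explained needs an EAF for every instrument")
        eaf = np.array([i.eaf for i in instruments])
        beta = np.array([i.gamma for i in instruments])
    if eaf is None or beta is None:
        raise ValueError("provide either records or eaf and beta arrays")
    eaf = np.asarray(eaf, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any((eaf <= 0) | (eaf >= 1)):
        raise ValueError("EAFs must lie in (0, 1)")
    return float(np.sum(2.0 * eaf * (1.0 - eaf) * beta**2) / var_exposure)


def variance_explained_raw(geno: np.ndarray, exposure: np.ndarray) -> float:
    """Multiple-regression R^2 of the exposure on all instrument dosages."""
    X = np.column_stack([np.ones(len(exposure)), np.asarray(geno, dtype=float)])
    y = np.asarray(exposure, dtype=float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(resid @ resid) / tss


def f_statistic(r_squared: float, n: float, k: int) -> float:
    """Univariable instrument-strength F = (n-k-1)/k * R^2/(1-R^2)."""
    if not 0.0 <= r_squared < 1.0:
        raise ValueError("r_squared must be in [0, 1)")
    if k < 1 or n <= k + 1:
        raise ValueError("require n > k + 1 and k >= 1")
    return (n - k - 1) / k * r_squared / (1.0 - r_squared)


def strength_report(
    r_squared: float, n: float, k: int, conditional: Optional[dict[str, float]] = None
) -> StrengthReport:
    f = f_statistic(r_squared, n, k)
    return StrengthReport(
        r_squared=r_squared, f_stat=f, n=n, k=k, strong=f > 10.0, conditional_f=conditional
    )


def conditional_f(
    instruments: InstrumentSet,
    n: Optional[float] = None,
    exposure_names: tuple[str, str] = ("exposure1", "exposure2"),
) -> dict[str, float]:
    """Conditional instrument strength for each of two exposures.

    For exposure k, the other exposure's instrument effects are regressed out
    of exposure k's (weighted by 1/se_gamma_k^2, no intercept) and the
    weighted residual sum of squares Q_k is scaled by the residual degrees of
    freedom: F_cond = Q_k / (J - K) with K = 2 exposures. Orthogonal effect
    vectors recover (approximately) the univariable mean-F; collinear ones
    drive the statistic to ~0 (returned with a warning, not an error).
    """
    if not instruments.has_second_exposure:
        raise ValueError("conditional_f requires instruments carrying two exposures")
    J = len(instruments)
    if J < 3:
        raise ValueError("conditional_f requires at least 3 instruments")
    arr = instruments.arrays()
    pairs = {
        exposure_names[0]: (arr["gamma"], arr["se_gamma"], arr["gamma2"]),
        exposure_names[1]: (arr["gamma2"], arr["se_gamma2"], arr["gamma"]),
    }
    out: dict[str, float] = {}
    for name, (target, se_target, other) in pairs.items():
        w = 1.0 / se_target**2
        denom = float(np.sum(w * other**2))
        delta = float(np.sum(w * other * target) / denom) if denom > 0 else 0.0
        q = float(np.sum(w * (target - delta * other) ** 2))
        fc = q / (J - 2)
        if fc < 1.0:
            warnings.warn(
                f"conditional F for {name} is {fc:.2f}: instrument effects nearly collinear",
                stacklevel=2,
            )
        out[name] = fc
    return out


def mr_power(
    n_cases: float,
    n_controls: float,
    r_squared: float,
    odds_ratio: float,
    alpha: float = 0.05,
) -> float:
    """Analytic power of the two-sided MR Wald test for a binary outcome.

    Normal approximation: with N = cases + controls, case fraction cf and
    b = log(OR) per unit exposure, the test statistic is ~ N(sqrt(NCP), 1)
    with NCP = N * R^2 * cf * (1-cf) * b^2, giving
    power = Phi(-z + sqrt(NCP)) + Phi(-z - sqrt(NCP)), z = z_{1-alpha/2}.
    Equals alpha at OR = 1 and is symmetric in cases/controls and in
    OR vs 1/OR.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    if not 0.0 < r_squared < 1.0:
        raise ValueError("r_squared must be in (0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    n_total = n_cases + n_controls
    cf = n_cases / n_total
    ncp = n_total * r_squared * cf * (1.0 - cf) * np.log(odds_ratio) ** 2
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    root = np.sqrt(ncp)
    return float(stats.norm.cdf(root - z) + stats.norm.cdf(-root - z))
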