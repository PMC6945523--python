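"""Causal estimators for summary-data Mendelian randomization.

All estimators consume a harmonized :class:`~adipomr.sumstats.InstrumentSet`
whose per-SNP pairs (gamma_j, Gamma_j) are the exposure association and the
outcome log-odds association on a common effect allele. Estimates are causal
log odds ratios per one unit of the exposure (e.g. per 1 kg/m^2), reported
with 95% Wald intervals and exponentiated ORs.

Methods
-------
ratio_estimates
    Per-SNP Wald ratios Gamma_j / gamma_j with first-order delta SEs.
ivw
    Inverse-variance-weighted meta-analysis of the ratios, fixed-effect or
    with multiplicative random effects (SE inflated by sqrt(Q/(J-1)), floored
    at 1), with Cochran's Q heterogeneity.
weighted_median
    Weighted median of the ratios (consistent when >=50% of the weight comes
    from valid instruments); SE by seeded parametric bootstrap.
mr_egger
    Weighted regression with intercept after orienting all SNPs
    exposure-positive; the intercept estimates average directional pleiotropy.
mvmr
    Multivariable MR: joint no-intercept weighted regression on two
    exposures' instrument effects, giving mutually adjusted direct effects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .sumstats import InstrumentSet

__all__ = [
    "RatioEstimate",
    "MREstimate",
    "ratio_estimates",
    "ivw",
    "weighted_median",
    "weighted_median_point",
    "mr_egger",
    "mvmr",
]

Z95 = stats.norm.ppf(0.975)


@dataclass
class RatioEstimate:
    variant_id: str
    ratio: float
    se_ratio: float


@dataclass
class MREstimate:
    """A causal-effect estimate on the log-OR scale with Wald inference."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    n_snps: int
    cochran_q: Optional[float] = None
    q_pval: Optional[float] = None
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_pval: Optional[float] = None
    exposure: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "exposure": self.exposure,
            "n_snps": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "or": self.odds_ratio,
            "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
            "q": self.cochran_q,
            "q_pval": self.q_pval,
            "egger_intercept": self.egger_intercept,
            "intercept_p": self.egger_intercept_pval,
        }


def _make_estimate(
    method: str,
    beta: float,
    se: float,
    n_snps: int,
    pval: Optional[float] = None,
    **extra,
) -> MREstimate:
    if pval is None:
        pval = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else float("nan")
    lo, hi = beta - Z95 * se, beta + Z95 * se
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=lo,
        ci_high=hi,
        pval=pval,
        odds_ratio=math.exp(beta),
        or_ci_low=math.exp(lo),
        or_ci_high=math.exp(hi),
        n_snps=n_snps,
        **extra,
    )


def _arrays(instruments: InstrumentSet) -> dict[str, np.ndarray]:
    arr = instruments.arrays()
    if np.any(arr["gamma"] == 0.0):
        bad = [
            i.variant_id for i in instruments.instruments if i.gamma == 0.0
        ]
        raise ValueError(f"zero exposure association for SNP(s) {bad}: ratio undefined")
    return arr


def ratio_estimates(instruments: InstrumentSet) -> list[RatioEstimate]:
    """Per-SNP Wald ratios, order preserved.

    SE is the first-order delta approximation se(Gamma)/|gamma| (uncertainty
    in the exposure association enters the sampling model only through the
    estimators' resampling procedures).
    """
    arr = _arrays(instruments)
    ratios = arr["Gamma"] / arr["gamma"]
    ses = arr["se_Gamma"] / np.abs(arr["gamma"])
    return [
        RatioEstimate(variant_id=i.variant_id, ratio=float(r), se_ratio=float(s))
        for i, r, s in zip(instruments.instruments, ratios, ses)
    ]


def ivw(instruments: InstrumentSet, effects_model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted combination of the per-SNP ratios.

    ``effects_model='fixed'`` gives SE = (sum w_j)^(-1/2); the default
    multiplicative random-effects model inflates it by sqrt(Q/(J-1)) floored
    at 1. Algebraically identical to weighted no-intercept least squares of
    Gamma on gamma with weights 1/se_Gamma^2. A single instrument collapses
    to its ratio estimate with Q undefined.
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise ValueError("effects_model must be 'fixed' or 'multiplicative_random'")
    if len(instruments) < 1:
        raise ValueError("IVW requires at least one instrument")
    arr = _arrays(instruments)
    r = arr["Gamma"] / arr["gamma"]
    w = (np.abs(arr["gamma"]) / arr["se_Gamma"]) ** 2
    beta = float(w @ r / w.sum())
    se_fixed = float(1.0 / math.sqrt(w.sum()))
    J = len(r)
    if J == 1:
        return _make_estimate("ivw", beta, se_fixed, 1)
    q = float(w @ (r - beta) ** 2)
    q_pval = float(stats.chi2.sf(q, J - 1))
    se = se_fixed
    if effects_model == "multiplicative_random":
        se = se_fixed * max(1.0, math.sqrt(q / (J - 1)))
    return _make_estimate("ivw", beta, se, J, cochran_q=q, q_pval=q_pval)


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Median of the weighted empirical distribution of ratio estimates.

    Inverted-CDF convention: the smallest ratio whose cumulative normalized
    weight reaches 0.5, averaging the two straddling ratios at an exact tie.
    Equal weights with odd J reduce to the simple median; a SNP carrying more
    than half the total weight is returned exactly.
    """
    order = np.argsort(ratios)
    r = np.asarray(ratios, dtype=float)[order]
    cw = np.cumsum(np.asarray(weights, dtype=float)[order])
    cw /= cw[-1]
    idx = int(np.searchsorted(cw, 0.5, side="left"))
    if abs(cw[idx] - 0.5) < 1e-12 and idx + 1 < len(r):
        return float(0.5 * (r[idx] + r[idx + 1]))
    return float(r[idx])


def weighted_median(instruments: InstrumentSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted median estimator with parametric-bootstrap SE.

    IVW weights (inverse squared delta SEs) define the weighted empirical
    distribution; the SE is the standard deviation of the estimate over
    ``n_boot`` parametric resamples of (gamma_j, Gamma_j) from normal
    distributions centred on the observed values. Deterministic given seed.
    """
    if len(instruments) < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable bootstrap SEs", stacklevel=2)
    arr = _arrays(instruments)
    ratios = arr["Gamma"] / arr["gamma"]
    weights = (np.abs(arr["gamma"]) / arr["se_Gamma"]) ** 2
    beta = weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    J = len(ratios)
    g_star = rng.normal(arr["gamma"], arr["se_gamma"], size=(n_boot, J))
    G_star = rng.normal(arr["Gamma"], arr["se_Gamma"], size=(n_boot, J))
    g_star = np.where(g_star == 0.0, np.finfo(float).tiny, g_star)
    r_star = G_star / g_star
    w_star = (np.abs(g_star) / arr["se_Gamma"]) ** 2

    order = np.argsort(r_star, axis=1)
    r_sorted = np.take_along_axis(r_star, order, axis=1)
    cw = np.cumsum(np.take_along_axis(w_star, order, axis=1), axis=1)
    cw /= cw[:, -1][:, None]
    idx = (cw < 0.5).sum(axis=1)
    boot = r_sorted[np.arange(n_boot), idx]
    se = float(boot.std(ddof=1))
    return _make_estimate("weighted_median", beta, se, J)


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least squares: coefficients, unscaled covariance, weighted RSS."""
    Xw = X * np.sqrt(w)[:, None]
    yw = y * np.sqrt(w)
    xtx = Xw.T @ Xw
    coef = np.linalg.solve(xtx, Xw.T @ yw)
    resid = yw - Xw @ coef
    return coef, np.linalg.inv(xtx), float(resid @ resid)


def mr_egger(instruments: InstrumentSet, t_dist: bool = False) -> MREstimate:
    """MR-Egger regression: slope = causal effect, intercept = average
    directional pleiotropy.

    SNPs are first oriented so every exposure association is positive (the
    intercept is not identified otherwise). Weights are 1/se_Gamma^2; both
    coefficients' SEs carry the multiplicative random-effects inflation
    sqrt(RSS_w/(J-2)) floored at 1. P-values use the standard normal by
    default (``t_dist=True`` switches to t with J-2 df).
    """
    J = len(instruments)
    if J < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    arr = _arrays(instruments)
    s = np.sign(arr["gamma"])
    x = s * arr["gamma"]
    y = s * arr["Gamma"]
    if np.std(x) == 0.0 or np.allclose(x, x[0]):
        raise ValueError("no spread in |gamma|: Egger design degenerate")
    w = 1.0 / arr["se_Gamma"] ** 2
    X = np.column_stack([np.ones(J), x])
    coef, cov_unscaled, rss = _wls(X, y, w)
    phi = max(1.0, rss / (J - 2))
    ses = np.sqrt(phi * np.diag(cov_unscaled))

    if t_dist:
        pf = lambda b, se: 2.0 * stats.t.sf(abs(b / se), J - 2)
    else:
        pf = lambda b, se: 2.0 * stats.norm.sf(abs(b / se))
    q_pval = float(stats.chi2.sf(rss, J - 2))
    return _make_estimate(
        "mr_egger",
        float(coef[1]),
        float(ses[1]),
        J,
        pval=float(pf(coef[1], ses[1])),
        cochran_q=rss,
        q_pval=q_pval,
        egger_intercept=float(coef[0]),
        egger_intercept_se=float(ses[0]),
        egger_intercept_pval=float(pf(coef[0], ses[0])),
    )


def mvmr(
    instruments: InstrumentSet,
    exposure_names: tuple[str, str] = ("exposure1", "exposure2"),
    effects_model: str = "multiplicative_random",
) -> dict[str, Optional[MREstimate]]:
    """Multivariable MR direct effects for two exposures.

    Weighted no-intercept regression of Gamma on both exposures' instrument
    effects (weights 1/se_Gamma^2); each coefficient is that exposure's
    effect adjusted for the other. An identically-zero effect column is
    dropped with a warning (its entry is None) and the remaining exposure is
    fit univariably; collinear nonzero columns raise.
    """
    if not instruments.has_second_exposure:
        raise ValueError("mvmr requires instruments carrying two exposures")
    J = len(instruments)
    if J < 3:
        raise ValueError("mvmr requires at least 3 instruments")
    arr = _arrays(instruments)
    cols = {exposure_names[0]: arr["gamma"], exposure_names[1]: arr["gamma2"]}
    w = 1.0 / arr["se_Gamma"] ** 2

    zero = [name for name, v in cols.items() if np.allclose(v, 0.0)]
    active = [name for name in exposure_names if name not in zero]
    if not active:
        raise ValueError("both exposure effect columns are zero")
    if zero:
        warnings.warn(
            f"exposure(s) {zero} have all-zero instrument effects; dropped from the joint model",
            stacklevel=2,
        )
    X = np.column_stack([cols[name] for name in active])
    sv = np.linalg.svd(X * np.sqrt(w)[:, None], compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        raise ValueError("exposure instrument-effect vectors are collinear: design rank-deficient")
    coef, cov_unscaled, rss = _wls(X, arr["Gamma"], w)
    K = X.shape[1]
    phi = rss / (J - K)
    if effects_model == "multiplicative_random":
        phi = max(1.0, phi)
    elif effects_model == "fixed":
        phi = 1.0
    else:
        raise ValueError("effects_model must be 'fixed' or 'multiplicative_random'")
    ses = np.sqrt(phi * np.diag(cov_unscaled))

    q_pval = float(stats.chi2.sf(rss, J - K))
    out: dict[str, Optional[MREstimate]] = {name: None for name in exposure_names}
    for k, name in enumerate(active):
        out[name] = _make_estimate(
            "mvmr",
            float(coef[k]),
            float(ses[k]),
            J,
            cochran_q=rss,
            q_pval=q_pval,
            exposure=name,
        )
    return out
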