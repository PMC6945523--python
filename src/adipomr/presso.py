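"""MR-PRESSO: residual-sum resampling test for pleiotropic outlier SNPs.

Three stages, all driven by one simulated null ensemble:

1. *Global test.* The observed residual sum of squares (RSS) accumulates each
   SNP's weighted squared deviation of its outcome association from the
   leave-one-out fixed-effect IVW prediction. Its null distribution is built
   by resampling Gaussian (gamma*, Gamma*) pairs around the leave-one-out
   fitted model with the observed standard errors and recomputing the RSS.
2. *Outlier test.* Each SNP's observed weighted squared residual is compared
   with its own simulated distribution; the empirical tail probability is
   Bonferroni-scaled by the number of SNPs (capped at 1) and SNPs below the
   exclusion threshold (0.10 by default) are flagged.
3. *Outlier-corrected estimate and distortion test.* The random-effects IVW
   is recomputed without the flagged SNPs; the raw-vs-corrected difference is
   referred to the distribution of differences obtained by removing random
   SNP subsets of the same size.

Empirical p-values use the (1 + exceedances) / (1 + n_sim) convention and are
therefore never exactly zero. With the default Bonferroni scaling, ``n_sim``
must exceed ``J / alpha`` for any SNP to be flaggable (e.g. 960 for 96 SNPs
at the 0.10 rule); the default n_sim=1000 satisfies this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .estimators import MREstimate, ivw
from .sumstats import InstrumentSet

__all__ = ["PressoResult", "presso", "presso_global", "presso_outlier_test",
           "outlier_corrected_estimate"]


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    per_snp_residuals: np.ndarray
    per_snp_outlier_p: np.ndarray        # Bonferroni-scaled unless adjust='raw'
    outliers: list[str]
    raw_estimate: MREstimate
    corrected_estimate: Optional[MREstimate]
    distortion_p: Optional[float]
    n_sim: int
    seed: int
    variant_ids: list[str] = field(default_factory=list)


def _loo_ivw_weighted_residuals(
    gamma: np.ndarray, Gamma: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out fixed-effect IVW slopes and weighted squared residuals.

    The fixed-effect IVW slope is sum(w*gamma*Gamma)/sum(w*gamma^2), so each
    leave-one-out fit follows from subtracting one term from both sums.
    """
    num = w * gamma * Gamma
    den = w * gamma**2
    beta_loo = (num.sum() - num) / (den.sum() - den)
    resid = w * (Gamma - beta_loo * gamma) ** 2
    return beta_loo, resid


def presso_global(
    instruments: InstrumentSet, n_sim: int = 1000, seed: int = 0
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Observed RSS, empirical global p, observed and simulated residuals.

    Returns ``(rss_obs, global_p, obs_resid, sim_resid)`` where ``sim_resid``
    has shape (n_sim, J); the caller reuses it for the outlier test.
    """
    J = len(instruments)
    if J < 4:
        raise ValueError("MR-PRESSO requires at least 4 instruments")
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    arr = instruments.arrays()
    gamma, se_gamma = arr["gamma"], arr["se_gamma"]
    Gamma, se_Gamma = arr["Gamma"], arr["se_Gamma"]
    w = 1.0 / se_Gamma**2

    beta_loo, obs_resid = _loo_ivw_weighted_residuals(gamma, Gamma, w)
    rss_obs = float(obs_resid.sum())

    rng = np.random.default_rng(seed)
    g_star = rng.normal(gamma, se_gamma, size=(n_sim, J))
    G_star = rng.normal(beta_loo * gamma, se_Gamma, size=(n_sim, J))

    num = w * g_star * G_star
    den = w * g_star**2
    beta_loo_star = (num.sum(axis=1, keepdims=True) - num) / (
        den.sum(axis=1, keepdims=True) - den
    )
    sim_resid = w * (G_star - beta_loo_star * g_star) ** 2
    rss_sim = sim_resid.sum(axis=1)
    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    return rss_obs, global_p, obs_resid, sim_resid


def presso_outlier_test(
    obs_resid: np.ndarray,
    sim_resid: np.ndarray,
    alpha: float = 0.10,
    multiple_testing: str = "bonferroni",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP empirical outlier p-values and the boolean flag vector."""
    if multiple_testing not in ("bonferroni", "raw"):
        raise ValueError("multiple_testing must be 'bonferroni' or 'raw'")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    n_sim, J = sim_resid.shape
    pvals = (1 + (sim_resid >= obs_resid[None, :]).sum(axis=0)) / (n_sim + 1)
    if multiple_testing == "bonferroni":
        pvals = np.minimum(1.0, pvals * J)
    flags = pvals < alpha
    return pvals, flags


def outlier_corrected_estimate(
    instruments: InstrumentSet,
    outliers: list[str],
    n_sim: int = 1000,
    seed: int = 0,
    distortion: bool = True,
) -> tuple[MREstimate, Optional[float]]:
    """Random-effects IVW without the flagged SNPs, plus the distortion p.

    The distortion test refers the corrected-minus-raw difference to the
    differences obtained by excluding ``n_sim`` random subsets of the same
    size, two-sided on |difference|. Absent (None) when no SNP was flagged.
    """
    J = len(instruments)
    out_set = set(outliers)
    unknown = out_set - {i.variant_id for i in instruments.instruments}
    if unknown:
        raise ValueError(f"outliers not in instrument set: {sorted(unknown)}")
    if len(out_set) >= J:
        raise ValueError("all instruments flagged as outliers: nothing to estimate")
    retained = instruments.subset(
        [i.variant_id for i in instruments.instruments if i.variant_id not in out_set]
    )
    if len(retained) < 3:
        warnings.warn(
            f"only {len(retained)} instrument(s) retained after outlier removal",
            stacklevel=2,
        )
    corrected = ivw(retained, "multiplicative_random")
    if not out_set or not distortion:
        return corrected, None

    arr = instruments.arrays()
    w = 1.0 / arr["se_Gamma"] ** 2
    num = w * arr["gamma"] * arr["Gamma"]
    den = w * arr["gamma"] ** 2
    beta_raw = num.sum() / den.sum()
    d_obs = corrected.beta - beta_raw

    rng = np.random.default_rng(seed)
    k = len(out_set)
    d_sim = np.empty(n_sim)
    for b in range(n_sim):
        drop = rng.choice(J, size=k, replace=False)
        d_sim[b] = (num.sum() - num[drop].sum()) / (den.sum() - den[drop].sum()) - beta_raw
    distortion_p = float((1 + np.sum(np.abs(d_sim) >= abs(d_obs))) / (n_sim + 1))
    return corrected, distortion_p


def presso(
    instruments: InstrumentSet,
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.10,
    multiple_testing: str = "bonferroni",
    distortion: bool = True,
) -> PressoResult:
    """Run the full MR-PRESSO sequence; deterministic given ``seed``."""
    rss_obs, global_p, obs_resid, sim_resid = presso_global(instruments, n_sim, seed)
    pvals, flags = presso_outlier_test(obs_resid, sim_resid, alpha, multiple_testing)
    ids = [i.variant_id for i in instruments.instruments]
    outliers = [ids[j] for j in np.flatnonzero(flags)]
    raw = ivw(instruments, "multiplicative_random")
    if outliers:
        corrected, distortion_p = outlier_corrected_estimate(
            instruments, outliers, n_sim=n_sim, seed=seed + 1, distortion=distortion
        )
    else:
        corrected, distortion_p = raw, None
    return PressoResult(
        global_rss=rss_obs,
        global_p=global_p,
        per_snp_residuals=obs_resid,
        per_snp_outlier_p=pvals,
        outliers=outliers,
        raw_estimate=raw,
        corrected_estimate=corrected,
        distortion_p=distortion_p,
        n_sim=n_sim,
        seed=seed,
        variant_ids=ids,
    )
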