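"""Causal-effect estimators for two-sample Mendelian randomization.

Given harmonized per-variant effect pairs (gamma_j on the exposure, Gamma_j
on the outcome), the estimators here are:

* per-SNP Wald ratio Gamma_j / gamma_j;
* inverse-variance weighted (IVW): weighted regression of Gamma on gamma
  through the origin with weights 1/se_Gamma^2, in fixed-effect form or
  with multiplicative random-effects inflation gated on Cochran's Q;
* MR-Egger: the same weighted regression with a free intercept, whose
  intercept estimates average directional pleiotropy (t inference, J-2 df);
* weighted median: consistent when less than half the instrument weight
  comes from invalid instruments, with a parametric-bootstrap SE.

Effects are on the log-odds scale for binary outcomes; use
:func:`to_odds_ratio` for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .gwas_io import HarmonizedSet

__all__ = [
    "MREstimate",
    "InsufficientInstrumentsError",
    "DegenerateInstrumentError",
    "wald_ratio",
    "ivw",
    "cochran_q_statistic",
    "egger",
    "weighted_median",
    "to_odds_ratio",
]

Z95 = float(stats.norm.ppf(0.975))


class InsufficientInstrumentsError(ValueError):
    """Too few instruments for the requested estimator."""


class DegenerateInstrumentError(ValueError):
    """A Wald ratio was requested for a null instrument (gamma = 0)."""


@dataclass
class MREstimate:
    """One estimator's causal effect on the log-odds scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.se <= 0 or not np.isfinite(self.se):
            raise ValueError("se must be positive and finite")
        if self.ci_low >= self.ci_high:
            raise ValueError("ci_low must be below ci_high")


def _normal_estimate(method: str, beta: float, se: float, n_snps: int, extras=None) -> MREstimate:
    z = beta / se
    p = 2 * stats.norm.sf(abs(z))
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pvalue=float(p),
        n_snps=n_snps,
        extras=extras or {},
    )


def wald_ratio(
    gamma: float,
    se_gamma: float,
    Gamma: float,
    se_Gamma: float,
    order: str = "first",
) -> MREstimate:
    """Single-instrument causal estimate Gamma/gamma.

    ``order="first"`` propagates only the outcome uncertainty
    (se = se_Gamma/|gamma|); ``order="second"`` adds the exposure
    contribution Gamma^2 se_gamma^2 / gamma^4 under the square root.
    """
    if gamma == 0:
        raise DegenerateInstrumentError("gamma = 0: Wald ratio undefined")
    if se_gamma <= 0 or se_Gamma <= 0:
        raise ValueError("standard errors must be positive")
    beta = Gamma / gamma
    var = (se_Gamma / gamma) ** 2
    if order == "second":
        var += Gamma**2 * se_gamma**2 / gamma**4
    elif order != "first":
        raise ValueError(f"unknown order {order!r}")
    return _normal_estimate(f"wald_{order}", beta, np.sqrt(var), n_snps=1)


def _ivw_core(gamma: np.ndarray, Gamma: np.ndarray, se_Gamma: np.ndarray):
    """Origin-regression IVW slope, fixed-effect SE, and Cochran's Q."""
    w = 1.0 / se_Gamma**2
    swg2 = np.sum(w * gamma**2)
    beta = np.sum(w * gamma * Gamma) / swg2
    se_fixed = swg2**-0.5
    q = float(np.sum(w * (Gamma - beta * gamma) ** 2))
    return float(beta), float(se_fixed), q


def cochran_q_statistic(h: HarmonizedSet, beta: float) -> float:
    """Cochran's Q about a given slope, with IVW weights 1/se_Gamma^2."""
    w = 1.0 / h.se_Gamma**2
    return float(np.sum(w * (h.Gamma - beta * h.gamma) ** 2))


def ivw(h: HarmonizedSet, model: str = "auto") -> MREstimate:
    """Inverse-variance weighted estimate.

    ``model="fixed"`` uses the origin-regression SE; ``"random"`` applies
    multiplicative over-dispersion, inflating the SE by
    max(1, sqrt(Q/(J-1))); ``"auto"`` (the default analysis rule) picks the
    random-effects form when the Cochran-Q p-value is below .05. A
    single-instrument set falls back to the first-order Wald ratio with a
    warning flag in ``extras``.
    """
    if model not in ("fixed", "random", "auto"):
        raise ValueError(f"unknown model {model!r}")
    j = h.n_snps
    if j < 2:
        warnings.warn("IVW with a single instrument reduces to the Wald ratio")
        est = wald_ratio(h.gamma[0], h.se_gamma[0], h.Gamma[0], h.se_Gamma[0], "first")
        est.method = "ivw_fixed"
        est.extras["single_snp_fallback"] = True
        return est

    beta, se_fixed, q = _ivw_core(h.gamma, h.Gamma, h.se_Gamma)
    q_p = float(stats.chi2.sf(q, j - 1))
    inflation = max(1.0, np.sqrt(q / (j - 1)))
    if model == "auto":
        model = "random" if q_p < 0.05 else "fixed"
    se = se_fixed * inflation if model == "random" else se_fixed
    extras = {"cochran_q": q, "cochran_q_p": q_p, "se_inflation": inflation}
    return _normal_estimate(f"ivw_{model}", beta, se, n_snps=j, extras=extras)


def egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: weighted fit of Gamma on gamma with a free intercept.

    Requires the orientation convention gamma_j >= 0 (the intercept is not
    identified otherwise). The intercept, its SE, and its two-sided p-value
    (t, J-2 df) are returned in ``extras`` as the directional-pleiotropy test.
    """
    j = h.n_snps
    if j < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 instruments")
    if np.any(h.gamma < 0):
        raise ValueError("MR-Egger requires gamma >= 0 (orient the set first)")

    w = 1.0 / h.se_Gamma**2
    x, y = h.gamma, h.Gamma
    sw = np.sum(w)
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    if sxx <= 0:
        raise ValueError("degenerate design: all gamma equal")
    slope = np.sum(w * (x - xbar) * (y - ybar)) / sxx
    intercept = ybar - slope * xbar

    resid = y - intercept - slope * x
    # freely estimated WLS dispersion with J-2 residual df: paired with t
    # quantiles this keeps the intercept test exactly calibrated under the null
    sigma2 = float(np.sum(w * resid**2) / (j - 2))
    se_slope = np.sqrt(sigma2 / sxx)
    se_int = np.sqrt(sigma2 * (1 / sw + xbar**2 / sxx))
    # exact fits: keep SEs positive and CI bounds distinct in floating point
    floor = 1e-12 * (1.0 + abs(slope) + abs(intercept))
    se_slope = max(se_slope, floor)
    se_int = max(se_int, floor)

    tq = float(stats.t.ppf(0.975, j - 2))
    p_slope = 2 * stats.t.sf(abs(slope / se_slope), j - 2)
    p_int = 2 * stats.t.sf(abs(intercept / se_int), j - 2)
    return MREstimate(
        method="egger",
        beta=float(slope),
        se=float(se_slope),
        ci_low=float(slope - tq * se_slope),
        ci_high=float(slope + tq * se_slope),
        pvalue=float(p_slope),
        n_snps=j,
        extras={
            "egger_intercept": float(intercept),
            "egger_intercept_se": float(se_int),
            "egger_intercept_p": float(p_int),
        },
    )


def weighted_median(h: HarmonizedSet, n_boot: int = 5000, seed: int | None = None) -> MREstimate:
    """Weighted median of per-SNP Wald ratios.

    Ratios are sorted ascending with normalized weights
    w_j = gamma_j^2 / se_Gamma_j^2; the estimate interpolates linearly
    between the two ratios whose half-step cumulative weights bracket 0.5.
    The SE comes from a seeded parametric bootstrap that resamples
    (gamma_j, Gamma_j) from their normal sampling distributions.
    """
    j = h.n_snps
    if j < 3:
        raise InsufficientInstrumentsError("weighted median needs at least 3 instruments")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives an unstable bootstrap SE")
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")

    beta = _weighted_median_point(h.gamma, h.Gamma, h.se_Gamma)

    rng = np.random.default_rng(seed)
    g = rng.normal(h.gamma, h.se_gamma, size=(n_boot, j))
    G = rng.normal(h.Gamma, h.se_Gamma, size=(n_boot, j))
    boot = np.array([_weighted_median_point(g[b], G[b], h.se_Gamma) for b in range(n_boot)])
    se = float(np.std(boot, ddof=1))
    est = _normal_estimate("weighted_median", beta, se, n_snps=j)
    est.extras["n_boot"] = n_boot
    est.extras["seed"] = seed
    return est


def _weighted_median_point(gamma: np.ndarray, Gamma: np.ndarray, se_Gamma: np.ndarray) -> float:
    ratios = Gamma / gamma
    weights = gamma**2 / se_Gamma**2
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    w = w / w.sum()
    s = np.cumsum(w) - w / 2
    if s[0] >= 0.5:
        return float(r[0])
    if s[-1] <= 0.5:
        return float(r[-1])
    k = int(np.searchsorted(s, 0.5))
    # linear interpolation between the bracketing ratios
    return float(r[k - 1] + (r[k] - r[k - 1]) * (0.5 - s[k - 1]) / (s[k] - s[k - 1]))


def to_odds_ratio(e: MREstimate) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate and its CI to an odds-ratio triple."""
    return float(np.exp(e.beta)), float(np.exp(e.ci_low)), float(np.exp(e.ci_high))
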