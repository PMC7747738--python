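"""Inference on the quantile slope function.

Three tools: orthogonal-polynomial trend tests asking whether the slope
function beta_FS(tau) is constant or changes as a linear, quadratic or cubic
function of the percentile; pairwise contrasts between two grid percentiles
with covariance-correct standard errors and fold ratios; and the Falconer
conversion of a full-sib slope into a heritability bound (h^2 = 2 beta_FS,
valid when dominance, common environment and assortative mating are
negligible — in general beta_FS estimates (0.5 V_A + 0.25 V_D + V_Ec)/V_P).

All t references use the double-entry adjusted degrees of freedom
sum(k_i - 1) carried on the slope function, not a normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .qreg_engine import QuantileSlopeFunction

_DEGREES = {"linear": 1, "quadratic": 2, "cubic": 3}

#: documentation of the estimand behind the Falconer conversion
FALCONER_ESTIMAND = "beta_FS = (0.5*V_A + 0.25*V_D + V_Ec) / V_P"
FALCONER_ASSUMPTIONS = ("dominance, common environment, and assortative "
                        "mating effects assumed negligible")


@dataclass
class TrendTestResult:
    """Wald test of one polynomial component of the slope-vs-percentile curve.

    ``estimate`` is the unit-norm Gram-contrast projection c'beta (slope
    units); for the linear degree the same trend is also re-expressed as
    ``rate_per_percentile``, the least-squares line through the (tau, beta)
    points, with its own SE on the identical t statistic.
    """

    degree: str
    estimate: float
    se: float
    t: float
    p: float
    df: int
    rate_per_percentile: float | None = None
    rate_se: float | None = None


@dataclass
class SlopeContrast:
    """Difference and fold ratio between the slopes at two grid percentiles."""

    tau_hi: float
    tau_lo: float
    estimate: float
    se: float
    t: float
    p: float
    df: int
    fold_ratio: float
    fold_interval: tuple[float, float] | None = None


@dataclass
class FalconerResult:
    beta_fs: float
    se_beta: float
    h2: float
    se_h2: float
    assumptions: str = FALCONER_ASSUMPTIONS
    estimand: str = FALCONER_ESTIMAND


def gram_contrasts(taus: np.ndarray, max_degree: int = 3) -> np.ndarray:
    """Unit-norm discrete orthogonal (Gram) polynomial contrasts on a grid.

    Returns an array of shape (max_degree, len(taus)); row d-1 is the
    degree-d contrast, orthogonal to the constant vector and to every lower
    degree, normalised to unit length with the last element positive.  On an
    equally spaced grid these are proportional to the classical polynomial
    contrast tables.  Built by QR (Gram-Schmidt) on a centered/scaled
    Vandermonde basis for numerical stability at 91 points.
    """
    taus = np.asarray(taus, dtype=float)
    d = np.diff(taus)
    if len(taus) < max_degree + 1:
        raise ValueError("grid too short for the requested degree")
    if not np.allclose(d, d[0], rtol=1e-9):
        raise ValueError("orthogonal-polynomial contrasts require an equally spaced grid")
    t = (taus - taus.mean()) / (taus.max() - taus.min())
    V = np.vander(t, N=max_degree + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    C = Q[:, 1:].T  # drop the constant column
    for row in C:
        if row[-1] < 0:
            row *= -1
    return C


def orthogonal_trend_test(qsf: QuantileSlopeFunction, degree: str = "linear"
                          ) -> TrendTestResult:
    """Test one polynomial component of the slope function.

    The contrast vector c is the unit-norm Gram polynomial of the requested
    degree on the grid; the estimate is c'beta, its SE is sqrt(c' VCV c) from
    the bootstrap, and the t statistic is referred to a t distribution on the
    double-entry effective df.
    """
    if degree not in _DEGREES:
        raise ValueError(f"degree must be one of {sorted(_DEGREES)}, got {degree!r}")
    if qsf.vcv is None:
        raise ValueError("trend test needs a bootstrap variance-covariance matrix")
    taus = qsf.grid.taus
    c = gram_contrasts(taus, max_degree=_DEGREES[degree])[_DEGREES[degree] - 1]
    est = float(c @ qsf.slopes)
    var = float(c @ qsf.vcv @ c)
    if var < 0:
        var = 0.0
    se = float(np.sqrt(var))
    df = qsf.effective_df
    t = est / se if se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(t), df))
    rate = rate_se = None
    if degree == "linear":
        # same trend re-expressed as the LS line through (tau, beta):
        # the centered-tau contrast is proportional to c, so the t and p match
        ct = taus - taus.mean()
        stt = float(ct @ ct)
        rate = float(ct @ qsf.slopes / stt)
        rate_se = float(np.sqrt(max(ct @ qsf.vcv @ ct, 0.0)) / stt)
    return TrendTestResult(degree=degree, estimate=est, se=se, t=float(t), p=p,
                           df=df, rate_per_percentile=rate, rate_se=rate_se)


def slope_contrast(qsf: QuantileSlopeFunction, tau_hi: float, tau_lo: float
                   ) -> SlopeContrast:
    """beta(tau_hi) - beta(tau_lo) with covariance-correct SE, plus fold ratio.

    The fold ratio beta(tau_hi)/beta(tau_lo) is NaN when the denominator is
    zero.  When bootstrap replicates are available a 95% percentile interval
    of the replicate ratios is attached (the delta method is unreliable near
    small denominators).
    """
    if qsf.vcv is None:
        raise ValueError("slope contrast needs a bootstrap variance-covariance matrix")
    hi = qsf.grid.index_of(tau_hi)
    lo = qsf.grid.index_of(tau_lo)
    est = float(qsf.slopes[hi] - qsf.slopes[lo])
    var = float(qsf.vcv[hi, hi] + qsf.vcv[lo, lo] - 2 * qsf.vcv[hi, lo])
    se = float(np.sqrt(max(var, 0.0)))
    df = qsf.effective_df
    t = est / se if se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(t), df))
    b_lo = qsf.slopes[lo]
    fold = float(qsf.slopes[hi] / b_lo) if b_lo != 0 else float("nan")
    interval = None
    if qsf.replicates is not None:
        denom = qsf.replicates[:, lo]
        ok = denom != 0
        if ok.sum() >= 50:
            ratios = qsf.replicates[ok, hi] / denom[ok]
            interval = tuple(np.percentile(ratios, [2.5, 97.5]))
    return SlopeContrast(tau_hi=tau_hi, tau_lo=tau_lo, estimate=est, se=se,
                         t=float(t), p=p, df=df, fold_ratio=fold,
                         fold_interval=interval)


def falconer_h2(beta_fs: float, se: float = float("nan")) -> FalconerResult:
    """Convert a full-sib regression slope to a heritability estimate.

    h^2 = 2 * beta_FS with SE doubled accordingly.  The result carries an
    explicit statement of the negligibility assumptions and of the estimand
    the slope actually measures.
    """
    if not np.isfinite(beta_fs):
        raise ValueError("beta_FS must be finite")
    return FalconerResult(beta_fs=float(beta_fs), se_beta=float(se),
                          h2=2.0 * float(beta_fs), se_h2=2.0 * float(se))
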