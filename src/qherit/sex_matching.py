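"""Comparing female and male slope functions at equal concentrations.

Comparing the sexes' slope functions at the same percentile of their separate
distributions compares them at different concentrations, because the female
phenotype distribution sits to the right of the male one.  The
probability-probability (P-P) construction fixes this: for each percentile p
of the pooled (combined-sex) distribution, find the concentration
c = Q_combined(p) and the percentiles p_female = F_female(c) and
p_male = F_male(c) at which each sex reaches that same concentration; then
evaluate each sex's slope function at its own mapped percentile.  Matched
curves are comparable concentration by concentration.

ECDF convention: midpoint plotting positions (i - 0.5)/n with linear
interpolation between order statistics, used consistently for both the
quantile function and its inverse, so Q(F(v)) ~ v within the data range.
Slope functions are interpolated linearly in tau and never extrapolated
outside the fitted grid (the tails are unstable); unmatched points are
flagged undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .qreg_engine import QuantileGrid, QuantileSlopeFunction


@dataclass
class EmpiricalDistribution:
    """Sorted sample with midpoint-plotting-position CDF and quantile."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        v = v[~np.isnan(v)]
        if v.size == 0:
            raise ValueError("empirical distribution needs at least one value")
        self.values = np.sort(v)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def _positions(self) -> np.ndarray:
        return (np.arange(1, self.n + 1) - 0.5) / self.n

    def quantile(self, p) -> np.ndarray:
        """Value at probability p in [0, 1] (clamped to the data range)."""
        return np.interp(np.asarray(p, dtype=float), self._positions, self.values)

    def cdf(self, v) -> np.ndarray:
        """Probability at value v (clamped to [0.5/n, 1 - 0.5/n])."""
        return np.interp(np.asarray(v, dtype=float), self.values, self._positions)


@dataclass
class PPMap:
    """Percentile correspondence between each sex and the pooled distribution.

    At each pooled percentile ``p`` (percent): ``concentration`` is the pooled
    quantile, and ``p_female``/``p_male`` are the percentiles of the sex
    distributions reaching that concentration.
    """

    p: np.ndarray
    concentration: np.ndarray
    p_female: np.ndarray
    p_male: np.ndarray


@dataclass
class MatchedSlopeCurves:
    """Sex slope functions evaluated at equal concentrations.

    ``beta_female``/``beta_male`` are interpolated at the mapped percentiles;
    NaN with ``defined=False`` where a mapped percentile falls outside the
    fitted grid.  ``se_female``/``se_male`` are interpolated bootstrap SEs
    when the slope functions carry a VCV.
    """

    p: np.ndarray
    beta_female: np.ndarray
    beta_male: np.ndarray
    defined: np.ndarray
    se_female: np.ndarray | None = None
    se_male: np.ndarray | None = None


def pp_map(dist_female: EmpiricalDistribution, dist_male: EmpiricalDistribution,
           dist_combined: EmpiricalDistribution,
           grid: QuantileGrid | None = None) -> PPMap:
    """Build the P-P percentile map at every grid percentile of the pooled sample.

    ``dist_combined`` should be the pooled individual values of both sexes,
    not an average of sex-specific quantiles.
    """
    grid = grid or QuantileGrid.default()
    p = grid.taus
    conc = dist_combined.quantile(p / 100.0)
    return PPMap(
        p=p,
        concentration=conc,
        p_female=100.0 * dist_female.cdf(conc),
        p_male=100.0 * dist_male.cdf(conc),
    )


def match_slopes(ppmap: PPMap, qsf_female: QuantileSlopeFunction,
                 qsf_male: QuantileSlopeFunction) -> MatchedSlopeCurves:
    """Evaluate each sex's slope function at its concentration-matched percentile."""
    bf = qsf_female.slope_at(ppmap.p_female)
    bm = qsf_male.slope_at(ppmap.p_male)
    defined = ~np.isnan(bf) & ~np.isnan(bm)
    sef = sem = None
    if qsf_female.vcv is not None and qsf_male.vcv is not None:
        sef = qsf_female.se_at(ppmap.p_female)
        sem = qsf_male.se_at(ppmap.p_male)
    return MatchedSlopeCurves(p=ppmap.p, beta_female=bf, beta_male=bm,
                              defined=defined, se_female=sef, se_male=sem)
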