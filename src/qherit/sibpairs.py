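"""Double-entered full-sib pairs and the traditional least-squares slope.

Within each family every ordered pair of distinct sibs (i, j) contributes one
row, with sib i as the dependent observation and sib j as the independent
one ("double entry": each unordered pair appears in both orientations).
Because double entry inflates the row count, inference uses the adjusted
degrees of freedom sum(k_i - 1) over families, where k_i is the number of
sibs in family i usable in the analysis, never n_pairs - 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import Cohort, PhenotypeVector


@dataclass
class SibPairSet:
    """Materialized double-entered sib pairs for one analysis."""

    family_id: np.ndarray
    dep_id: np.ndarray
    dep_value: np.ndarray
    indep_id: np.ndarray
    indep_value: np.ndarray
    dep_sex_filter: str
    effective_df: int

    @property
    def n_pairs(self) -> int:
        return len(self.dep_value)


@dataclass
class OLSBetaFS:
    """Traditional least-squares full-sib regression slope with double-entry df."""

    slope: float
    intercept: float
    se: float
    t: float
    p: float
    df: int
    n_pairs: int


def build_pairs(
    cohort: Cohort,
    dep_values: PhenotypeVector,
    indep_values: PhenotypeVector,
    dep_sex_filter: str = "all",
    co_sib_mean: bool = False,
) -> SibPairSet:
    """Construct all double-entered within-family pairs.

    Parameters
    ----------
    dep_values, indep_values
        Cohort-aligned phenotype vectors for the dependent and independent
        roles (identical for a plain analysis; they differ when the dependent
        sib is left unadjusted).  A sib with a missing value in either role is
        excluded from this analysis.
    dep_sex_filter
        ``"all"``, or ``"F"``/``"M"`` to keep only pairs whose dependent sib
        has that sex; the independent sib may be of either sex.
    co_sib_mean
        If True, each dependent sib is paired once against the mean of all
        co-sib independent values instead of each co-sib separately.

    The effective degrees of freedom are sum over contributing families of
    (usable sibs - 1); singleton families contribute no pairs and no df.
    """
    if dep_sex_filter not in ("all", "F", "M"):
        raise ValueError(f"dep_sex_filter must be all/F/M, got {dep_sex_filter!r}")
    if len(dep_values) != cohort.n or len(indep_values) != cohort.n:
        raise ValueError("value vectors must be aligned to the cohort")

    fam = cohort.data["family_id"].to_numpy()
    pid = cohort.data["person_id"].to_numpy()
    sex = cohort.data["sex"].to_numpy()
    dep = dep_values.values
    ind = indep_values.values
    usable = ~np.isnan(dep) & ~np.isnan(ind)

    fam_ids, dep_ids, dep_vals, ind_ids, ind_vals = [], [], [], [], []
    effective_df = 0
    order = np.argsort(fam[usable], kind="stable")
    idx_usable = np.flatnonzero(usable)[order]
    for f in np.unique(fam[usable]):
        members = idx_usable[fam[idx_usable] == f]
        k = len(members)
        if k < 2:
            continue
        contributed = False
        for i in members:
            if dep_sex_filter != "all" and sex[i] != dep_sex_filter:
                continue
            cosibs = members[members != i]
            if co_sib_mean:
                fam_ids.append(f)
                dep_ids.append(pid[i])
                dep_vals.append(dep[i])
                ind_ids.append("+".join(map(str, pid[cosibs])))
                ind_vals.append(float(np.mean(ind[cosibs])))
                contributed = True
            else:
                for j in cosibs:
                    fam_ids.append(f)
                    dep_ids.append(pid[i])
                    dep_vals.append(dep[i])
                    ind_ids.append(pid[j])
                    ind_vals.append(ind[j])
                    contributed = True
        if contributed:
            effective_df += k - 1
    if not fam_ids:
        raise ValueError("no eligible families: need >= 1 family with >= 2 usable sibs"
                         f" (dep_sex_filter={dep_sex_filter!r})")
    return SibPairSet(
        family_id=np.asarray(fam_ids),
        dep_id=np.asarray(dep_ids),
        dep_value=np.asarray(dep_vals, dtype=float),
        indep_id=np.asarray(ind_ids),
        indep_value=np.asarray(ind_vals, dtype=float),
        dep_sex_filter=dep_sex_filter,
        effective_df=int(effective_df),
    )


def ols_beta_fs(pairs: SibPairSet) -> OLSBetaFS:
    """Least-squares slope of dependent on independent sib values.

    The standard error and two-sided p-value are computed on the double-entry
    adjusted degrees of freedom ``pairs.effective_df``.
    """
    if pairs.n_pairs < 3:
        raise ValueError("need at least 3 pairs")
    x = pairs.indep_value
    y = pairs.dep_value
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx <= 0:
        raise ValueError("independent sib values have zero variance")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    rss = float(np.sum((y - intercept - slope * x) ** 2))
    df = pairs.effective_df
    if df <= 0:
        raise ValueError("effective degrees of freedom must be positive")
    se = float(np.sqrt(rss / df / sxx))
    t = slope / se if se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(t), df))
    return OLSBetaFS(slope=slope, intercept=intercept, se=se, t=float(t), p=p,
                     df=df, n_pairs=pairs.n_pairs)
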